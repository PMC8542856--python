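"""Ground-truth simulators for every stage of the pipeline.

`generate_panel` emulates the statistical structure of the published
reference panel: species clusters of full-length marker genes (2,448-2,466
bp) that all carry the PCR primer sites at the anchoring gene positions
(product 348-1,426), controlled intra-/inter-species divergence under an
equal-rate substitution model, and a pairwise dDDH matrix produced by
pushing realized gene identities through a planted monotone
identity->dDDH curve plus Gaussian noise.

`generate_calibration_cloud` emulates the calibration scatter directly:
(identity, dDDH) points from a planted exp3p curve with additive noise.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .amplicon import DEFAULT_PRIMERS, PrimerPair, WindowSpec, DEFAULT_WINDOW
from .genomes import GenomeRecord
from .genomospecies import DEFAULT_DDH_CURVE, DdhCurve, DdhMatrix, SpeciesPartition
from .amplicon import MarkerSequence
from .sequences import random_sequence, reverse_complement

GENE_LENGTH_RANGE = (2448, 2466)
FORWARD_ANCHOR = 348   # 1-based gene position of the forward primer 5' end
REVERSE_ANCHOR = 1426  # 1-based gene position of the product 3' end

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a simulated reference panel.

    Rates are per-site substitution probabilities: species ancestors
    diverge from a common root at `inter_sub_rate`, strains from their
    species ancestor at `intra_sub_rate` (so expected pairwise divergence
    is roughly twice the rate). Defaults give intra-species window
    identities near 99.4% and inter-species near 90%, bracketing the
    98.6% threshold the way the real panel does.
    """

    n_species: int = 8
    strains_per_species: Union[int, Sequence[int]] = 4
    gene_length: Optional[int] = None  # drawn from GENE_LENGTH_RANGE when None
    intra_sub_rate: float = 0.003
    inter_sub_rate: float = 0.05
    indel_rate: float = 0.0
    ddh_curve: DdhCurve = DEFAULT_DDH_CURVE
    ddh_noise_sd: float = 1.0
    primers: PrimerPair = DEFAULT_PRIMERS
    degrade_primers: bool = False  # mutate primer sites too (failure-path testing)
    flank_length: int = 400        # random genomic flank per side when embedding
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.intra_sub_rate < 0.5 or not 0 <= self.inter_sub_rate < 0.5:
            raise ValueError("substitution rates must lie in [0, 0.5)")
        if self.inter_sub_rate <= self.intra_sub_rate:
            raise ValueError("inter_sub_rate must exceed intra_sub_rate")
        if not 0 <= self.indel_rate < 0.5:
            raise ValueError("indel_rate must lie in [0, 0.5)")
        if self.n_species < 1:
            raise ValueError("need at least one species")

    def counts(self) -> List[int]:
        if isinstance(self.strains_per_species, int):
            return [self.strains_per_species] * self.n_species
        counts = list(self.strains_per_species)
        if len(counts) != self.n_species:
            raise ValueError("strains_per_species list length != n_species")
        return counts


@dataclass
class SyntheticPanel:
    spec: PanelSpec
    genes: List[MarkerSequence]          # region="complete_gene"
    partition: SpeciesPartition          # planted truth
    ddh: DdhMatrix                       # planted truth (source="simulated")
    gene_identity: np.ndarray            # realized pairwise gene identities

    @property
    def strain_ids(self) -> List[str]:
        return [g.strain_id for g in self.genes]

    def genomes(self) -> List[GenomeRecord]:
        """Embed each gene in a random-flank contig (deterministic per seed)."""
        rng = np.random.default_rng(self.spec.seed + 777)
        records = []
        for g in self.genes:
            left = random_sequence(rng, self.spec.flank_length)
            right = random_sequence(rng, self.spec.flank_length)
            contig = left + g.sequence + right
            if rng.random() < 0.5:  # half the assemblies carry the gene on '-'
                contig = reverse_complement(contig)
            records.append(GenomeRecord(g.strain_id, [contig],
                                        completeness=99.0, contamination=1.0))
        return records


def _mutate(rng, seq: np.ndarray, rate: float, protected: np.ndarray) -> np.ndarray:
    """Equal-rate substitution at `rate` per site outside `protected`."""
    out = seq.copy()
    hits = np.flatnonzero((rng.random(len(seq)) < rate) & ~protected)
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_panel(spec: PanelSpec) -> SyntheticPanel:
    """Simulate a marker-gene panel with planted species structure.

    Primer annealing sites are written into the root at the anchoring
    positions and (unless `degrade_primers`) masked from mutation, so
    in-silico PCR yields exactly one 1,079-bp product per gene.
    """
    rng = np.random.default_rng(spec.seed)
    length = spec.gene_length or int(rng.integers(GENE_LENGTH_RANGE[0],
                                                  GENE_LENGTH_RANGE[1] + 1))
    if length < REVERSE_ANCHOR:
        raise ValueError(f"gene_length must be >= {REVERSE_ANCHOR}")
    root = np.array(list(random_sequence(rng, length)))
    fwd = spec.primers.forward
    rev_site = reverse_complement(spec.primers.reverse)
    f0 = FORWARD_ANCHOR - 1
    r0 = REVERSE_ANCHOR - len(rev_site)
    root[f0:f0 + len(fwd)] = list(fwd)
    root[r0:r0 + len(rev_site)] = list(rev_site)
    protected = np.zeros(length, dtype=bool)
    if not spec.degrade_primers:
        protected[f0:f0 + len(fwd)] = True
        protected[r0:r0 + len(rev_site)] = True

    genes: List[MarkerSequence] = []
    assignment: Dict[str, str] = {}
    for s, count in enumerate(spec.counts(), start=1):
        ancestor = _mutate(rng, root, spec.inter_sub_rate, protected)
        label = f"SP{s:02d}"
        for k in range(1, count + 1):
            strain = f"S{s:02d}_{k:02d}"
            seq = _mutate(rng, ancestor, spec.intra_sub_rate, protected)
            genes.append(MarkerSequence(strain, "complete_gene", "".join(seq)))
            assignment[strain] = label
    partition = SpeciesPartition(assignment, threshold=70.0)

    n = len(genes)
    arr = np.frombuffer("".join(g.sequence for g in genes).encode(),
                        dtype="S1").reshape(n, length)
    ident = np.full((n, n), 100.0)
    for i in range(n - 1):
        diff = (arr[i] != arr[i + 1:]).mean(axis=1)
        ident[i, i + 1:] = ident[i + 1:, i] = 100.0 * (1.0 - diff)
    ddh_values = np.asarray(spec.ddh_curve(ident), dtype=float)
    if spec.ddh_noise_sd > 0:
        noise = rng.normal(0.0, spec.ddh_noise_sd, size=(n, n))
        noise = np.triu(noise, 1)
        ddh_values = ddh_values + noise + noise.T
    ddh_values = np.clip(ddh_values, 0.0, 100.0)
    np.fill_diagonal(ddh_values, 100.0)
    ddh = DdhMatrix([g.strain_id for g in genes], ddh_values, source="simulated")
    return SyntheticPanel(spec, genes, partition, ddh, ident)


def generate_calibration_cloud(a: float, b: float, c: float,
                               x_range: Tuple[float, float] = (85.0, 100.0),
                               n: int = 200, noise_sd: float = 1.0,
                               seed: int = 0) -> List[Tuple[float, float]]:
    """(identity, dDDH) points from y = a*exp(b*x) + c with Gaussian noise."""
    if n < 4:
        raise ValueError("need at least 4 points")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], size=n)
    y = a * np.exp(b * x) + c + rng.normal(0.0, noise_sd, size=n)
    return list(zip(x.tolist(), y.tolist()))
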