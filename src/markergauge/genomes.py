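"""Genome records, the quality gate, and assembly composition statistics.

The reference panel used throughout the package is a 91-genome table
(90 in-group Myxococcus/Corallococcus/Pyxidicoccus strains plus an
Aggregicoccus outgroup) shipped as a TSV fixture. Quality gating follows
the CheckM-style convention: completeness strictly above 95% and
contamination strictly below 5%, both configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .sequences import gc_fraction

ASSEMBLY_LEVELS = ("complete", "draft", "unknown")


@dataclass
class GenomeRecord:
    """One strain's assembly contigs plus QC/annotation metadata."""

    strain_id: str
    contigs: List[str] = field(default_factory=list)
    completeness: Optional[float] = None
    contamination: Optional[float] = None
    group_label: Optional[str] = None
    species_label: Optional[str] = None
    accession: Optional[str] = None
    assembly_level: str = "unknown"

    def __post_init__(self) -> None:
        if self.assembly_level not in ASSEMBLY_LEVELS:
            raise ValueError(f"assembly_level must be one of {ASSEMBLY_LEVELS}")
        for name in ("completeness", "contamination"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v}")

    @property
    def sequence(self) -> str:
        return "".join(self.contigs)


@dataclass(frozen=True)
class GenomeStats:
    strain_id: str
    size_bp: int
    gc_percent: Optional[float]  # None when no unambiguous bases exist


@dataclass(frozen=True)
class QcFailure:
    record: GenomeRecord
    reasons: Tuple[str, ...]


def qc_filter(records: Sequence[GenomeRecord],
              min_completeness: float = 95.0,
              max_contamination: float = 5.0,
              ) -> Tuple[List[GenomeRecord], List[QcFailure]]:
    """Partition records into those passing the quality gate and failures.

    A record passes iff completeness > min_completeness AND contamination
    < max_contamination (strict inequalities). Records missing either
    metric are routed to the failures with reason "missing QC metadata".
    """
    if not (0 <= min_completeness <= 100 and 0 <= max_contamination <= 100):
        raise ValueError("QC thresholds must lie in [0, 100]")
    passed: List[GenomeRecord] = []
    failed: List[QcFailure] = []
    for rec in records:
        if rec.completeness is None or rec.contamination is None:
            failed.append(QcFailure(rec, ("missing QC metadata",)))
            continue
        reasons = []
        if not rec.completeness > min_completeness:
            reasons.append(f"completeness {rec.completeness} <= {min_completeness}")
        if not rec.contamination < max_contamination:
            reasons.append(f"contamination {rec.contamination} >= {max_contamination}")
        if reasons:
            failed.append(QcFailure(rec, tuple(reasons)))
        else:
            passed.append(rec)
    return passed, failed


def genome_stats(record: GenomeRecord) -> GenomeStats:
    """Assembly size and G+C content.

    size_bp counts every residue including ambiguity codes; gc_percent is
    computed over unambiguous A/C/G/T only and is None when a sequence
    contains no unambiguous base at all ("undefined GC").
    """
    if not record.contigs:
        raise ValueError(f"{record.strain_id}: no contigs")
    size = sum(len(c) for c in record.contigs)
    frac = gc_fraction(record.sequence)
    return GenomeStats(record.strain_id, size, None if frac is None else 100.0 * frac)


def load_reference_metadata(apply_qc_gate: bool = False) -> pd.DataFrame:
    """Load the packaged 91-row reference genome table.

    Columns: strain_id, original_name, group, species, accession, size_mbp,
    gc_percent, completeness, contamination, assembly_level, is_outgroup.

    By default all rows are kept, matching the published panel; note that
    one row (C. praedator CA031B, contamination 5.1%) nominally violates
    the stated "< 5% contamination" gate, so gating is opt-in.
    """
    ref = resources.files("markergauge.data").joinpath("table1_genomes.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"group": "string", "species": "string"})
    df["is_outgroup"] = df["is_outgroup"].astype(bool)
    if apply_qc_gate:
        df = df[(df["completeness"] > 95.0) & (df["contamination"] < 5.0)].reset_index(drop=True)
    return df


@dataclass(frozen=True)
class MetadataSummary:
    n: int
    size_mean: float
    size_sd: Optional[float]
    size_min: float
    size_max: float
    gc_mean: float
    gc_sd: Optional[float]
    gc_min: float
    gc_max: float
    group_counts: Dict[str, int]
    assembly_level_counts: Dict[str, int]

    def rounded(self, ndigits: int = 2) -> "MetadataSummary":
        """Half-even rounding of the continuous summaries for reporting."""
        def r(v):
            return None if v is None else round(v, ndigits)
        return MetadataSummary(
            self.n, r(self.size_mean), r(self.size_sd), r(self.size_min), r(self.size_max),
            r(self.gc_mean), r(self.gc_sd), r(self.gc_min), r(self.gc_max),
            self.group_counts, self.assembly_level_counts,
        )


def summarize_metadata(table: pd.DataFrame, exclude_outgroup: bool = True) -> MetadataSummary:
    """Summary statistics of genome size (Mbp) and G+C (%) over a panel table.

    Standard deviations use the sample (n-1) denominator and are reported
    as absent for a single-row table. Outgroup rows are excluded by default.
    """
    if table.empty:
        raise ValueError("empty metadata table")
    df = table
    if exclude_outgroup and "is_outgroup" in df.columns:
        df = df[~df["is_outgroup"].astype(bool)]
    if df.empty:
        raise ValueError("no rows left after outgroup exclusion")
    size = df["size_mbp"].astype(float)
    gc = df["gc_percent"].astype(float)
    n = len(df)
    sd = (lambda s: float(s.std(ddof=1)) if n > 1 else None)
    groups = df["group"].fillna("").astype(str)
    return MetadataSummary(
        n=n,
        size_mean=float(size.mean()), size_sd=sd(size),
        size_min=float(size.min()), size_max=float(size.max()),
        gc_mean=float(gc.mean()), gc_sd=sd(gc),
        gc_min=float(gc.min()), gc_max=float(gc.max()),
        group_counts=groups[groups != ""].value_counts().to_dict(),
        assembly_level_counts=df["assembly_level"].value_counts().to_dict(),
    )
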