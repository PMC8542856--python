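"""Classifying query amplicons against a calibrated reference panel.

The decision rule mirrors field practice for marker-based typing:

1. compute the query's identity to every reference window;
2. no hit at or above the species threshold -> putative new species;
3. all hits above the threshold from one species, best hit outside the
   intra/inter overlap zone -> assigned;
4. hits spanning several species, or a best hit inside the overlap zone ->
   resolve by neighbor-joining placement: the query takes the species of
   its smallest enclosing reference cluster on the tree if that cluster is
   species-pure, otherwise the call is ambiguous.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np

from .amplicon import MarkerSequence, trim_to_window, DEFAULT_WINDOW
from .genomospecies import SpeciesPartition
from .identity import IdentityMatrix, identity_matrix, pair_identity
from .trees import identities_to_distances, nj_tree

DEFAULT_WINDOW_THRESHOLD = 98.6  # percent identity of the 966-bp window at 70% dDDH

Call = Literal["assigned", "putative_new_species", "ambiguous"]


@dataclass
class ReferencePanel:
    """Reference marker windows with their species partition and threshold."""

    markers: List[MarkerSequence]
    partition: SpeciesPartition
    threshold: float = DEFAULT_WINDOW_THRESHOLD
    overlap_interval: Optional[Tuple[float, float]] = None
    _identity: Optional[IdentityMatrix] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("empty reference panel")
        if not 0.0 < self.threshold < 100.0:
            raise ValueError("threshold must lie in (0, 100)")
        missing = {m.strain_id for m in self.markers} - set(self.partition.assignment)
        if missing:
            raise ValueError(f"markers without species assignment: {sorted(missing)[:5]}")
        regions = {m.region for m in self.markers}
        if regions != {"window"}:
            raise ValueError("reference panel must hold window-region markers")

    def species_of(self, strain_id: str) -> str:
        return self.partition.assignment[strain_id]

    @property
    def reference_identity(self) -> IdentityMatrix:
        if self._identity is None:
            self._identity = identity_matrix(self.markers)
        return self._identity


@dataclass(frozen=True)
class ClassificationResult:
    query_id: str
    best_hit: str
    best_identity: float
    hits_above_threshold: Tuple[Tuple[str, str, float], ...]  # (strain, species, identity)
    call: Call
    species: Optional[str]
    overlap_zone: bool
    placement_species: Optional[str] = None


def _placement_species(panel: ReferencePanel, query: MarkerSequence,
                       identity_by_ref: dict) -> Optional[str]:
    """Species of the query's smallest enclosing species-pure reference
    cluster on the NJ tree, or None when the first enclosing cluster mixes
    species."""
    ref = panel.reference_identity
    n = len(ref)
    values = np.full((n + 1, n + 1), 100.0)
    values[:n, :n] = ref.values
    qcol = [identity_by_ref[s] for s in ref.strain_ids]
    values[n, :n] = values[:n, n] = qcol
    ids = ref.strain_ids + [query.strain_id]
    combined = type(ref)(ids, values, region=ref.region)
    tree = nj_tree(identities_to_distances(combined), ids)
    tip = tree.find(query.strain_id)
    node = tip.parent
    while node is not None:
        species = {panel.species_of(t.name) for t in node.tips()
                   if t.name != query.strain_id}
        if species:
            return species.pop() if len(species) == 1 else None
        node = node.parent
    return None


def classify(query: MarkerSequence, panel: ReferencePanel) -> ClassificationResult:
    """Classify one query marker against a reference panel.

    Queries not already in window form are trimmed first. Deterministic:
    permuting panel order changes neither the call nor the best hit
    (best-hit ties break by species majority among tied hits, then by
    lexicographic strain id).
    """
    if query.region != "window":
        query = trim_to_window(query, DEFAULT_WINDOW)
    order = sorted(range(len(panel.markers)), key=lambda i: panel.markers[i].strain_id)
    markers = [panel.markers[i] for i in order]
    idents = [pair_identity(query.sequence, m.sequence) for m in markers]

    best_identity = max(idents)
    tied = [m.strain_id for m, v in zip(markers, idents) if v == best_identity]
    if len(tied) == 1:
        best_hit = tied[0]
    else:
        majority = Counter(panel.species_of(s) for s in tied).most_common()
        top_species = sorted(sp for sp, c in majority if c == majority[0][1])[0]
        best_hit = min(s for s in tied if panel.species_of(s) == top_species)

    hits = tuple((m.strain_id, panel.species_of(m.strain_id), v)
                 for m, v in zip(markers, idents) if v >= panel.threshold)
    overlap_zone = bool(
        panel.overlap_interval
        and panel.overlap_interval[0] <= best_identity <= panel.overlap_interval[1])

    if not hits:
        return ClassificationResult(query.strain_id, best_hit, best_identity, hits,
                                    "putative_new_species", None, overlap_zone)
    hit_species = {sp for _, sp, _ in hits}
    if len(hit_species) == 1 and not overlap_zone:
        return ClassificationResult(query.strain_id, best_hit, best_identity, hits,
                                    "assigned", hit_species.pop(), overlap_zone)
    # overlap zone or conflicting hits: fall back to tree placement
    ident_by_ref = {m.strain_id: v for m, v in zip(markers, idents)}
    placed = (_placement_species(panel, query, ident_by_ref)
              if len(panel.markers) >= 3 else None)
    if placed is None and len(hit_species) == 1:
        placed = hit_species.pop()  # placement inconclusive, threshold vote is unanimous
    if placed is not None:
        return ClassificationResult(query.strain_id, best_hit, best_identity, hits,
                                    "assigned", placed, overlap_zone, placed)
    return ClassificationResult(query.strain_id, best_hit, best_identity, hits,
                                "ambiguous", None, overlap_zone)
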