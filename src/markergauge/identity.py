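"""Pairwise sequence identity: global alignment, identity matrices, and
intra- vs inter-species identity statistics.

Identity is defined from optimal pairwise global alignment under affine-gap
scoring (match +2, mismatch -1, gap open -5, gap extend -1 by default) as

    100 * matches / (alignment columns excluding terminal-gap columns),

i.e. semi-global identity: overhangs at either end do not count against a
pair, internal gaps do. Matches require exact base equality by default;
IUPAC-compatible matching can be enabled for sequences with ambiguity calls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .sequences import IUPAC, bases_compatible
from .amplicon import MarkerSequence


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0   # score of a gap of length 1
    gap_extend: float = -1.0  # per additional gapped base


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float


def _make_aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def global_align(seq_a: str, seq_b: str,
                 scoring: AlignmentScoring = DEFAULT_SCORING) -> PairwiseAlignment:
    """Optimal global alignment of two nucleotide sequences.

    Affine gap cost: a gap of length L scores gap_open + (L-1)*gap_extend.
    Among co-optimal alignments the first in the aligner's deterministic
    enumeration order is returned; the score is unique.
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        bad = set(seq.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{name} contains non-IUPAC characters: {sorted(bad)}")
    aligner = _make_aligner(scoring)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    return PairwiseAlignment(a, b, float(aln.score))


def percent_identity(alignment: PairwiseAlignment,
                     exclude_terminal_gaps: bool = True,
                     iupac_matches: bool = False) -> float:
    """Percent identity of an alignment.

    Terminal-gap columns (leading/trailing gap runs in either sequence) are
    excluded from the denominator by default; internal gap columns count.
    """
    a, b = alignment.aligned_a, alignment.aligned_b
    if len(a) != len(b):
        raise ValueError("aligned strings differ in length")
    lo, hi = 0, len(a)
    if exclude_terminal_gaps:
        while lo < hi and (a[lo] == "-" or b[lo] == "-"):
            lo += 1
        while hi > lo and (a[hi - 1] == "-" or b[hi - 1] == "-"):
            hi -= 1
    columns = hi - lo
    if columns == 0:
        raise ValueError("zero-length effective alignment")
    if iupac_matches:
        same = sum(1 for x, y in zip(a[lo:hi], b[lo:hi])
                   if x != "-" and y != "-" and bases_compatible(x, y))
    else:
        same = sum(1 for x, y in zip(a[lo:hi], b[lo:hi]) if x == y and x != "-")
    return 100.0 * same / columns


def pair_identity(seq_a: str, seq_b: str,
                  scoring: AlignmentScoring = DEFAULT_SCORING, **kwargs) -> float:
    """Convenience: align two sequences and return their percent identity."""
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) == len(b):
        # Gap-free shortcut, exact whenever the ungapped alignment already
        # attains the optimal score (the usual case for fixed windows).
        ungapped = sum(1 for x, y in zip(a, b) if x == y)
        ungapped_score = (ungapped * scoring.match
                          + (len(a) - ungapped) * scoring.mismatch)
        opt = float(_make_aligner(scoring).score(a, b))
        if opt <= ungapped_score:
            return percent_identity(PairwiseAlignment(a, b, ungapped_score), **kwargs)
    return percent_identity(global_align(a, b, scoring), **kwargs)


class PercentMatrix:
    """Symmetric percent-valued matrix over an ordered strain panel."""

    def __init__(self, strain_ids: Sequence[str], values: np.ndarray):
        ids = list(strain_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate strain ids")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(ids), len(ids)):
            raise ValueError("matrix shape does not match strain ids")
        if not np.all(np.isfinite(values)):
            raise ValueError("matrix contains non-finite values")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("matrix is not symmetric")
        self.strain_ids = ids
        self.values = values
        self._index = {s: i for i, s in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.strain_ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def off_diagonal_pairs(self) -> List[Tuple[str, str, float]]:
        out = []
        for i, j in itertools.combinations(range(len(self)), 2):
            out.append((self.strain_ids[i], self.strain_ids[j], float(self.values[i, j])))
        return out

    def reorder(self, strain_ids: Sequence[str]) -> "PercentMatrix":
        idx = [self._index[s] for s in strain_ids]
        return type(self)(list(strain_ids), self.values[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strain_ids, columns=self.strain_ids)

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="strain_id")


class IdentityMatrix(PercentMatrix):
    def __init__(self, strain_ids, values, region: str = "window"):
        super().__init__(strain_ids, values)
        self.region = region
        if not np.allclose(np.diag(self.values), 100.0):
            raise ValueError("identity matrix diagonal must be 100")

    @classmethod
    def read_csv(cls, path, region: str = "window") -> "IdentityMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels differ")
        return cls(list(df.index), df.to_numpy(float), region=region)


def identity_matrix(markers: Sequence[MarkerSequence],
                    scoring: AlignmentScoring = DEFAULT_SCORING,
                    **identity_kwargs) -> IdentityMatrix:
    """All-vs-all percent identities over a marker panel (one region tag)."""
    if len(markers) < 2:
        raise ValueError("need at least two sequences")
    regions = {m.region for m in markers}
    if len(regions) != 1:
        raise ValueError(f"mixed region tags: {sorted(regions)}")
    ids = [m.strain_id for m in markers]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids in marker panel")
    n = len(markers)
    values = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        pid = pair_identity(markers[i].sequence, markers[j].sequence,
                            scoring, **identity_kwargs)
        values[i, j] = values[j, i] = pid
    return IdentityMatrix(ids, values, region=regions.pop())


@dataclass(frozen=True)
class IdentityPartitionStats:
    intra_values: Tuple[float, ...]
    inter_values: Tuple[float, ...]
    intra_mean: Optional[float]
    intra_min: Optional[float]
    intra_max: Optional[float]
    inter_mean: Optional[float]
    inter_min: Optional[float]
    inter_max: Optional[float]
    t_statistic: Optional[float]
    p_value: Optional[float]
    overlap_interval: Optional[Tuple[float, float]]


def partition_stats(matrix: PercentMatrix, partition) -> IdentityPartitionStats:
    """Split off-diagonal identities into intra-/inter-species samples.

    Reports means and ranges of both samples, Welch's unequal-variance
    two-sided t-test, and the intra/inter overlap interval
    (min intra, max inter) whenever the two ranges intersect.
    """
    assignment = partition.assignment if hasattr(partition, "assignment") else dict(partition)
    missing = set(matrix.strain_ids) - set(assignment)
    if missing:
        raise ValueError(f"partition does not cover strains: {sorted(missing)[:5]}")
    intra, inter = [], []
    for a, b, v in matrix.off_diagonal_pairs():
        (intra if assignment[a] == assignment[b] else inter).append(v)

    def _summary(vals):
        if not vals:
            return None, None, None
        arr = np.asarray(vals)
        return float(arr.mean()), float(arr.min()), float(arr.max())

    intra_mean, intra_min, intra_max = _summary(intra)
    inter_mean, inter_min, inter_max = _summary(inter)
    t_stat = p_val = None
    if len(intra) >= 2 and len(inter) >= 2:
        res = stats.ttest_ind(intra, inter, equal_var=False)
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    overlap = None
    if intra and inter and inter_max >= intra_min:
        overlap = (intra_min, inter_max)
    return IdentityPartitionStats(
        tuple(intra), tuple(inter),
        intra_mean, intra_min, intra_max,
        inter_mean, inter_min, inter_max,
        t_stat, p_val, overlap,
    )


def correlate(x_values: Sequence[float], y_values: Sequence[float],
              model: str = "linear") -> Tuple[float, float, float]:
    """Ordinary least squares y = slope*x + intercept; returns
    (slope, intercept, r_squared)."""
    if model != "linear":
        raise ValueError("only the linear model is supported here")
    x = np.asarray(x_values, float)
    y = np.asarray(y_values, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue) ** 2
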