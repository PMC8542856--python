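"""Distance-based trees: neighbor joining, newick round-trips, and a
column-resampling bootstrap.

NJ (via scikit-bio's canonical Q-criterion implementation, negative branch
lengths clamped to zero) serves as the desk-scale placement engine for the
classifier; it exactly recovers additive distance matrices.
"""

from __future__ import annotations

import io
from typing import Dict, FrozenSet, List, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from .amplicon import MarkerSequence


class NewickError(ValueError):
    pass


def nj_tree(distance_matrix, strain_ids: Optional[Sequence[str]] = None) -> TreeNode:
    """Neighbor-joining tree from a symmetric non-negative distance matrix.

    Accepts a PercentMatrix-like object or a square array plus
    `strain_ids`; values are taken as distances as-is (use
    identities_to_distances to convert an identity matrix first).
    Requires n >= 3.
    """
    if hasattr(distance_matrix, "strain_ids") and hasattr(distance_matrix, "values"):
        ids = list(distance_matrix.strain_ids)
        values = np.asarray(distance_matrix.values, float)
    else:
        values = np.asarray(distance_matrix, float)
        if strain_ids is None:
            raise ValueError("strain_ids required with a bare array")
        ids = list(strain_ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if np.any(values < 0):
        raise ValueError("distances must be non-negative")
    dm = DistanceMatrix(values, ids)
    return _skbio_nj(dm, neg_as_zero=True)


def identities_to_distances(identity_matrix) -> np.ndarray:
    """p-distance transform of a percent identity matrix: (100 - id)/100."""
    d = (100.0 - np.asarray(identity_matrix.values, float)) / 100.0
    np.fill_diagonal(d, 0.0)
    return d


def newick_write(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def newick_read(text: str) -> TreeNode:
    """Parse a newick string; unbalanced parentheses are reported with the
    0-based offset of the first unmatched character."""
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickError(f"unbalanced ')' at offset {i}")
    if depth != 0:
        raise NewickError(f"unbalanced '(' ({depth} unclosed) at offset {len(text) - 1}")
    try:
        return TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise NewickError(f"newick parse error: {exc}") from exc


def tree_bipartitions(tree: TreeNode) -> List[FrozenSet[str]]:
    """Non-trivial bipartitions as frozensets of tip names (smaller side,
    ties broken lexicographically) for internal edges."""
    all_tips = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min((side, other), key=lambda s: (len(s), tuple(sorted(s))))
        parts.add(canon)
    return sorted(parts, key=lambda s: (len(s), tuple(sorted(s))))


def _p_distance_matrix(seqs: np.ndarray) -> np.ndarray:
    n = seqs.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        diff = (seqs[i] != seqs[i + 1:]).mean(axis=1) if i + 1 < n else []
        for k, v in enumerate(diff, start=i + 1):
            d[i, k] = d[k, i] = v
    return d


def bootstrap_support(markers: Sequence[MarkerSequence], n_replicates: int = 100,
                      seed: int = 0) -> Dict[FrozenSet[str], float]:
    """Column-resampling bootstrap support for the NJ tree of a marker panel.

    Alignment columns are resampled with replacement, an NJ tree is rebuilt
    from p-distances per replicate, and each internal bipartition of the
    original tree is reported with the percent of replicates containing it.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    lengths = {len(m.sequence) for m in markers}
    if len(lengths) != 1:
        raise ValueError("bootstrap requires aligned equal-length sequences")
    if len(markers) < 4:
        raise ValueError("need at least 4 taxa for internal edges")
    ids = [m.strain_id for m in markers]
    arr = np.array([list(m.sequence) for m in markers])
    L = arr.shape[1]
    base_tree = nj_tree(_p_distance_matrix(arr), ids)
    targets = tree_bipartitions(base_tree)
    counts = {bp: 0 for bp in targets}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        rep = set(tree_bipartitions(nj_tree(_p_distance_matrix(arr[:, cols]), ids)))
        for bp in targets:
            if bp in rep:
                counts[bp] += 1
    return {bp: 100.0 * c / n_replicates for bp, c in counts.items()}
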