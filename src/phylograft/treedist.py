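"""Tree comparison metrics: normalized Robinson-Foulds and branch-score distance.

Both metrics work on unrooted bipartitions of a shared tip set.  The RF
distance counts splits present in one tree but not the other; it is
normalized by the *sum* of the two trees' non-trivial split counts, so two
maximally different binary trees score 1.0.  The branch-score (squared
Euclidean) distance of Kuhner & Felsenstein sums squared branch-length
differences over the union of bipartitions — terminal branches included, and
a bipartition absent from one tree contributes its full length squared; its
normalization divides by the bipartition count, configurable as the union
size (default) or the same sum convention as RF.
"""

from __future__ import annotations

from dataclasses import dataclass

from .trees import Chronogram, TreeError

__all__ = ["TreeDistanceResult", "rf_distance", "branch_score", "compare_trees"]


@dataclass(frozen=True)
class TreeDistanceResult:
    rf_raw: int
    rf_normalized: float
    sqeuclid_raw: float
    sqeuclid_normalized: float
    n_splits_t1: int
    n_splits_t2: int
    n_union_bipartitions: int


def _check_tips(t1: Chronogram, t2: Chronogram) -> None:
    s1, s2 = set(t1.tip_labels()), set(t2.tip_labels())
    if s1 != s2:
        raise TreeError(
            f"tip-set mismatch: {sorted(s1 ^ s2)} not shared between the trees"
        )


def rf_distance(t1: Chronogram, t2: Chronogram) -> tuple[int, float]:
    """Robinson-Foulds distance over non-trivial unrooted splits.

    Returns (raw symmetric difference, raw / (|splits(t1)| + |splits(t2)|)).
    Trees with fewer than 4 tips have no non-trivial splits and are rejected.
    """
    _check_tips(t1, t2)
    if t1.n_tips() < 4:
        raise TreeError("RF distance needs >= 4 tips")
    s1 = t1.bipartitions(nontrivial_only=True)
    s2 = t2.bipartitions(nontrivial_only=True)
    raw = len(s1 ^ s2)
    denom = len(s1) + len(s2)
    return raw, (raw / denom if denom else 0.0)


def branch_score(
    t1: Chronogram, t2: Chronogram, denominator: str = "union"
) -> tuple[float, float]:
    """Kuhner-Felsenstein squared branch-length distance.

    ``raw = sum over the union of bipartitions (trivial tip splits included)
    of (l1 - l2)^2`` with absent bipartitions contributing length 0.
    ``denominator``: ``union`` (size of the bipartition union, default) or
    ``sum`` (|bipartitions(t1)| + |bipartitions(t2)|).
    """
    _check_tips(t1, t2)
    if denominator not in ("union", "sum"):
        raise ValueError(f"unknown denominator {denominator!r}")
    l1 = t1.split_lengths(include_trivial=True)
    l2 = t2.split_lengths(include_trivial=True)
    union = set(l1) | set(l2)
    raw = sum((l1.get(s, 0.0) - l2.get(s, 0.0)) ** 2 for s in union)
    denom = len(union) if denominator == "union" else len(l1) + len(l2)
    return raw, (raw / denom if denom else 0.0)


def compare_trees(
    t1: Chronogram, t2: Chronogram, denominator: str = "union"
) -> TreeDistanceResult:
    rf_raw, rf_norm = rf_distance(t1, t2)
    sq_raw, sq_norm = branch_score(t1, t2, denominator=denominator)
    l1 = t1.split_lengths(include_trivial=True)
    l2 = t2.split_lengths(include_trivial=True)
    return TreeDistanceResult(
        rf_raw=rf_raw,
        rf_normalized=rf_norm,
        sqeuclid_raw=sq_raw,
        sqeuclid_normalized=sq_norm,
        n_splits_t1=len(t1.bipartitions()),
        n_splits_t2=len(t2.bipartitions()),
        n_union_bipartitions=len(set(l1) | set(l2)),
    )
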