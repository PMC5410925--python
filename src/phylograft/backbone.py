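"""Backbone inference and dating.

The built-in inference is distance-based (neighbor joining on JC69 distances
with column-resampling bootstrap), and the built-in dating is a mean-path-
length ultrametricisation followed by global scaling to the fossil minima.
Both are explicit offline stand-ins so that the whole divide-and-graft
pipeline runs and is testable without external binaries; maximum-likelihood /
Bayesian engines and penalized-likelihood dating plug in through the adapter
contract in :mod:`phylograft.adapters`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .distances import MISSING, SaturationError, encode
from .model import FossilCalibration
from .trees import Chronogram, Node, TreeError

__all__ = [
    "nj_tree",
    "matrix_distances",
    "bootstrap_support",
    "majority_consensus",
    "CalibrationPlacement",
    "place_fossils",
    "date_tree",
    "mpl_ultrametricize",
]


# -- distances from a concatenated matrix ------------------------------------

def matrix_distances(
    matrix: dict[str, str],
    model: str = "JC69",
    columns: Optional[np.ndarray] = None,
    missing: str = "error",
) -> tuple[list[str], np.ndarray]:
    """Pairwise distances over the rows of a '?'-padded matrix.

    ``columns`` optionally selects (resampled) column indices.  A pair with
    zero comparable sites raises :class:`SaturationError` (default) or, with
    ``missing='impute'``, receives 1.5 x the largest finite distance — the
    distance-based stand-in's analogue of how likelihood engines tolerate
    non-overlapping taxa in sparse supermatrices.
    """
    if missing not in ("error", "impute"):
        raise ValueError(f"unknown missing-pair policy {missing!r}")
    labels = sorted(matrix)
    arrays = np.stack([encode(matrix[l]) for l in labels])
    if columns is not None:
        arrays = arrays[:, columns]
    n = len(labels)
    d = np.zeros((n, n))
    imputed: list[tuple[int, int]] = []
    for i in range(n):
        usable_i = arrays[i] != MISSING
        for j in range(i + 1, n):
            usable = usable_i & (arrays[j] != MISSING)
            m = int(usable.sum())
            if m == 0:
                if missing == "error":
                    raise SaturationError(
                        f"zero comparable sites between {labels[i]!r} and {labels[j]!r}"
                    )
                imputed.append((i, j))
                continue
            p = float((arrays[i, usable] != arrays[j, usable]).sum()) / m
            if model in ("p", "p-distance"):
                d[i, j] = d[j, i] = p
            elif model == "JC69":
                d[i, j] = d[j, i] = (
                    math.inf if p >= 0.75 else -0.75 * math.log1p(-4.0 * p / 3.0)
                )
            else:
                raise ValueError(f"unknown model {model!r}")
    if not np.isfinite(d).all():
        # saturated pairs get the largest finite distance; NJ needs numbers
        finite_max = d[np.isfinite(d)].max(initial=1.0)
        d[~np.isfinite(d)] = finite_max * 1.5
    if imputed:
        # three-point (ultrametric) estimate: d_ij <= max(d_ik, d_jk) with
        # equality for any k outside the (i, j) cherry, so the tightest such
        # bound over third taxa is the natural clock-based fill-in
        missing_mask = np.zeros((n, n), dtype=bool)
        for i, j in imputed:
            missing_mask[i, j] = missing_mask[j, i] = True
        finite_max = d[~missing_mask].max(initial=1.0)
        for i, j in imputed:
            third = [
                k
                for k in range(n)
                if k not in (i, j) and not missing_mask[i, k] and not missing_mask[j, k]
            ]
            est = min((max(d[i, k], d[j, k]) for k in third), default=finite_max * 1.5)
            d[i, j] = d[j, i] = est
        warnings.warn(
            f"{len(imputed)} taxon pair(s) without comparable sites; "
            "distances imputed from the three-point bound",
            stacklevel=2,
        )
    return labels, d


# -- neighbor joining ---------------------------------------------------------

def nj_tree(labels: Sequence[str], dist: np.ndarray) -> Chronogram:
    """Standard neighbor joining; returns an unrooted tree (trifurcating root).

    Negative inferred branch lengths are clamped to 0 with a warning.  Ties in
    the Q criterion break on the lexicographically smallest representative
    label pair, so the topology is deterministic.
    """
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    order = sorted(range(n), key=lambda i: labels[i])
    d = dist[np.ix_(order, order)].astype(float).copy()
    nodes = [Node(label=labels[i]) for i in order]
    reps = [labels[i] for i in order]  # smallest member label per cluster
    active = list(range(n))
    clamped = False

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                key = (q[a, b], tuple(sorted((reps[active[a]], reps[active[b]]))))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        li = 0.5 * sub[a, b] + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = sub[a, b] - li
        if li < 0 or lj < 0:
            clamped = True
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_d = 0.5 * (d[i, active] + d[j, active] - d[i, j])
        d[i, active] = new_d
        d[active, i] = new_d
        d[i, i] = 0.0
        nodes[i] = parent
        reps[i] = min(reps[i], reps[j])
        active.remove(j)

    i, j, k = active
    root = Node()
    lij = d[i, j]
    lik = d[i, k]
    ljk = d[j, k]
    li = 0.5 * (lij + lik - ljk)
    lj = 0.5 * (lij + ljk - lik)
    lk = 0.5 * (lik + ljk - lij)
    if min(li, lj, lk) < 0:
        clamped = True
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = max(length, 0.0)
        root.add_child(node)
    if clamped:
        warnings.warn("negative NJ branch length(s) clamped to 0", stacklevel=2)
    return Chronogram(root)


def nj_from_matrix(
    matrix: dict[str, str], model: str = "JC69", missing: str = "error"
) -> Chronogram:
    labels, d = matrix_distances(matrix, model=model, missing=missing)
    return nj_tree(labels, d)


# -- bootstrap ----------------------------------------------------------------

def bootstrap_support(
    matrix: dict[str, str],
    partitions: Sequence[tuple[str, int, int]],
    replicates: int = 100,
    seed: int = 0,
    model: str = "JC69",
    missing: str = "error",
) -> Chronogram:
    """NJ tree with split support from per-partition column resampling.

    Support on each internal node is the fraction of replicate trees whose
    unrooted split set contains that node's split.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = nj_from_matrix(matrix, model=model, missing=missing)
    target = tree.bipartitions()
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    blocks = [(start - 1, end) for _, start, end in partitions]
    for _ in range(replicates):
        cols = np.concatenate(
            [rng.integers(lo, hi, size=hi - lo) for lo, hi in blocks]
        )
        try:
            labels, d = matrix_distances(matrix, model=model, columns=cols, missing=missing)
        except SaturationError:
            continue  # a pathological resample loses all overlap for a pair
        rep = nj_tree(labels, d)
        for split in rep.bipartitions():
            if split in counts:
                counts[split] += 1
    all_tips = frozenset(tree.tip_labels())
    ref = min(all_tips)
    tipsets = tree.tipsets()
    for node, ts in tipsets.items():
        if node is tree.root or node.is_leaf:
            continue
        side = all_tips - ts if ref in ts else ts
        if side in counts:
            node.support = counts[side] / replicates
    return tree


# -- consensus ----------------------------------------------------------------

def majority_consensus(trees: Sequence[Chronogram], threshold: float = 0.5) -> Chronogram:
    """Majority-rule consensus of rooted trees on the same tip set.

    Clades with frequency strictly greater than ``threshold`` are retained;
    where no clade wins, the consensus shows a polytomy.  Clade frequencies
    are stored as support; branch lengths are means over the trees containing
    the clade.
    """
    if not trees:
        raise ValueError("no trees")
    if not 0.5 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0.5, 1]")
    tipset = frozenset(trees[0].tip_labels())
    counts: dict[frozenset, int] = {}
    lengths: dict[frozenset, list[float]] = {}
    for t in trees:
        if frozenset(t.tip_labels()) != tipset:
            raise TreeError("consensus input trees have different tip sets")
        tipsets = t.tipsets()
        for node, ts in tipsets.items():
            if node is t.root:
                continue
            counts[ts] = counts.get(ts, 0) + 1
            if node.length is not None:
                lengths.setdefault(ts, []).append(node.length)
    n = len(trees)
    winners = {ts for ts, c in counts.items() if c / n > threshold}
    # tips are always present; build the consensus top-down by containment
    keep = sorted(winners, key=lambda ts: (-len(ts), sorted(ts)))
    root = Node()
    clade_node: dict[frozenset, Node] = {tipset: root}
    placed: list[frozenset] = [tipset]
    for ts in keep:
        if len(ts) == len(tipset):
            continue
        parent_ts = min(
            (p for p in placed if ts < p), key=len
        )
        node = Node() if len(ts) > 1 else Node(label=next(iter(ts)))
        node.support = counts[ts] / n
        ls = lengths.get(ts)
        node.length = sum(ls) / len(ls) if ls else None
        clade_node[parent_ts].add_child(node)
        clade_node[ts] = node
        placed.append(ts)
    # attach any tip not yet placed under its smallest containing winner
    for tip in sorted(tipset):
        ts = frozenset([tip])
        if ts in clade_node:
            continue
        parent_ts = min((p for p in placed if ts < p), key=len)
        node = Node(label=tip)
        node.support = counts.get(ts, n) / n
        ls = lengths.get(ts)
        node.length = sum(ls) / len(ls) if ls else None
        clade_node[parent_ts].add_child(node)
    for node in root.preorder():  # deterministic child order
        node.children.sort(key=lambda c: min(l.label for l in c.leaves()))
    return Chronogram(root)


# -- fossil placement ---------------------------------------------------------

@dataclass
class CalibrationPlacement:
    calib_ids: tuple[str, ...]
    node: Node
    min_age: float
    max_age: Optional[float]


def place_fossils(
    tree: Chronogram,
    calibrations: Sequence[FossilCalibration],
    restrict: bool = False,
) -> list[CalibrationPlacement]:
    """Map fossil calibrations onto MRCA nodes of a rooted tree.

    Calibrations naming missing tips are skipped with a warning; with
    ``restrict=True`` (how a fossil behaves on a subsampled tree, e.g. the
    exemplar backbone) the calibration instead resolves to the MRCA of its
    *present* taxa and is skipped only when fewer than two remain.  Several
    calibrations resolving to one node combine as (max of minima, min of
    maxima); an ancestor whose max is below a descendant's min is a conflict.
    """
    tips = set(tree.tip_labels())
    per_node: dict[int, list[FossilCalibration]] = {}
    node_by_id: dict[int, Node] = {}
    for calib in calibrations:
        present = [t for t in calib.mrca_taxa if t in tips]
        missing = set(calib.mrca_taxa) - tips
        if (missing and not restrict) or len(present) < 2:
            warnings.warn(
                f"calibration {calib.calib_id!r} skipped; missing taxa {sorted(missing)}",
                stacklevel=2,
            )
            continue
        node = tree.mrca(present)
        if node.is_leaf:
            raise TreeError(f"calibration {calib.calib_id!r} resolves to a tip")
        per_node.setdefault(id(node), []).append(calib)
        node_by_id[id(node)] = node
    placements: list[CalibrationPlacement] = []
    for key, calibs in per_node.items():
        node = node_by_id[key]
        min_age = max(c.min_age for c in calibs)
        maxima = [c.max_age for c in calibs if c.max_age is not None]
        max_age = min(maxima) if maxima else None
        if max_age is not None and max_age < min_age:
            raise TreeError(
                f"calibrations {[c.calib_id for c in calibs]} combine to min > max"
            )
        placements.append(
            CalibrationPlacement(tuple(c.calib_id for c in calibs), node, min_age, max_age)
        )
    # ancestor/descendant conflicts
    for p in placements:
        ancestors = set()
        node = p.node.parent
        while node is not None:
            ancestors.add(id(node))
            node = node.parent
        for q in placements:
            if id(q.node) in ancestors and q.max_age is not None and p.min_age > q.max_age:
                raise TreeError(
                    f"calibration {p.calib_ids} min {p.min_age} exceeds "
                    f"ancestor {q.calib_ids} max {q.max_age}"
                )
    return placements


# -- dating -------------------------------------------------------------------

def mpl_ultrametricize(tree: Chronogram) -> Chronogram:
    """Mean-path-length ultrametricisation of a rooted phylogram.

    Each internal node's relative age is the mean of its node-to-tip path
    lengths, clamped so a parent is never younger than its children; tip ages
    are 0.  Branch lengths are rewritten as age differences.
    """
    out = tree.copy()
    # mean node-to-tip path length per node
    sums: dict[Node, float] = {}
    ntips: dict[Node, int] = {}
    for node in out.postorder():
        if node.is_leaf:
            sums[node], ntips[node] = 0.0, 1
        else:
            sums[node] = sum(sums[c] + (c.length or 0.0) * ntips[c] for c in node.children)
            ntips[node] = sum(ntips[c] for c in node.children)
    for node in out.postorder():
        if node.is_leaf:
            node.age = 0.0
        else:
            mpl = sums[node] / ntips[node]
            node.age = max([mpl] + [c.age for c in node.children])
    out.set_lengths_from_ages()
    return out


def date_tree(
    phylogram: Chronogram,
    calibrations: Sequence[FossilCalibration],
    method: str = "mpl-scale",
    restrict: bool = False,
) -> Chronogram:
    """Date a rooted phylogram against fossil calibrations.

    The built-in ``mpl-scale`` method ultrametricises by mean path length and
    applies one global scale factor ``f = max_i(min_age_i / relative_age_i)``,
    so every minimum-age constraint is satisfied and at least one is met
    exactly.  Maximum-age constraints are verified after scaling and violations
    raise :class:`TreeError`.  This is a stand-in for penalized-likelihood
    rate smoothing, not an approximation of it.
    """
    if method != "mpl-scale":
        raise ValueError(f"unknown dating method {method!r}; external engines use adapters")
    rel = mpl_ultrametricize(phylogram)
    if rel.root.age <= 0:
        raise TreeError("zero-depth tree cannot be dated")
    placements = place_fossils(rel, calibrations, restrict=restrict)
    if not placements:
        raise TreeError("no usable calibration could be placed")
    f = 0.0
    for p in placements:
        if p.node.age <= 0:
            raise TreeError(f"calibration {p.calib_ids} sits on a zero-age node")
        f = max(f, p.min_age / p.node.age)
    rel.scale(f)
    for p in placements:
        if p.max_age is not None and p.node.age > p.max_age + 1e-9:
            raise TreeError(
                f"max-age constraint {p.calib_ids} ({p.max_age} Ma) unsatisfiable "
                f"by global scaling (scaled age {p.node.age:.6g} Ma)"
            )
    rel.set_lengths_from_ages()
    rel.validate_dated()
    return rel
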