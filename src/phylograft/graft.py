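"""Backbone decomposition, clade-tree inference, rescaling and grafting.

After the dated backbone is built from exemplar pairs, each genus (or merged
group of genera whose exemplars interleave in the backbone) becomes a clade
task: its full species set is inferred separately on a *relative* time scale,
rescaled so the exemplars' MRCA matches the backbone age of the equivalent
node, and grafted in place of the exemplar pair.  When the exemplars do not
span the clade root, the rescaled root is older than the backbone node and
the difference is taken out of the stem branch; if the stem cannot absorb it
the graft would create a negative branch length — a hard error by default,
with an explicit clamp mode for exploratory runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .backbone import mpl_ultrametricize, nj_tree
from .distances import MISSING, encode
from .model import SequenceRecord, TaxaTable
from .trees import Chronogram, Node, TreeError

__all__ = [
    "CladeTask",
    "GraftError",
    "assess_monophyly",
    "build_clade_tasks",
    "infer_clade_tree",
    "rescale_subtree",
    "graft_subtree",
    "graft_all",
]


class GraftError(TreeError):
    """A graft would create a negative branch length (or other graft failure)."""


# -- monophyly ----------------------------------------------------------------

def assess_monophyly(backbone: Chronogram, taxa_table: TaxaTable) -> dict[str, bool]:
    """Per-genus verdict: does the MRCA of the genus' exemplar tips subtend
    only tips of that genus?  Singleton genera are trivially monophyletic."""
    tips_by_genus: dict[str, list[str]] = {}
    for tip in backbone.tip_labels():
        if tip not in taxa_table:
            raise KeyError(f"backbone tip {tip!r} not in taxa table")
        tips_by_genus.setdefault(taxa_table.genus_of[tip], []).append(tip)
    tipsets = backbone.tipsets()
    verdict: dict[str, bool] = {}
    for genus, tips in tips_by_genus.items():
        if len(tips) == 1:
            verdict[genus] = True
            continue
        mrca = backbone.mrca(tips)
        verdict[genus] = tipsets[mrca] <= set(tips)
    return verdict


# -- clade tasks --------------------------------------------------------------

@dataclass
class CladeTask:
    task_id: str
    genera: tuple[str, ...]
    species: tuple[str, ...]          # full species set from the taxa table
    exemplars: tuple[str, ...]        # backbone tips involved
    calibration_age: float            # dated-backbone age of the exemplar MRCA
    hpd: Optional[tuple[float, float]] = None
    alignment_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.genera:
            raise ValueError("clade task needs >= 1 genus")
        if self.calibration_age <= 0:
            raise ValueError(f"task {self.task_id!r} calibration age must be > 0")
        if not set(self.exemplars) <= set(self.species):
            raise ValueError(f"task {self.task_id!r}: exemplars not within species set")


def build_clade_tasks(
    consensus_backbone: Chronogram,
    dated_backbone: Chronogram,
    taxa_table: TaxaTable,
    alignments: dict[str, Sequence[SequenceRecord]],
) -> list[CladeTask]:
    """Merge non-monophyletic genera and emit one task per resulting group.

    A non-monophyletic genus is merged with every genus that has exemplars
    under the smallest backbone clade containing the offender's exemplars;
    merging iterates to a fixed point (union-find), so each final group's
    exemplar MRCA subtends only that group's tips.  The task's calibration age
    is the dated-backbone age of the MRCA of all its exemplars (HPD copied
    when annotated).  Groups reduced to a single species yield no task.
    """
    verdicts = assess_monophyly(consensus_backbone, taxa_table)
    tips_by_genus: dict[str, list[str]] = {}
    for tip in consensus_backbone.tip_labels():
        tips_by_genus.setdefault(taxa_table.genus_of[tip], []).append(tip)
    genera = sorted(tips_by_genus)
    parent = {g: g for g in genera}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # keep the lexicographically smallest as representative
            lo, hi = sorted((ra, rb))
            parent[hi] = lo

    tipsets = consensus_backbone.tipsets()
    changed = True
    while changed:
        changed = False
        groups: dict[str, list[str]] = {}
        for g in genera:
            groups.setdefault(find(g), []).append(g)
        for rep, members in groups.items():
            group_tips = [t for g in members for t in tips_by_genus[g]]
            if len(members) == 1 and verdicts[members[0]]:
                continue
            mrca = consensus_backbone.mrca(group_tips)
            covered = tipsets[mrca]
            if covered == set(group_tips):
                continue
            for tip in covered:
                if find(taxa_table.genus_of[tip]) != rep:
                    union(rep, taxa_table.genus_of[tip])
                    changed = True

    groups: dict[str, list[str]] = {}
    for g in genera:
        groups.setdefault(find(g), []).append(g)
    if len(groups) == 1 and len(genera) > 1:
        warnings.warn("genus merging escalated to the backbone root; single task", stacklevel=2)

    dated_tipset = set(dated_backbone.tip_labels())
    if dated_backbone.root.age is None:
        dated_backbone.compute_ages()
    tasks: list[CladeTask] = []
    for rep in sorted(groups):
        members = sorted(groups[rep])
        species = sorted(sp for g in members for sp in taxa_table.genera()[g])
        exemplar_tips = sorted(t for g in members for t in tips_by_genus[g])
        if len(species) < 2:
            continue  # nothing to graft; the backbone tip already covers it
        if len(exemplar_tips) < 2:
            warnings.warn(
                f"group {members} has a single backbone exemplar; cannot anchor a "
                "clade age, left ungrafted",
                stacklevel=2,
            )
            continue
        if not set(exemplar_tips) <= dated_tipset:
            raise TreeError(f"dated backbone lacks exemplars {exemplar_tips}")
        node = dated_backbone.mrca(exemplar_tips)
        hpd = None
        if node.hpd_min is not None and node.hpd_max is not None:
            hpd = (node.hpd_min, node.hpd_max)
        aln_ids = tuple(
            aid
            for aid in sorted(alignments)
            if sum(1 for r in alignments[aid] if r.species_id in set(species)) >= 2
        )
        tasks.append(
            CladeTask(
                task_id=f"task_{rep}",
                genera=tuple(members),
                species=tuple(species),
                exemplars=tuple(exemplar_tips),
                calibration_age=node.age,
                hpd=hpd,
                alignment_ids=aln_ids,
            )
        )
    return tasks


# -- clade inference ----------------------------------------------------------

def infer_clade_tree(
    task: CladeTask,
    alignments: dict[str, Sequence[SequenceRecord]],
    model: str = "JC69",
    bootstrap_replicates: int = 0,
    seed: int = 0,
) -> Optional[Chronogram]:
    """Built-in clade inference: NJ on mean pairwise distances across the
    task's alignments, midpoint-rooted, MPL-ultrametricised, root at relative
    age 1.0.  Returns ``None`` for tasks with < 3 species with data (the
    backbone exemplars pass through unchanged).  With bootstrap replicates,
    per-clade relative-age 2.5/97.5% quantiles populate the HPDs.
    """
    species = sorted(
        {
            r.species_id
            for aid in task.alignment_ids
            for r in alignments[aid]
            if r.species_id in set(task.species)
        }
    )
    if len(species) < 3:
        return None

    def mean_distance_matrix(column_rng=None) -> np.ndarray:
        idx = {sp: i for i, sp in enumerate(species)}
        total = np.zeros((len(species), len(species)))
        count = np.zeros((len(species), len(species)), dtype=int)
        for aid in task.alignment_ids:
            rows = {
                r.species_id: encode(r.residues)
                for r in alignments[aid]
                if r.species_id in idx
            }
            if len(rows) < 2:
                continue
            labels = sorted(rows)
            arrays = np.stack([rows[l] for l in labels])
            if column_rng is not None:
                cols = column_rng.integers(0, arrays.shape[1], size=arrays.shape[1])
                arrays = arrays[:, cols]
            for a in range(len(labels)):
                ua = arrays[a] != MISSING
                for b in range(a + 1, len(labels)):
                    usable = ua & (arrays[b] != MISSING)
                    m = int(usable.sum())
                    if m == 0:
                        continue
                    p = float((arrays[a, usable] != arrays[b, usable]).sum()) / m
                    if model == "JC69":
                        if p >= 0.75:
                            continue
                        dval = -0.75 * np.log1p(-4.0 * p / 3.0)
                    else:
                        dval = p
                    i, j = idx[labels[a]], idx[labels[b]]
                    total[i, j] += dval
                    total[j, i] += dval
                    count[i, j] += 1
                    count[j, i] += 1
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        np.fill_diagonal(mean, 0.0)
        if np.isnan(mean).any():
            # clock-based three-point fill-in, as in the backbone distances
            finite_max = float(np.nanmax(mean)) if np.isfinite(np.nanmax(mean)) else 1.0
            nan_mask = np.isnan(mean)
            n = mean.shape[0]
            for i in range(n):
                for j in range(i + 1, n):
                    if not nan_mask[i, j]:
                        continue
                    third = [
                        k
                        for k in range(n)
                        if k not in (i, j) and not nan_mask[i, k] and not nan_mask[j, k]
                    ]
                    est = min(
                        (max(mean[i, k], mean[j, k]) for k in third),
                        default=finite_max * 1.5,
                    )
                    mean[i, j] = mean[j, i] = est
            warnings.warn(
                f"task {task.task_id!r}: species pairs without shared data; "
                "distances imputed from the three-point bound",
                stacklevel=3,
            )
        return mean

    def build(dmat: np.ndarray) -> Chronogram:
        tree = nj_tree(species, dmat)
        tree = tree.midpoint_root()
        tree = mpl_ultrametricize(tree)
        root_age = tree.root.age
        if root_age <= 0:
            raise TreeError(f"task {task.task_id!r}: zero-depth clade tree")
        tree.scale(1.0 / root_age)
        tree.root.age = 1.0
        tree.set_lengths_from_ages()
        return tree

    tree = build(mean_distance_matrix())
    if bootstrap_replicates > 0:
        rng = np.random.default_rng(seed)
        clade_ages: dict[frozenset, list[float]] = {}
        for _ in range(bootstrap_replicates):
            try:
                rep = build(mean_distance_matrix(column_rng=rng))
            except (TreeError, ValueError):
                continue
            tipsets = rep.tipsets()
            for node, ts in tipsets.items():
                if not node.is_leaf:
                    clade_ages.setdefault(ts, []).append(node.age)
        tipsets = tree.tipsets()
        for node, ts in tipsets.items():
            ages = clade_ages.get(ts)
            if node.is_leaf or not ages:
                continue
            node.hpd_min = float(np.quantile(ages, 0.025))
            node.hpd_max = float(np.quantile(ages, 0.975))
            node.hpd_min = min(node.hpd_min, node.age)
            node.hpd_max = max(node.hpd_max, node.age)
    return tree


# -- rescale and graft --------------------------------------------------------

def rescale_subtree(subtree: Chronogram, task: CladeTask) -> Chronogram:
    """Scale a relative-time clade tree so the exemplar MRCA hits the backbone age.

    Every node age and HPD bound is multiplied by
    ``f = calibration_age / relative_age(exemplar MRCA)``; the exemplar MRCA's
    age is then pinned to the backbone age exactly (bit-for-bit).
    """
    present = set(subtree.tip_labels())
    anchors = [e for e in task.exemplars if e in present]
    if len(anchors) < 2:
        raise GraftError(
            f"task {task.task_id!r}: fewer than two exemplars in the clade tree"
        )
    out = subtree.copy()
    if out.root.age is None:
        out.compute_ages()
    mrca = out.mrca(anchors)
    if mrca.age <= 0:
        raise GraftError(f"task {task.task_id!r}: exemplar MRCA at age 0")
    f = task.calibration_age / mrca.age
    out.scale(f)
    mrca.age = task.calibration_age
    out.set_lengths_from_ages()
    return out


def graft_subtree(
    backbone: Chronogram,
    subtree: Chronogram,
    task: CladeTask,
    mode: str = "error",
    eps: float = 1e-6,
) -> Chronogram:
    """Replace the exemplar pair's backbone clade with a rescaled subtree.

    If the rescaled subtree root is older than the backbone exemplar-MRCA, the
    excess ``d`` is subtracted from the stem branch.  ``d >= stem`` raises
    :class:`GraftError` (default) or, in ``clamp`` mode, re-rescales the
    subtree so its root sits ``eps`` below the backbone parent node (loud
    diagnostic; the exemplar-MRCA anchor is sacrificed).
    """
    if mode not in ("error", "clamp"):
        raise ValueError(f"unknown graft mode {mode!r}")
    out = backbone.copy()
    if out.root.age is None:
        out.compute_ages()
    sub = subtree.copy()
    if sub.root.age is None:
        sub.compute_ages()
    anchors = [e for e in task.exemplars if e in set(out.tip_labels())]
    if len(anchors) < 2:
        raise GraftError(f"task {task.task_id!r}: exemplar pair not in backbone")
    target = out.mrca(anchors)
    d = sub.root.age - target.age
    if d < -1e-9:
        raise GraftError(
            f"task {task.task_id!r}: rescaled subtree root ({sub.root.age:.6g} Ma) "
            f"younger than the backbone node ({target.age:.6g} Ma); rescale first"
        )
    if target is out.root:
        sub.root.length = None
        sub.validate_dated()
        return sub
    parent = target.parent
    stem = parent.age - target.age
    if d > 1e-9:
        new_stem = parent.age - sub.root.age
        if new_stem <= 0:
            if mode == "error":
                raise GraftError(
                    f"task {task.task_id!r}: negative branch length — rescaled clade "
                    f"root ({sub.root.age:.6g} Ma) reaches past the backbone stem "
                    f"(parent at {parent.age:.6g} Ma, stem {stem:.6g} Ma)"
                )
            factor = (parent.age - eps) / sub.root.age
            warnings.warn(
                f"task {task.task_id!r}: clade root overshoots its stem; clamped "
                f"by factor {factor:.6g} (exemplar-MRCA age no longer anchored)",
                stacklevel=2,
            )
            sub.scale(factor)
            sub.set_lengths_from_ages()
    idx = parent.children.index(target)
    sub.root.parent = parent
    sub.root.length = parent.age - sub.root.age
    parent.children[idx] = sub.root
    out.set_lengths_from_ages()
    out.validate_dated()
    return out


def graft_all(
    backbone: Chronogram,
    subtrees: dict[str, Chronogram],
    tasks: Sequence[CladeTask],
    mode: str = "error",
) -> Chronogram:
    """Apply all grafts in descending backbone-age order.

    Tasks' exemplar clades must be disjoint in the backbone.  Any failing
    graft aborts with a :class:`GraftError` carrying a per-clade report; the
    partial result (grafts applied so far) is attached as ``partial``.
    """
    if backbone.root.age is None:
        backbone.compute_ages()
    by_id = {t.task_id: t for t in tasks}
    todo = []
    claimed: set[str] = set()
    for task in tasks:
        if task.task_id not in subtrees or subtrees[task.task_id] is None:
            continue
        anchors = [e for e in task.exemplars if e in set(backbone.tip_labels())]
        node = backbone.mrca(anchors)
        clade_tips = {t.label for t in node.leaves()}
        if clade_tips & claimed:
            raise GraftError(f"task {task.task_id!r} overlaps a previously claimed clade")
        claimed |= clade_tips
        todo.append((node.age, task.task_id))
    todo.sort(key=lambda t: (-t[0], t[1]))

    current = backbone
    done: list[str] = []
    for _, task_id in todo:
        task = by_id[task_id]
        rescaled = rescale_subtree(subtrees[task_id], task)
        try:
            current = graft_subtree(current, rescaled, task, mode=mode)
        except GraftError as exc:
            err = GraftError(f"graft failed at {task_id!r} after {done}: {exc}")
            err.partial = current
            err.completed = list(done)
            raise err from exc
        done.append(task_id)
    current.validate_dated()
    return current
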