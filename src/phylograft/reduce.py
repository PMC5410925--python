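"""Per-species sequence selection, orthology merging and profile alignment.

Homology clusters mined from public databases are heavily biased toward
well-studied species.  ``reduce_cluster`` trims each cluster to a fixed number
of representatives per species, preferring complete sequences: fewest IUPAC
ambiguity symbols first, then gap-free length closest to the species' median
length in that cluster, then seq_id for determinism.

Sister clusters of the same marker are detected with an all-versus-all
similarity comparison of their *seed* sequences (k-mer Jaccard stands in for
a BLAST search; an external similarity tool can be slotted in through the
aligner adapter) and merged by single linkage; their alignments are then
reconciled by profile alignment, a dynamic program over column frequency
profiles.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import AMBIGUITY_CODES, SequenceCluster, SequenceRecord

__all__ = [
    "ReductionPolicy",
    "SimilarityConfig",
    "ProfileScoring",
    "reduce_cluster",
    "seed_similarity",
    "merge_sister_clusters",
    "profile_align",
    "merge_cluster_group",
]


@dataclass(frozen=True)
class ReductionPolicy:
    per_species_keep: int = 1

    def __post_init__(self):
        if self.per_species_keep < 1:
            raise ValueError("per_species_keep must be >= 1")


@dataclass(frozen=True)
class SimilarityConfig:
    kmer_size: int = 8
    min_similarity: float = 0.5

    def __post_init__(self):
        if self.kmer_size < 2:
            raise ValueError("kmer_size must be >= 2")
        if not 0.0 <= self.min_similarity <= 1.0:
            raise ValueError("min_similarity must be in [0, 1]")


def reduce_cluster(cluster: SequenceCluster, policy: ReductionPolicy = ReductionPolicy()) -> SequenceCluster:
    """Keep at most ``per_species_keep`` sequences per species.

    Ranking within a species is lexicographic on (ambiguity count ascending,
    |gap-free length - species median gap-free length| ascending, seq_id
    ascending).  Idempotent: reducing a reduced cluster is a no-op.
    """
    kept: list[SequenceRecord] = []
    for species, records in cluster.by_species().items():
        median_len = statistics.median(r.ungapped_length for r in records)
        ranked = sorted(
            records,
            key=lambda r: (r.ambiguity_count, abs(r.ungapped_length - median_len), r.seq_id),
        )
        kept.extend(ranked[: policy.per_species_keep])
    kept.sort(key=lambda r: r.seq_id)
    return SequenceCluster(
        cluster_id=cluster.cluster_id,
        seed_id=cluster.seed_id,
        members=kept,
        aligned=cluster.aligned,
        seed_residues=cluster.seed_residues,
    )


def _kmer_set(residues: str, k: int) -> set[str]:
    s = residues.replace("-", "").upper()
    return {s[i : i + k] for i in range(len(s) - k + 1)}


def seed_similarity(a: str, b: str, config: SimilarityConfig = SimilarityConfig()) -> float:
    """Jaccard index of the two sequences' k-mer sets (gaps stripped)."""
    ka = _kmer_set(a, config.kmer_size)
    kb = _kmer_set(b, config.kmer_size)
    if not ka or not kb:
        warnings.warn("sequence shorter than kmer_size; similarity set to 0", stacklevel=2)
        return 0.0
    inter = len(ka & kb)
    union = len(ka | kb)
    return inter / union


def merge_sister_clusters(
    clusters: list[SequenceCluster],
    config: SimilarityConfig = SimilarityConfig(),
) -> list[list[SequenceCluster]]:
    """Single-linkage grouping of clusters by seed-sequence similarity.

    Two clusters land in one group iff a chain of seed pairs with similarity
    >= ``min_similarity`` connects them.  Groups are returned sorted by their
    lexicographically smallest member cluster_id, members sorted within.
    """
    for c in clusters:
        if c.seed_residues is None:
            raise ValueError(f"cluster {c.cluster_id!r} has no reachable seed sequence")
    n = len(clusters)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            sim = seed_similarity(clusters[i].seed_residues, clusters[j].seed_residues, config)
            if sim >= config.min_similarity:
                parent[find(i)] = find(j)
    groups: dict[int, list[SequenceCluster]] = {}
    for i, c in enumerate(clusters):
        groups.setdefault(find(i), []).append(c)
    out = [sorted(g, key=lambda c: c.cluster_id) for g in groups.values()]
    out.sort(key=lambda g: g[0].cluster_id)
    return out


# -- profile alignment --------------------------------------------------------

@dataclass(frozen=True)
class ProfileScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    terminal_gaps_free: bool = True


_RES = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_GAP = 4


def _profile(records: list[SequenceRecord]) -> np.ndarray:
    """Column frequency profile over {A, C, G, T, gap}.

    Ambiguity codes are counted as gaps for scoring purposes (they carry no
    residue identity the sum-of-pairs score could use).
    """
    length = len(records[0].residues)
    prof = np.zeros((length, 5))
    for rec in records:
        for i, ch in enumerate(rec.residues.upper()):
            prof[i, _RES.get(ch, _GAP)] += 1
    return prof / len(records)


def _column_scores(pa: np.ndarray, pb: np.ndarray, sc: ProfileScoring) -> np.ndarray:
    """Expected sum-of-pairs score for every column pair (m x n matrix)."""
    res_a, gap_a = pa[:, :4], pa[:, 4]
    res_b, gap_b = pb[:, :4], pb[:, 4]
    match = res_a @ res_b.T  # sum over identical residues
    tot = np.outer(res_a.sum(axis=1), res_b.sum(axis=1))
    mismatch = tot - match
    gap_pair = np.outer(res_a.sum(axis=1), gap_b) + np.outer(gap_a, res_b.sum(axis=1))
    return sc.match * match + sc.mismatch * mismatch + sc.gap * gap_pair


def profile_align(
    aln_a: list[SequenceRecord],
    aln_b: list[SequenceRecord],
    scoring: ProfileScoring = ProfileScoring(),
) -> list[SequenceRecord]:
    """Merge two alignments by global DP over their column profiles.

    Columns of each input keep their relative order; rows are never reordered
    and residues within a row are preserved.  Inserted columns are all-gap for
    the other profile's rows.  Traceback ties prefer aligning a column pair
    when its expected score is positive; otherwise a gap column is inserted
    (second input consumed first), so disagreeing columns stay unaligned.
    """
    for aln, name in ((aln_a, "first"), (aln_b, "second")):
        if not aln:
            raise ValueError(f"{name} alignment is empty")
        if len({len(r.residues) for r in aln}) != 1:
            raise ValueError(f"{name} input is not aligned (unequal row lengths)")
    pa, pb = _profile(aln_a), _profile(aln_b)
    m, n = len(pa), len(pb)
    S = _column_scores(pa, pb, scoring)
    gap_a = scoring.gap * pa[:, :4].sum(axis=1)  # cost of putting column i of A against gaps
    gap_b = scoring.gap * pb[:, :4].sum(axis=1)
    NEG = -np.inf
    F = np.full((m + 1, n + 1), NEG)
    F[0, 0] = 0.0
    if scoring.terminal_gaps_free:
        F[:, 0] = 0.0
        F[0, :] = 0.0
    else:
        F[1:, 0] = np.cumsum(gap_a)
        F[0, 1:] = np.cumsum(gap_b)
    for i in range(1, m + 1):
        diag = F[i - 1, :-1] + S[i - 1]
        up = F[i - 1, 1:] + gap_a[i - 1]
        for j in range(1, n + 1):
            F[i, j] = max(diag[j - 1], up[j - 1], F[i, j - 1] + gap_b[j - 1])
    # semi-global end: free terminal gaps means we may finish anywhere on the
    # last row/column and pad the rest
    if scoring.terminal_gaps_free:
        end_candidates = [(F[m, j], m, j) for j in range(n + 1)] + [
            (F[i, n], i, n) for i in range(m + 1)
        ]
        # prefer the endpoint with the most aligned columns on score ties
        best = max(end_candidates, key=lambda t: (t[0], t[1] + t[2]))
        _, ei, ej = best
    else:
        ei, ej = m, n
    ops: list[str] = []
    ops.extend("B" * (n - ej))  # trailing columns of B
    ops.extend("A" * (m - ei))
    i, j = ei, ej
    while i > 0 or j > 0:
        free = scoring.terminal_gaps_free and (i == 0 or j == 0)
        diag_ok = i > 0 and j > 0 and np.isclose(
            F[i, j], F[i - 1, j - 1] + S[i - 1, j - 1]
        )
        # on ties, align the columns only when they actually agree (positive
        # expected score); otherwise keep disagreeing columns unaligned by
        # inserting a gap column instead
        if diag_ok and S[i - 1, j - 1] > 0:
            ops.append("M")
            i, j = i - 1, j - 1
        elif j > 0 and np.isclose(F[i, j], F[i, j - 1] + (0.0 if free else gap_b[j - 1])):
            ops.append("B")
            j -= 1
        elif i > 0 and np.isclose(F[i, j], F[i - 1, j] + (0.0 if free else gap_a[i - 1])):
            ops.append("A")
            i -= 1
        elif diag_ok:
            ops.append("M")
            i, j = i - 1, j - 1
        elif i > 0:  # numerical fallback
            ops.append("A")
            i -= 1
        else:
            ops.append("B")
            j -= 1
    ops.reverse()

    def expand(row: str, keep: str) -> str:
        out = []
        k = 0
        for op in ops:
            if op == "M":
                out.append(row[k])
                k += 1
            elif op == keep:
                out.append(row[k])
                k += 1
            else:
                out.append("-")
        return "".join(out)

    merged: list[SequenceRecord] = []
    for rec in aln_a:
        merged.append(
            SequenceRecord(rec.seq_id, rec.species_id, expand(rec.residues, "A"), is_aligned=True)
        )
    for rec in aln_b:
        merged.append(
            SequenceRecord(rec.seq_id, rec.species_id, expand(rec.residues, "B"), is_aligned=True)
        )
    return merged


def merge_cluster_group(group: list[SequenceCluster], scoring: ProfileScoring = ProfileScoring()) -> SequenceCluster:
    """Fold a single-linkage group of aligned clusters into one by repeated
    profile alignment (in cluster_id order; id and seed from the first)."""
    for c in group:
        if not c.aligned:
            raise ValueError(f"cluster {c.cluster_id!r} must be aligned before merging")
    group = sorted(group, key=lambda c: c.cluster_id)
    records = list(group[0].members)
    for other in group[1:]:
        records = profile_align(records, list(other.members), scoring)
    return SequenceCluster(
        cluster_id=group[0].cluster_id,
        seed_id=group[0].seed_id,
        members=records,
        aligned=True,
        seed_residues=group[0].seed_residues,
    )
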