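"""Greedy knapsack assembly of a minimally sparse supermatrix.

Candidate alignments that pass a saturation filter (mean pairwise divergence)
are packed greedily: exemplar species are visited in ascending order of
participation (rarely sequenced species first), and for the focal species its
alignments are added in descending taxon coverage until the species reaches
its maximum marker count or candidates run out.  The maximum is a stopping
rule for the focal species only — other species may exceed it through shared
alignments.  Species that end below the minimum are dropped afterwards and
reported.  All ties break lexicographically, so the selection is a pure
function of the occupancy structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .distances import SaturationError, distance_matrix, pairwise_distance
from .model import SequenceRecord

__all__ = [
    "SupermatrixConfig",
    "SelectionResult",
    "MarkerGraphStats",
    "average_divergence",
    "assemble_supermatrix",
    "concatenate",
    "marker_graph_stats",
]


@dataclass(frozen=True)
class SupermatrixConfig:
    max_avg_divergence: float = 0.25
    min_markers_per_species: int = 1
    max_markers_per_species: int = 10

    def __post_init__(self):
        if self.min_markers_per_species < 1:
            raise ValueError("min_markers_per_species must be >= 1")
        if self.max_markers_per_species < self.min_markers_per_species:
            raise ValueError("max_markers_per_species must be >= min")


def average_divergence(alignment: Sequence[SequenceRecord], model: str = "JC69") -> float:
    """Mean of all finite pairwise distances in the alignment.

    Saturated (+inf) pairs are excluded from the mean; if every pair is
    saturated a :class:`SaturationError` is raised.
    """
    rows = {rec.seq_id: rec.residues for rec in alignment}
    if len(rows) < 2:
        raise ValueError("average_divergence needs >= 2 rows")
    labels = sorted(rows)
    finite: list[float] = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d = pairwise_distance(rows[labels[i]], rows[labels[j]], model=model)
            if math.isfinite(d):
                finite.append(d)
    if not finite:
        raise SaturationError("all pairs saturated")
    return sum(finite) / len(finite)


@dataclass
class SelectionResult:
    selected: list[str]                      # alignment ids in selection order
    retained_species: list[str]
    dropped_species: list[tuple[str, int]]   # (species, selected-count below min)
    dropped_alignments: list[str]            # selected but emptied by species drops
    counts: dict[str, int]                   # per-species selected-count (pre-drop)


def assemble_supermatrix(
    occupancy: dict[str, set[str]],
    exemplar_species: Sequence[str],
    config: SupermatrixConfig = SupermatrixConfig(),
) -> SelectionResult:
    """Run the greedy selection over an occupancy structure.

    ``occupancy`` maps alignment id -> species set; it must already be
    restricted to exemplar species and to alignments passing the divergence
    filter (see :func:`average_divergence`).
    """
    species = sorted(set(exemplar_species))
    occupancy = {aid: (members & set(species)) for aid, members in occupancy.items()}
    occupancy = {aid: members for aid, members in occupancy.items() if members}
    if not occupancy:
        raise ValueError("no candidate alignments survive the filters")
    participation = {sp: sum(1 for m in occupancy.values() if sp in m) for sp in species}
    coverage = {aid: len(m) for aid, m in occupancy.items()}

    order = sorted(species, key=lambda sp: (participation[sp], sp))
    selected: list[str] = []
    selected_set: set[str] = set()
    counts = {sp: 0 for sp in species}
    for focal in order:
        candidates = sorted(
            (aid for aid, m in occupancy.items() if focal in m),
            key=lambda aid: (-coverage[aid], aid),
        )
        for aid in candidates:
            if counts[focal] >= config.max_markers_per_species:
                break
            if aid in selected_set:
                continue
            selected.append(aid)
            selected_set.add(aid)
            for sp in occupancy[aid]:
                counts[sp] += 1

    dropped = sorted(
        (sp, counts[sp]) for sp in species if counts[sp] < config.min_markers_per_species
    )
    dropped_set = {sp for sp, _ in dropped}
    retained = [sp for sp in species if sp not in dropped_set]
    dropped_alignments = [
        aid for aid in selected if not (occupancy[aid] - dropped_set)
    ]
    selected = [aid for aid in selected if aid not in set(dropped_alignments)]
    return SelectionResult(
        selected=selected,
        retained_species=retained,
        dropped_species=dropped,
        dropped_alignments=dropped_alignments,
        counts=counts,
    )


def concatenate(
    alignments: dict[str, Sequence[SequenceRecord]],
    selection: Sequence[str],
    retained_species: Sequence[str],
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate the selected alignments into a '?'-padded matrix.

    Returns (matrix rows keyed by species, partitions as 1-based inclusive
    (name, start, end) in selection order).
    """
    if not selection:
        raise ValueError("empty selection")
    matrix = {sp: [] for sp in retained_species}
    partitions: list[tuple[str, int, int]] = []
    col = 0
    for aid in selection:
        aln = alignments[aid]
        rows: dict[str, str] = {}
        for rec in aln:
            if rec.species_id in rows:
                raise ValueError(f"duplicate species row {rec.species_id!r} in {aid!r}")
            rows[rec.species_id] = rec.residues
        length = len(next(iter(rows.values())))
        for sp in retained_species:
            matrix[sp].append(rows.get(sp, "?" * length))
        partitions.append((aid, col + 1, col + length))
        col += length
    return {sp: "".join(parts) for sp, parts in matrix.items()}, partitions


@dataclass(frozen=True)
class MarkerGraphStats:
    density: float
    mean_path_length: float       # averaged over pairs in the largest component
    n_components: int
    n_species: int
    n_edges: int


def marker_graph_stats(occupancy: dict[str, set[str]]) -> MarkerGraphStats:
    """Diagnostics on the marker graph: species connected iff they share a marker."""
    species = sorted(set().union(*occupancy.values()))
    if len(species) < 2:
        raise ValueError("marker graph needs >= 2 species")
    g = nx.Graph()
    g.add_nodes_from(species)
    for members in occupancy.values():
        mm = sorted(members)
        for i in range(len(mm)):
            for j in range(i + 1, len(mm)):
                g.add_edge(mm[i], mm[j])
    components = list(nx.connected_components(g))
    largest = max(components, key=len)
    sub = g.subgraph(largest)
    mean_path = (
        nx.average_shortest_path_length(sub) if len(largest) > 1 else 0.0
    )
    return MarkerGraphStats(
        density=nx.density(g),
        mean_path_length=mean_path,
        n_components=len(components),
        n_species=len(species),
        n_edges=g.number_of_edges(),
    )
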