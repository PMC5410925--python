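"""Dispersal events through time from an area-annotated chronogram.

A lineage whose reconstructed range gains an area along a branch records a
dispersal (range-expansion) event from each area of the parent's range into
the gained area; by default each source contributes weight 1/|parent range|
so a single range gain always counts one event in total (a flag switches to
one full event per source pair).  Events are smeared over 5-Ma time bins in
proportion to the fraction of the carrying branch that falls into each bin —
a branch lying half inside a bin deposits half the event there — and the
relative series divides each bin's count by the total branch length present
in the bin, correcting for the growing number of lineages toward the present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .trees import Chronogram, Node, TreeError

__all__ = ["DispersalEvent", "DispersalBinSeries", "infer_dispersal_events", "bin_dispersals"]


@dataclass(frozen=True)
class DispersalEvent:
    source: str
    gained: str
    weight: float          # in (0, 1]
    branch_start: float    # older end, Ma
    branch_end: float      # younger end, Ma

    def __post_init__(self):
        if not 0.0 < self.weight <= 1.0:
            raise ValueError("event weight must be in (0, 1]")
        if self.branch_start < self.branch_end:
            raise ValueError("branch start age must be >= end age")


def infer_dispersal_events(
    tree: Chronogram, split_sources: bool = True
) -> list[DispersalEvent]:
    """Enumerate range-gain events on every branch of an annotated chronogram.

    Every node must carry a non-empty ``area_set``.  For a branch whose child
    range holds areas absent from the parent range, each gained area ``b``
    yields events ``a -> b`` for every parent area ``a``, weighted
    ``1/|parent range|`` (or a full 1 per source with
    ``split_sources=False``).  Area losses are ignored.
    """
    if tree.root.age is None:
        tree.compute_ages()
    for node in tree.nodes():
        if not node.area_set:
            raise TreeError(f"node {node.label!r} is missing its area annotation")
    events: list[DispersalEvent] = []
    for node in tree.nodes():
        if node is tree.root:
            continue
        parent_range = node.parent.area_set
        gains = node.area_set - parent_range
        weight = 1.0 / len(parent_range) if split_sources else 1.0
        for gained in sorted(gains):
            for source in sorted(parent_range):
                events.append(
                    DispersalEvent(
                        source=source,
                        gained=gained,
                        weight=weight,
                        branch_start=node.parent.age,
                        branch_end=node.age,
                    )
                )
    return events


@dataclass
class DispersalBinSeries:
    """Per-bin dispersal counts; bins are anchored at 0 Ma, closed on the older edge."""

    bin_width: float
    bin_edges: list[tuple[float, float]]                  # (younger, older) per bin
    absolute: dict[tuple[str, str], list[float]]          # (source, gained) -> per-bin counts
    branch_length: list[float]                            # total tree length per bin
    relative: dict[tuple[str, str], list[float]] = field(default_factory=dict)

    def totals(self) -> dict[tuple[str, str], float]:
        return {pair: sum(series) for pair, series in self.absolute.items()}

    def to_rows(self) -> list[tuple]:
        rows = []
        for pair in sorted(self.absolute):
            for b, (lo, hi) in enumerate(self.bin_edges):
                rows.append(
                    (
                        f"{lo:g}-{hi:g}",
                        f"{pair[0]}->{pair[1]}",
                        self.absolute[pair][b],
                        self.branch_length[b],
                        self.relative[pair][b],
                    )
                )
        return rows


def _overlap(lo: float, hi: float, start: float, end: float) -> float:
    """Length of the intersection of [end, start] (branch) with [lo, hi] (bin)."""
    return max(0.0, min(hi, start) - max(lo, end))


def bin_dispersals(
    events: Sequence[DispersalEvent], tree: Chronogram, bin_width: float = 5.0
) -> DispersalBinSeries:
    """Distribute event weights over time bins by branch overlap.

    Each event's weight is split across bins proportionally to its branch's
    length overlap with the bin; per-bin branch-length totals are computed
    over *all* branches and the relative series is absolute / branch length
    (0/0 treated as 0).  Requires a dated tree (ages present).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if tree.root.age is None:
        tree.compute_ages()
    root_age = tree.root.age
    if root_age <= 0:
        raise TreeError("undated or zero-depth tree")
    n_bins = max(1, int(-(-root_age // bin_width)))  # ceil
    edges = [(i * bin_width, (i + 1) * bin_width) for i in range(n_bins)]

    branch_length = [0.0] * n_bins
    for node in tree.nodes():
        if node is tree.root:
            continue
        start, end = node.parent.age, node.age
        for b, (lo, hi) in enumerate(edges):
            branch_length[b] += _overlap(lo, hi, start, end)

    absolute: dict[tuple[str, str], list[float]] = {}
    for ev in events:
        pair = (ev.source, ev.gained)
        series = absolute.setdefault(pair, [0.0] * n_bins)
        span = ev.branch_start - ev.branch_end
        if span <= 0.0:
            # zero-length branch: the whole event lands in the bin holding its age
            b = min(int(ev.branch_end // bin_width), n_bins - 1)
            series[b] += ev.weight
            continue
        for b, (lo, hi) in enumerate(edges):
            frac = _overlap(lo, hi, ev.branch_start, ev.branch_end) / span
            if frac > 0.0:
                series[b] += ev.weight * frac

    relative = {
        pair: [
            (series[b] / branch_length[b] if branch_length[b] > 0 else 0.0)
            for b in range(n_bins)
        ]
        for pair, series in absolute.items()
    }
    return DispersalBinSeries(
        bin_width=bin_width,
        bin_edges=edges,
        absolute=absolute,
        branch_length=branch_length,
        relative=relative,
    )


def write_dispersal_tsv(series: DispersalBinSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin\tpair\tabsolute\tbranch_length\trelative\n")
        for row in series.to_rows():
            fh.write("\t".join(str(x) for x in row) + "\n")
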