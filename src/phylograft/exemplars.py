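"""Sparse-taxon filtering and per-genus exemplar selection.

The backbone tree is built from two *exemplar* species per genus, ideally a
pair whose divergence spans the genus root.  Within every candidate alignment
and genus, all congener pairwise distances are computed and the maximal pair
receives a vote of weight ``n - 1``, where ``n = k(k-1)/2`` is the number of
pairwise comparisons among the ``k`` congeners present: the most distal pair
among many comparisons is more likely to cross the genus root than a distal
pair found in a small alignment (two-species alignments carry zero weight).
The pair with the highest accumulated weight across alignments becomes the
genus' exemplars.  All ties break lexicographically by species_id so the
choice is independent of input order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from .distances import distance_matrix, pairwise_distance
from .model import SequenceCluster, SequenceRecord, TaxaTable

__all__ = [
    "SparsityFilter",
    "ExemplarResult",
    "pairwise_distance",
    "filter_sparse_taxa",
    "select_exemplars",
    "alignment_species",
]


@dataclass(frozen=True)
class SparsityFilter:
    """Minimum numbers of alignments a species must share with congeners and
    with members of other genera to be retained."""

    min_shared_intra: int = 1
    min_shared_inter: int = 1

    def __post_init__(self):
        if self.min_shared_intra < 0 or self.min_shared_inter < 0:
            raise ValueError("thresholds must be >= 0")


def alignment_species(alignment: Sequence[SequenceRecord]) -> set[str]:
    return {r.species_id for r in alignment}


def filter_sparse_taxa(
    alignments: dict[str, Sequence[SequenceRecord]],
    taxa_table: TaxaTable,
    filt: SparsityFilter = SparsityFilter(),
) -> tuple[set[str], list[tuple[str, str]]]:
    """Drop species that share too few markers with other taxa.

    A species is retained iff it co-occurs with at least one congener in
    >= ``min_shared_intra`` alignments AND with at least one non-congener in
    >= ``min_shared_inter`` alignments.  Monotypic genera are exempt from the
    intrageneric rule.  Returns (retained species, exclusion report of
    (species_id, failed-rule) pairs).
    """
    species_sets = {aid: alignment_species(aln) for aid, aln in alignments.items()}
    all_species = sorted(set().union(*species_sets.values()) if species_sets else set())
    genera = taxa_table.genera()
    retained: set[str] = set()
    report: list[tuple[str, str]] = []
    for sp in all_species:
        genus = taxa_table.genus_of[sp]
        monotypic = len(genera[genus]) == 1
        intra = sum(
            1
            for ss in species_sets.values()
            if sp in ss and any(taxa_table.genus_of[o] == genus for o in ss if o != sp)
        )
        inter = sum(
            1
            for ss in species_sets.values()
            if sp in ss and any(taxa_table.genus_of[o] != genus for o in ss)
        )
        if not monotypic and intra < filt.min_shared_intra:
            report.append((sp, "intra"))
        elif inter < filt.min_shared_inter:
            report.append((sp, "inter"))
        else:
            retained.add(sp)
    return retained, report


@dataclass(frozen=True)
class ExemplarResult:
    genus: str
    exemplars: tuple[str, ...]  # one or two species ids
    weight: float
    n_voting_alignments: int


def _species_rows(alignment: Sequence[SequenceRecord]) -> dict[str, str]:
    rows: dict[str, str] = {}
    for rec in alignment:
        if rec.species_id in rows:
            raise ValueError(
                f"more than one row for species {rec.species_id!r}; reduce the cluster first"
            )
        rows[rec.species_id] = rec.residues
    return rows


def select_exemplars(
    alignments: dict[str, Sequence[SequenceRecord]],
    taxa_table: TaxaTable,
    model: str = "JC69",
) -> dict[str, ExemplarResult]:
    """Pick the exemplar pair (or singleton) for every sequenced genus.

    Genera with exactly one sequenced species yield a singleton; with exactly
    two, that pair.  Genera with more use the weighted distal-pair vote.  A
    genus whose species never co-occur falls back to the lexicographically
    smallest pair with a warning.  Genera with zero sequenced species are
    omitted with a warning.
    """
    sequenced: dict[str, set[str]] = {}
    for aid, aln in alignments.items():
        for sp in alignment_species(aln):
            if sp not in taxa_table:
                raise KeyError(f"species {sp!r} not in taxa table")
            sequenced.setdefault(taxa_table.genus_of[sp], set()).add(sp)

    tallies: dict[str, dict[tuple[str, str], float]] = {}
    voters: dict[str, set[str]] = {}
    for aid in sorted(alignments):
        rows = _species_rows(alignments[aid])
        by_genus: dict[str, list[str]] = {}
        for sp in rows:
            by_genus.setdefault(taxa_table.genus_of[sp], []).append(sp)
        for genus, members in by_genus.items():
            if len(members) < 2:
                continue
            members.sort()
            k = len(members)
            n_comparisons = k * (k - 1) // 2
            weight = n_comparisons - 1
            best_pair: Optional[tuple[str, str]] = None
            best_d = -math.inf
            for i in range(k):
                for j in range(i + 1, k):
                    d = pairwise_distance(rows[members[i]], rows[members[j]], model=model)
                    if math.isinf(d):
                        d = math.inf  # saturated pairs are maximally distal
                    pair = (members[i], members[j])
                    if d > best_d or (d == best_d and pair < best_pair):
                        best_d, best_pair = d, pair
            tallies.setdefault(genus, {})
            tallies[genus][best_pair] = tallies[genus].get(best_pair, 0.0) + weight
            voters.setdefault(genus, set()).add(aid)

    out: dict[str, ExemplarResult] = {}
    for genus in sorted(taxa_table.genera()):
        present = sorted(sequenced.get(genus, ()))
        if not present:
            warnings.warn(f"genus {genus!r} has no sequenced species; omitted", stacklevel=2)
            continue
        if len(present) == 1:
            out[genus] = ExemplarResult(genus, (present[0],), 0.0, 0)
            continue
        if len(present) == 2:
            out[genus] = ExemplarResult(
                genus, tuple(present), 0.0, len(voters.get(genus, ()))
            )
            continue
        genus_tallies = tallies.get(genus, {})
        if not genus_tallies:
            warnings.warn(
                f"genus {genus!r}: no alignment holds two congeners; "
                "falling back to lexicographically smallest pair",
                stacklevel=2,
            )
            out[genus] = ExemplarResult(genus, (present[0], present[1]), 0.0, 0)
            continue
        best_pair = min(
            genus_tallies, key=lambda p: (-genus_tallies[p], p)
        )
        out[genus] = ExemplarResult(
            genus, best_pair, genus_tallies[best_pair], len(voters[genus])
        )
    return out


def write_exemplar_report(results: dict[str, ExemplarResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("genus\texemplar_1\texemplar_2\tweight\tn_voting_alignments\n")
        for genus in sorted(results):
            r = results[genus]
            ex2 = r.exemplars[1] if len(r.exemplars) > 1 else ""
            fh.write(f"{genus}\t{r.exemplars[0]}\t{ex2}\t{format(r.weight, 'g')}\t{r.n_voting_alignments}\n")
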