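"""Shared domain types: sequences, clusters, taxa tables, fossil calibrations."""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "IUPAC_DNA",
    "AMBIGUITY_CODES",
    "SequenceRecord",
    "SequenceCluster",
    "TaxaTable",
    "FossilCalibration",
]

#: characters accepted in DNA residue strings
IUPAC_DNA = frozenset("ACGTURYSWKMBDHVN-?")
#: anything that is not an unambiguous base or a gap counts as an ambiguity symbol
AMBIGUITY_CODES = frozenset("URYSWKMBDHVN?")


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence tied to a species.

    ``residues`` may contain gaps when the record sits inside an alignment
    (``is_aligned=True``); length bookkeeping for selection criteria is always
    gap-free.
    """

    seq_id: str
    species_id: str
    residues: str
    is_aligned: bool = False

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"empty sequence for {self.seq_id!r}")
        bad = set(self.residues.upper()) - IUPAC_DNA
        if bad:
            raise ValueError(f"non-IUPAC characters {sorted(bad)} in {self.seq_id!r}")

    @property
    def ungapped_length(self) -> int:
        return sum(1 for c in self.residues if c != "-")

    @property
    def ambiguity_count(self) -> int:
        return sum(1 for c in self.residues.upper() if c in AMBIGUITY_CODES)


@dataclass
class SequenceCluster:
    """Putatively homologous sequences grouped around a seed sequence."""

    cluster_id: str
    seed_id: str
    members: list[SequenceRecord]
    aligned: bool = False
    #: gap-free residues of the seed, kept even if the seed member is later
    #: dropped by per-species reduction (merging needs it)
    seed_residues: Optional[str] = None

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"cluster {self.cluster_id!r} has no members")
        ids = [m.seq_id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate seq_id(s) {dupes} in cluster {self.cluster_id!r}")
        if self.aligned:
            lengths = {len(m.residues) for m in self.members}
            if len(lengths) > 1:
                raise ValueError(f"aligned cluster {self.cluster_id!r} has unequal row lengths")
        if self.seed_residues is None:
            for m in self.members:
                if m.seq_id == self.seed_id:
                    self.seed_residues = m.residues.replace("-", "")
                    break

    @property
    def species_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(m.species_id, None)
        return list(seen)

    def by_species(self) -> dict[str, list[SequenceRecord]]:
        out: dict[str, list[SequenceRecord]] = {}
        for m in self.members:
            out.setdefault(m.species_id, []).append(m)
        return out

    @property
    def alignment_length(self) -> int:
        if not self.aligned:
            raise ValueError(f"cluster {self.cluster_id!r} is not aligned")
        return len(self.members[0].residues)


class TaxaTable:
    """Species -> genus (and optional higher ranks) mapping.

    The taxonomic frame for exemplar selection and clade decomposition.
    Species ids must be unique and every species must carry a non-empty genus,
    so genus membership partitions the species set.
    """

    def __init__(self, rows: Iterable[tuple]):
        self.species_name: dict[str, str] = {}
        self.genus_of: dict[str, str] = {}
        self.higher_ranks: dict[str, dict[str, str]] = {}
        for row in rows:
            species_id, species_name, genus = row[0], row[1], row[2]
            ranks = row[3] if len(row) > 3 and row[3] else {}
            if species_id in self.genus_of:
                raise ValueError(f"duplicate species_id {species_id!r}")
            if not genus:
                raise ValueError(f"species {species_id!r} has an empty genus")
            self.species_name[species_id] = species_name
            self.genus_of[species_id] = genus
            if ranks:
                self.higher_ranks[species_id] = dict(ranks)
        if not self.genus_of:
            raise ValueError("empty taxa table")

    @property
    def species(self) -> list[str]:
        return list(self.genus_of)

    def genera(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sp, g in self.genus_of.items():
            out.setdefault(g, []).append(sp)
        return out

    def congeners(self, species_id: str) -> list[str]:
        g = self.genus_of[species_id]
        return [s for s in self.genus_of if self.genus_of[s] == g and s != species_id]

    def __len__(self) -> int:
        return len(self.genus_of)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self.genus_of


@dataclass(frozen=True)
class FossilCalibration:
    """A minimum (and optional maximum) age constraint on the MRCA of >= 2 taxa."""

    calib_id: str
    mrca_taxa: tuple[str, ...]
    min_age: float
    max_age: Optional[float] = None

    def __post_init__(self):
        if len(self.mrca_taxa) < 2:
            raise ValueError(f"calibration {self.calib_id!r} needs >= 2 taxa")
        if self.min_age <= 0:
            raise ValueError(f"calibration {self.calib_id!r} min_age must be > 0")
        if self.max_age is not None and self.max_age < self.min_age:
            raise ValueError(f"calibration {self.calib_id!r} has max_age < min_age")
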