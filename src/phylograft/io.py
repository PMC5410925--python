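"""Readers and writers for the standard formats the pipeline touches.

File conventions (the upstream literature never fixes formats, so these are
this package's documented contracts):

* **FASTA clusters** — one file per homology cluster; the header encodes both
  ids as ``seq_id|species_id`` by default.  The first record is taken as the
  seed sequence unless a header carries a ``*`` suffix on the seq_id.
* **Taxa table (TSV)** — columns ``species_id``, ``species_name``, ``genus``
  plus any further columns treated as ordered higher ranks.
* **Fossil table (TSV)** — ``calib_id``, ``taxa`` (comma-separated, >= 2),
  ``min_age``, ``max_age`` (may be empty).
* **Supermatrix** — relaxed PHYLIP with a RAxML-style partition sidecar, or a
  NEXUS file with a ``sets`` block.  Partition coordinates are 1-based
  inclusive; missing cells are ``?``.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .model import FossilCalibration, SequenceCluster, SequenceRecord, TaxaTable
from .trees import Chronogram

__all__ = [
    "read_fasta_cluster",
    "write_fasta_cluster",
    "read_taxa_table",
    "write_taxa_table",
    "read_fossil_table",
    "write_fossil_table",
    "read_tree",
    "write_tree",
    "write_supermatrix",
    "read_occupancy",
    "write_occupancy",
]

HeaderRule = Callable[[str], tuple[str, str]]


def _pipe_rule(header: str) -> tuple[str, str]:
    seq_id, sep, species_id = header.partition("|")
    if not sep or not species_id:
        raise ValueError(f"header {header!r} does not match 'seqid|speciesid'")
    return seq_id, species_id


def read_fasta_cluster(
    path: Union[str, Path],
    species_id_rule: Optional[HeaderRule] = None,
    cluster_id: Optional[str] = None,
) -> SequenceCluster:
    """Read one cluster from FASTA.

    The aligned flag is set when all sequences have equal length and any gap
    characters are present.  A trailing ``*`` on a seq_id marks the seed;
    otherwise the first record is the seed.
    """
    path = Path(path)
    rule = species_id_rule or _pipe_rule
    members: list[SequenceRecord] = []
    seed_id: Optional[str] = None
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, species_id = rule(rec.id)
        if seq_id.endswith("*"):
            seq_id = seq_id[:-1]
            seed_id = seq_id
        members.append(
            SequenceRecord(seq_id=seq_id, species_id=species_id, residues=str(rec.seq).upper())
        )
    if not members:
        raise ValueError(f"{path}: empty FASTA file")
    lengths = {len(m.residues) for m in members}
    gapped = any("-" in m.residues for m in members)
    aligned = len(lengths) == 1 and gapped
    if seed_id is None:
        seed_id = members[0].seq_id
    if aligned:
        members = [
            SequenceRecord(m.seq_id, m.species_id, m.residues, is_aligned=True) for m in members
        ]
    return SequenceCluster(
        cluster_id=cluster_id or path.stem,
        seed_id=seed_id,
        members=members,
        aligned=aligned,
    )


def write_fasta_cluster(cluster: SequenceCluster, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for m in cluster.members:
            star = "*" if m.seq_id == cluster.seed_id else ""
            fh.write(f">{m.seq_id}{star}|{m.species_id}\n{m.residues}\n")


# -- TSV tables --------------------------------------------------------------

def read_taxa_table(path: Union[str, Path]) -> TaxaTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["species_id", "species_name", "genus"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"taxa table missing column {col!r}")
    rank_cols = [c for c in df.columns if c not in required]
    rows = []
    for _, r in df.iterrows():
        ranks = {c: r[c] for c in rank_cols if r[c]}
        rows.append((r["species_id"], r["species_name"], r["genus"], ranks))
    return TaxaTable(rows)


def write_taxa_table(table: TaxaTable, path: Union[str, Path]) -> None:
    rank_cols: list[str] = []
    for ranks in table.higher_ranks.values():
        for c in ranks:
            if c not in rank_cols:
                rank_cols.append(c)
    with open(path, "w") as fh:
        fh.write("\t".join(["species_id", "species_name", "genus"] + rank_cols) + "\n")
        for sp in table.species:
            ranks = table.higher_ranks.get(sp, {})
            row = [sp, table.species_name[sp], table.genus_of[sp]]
            row += [ranks.get(c, "") for c in rank_cols]
            fh.write("\t".join(row) + "\n")


def read_fossil_table(path: Union[str, Path]) -> list[FossilCalibration]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        max_age = r.get("max_age")
        max_age = float(max_age) if max_age not in (None, "") and pd.notna(max_age) else None
        out.append(
            FossilCalibration(
                calib_id=r["calib_id"],
                mrca_taxa=tuple(t.strip() for t in r["taxa"].split(",") if t.strip()),
                min_age=float(r["min_age"]),
                max_age=max_age,
            )
        )
    return out


def write_fossil_table(calibrations: Sequence[FossilCalibration], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("calib_id\ttaxa\tmin_age\tmax_age\n")
        for c in calibrations:
            max_age = "" if c.max_age is None else format(c.max_age, ".12g")
            fh.write(
                f"{c.calib_id}\t{','.join(c.mrca_taxa)}\t{format(c.min_age, '.12g')}\t{max_age}\n"
            )


# -- trees --------------------------------------------------------------------

def read_tree(path: Union[str, Path], dialect: str = "plain", **kwargs) -> Chronogram:
    """Read a Newick tree.

    dialect: ``plain`` | ``support`` (internal labels are support values) |
    ``annotated`` (bracket comments carry support/HPD/areas).
    """
    if dialect not in ("plain", "support", "annotated"):
        raise ValueError(f"unknown Newick dialect {dialect!r}")
    return Chronogram.read(path, support_labels=(dialect == "support"), **kwargs)


def write_tree(tree: Chronogram, path: Union[str, Path], dialect: str = "annotated") -> None:
    tree.write(path, annotations=(dialect == "annotated"), support_as_label=(dialect == "support"))


# -- supermatrix --------------------------------------------------------------

_SANITIZE = re.compile(r"[\s():;,\[\]']")


def sanitize_label(label: str) -> str:
    return _SANITIZE.sub("_", label)


def _check_partitions(partitions: Sequence[tuple[str, int, int]], ncol: int) -> None:
    covered = 0
    prev_end = 0
    for name, start, end in partitions:
        if start != prev_end + 1 or end < start:
            raise ValueError(
                f"partitions must tile the columns; {name!r} spans {start}-{end} "
                f"after column {prev_end}"
            )
        prev_end = end
        covered += end - start + 1
    if covered != ncol:
        raise ValueError(
            f"partitions must tile the columns: they cover {covered}, matrix has {ncol}"
        )


def write_supermatrix(
    matrix: dict[str, str],
    partitions: Sequence[tuple[str, int, int]],
    path: Union[str, Path],
    fmt: str = "phylip",
) -> None:
    """Write a concatenated matrix with its partition definition.

    ``matrix`` maps taxon label to the full concatenated row (``?`` for
    missing cells).  ``partitions`` are (name, start, end), 1-based inclusive.
    ``phylip`` emits relaxed PHYLIP plus a ``<path>.partitions`` sidecar;
    ``nexus`` emits a single NEXUS file with a charset per partition.
    """
    if not matrix:
        raise ValueError("empty supermatrix")
    ncols = {len(row) for row in matrix.values()}
    if len(ncols) != 1:
        raise ValueError("supermatrix rows have unequal lengths")
    ncol = ncols.pop()
    _check_partitions(partitions, ncol)
    labels = {}
    for taxon in matrix:
        clean = sanitize_label(taxon)
        if clean in labels:
            raise ValueError(f"taxon label collision after sanitization: {clean!r}")
        labels[clean] = taxon
    path = Path(path)
    if fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(matrix)} {ncol}\n")
            for clean in sorted(labels):
                fh.write(f"{clean}  {matrix[labels[clean]]}\n")
        with open(path.with_suffix(path.suffix + ".partitions"), "w") as fh:
            for name, start, end in partitions:
                fh.write(f"DNA, {sanitize_label(name)} = {start}-{end}\n")
    elif fmt == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\nbegin data;\n")
            fh.write(f"  dimensions ntax={len(matrix)} nchar={ncol};\n")
            fh.write("  format datatype=dna missing=? gap=-;\n  matrix\n")
            for clean in sorted(labels):
                fh.write(f"    {clean}  {matrix[labels[clean]]}\n")
            fh.write("  ;\nend;\nbegin sets;\n")
            for name, start, end in partitions:
                fh.write(f"  charset {sanitize_label(name)} = {start}-{end};\n")
            fh.write("end;\n")
    else:
        raise ValueError(f"unknown supermatrix format {fmt!r}")


# -- occupancy ----------------------------------------------------------------

def write_occupancy(
    occupancy: dict[str, set[str]], species: Sequence[str], path: Union[str, Path]
) -> None:
    """``occupancy`` maps alignment/cluster id -> set of species present."""
    aln_ids = sorted(occupancy)
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(aln_ids) + "\n")
        for sp in species:
            row = ["1" if sp in occupancy[a] else "0" for a in aln_ids]
            fh.write(sp + "\t" + "\t".join(row) + "\n")


def read_occupancy(path: Union[str, Path]) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {aln: set(df.index[df[aln] == 1]) for aln in df.columns}
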