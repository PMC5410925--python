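"""Stage-wise orchestration of the divide-and-graft pipeline.

Each stage reads documented files from a working directory, writes its
outputs plus a ``<stage>.manifest.json`` recording the configuration and
input hashes, and is idempotent: re-running with unchanged inputs and
configuration reproduces byte-identical outputs.  The stage layout exists so
external-engine adapters can be slotted between stages by hand — e.g. a
treePL run replacing ``backbone_dated.nwk`` before ``decompose``.

Stage order:
``replicate`` -> ``reduce`` -> ``merge`` -> ``exemplars`` -> ``supermatrix``
-> ``bbinfer`` -> ``bbdate`` -> ``decompose`` -> ``cladeinfer`` -> ``graft``;
``treedist`` and ``dispersal`` are stand-alone analyses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import io as gio
from .backbone import bootstrap_support, date_tree, majority_consensus, nj_from_matrix
from .exemplars import SparsityFilter, filter_sparse_taxa, select_exemplars, write_exemplar_report
from .graft import CladeTask, build_clade_tasks, graft_all, infer_clade_tree
from .model import SequenceCluster, SequenceRecord, TaxaTable
from .reduce import (
    ReductionPolicy,
    SimilarityConfig,
    merge_cluster_group,
    merge_sister_clusters,
    reduce_cluster,
)
from .replicate import BDParams, ReplicateBundle, generate_bundle
from .substmodels import SubstModelSpec
from .supermatrix import SupermatrixConfig, assemble_supermatrix, average_divergence, concatenate
from .trees import Chronogram

__all__ = ["PipelineConfig", "Workspace", "run", "STAGES", "recover_tree"]

STAGES = (
    "replicate",
    "reduce",
    "merge",
    "exemplars",
    "supermatrix",
    "bbinfer",
    "bbdate",
    "decompose",
    "cladeinfer",
    "graft",
)


@dataclass
class PipelineConfig:
    seed: int = 1
    # replicate stage (the stated validation world)
    n_species: int = 40
    genus_sizes: tuple[int, ...] = (10, 8, 6, 5, 4, 3, 2, 2)
    birth: float = 0.3
    death: float = 0.1
    n_clusters: int = 6
    cluster_length: int = 1500
    clock_rate: float = 0.005
    occupancy_prob: float = 0.75
    # reduction / merging
    per_species_keep: int = 1
    kmer_size: int = 8
    min_similarity: float = 0.5
    # exemplars
    min_shared_intra: int = 1
    min_shared_inter: int = 1
    distance_model: str = "JC69"
    # supermatrix
    max_avg_divergence: float = 0.25
    min_markers_per_species: int = 1
    max_markers_per_species: int = 6
    # backbone
    bootstrap_replicates: int = 100
    # grafting
    graft_mode: str = "clamp"
    clade_bootstrap: int = 0
    max_clade_size: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "genus_sizes" in data:
            data["genus_sizes"] = tuple(data["genus_sizes"])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    pass


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class Workspace:
    """Fixed file layout inside one working directory."""

    def __init__(self, root):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def path(self, name: str) -> Path:
        return self.root / name

    def cluster_dir(self, stage: str) -> Path:
        d = self.root / stage
        d.mkdir(exist_ok=True)
        return d

    def read_clusters(self, stage: str) -> list[SequenceCluster]:
        d = self.root / stage
        if not d.is_dir():
            raise StageError(f"missing {d.name}/; run the upstream stage first")
        clusters = []
        for path in sorted(d.glob("*.fasta")):
            cluster = gio.read_fasta_cluster(path)
            # equal-length gap-free clusters (synthetic data) are alignments too
            if not cluster.aligned and len({len(m.residues) for m in cluster.members}) == 1:
                cluster = SequenceCluster(
                    cluster.cluster_id,
                    cluster.seed_id,
                    [SequenceRecord(m.seq_id, m.species_id, m.residues, True) for m in cluster.members],
                    aligned=True,
                    seed_residues=cluster.seed_residues,
                )
            clusters.append(cluster)
        if not clusters:
            raise StageError(f"no clusters under {d}/")
        return clusters

    def require(self, name: str, producer: str) -> Path:
        path = self.path(name)
        if not path.exists():
            raise StageError(f"missing {name}; run stage {producer!r} first")
        return path

    def manifest(self, stage: str, config: PipelineConfig, inputs: Sequence[Path], outputs: Sequence[Path]) -> None:
        data = {
            "stage": stage,
            "config": config.to_dict(),
            "inputs": {p.name: _sha(p) for p in inputs if p.is_file()},
            "outputs": [p.name for p in outputs],
        }
        with open(self.root / f"{stage}.manifest.json", "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)


# -- stages -------------------------------------------------------------------

def stage_replicate(ws: Workspace, cfg: PipelineConfig) -> ReplicateBundle:
    """Generate the synthetic truth: tree, taxa, clusters, fossils."""
    bundle = generate_bundle(
        seed=cfg.seed,
        n_species=cfg.n_species,
        genus_sizes=cfg.genus_sizes,
        bd=BDParams(birth=cfg.birth, death=cfg.death),
        n_clusters=cfg.n_clusters,
        length=cfg.cluster_length,
        rate=cfg.clock_rate,
        occupancy_prob=cfg.occupancy_prob,
    )
    bundle.tree.write(ws.path("truth.nwk"))
    gio.write_taxa_table(bundle.taxa_table, ws.path("taxa.tsv"))
    cdir = ws.cluster_dir("clusters")
    for cluster in bundle.clusters:
        gio.write_fasta_cluster(cluster, cdir / f"{cluster.cluster_id}.fasta")
    gio.write_occupancy(bundle.occupancy, bundle.taxa_table.species, ws.path("occupancy.tsv"))
    gio.write_fossil_table(truth_calibrations(bundle), ws.path("fossils.tsv"))
    ws.manifest("replicate", cfg, [], [ws.path("truth.nwk"), ws.path("taxa.tsv")])
    return bundle


def truth_calibrations(bundle: ReplicateBundle):
    """Fossil table derived from the simulated truth.

    Minimum-age constraints on the root and the two oldest internal nodes at
    which *whole genera* diverge (each child subtends at least one complete
    genus).  Such nodes keep their identity when the tree is subsampled to
    two exemplars per genus, mirroring how real fossil tables calibrate
    genus- or family-level splits rather than arbitrary nodes.
    """
    from .model import FossilCalibration

    tree = bundle.tree
    if tree.root.age is None:
        tree.compute_ages()
    genera = bundle.taxa_table.genera()
    tipsets = tree.tipsets()

    def genus_split(node) -> bool:
        return all(
            any(set(members) <= tipsets[c] for members in genera.values())
            for c in node.children
        )

    internals = sorted(
        (n for n in tree.nodes() if not n.is_leaf and (n is tree.root or genus_split(n))),
        key=lambda n: -n.age,
    )
    chosen = internals[:3]
    calibs = []
    for i, node in enumerate(chosen):
        # all descendants, so the constraint lands on the equivalent node of
        # any tree sampled from a subset of the species (e.g. the backbone)
        taxa = tuple(sorted(l.label for l in node.leaves()))
        calibs.append(
            FossilCalibration(
                calib_id=f"fossil{i + 1}",
                mrca_taxa=taxa,
                min_age=node.age,
            )
        )
    return calibs


def stage_reduce(ws: Workspace, cfg: PipelineConfig) -> None:
    clusters = ws.read_clusters("clusters")
    policy = ReductionPolicy(per_species_keep=cfg.per_species_keep)
    outdir = ws.cluster_dir("reduced")
    outputs = []
    for cluster in clusters:
        red = reduce_cluster(cluster, policy)
        path = outdir / f"{red.cluster_id}.fasta"
        gio.write_fasta_cluster(red, path)
        outputs.append(path)
    ws.manifest("reduce", cfg, sorted(ws.path("clusters").glob("*.fasta")), outputs)


def stage_merge(ws: Workspace, cfg: PipelineConfig) -> None:
    clusters = ws.read_clusters("reduced")
    config = SimilarityConfig(kmer_size=cfg.kmer_size, min_similarity=cfg.min_similarity)
    groups = merge_sister_clusters(clusters, config)
    outdir = ws.cluster_dir("merged")
    outputs = []
    for group in groups:
        merged = group[0] if len(group) == 1 else merge_cluster_group(group)
        path = outdir / f"{merged.cluster_id}.fasta"
        gio.write_fasta_cluster(merged, path)
        outputs.append(path)
    ws.manifest("merge", cfg, sorted(ws.path("reduced").glob("*.fasta")), outputs)


def _alignments(clusters: list[SequenceCluster]) -> dict[str, list[SequenceRecord]]:
    return {c.cluster_id: list(c.members) for c in clusters}


def stage_exemplars(ws: Workspace, cfg: PipelineConfig) -> None:
    taxa = gio.read_taxa_table(ws.require("taxa.tsv", "replicate"))
    alignments = _alignments(ws.read_clusters("merged"))
    filt = SparsityFilter(cfg.min_shared_intra, cfg.min_shared_inter)
    retained, report = filter_sparse_taxa(alignments, taxa, filt)
    filtered = {
        aid: [r for r in aln if r.species_id in retained]
        for aid, aln in alignments.items()
    }
    filtered = {aid: aln for aid, aln in filtered.items() if aln}
    results = select_exemplars(filtered, taxa, model=cfg.distance_model)
    write_exemplar_report(results, ws.path("exemplars.tsv"))
    with open(ws.path("sparse_exclusions.tsv"), "w") as fh:
        fh.write("species_id\tfailed_rule\n")
        for sp, rule in report:
            fh.write(f"{sp}\t{rule}\n")
    ws.manifest("exemplars", cfg, [ws.path("taxa.tsv")], [ws.path("exemplars.tsv")])


def read_exemplars(path) -> dict[str, tuple[str, ...]]:
    out = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            genus, ex1, ex2, _w, _n = line.rstrip("\n").split("\t")
            out[genus] = (ex1, ex2) if ex2 else (ex1,)
    return out


def stage_supermatrix(ws: Workspace, cfg: PipelineConfig) -> None:
    exemplars = read_exemplars(ws.require("exemplars.tsv", "exemplars"))
    exemplar_species = sorted({sp for pair in exemplars.values() for sp in pair})
    alignments = _alignments(ws.read_clusters("merged"))
    config = SupermatrixConfig(
        max_avg_divergence=cfg.max_avg_divergence,
        min_markers_per_species=cfg.min_markers_per_species,
        max_markers_per_species=cfg.max_markers_per_species,
    )
    candidates = {}
    for aid, aln in alignments.items():
        rows = [r for r in aln if r.species_id in exemplar_species]
        if len(rows) < 2:
            continue
        if average_divergence(rows, model=cfg.distance_model) <= config.max_avg_divergence:
            candidates[aid] = rows
    occupancy = {aid: {r.species_id for r in rows} for aid, rows in candidates.items()}
    result = assemble_supermatrix(occupancy, exemplar_species, config)
    matrix, partitions = concatenate(candidates, result.selected, result.retained_species)
    gio.write_supermatrix(matrix, partitions, ws.path("supermatrix.phy"), fmt="phylip")
    with open(ws.path("selection.tsv"), "w") as fh:
        fh.write("alignment\torder\n")
        for i, aid in enumerate(result.selected):
            fh.write(f"{aid}\t{i + 1}\n")
        for sp, count in result.dropped_species:
            fh.write(f"#dropped\t{sp} (markers={count})\n")
    ws.manifest("supermatrix", cfg, [ws.path("exemplars.tsv")], [ws.path("supermatrix.phy")])


def _read_phylip(path: Path) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    with open(path) as fh:
        header = fh.readline()
        matrix = {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            matrix[name] = seq.strip()
    partitions = []
    sidecar = path.with_suffix(path.suffix + ".partitions")
    with open(sidecar) as fh:
        for line in fh:
            _, rest = line.split(",", 1)
            name, span = rest.split("=")
            start, end = span.strip().split("-")
            partitions.append((name.strip(), int(start), int(end)))
    return matrix, partitions


def stage_bbinfer(ws: Workspace, cfg: PipelineConfig) -> None:
    matrix, partitions = _read_phylip(ws.require("supermatrix.phy", "supermatrix"))
    tree = bootstrap_support(
        matrix, partitions, replicates=cfg.bootstrap_replicates, seed=cfg.seed,
        model=cfg.distance_model, missing="impute",
    )
    tree.write(ws.path("backbone.nwk"))
    ws.manifest("bbinfer", cfg, [ws.path("supermatrix.phy")], [ws.path("backbone.nwk")])


def stage_bbdate(ws: Workspace, cfg: PipelineConfig) -> None:
    tree = Chronogram.read(ws.require("backbone.nwk", "bbinfer"))
    calibrations = gio.read_fossil_table(ws.require("fossils.tsv", "replicate"))
    rooted = tree.midpoint_root()
    dated = date_tree(rooted, calibrations, restrict=True)
    dated.write(ws.path("backbone_dated.nwk"))
    ws.manifest("bbdate", cfg, [ws.path("backbone.nwk"), ws.path("fossils.tsv")], [ws.path("backbone_dated.nwk")])


def stage_decompose(ws: Workspace, cfg: PipelineConfig) -> list[CladeTask]:
    dated = Chronogram.read(ws.require("backbone_dated.nwk", "bbdate"), require_ultrametric=True, ultrametric_tol=1e-3)
    taxa = gio.read_taxa_table(ws.require("taxa.tsv", "replicate"))
    alignments = _alignments(ws.read_clusters("merged"))
    tasks = build_clade_tasks(dated, dated, taxa, alignments)
    for task in tasks:
        if len(task.species) > cfg.max_clade_size:
            import warnings

            warnings.warn(
                f"task {task.task_id} exceeds max_clade_size "
                f"({len(task.species)} > {cfg.max_clade_size}); proceeding",
                stacklevel=2,
            )
    with open(ws.path("tasks.tsv"), "w") as fh:
        fh.write("task_id\tgenera\tn_species\tspecies\texemplars\tcalibration_age\thpd\talignments\n")
        for task in tasks:
            hpd = f"{task.hpd[0]:.12g},{task.hpd[1]:.12g}" if task.hpd else ""
            fh.write(
                "\t".join(
                    [
                        task.task_id,
                        ",".join(task.genera),
                        str(len(task.species)),
                        ",".join(task.species),
                        ",".join(task.exemplars),
                        format(task.calibration_age, ".12g"),
                        hpd,
                        ",".join(task.alignment_ids),
                    ]
                )
                + "\n"
            )
    ws.manifest("decompose", cfg, [ws.path("backbone_dated.nwk")], [ws.path("tasks.tsv")])
    return tasks


def read_tasks(path) -> list[CladeTask]:
    tasks = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            tid, genera, _n, species, exemplars, age, hpd, alns = line.rstrip("\n").split("\t")
            tasks.append(
                CladeTask(
                    task_id=tid,
                    genera=tuple(genera.split(",")),
                    species=tuple(species.split(",")),
                    exemplars=tuple(exemplars.split(",")),
                    calibration_age=float(age),
                    hpd=tuple(float(x) for x in hpd.split(",")) if hpd else None,
                    alignment_ids=tuple(a for a in alns.split(",") if a),
                )
            )
    return tasks


def stage_cladeinfer(ws: Workspace, cfg: PipelineConfig) -> None:
    tasks = read_tasks(ws.require("tasks.tsv", "decompose"))
    alignments = _alignments(ws.read_clusters("merged"))
    outdir = ws.cluster_dir("clades")
    outputs = []
    for task in tasks:
        tree = infer_clade_tree(
            task, alignments, model=cfg.distance_model,
            bootstrap_replicates=cfg.clade_bootstrap, seed=cfg.seed,
        )
        if tree is None:
            continue
        path = outdir / f"{task.task_id}.nwk"
        tree.write(path)
        outputs.append(path)
    ws.manifest("cladeinfer", cfg, [ws.path("tasks.tsv")], outputs)


def stage_graft(ws: Workspace, cfg: PipelineConfig) -> Chronogram:
    tasks = read_tasks(ws.require("tasks.tsv", "decompose"))
    backbone = Chronogram.read(
        ws.require("backbone_dated.nwk", "bbdate"), require_ultrametric=True, ultrametric_tol=1e-3
    )
    cdir = ws.path("clades")
    if not cdir.is_dir():
        raise StageError("missing clades/; run stage 'cladeinfer' first")
    subtrees = {}
    for task in tasks:
        path = cdir / f"{task.task_id}.nwk"
        if path.exists():
            subtrees[task.task_id] = Chronogram.read(path, require_ultrametric=True, ultrametric_tol=1e-6)
    final = graft_all(backbone, subtrees, tasks, mode=cfg.graft_mode)
    final.write(ws.path("final.nwk"))
    ws.manifest("graft", cfg, [ws.path("backbone_dated.nwk"), ws.path("tasks.tsv")], [ws.path("final.nwk")])
    return final


_STAGE_FUNCS = {
    "replicate": stage_replicate,
    "reduce": stage_reduce,
    "merge": stage_merge,
    "exemplars": stage_exemplars,
    "supermatrix": stage_supermatrix,
    "bbinfer": stage_bbinfer,
    "bbdate": stage_bbdate,
    "decompose": stage_decompose,
    "cladeinfer": stage_cladeinfer,
    "graft": stage_graft,
}


def run(stage_name: str, workdir, config: Optional[PipelineConfig] = None):
    """Run one pipeline stage in ``workdir``."""
    if stage_name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage_name!r}; stages: {', '.join(STAGES)}")
    cfg = config or PipelineConfig()
    ws = Workspace(workdir)
    return _STAGE_FUNCS[stage_name](ws, cfg)


def run_all(workdir, config: Optional[PipelineConfig] = None) -> Chronogram:
    cfg = config or PipelineConfig()
    for stage in STAGES:
        result = run(stage, workdir, cfg)
    return result


# -- in-memory end-to-end (no file round-trips) -------------------------------

def recover_tree(bundle: ReplicateBundle, cfg: Optional[PipelineConfig] = None) -> Chronogram:
    """Run the full analysis on an in-memory bundle and return the final tree.

    Mirrors the staged pipeline (reduce -> exemplars -> supermatrix ->
    backbone inference -> dating -> decompose -> clade inference -> graft)
    without file I/O; used by the validation study.
    """
    cfg = cfg or PipelineConfig()
    policy = ReductionPolicy(per_species_keep=cfg.per_species_keep)
    clusters = [reduce_cluster(c, policy) for c in bundle.clusters]
    groups = merge_sister_clusters(
        clusters, SimilarityConfig(cfg.kmer_size, cfg.min_similarity)
    )
    merged = [g[0] if len(g) == 1 else merge_cluster_group(g) for g in groups]
    alignments = _alignments(merged)
    taxa = bundle.taxa_table

    retained, _ = filter_sparse_taxa(
        alignments, taxa, SparsityFilter(cfg.min_shared_intra, cfg.min_shared_inter)
    )
    filtered = {
        aid: [r for r in aln if r.species_id in retained]
        for aid, aln in alignments.items()
    }
    filtered = {aid: aln for aid, aln in filtered.items() if aln}
    exemplars = select_exemplars(filtered, taxa, model=cfg.distance_model)
    exemplar_species = sorted({sp for r in exemplars.values() for sp in r.exemplars})

    smx_cfg = SupermatrixConfig(
        cfg.max_avg_divergence, cfg.min_markers_per_species, cfg.max_markers_per_species
    )
    candidates = {}
    for aid, aln in alignments.items():
        rows = [r for r in aln if r.species_id in exemplar_species]
        if len(rows) >= 2 and average_divergence(rows, model=cfg.distance_model) <= smx_cfg.max_avg_divergence:
            candidates[aid] = rows
    occupancy = {aid: {r.species_id for r in rows} for aid, rows in candidates.items()}
    selection = assemble_supermatrix(occupancy, exemplar_species, smx_cfg)
    matrix, partitions = concatenate(candidates, selection.selected, selection.retained_species)

    backbone = bootstrap_support(
        matrix, partitions, replicates=cfg.bootstrap_replicates, seed=cfg.seed,
        model=cfg.distance_model, missing="impute",
    )
    calibrations = truth_calibrations(bundle)
    dated = date_tree(backbone.midpoint_root(), calibrations, restrict=True)
    tasks = build_clade_tasks(dated, dated, taxa, alignments)
    subtrees = {}
    for task in tasks:
        tree = infer_clade_tree(
            task, alignments, model=cfg.distance_model,
            bootstrap_replicates=cfg.clade_bootstrap, seed=cfg.seed,
        )
        if tree is not None:
            subtrees[task.task_id] = tree
    return graft_all(dated, subtrees, tasks, mode=cfg.graft_mode)
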