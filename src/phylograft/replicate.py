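"""Simulation-based validation machinery: replicate a reference dataset.

The generator mirrors a reference dataset's size, genus structure and
sampling bias: a constant-rate birth–death model is fitted by maximum
likelihood to the reference chronogram, a tree of the same tip count is
simulated under the fitted rates, its tips are assigned to genera
approximating the reference genus size/age profile (keeping genera
monophyletic), substitution models are fitted to each reference cluster, and
sequences are simulated along the new tree on the reference occupancy
pattern.  Invariable simulated clusters are removed.  The same machinery,
driven by stated parameters instead of fitted ones, doubles as the pipeline's
fixture generator (:func:`generate_bundle`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from .backbone import nj_from_matrix
from .model import SequenceCluster, SequenceRecord, TaxaTable
from .substmodels import (
    EigenQ,
    PruningTree,
    SubstModelSpec,
    compress_patterns,
    discrete_gamma_rates,
    simulate_sequences,
)
from .trees import Chronogram, Node, TreeError

__all__ = [
    "BDParams",
    "ReplicateBundle",
    "fit_birth_death",
    "bd_loglik",
    "simulate_bd_tree",
    "assign_genera",
    "fit_subst_model",
    "simulate_alignment",
    "generate_bundle",
    "replicate_dataset",
]


# -- birth-death --------------------------------------------------------------

@dataclass(frozen=True)
class BDParams:
    """Constant-rate birth-death parameters, per lineage per Ma."""

    birth: float  # lambda
    death: float  # mu

    def __post_init__(self):
        if self.birth <= 0:
            raise ValueError("birth rate must be > 0")
        if self.death < 0:
            raise ValueError("death rate must be >= 0")

    @property
    def net_diversification(self) -> float:
        return self.birth - self.death

    @property
    def turnover(self) -> float:
        return self.death / self.birth


def branching_times(tree: Chronogram) -> np.ndarray:
    """Internal node ages of an ultrametric tree, descending (root first)."""
    if tree.root.age is None:
        tree.compute_ages()
    ages = sorted(
        (n.age for n in tree.nodes() if not n.is_leaf), reverse=True
    )
    return np.asarray(ages)


def bd_loglik(times: np.ndarray, r: float, eps: float) -> float:
    """Log-likelihood of branching times under the conditioned birth-death model.

    ``r`` is the net diversification rate (lambda - mu) and ``eps`` the
    turnover (mu / lambda).  Conditioned on the number of tips and the crown
    age, as in the classical constant-rates likelihood on branching times.
    """
    n = len(times) + 1  # tips
    if r <= 0 or not 0.0 <= eps < 1.0:
        return -np.inf
    root = times[0]
    non_root = times[1:]
    ll = (
        gammaln(n)
        + (n - 2) * math.log(r)
        + r * float(non_root.sum())
        + n * math.log(1.0 - eps)
        - 2.0 * float(np.log(np.exp(r * times) - eps).sum())
    )
    return ll


def fit_birth_death(tree: Chronogram) -> tuple[BDParams, float]:
    """Maximum-likelihood (lambda, mu) from an ultrametric tree's node ages.

    Optimises over (net diversification r, turnover eps) with bounded
    L-BFGS-B from several starts; the turnover is bounded in [0, 1 - 1e-6].
    """
    times = branching_times(tree)
    if len(times) < 2:
        raise ValueError("need >= 2 branching times (>= 3 tips)")

    def neg(theta):
        return -bd_loglik(times, theta[0], theta[1])

    n = len(times) + 1
    r0 = max((n - 2) / max(times[1:].sum(), 1e-9), 1e-3)  # Yule-flavoured start
    best = None
    for eps0 in (0.0, 0.3, 0.6, 0.9):
        res = minimize(
            neg,
            x0=[r0, eps0],
            method="L-BFGS-B",
            bounds=[(1e-8, None), (0.0, 1.0 - 1e-6)],
        )
        if best is None or res.fun < best.fun:
            best = res
    r, eps = best.x
    lam = r / (1.0 - eps)
    mu = lam * eps
    return BDParams(birth=lam, death=mu), -best.fun


def simulate_bd_tree(
    params: BDParams, n_tips: int, seed: int, max_tries: int = 10_000
) -> Chronogram:
    """Simulate a birth-death tree conditioned on ``n_tips`` extant tips.

    Forward simulation from two crown lineages; the process stops at a
    uniform point of the waiting interval after the extant count first
    reaches ``n_tips``; extinct lineages are pruned.  Full extinction (or an
    overshoot before reaching the target) triggers a rejection and restart.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if params.birth <= params.death:
        raise ValueError("need birth > death to condition on extant tips")
    rng = np.random.default_rng(seed)
    lam, mu = params.birth, params.death
    total_rate = lam + mu
    for _ in range(max_tries):
        root = Node()
        start = [root.add_child(Node()), root.add_child(Node())]
        birth_time = {id(root): 0.0, id(start[0]): 0.0, id(start[1]): 0.0}
        active = list(start)
        t = 0.0
        ok = True
        while len(active) != n_tips:
            if not active:
                ok = False
                break
            t += rng.exponential(1.0 / (total_rate * len(active)))
            k = rng.integers(0, len(active))
            lineage = active.pop(k)
            if rng.random() < lam / total_rate:
                lineage.length = t - birth_time[id(lineage)]
                for _ in range(2):
                    child = lineage.add_child(Node())
                    birth_time[id(child)] = t
                    active.append(child)
            else:
                lineage.length = t - birth_time[id(lineage)]  # dies at t
        if not ok:
            continue
        # stop uniformly inside the next waiting interval
        w = rng.exponential(1.0 / (total_rate * n_tips))
        t_stop = t + rng.random() * w
        for lineage in active:
            lineage.length = t_stop - birth_time[id(lineage)]
            lineage.label = "extant"
        tree = Chronogram(root)
        # prune extinct tips (those never marked extant)
        extinct = [n for n in tree.tips() if n.label != "extant"]
        while extinct:
            for node in extinct:
                node.parent.remove_child(node)
            for node in list(tree.postorder()):
                if not node.is_leaf and not node.children and node.parent is not None:
                    node.parent.remove_child(node)
            tree.suppress_unifurcations()
            extinct = [n for n in tree.tips() if n.label != "extant"]
        if tree.n_tips() != n_tips:
            continue
        for i, tip in enumerate(tree.tips()):
            tip.label = f"t{i + 1}"
        tree.root.length = None
        tree.compute_ages()
        tree.validate_dated()
        return tree
    raise RuntimeError(
        f"rejection budget exhausted simulating {n_tips} tips at "
        f"lambda={lam}, mu={mu}"
    )


# -- genus assignment ---------------------------------------------------------

def assign_genera(
    sim_tree: Chronogram,
    reference_profile: Sequence[tuple[str, int, float]],
    seed: int,
) -> tuple[dict[str, str], list[str]]:
    """Assign simulated tips to genera approximating a reference profile.

    ``reference_profile`` rows are (genus_id, size, crown age in Ma).  Genera
    are processed in descending size; each takes the unused clade whose tip
    count is closest to the target (ties: crown age closest, then seeded
    random), so every genus is monophyletic by construction.  When no disjoint
    clade of at least 2 tips remains for a multi-species genus, the genus is
    assigned the best available smaller clade and reported.  Leftover tips
    become monotypic genera.  Returns (tip -> genus map, report lines).
    """
    if sim_tree.root.age is None:
        sim_tree.compute_ages()
    total = sum(size for _, size, _ in reference_profile)
    if total > sim_tree.n_tips():
        raise ValueError("reference profile larger than the simulated tree")
    rng = np.random.default_rng(seed)
    tipsets = sim_tree.tipsets()
    candidates = [
        (node, tipsets[node]) for node in sim_tree.nodes()
    ]
    used: set[str] = set()
    genus_map: dict[str, str] = {}
    report: list[str] = []
    ordered = sorted(reference_profile, key=lambda p: (-p[1], p[0]))
    for genus_id, size, ref_age in ordered:
        free = [
            (node, ts)
            for node, ts in candidates
            if not (ts & used) and len(ts) <= max(size * 2, size + 2)
        ]
        if not free:
            report.append(f"{genus_id}: no free clade left; genus dropped")
            continue
        best_count = min(abs(len(ts) - size) for _, ts in free)
        pool = [(node, ts) for node, ts in free if abs(len(ts) - size) == best_count]
        ages = np.array([node.age or 0.0 for node, _ in pool])
        best_age = np.min(np.abs(ages - ref_age))
        pool = [
            (node, ts)
            for (node, ts), a in zip(pool, ages)
            if abs(a - ref_age) == best_age
        ]
        node, ts = pool[rng.integers(0, len(pool))]
        if len(ts) != size:
            report.append(
                f"{genus_id}: target size {size}, assigned clade of {len(ts)}"
            )
        for tip in ts:
            genus_map[tip] = genus_id
        used |= ts
    leftover = [t for t in sim_tree.tip_labels() if t not in genus_map]
    taken = {genus_id for genus_id, _, _ in reference_profile}
    counter = 0
    for tip in sorted(leftover):
        counter += 1
        name = f"mono{counter}"
        while name in taken:  # never collide with a reference genus id
            counter += 1
            name = f"mono{counter}"
        genus_map[tip] = name
    return genus_map, report


# -- substitution model fitting -----------------------------------------------

_CANDIDATES = [
    ("JC69", False), ("JC69", True),
    ("K2P", False), ("K2P", True),
    ("HKY85", False), ("HKY85", True),
    ("GTR", False), ("GTR", True),
]


def _empirical_freqs(records: Sequence[SequenceRecord]) -> np.ndarray:
    counts = np.zeros(4)
    lookup = {"A": 0, "C": 1, "G": 2, "T": 3}
    for rec in records:
        for ch in rec.residues.upper():
            idx = lookup.get(ch)
            if idx is not None:
                counts[idx] += 1
    counts = np.maximum(counts, 1.0)
    return counts / counts.sum()


def _pack_spec(name: str, gamma: bool, freqs: np.ndarray, theta: np.ndarray, length: int) -> SubstModelSpec:
    kappa = None
    exch = None
    alpha = None
    pos = 1  # theta[0] is the log branch-scale
    if name in ("K2P", "HKY85"):
        kappa = float(np.exp(theta[pos]))
        pos += 1
    if name == "GTR":
        exch = tuple(np.exp(theta[pos : pos + 5])) + (1.0,)
        pos += 5
    if gamma:
        alpha = float(np.exp(theta[pos]))
        pos += 1
    use_freqs = (0.25,) * 4 if name in ("JC69", "K2P") else tuple(freqs)
    return SubstModelSpec(
        name=name, freqs=use_freqs, kappa=kappa, exchangeabilities=exch,
        alpha=alpha, length=length,
    )


def fit_subst_model(
    records: Sequence[SequenceRecord],
) -> tuple[SubstModelSpec, dict[str, float]]:
    """Select a substitution model for an alignment by AIC.

    Candidates are {JC69, K2P, HKY85, GTR} x {+G4, homogeneous}, scored by
    maximised log-likelihood on a fixed NJ guide topology.  Branch lengths are
    taken from the NJ tree and a single global rate-scale factor is optimised
    jointly with the substitution parameters (full per-branch optimisation is
    deliberately out of budget; the scale factor absorbs the overall rate).
    Base frequencies for HKY85/GTR are empirical.  AIC ties go to the simpler
    model.  Returns (winning spec, {model label: AIC}).
    """
    if len(records) < 3:
        raise ValueError("model fitting needs >= 3 sequences")
    labels, patterns, weights = compress_patterns(records)
    variable = (
        np.array(
            [len({v for v in col if v != 255}) > 1 for col in patterns.T]
        )
    )
    if not variable.any():
        raise ValueError("all sites invariable; nothing to fit")
    matrix = {r.seq_id: r.residues for r in records}
    guide = nj_from_matrix(matrix, model="JC69")
    ptree = PruningTree(guide, labels)
    freqs = _empirical_freqs(records)
    length = len(records[0].residues)

    results: dict[str, float] = {}
    fitted: dict[str, tuple[SubstModelSpec, float]] = {}
    for name, gamma in _CANDIDATES:
        x0 = [0.0]
        if name in ("K2P", "HKY85"):
            x0.append(math.log(2.0))
        if name == "GTR":
            x0.extend([0.0, math.log(2.0), 0.0, 0.0, math.log(2.0)])
        if gamma:
            x0.append(0.0)  # alpha = 1

        def neg(theta, name=name, gamma=gamma):
            spec = _pack_spec(name, gamma, freqs, theta, length)
            eig = EigenQ(spec.q_matrix(), spec.freqs)
            rates = discrete_gamma_rates(spec.alpha) if gamma else None
            return -ptree.loglik(
                eig, patterns, weights, scale=math.exp(theta[0]), gamma_rates=rates
            )

        res = minimize(neg, x0=np.array(x0), method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": 1e-3, "maxiter": 400})
        spec = _pack_spec(name, gamma, freqs, res.x, length)
        ll = -res.fun
        k = spec.n_free_params() + 1  # + the branch-scale factor
        aic = 2.0 * k - 2.0 * ll
        label = name + ("+G" if gamma else "")
        results[label] = aic
        fitted[label] = (spec, ll)

    order = [name + ("+G" if g else "") for name, g in _CANDIDATES]
    winner = min(order, key=lambda lab: (round(results[lab], 9), order.index(lab)))
    return fitted[winner][0], results


# -- alignment simulation -----------------------------------------------------

def simulate_alignment(
    tree: Chronogram,
    spec: SubstModelSpec,
    species_subset: Sequence[str],
    seed: int,
    rate: float = 0.005,
    indel_rate: float = 0.0,
    indel_mean_length: float = 3.0,
) -> list[SequenceRecord]:
    """Simulate one aligned cluster on a chronogram.

    ``rate`` converts Ma to expected substitutions/site.  The optional indel
    overlay (default OFF) applies a Poisson number of deletions per branch
    (geometric lengths), producing gap spans shared by descendant lineages.
    """
    subset = sorted(set(species_subset))
    if not subset:
        raise ValueError("empty species subset")
    missing = set(subset) - set(tree.tip_labels())
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)}")
    seqs = simulate_sequences(tree, spec, seed=seed, rate=rate)
    n_sites = spec.length
    if indel_rate > 0.0:
        rng = np.random.default_rng(seed + 1)
        gaps: dict[str, np.ndarray] = {t: np.zeros(n_sites, bool) for t in tree.tip_labels()}
        for node in tree.nodes():
            if node is tree.root or node.length is None:
                continue
            n_events = rng.poisson(indel_rate * node.length * n_sites)
            if n_events == 0:
                continue
            tips_below = [l.label for l in node.leaves()]
            for _ in range(n_events):
                start = rng.integers(0, n_sites)
                span = rng.geometric(1.0 / indel_mean_length)
                for t in tips_below:
                    gaps[t][start : start + span] = True
        seqs = {
            t: "".join("-" if g else c for c, g in zip(s, gaps[t]))
            for t, s in seqs.items()
        }
    return [
        SequenceRecord(
            seq_id=f"{sp}_seq", species_id=sp, residues=seqs[sp], is_aligned=True
        )
        for sp in subset
    ]


def is_invariable(records: Sequence[SequenceRecord]) -> bool:
    rows = [r.residues.upper() for r in records]
    for col in zip(*rows):
        observed = {c for c in col if c in "ACGT"}
        if len(observed) > 1:
            return False
    return True


# -- bundles ------------------------------------------------------------------

@dataclass
class ReplicateBundle:
    """A simulated 'truth' plus everything the pipeline consumes."""

    tree: Chronogram
    taxa_table: TaxaTable
    clusters: list[SequenceCluster]
    summary: list[dict] = field(default_factory=list)

    @property
    def occupancy(self) -> dict[str, set[str]]:
        return {c.cluster_id: set(c.species_ids) for c in self.clusters}


#: genus size profile of the stated 40-species / 8-genus validation world
DEFAULT_GENUS_SIZES = (10, 8, 6, 5, 4, 3, 2, 2)


def generate_bundle(
    seed: int,
    n_species: int = 40,
    genus_sizes: Sequence[int] = DEFAULT_GENUS_SIZES,
    bd: BDParams = BDParams(birth=0.3, death=0.1),
    n_clusters: int = 6,
    length: int = 1500,
    spec: Optional[SubstModelSpec] = None,
    rate: float = 0.005,
    occupancy_prob: float = 0.75,
) -> ReplicateBundle:
    """Simulate a stated-world dataset: tree, genera, clusters, taxa table.

    Defaults encode the validation world: 40 species in 8 genera under a
    birth-death process with lambda=0.3, mu=0.1 /lineage/Ma, 6 clusters of
    1500 sites under HKY85+G (kappa=4, alpha=0.5, mildly AT-rich base
    frequencies), a clock rate of 0.005 substitutions/site/Ma, and independent
    75% per-species cluster occupancy (every species guaranteed >= 1 cluster).
    """
    if sum(genus_sizes) != n_species:
        raise ValueError("genus sizes must sum to n_species")
    if spec is None:
        spec = SubstModelSpec(
            name="HKY85", freqs=(0.3, 0.2, 0.2, 0.3), kappa=4.0, alpha=0.5,
            length=length,
        )
    rng = np.random.default_rng(seed)
    tree = simulate_bd_tree(bd, n_species, seed=int(rng.integers(2**31)))
    profile = [
        (f"G{i + 1}", size, 0.0) for i, size in enumerate(genus_sizes)
    ]
    genus_map, _ = assign_genera(tree, profile, seed=int(rng.integers(2**31)))
    # species ids: genus-prefixed for readability
    rename: dict[str, str] = {}
    counters: dict[str, int] = {}
    for tip in sorted(tree.tip_labels(), key=lambda t: (genus_map[t], t)):
        genus = genus_map[tip]
        counters[genus] = counters.get(genus, 0) + 1
        rename[tip] = f"{genus}_sp{counters[genus]:02d}"
    for node in tree.tips():
        node.label = rename[node.label]
    taxa = TaxaTable(
        [
            (sp, sp.replace("_", " "), sp.split("_")[0])
            for sp in sorted(rename.values())
        ]
    )
    species = taxa.species
    clusters: list[SequenceCluster] = []
    for c in range(n_clusters):
        members = [sp for sp in species if rng.random() < occupancy_prob]
        if len(members) < 4:
            members = sorted(rng.choice(species, size=4, replace=False))
        records = simulate_alignment(
            tree, spec, members, seed=int(rng.integers(2**31)), rate=rate
        )
        if is_invariable(records):
            continue
        clusters.append(
            SequenceCluster(
                cluster_id=f"cluster{c + 1:02d}",
                seed_id=records[0].seq_id,
                members=records,
                aligned=True,
            )
        )
    # guarantee every species appears in at least one cluster
    covered = set().union(*(set(c.species_ids) for c in clusters))
    orphans = [sp for sp in species if sp not in covered]
    if orphans and clusters:
        c0 = clusters[0]
        extra = simulate_alignment(
            tree, spec, sorted(set(c0.species_ids) | set(orphans)),
            seed=int(rng.integers(2**31)), rate=rate,
        )
        clusters[0] = SequenceCluster(
            cluster_id=c0.cluster_id, seed_id=extra[0].seq_id,
            members=extra, aligned=True,
        )
    return ReplicateBundle(tree=tree, taxa_table=taxa, clusters=clusters)


def _genus_profile(tree: Chronogram, taxa: TaxaTable) -> list[tuple[str, int, float]]:
    if tree.root.age is None:
        tree.compute_ages()
    tipset = set(tree.tip_labels())
    profile = []
    for genus, members in sorted(taxa.genera().items()):
        present = [m for m in members if m in tipset]
        if not present:
            continue
        age = 0.0 if len(present) == 1 else tree.mrca(present).age
        profile.append((genus, len(present), age))
    return profile


def _cluster_summary(cluster: SequenceCluster, divergence: float) -> dict:
    return {
        "cluster_id": cluster.cluster_id,
        "n_sequences": len(cluster.members),
        "length": cluster.alignment_length,
        "mean_divergence": divergence,
    }


def replicate_dataset(reference: ReplicateBundle, seed: int) -> ReplicateBundle:
    """Replicate a reference dataset by simulation.

    Fits a birth-death model to the reference tree, simulates a tree of the
    same size, shuffles monophyletic genera onto it following the reference
    genus profile, fits a substitution model per reference cluster, and
    simulates each cluster on the occupancy row of the mapped species.
    Invariable simulated clusters are dropped (and reported in the summary).
    """
    from .supermatrix import average_divergence

    rng = np.random.default_rng(seed)
    ref_tree = reference.tree
    if ref_tree.root.age is None:
        ref_tree.compute_ages()
    params, _ = fit_birth_death(ref_tree)
    if params.birth <= params.death:  # boundary fit: nudge to a usable simulator
        params = BDParams(birth=params.birth, death=0.9 * params.birth)
    sim = simulate_bd_tree(params, ref_tree.n_tips(), seed=int(rng.integers(2**31)))
    profile = _genus_profile(ref_tree, reference.taxa_table)
    genus_map, genus_report = assign_genera(sim, profile, seed=int(rng.integers(2**31)))

    # genus-preserving bijection reference species -> simulated tips
    sim_by_genus: dict[str, list[str]] = {}
    for tip, genus in genus_map.items():
        sim_by_genus.setdefault(genus, []).append(tip)
    for tips in sim_by_genus.values():
        tips.sort()
    profile_ids = {genus_id for genus_id, _, _ in profile}
    spare = sorted(
        t for g, tips in sim_by_genus.items() if g not in profile_ids for t in tips
    )
    mapping: dict[str, str] = {}
    for genus, size, _ in profile:
        ref_species = sorted(
            sp for sp in reference.taxa_table.genera().get(genus, [])
            if sp in set(ref_tree.tip_labels())
        )
        assigned = sim_by_genus.get(genus, [])
        for i, sp in enumerate(ref_species):
            if i < len(assigned):
                mapping[sp] = assigned[i]
            elif spare:
                mapping[sp] = spare.pop(0)
            else:
                raise RuntimeError("ran out of simulated tips during mapping")

    # rename simulated tips to the mapped reference species ids; tips that
    # received no reference species are pruned so both trees span one taxon set
    reverse = {v: k for k, v in mapping.items()}
    for tip in sim.tips():
        tip.label = reverse.get(tip.label, tip.label)
    unmapped = [t for t in sim.tip_labels() if t not in mapping]
    if unmapped:
        sim.prune_tips(unmapped)
        sim.compute_ages()

    clusters: list[SequenceCluster] = []
    summary: list[dict] = []
    for cluster in reference.clusters:
        spec, _aics = fit_subst_model(list(cluster.members))
        occupancy_row = [sp for sp in cluster.species_ids if sp in mapping]
        # clock rate estimated from the reference: mean divergence over mean
        # pairwise time separation of the cluster's species
        ref_div = average_divergence(list(cluster.members))
        times = []
        sp_list = [sp for sp in cluster.species_ids if sp in set(ref_tree.tip_labels())]
        for i in range(len(sp_list)):
            for j in range(i + 1, len(sp_list)):
                times.append(2.0 * ref_tree.mrca([sp_list[i], sp_list[j]]).age)
        mean_time = float(np.mean(times)) if times else 1.0
        est_rate = max(ref_div / max(mean_time, 1e-9), 1e-6)
        records = simulate_alignment(
            sim, spec, occupancy_row, seed=int(rng.integers(2**31)), rate=est_rate
        )
        entry = _cluster_summary(cluster, ref_div)
        if is_invariable(records):
            entry["replicate"] = "dropped (invariable)"
            summary.append(entry)
            continue
        rep_cluster = SequenceCluster(
            cluster_id=cluster.cluster_id,
            seed_id=records[0].seq_id,
            members=records,
            aligned=True,
        )
        entry["replicate"] = "ok"
        entry["replicate_divergence"] = average_divergence(records)
        summary.append(entry)
        clusters.append(rep_cluster)
    if genus_report:
        summary.append({"genus_assignment": "; ".join(genus_report)})

    taxa = TaxaTable(
        [
            (sp, reference.taxa_table.species_name.get(sp, sp), reference.taxa_table.genus_of[sp])
            for sp in sorted(mapping)
        ]
    )
    return ReplicateBundle(tree=sim, taxa_table=taxa, clusters=clusters, summary=summary)
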