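"""Nucleotide substitution models: rate matrices, likelihoods, simulation.

Supports the reversible family JC69 / K2P / HKY85 / GTR, each optionally with
4-category discrete-gamma rate heterogeneity (mean-of-interval category rates,
Yang 1994 style).  Likelihood evaluation is Felsenstein pruning over
site-pattern-compressed alignments with per-node rescaling; transition
matrices come from the symmetrised eigendecomposition of the rate matrix, so
a whole vector of branch lengths is exponentiated at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .distances import MISSING, encode
from .model import SequenceRecord
from .trees import Chronogram, Node

__all__ = [
    "SubstModelSpec",
    "rate_matrix",
    "discrete_gamma_rates",
    "EigenQ",
    "PruningTree",
    "simulate_sequences",
]

MODEL_NAMES = ("JC69", "K2P", "HKY85", "GTR")
# GTR exchangeability order: AC, AG, AT, CG, CT, GT (GT fixed to 1)
_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T


@dataclass
class SubstModelSpec:
    """A fitted (or stated) substitution model.

    ``kappa`` is the transition/transversion rate ratio (K2P/HKY85);
    ``exchangeabilities`` are the six GTR rates with GT == 1; ``alpha`` is the
    gamma shape (``None`` = rate homogeneity); ``length`` is the alignment
    length in sites.
    """

    name: str
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    kappa: Optional[float] = None
    exchangeabilities: Optional[tuple[float, ...]] = None
    alpha: Optional[float] = None
    length: int = 1000

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}")
        if abs(sum(self.freqs) - 1.0) > 1e-6:
            raise ValueError("base frequencies must sum to 1")
        if any(f <= 0 for f in self.freqs):
            raise ValueError("base frequencies must be positive")

    def q_matrix(self) -> np.ndarray:
        if self.name == "JC69":
            return rate_matrix((0.25,) * 4, (1.0,) * 6)
        if self.name == "K2P":
            k = self.kappa if self.kappa is not None else 2.0
            return rate_matrix((0.25,) * 4, (1.0, k, 1.0, 1.0, k, 1.0))
        if self.name == "HKY85":
            k = self.kappa if self.kappa is not None else 2.0
            return rate_matrix(self.freqs, (1.0, k, 1.0, 1.0, k, 1.0))
        return rate_matrix(self.freqs, self.exchangeabilities or (1.0,) * 6)

    def n_free_params(self) -> int:
        n = {"JC69": 0, "K2P": 1, "HKY85": 4, "GTR": 8}[self.name]
        if self.alpha is not None:
            n += 1
        return n


def rate_matrix(freqs: Sequence[float], exch: Sequence[float]) -> np.ndarray:
    """Reversible rate matrix Q_ij = s_ij * pi_j, normalised to mean rate 1."""
    pi = np.asarray(freqs, dtype=float)
    q = np.zeros((4, 4))
    for rate, (i, j) in zip(exch, _PAIRS):
        q[i, j] = rate * pi[j]
        q[j, i] = rate * pi[i]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -(pi * np.diag(q)).sum()
    return q / mean_rate


def discrete_gamma_rates(alpha: float, k: int = 4) -> np.ndarray:
    """Mean rates of k equal-probability gamma(alpha, 1/alpha) categories."""
    edges = gamma_dist.ppf(np.linspace(0.0, 1.0, k + 1), a=alpha, scale=1.0 / alpha)
    # mean of each segment via the incomplete gamma of shape alpha + 1
    upper = gammainc(alpha + 1.0, edges[1:] * alpha)
    lower = gammainc(alpha + 1.0, edges[:-1] * alpha)
    rates = k * (upper - lower)
    return rates / rates.mean() * 1.0


class EigenQ:
    """Eigendecomposition of a reversible Q for fast P(t) over many branches."""

    def __init__(self, q: np.ndarray, freqs: Sequence[float]):
        pi = np.asarray(freqs, dtype=float)
        sqrt_pi = np.sqrt(pi)
        # B = D Q D^-1 with D = diag(sqrt(pi)) is symmetric for reversible Q:
        # B_ij = s_ij * sqrt(pi_i * pi_j)
        b = (q * sqrt_pi[:, None]) / sqrt_pi[None, :]
        b = 0.5 * (b + b.T)  # guard against rounding only
        vals, vecs = np.linalg.eigh(b)
        self.vals = vals
        # P(t) = D^-1 V exp(Lambda t) V^T D
        self.right = vecs / sqrt_pi[:, None]
        self.left = vecs.T * sqrt_pi[None, :]
        self.freqs = pi

    def transition_matrices(self, t: np.ndarray) -> np.ndarray:
        """P(t) for a vector of branch lengths; shape (len(t), 4, 4)."""
        t = np.asarray(t, dtype=float)
        ex = np.exp(np.outer(t, self.vals))  # (B, 4)
        p = np.einsum("ik,bk,kj->bij", self.right, ex, self.left)
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=2, keepdims=True)
        return p


# -- pruning likelihood -------------------------------------------------------

def compress_patterns(
    records: Sequence[SequenceRecord],
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Site-pattern compression.  Returns (row labels, patterns S x P, weights)."""
    labels = [r.seq_id for r in records]
    data = np.stack([encode(r.residues) for r in records])
    patterns, counts = np.unique(data, axis=1, return_counts=True)
    return labels, patterns, counts.astype(float)


class PruningTree:
    """Flattened rooted topology for repeated likelihood evaluations.

    Branch lengths live in ``self.lengths`` (indexed like ``self.nodes``,
    root entry unused) and can be rescaled between evaluations.
    """

    def __init__(self, tree: Chronogram, row_labels: Sequence[str]):
        self.nodes: list[Node] = list(tree.postorder())
        self.index = {id(n): i for i, n in enumerate(self.nodes)}
        self.lengths = np.array(
            [n.length if n.length is not None else 0.0 for n in self.nodes]
        )
        self.children = [
            [self.index[id(c)] for c in n.children] for n in self.nodes
        ]
        label_to_row = {lab: i for i, lab in enumerate(row_labels)}
        self.leaf_row = [
            label_to_row.get(n.label, -1) if n.is_leaf else -1 for n in self.nodes
        ]
        missing = [n.label for n in self.nodes if n.is_leaf and n.label not in label_to_row]
        if missing:
            raise ValueError(f"alignment lacks rows for tips {missing}")

    def loglik(
        self,
        eig: EigenQ,
        patterns: np.ndarray,
        weights: np.ndarray,
        scale: float = 1.0,
        gamma_rates: Optional[np.ndarray] = None,
    ) -> float:
        from scipy.special import logsumexp

        rates = np.array([1.0]) if gamma_rates is None else np.asarray(gamma_rates)
        n_pat = patterns.shape[1]
        per_cat = np.empty((len(rates), n_pat))
        for ci, rate in enumerate(rates):
            pmats = eig.transition_matrices(self.lengths * scale * rate)
            partial = np.empty((len(self.nodes), n_pat, 4))
            log_scale = np.zeros(n_pat)
            for i, node in enumerate(self.nodes):
                if not self.children[i]:
                    row = patterns[self.leaf_row[i]]
                    leaf = np.zeros((n_pat, 4))
                    observed = row != MISSING
                    leaf[observed, row[observed].astype(int)] = 1.0
                    leaf[~observed] = 1.0
                    partial[i] = leaf
                else:
                    acc = np.ones((n_pat, 4))
                    for c in self.children[i]:
                        acc *= partial[c] @ pmats[c].T
                    mx = acc.max(axis=1)
                    mx = np.where(mx > 0, mx, 1.0)
                    acc /= mx[:, None]
                    log_scale += np.log(mx)
                    partial[i] = acc
            root_like = np.maximum(partial[len(self.nodes) - 1] @ eig.freqs, 1e-300)
            per_cat[ci] = np.log(root_like) + log_scale
        site_loglik = logsumexp(per_cat, axis=0) - np.log(len(rates))
        return float(np.sum(weights * site_loglik))


# -- simulation ---------------------------------------------------------------

def simulate_sequences(
    tree: Chronogram,
    spec: SubstModelSpec,
    seed: int,
    rate: float = 1.0,
    length: Optional[int] = None,
) -> dict[str, str]:
    """Evolve sequences along a tree under ``spec``.

    Branch lengths are multiplied by ``rate`` (substitutions/site per unit of
    branch length — e.g. per Ma when the tree is a chronogram).  With a gamma
    shape, every site draws one of the 4 discrete category rates.  Returns
    tip label -> sequence.
    """
    rng = np.random.default_rng(seed)
    n_sites = length if length is not None else spec.length
    pi = np.asarray(spec.freqs)
    eig = EigenQ(spec.q_matrix(), pi)
    if spec.alpha is not None:
        cat_rates = discrete_gamma_rates(spec.alpha)
        site_cat = rng.integers(0, len(cat_rates), size=n_sites)
    else:
        cat_rates = np.array([1.0])
        site_cat = np.zeros(n_sites, dtype=int)

    states = {id(tree.root): rng.choice(4, size=n_sites, p=pi)}
    letters = np.array(list("ACGT"))
    out: dict[str, str] = {}
    for node in tree.nodes():
        if node is tree.root:
            parent_state = states[id(node)]
        else:
            t = (node.length or 0.0) * rate
            pmats = eig.transition_matrices(t * cat_rates)  # (k, 4, 4)
            cum = np.cumsum(pmats, axis=2)
            parent_state = states[id(node.parent)]
            u = rng.random(n_sites)
            rows = cum[site_cat, parent_state]  # (L, 4)
            child_state = (u[:, None] > rows).sum(axis=1)
            states[id(node)] = child_state
            parent_state = child_state
        if node.is_leaf:
            out[node.label] = "".join(letters[parent_state])
    # free interior states as we only need tips
    return out
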