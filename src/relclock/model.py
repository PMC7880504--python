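"""Posterior components: HKY tree likelihood, Yule tree prior, hyperpriors.

The posterior over (tree T, branch rates R, clock sd sigma, clock rate mu_C,
substitution parameters, birth rate lambda) given an alignment D factorises as

    p(T, R, sigma, mu_C, theta | D) propto
        p(D | T, r(R), mu_C, theta) p(T | lambda) p(R | sigma)
        p(sigma) p(mu_C) p(kappa) p(freqs) p(lambda)

The likelihood is Felsenstein pruning over compressed site patterns under a
per-partition HKY model, with per-branch expected substitutions
``mu_C * r_i * tau_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from Bio import SeqIO

from .treeio import TimeTree, TreeError, tree_length
from .clock import BranchRates, ClockModel

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
GAP = -1  # gaps and ambiguity codes: partial likelihood 1 for all states


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Nucleotide alignment: N taxa x L sites, integer-coded, partitioned.

    ``matrix[i, s]`` is 0..3 for ACGT and -1 for gap/ambiguity. ``partition``
    assigns each site to one of P partitions (0-based).
    """

    labels: list
    matrix: np.ndarray
    partition: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.partition is None:
            self.partition = np.zeros(self.matrix.shape[1], dtype=np.int64)
        self.partition = np.asarray(self.partition, dtype=np.int64)

    @property
    def n_taxa(self):
        return self.matrix.shape[0]

    @property
    def n_sites(self):
        return self.matrix.shape[1]

    @property
    def n_partitions(self):
        return int(self.partition.max()) + 1

    def partition_sites(self, p: int) -> np.ndarray:
        return self.matrix[:, self.partition == p]

    @classmethod
    def from_fasta(cls, path, partition_ranges=None) -> "Alignment":
        records = list(SeqIO.parse(path, "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        labels = [r.id for r in records]
        L = len(records[0].seq)
        mat = np.full((len(records), L), GAP, dtype=np.int8)
        for i, r in enumerate(records):
            if len(r.seq) != L:
                raise ValueError("sequences are not aligned (unequal lengths)")
            for s, ch in enumerate(str(r.seq).upper()):
                mat[i, s] = _CODE.get(ch, GAP)
        part = None
        if partition_ranges:
            part = np.zeros(L, dtype=np.int64)
            for p, (lo, hi) in enumerate(partition_ranges):  # 1-based inclusive
                part[lo - 1:hi] = p
        return cls(labels, mat, part)

    def to_fasta(self) -> str:
        rev = {0: "A", 1: "C", 2: "G", 3: "T", GAP: "-"}
        chunks = []
        for i, lab in enumerate(self.labels):
            seq = "".join(rev[int(c)] for c in self.matrix[i])
            chunks.append(f">{lab}\n{seq}\n")
        return "".join(chunks)


def compress_site_patterns(columns: np.ndarray):
    """Unique alignment columns and their multiplicities (weights sum to L)."""
    patterns, weights = np.unique(columns, axis=1, return_counts=True)
    return patterns, weights


# ---------------------------------------------------------------------------
# HKY substitution model
# ---------------------------------------------------------------------------

def hky_rate_matrix(kappa: float, freqs) -> np.ndarray:
    """Frequency-normalised HKY rate matrix (expected 1 substitution/unit)."""
    pi = np.asarray(freqs, dtype=float)
    Q = np.tile(pi, (4, 1)).copy()
    for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # transitions A<->G, C<->T
        Q[i, j] *= kappa
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    beta = -1.0 / np.dot(pi, np.diag(Q))
    return Q * beta


def hky_transition_probs(d, kappa: float, freqs) -> np.ndarray:
    """HKY transition matrices, closed form, vectorised over distances.

    Parameters
    ----------
    d : float or (k,) array
        Expected substitutions per site on each branch.

    Returns
    -------
    (4,4) or (k,4,4) row-stochastic matrices.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("negative expected substitutions")
    scalar = d.ndim == 0
    d = np.atleast_1d(d)[:, None, None]
    pi = np.asarray(freqs, dtype=float)
    piR, piY = pi[0] + pi[2], pi[1] + pi[3]
    beta = 1.0 / (2 * kappa * (pi[0] * pi[2] + pi[1] * pi[3]) + 2 * piR * piY)

    group = np.array([piR, piY, piR, piY])          # Pi_j: group frequency of j
    A = 1.0 + group * (kappa - 1.0)
    e2 = np.exp(-beta * d)                          # (k,1,1)
    e3 = np.exp(-beta * d * A[None, None, :])       # (k,1,4)

    pj = pi[None, None, :]
    gj = group[None, None, :]
    same_group = np.equal.outer(np.isin(np.arange(4), (0, 2)),
                                np.isin(np.arange(4), (0, 2)))  # R/Y blocks
    eye = np.eye(4, dtype=bool)

    P = np.where(same_group,
                 pj + pj * (1.0 / gj - 1.0) * e2 - (pj / gj) * e3,
                 pj * (1.0 - e2))
    diag = pj + pj * (1.0 / gj - 1.0) * e2 + ((gj - pj) / gj) * e3
    P = np.where(eye, diag, P)
    # rounding can push entries a few ulp below zero at tiny or huge d
    np.clip(P, 0.0, 1.0, out=P)
    return P[0] if scalar else P


# ---------------------------------------------------------------------------
# substitution model container / state
# ---------------------------------------------------------------------------

@dataclass
class SubstModel:
    """Per-partition HKY parameters plus relative clock rates mu_C.

    ``mu_c`` must average to 1 weighted by partition site counts (enforced by
    the operator scheme; a single partition pins mu_c = 1).
    """

    kappa: np.ndarray
    freqs: np.ndarray   # (P, 4)
    mu_c: np.ndarray

    def __post_init__(self):
        self.kappa = np.atleast_1d(np.asarray(self.kappa, dtype=float))
        self.freqs = np.atleast_2d(np.asarray(self.freqs, dtype=float))
        self.mu_c = np.atleast_1d(np.asarray(self.mu_c, dtype=float))

    @classmethod
    def default(cls, n_partitions: int = 1) -> "SubstModel":
        return cls(np.full(n_partitions, 2.0),
                   np.full((n_partitions, 4), 0.25),
                   np.ones(n_partitions))

    @property
    def n_partitions(self):
        return len(self.kappa)

    def copy(self):
        return SubstModel(self.kappa.copy(), self.freqs.copy(), self.mu_c.copy())


@dataclass
class PhyloState:
    """Full MCMC state: tree, branch rates, clock, substitution model, lambda."""

    tree: TimeTree
    rates: BranchRates
    clock: ClockModel
    subst: SubstModel
    lam: float = 1.0

    def __post_init__(self):
        if len(self.rates.values) != self.tree.n_nodes - 1:
            raise ValueError("rate vector length must be 2N-2")
        if self.tree.root != self.tree.n_nodes - 1:
            raise ValueError("root must be the last node index")

    def real_rates(self) -> np.ndarray:
        """Real rate per non-root node id 0..2N-3."""
        return self.rates.real_rates(self.clock)

    def copy(self) -> "PhyloState":
        return PhyloState(self.tree.copy(), self.rates.copy(), self.clock.copy(),
                          self.subst.copy(), self.lam)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class _PartitionData:
    def __init__(self, patterns, weights):
        self.patterns = patterns          # (N, n_pat) int8
        self.weights = weights.astype(float)
        # leaf partial helpers: clipped codes + gap masks
        self.codes = np.clip(patterns, 0, 3).astype(np.intp)
        self.gaps = patterns < 0


def prepare_alignment(aln: Alignment, tree: TimeTree):
    """Reorder taxa to tree leaf order and compress patterns per partition."""
    if set(aln.labels) != set(tree.labels):
        raise ValueError("alignment taxa do not match tree leaves")
    order = [aln.labels.index(lab) for lab in tree.labels]
    mat = aln.matrix[order]
    parts = []
    for p in range(aln.n_partitions):
        cols = mat[:, aln.partition == p]
        parts.append(_PartitionData(*compress_site_patterns(cols)))
    return parts


def _pruning_loglik(tree: TimeTree, bl_subst: np.ndarray, kappa, freqs, part,
                    rescale=False):
    """Felsenstein pruning over one partition's compressed patterns.

    Runs unscaled by default (fast); on underflow it retries with per-node
    rescaling of the partial likelihoods.
    """
    P = hky_transition_probs(bl_subst, kappa, freqs)  # (2N-2, 4, 4)
    N = tree.n_taxa
    partials = {}

    def down(c):
        if c < N:  # leaf: one-hot partial => a transition-matrix column
            d = P[c][:, part.codes[c]].T.copy()
            g = part.gaps[c]
            if g.any():
                d[g] = 1.0
            return d
        return partials.pop(c) @ P[c].T

    scale = 0.0
    for i in tree.postorder():
        prod = down(int(tree.children[i, 0])) * down(int(tree.children[i, 1]))
        if rescale:
            mx = prod.max(axis=1)
            mx[mx == 0] = 1.0
            prod /= mx[:, None]
            scale += float(np.dot(part.weights, np.log(mx)))
        partials[i] = prod
    site_lik = partials[tree.root] @ np.asarray(freqs, dtype=float)
    if np.any(site_lik <= 0) or not np.all(np.isfinite(site_lik)):
        if not rescale:
            return _pruning_loglik(tree, bl_subst, kappa, freqs, part, True)
        return -np.inf
    return scale + float(np.dot(part.weights, np.log(site_lik)))


def tree_log_likelihood(state: PhyloState, aln: Alignment, prepared=None) -> float:
    """log p(D | T, r(R), mu_C, kappa, freqs), summed over partitions."""
    tree = state.tree
    if prepared is None:
        prepared = prepare_alignment(aln, tree)
    rates = state.real_rates()
    nonroot = np.arange(tree.n_nodes - 1)
    tau = tree.heights[tree.parent[nonroot]] - tree.heights[nonroot]
    if np.any(tau <= 0):
        return -np.inf
    total = 0.0
    for p, part in enumerate(prepared):
        d = state.subst.mu_c[p] * rates * tau
        total += _pruning_loglik(tree, d, state.subst.kappa[p],
                                 state.subst.freqs[p], part)
    return total


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------

def yule_log_prior(tree: TimeTree, lam: float) -> float:
    """Yule (pure-birth) tree prior on labelled histories.

    Every lineage splits independently at rate lambda, giving
    ``log p(T | lambda) = (N - 1) log(lambda) - lambda * l`` with ``l`` the
    tree length. The normalising constant over trees is lambda-free, so
    lambda's prior-sample marginal equals its hyperprior.
    """
    if lam <= 0:
        return -np.inf
    N = tree.n_taxa
    tips = tree.heights[:N]
    if np.max(np.abs(tips)) > 1e-8 * max(tree.heights[tree.root], 1.0):
        raise TreeError("Yule prior requires an ultrametric tree (tips at 0)")
    return (N - 1) * np.log(lam) - lam * tree_length(tree)


# hyperpriors (frozen scipy distributions, used for sampling and as the
# reference in tests); Log-normal(a, b) has a, b = mean and sd of the log;
# Gamma is (shape, scale).
SIGMA_PRIOR = stats.gamma(a=0.5396, scale=0.3819)
KAPPA_PRIOR = stats.lognorm(s=1.25, scale=np.exp(1.0))
LAMBDA_PRIOR = stats.lognorm(s=1.25, scale=np.exp(1.0))
MU_C_PRIOR = stats.lognorm(s=0.6, scale=np.exp(-0.18))
FREQS_PRIOR = stats.dirichlet([10.0, 10.0, 10.0, 10.0])

from scipy.special import gammaln as _gammaln

_LOG_2PI = np.log(2 * np.pi)
_SIGMA_A, _SIGMA_SCALE = 0.5396, 0.3819
_SIGMA_CONST = -_SIGMA_A * np.log(_SIGMA_SCALE) - _gammaln(_SIGMA_A)
_DIRICHLET_CONST = float(_gammaln(40.0) - 4 * _gammaln(10.0))


def _lognorm_logpdf(x, m, s):
    lx = np.log(x)
    return -lx - np.log(s) - 0.5 * _LOG_2PI - 0.5 * ((lx - m) / s) ** 2


def hyperprior_log_densities(state: PhyloState) -> float:
    """Sum of hyperprior log densities; -inf outside support.

    sigma ~ Gamma(0.5396, 0.3819) (shape, scale); kappa, lambda ~
    Log-normal(1, 1.25); freqs ~ Dirichlet(10,10,10,10); mu_C ~
    Log-normal(-0.18, 0.6) when more than one partition is free.
    """
    sigma = state.clock.sigma
    if sigma <= 0 or state.lam <= 0:
        return -np.inf
    total = ((_SIGMA_A - 1) * np.log(sigma) - sigma / _SIGMA_SCALE
             + _SIGMA_CONST)
    total += _lognorm_logpdf(state.lam, 1.0, 1.25)
    sm = state.subst
    for p in range(sm.n_partitions):
        if sm.kappa[p] <= 0:
            return -np.inf
        total += _lognorm_logpdf(sm.kappa[p], 1.0, 1.25)
        f = sm.freqs[p]
        if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
            return -np.inf
        total += 9.0 * np.sum(np.log(f)) + _DIRICHLET_CONST
    if sm.n_partitions > 1:
        # mean-1 constraint handled by the operator scheme; density evaluated
        # on the unconstrained product form
        for p in range(sm.n_partitions):
            if sm.mu_c[p] <= 0:
                return -np.inf
            total += _lognorm_logpdf(sm.mu_c[p], -0.18, 0.6)
    return float(total)


def log_prior(state: PhyloState) -> float:
    lp = hyperprior_log_densities(state)
    if not np.isfinite(lp):
        return -np.inf
    lp += yule_log_prior(state.tree, state.lam)
    lp += state.rates.log_prior(state.clock)
    return float(lp)


def log_posterior(state: PhyloState, aln: Alignment = None, prepared=None) -> float:
    """Unnormalised log posterior; the likelihood term is skipped when
    ``aln`` is None (sampling the prior)."""
    lp = log_prior(state)
    if not np.isfinite(lp):
        return -np.inf
    if aln is not None:
        lp += tree_log_likelihood(state, aln, prepared)
    return float(lp)
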