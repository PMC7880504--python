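"""MCMC proposal operators for the relaxed clock model.

Every operator returns a :class:`Proposal` carrying the proposed state, the
log Hastings ratio, and the log absolute Jacobian determinant (Green ratio)
of any deterministic reparameterisation it applies. A proposal that exits the
parameter domain returns the reject sentinel (``state=None``).

The constant-distance family (ConstantDistance, SimpleDistance, SmallPulley)
moves node heights and branch rates jointly so every affected genetic
distance ``r_i * tau_i`` -- and hence the tree likelihood -- is unchanged;
these operators "walk along the ridge" of a peaked likelihood. In the *quant*
parameterisation the rates are stored as quantiles, so each rate written back
through the piecewise inverse-CDF map contributes an extra Jacobian factor
(the ratio of map derivatives at the old and new quantiles).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from .clock import REAL, CAT, QUANT
from .kernels import Kernel
from .model import PhyloState, SIGMA_PRIOR

REJECT_LOG = -np.inf

# quantiles beyond this cannot round-trip through the inverse-CDF map at
# double precision; proposals that push a rate this deep into a tail reject
QUANT_EPS = 1e-9


@dataclass
class Proposal:
    """Proposed state plus log Hastings ratio and log |J| (Green ratio)."""

    state: PhyloState = None
    log_hastings: float = 0.0
    log_jacobian: float = 0.0
    operator: str = ""
    changes_likelihood: bool = True

    @property
    def rejected(self) -> bool:
        return self.state is None

    @classmethod
    def reject(cls, operator=""):
        return cls(None, REJECT_LOG, 0.0, operator)


def _reject(op):
    return Proposal.reject(op.name)


# ---------------------------------------------------------------------------
# rate read/write across parameterisations
# ---------------------------------------------------------------------------

def get_real_rate(state: PhyloState, nodes):
    """Real rate(s) of the given non-root node id(s)."""
    r = state.real_rates()
    return r[nodes]


def set_real_rates(state: PhyloState, nodes, new_r):
    """Write real rates back into the state's parameterisation.

    Returns the extra log-Jacobian contribution of the quantile map in *quant*
    mode (0 for *real*), or None to signal rejection (non-positive rate or a
    quantile hitting the open-interval boundary).
    """
    new_r = np.atleast_1d(np.asarray(new_r, dtype=float))
    nodes = np.atleast_1d(nodes)
    if np.any(new_r <= 0):
        return None
    if state.rates.mode == REAL:
        state.rates.values[nodes] = new_r
        return 0.0
    if state.rates.mode == QUANT:
        approx = state.clock.approx
        q_old = state.rates.values[nodes]
        q_new = approx.cdf(new_r)
        q_new = np.atleast_1d(q_new)
        if np.any(q_new <= QUANT_EPS) or np.any(q_new >= 1 - QUANT_EPS):
            return None
        extra = float(np.sum(np.log(approx.icdf_deriv(q_old))
                             - np.log(approx.icdf_deriv(q_new))))
        state.rates.values[nodes] = q_new
        return extra
    raise ValueError("rate write-back not defined for the cat parameterisation")


# ---------------------------------------------------------------------------
# base class
# ---------------------------------------------------------------------------

class Operator:
    """Base proposal operator; subclasses implement :meth:`_propose`."""

    name = "operator"
    modes = (REAL, CAT, QUANT)
    changes_likelihood = True

    def __init__(self, kernel: Kernel = None, name: str = None):
        self.kernel = kernel if kernel is not None else Kernel()
        if name is not None:
            self.name = name
        self.proposed = 0
        self.accepted = 0

    def propose(self, state: PhyloState, rng: np.random.Generator) -> Proposal:
        self.proposed += 1
        prop = self._propose(state, rng)
        prop.operator = self.name
        prop.changes_likelihood = prop.changes_likelihood and self.changes_likelihood
        return prop

    def feedback(self, accepted: bool):
        """Accept/reject outcome, used for step-size tuning and counters."""
        self.accepted += accepted
        if self.kernel is not None:
            self.kernel.record(accepted)

    def observe(self, state: PhyloState):
        """Hook for operators that learn from the sampled trajectory."""

    def available(self, state: PhyloState) -> bool:
        return state.rates.mode in self.modes

    def __repr__(self):
        return f"<{type(self).__name__} {self.name}>"


# ---------------------------------------------------------------------------
# simple element-wise operators
# ---------------------------------------------------------------------------

def _node_pool(state, node_filter):
    """Non-root node ids targeted by a rate operator ('all'/'leaf'/'internal')."""
    N = state.tree.n_taxa
    if node_filter == "leaf":
        return np.arange(N)
    if node_filter == "internal":
        return np.arange(N, state.tree.n_nodes - 1)
    return np.arange(state.tree.n_nodes - 1)


class RandomWalk(Operator):
    """Shift one element of the target by s*Sigma; symmetric, HR = 0."""

    changes_likelihood = True

    def __init__(self, target="rates", node_filter="all", **kw):
        super().__init__(**kw)
        self.target = target
        self.node_filter = node_filter
        self.name = kw.get("name") or f"RandomWalk({target})"
        self.changes_likelihood = target != "sigma"

    def _propose(self, state, rng):
        new = state.copy()
        step = self.kernel.step(rng)
        if self.target == "sigma":
            x = new.clock.sigma + step
            if x <= 0:
                return _reject(self)
            new.clock.sigma = x
            return Proposal(new)
        pool = _node_pool(state, self.node_filter)
        i = int(rng.choice(pool))
        mode = new.rates.mode
        if mode == CAT:
            delta = int(np.sign(step) * np.ceil(abs(step)))
            if delta == 0:
                delta = 1 if rng.random() < 0.5 else -1
            x = new.rates.values[i] + delta
            if x < 0 or x >= new.rates.n_categories:
                return _reject(self)
        else:
            x = new.rates.values[i] + step
            if mode == REAL and x <= 0:
                return _reject(self)
            if mode == QUANT and not (0 < x < 1):
                return _reject(self)
        new.rates.values[i] = x
        return Proposal(new)


class Scale(Operator):
    """Multiply a positive scalar by exp(s*Sigma); HR = log(x'/x)."""

    def __init__(self, target="rates", node_filter="all", **kw):
        super().__init__(**kw)
        self.target = target
        self.node_filter = node_filter
        self.name = kw.get("name") or f"Scale({target})"
        self.changes_likelihood = target in ("rates", "kappa")

    def available(self, state):
        if self.target == "rates":
            return state.rates.mode == REAL
        return True

    def _propose(self, state, rng):
        new = state.copy()
        f = float(np.exp(self.kernel.step(rng)))
        if self.target == "rates":
            pool = _node_pool(state, self.node_filter)
            i = int(rng.choice(pool))
            new.rates.values[i] *= f
        elif self.target == "sigma":
            new.clock.sigma *= f
        elif self.target == "kappa":
            p = int(rng.integers(new.subst.n_partitions))
            new.subst.kappa[p] *= f
        elif self.target == "lambda":
            new.lam *= f
        else:
            raise ValueError(f"unknown scale target {self.target}")
        return Proposal(new, log_hastings=np.log(f))


class Interval(Operator):
    """Random walk on the logit of a quantile (quant mode only)."""

    modes = (QUANT,)

    def __init__(self, node_filter="all", **kw):
        super().__init__(**kw)
        self.node_filter = node_filter
        self.name = kw.get("name") or "Interval(rates)"

    def _propose(self, state, rng):
        new = state.copy()
        pool = _node_pool(state, self.node_filter)
        i = int(rng.choice(pool))
        q = new.rates.values[i]
        y = np.log(q / (1 - q)) + self.kernel.step(rng)
        q2 = 1.0 / (1.0 + np.exp(-y))
        if not 0 < q2 < 1:
            return _reject(self)
        new.rates.values[i] = q2
        lh = np.log(q2 * (1 - q2)) - np.log(q * (1 - q))
        return Proposal(new, log_hastings=float(lh))


class Swap(Operator):
    """Exchange two random elements of the rate vector; self-inverse, HR = 0."""

    def __init__(self, node_filter="all", **kw):
        super().__init__(kernel=None, **kw)
        self.kernel = None
        self.node_filter = node_filter
        self.name = kw.get("name") or "Swap(rates)"

    def _propose(self, state, rng):
        pool = _node_pool(state, self.node_filter)
        if len(pool) < 2:
            return _reject(self)
        new = state.copy()
        i, j = rng.choice(pool, size=2, replace=False)
        v = new.rates.values
        v[i], v[j] = v[j], v[i]
        return Proposal(new)


class UniformResample(Operator):
    """Resample one element from its flat domain (cat bins / quant interval)."""

    modes = (CAT, QUANT)

    def __init__(self, node_filter="all", **kw):
        super().__init__(kernel=None, **kw)
        self.kernel = None
        self.node_filter = node_filter
        self.name = kw.get("name") or "Uniform(rates)"

    def _propose(self, state, rng):
        new = state.copy()
        pool = _node_pool(state, self.node_filter)
        i = int(rng.choice(pool))
        if new.rates.mode == CAT:
            new.rates.values[i] = rng.integers(new.rates.n_categories)
        elif new.rates.mode == QUANT:
            new.rates.values[i] = rng.uniform(0.0, 1.0)
        else:
            raise ValueError("Uniform resample needs the cat or quant mode")
        return Proposal(new)


class SampleFromPrior(Operator):
    """Resample psi ~ Binomial(n, s/n) random elements from their prior.

    The boldest proposal available; its Hastings ratio is the prior density of
    the replaced values over that of the new ones (independence proposal).
    """

    def __init__(self, target="rates", node_filter="all", **kw):
        super().__init__(**kw)
        self.target = target
        self.node_filter = node_filter
        self.name = kw.get("name") or f"SampleFromPrior({target})"
        self.changes_likelihood = target == "rates"

    def _propose(self, state, rng):
        new = state.copy()
        if self.target == "sigma":
            pool_len = 1
        else:
            pool = _node_pool(state, self.node_filter)
            pool_len = len(pool)
        p = min(self.kernel.scale / pool_len, 1.0)
        psi = int(rng.binomial(pool_len, p))
        if psi == 0:
            return Proposal(new, changes_likelihood=False)
        lh = 0.0
        if self.target == "sigma":
            old = new.clock.sigma
            draw = float(SIGMA_PRIOR.rvs(random_state=rng))
            lh = float(SIGMA_PRIOR.logpdf(old) - SIGMA_PRIOR.logpdf(draw))
            new.clock.sigma = draw
            return Proposal(new, log_hastings=lh)
        idx = rng.choice(pool, size=psi, replace=False)
        mode = new.rates.mode
        if mode == REAL:
            sigma = new.clock.sigma
            old = new.rates.values[idx]
            draw = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=psi))
            from .clock import lognormal_rate_logpdf
            lh = float(np.sum(lognormal_rate_logpdf(old, sigma))
                       - np.sum(lognormal_rate_logpdf(draw, sigma)))
        elif mode == CAT:
            draw = rng.integers(new.rates.n_categories, size=psi)
        else:
            draw = rng.uniform(0.0, 1.0, size=psi)
        new.rates.values[idx] = draw
        return Proposal(new, log_hastings=lh)


# ---------------------------------------------------------------------------
# constant-distance family
# ---------------------------------------------------------------------------

class ConstantDistance(Operator):
    """Move an internal node height, rescaling the three incident branch rates
    so all three genetic distances are exactly preserved (likelihood-neutral).
    """

    modes = (REAL, QUANT)

    def __init__(self, node_filter="all", **kw):
        super().__init__(**kw)
        self.node_filter = node_filter
        suffix = "" if node_filter == "all" else f",{node_filter}"
        self.name = kw.get("name") or f"ConstantDistance(rates,t{suffix})"
    # likelihood is invariant by construction, but priors on t and r change
    changes_likelihood = False

    def _eligible(self, state):
        tree = state.tree
        nodes = tree.internal_nodes(include_root=False)
        if self.node_filter == "leaf":
            nodes = [i for i in nodes
                     if tree.is_leaf(int(tree.children[i, 0]))
                     or tree.is_leaf(int(tree.children[i, 1]))]
        elif self.node_filter == "internal":
            nodes = [i for i in nodes
                     if not tree.is_leaf(int(tree.children[i, 0]))
                     or not tree.is_leaf(int(tree.children[i, 1]))]
        return nodes

    def _propose(self, state, rng):
        nodes = self._eligible(state)
        if not nodes:
            return _reject(self)
        x = int(rng.choice(nodes))
        new = state.copy()
        tree = new.tree
        c1, c2 = (int(c) for c in tree.children[x])
        tp = float(tree.heights[tree.parent[x]])
        tx = float(tree.heights[x])
        lo = max(float(tree.heights[c1]), float(tree.heights[c2]))
        tx2 = tx + float(self.kernel.step(rng))
        if not lo < tx2 < tp:
            return _reject(self)
        r = get_real_rate(state, [c1, c2, x])
        tc = np.array([tree.heights[c1], tree.heights[c2]])
        new_r = np.empty(3)
        new_r[:2] = r[:2] * (tx - tc) / (tx2 - tc)
        new_r[2] = r[2] * (tp - tx) / (tp - tx2)
        tree.heights[x] = tx2
        logj = float(np.sum(np.log(tx - tc) - np.log(tx2 - tc))
                     + np.log(tp - tx) - np.log(tp - tx2))
        extra = set_real_rates(new, [c1, c2, x], new_r)
        if extra is None:
            return _reject(self)
        return Proposal(new, log_jacobian=logj + extra)


class SimpleDistance(Operator):
    """ConstantDistance applied to the root: move the root height, rescale the
    two root-child rates so root-child genetic distances are preserved."""

    modes = (REAL, QUANT)
    name = "SimpleDistance(rates,t)"
    changes_likelihood = False

    def _propose(self, state, rng):
        new = state.copy()
        tree = new.tree
        root = tree.root
        c1, c2 = (int(c) for c in tree.children[root])
        tr = float(tree.heights[root])
        tc = np.array([tree.heights[c1], tree.heights[c2]])
        tr2 = tr + float(self.kernel.step(rng))
        if tr2 <= tc.max():
            return _reject(self)
        r = get_real_rate(state, [c1, c2])
        new_r = r * (tr - tc) / (tr2 - tc)
        tree.heights[root] = tr2
        logj = float(np.sum(np.log(tr - tc) - np.log(tr2 - tc)))
        extra = set_real_rates(new, [c1, c2], new_r)
        if extra is None:
            return _reject(self)
        return Proposal(new, log_jacobian=logj + extra)


class SmallPulley(Operator):
    """Shift genetic distance between the two root branches, total conserved.

    Heights are untouched; the move is a symmetric random walk on the first
    root-child distance, so HR = 0 and |J| = 1 (the distance<->rate
    reparameterisation Jacobians cancel).
    """

    modes = (REAL, QUANT)
    name = "SmallPulley(rates)"
    changes_likelihood = False

    def _propose(self, state, rng):
        new = state.copy()
        tree = new.tree
        root = tree.root
        c1, c2 = (int(c) for c in tree.children[root])
        tau = tree.heights[root] - tree.heights[[c1, c2]]
        r = get_real_rate(state, [c1, c2])
        d = r * tau
        total = float(d.sum())
        d1 = float(d[0] + self.kernel.step(rng))
        if not 0.0 < d1 < total:
            return _reject(self)
        new_r = np.array([d1 / tau[0], (total - d1) / tau[1]])
        extra = set_real_rates(new, [c1, c2], new_r)
        if extra is None:
            return _reject(self)
        return Proposal(new, log_jacobian=extra)


class CisScale(Operator):
    """Scale sigma and recompute the rate vector in the clock's own space.

    *real*: rates are recomputed so their log-normal quantiles are unchanged.
    *quant*: quantiles are recomputed so the real rates are unchanged.
    The log |J| collects the per-element derivatives of the recomputation.
    """

    modes = (REAL, QUANT)
    name = "CisScale(sigma,rates)"
    # real: likelihood invariant in quantile-preserving form? No: rates change.
    changes_likelihood = True

    def _propose(self, state, rng):
        new = state.copy()
        f = float(np.exp(self.kernel.step(rng)))
        sigma, sigma2 = state.clock.sigma, state.clock.sigma * f
        lh = np.log(f)  # scale move on sigma
        new.clock.sigma = sigma2
        if state.rates.mode == REAL:
            r = state.rates.values
            z = (np.log(r) + 0.5 * sigma**2) / sigma
            r2 = np.exp(-0.5 * sigma2**2 + sigma2 * z)
            if np.any(r2 <= 0) or not np.all(np.isfinite(r2)):
                return _reject(self)  # double-precision under/overflow
            logj = float(np.sum(np.log(r2) - np.log(r))
                         + len(r) * (np.log(sigma2) - np.log(sigma)))
            new.rates.values[:] = r2
            # quantiles preserved => likelihood changes (rates moved)
            return Proposal(new, log_hastings=lh, log_jacobian=logj)
        # quant: keep real rates fixed, recompute quantiles under sigma'
        old_approx = state.clock.approx
        new_approx = new.clock.approx
        q = state.rates.values
        r = old_approx.icdf(q)
        q2 = np.atleast_1d(new_approx.cdf(r))
        if np.any(q2 <= QUANT_EPS) or np.any(q2 >= 1 - QUANT_EPS):
            return _reject(self)
        logj = float(np.sum(np.log(old_approx.icdf_deriv(q))
                            - np.log(new_approx.icdf_deriv(q2))))
        new.rates.values[:] = q2
        return Proposal(new, log_hastings=lh, log_jacobian=logj,
                        changes_likelihood=False)


# ---------------------------------------------------------------------------
# adaptive multivariate leaf-rate operator
# ---------------------------------------------------------------------------

class LeafAVMVN(Operator):
    """Joint multivariate-normal proposal on all N transformed leaf rates.

    Works on x = log(r) (*real*) or logit(q) (*quant*). A streaming covariance
    estimate Sigma_N is learned from the sampled trajectory; proposals use
    covariance c * ((1-beta) Sigma_N + beta I) with beta = 0.05 and the
    standard adaptive-MVN scale c = 2.38^2 / N. The Gaussian random walk is
    symmetric, so the Hastings ratio reduces to the transform Jacobians.
    """

    modes = (REAL, QUANT)
    name = "LeafAVMVN(leaf rates)"

    def __init__(self, beta: float = 0.05, min_samples: int = 200, **kw):
        super().__init__(kernel=None, **kw)
        self.kernel = None
        self.beta = beta
        self.min_samples = min_samples
        self._count = 0
        self._mean = None
        self._m2 = None

    def _transform(self, state):
        N = state.tree.n_taxa
        v = state.rates.values[:N]
        if state.rates.mode == REAL:
            return np.log(v)
        return np.log(v / (1 - v))

    def observe(self, state):
        x = self._transform(state)
        if self._mean is None:
            self._mean = np.zeros_like(x)
            self._m2 = np.zeros((len(x), len(x)))
        self._count += 1
        delta = x - self._mean
        self._mean += delta / self._count
        self._m2 += np.outer(delta, x - self._mean)

    def available(self, state):
        return (state.rates.mode in self.modes
                and self._count >= max(self.min_samples, 2))

    def covariance(self):
        return self._m2 / (self._count - 1)

    def _propose(self, state, rng):
        if not self.available(state):
            return _reject(self)
        N = state.tree.n_taxa
        c = 2.38**2 / N
        cov = c * ((1 - self.beta) * self.covariance() + self.beta * np.eye(N))
        x = self._transform(state)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            return _reject(self)
        x2 = x + chol @ rng.standard_normal(N)
        new = state.copy()
        if state.rates.mode == REAL:
            new.rates.values[:N] = np.exp(x2)
            lh = float(np.sum(x2 - x))
        else:
            q2 = 1.0 / (1.0 + np.exp(-x2))
            if np.any(q2 <= 0) or np.any(q2 >= 1):
                return _reject(self)
            new.rates.values[:N] = q2
            q = state.rates.values[:N]
            lh = float(np.sum(np.log(q2 * (1 - q2)) - np.log(q * (1 - q))))
        return Proposal(new, log_hastings=lh)


# ---------------------------------------------------------------------------
# tree plumbing operators
# ---------------------------------------------------------------------------

class UniformNodeHeight(Operator):
    """Redraw one internal (non-root) node height uniformly between its
    tallest child and its parent; symmetric, HR = 0."""

    name = "UniformNodeHeight(t)"

    def __init__(self, **kw):
        super().__init__(kernel=None, **kw)
        self.kernel = None

    def _propose(self, state, rng):
        nodes = state.tree.internal_nodes(include_root=False)
        if not nodes:
            return _reject(self)
        new = state.copy()
        tree = new.tree
        i = int(rng.choice(nodes))
        lo = float(tree.heights[tree.children[i]].max())
        hi = float(tree.heights[tree.parent[i]])
        tree.heights[i] = rng.uniform(lo, hi)
        return Proposal(new)


class RootScale(Operator):
    """Scale the root height; reject below the taller child."""

    name = "RootScale(t)"

    def _propose(self, state, rng):
        new = state.copy()
        tree = new.tree
        f = float(np.exp(self.kernel.step(rng)))
        root = tree.root
        t2 = tree.heights[root] * f
        if t2 <= tree.heights[tree.children[root]].max():
            return _reject(self)
        tree.heights[root] = t2
        return Proposal(new, log_hastings=np.log(f))


class UpDown(Operator):
    """Joint scale of the time axis against the rates: all internal node
    heights are multiplied by f = exp(s*Sigma) and all branch rates divided
    by f, leaving every genetic distance (and the likelihood) unchanged.
    The essential move along the rate-time ridge. Hastings ratio:
    (N-1) heights scale up, 2N-2 rates scale down."""

    modes = (REAL, QUANT)
    name = "UpDown(t,rates)"
    changes_likelihood = False

    def _propose(self, state, rng):
        new = state.copy()
        tree = new.tree
        f = float(np.exp(self.kernel.step(rng)))
        N = tree.n_taxa
        tips = tree.heights[:N]
        if np.max(np.abs(tips)) > 1e-12 * max(tree.heights[tree.root], 1.0):
            return _reject(self)  # non-contemporaneous tips: scaling invalid
        tree.heights[N:] *= f
        lh = (N - 1) * np.log(f)
        old_r = get_real_rate(state, np.arange(tree.n_nodes - 1))
        extra = set_real_rates(new, np.arange(tree.n_nodes - 1), old_r / f)
        if extra is None:
            return _reject(self)
        lh -= (tree.n_nodes - 1) * np.log(f)
        return Proposal(new, log_hastings=lh, log_jacobian=extra)


class TreeScale(Operator):
    """Scale all internal node heights by exp(s*Sigma) (rates untouched)."""

    name = "TreeScale(t)"

    def _propose(self, state, rng):
        new = state.copy()
        tree = new.tree
        N = tree.n_taxa
        tips = tree.heights[:N]
        if np.max(np.abs(tips)) > 1e-12 * max(tree.heights[tree.root], 1.0):
            return _reject(self)
        f = float(np.exp(self.kernel.step(rng)))
        tree.heights[N:] *= f
        return Proposal(new, log_hastings=(N - 1) * np.log(f))


class LambdaConditional(Operator):
    """Independence proposal for the Yule birth rate from its conditional
    given the tree: lambda' ~ Gamma(N, 1/l). The gamma proposal density
    cancels the Yule term lambda^(N-1) exp(-lambda l) exactly, so the move
    accepts on the hyperprior ratio alone and mixes lambda near-independently."""

    name = "LambdaConditional(lambda)"
    changes_likelihood = False

    def __init__(self, **kw):
        super().__init__(kernel=None, **kw)
        self.kernel = None

    def _propose(self, state, rng):
        from .treeio import tree_length
        new = state.copy()
        n = new.tree.n_taxa
        scale = 1.0 / tree_length(new.tree)
        lam2 = float(rng.gamma(n, scale))
        if lam2 <= 0:
            return _reject(self)
        lam = new.lam
        # log q(lam) - log q(lam2) under Gamma(N, scale)
        lh = (n - 1) * (np.log(lam) - np.log(lam2)) - (lam - lam2) / scale
        new.lam = lam2
        return Proposal(new, log_hastings=lh)


class FreqExchange(Operator):
    """Transfer probability mass between two nucleotide frequencies;
    symmetric delta exchange keeping the simplex constraint."""

    name = "FreqExchange(freqs)"

    def _propose(self, state, rng):
        new = state.copy()
        p = int(rng.integers(new.subst.n_partitions))
        i, j = rng.choice(4, size=2, replace=False)
        delta = float(self.kernel.step(rng))
        f = new.subst.freqs[p]
        if f[i] + delta <= 0 or f[j] - delta <= 0:
            return _reject(self)
        f[i] += delta
        f[j] -= delta
        return Proposal(new)


class MuCExchange(Operator):
    """Weighted delta exchange on two partition clock rates mu_C, preserving
    the site-count-weighted mean of 1."""

    name = "MuCExchange(mu_c)"

    def __init__(self, site_counts, **kw):
        super().__init__(**kw)
        self.weights = np.asarray(site_counts, dtype=float)

    def available(self, state):
        return state.subst.n_partitions > 1

    def _propose(self, state, rng):
        new = state.copy()
        P = new.subst.n_partitions
        i, j = rng.choice(P, size=2, replace=False)
        delta = float(self.kernel.step(rng))
        mu = new.subst.mu_c
        mi = mu[i] + delta / self.weights[i]
        mj = mu[j] - delta / self.weights[j]
        if mi <= 0 or mj <= 0:
            return _reject(self)
        mu[i], mu[j] = mi, mj
        return Proposal(new)
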