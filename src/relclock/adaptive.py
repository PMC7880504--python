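"""Adaptive operator weighting: the AdaptiveOperatorSampler meta-operator.

The meta-operator owns a roster of sub-operators and learns how much each one
moves the parameters of interest (POI) per second of runtime. It runs in
three phases over the chain: *burn-in* (uniform sampling, nothing recorded),
*learn-in* (uniform sampling, statistics accumulate), and *sampling*, where
sub-operator omega is drawn with probability

    p(omega) propto  Omega/K  uniform mixture floor
              + (1-Omega) * [ sum of accepted-move distances / T(omega) ]

with T(omega) the cumulative wall time spent on omega (proposal through the
accept/reject decision, so slow likelihood recomputations are charged to the
operator that caused them). The distance of an accepted move is the squared
Robinson-Foulds distance when the POI is the tree, and the squared norm of
the change scaled by the parameter's sample standard deviation and dimension
when the POI is numerical; a meta-operator uses one or the other, never both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import robinson_foulds
from .operators import Operator, Proposal

BURNIN, LEARNIN, SAMPLING = "burnin", "learnin", "sampling"


# ---------------------------------------------------------------------------
# parameters of interest
# ---------------------------------------------------------------------------

@dataclass
class NumericalPOI:
    """A numerical parameter of interest: name + state extractor."""

    name: str
    extract: callable  # state -> 1-D float array

    def __hash__(self):
        return hash(self.name)


def poi_sigma():
    return NumericalPOI("sigma", lambda s: np.array([s.clock.sigma]))


def poi_rates(node_filter="all"):
    def extract(state):
        v = np.asarray(state.rates.values, dtype=float)
        N = state.tree.n_taxa
        if node_filter == "leaf":
            return v[:N]
        if node_filter == "internal":
            return v[N:]
        return v
    return NumericalPOI(f"rates[{node_filter}]", extract)


def poi_heights():
    return NumericalPOI("heights", lambda s: s.tree.heights.astype(float))


TREE_POI = "tree"


def proposal_distance(x, x_new, sigma_p=None):
    """Distance D(x, x') of Eq-style adaptive weighting.

    Trees: squared RF distance. Numerical vectors: squared scaled norm
    ``(1/|p|) * (||x - x'|| / sigma_p)^2``; zero while the parameter has not
    started varying (sigma_p == 0).
    """
    if sigma_p is None:  # tree case
        return float(robinson_foulds(x, x_new) ** 2)
    x = np.asarray(x, dtype=float)
    x_new = np.asarray(x_new, dtype=float)
    if sigma_p <= 0:
        return 0.0
    return float(np.sum((x - x_new) ** 2) / (sigma_p**2 * len(x)))


class _Streaming:
    """Welford accumulator pooled over vector components."""

    __slots__ = ("n", "mean", "m2")

    def __init__(self):
        self.n = 0
        self.mean = 0.0
        self.m2 = 0.0

    def update(self, values):
        for v in np.atleast_1d(values):
            self.n += 1
            d = v - self.mean
            self.mean += d / self.n
            self.m2 += d * (v - self.mean)

    @property
    def sd(self):
        if self.n < 2:
            return 0.0
        return float(np.sqrt(self.m2 / (self.n - 1)))


# ---------------------------------------------------------------------------
# the meta-operator
# ---------------------------------------------------------------------------

@dataclass
class OperatorStats:
    runtime: float = 0.0
    proposed: int = 0
    accepted: int = 0
    distance_sum: float = 0.0
    weight: float = 0.0  # learned sampling probability, for reporting


class AdaptiveOperatorSampler(Operator):
    """Meta-operator that learns sub-operator weights during MCMC."""

    def __init__(self, operators, poi, name="AdaptiveOperatorSampler",
                 mixture_floor=0.01, burnin_frac=0.1, learnin_frac=0.1):
        super().__init__(kernel=None, name=name)
        self.kernel = None
        self.operators = list(operators)
        self.poi = poi  # TREE_POI or list of NumericalPOI
        self.mixture_floor = mixture_floor
        self.burnin_frac = burnin_frac
        self.learnin_frac = learnin_frac
        self.stats = {op.name: OperatorStats() for op in self.operators}
        self.sigma_p = {}
        if poi != TREE_POI:
            self.sigma_p = {p.name: _Streaming() for p in poi}
        self.phase = BURNIN
        self._last = None

    # -- phase control ------------------------------------------------------
    def set_progress(self, frac: float):
        """Update the phase from the chain progress fraction in [0, 1]."""
        if frac < self.burnin_frac:
            phase = BURNIN
        elif frac < self.burnin_frac + self.learnin_frac:
            phase = LEARNIN
        else:
            phase = SAMPLING
        if phase == SAMPLING and self.phase != SAMPLING:
            for op in self.operators:  # freeze step-size tuning: learned
                if op.kernel is not None:  # weights stay meaningful
                    op.kernel.frozen = True
        self.phase = phase

    # -- selection ----------------------------------------------------------
    def weights(self, candidates=None):
        """Current sampling distribution over (available) sub-operators."""
        ops = candidates if candidates is not None else self.operators
        K = len(ops)
        uniform = np.full(K, 1.0 / K)
        if self.phase != SAMPLING:
            return uniform
        scores = np.zeros(K)
        for k, op in enumerate(ops):
            st = self.stats[op.name]
            if st.runtime > 0:
                scores[k] = st.distance_sum / st.runtime
        total = scores.sum()
        if total <= 0:
            return uniform
        return self.mixture_floor * uniform + (1 - self.mixture_floor) * scores / total

    def sample_operator(self, state, rng):
        cand = [op for op in self.operators if op.available(state)]
        if not cand:
            return None
        probs = self.weights(cand)
        return cand[int(rng.choice(len(cand), p=probs))]

    def available(self, state):
        return any(op.available(state) for op in self.operators)

    def _propose(self, state, rng):
        op = self.sample_operator(state, rng)
        if op is None:
            self._last = None
            return Proposal.reject(self.name)
        self._last = op
        prop = op.propose(state, rng)
        return prop

    # -- bookkeeping ---------------------------------------------------------
    def feedback(self, accepted: bool):
        if self._last is not None:
            self._last.feedback(accepted)

    def record_outcome(self, accepted, old_state, new_state, elapsed):
        """Charge runtime and (if accepted) the move distance to the last
        sub-operator; update POI spreads from the post-decision state."""
        if self.phase == BURNIN or self._last is None:
            return
        st = self.stats[self._last.name]
        st.runtime += elapsed
        st.proposed += 1
        if accepted:
            st.accepted += 1
            st.distance_sum += self._distance(old_state, new_state)
        if self.poi != TREE_POI:
            current = new_state if accepted else old_state
            for p in self.poi:
                self.sigma_p[p.name].update(p.extract(current))

    def _distance(self, old_state, new_state):
        if self.poi == TREE_POI:
            return proposal_distance(old_state.tree, new_state.tree)
        total = 0.0
        for p in self.poi:
            total += proposal_distance(p.extract(old_state), p.extract(new_state),
                                       self.sigma_p[p.name].sd)
        return total

    def observe(self, state):
        for op in self.operators:
            op.observe(state)

    def report(self):
        """Learned weights and per-operator statistics (for the run report)."""
        probs = self.weights()
        rows = []
        for op, w in zip(self.operators, probs):
            st = self.stats[op.name]
            st.weight = float(w)
            rate = st.accepted / st.proposed if st.proposed else float("nan")
            rows.append({"meta": self.name, "operator": op.name,
                         "learned_weight": float(w), "proposed": st.proposed,
                         "accepted": st.accepted, "accept_rate": rate,
                         "runtime_s": st.runtime,
                         "distance_sum": st.distance_sum})
        return rows


# ---------------------------------------------------------------------------
# standard groupings
# ---------------------------------------------------------------------------

def build_groupings(mode, kernel_factory=None, avmvn=False, ner=True):
    """The standard meta-operator rosters, filtered by parameterisation.

    Returns a dict of AdaptiveOperatorSampler instances keyed by
    'sigma', 'rates' (or 'leaf'+'internal' when ``avmvn``), 'root', 'ner'.
    Operators incompatible with ``mode`` are silently excluded.
    """
    from . import operators as ops
    from .ner import NEROperator
    from .clock import REAL, CAT, QUANT

    if kernel_factory is None:
        from .kernels import Kernel
        kernel_factory = Kernel

    def filt(candidates):
        return [op for op in candidates if mode in op.modes]

    def small():  # height/distance moves live on the tree's (small) time scale
        k = kernel_factory()
        k.scale = 0.05
        return k

    out = {}
    out["sigma"] = AdaptiveOperatorSampler(
        filt([ops.CisScale(kernel=kernel_factory()),
              ops.RandomWalk("sigma", kernel=small()),
              ops.Scale("sigma", kernel=kernel_factory()),
              ops.SampleFromPrior("sigma", kernel=kernel_factory())]),
        poi=[poi_sigma()], name="AdaptiveOperatorSampler(sigma)")

    def rate_ops(node_filter):
        cand = [ops.ConstantDistance(node_filter, kernel=small()),
                ops.RandomWalk("rates", node_filter, kernel=kernel_factory()),
                ops.Scale("rates", node_filter, kernel=kernel_factory()),
                ops.Interval(node_filter, kernel=kernel_factory()),
                ops.Swap(node_filter),
                ops.UniformResample(node_filter),
                ops.SampleFromPrior("rates", node_filter,
                                    kernel=kernel_factory())]
        picked = []
        for op in cand:
            if mode not in op.modes:
                continue
            if isinstance(op, ops.Scale) and mode != REAL:
                continue  # Scale(R) applies to real rates only
            picked.append(op)
        return picked

    if avmvn:
        leaf = rate_ops("leaf")
        leaf.insert(1, ops.LeafAVMVN())
        out["leaf"] = AdaptiveOperatorSampler(
            leaf, poi=[poi_rates("leaf"), poi_heights()],
            name="AdaptiveOperatorSampler(leaf)")
        out["internal"] = AdaptiveOperatorSampler(
            rate_ops("internal"), poi=[poi_rates("internal"), poi_heights()],
            name="AdaptiveOperatorSampler(internal)")
    else:
        out["rates"] = AdaptiveOperatorSampler(
            rate_ops("all"), poi=[poi_rates(), poi_heights()],
            name="AdaptiveOperatorSampler(rates)")

    if mode in (REAL, QUANT):
        out["root"] = AdaptiveOperatorSampler(
            [ops.SimpleDistance(kernel=small()),
             ops.SmallPulley(kernel=small())],
            poi=[poi_rates(), poi_heights()],
            name="AdaptiveOperatorSampler(root)")

    if ner and mode in (REAL, QUANT):
        out["ner"] = AdaptiveOperatorSampler(
            [NEROperator(()), NEROperator(("DAE", "DBE", "DCE"))],
            poi=TREE_POI, name="AdaptiveOperatorSampler(NER)")
    return out
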