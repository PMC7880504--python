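"""Metropolis-Hastings-Green chain driver, trace logging, ESS diagnostics.

A proposed state x' from x is accepted with probability

    alpha = min(1, posterior_ratio * Hastings_ratio * |J|)

where |J| is the Green (Jacobian) ratio of any deterministic reparameterisation
inside the proposal. The driver samples operators by weight, times every
proposal through its accept/reject decision (feeding the adaptive weighting),
tunes kernel step sizes, and logs a tab-separated trace of scalar summaries
plus an optional tree log.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .treeio import tree_length, write_newick
from .model import PhyloState, Alignment, log_prior, tree_log_likelihood, prepare_alignment
from .operators import Operator
from .adaptive import AdaptiveOperatorSampler


def accept_probability(logpost_new, logpost_old, log_hastings=0.0, log_jacobian=0.0):
    """Metropolis-Hastings-Green acceptance probability."""
    if not np.isfinite(logpost_old):
        raise ValueError("current state has non-finite posterior")
    log_alpha = logpost_new - logpost_old + log_hastings + log_jacobian
    if not np.isfinite(log_alpha):
        return 0.0
    return float(min(1.0, np.exp(min(log_alpha, 0.0))))


@dataclass
class ChainConfig:
    """MCMC run settings: length, logging, operator schedule."""

    chain_length: int = 100_000
    log_every: int = 100
    operators: list = field(default_factory=list)  # (Operator, weight) pairs
    sample_trees: bool = False
    observe_every: int = 5
    burnin_frac: float = 0.1


@dataclass
class Trace:
    """Sampled scalar series, optional tree log, per-operator statistics."""

    samples: pd.DataFrame
    trees: list = field(default_factory=list)
    operator_report: pd.DataFrame = None

    def ess(self, column: str, burnin_frac: float = 0.1):
        x = self.samples[column].to_numpy()
        return effective_sample_size(x[int(len(x) * burnin_frac):])

    def to_tsv(self, path):
        self.samples.to_csv(path, sep="\t", index=False)


def _trace_row(step, state, lp_prior, lp_lik):
    rates = state.real_rates()
    row = {
        "state": step,
        "posterior": lp_prior + lp_lik,
        "likelihood": lp_lik,
        "prior": lp_prior,
        "tree_length": tree_length(state.tree),
        "tree_height": float(state.tree.heights[state.tree.root]),
        "mean_rate": float(np.mean(rates)),
        "sigma": state.clock.sigma,
        "kappa": float(state.subst.kappa[0]),
        "lambda": state.lam,
        "mu_c": float(state.subst.mu_c[0]),
    }
    for p in range(state.subst.n_partitions):
        row[f"freq_A_{p}"] = float(state.subst.freqs[p][0])
    return row


def run_chain(state0: PhyloState, aln: Alignment, config: ChainConfig,
              rng) -> Trace:
    """Run one Metropolis-Hastings-Green chain; ``aln=None`` samples the prior.

    Deterministic given the generator's seed. Raises if the initial state has
    a non-finite posterior.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    state = state0.copy()
    prepared = prepare_alignment(aln, state.tree) if aln is not None else None
    lp_prior = log_prior(state)
    lp_lik = tree_log_likelihood(state, aln, prepared) if aln is not None else 0.0
    if not np.isfinite(lp_prior + lp_lik):
        raise ValueError("initial state has -inf posterior")

    ops = [op for op, _ in config.operators]
    weights = np.array([w for _, w in config.operators], dtype=float)
    if np.any(weights <= 0):
        raise ValueError("operator weights must be positive")
    probs = weights / weights.sum()
    adaptive = [op for op in ops if isinstance(op, AdaptiveOperatorSampler)]

    rows = [_trace_row(0, state, lp_prior, lp_lik)]
    trees = [write_newick(state.tree)] if config.sample_trees else []
    n = config.chain_length
    burnin_end = int(config.burnin_frac * n)
    perf = time.perf_counter

    for step in range(1, n + 1):
        if adaptive and step % 100 == 1:
            frac = step / n
            for a in adaptive:
                a.set_progress(frac)
        op = ops[int(rng.choice(len(ops), p=probs))]
        t0 = perf()
        prop = op.propose(state, rng)
        accepted = False
        if not prop.rejected:
            new_prior = log_prior(prop.state)
            if np.isfinite(new_prior):
                if aln is None or not prop.changes_likelihood:
                    new_lik = lp_lik
                else:
                    new_lik = tree_log_likelihood(prop.state, aln, prepared)
                alpha = accept_probability(new_prior + new_lik, lp_prior + lp_lik,
                                           prop.log_hastings, prop.log_jacobian)
                if alpha >= 1.0 or rng.random() < alpha:
                    accepted = True
        elapsed = perf() - t0
        old_state = state
        if accepted:
            state = prop.state
            lp_prior, lp_lik = new_prior, new_lik
        op.feedback(accepted)
        if isinstance(op, AdaptiveOperatorSampler):
            op.record_outcome(accepted, old_state, state, elapsed)
        if step > burnin_end and step % config.observe_every == 0:
            for o in ops:
                o.observe(state)
        if step % config.log_every == 0:
            rows.append(_trace_row(step, state, lp_prior, lp_lik))
            if config.sample_trees:
                trees.append(write_newick(state.tree))

    report = []
    for a in adaptive:
        report.extend(a.report())
    report_df = pd.DataFrame(report) if report else None
    return Trace(pd.DataFrame(rows), trees, report_df)


def effective_sample_size(series) -> float:
    """ESS by the initial-positive-sequence autocorrelation truncation rule.

    ESS = n / (1 + 2 * sum(rho_k)), summing consecutive autocorrelations while
    the paired sums rho_{2t} + rho_{2t+1} stay positive. A constant series is
    degenerate and reported as n.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("series too short for an ESS estimate")
    v = np.var(x)
    if v == 0:
        return float(n)  # degenerate: no variation to autocorrelate
    xc = x - x.mean()
    full = np.correlate(xc, xc, mode="full")[n - 1:]
    rho = full / full[0]
    # Geyer: tau = 2 * sum of initial positive pair sums (rho_2t + rho_2t+1) - 1
    acc = 0.0
    t = 0
    while 2 * t + 1 < n:
        pair = rho[2 * t] + rho[2 * t + 1]
        if pair <= 0:
            break
        acc += pair
        t += 1
    tau = max(2.0 * acc - 1.0, 1.0 / n)
    return float(n / tau)
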