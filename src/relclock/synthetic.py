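"""Synthetic data generation and simulation-based experiment harnesses.

Generates Yule time trees, i.i.d. log-normal branch rates, and alignments
evolved under HKY (Jukes-Cantor as the equal-rates special case), and houses
the three study protocols: acceptance-rate screening of narrow-exchange-rate
variants against classic narrow exchange, ESS-per-state benchmarking of
operator configurations, and well-calibrated coverage studies in which truths
are drawn from the priors and credible intervals must cover them at the
nominal rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .treeio import TimeTree, NO_PARENT
from .clock import BranchRates, ClockModel, REAL, CAT, QUANT, lognormal_cdf
from .model import (Alignment, SubstModel, PhyloState, hky_transition_probs,
                    SIGMA_PRIOR, KAPPA_PRIOR, LAMBDA_PRIOR)
from .mcmc import run_chain


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_yule_tree(N: int, lam: float, rng) -> TimeTree:
    """Forward-simulate a Yule tree conditioned on N tips.

    Every lineage splits at rate lambda; after the Nth lineage appears the
    present is placed Exp(N*lambda) later, which makes the simulation density
    proportional to lambda^(N-1) * exp(-lambda * tree length) -- exactly the
    prior evaluated by :func:`relclock.model.yule_log_prior`.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if N < 2:
        raise ValueError("need at least 2 taxa")
    deltas = [rng.exponential(1.0 / (k * lam)) for k in range(2, N + 1)]
    height = float(np.sum(deltas))

    M = 2 * N - 1
    parent = np.full(M, NO_PARENT, dtype=np.int64)
    children = np.full((M, 2), NO_PARENT, dtype=np.int64)
    heights = np.zeros(M)
    root = M - 1
    heights[root] = height
    # active lineages as (parent node, child slot); internal ids descend from root
    active = [(root, 0), (root, 1)]
    depth = 0.0
    next_internal = root - 1
    for k in range(2, N):
        depth += deltas[k - 2]
        slot = int(rng.integers(len(active)))
        pnode, pslot = active.pop(slot)
        node = next_internal
        next_internal -= 1
        children[pnode, pslot] = node
        parent[node] = pnode
        heights[node] = height - depth
        active.extend([(node, 0), (node, 1)])
    leaf_ids = rng.permutation(N)
    for leaf, (pnode, pslot) in zip(leaf_ids, active):
        children[pnode, pslot] = leaf
        parent[leaf] = pnode
    labels = [f"t{i}" for i in range(N)]
    tree = TimeTree(labels, parent, children, heights)
    tree.validate()
    return tree


def simulate_branch_rates(n_branches: int, sigma: float, rng) -> np.ndarray:
    """i.i.d. mean-1 log-normal rates; the strict-clock limit sigma=0 gives 1."""
    if sigma == 0:
        return np.ones(n_branches)
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_branches))


def evolve_alignment(tree: TimeTree, rates: np.ndarray, L: int, kappa: float,
                     freqs, rng, mu_c: float = 1.0) -> Alignment:
    """Evolve nucleotides down the tree: per-branch expected substitutions
    are ``mu_c * r_i * tau_i``."""
    freqs = np.asarray(freqs, dtype=float)
    seq = {tree.root: rng.choice(4, size=L, p=freqs)}
    order = [tree.root]
    stack = [tree.root]
    while stack:
        i = stack.pop()
        if not tree.is_leaf(i):
            stack.extend(int(c) for c in tree.children[i])
            order.extend(int(c) for c in tree.children[i])
    for i in order[1:]:
        d = mu_c * rates[i] * tree.branch_length(i)
        P = hky_transition_probs(d, kappa, freqs)
        cum = np.cumsum(P, axis=1)
        u = rng.random(L)
        seq[i] = (u[:, None] > cum[seq[int(tree.parent[i])]]).sum(axis=1)
    mat = np.stack([seq[i] for i in range(tree.n_taxa)]).astype(np.int8)
    return Alignment(list(tree.labels), mat)


def simulate_dataset(N: int, L: int, sigma: float, lam: float = 5.0,
                     kappa: float = 2.0, freqs=(0.25, 0.25, 0.25, 0.25),
                     seed=None, rng=None):
    """Yule tree + log-normal branch rates + HKY alignment.

    Returns (TimeTree, rates indexed by non-root node, Alignment).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tree = simulate_yule_tree(N, lam, rng)
    rates = np.ones(tree.n_nodes)
    rates[:tree.n_nodes - 1] = simulate_branch_rates(tree.n_nodes - 1, sigma, rng)
    aln = evolve_alignment(tree, rates, L, kappa, freqs, rng)
    return tree, rates[:tree.n_nodes - 1], aln


def random_state(N: int, mode: str = REAL, rng=None, tree: TimeTree = None,
                 n_partitions: int = 1) -> PhyloState:
    """Draw a full state from the prior (initial state for a chain)."""
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    lam = float(LAMBDA_PRIOR.rvs(random_state=rng))
    sigma = float(SIGMA_PRIOR.rvs(random_state=rng))
    if tree is None:
        tree = simulate_yule_tree(N, lam, rng)
    k = tree.n_nodes - 1
    if mode == REAL:
        values = simulate_branch_rates(k, sigma, rng)
    elif mode == CAT:
        values = rng.integers(k, size=k)
    else:
        values = rng.uniform(size=k)
    rates = BranchRates(values, mode)
    subst = SubstModel(
        np.array([float(KAPPA_PRIOR.rvs(random_state=rng))] * n_partitions),
        np.atleast_2d(rng.dirichlet([10.0] * 4, size=n_partitions)),
        np.ones(n_partitions))
    return PhyloState(tree, rates, ClockModel(sigma), subst, lam)


# ---------------------------------------------------------------------------
# NER screening
# ---------------------------------------------------------------------------

def two_proportion_z(acc1, n1, acc2, n2):
    """Pooled one-sided two-proportion z statistic for rate1 > rate2."""
    if n1 == 0 or n2 == 0:
        return 0.0
    p1, p2 = acc1 / n1, acc2 / n2
    pooled = (acc1 + acc2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0
    return float((p1 - p2) / se)


def screen_ner_variants(variants, datasets, chain_length=4000, seed=0,
                        p_threshold=0.001, mode=REAL):
    """Acceptance-rate screening of NER variants against the null NER{}.

    ``variants`` is a list of constraint-name tuples; ``datasets`` a list of
    dicts with keys N, L, sigma (and optionally lam, kappa). For each dataset
    a chain is run from the generating truth with fixed (untuned) kernels, all
    variants plus the null proposing in the same chain; one-sided pooled
    z-tests compare each variant's acceptance rate against the null in both
    directions. Returns a tidy DataFrame, one row per (dataset, variant).
    """
    from .ner import NEROperator
    from .configs import build_config

    rng = np.random.default_rng(seed)
    z_crit = float(stats.norm.ppf(1 - p_threshold))
    rows = []
    for idx, ds in enumerate(datasets):
        tree, true_rates, aln = simulate_dataset(
            ds["N"], ds["L"], ds["sigma"], ds.get("lam", 5.0),
            ds.get("kappa", 2.0), rng=rng)
        state = random_state(ds["N"], mode, rng, tree=tree)
        state.clock.sigma = max(ds["sigma"], 0.05)
        if mode == REAL:
            state.rates.values[:] = true_rates
        elif mode == QUANT:
            state.rates.values[:] = np.clip(
                lognormal_cdf(true_rates, state.clock.sigma), 1e-6, 1 - 1e-6)
        null_op = NEROperator(())
        variant_ops = [NEROperator(v) for v in variants]
        config = build_config("nocons", mode, ds["N"],
                              chain_length=chain_length, log_every=chain_length,
                              tune=False)
        for op in [null_op] + variant_ops:
            config.operators.append((op, 15.0))
        run_chain(state, aln, config, rng)
        counts = {op.name: (op.proposed, op.accepted)
                  for op in [null_op] + variant_ops}
        n0, a0 = counts[null_op.name]
        for op in variant_ops:
            n1, a1 = counts[op.name]
            z_better = two_proportion_z(a1, n1, a0, n0)
            rows.append({
                "dataset": idx, "N": ds["N"], "L": ds["L"],
                "sigma": ds["sigma"], "variant": op.name,
                "proposed": n1, "accepted": a1,
                "accept_rate": a1 / n1 if n1 else np.nan,
                "null_proposed": n0, "null_accepted": a0,
                "null_accept_rate": a0 / n0 if n0 else np.nan,
                "z": z_better,
                "better": z_better > z_crit,
                "worse": -z_better > z_crit,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration benchmarking
# ---------------------------------------------------------------------------

KEY_PARAMS = ("likelihood", "prior", "tree_length", "mean_rate", "sigma", "kappa")


def benchmark_configurations(config_names, dataset, replicates=3,
                             chain_length=20000, log_every=20, seed=0,
                             mode=REAL):
    """Mean ESS-per-state (+/- s.e.) of key parameters per configuration.

    ``dataset`` is a dict with N, L, sigma (a fresh alignment is simulated
    once and shared); kappa serves as a positive control since clock-model
    operators should not affect its mixing.
    """
    from .configs import build_config

    rng = np.random.default_rng(seed)
    tree, true_rates, aln = simulate_dataset(
        dataset["N"], dataset["L"], dataset["sigma"], dataset.get("lam", 5.0),
        rng=rng)
    rows = []
    for name in config_names:
        per_param = {p: [] for p in KEY_PARAMS}
        for rep in range(replicates):
            state = random_state(dataset["N"], mode, rng, tree=tree.copy())
            config = build_config(name, mode, dataset["N"],
                                  chain_length=chain_length, log_every=log_every)
            trace = run_chain(state, aln, config, rng)
            for p in KEY_PARAMS:
                ess = trace.ess(p)
                per_param[p].append(ess / chain_length)
        for p in KEY_PARAMS:
            v = np.asarray(per_param[p])
            rows.append({"config": name, "parameter": p,
                         "ess_per_state": float(v.mean()),
                         "se": float(v.std(ddof=1) / np.sqrt(len(v)))
                         if len(v) > 1 else np.nan,
                         "replicates": replicates})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# well-calibrated coverage study
# ---------------------------------------------------------------------------

def coverage_study(replicates=50, N=8, L=500, chain_length=12000,
                   log_every=20, seed=0, mode=REAL, config_name="adapt",
                   level=0.95):
    """Well-calibrated simulation study: truths from the priors, data
    simulated, chains run; reports per-parameter credible-interval coverage.

    Returns (per-replicate DataFrame, coverage dict). Monitored: sigma, tree
    length, kappa.
    """
    from .configs import build_config

    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for rep in range(replicates):
        truth = random_state(N, REAL, rng)
        aln = evolve_alignment(
            truth.tree,
            np.concatenate([truth.rates.values, [1.0]]),
            L, float(truth.subst.kappa[0]), truth.subst.freqs[0], rng)
        from .treeio import tree_length as tl
        true_vals = {"sigma": truth.clock.sigma,
                     "tree_length": tl(truth.tree),
                     "kappa": float(truth.subst.kappa[0])}
        # stationary start: the truth is itself a draw from the joint
        # distribution of (parameters, data), so the chain starts in
        # equilibrium and every sample is a valid posterior draw
        state = truth.copy()
        config = build_config(config_name, mode, N, chain_length=chain_length,
                              log_every=log_every)
        trace = run_chain(state, aln, config, rng)
        burn = int(0.1 * len(trace.samples))
        post = trace.samples.iloc[burn:]
        row = {"replicate": rep}
        for p, truth_v in true_vals.items():
            lo, hi = post[p].quantile(lo_q), post[p].quantile(hi_q)
            row[f"{p}_true"] = truth_v
            row[f"{p}_lo"], row[f"{p}_hi"] = float(lo), float(hi)
            row[f"{p}_covered"] = bool(lo <= truth_v <= hi)
        rows.append(row)
    df = pd.DataFrame(rows)
    coverage = {p: float(df[f"{p}_covered"].mean())
                for p in ("sigma", "tree_length", "kappa")}
    return df, coverage


def binomial_coverage_band(n: int, p: float = 0.95, conf: float = 0.95):
    """Exact binomial acceptance band for an observed coverage count."""
    lo = int(stats.binom.ppf((1 - conf) / 2, n, p))
    hi = int(stats.binom.isf((1 - conf) / 2, n, p))
    return lo / n, hi / n
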