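import numpy as np
import pytest
from scipy import stats

from relclock import operators as ops
from relclock.treeio import TimeTree, NO_PARENT
from relclock.clock import BranchRates, ClockModel, REAL, CAT, QUANT
from relclock.model import PhyloState, SubstModel, tree_log_likelihood
from relclock.synthetic import simulate_dataset
from conftest import random_yule_state


class FixedKernel:
    """Deterministic step stub for exercising analytic formulas."""

    def __init__(self, value):
        self.value = value
        self.scale = 1.0
        self.frozen = True

    def step(self, rng, size=None):
        return self.value

    def record(self, accepted):
        pass


def make_state(heights, parent, children, rates, n_leaves, mode=REAL, sigma=0.6):
    labels = [f"L{i}" for i in range(n_leaves)]
    tree = TimeTree(labels, np.array(parent), np.array(children),
                    np.array(heights, dtype=float))
    return PhyloState(tree, BranchRates(np.array(rates, dtype=float), mode),
                      ClockModel(sigma), SubstModel.default())


@pytest.fixture
def cd_state():
    """One internal node X (heights: A=2, B=4, X=10, C=0, root P=20)."""
    return make_state(
        heights=[2.0, 4.0, 0.0, 10.0, 20.0],
        parent=[3, 3, 4, 4, NO_PARENT],
        children=[[NO_PARENT] * 2] * 3 + [[0, 1], [3, 2]],
        rates=[1.0, 1.0, 1.0, 1.0], n_leaves=3)


def test_random_walk_identity_and_domain(four_taxon_state, rng):
    op = ops.RandomWalk("rates", kernel=FixedKernel(0.0))
    prop = op.propose(four_taxon_state, rng)
    assert not prop.rejected
    assert np.array_equal(prop.state.rates.values, four_taxon_state.rates.values)
    assert prop.log_hastings == 0.0
    # quant domain exit
    st = random_yule_state(4, rng, mode=QUANT)
    st.rates.values[:] = 0.99
    prop = ops.RandomWalk("rates", kernel=FixedKernel(0.5)).propose(st, rng)
    assert prop.rejected


def test_random_walk_proposals_symmetric(four_taxon_state, rng):
    from relclock.kernels import Kernel
    op = ops.RandomWalk("rates", kernel=Kernel(scale=0.1))
    steps = []
    for _ in range(4000):
        prop = op.propose(four_taxon_state, rng)
        if not prop.rejected:
            steps.append((prop.state.rates.values
                          - four_taxon_state.rates.values).sum())
    steps = np.array(steps)
    assert abs(np.mean(steps > 0) - 0.5) < 0.03


def test_scale_hastings_matches_density_oracle(four_taxon_state, rng):
    """Uniform-kernel scale move: q(x'|x) = 1/(2 s x'), so the analytic HR
    log(x'/x) must equal log q(x|x') - log q(x'|x)."""
    from relclock.kernels import Kernel, UNIFORM
    op = ops.Scale("sigma", kernel=Kernel(family=UNIFORM, scale=0.7))
    for _ in range(5):
        prop = op.propose(four_taxon_state, rng)
        x, x2 = four_taxon_state.clock.sigma, prop.state.clock.sigma
        dens_ratio = np.log(1 / (2 * 0.7 * x)) - np.log(1 / (2 * 0.7 * x2))
        assert prop.log_hastings == pytest.approx(dens_ratio, rel=1e-12)


def test_interval_hastings_matches_numeric_jacobian(rng):
    st = random_yule_state(4, rng, mode=QUANT)
    u = 0.37
    op = ops.Interval(kernel=FixedKernel(u))
    prop = op.propose(st, rng)
    (i,) = np.where(prop.state.rates.values != st.rates.values)[0:1][0]
    q, q2 = st.rates.values[i], prop.state.rates.values[i]
    # dq'/dq at fixed logit step, by finite differences
    eps = 1e-7
    f = lambda v: 1 / (1 + np.exp(-(np.log(v / (1 - v)) + u)))
    fd = (f(q + eps) - f(q - eps)) / (2 * eps)
    assert prop.log_hastings == pytest.approx(np.log(fd), rel=1e-5)


def test_swap_is_involution_and_conserves_multiset(four_taxon_state, rng):
    op = ops.Swap()
    prop = op.propose(four_taxon_state, rng)
    assert sorted(prop.state.rates.values) == sorted(four_taxon_state.rates.values)
    assert prop.log_hastings == 0.0


def test_uniform_resample_cat_frequencies(rng):
    st = random_yule_state(3, rng, mode=CAT)
    st.rates.values[:] = 0
    op = ops.UniformResample()
    n = st.rates.n_categories
    counts = np.zeros(n)
    draws = 20_000
    for _ in range(draws):
        prop = op.propose(st, rng)
        changed = prop.state.rates.values[prop.state.rates.values != 0]
        if changed.size:
            counts[changed[0]] += 1
    counts[0] = draws - counts.sum()  # resampled value 0 leaves vector unchanged
    p = stats.chisquare(counts).pvalue
    assert p > 1e-3


def test_sample_from_prior_psi_binomial(rng):
    st = random_yule_state(6, rng)
    op = ops.SampleFromPrior("rates", kernel=FixedKernel(0.0))
    op.kernel.scale = 3.0
    psis = []
    for _ in range(3000):
        prop = op.propose(st, rng)
        psis.append(int(np.sum(prop.state.rates.values != st.rates.values)))
    m = np.mean(psis)
    se = np.std(psis) / np.sqrt(len(psis))
    assert abs(m - 3.0) < 4 * se + 0.05  # E[psi] = s
    # s > |x| clamps to resampling everything
    op.kernel.scale = 100.0
    prop = op.propose(st, rng)
    assert np.all(prop.state.rates.values != st.rates.values)


def test_constant_distance_worked_example(cd_state, rng):
    op = ops.ConstantDistance(kernel=FixedKernel(2.0))  # t_X: 10 -> 12
    prop = op.propose(cd_state, rng)
    assert not prop.rejected
    v = prop.state.rates.values
    assert v[0] == pytest.approx(0.8)    # child A: 8/10
    assert v[1] == pytest.approx(0.75)   # child B: 6/8
    assert v[3] == pytest.approx(1.25)   # X itself: 10/8
    assert prop.log_jacobian == pytest.approx(np.log(0.75))
    assert prop.state.tree.heights[3] == 12.0
    # identity case
    prop0 = ops.ConstantDistance(kernel=FixedKernel(0.0)).propose(cd_state, rng)
    assert prop0.log_jacobian == pytest.approx(0.0)
    # out of bounds
    assert ops.ConstantDistance(kernel=FixedKernel(11.0)).propose(cd_state, rng).rejected


def test_constant_distance_preserves_genetic_distances(rng):
    for mode in (REAL, QUANT):
        st = random_yule_state(8, rng, mode=mode)
        from relclock.kernels import Kernel
        op = ops.ConstantDistance(kernel=Kernel(scale=0.02))
        kept = 0
        for _ in range(300):
            prop = op.propose(st, rng)
            if prop.rejected:
                continue
            kept += 1
            r0, r1 = st.real_rates(), prop.state.real_rates()
            t0, t1 = st.tree, prop.state.tree
            for i in range(t0.n_nodes - 1):
                d0 = r0[i] * t0.branch_length(i)
                d1 = r1[i] * t1.branch_length(i)
                if mode == REAL:
                    assert d1 == pytest.approx(d0, abs=1e-12)
                else:  # quantile-map round trip loses tail precision
                    assert d1 == pytest.approx(d0, rel=1e-6)
        assert kept > 50


def test_simple_distance_worked_example(rng):
    st = make_state(heights=[2.0, 4.0, 10.0], parent=[2, 2, NO_PARENT],
                    children=[[NO_PARENT] * 2] * 2 + [[0, 1]],
                    rates=[1.0, 1.0], n_leaves=2)
    prop = ops.SimpleDistance(kernel=FixedKernel(2.0)).propose(st, rng)
    assert np.allclose(prop.state.rates.values, [0.8, 0.75])
    assert prop.log_jacobian == pytest.approx(np.log(0.6))
    assert ops.SimpleDistance(kernel=FixedKernel(-7.0)).propose(st, rng).rejected


def test_small_pulley_worked_example(rng):
    st = make_state(heights=[0.0, 0.0, 10.0], parent=[2, 2, NO_PARENT],
                    children=[[NO_PARENT] * 2] * 2 + [[0, 1]],
                    rates=[1.0, 1.0], n_leaves=2)
    prop = ops.SmallPulley(kernel=FixedKernel(2.0)).propose(st, rng)
    assert np.allclose(prop.state.rates.values, [1.2, 0.8])
    assert np.array_equal(prop.state.tree.heights, st.tree.heights)
    # total root distance conserved
    assert 1.2 * 10 + 0.8 * 10 == pytest.approx(20.0)
    assert ops.SmallPulley(kernel=FixedKernel(25.0)).propose(st, rng).rejected


def test_cis_scale_real_quantile_algebra(rng):
    st = random_yule_state(5, rng, sigma=0.6)
    st.rates.values[:] = 1.0
    f = 0.5  # sigma 0.6 -> 0.3
    prop = ops.CisScale(kernel=FixedKernel(np.log(f))).propose(st, rng)
    assert prop.state.clock.sigma == pytest.approx(0.3)
    assert np.allclose(prop.state.rates.values, np.exp(0.045))
    # quantiles preserved
    from relclock.clock import lognormal_cdf
    q0 = lognormal_cdf(1.0, 0.6)
    q1 = lognormal_cdf(np.exp(0.045), 0.3)
    assert q1 == pytest.approx(q0, abs=1e-9)


def test_cis_scale_quant_preserves_rates(rng):
    st = random_yule_state(5, rng, mode=QUANT, sigma=0.6)
    r_before = st.real_rates().copy()
    prop = ops.CisScale(kernel=FixedKernel(0.3)).propose(st, rng)
    assert not prop.rejected
    assert np.allclose(prop.state.real_rates(), r_before, rtol=1e-9)
    assert not prop.changes_likelihood


def test_constant_distance_family_likelihood_invariant(rng):
    """The 'walks along the ridge' property: likelihood identical before and
    after any constant-distance proposal."""
    tree, rates, aln = simulate_dataset(6, 200, 0.5, seed=5)
    from relclock.kernels import Kernel
    for mode in (REAL, QUANT):
        st = random_yule_state(6, rng, mode=mode)
        st.tree = tree.copy()
        ll = tree_log_likelihood(st, aln)
        for op in (ops.ConstantDistance(kernel=Kernel(scale=0.02)),
                   ops.SimpleDistance(kernel=Kernel(scale=0.02)),
                   ops.SmallPulley(kernel=Kernel(scale=0.02)),
                   ops.UpDown(kernel=Kernel(scale=0.2))):
            done = 0
            while done < 20:
                prop = op.propose(st, rng)
                if prop.rejected:
                    continue
                done += 1
                assert tree_log_likelihood(prop.state, aln) == pytest.approx(
                    ll, abs=1e-8)


def _numeric_logjac_cd(state, node, t_new):
    """Finite-difference |J| of the constant-distance map at one node."""
    tree = state.tree
    c1, c2 = (int(c) for c in tree.children[node])
    tp = float(tree.heights[tree.parent[node]])
    tx = float(tree.heights[node])

    def fwd(v):
        rc1, rc2, rx, t = v
        return np.array([
            rc1 * (t - tree.heights[c1]) / (t_new - tree.heights[c1]),
            rc2 * (t - tree.heights[c2]) / (t_new - tree.heights[c2]),
            rx * (tp - t) / (tp - t_new),
            t + (t_new - tx),
        ])

    x0 = np.array([*state.real_rates()[[c1, c2, node]], tx])
    eps = 1e-7
    J = np.zeros((4, 4))
    for j in range(4):
        dp, dm = x0.copy(), x0.copy()
        dp[j] += eps
        dm[j] -= eps
        J[:, j] = (fwd(dp) - fwd(dm)) / (2 * eps)
    return np.log(abs(np.linalg.det(J)))


def test_constant_distance_jacobian_matches_finite_differences(rng):
    st = random_yule_state(7, rng)
    from relclock.kernels import Kernel
    op = ops.ConstantDistance(kernel=Kernel(scale=0.03))
    checked = 0
    while checked < 50:
        prop = op.propose(st, rng)
        if prop.rejected:
            continue
        (moved,) = np.where(prop.state.tree.heights != st.tree.heights)[0:1][0],
        node = int(np.where(prop.state.tree.heights != st.tree.heights)[0][0])
        t_new = float(prop.state.tree.heights[node])
        num = _numeric_logjac_cd(st, node, t_new)
        assert prop.log_jacobian == pytest.approx(num, abs=1e-6)
        checked += 1


def test_updown_scales_and_keeps_distances(rng):
    st = random_yule_state(6, rng)
    prop = ops.UpDown(kernel=FixedKernel(np.log(1.3))).propose(st, rng)
    assert prop.state.tree.heights[prop.state.tree.root] == pytest.approx(
        1.3 * st.tree.heights[st.tree.root])
    assert np.allclose(prop.state.rates.values, st.rates.values / 1.3)
    N = st.tree.n_taxa
    assert prop.log_hastings == pytest.approx(-(N - 1) * np.log(1.3))


def test_leaf_avmvn_recovers_correlation(rng):
    st = make_state(heights=[0.0, 0.0, 1.0], parent=[2, 2, NO_PARENT],
                    children=[[NO_PARENT] * 2] * 2 + [[0, 1]],
                    rates=[1.0, 1.0], n_leaves=2)
    op = ops.LeafAVMVN(min_samples=100)
    cov = np.array([[1.0, 0.9], [0.9, 1.0]])  # strong positive correlation
    chol = np.linalg.cholesky(cov)
    for _ in range(2000):
        x = chol @ rng.standard_normal(2)
        obs = st.copy()
        obs.rates.values[:2] = np.exp(x)
        op.observe(obs)
    assert op.available(st)
    est = op.covariance()
    est_corr = est[0, 1] / np.sqrt(est[0, 0] * est[1, 1])
    assert est_corr == pytest.approx(0.9, abs=0.05)
    steps = []
    for _ in range(2000):
        prop = op.propose(st, rng)
        steps.append(np.log(prop.state.rates.values[:2]))
    corr = np.corrcoef(np.array(steps).T)[0, 1]
    assert corr == pytest.approx(0.9, abs=0.1)
    # proposal dimension = leaf count
    assert len(steps[0]) == st.tree.n_taxa
    # beta = 1 degenerates to an isotropic proposal
    iso = ops.LeafAVMVN(beta=1.0, min_samples=100)
    iso._count, iso._mean, iso._m2 = op._count, op._mean, op._m2
    stp = [np.log(iso.propose(st, rng).state.rates.values[:2]) for _ in range(3000)]
    assert abs(np.corrcoef(np.array(stp).T)[0, 1]) < 0.1


def test_avmvn_unavailable_before_learning(rng):
    st = random_yule_state(4, rng)
    op = ops.LeafAVMVN()
    assert not op.available(st)
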