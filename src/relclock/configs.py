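"""Named operator configurations for benchmarking and analysis.

Five configurations are expressible by name, matching the benchmarked operator
schemes: ``nocons`` (standard one-dimensional clock operators), ``cons``
(adds the constant-distance family), ``adapt`` (everything under adaptive
weight learning), ``avmvn`` (adapt with the leaf/internal split and the
LeafAVMVN joint proposal), and ``ner`` (adapt plus the adaptive
narrow-exchange-rate pair). Within each configuration the weight targeting
the rate vector sums to 30, the sigma weight is 10, and the topology
(narrow-exchange family) weight is 15; node-set operators are weighted by
leaf count N (e.g. 30*(2N-2)/(2N-1) for all-rates, 30/(2N-1) for the root).
"""

from __future__ import annotations

from . import operators as ops
from .clock import REAL, CAT, QUANT
from .kernels import Kernel, BACTRIAN
from .mcmc import ChainConfig
from .ner import NEROperator
from .adaptive import build_groupings

CONFIG_NAMES = ("nocons", "cons", "adapt", "avmvn", "ner")


def _base_operators(kf, mode, n_partitions=1, site_counts=None,
                    estimate_tree=True):
    """Plumbing shared by all configurations: substitution-model, birth-rate,
    node-height and rate-time ridge moves."""
    out = [
        (ops.Scale("kappa", kernel=kf()), 3.0),
        (ops.FreqExchange(kernel=kf(scale=0.1)), 3.0),
        (ops.Scale("lambda", kernel=kf()), 3.0),
        (ops.LambdaConditional(), 3.0),
    ]
    if estimate_tree:
        out += [
            (ops.UniformNodeHeight(), 15.0),
            (ops.RootScale(kernel=kf(scale=0.1)), 3.0),
        ]
        if mode == CAT:
            out.append((ops.TreeScale(kernel=kf(scale=0.3)), 10.0))
        else:
            out.append((ops.UpDown(kernel=kf(scale=0.3)), 10.0))
    if n_partitions > 1:
        out.append((ops.MuCExchange(site_counts, kernel=kf(scale=0.1)), 3.0))
    return out


def build_config(name: str, mode: str = REAL, N: int = 10,
                 chain_length: int = 100_000, log_every: int = 100,
                 kernel_family: str = BACTRIAN, tune: bool = True,
                 estimate_tree: bool = True, n_partitions: int = 1,
                 site_counts=None, sample_trees: bool = False) -> ChainConfig:
    """Assemble a :class:`~relclock.mcmc.ChainConfig` for a named scheme."""
    if name not in CONFIG_NAMES:
        raise ValueError(f"unknown configuration {name!r}; choose from {CONFIG_NAMES}")
    if mode not in (REAL, CAT, QUANT):
        raise ValueError(f"unknown parameterisation {mode!r}")
    if name in ("cons", "avmvn", "ner") and mode == CAT:
        raise ValueError(f"configuration {name!r} requires real or quant rates"
                         " (constant-distance operators are incompatible with cat)")

    def kf(scale=0.5):
        k = Kernel(family=kernel_family, scale=scale)
        k.frozen = not tune
        return k

    two_n = 2.0 * N
    w_all_rates = 30.0 * (two_n - 2) / (two_n - 1)
    w_root = 30.0 / (two_n - 1)
    schedule = _base_operators(kf, mode, n_partitions, site_counts,
                               estimate_tree)

    if name == "nocons":
        if mode == REAL:
            schedule += [(ops.RandomWalk("rates", kernel=kf()), 10.0),
                         (ops.Scale("rates", kernel=kf()), 10.0),
                         (ops.Swap(), 10.0)]
        elif mode == CAT:
            schedule += [(ops.RandomWalk("rates", kernel=kf()), 10.0),
                         (ops.UniformResample(), 10.0),
                         (ops.Swap(), 10.0)]
        else:
            schedule += [(ops.UniformResample(), 10.0),
                         (ops.Interval(kernel=kf()), 10.0),
                         (ops.Swap(), 10.0)]
        schedule.append((ops.Scale("sigma", kernel=kf()), 10.0))

    elif name == "cons":
        w_cd = 20.0 * (two_n - 2) / (two_n - 1)
        w_rs = 10.0 / (two_n - 1)
        # height/distance moves live on the tree's (small) time scale
        schedule += [(ops.ConstantDistance(kernel=kf(scale=0.05)), w_cd),
                     (ops.SimpleDistance(kernel=kf(scale=0.05)), w_rs),
                     (ops.SmallPulley(kernel=kf(scale=0.05)), w_rs)]
        if mode == REAL:
            schedule += [(ops.RandomWalk("rates", kernel=kf()), 5.0),
                         (ops.Scale("rates", kernel=kf()), 2.5),
                         (ops.Swap(), 2.5),
                         (ops.CisScale(kernel=kf()), 10.0)]
        else:
            schedule += [(ops.UniformResample(), 5.0),
                         (ops.Interval(kernel=kf()), 2.5),
                         (ops.Swap(), 2.5),
                         (ops.Scale("sigma", kernel=kf()), 10.0)]

    groups = None
    if name in ("adapt", "avmvn", "ner"):
        groups = build_groupings(mode, kernel_factory=kf,
                                 avmvn=(name == "avmvn"), ner=(name == "ner"))
        schedule.append((groups["sigma"], 10.0))
        if name == "avmvn":
            w_leaf = 30.0 * N / (two_n - 1)
            w_int = 30.0 * (N - 2) / (two_n - 1)
            schedule += [(groups["leaf"], w_leaf), (groups["internal"], w_int)]
        elif mode == CAT:
            schedule.append((groups["rates"], 30.0))
        else:
            schedule.append((groups["rates"], w_all_rates))
        if "root" in groups:
            schedule.append((groups["root"], w_root))

    # topology: the adaptive NER pair in the 'ner' config, plain narrow
    # exchange (the null NER) everywhere else
    if estimate_tree:
        if name == "ner":
            schedule.append((groups["ner"], 15.0))
        else:
            schedule.append((NEROperator(()), 15.0))

    return ChainConfig(chain_length=chain_length, log_every=log_every,
                       operators=schedule, sample_trees=sample_trees)
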