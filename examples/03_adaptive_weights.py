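"""Watch the adaptive meta-operator learn which sub-operators earn their keep.

On a simulated 8-taxon, 2 kb alignment the AdaptiveOperatorSampler runs its
burn-in / learn-in / sampling phases and weights each sub-operator by the
accepted squared scaled move distance it generates per second of runtime.
Printed: the learned sampling probability, acceptance rate and time spent for
every sub-operator. On a long alignment the constant-distance operator (which
keeps the likelihood fixed while moving rates and times jointly) typically
earns a large weight; SampleFromPrior is bold but rarely accepted here.
"""

import numpy as np

from relclock.synthetic import simulate_dataset, random_state
from relclock.configs import build_config
from relclock.mcmc import run_chain

tree, rates, aln = simulate_dataset(8, 2000, 0.6, seed=11)
state = random_state(8, "real", 3, tree=tree.copy())
config = build_config("adapt", "real", 8, chain_length=20_000, log_every=100)
trace = run_chain(state, aln, config, np.random.default_rng(3))

report = trace.operator_report
report["runtime_s"] = report["runtime_s"].round(2)
cols = ["meta", "operator", "learned_weight", "accept_rate", "runtime_s"]
with np.printoptions(precision=3):
    print(report[cols].round(3).to_string(index=False))
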