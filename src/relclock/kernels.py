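"""Proposal step-size kernels and acceptance-rate auto-tuning.

A kernel draws a unit step Sigma (mean 0) that operators apply as ``s * Sigma``
with tunable scale ``s``. Two families: the uniform kernel on (-1, 1) and the
Bactrian(m) kernel, a two-humped mixture

    Sigma ~ 1/2 Normal(-m, sqrt(1-m^2)) + 1/2 Normal(+m, sqrt(1-m^2))

which has mean 0 and variance 1 for any modality 0 <= m < 1 and avoids
wastefully small steps. Scales are tuned toward a target acceptance rate
(0.234 for uniform, 0.3 for Bactrian) with a diminishing-adaptation schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UNIFORM, BACTRIAN = "uniform", "bactrian"


def bactrian_draw(m: float, rng: np.random.Generator, size=None):
    """Draw from Bactrian(m); m = 0 reduces to Normal(0, 1)."""
    if not 0 <= m < 1:
        raise ValueError("modality m must satisfy 0 <= m < 1")
    sd = np.sqrt(1.0 - m * m)
    sign = np.where(rng.random(size) < 0.5, -1.0, 1.0)
    return sign * m + rng.normal(0.0, sd, size)


@dataclass
class Kernel:
    """Step-size kernel with Robbins-Monro scale tuning.

    Tuning: after each batch of ``batch_size`` proposals the log scale moves by
    ``(observed rate - target) / sqrt(batch index)``; the step vanishes as the
    batch index grows (diminishing adaptation). ``frozen`` stops all tuning.
    """

    family: str = BACTRIAN
    m: float = 0.95
    scale: float = 0.5
    target: float = None
    batch_size: int = 50
    frozen: bool = False
    _acc: int = field(default=0, repr=False)
    _prop: int = field(default=0, repr=False)
    _batch: int = field(default=0, repr=False)

    def __post_init__(self):
        if self.family not in (UNIFORM, BACTRIAN):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.target is None:
            self.target = 0.234 if self.family == UNIFORM else 0.3

    def draw(self, rng: np.random.Generator, size=None):
        if self.family == UNIFORM:
            return rng.uniform(-1.0, 1.0, size)
        return bactrian_draw(self.m, rng, size)

    def step(self, rng: np.random.Generator, size=None):
        return self.scale * self.draw(rng, size)

    def record(self, accepted: bool):
        """Register one accept/reject outcome and tune at batch boundaries."""
        if self.frozen:
            return
        self._prop += 1
        self._acc += accepted
        if self._prop >= self.batch_size:
            self._batch += 1
            rate = self._acc / self._prop
            self.scale = float(np.exp(
                np.log(self.scale) + (rate - self.target) / np.sqrt(self._batch)))
            self._acc = 0
            self._prop = 0

    def copy(self) -> "Kernel":
        return Kernel(self.family, self.m, self.scale, self.target,
                      self.batch_size, self.frozen)


def tune_scale(kernel: Kernel, accepted: int, proposed: int) -> float:
    """One tuning update from aggregate counts; returns the new scale."""
    if proposed <= 0:
        raise ValueError("proposed count must be positive")
    kernel._batch += 1
    rate = accepted / proposed
    kernel.scale = float(np.exp(
        np.log(kernel.scale) + (rate - kernel.target) / np.sqrt(kernel._batch)))
    return kernel.scale
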