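"""Branch-rate parameterisations for the uncorrelated log-normal relaxed clock.

A relaxed clock assigns every branch its own substitution rate. Rates are
i.i.d. log-normal with log-mean ``mu = -sigma^2/2`` so the prior mean rate is
exactly 1 (identifiable against the overall clock rate). Three equivalent
parameterisations of the rate vector are supported:

* ``real``  -- the rates themselves, positive reals; log-normal prior density.
* ``cat``   -- each branch holds an integer bin ``0..n-1``; the bin's rate is
  the log-normal quantile at the bin midpoint ``(R+0.5)/n``; flat prior 1/n.
* ``quant`` -- each branch holds the rate's quantile in (0,1); flat prior 1;
  rates come from a piecewise-linear approximation of the inverse CDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

REAL, CAT, QUANT = "real", "cat", "quant"
MODES = (REAL, CAT, QUANT)


def lognormal_mu(sigma: float) -> float:
    """Log-mean giving a mean-1 log-normal at clock standard deviation sigma."""
    return -0.5 * sigma * sigma


def lognormal_rate_logpdf(r, sigma: float):
    """Log density of the mean-1 log-normal rate prior; -inf for r <= 0."""
    r = np.asarray(r, dtype=float)
    out = np.full(r.shape, -np.inf)
    ok = r > 0
    if np.any(ok):
        mu = lognormal_mu(sigma)
        lr = np.log(r[ok])
        out[ok] = (-lr - np.log(sigma) - 0.5 * np.log(2 * np.pi)
                   - 0.5 * ((lr - mu) / sigma) ** 2)
    return out if out.shape else float(out)


def lognormal_icdf(q, sigma: float):
    q = np.asarray(q, dtype=float)
    return np.exp(lognormal_mu(sigma) + sigma * stats.norm.ppf(q))


def lognormal_cdf(r, sigma: float):
    r = np.asarray(r, dtype=float)
    return stats.norm.cdf((np.log(r) - lognormal_mu(sigma)) / sigma)


def cat_rate(R_i, n: int, sigma: float):
    """Rate of category R_i: the log-normal quantile at the bin midpoint."""
    R_i = np.asarray(R_i)
    if np.any(R_i < 0) or np.any(R_i >= n):
        raise ValueError(f"category index out of range 0..{n - 1}")
    return lognormal_icdf((R_i + 0.5) / n, sigma)


class PiecewiseICDF:
    """Piecewise-linear approximation of the mean-1 log-normal inverse CDF.

    The quantile axis is cut into ``pieces`` equal bins. The first and final
    pieces evaluate the exact inverse CDF (the tails are unbounded); interior
    pieces interpolate linearly in rate space between exact knot values.
    """

    def __init__(self, sigma: float, pieces: int = 100):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.sigma = sigma
        self.pieces = pieces
        # interior knots q = 1/pieces .. (pieces-1)/pieces
        self.knots_q = np.arange(1, pieces) / pieces
        self.knots_r = lognormal_icdf(self.knots_q, sigma)

    def _interior(self, q):
        return (q >= self.knots_q[0]) & (q <= self.knots_q[-1])

    def icdf(self, q):
        """F_hat^{-1}(q) for q in (0,1)."""
        q = np.asarray(q, dtype=float)
        scalar = q.ndim == 0
        q = np.atleast_1d(q)
        if np.any(q <= 0) or np.any(q >= 1):
            raise ValueError("quantile must lie strictly in (0,1)")
        out = np.empty_like(q)
        inner = self._interior(q)
        out[~inner] = lognormal_icdf(q[~inner], self.sigma)
        out[inner] = np.interp(q[inner], self.knots_q, self.knots_r)
        return float(out[0]) if scalar else out

    def icdf_deriv(self, q):
        """d F_hat^{-1} / dq: piece slope inside, exact 1/f(F^{-1}) on tails."""
        q = np.asarray(q, dtype=float)
        scalar = q.ndim == 0
        q = np.atleast_1d(q)
        out = np.empty_like(q)
        inner = self._interior(q)
        if np.any(~inner):
            r = lognormal_icdf(q[~inner], self.sigma)
            pdf = np.exp(lognormal_rate_logpdf(r, self.sigma))
            out[~inner] = 1.0 / pdf
        if np.any(inner):
            idx = np.clip(np.searchsorted(self.knots_q, q[inner], side="right") - 1,
                          0, len(self.knots_q) - 2)
            slope = (self.knots_r[idx + 1] - self.knots_r[idx]) * self.pieces
            out[inner] = slope
        return float(out[0]) if scalar else out

    def cdf(self, r):
        """F_hat(r): exact inverse of :meth:`icdf` (monotone by construction)."""
        r = np.asarray(r, dtype=float)
        scalar = r.ndim == 0
        r = np.atleast_1d(r)
        out = np.empty_like(r)
        inner = (r >= self.knots_r[0]) & (r <= self.knots_r[-1])
        out[~inner] = lognormal_cdf(r[~inner], self.sigma)
        out[inner] = np.interp(r[inner], self.knots_r, self.knots_q)
        return float(out[0]) if scalar else out


class ClockModel:
    """Mean-1 log-normal clock with standard deviation sigma.

    Caches the piecewise inverse-CDF per sigma (rebuilt whenever sigma moves),
    which the *quant* parameterisation and the cis/trans sigma scalers use.
    """

    def __init__(self, sigma: float, pieces: int = 100):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.sigma = float(sigma)
        self.pieces = pieces
        self._approx = None

    @property
    def mu(self) -> float:
        return lognormal_mu(self.sigma)

    @property
    def approx(self) -> PiecewiseICDF:
        if self._approx is None or self._approx.sigma != self.sigma:
            self._approx = PiecewiseICDF(self.sigma, self.pieces)
        return self._approx

    def quant_rate(self, q):
        return self.approx.icdf(q)

    def copy(self) -> "ClockModel":
        return ClockModel(self.sigma, self.pieces)


def quant_rate(q, sigma: float, pieces: int = 100):
    """F_hat^{-1}(q): piecewise-approximated log-normal quantile rate."""
    return PiecewiseICDF(sigma, pieces).icdf(q)


@dataclass
class BranchRates:
    """Abstracted branch-rate vector of length 2N-2 plus its parameterisation.

    ``values[i]`` belongs to non-root node ``i`` (the root entry of a length
    2N-1 state vector is simply absent here; callers index by node id through
    :class:`~relclock.model.PhyloState`).
    """

    values: np.ndarray
    mode: str = REAL
    n_categories: int = 0  # cat only; default 2N-2 set by the caller

    def __post_init__(self):
        self.values = np.asarray(self.values,
                                 dtype=np.int64 if self.mode == CAT else float)
        if self.mode not in MODES:
            raise ValueError(f"unknown parameterisation {self.mode!r}")
        if self.mode == CAT and self.n_categories == 0:
            self.n_categories = len(self.values)
        self.check()

    def check(self):
        v = self.values
        if self.mode == REAL and np.any(v <= 0):
            raise ValueError("real rates must be positive")
        if self.mode == CAT and (np.any(v < 0) or np.any(v >= self.n_categories)):
            raise ValueError("category indices out of range")
        if self.mode == QUANT and (np.any(v <= 0) or np.any(v >= 1)):
            raise ValueError("quantiles must lie strictly in (0,1)")

    def real_rates(self, clock: ClockModel) -> np.ndarray:
        """Transform the abstraction into real branch rates r(R)."""
        if self.mode == REAL:
            return self.values
        if self.mode == CAT:
            return cat_rate(self.values, self.n_categories, clock.sigma)
        return clock.approx.icdf(self.values)

    def log_prior(self, clock: ClockModel) -> float:
        """log p(R | sigma): log-normal product (real), -k log n (cat), 0 (quant)."""
        if self.mode == REAL:
            return float(np.sum(lognormal_rate_logpdf(self.values, clock.sigma)))
        if self.mode == CAT:
            return -len(self.values) * np.log(self.n_categories)
        return 0.0

    def copy(self) -> "BranchRates":
        return BranchRates(self.values.copy(), self.mode, self.n_categories)
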