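"""Environmental time series, developmental cues and the selective optimum.

The environment ``eps`` is evaluated at two time points per generation: the
developmental cue at ``t - tau`` (a fraction ``tau`` of a generation before
selection) and the selection-time value at ``t``, which maps onto the
phenotypic optimum through ``theta_t = A + B * eps_t``.

Background stochasticity ``xi`` is an autocorrelated Gaussian (AR(1)) series
with per-generation lag-1 autocorrelation ``rho`` and stationary variance
``sigma_xi2``.  Because the cue is sampled at fractional times, ``xi`` is
simulated on a sub-generation grid of step ``h`` dividing both 1 and ``tau``,
with per-step coefficient ``rho**h`` and innovation variance
``sigma_xi2 * (1 - rho**(2h))``, so the per-generation autocorrelation is
exactly ``rho`` and ``cor(xi_{t-tau}, xi_t) = rho**tau``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import DegenerateSeriesError, ParameterError
from .params import EnvParams

__all__ = [
    "EnvSample",
    "EnvironmentProcess",
    "optimum",
    "ar1_noise",
    "theta_lag1_autocorrelation",
    "lagged_cue_optimum_correlation",
    "pearson",
]


@dataclass(frozen=True)
class EnvSample:
    """Environment of one generation: cue, selection-time value, optimum."""

    t: int
    cue: float
    env_at_selection: float
    theta: float


def optimum(env_value, params: EnvParams):
    """Phenotypic optimum ``theta = A + B * env_value``."""
    return params.A + params.B * np.asarray(env_value)


def ar1_noise(n_steps: int, step_size: float, sigma_xi2: float, rho: float,
              seed=None, rng: np.random.Generator | None = None) -> np.ndarray:
    """Stationary AR(1) Gaussian series on a grid of ``step_size`` generations.

    The marginal variance is ``sigma_xi2`` and the correlation between values
    ``h`` generations apart is ``rho**h``; values one *generation* apart thus
    have correlation exactly ``rho`` regardless of the grid refinement.
    """
    if n_steps < 1:
        raise ParameterError("n_steps must be >= 1")
    if not 0 <= rho < 1:
        raise ParameterError("rho must lie in [0, 1)")
    if sigma_xi2 < 0:
        raise ParameterError("sigma_xi2 must be >= 0")
    if step_size <= 0:
        raise ParameterError("step_size must be > 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    if sigma_xi2 == 0:
        return np.zeros(n_steps)
    phi = rho ** step_size
    innov_sd = np.sqrt(sigma_xi2 * (1.0 - phi * phi))
    xi = np.empty(n_steps)
    xi[0] = rng.normal(0.0, np.sqrt(sigma_xi2))
    shocks = rng.normal(0.0, innov_sd, size=n_steps - 1)
    for i in range(1, n_steps):
        xi[i] = phi * xi[i - 1] + shocks[i - 1]
    return xi


def _grid_step(tau: float) -> Fraction:
    """Sub-generation grid step dividing both 1 and ``tau`` (tau rational)."""
    if tau == 0:
        return Fraction(1)
    frac = Fraction(tau).limit_denominator(10**6)
    if abs(float(frac) - tau) > 1e-12:
        raise ParameterError("tau must be a rational fraction of a generation")
    return Fraction(1, frac.denominator)


class EnvironmentProcess:
    """Generator of ``(cue, env_at_selection, theta)`` per generation.

    The noise realization for generations ``0 .. n_generations`` is drawn up
    front from ``seed``, making every downstream run deterministic.  The grid
    extends one generation before ``t = 0`` so the founder cohort's cue at
    ``-tau`` is defined.
    """

    def __init__(self, params: EnvParams, n_generations: int,
                 seed=None, rng: np.random.Generator | None = None):
        if params.scenario == "two_patch":
            raise ParameterError(
                "two_patch is a spatial scenario resolved per individual in the "
                "IBM; it has no single global environment series")
        self.params = params
        self.n_generations = int(n_generations)
        h = _grid_step(params.tau)
        self._q = h.denominator  # grid points per generation
        n_points = self._q * (self.n_generations + 2) + 1
        self._offset = self._q  # index of s = 0; grid starts at s = -1
        self._xi = ar1_noise(n_points, float(h), params.sigma_xi2, params.rho,
                             seed=seed, rng=rng)

    def _index(self, s) -> np.ndarray:
        idx = np.rint(np.asarray(s) * self._q).astype(int) + self._offset
        if np.any(idx < 0) or np.any(idx >= len(self._xi)):
            raise ParameterError(
                f"time {s} outside the simulated window "
                f"[-1, {self.n_generations + 1}]")
        return idx

    def xi(self, s):
        """Background noise at (possibly fractional) generation ``s``."""
        return self._xi[self._index(s)]

    def eps(self, s):
        """Environment value at time ``s`` (deterministic part + noise)."""
        p = self.params
        s_arr = np.asarray(s, dtype=float)
        if p.scenario == "constant":
            det = np.full_like(s_arr, p.epsilon_const)
        elif p.scenario == "step":
            det = np.where(s_arr >= p.t_switch, p.delta, 0.0)
        elif p.scenario == "sinusoid":
            det = np.sin(p.f * s_arr)
        elif p.scenario == "stochastic":
            det = np.zeros_like(s_arr)
        else:  # pragma: no cover - excluded in __init__
            raise ParameterError(f"unsupported scenario {p.scenario!r}")
        return det + self.xi(s)

    def sample(self, t: int) -> EnvSample:
        """Cue, selection-time environment and optimum of generation ``t``."""
        if t < 0:
            raise ParameterError("t must be >= 0")
        cue = float(self.eps(t - self.params.tau))
        env = float(self.eps(t))
        return EnvSample(t=int(t), cue=cue, env_at_selection=env,
                         theta=float(optimum(env, self.params)))

    def series(self, n_generations: int | None = None):
        """Vectorized ``(cues, envs, thetas)`` for generations ``0 .. n-1``."""
        n = self.n_generations if n_generations is None else int(n_generations)
        t = np.arange(n, dtype=float)
        cues = self.eps(t - self.params.tau)
        envs = self.eps(t)
        return cues, envs, np.asarray(optimum(envs, self.params))


def pearson(x, y) -> float:
    """Pearson correlation with an explicit degenerate-series signal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ParameterError("series must have equal length >= 2")
    vx = np.var(x)
    vy = np.var(y)
    if vx < 1e-20 or vy < 1e-20:
        raise DegenerateSeriesError(
            "correlation undefined on a (numerically) zero-variance series")
    return float(np.corrcoef(x, y)[0, 1])


def theta_lag1_autocorrelation(f: float, n_periods: int = 1000) -> float:
    """Lag-1 autocorrelation of the sinusoidal optimum, ``cor(sin(ft), sin(f(t+1)))``.

    Evaluated over integer generations covering ``n_periods`` full periods
    (the closed-form limit is ``cos(f)``).  ``f = 0`` and ``f = pi`` give a
    zero-variance series on the integer grid and are signalled as degenerate.
    """
    if not 0 < f <= np.pi:
        raise DegenerateSeriesError(
            "lag-1 autocorrelation undefined for f outside (0, pi]")
    if n_periods < 1:
        raise ParameterError("n_periods must be >= 1")
    n = int(np.ceil(n_periods * 2 * np.pi / f)) + 1
    x = np.sin(f * np.arange(n))
    return pearson(x[:-1], x[1:])


def lagged_cue_optimum_correlation(trajectory, tau: float | None = None) -> float:
    """Correlation between the developmental cue ``eps_{t-tau}`` and the optimum.

    ``trajectory`` is anything exposing ``cue`` and ``theta`` columns (a
    Trajectory or a DataFrame); for a noiseless sinusoid the closed form is
    ``cos(f * tau)`` up to the discreteness of the generation grid.
    """
    frame = getattr(trajectory, "frame", trajectory)
    return pearson(frame["cue"].to_numpy(), frame["theta"].to_numpy())
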