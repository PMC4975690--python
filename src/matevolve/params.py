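"""Parameter containers for the recursion engine, the environment and the IBM.

All parameters are plain dataclasses validated on construction.  Defaults
follow the baseline parameterization used throughout: weak Gaussian
stabilizing selection (``omega_z2 = 40``), small costs of plasticity and
maternal effects (``omega_b2 = omega_m2 = 100``), additive genetic variances
``G_aa = 0.1``, ``G_bb = 0.045``, ``G_mm = 0.005`` and developmental noise
``sigma_e2 = 1``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

from .errors import ParameterError

SCENARIOS = ("constant", "step", "sinusoid", "stochastic", "two_patch")

#: Stability guard on the mean maternal-effect coefficient.  Phenotypic
#: variances diverge as |m| -> 1; the recursion aborts beyond this bound.
M_STABILITY_BOUND = 0.95


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class ModelParams:
    """Constants of the phenotype model, fitness function and G-matrix.

    Attributes
    ----------
    G_aa, G_bb, G_mm
        Additive genetic variances of the reaction-norm elevation ``a``,
        plasticity slope ``b`` and maternal-effect coefficient ``m``.
    omega_z2
        Squared width of the Gaussian fitness function around the optimum
        (inversely proportional to the strength of stabilizing selection).
    omega_b2, omega_m2
        Inverse cost measures for plasticity and maternal effects.
    sigma_e2
        Residual developmental variance of the phenotype.
    W_max
        Maximal individual fitness (1 without loss of generality).
    """

    G_aa: float = 0.1
    G_bb: float = 0.045
    G_mm: float = 0.005
    omega_z2: float = 40.0
    omega_b2: float = 100.0
    omega_m2: float = 100.0
    sigma_e2: float = 1.0
    W_max: float = 1.0

    def __post_init__(self) -> None:
        for name in ("G_aa", "G_bb", "G_mm", "sigma_e2"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        for name in ("omega_z2", "omega_b2", "omega_m2"):
            _require(getattr(self, name) > 0, f"{name} must be > 0")
        _require(0 <= self.G_mm < 1, "G_mm must lie in [0, 1)")
        _require(self.W_max > 0, "W_max must be > 0")

    def replace(self, **kw: Any) -> "ModelParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class EnvParams:
    """Environment process and optimum-map parameters.

    The optimum is ``theta_t = A + B * eps_t``.  The environment ``eps``
    follows one of five scenarios; background noise ``xi`` is an AR(1)
    Gaussian series with per-generation lag-1 autocorrelation ``rho`` and
    stationary variance ``sigma_xi2``.  Individuals perceive the
    developmental cue at time ``t - tau`` (a fraction of a generation before
    selection at time ``t``).
    """

    A: float = 0.0
    B: float = 2.0
    tau: float = 0.25
    sigma_xi2: float = 0.01
    rho: float = 0.5
    scenario: str = "constant"
    delta: float = 10.0
    t_switch: int = 10
    f: float = 0.5
    epsilon_const: float = 0.0
    dispersal_d: float = 0.1

    def __post_init__(self) -> None:
        _require(self.scenario in SCENARIOS,
                 f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        _require(self.sigma_xi2 >= 0, "sigma_xi2 must be >= 0")
        _require(0 <= self.rho < 1, "rho must lie in [0, 1)")
        _require(0 <= self.tau < 1, "tau must lie in [0, 1)")
        _require(self.f >= 0, "f must be >= 0")
        _require(0 <= self.dispersal_d <= 1, "dispersal_d must lie in [0, 1]")
        _require(self.t_switch >= 0, "t_switch must be >= 0")

    def replace(self, **kw: Any) -> "EnvParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class IBMParams:
    """Individual-based simulator parameters.

    ``N`` hermaphrodites with discrete generations; survival floored at
    ``w_min`` to prevent premature extinction away from the optimum;
    continuum-of-alleles mutation with per-allele probability ``mu_x`` and
    Gaussian increment variance ``sigma_mut_x2`` at each of the three
    unlinked diploid loci.
    """

    N: int = 5000
    w_min: float = 0.1
    mu_a: float = 0.02
    mu_b: float = 0.02
    mu_m: float = 0.02
    sigma_mut_a2: float = 0.0025
    sigma_mut_b2: float = 0.0025
    sigma_mut_m2: float = 0.0025
    n_generations: int = 50_000
    n_replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.N >= 2, "N must be >= 2")
        _require(0 <= self.w_min < 1, "w_min must lie in [0, 1)")
        for name in ("mu_a", "mu_b", "mu_m"):
            _require(0 <= getattr(self, name) <= 1, f"{name} must lie in [0, 1]")
        for name in ("sigma_mut_a2", "sigma_mut_b2", "sigma_mut_m2"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")
        _require(self.n_generations >= 1, "n_generations must be >= 1")
        _require(self.n_replicates >= 1, "n_replicates must be >= 1")

    def replace(self, **kw: Any) -> "IBMParams":
        return dataclasses.replace(self, **kw)
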