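"""Deterministic iteration of the mean-trait and moment recursions.

The phenotype of an individual in generation ``t`` is

    z_t = a_t + b_t * eps_{t-tau} + m_t * z*_{t-1} + e_t,

where ``a`` is the reaction-norm elevation, ``b`` the plasticity slope acting
on the developmental cue, ``m`` the maternal-effect coefficient acting on the
mother's post-selection phenotype ``z*``, and ``e ~ N(0, sigma_e2)``.
Survival follows a Gaussian fitness function of width ``omega_z2`` around the
optimum ``theta``, with additional Gaussian costs on ``b`` and ``m``.

Trait means evolve by the multivariate breeder's equation: each
per-generation change equals the trait's additive genetic variance times the
gradient of log mean fitness.  Because maternal effects make the phenotype
depend recursively on all ancestors, the phenotypic variance has no simple
closed form; the engine closes the moment hierarchy by tracking, per
generation, the after-selection mean and variance of the maternal phenotype
together with the covariances between each breeding value (a, b, m) and the
maternal phenotype (a Gaussian closure: third and higher central moments are
dropped).  At a constant environment and frozen trait means this closure's
fixed point reduces to the weak-selection equilibrium variance

    sigma_z^2 ~= [ (2+m)/(2-m) (G_aa + G_bb eps^2 + G_mm z^2)
                   + z^2 G_mm^2/(2-m)^2 + sigma_e^2 ] / (1 - G_mm - m^2),

whose (2-m) denominators arise from the geometric parent-offspring
covariance chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .environment import EnvironmentProcess
from .errors import DivergenceError, ParameterError
from .params import M_STABILITY_BOUND, ModelParams
from .trajectory import Trajectory

__all__ = [
    "TraitState", "mean_phenotype", "select", "mean_fitness",
    "phenotypic_variance_step", "variance_fixed_point", "equilibrium_variance",
    "trait_update", "delta_m_initial", "iterate", "iterate_ensemble",
]


@dataclass
class TraitState:
    """Population state entering a generation.

    ``z_bar_star`` and ``sigma_z2_star`` are the previous generation's
    after-selection phenotypic mean and variance (the maternal input);
    ``cov_a_zstar``, ``cov_b_zstar`` and ``cov_m_zstar`` are the retained
    covariances between the current generation's breeding values and the
    maternal post-selection phenotype, which close the variance recursion.
    ``z_bar`` and ``sigma_z2`` are filled in during development.
    """

    a_bar: float
    b_bar: float
    m_bar: float
    z_bar_star: float = 0.0
    sigma_z2_star: float = 1.0
    cov_a_zstar: float = 0.0
    cov_b_zstar: float = 0.0
    cov_m_zstar: float = 0.0
    z_bar: float = math.nan
    sigma_z2: float = math.nan

    @classmethod
    def founder(cls, params: ModelParams, a_bar: float = 1e-4,
                b_bar: float = 1e-4, m_bar: float = 1e-4) -> "TraitState":
        """Founder convention: no maternal input yet (``z*_{-1} = 0``).

        The maternal variance moment starts at its no-maternal-effect value
        in the reference environment and the parent-offspring covariances at
        zero.  Trait means default to the conventional 1e-4.
        """
        return cls(a_bar=a_bar, b_bar=b_bar, m_bar=m_bar,
                   z_bar_star=0.0,
                   sigma_z2_star=params.G_aa + params.sigma_e2,
                   cov_a_zstar=0.0, cov_b_zstar=0.0, cov_m_zstar=0.0)

    def copy(self) -> "TraitState":
        return replace(self)


def mean_phenotype(traits: TraitState, cue: float) -> float:
    """Mean phenotype before selection, ``z = a + b*cue + m*z*_{prev}``."""
    return traits.a_bar + traits.b_bar * cue + traits.m_bar * traits.z_bar_star


def _develop_moments(params: ModelParams, a_bar, b_bar, m_bar,
                     z_star, v_star, c_a, c_b, c_m, cue):
    """One-generation phenotypic moments from the parental state.

    Returns ``(z_bar, sigma_z2, cov_az, cov_bz, cov_mz)`` where the last
    three are within-generation covariances between breeding values and the
    freshly developed phenotype (the quantities transmitted, halved, to the
    next generation's maternal covariances).  Pure arithmetic so it
    broadcasts over ensemble arrays.
    """
    z_bar = a_bar + b_bar * cue + m_bar * z_star
    # Var(m z*) for jointly Gaussian (m, z*) plus the remaining terms of the
    # phenotype model; Cov(a, m z*) = m*c_a etc. under the Gaussian closure.
    sigma_z2 = (params.G_aa + params.G_bb * cue * cue
                + params.G_mm * (v_star + z_star * z_star)
                + m_bar * m_bar * v_star
                + 2.0 * m_bar * z_star * c_m + c_m * c_m
                + 2.0 * m_bar * (c_a + cue * c_b)
                + params.sigma_e2)
    cov_az = params.G_aa + m_bar * c_a
    cov_bz = params.G_bb * cue + m_bar * c_b
    cov_mz = params.G_mm * z_star + m_bar * c_m
    return z_bar, sigma_z2, cov_az, cov_bz, cov_mz


def phenotypic_variance_step(traits: TraitState, params: ModelParams,
                             cue: float) -> float:
    """Next-generation phenotypic variance implied by the phenotype model."""
    _check_m(traits.m_bar)
    _, sigma_z2, *_ = _develop_moments(
        params, traits.a_bar, traits.b_bar, traits.m_bar,
        traits.z_bar_star, traits.sigma_z2_star,
        traits.cov_a_zstar, traits.cov_b_zstar, traits.cov_m_zstar, cue)
    return sigma_z2


def select(z_bar, sigma_z2, theta, omega_z2):
    """Exact mean and variance of a Gaussian phenotype after Gaussian selection.

    Weighting ``N(z_bar, sigma_z2)`` by ``exp(-(z-theta)^2 / (2 omega_z2))``
    yields another Gaussian with

        z*      = z_bar - sigma_z2/(omega_z2+sigma_z2) * (z_bar - theta)
        sigma*^2 = sigma_z2 * omega_z2 / (omega_z2 + sigma_z2)
    """
    if np.any(np.asarray(sigma_z2) <= 0):
        raise ParameterError("sigma_z2 must be > 0 for selection")
    shrink = omega_z2 / (omega_z2 + sigma_z2)
    z_star = z_bar - (1.0 - shrink) * (z_bar - theta)
    return z_star, sigma_z2 * shrink


def mean_fitness(traits: TraitState, params: ModelParams, theta: float,
                 sigma_z2: float | None = None) -> float:
    """Weak-selection mean fitness of the population.

    ``W = W_max sqrt(g_z g_b g_m w_z^2 w_b^2 w_m^2)
         * exp(-1/2 [g_z (z-theta)^2 + g_b b^2 + g_m m^2])``

    with ``g_z = 1/(w_z^2 + sigma_z^2)``, ``g_b = 1/(w_b^2 + G_bb)`` and
    ``g_m = 1/(w_m^2 + G_mm)``; higher-order cost/selection cross terms are
    dropped.
    """
    s2 = traits.sigma_z2 if sigma_z2 is None else sigma_z2
    return _mean_fitness_values(traits.z_bar, s2, traits.b_bar, traits.m_bar,
                                params, theta)


def _mean_fitness_values(z_bar, sigma_z2, b_bar, m_bar,
                         params: ModelParams, theta):
    gz = 1.0 / (params.omega_z2 + sigma_z2)
    gb = 1.0 / (params.omega_b2 + params.G_bb)
    gm = 1.0 / (params.omega_m2 + params.G_mm)
    pref = np.sqrt(gz * gb * gm * params.omega_z2 * params.omega_b2
                   * params.omega_m2)
    expo = -0.5 * (gz * (z_bar - theta) ** 2 + gb * b_bar ** 2
                   + gm * m_bar ** 2)
    return params.W_max * pref * np.exp(expo)


def _gradient(params: ModelParams, st, cue, theta):
    """Per-generation gradient of log mean fitness in (a, b, m).

    Differentiates log W composed with the one-generation development map,
    holding the previous generation's state (z*, sigma*^2 and the retained
    covariances) fixed -- the per-generation structure of the breeder's
    equation.  Pure arithmetic; broadcasts over arrays.
    """
    a_bar, b_bar, m_bar, z_star, v_star, c_a, c_b, c_m = st
    z_bar, sigma_z2, *_ = _develop_moments(params, *st, cue)
    gz = 1.0 / (params.omega_z2 + sigma_z2)
    gb = 1.0 / (params.omega_b2 + params.G_bb)
    gm = 1.0 / (params.omega_m2 + params.G_mm)
    dev = z_bar - theta
    # dz/dx and dsigma^2/dx for x in (a, b, m) at fixed parental state.
    dz = (1.0, cue, z_star)
    ds_m = 2.0 * m_bar * v_star + 2.0 * z_star * c_m + 2.0 * (c_a + cue * c_b)
    ds = (0.0, 0.0, ds_m)
    # d lnW/dx = -g_z dev dz/dx + (-1/2 g_z + 1/2 g_z^2 dev^2) ds/dx - cost
    var_factor = 0.5 * gz * (gz * dev * dev - 1.0)
    grad_a = -gz * dev * dz[0] + var_factor * ds[0]
    grad_b = -gz * dev * dz[1] + var_factor * ds[1] - gb * b_bar
    grad_m = -gz * dev * dz[2] + var_factor * ds[2] - gm * m_bar
    return grad_a, grad_b, grad_m


def trait_update(traits: TraitState, params: ModelParams, theta: float,
                 cue: float):
    """Breeder's-equation change ``(da, db, dm)`` of the trait means.

    Each component is the trait's additive genetic variance times the
    gradient of log mean fitness with respect to that mean, evaluated on the
    one-generation maps at fixed parental state; the cost gradients
    ``-G_bb b/(w_b^2+G_bb)`` and ``-G_mm m/(w_m^2+G_mm)`` are included.
    """
    _check_m(traits.m_bar)
    st = (traits.a_bar, traits.b_bar, traits.m_bar, traits.z_bar_star,
          traits.sigma_z2_star, traits.cov_a_zstar, traits.cov_b_zstar,
          traits.cov_m_zstar)
    ga, gb, gm = _gradient(params, st, cue, theta)
    return params.G_aa * ga, params.G_bb * gb, params.G_mm * gm


def equilibrium_variance(m_bar: float, z_bar: float, eps: float,
                         params: ModelParams) -> float:
    """Closed-form equilibrium phenotypic variance in a constant environment.

    Weak-selection approximation at fixed trait means; the exact moment
    recursion's fixed point agrees with it to about 1 part in 100 at weak
    selection.
    """
    _check_m(m_bar)
    denom = 1.0 - params.G_mm - m_bar * m_bar
    if denom <= 0:
        raise DivergenceError(
            "phenotypic variance diverges: 1 - G_mm - m^2 <= 0")
    load = ((2.0 + m_bar) / (2.0 - m_bar)
            * (params.G_aa + params.G_bb * eps * eps
               + params.G_mm * z_bar * z_bar)
            + z_bar * z_bar * params.G_mm ** 2 / (2.0 - m_bar) ** 2
            + params.sigma_e2)
    return load / denom


def variance_fixed_point(m_bar: float, z_bar: float, eps: float,
                         params: ModelParams, b_bar: float = 0.0,
                         max_iter: int = 100_000, tol: float = 1e-13) -> float:
    """Fixed point of the iterated variance recursion at frozen trait means.

    The elevation is chosen so the mean phenotype equilibrates at ``z_bar``
    with the optimum held there (no directional selection); the full moment
    set (variance, after-selection moments, parent-offspring covariances) is
    iterated to convergence.
    """
    _check_m(m_bar)
    a_bar = z_bar * (1.0 - m_bar) - b_bar * eps
    st = TraitState(a_bar=a_bar, b_bar=b_bar, m_bar=m_bar,
                    z_bar_star=z_bar,
                    sigma_z2_star=params.G_aa + params.sigma_e2)
    theta = z_bar
    prev = math.inf
    for i in range(max_iter):
        zb, s2, caz, cbz, cmz = _develop_moments(
            params, st.a_bar, st.b_bar, st.m_bar, st.z_bar_star,
            st.sigma_z2_star, st.cov_a_zstar, st.cov_b_zstar,
            st.cov_m_zstar, eps)
        if not math.isfinite(s2) or s2 <= 0:
            raise DivergenceError("variance recursion diverged", generation=i)
        if abs(s2 - prev) < tol:
            return s2
        prev = s2
        z_star, v_star = select(zb, s2, theta, params.omega_z2)
        shrink = params.omega_z2 / (params.omega_z2 + s2)
        st.z_bar_star = z_star
        st.sigma_z2_star = v_star
        st.cov_a_zstar = 0.5 * shrink * caz
        st.cov_b_zstar = 0.5 * shrink * cbz
        st.cov_m_zstar = 0.5 * shrink * cmz
    raise DivergenceError("variance recursion failed to converge")


def delta_m_initial(z_bar: float, G_aa: float, G_mm: float, omega_z2: float,
                    sigma_e2: float = 1.0,
                    sigma_z2: float | None = None) -> float:
    """Initial selection response of a novel maternal effect.

    Evaluated at ``m = 0`` with the mean phenotype at the optimum and
    plasticity absent, differentiating log mean fitness along the
    constant-environment equilibrium manifold (variance at its equilibrium
    and the mean responding as ``z = a/(1-m)``):

        dm = -G_mm [4 G_aa + z^2 G_mm (12 + G_mm)]
             / (8 (w_z^2 + sigma_z^2) (1 - G_mm)),

    which is negative for any admissible parameters: in stationary
    environments novel maternal effects are always selected toward negative
    values (variance canalization).  With ``sigma_z^2`` dropped from the
    denominator this is the bare weak-selection form.
    """
    if not 0 < G_mm < 1:
        raise ParameterError("G_mm must lie in (0, 1)")
    if omega_z2 <= 0:
        raise ParameterError("omega_z2 must be > 0")
    if sigma_z2 is None:
        # equilibrium variance at m = 0, plasticity absent
        sigma_z2 = ((G_aa + G_mm * z_bar ** 2
                     + z_bar ** 2 * G_mm ** 2 / 4.0 + sigma_e2)
                    / (1.0 - G_mm))
    slope = (4.0 * G_aa + z_bar ** 2 * G_mm * (12.0 + G_mm)) \
        / (4.0 * (1.0 - G_mm))
    return -G_mm * slope / (2.0 * (omega_z2 + sigma_z2))


def _check_m(m_bar, generation: int | None = None) -> None:
    if np.any(np.abs(np.asarray(m_bar)) >= M_STABILITY_BOUND):
        raise DivergenceError(
            f"|m| >= {M_STABILITY_BOUND}: phenotypic variances tend to "
            "infinity for these values", generation=generation)


def iterate(params: ModelParams, env: EnvironmentProcess,
            init: TraitState | None = None, n_generations: int = 1000,
            *, stop_at_equilibrium: bool = False, eq_tol: float = 1e-10,
            eq_window: int = 100, engine_label: str = "analytic") -> Trajectory:
    """Iterate the coupled mean/moment recursions for ``n_generations``.

    Per generation: sample the environment, develop the phenotypic moments,
    record, apply Gaussian survival selection, update the trait means by the
    breeder's equation, and transmit the after-selection moments to the next
    generation.  Deterministic given the environment's noise seed.

    With ``stop_at_equilibrium`` the run ends early once the largest trait
    change stays below ``eq_tol`` for ``eq_window`` consecutive generations
    (constant-environment convergence detection).
    """
    if n_generations < 1:
        raise ParameterError("n_generations must be >= 1")
    if init is None:
        init = TraitState.founder(params)
    cues, envs, thetas = env.series(n_generations)
    cues_l = cues.tolist()
    envs_l = envs.tolist()
    thetas_l = thetas.tolist()

    p = params
    wz2 = p.omega_z2
    a, b, m = float(init.a_bar), float(init.b_bar), float(init.m_bar)
    zs, vs = float(init.z_bar_star), float(init.sigma_z2_star)
    ca, cb, cm = (float(init.cov_a_zstar), float(init.cov_b_zstar),
                  float(init.cov_m_zstar))
    gb_cost = 1.0 / (p.omega_b2 + p.G_bb)
    gm_cost = 1.0 / (p.omega_m2 + p.G_mm)

    rec = {k: [] for k in ("a", "b", "m", "z", "zstar", "s2")}
    n_run = 0
    quiet = 0
    for t in range(n_generations):
        cue = cues_l[t]
        theta = thetas_l[t]
        if abs(m) >= M_STABILITY_BOUND:
            raise DivergenceError(
                f"|m| >= {M_STABILITY_BOUND} at generation {t}", generation=t)
        # develop
        z = a + b * cue + m * zs
        s2 = (p.G_aa + p.G_bb * cue * cue + p.G_mm * (vs + zs * zs)
              + m * m * vs + 2.0 * m * zs * cm + cm * cm
              + 2.0 * m * (ca + cue * cb) + p.sigma_e2)
        if not (s2 > 0.0) or s2 != s2 or s2 == math.inf:
            raise DivergenceError(
                f"non-positive or non-finite variance at generation {t}",
                generation=t)
        cov_az = p.G_aa + m * ca
        cov_bz = p.G_bb * cue + m * cb
        cov_mz = p.G_mm * zs + m * cm
        # record (before selection)
        rec["a"].append(a); rec["b"].append(b); rec["m"].append(m)
        rec["z"].append(z); rec["s2"].append(s2)
        # select
        shrink = wz2 / (wz2 + s2)
        z_star = z - (1.0 - shrink) * (z - theta)
        v_star = s2 * shrink
        rec["zstar"].append(z_star)
        # breeder's-equation update at fixed parental state
        gz = 1.0 / (wz2 + s2)
        dev = z - theta
        ds_m = 2.0 * m * vs + 2.0 * zs * cm + 2.0 * (ca + cue * cb)
        var_factor = 0.5 * gz * (gz * dev * dev - 1.0)
        da = p.G_aa * (-gz * dev)
        db = p.G_bb * (-gz * dev * cue - gb_cost * b)
        dm = p.G_mm * (-gz * dev * zs + var_factor * ds_m - gm_cost * m)
        a += da
        b += db
        m += dm
        # transmit after-selection moments
        zs, vs = z_star, v_star
        half = 0.5 * shrink
        ca, cb, cm = half * cov_az, half * cov_bz, half * cov_mz
        n_run = t + 1
        if stop_at_equilibrium:
            if max(abs(da), abs(db), abs(dm)) < eq_tol:
                quiet += 1
                if quiet >= eq_window:
                    break
            else:
                quiet = 0

    gen = np.arange(n_run)
    z_arr = np.array(rec["z"])
    s2_arr = np.array(rec["s2"])
    b_arr = np.array(rec["b"])
    m_arr = np.array(rec["m"])
    wbar = _mean_fitness_values(z_arr, s2_arr, b_arr, m_arr, p,
                                np.array(thetas_l[:n_run]))
    return Trajectory.from_arrays(
        engine=engine_label, replicate=0, generation=gen,
        a_bar=np.array(rec["a"]), b_bar=b_arr, m_bar=m_arr,
        z_bar=z_arr, z_bar_star=np.array(rec["zstar"]), sigma_z2=s2_arr,
        theta=np.array(thetas_l[:n_run]), epsilon=np.array(envs_l[:n_run]),
        cue=np.array(cues_l[:n_run]), mean_fitness=wbar)


def iterate_ensemble(params: ModelParams, env: EnvironmentProcess,
                     inits: Sequence[TraitState], n_generations: int):
    """Vectorized iteration of many initial conditions under one environment.

    Returns the final states as a dict of arrays (keys ``a``, ``b``, ``m``,
    ``z_bar_star``, ``sigma_z2``); used for initial-condition sensitivity
    sweeps where per-generation records are not needed.
    """
    p = params
    wz2 = p.omega_z2
    a = np.array([s.a_bar for s in inits], dtype=float)
    b = np.array([s.b_bar for s in inits], dtype=float)
    m = np.array([s.m_bar for s in inits], dtype=float)
    zs = np.array([s.z_bar_star for s in inits], dtype=float)
    vs = np.array([s.sigma_z2_star for s in inits], dtype=float)
    ca = np.array([s.cov_a_zstar for s in inits], dtype=float)
    cb = np.array([s.cov_b_zstar for s in inits], dtype=float)
    cm = np.array([s.cov_m_zstar for s in inits], dtype=float)
    gb_cost = 1.0 / (p.omega_b2 + p.G_bb)
    gm_cost = 1.0 / (p.omega_m2 + p.G_mm)
    cues, envs, thetas = env.series(n_generations)
    s2 = np.full_like(a, np.nan)
    for t in range(n_generations):
        cue = cues[t]
        theta = thetas[t]
        if np.any(np.abs(m) >= M_STABILITY_BOUND):
            raise DivergenceError(
                f"|m| >= {M_STABILITY_BOUND} at generation {t}", generation=t)
        z = a + b * cue + m * zs
        s2 = (p.G_aa + p.G_bb * cue * cue + p.G_mm * (vs + zs * zs)
              + m * m * vs + 2.0 * m * zs * cm + cm * cm
              + 2.0 * m * (ca + cue * cb) + p.sigma_e2)
        if not np.all(np.isfinite(s2)) or np.any(s2 <= 0):
            raise DivergenceError(
                f"non-positive or non-finite variance at generation {t}",
                generation=t)
        cov_az = p.G_aa + m * ca
        cov_bz = p.G_bb * cue + m * cb
        cov_mz = p.G_mm * zs + m * cm
        shrink = wz2 / (wz2 + s2)
        z_star = z - (1.0 - shrink) * (z - theta)
        gz = 1.0 / (wz2 + s2)
        dev = z - theta
        ds_m = 2.0 * m * vs + 2.0 * zs * cm + 2.0 * (ca + cue * cb)
        var_factor = 0.5 * gz * (gz * dev * dev - 1.0)
        a = a + p.G_aa * (-gz * dev)
        b = b + p.G_bb * (-gz * dev * cue - gb_cost * b)
        m = m + p.G_mm * (-gz * dev * zs + var_factor * ds_m - gm_cost * m)
        zs = z_star
        vs = s2 * shrink
        half = 0.5 * shrink
        ca, cb, cm = half * cov_az, half * cov_bz, half * cov_mz
    return {"a": a, "b": b, "m": m, "z_bar_star": zs, "sigma_z2": s2}
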