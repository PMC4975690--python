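"""Preset experiment regimes, model variants and summary statistics.

Presets freeze the parameter sets of the study's canonical regimes (constant
environment, sudden shift, sinusoidal forcing at weak/strong selection,
developmental-lag sweeps, stochastic and two-patch environments).  Variants
("m_only", "b_only", "neither") remove plasticity and/or maternal effects:
in the recursion engine by zeroing the corresponding genetic variance and
starting the mean at 0, in the IBM by freezing the locus at 0 without
mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analytic import TraitState, iterate
from .environment import EnvironmentProcess, pearson
from .errors import ParameterError
from .ibm import run_ibm
from .params import EnvParams, IBMParams, ModelParams
from .trajectory import Trajectory

__all__ = [
    "Preset", "PRESETS", "get_preset", "apply_variant", "run_analytic_variant",
    "steady_cycle_mean", "maternal_info_correlation", "sign_changes",
    "SweepSpec", "frequency_sweep", "selection_cost_grid",
]

VARIANTS = ("both", "m_only", "b_only", "neither")


@dataclass(frozen=True)
class Preset:
    """A frozen, named experiment configuration."""

    name: str
    description: str
    model: ModelParams
    env: EnvParams
    ibm: IBMParams = field(default_factory=IBMParams)
    engines: tuple = ("analytic",)
    n_generations: int = 50_000


_BASE = ModelParams()  # G_aa=0.1, G_bb=0.045, G_mm=0.005, weak selection
_FLUCT = _BASE.replace(G_bb=0.045, G_mm=0.045)

PRESETS: dict[str, Preset] = {p.name: p for p in [
    Preset("fig1", "constant environment, fitness-vs-maternal-effect profile",
           _BASE, EnvParams(scenario="constant", epsilon_const=5.0,
                            sigma_xi2=0.0, tau=0.25)),
    Preset("fig2", "sudden environmental shift at t=10",
           _BASE, EnvParams(scenario="step", delta=10.0, t_switch=10,
                            sigma_xi2=0.01, rho=0.5, tau=0.25),
           engines=("analytic", "ibm")),
    Preset("fig3", "slow sinusoidal environment, weak selection",
           _FLUCT, EnvParams(scenario="sinusoid", f=0.5, sigma_xi2=0.01,
                             rho=0.5, tau=0.25)),
    Preset("fig4_weak", "frequency sweep, weak selection",
           _FLUCT, EnvParams(scenario="sinusoid", f=0.5, sigma_xi2=0.01,
                             rho=0.5, tau=0.25), engines=("analytic",)),
    Preset("fig4_strong", "frequency sweep, strong selection",
           _FLUCT.replace(omega_z2=0.7),
           EnvParams(scenario="sinusoid", f=0.5, sigma_xi2=0.01, rho=0.5,
                     tau=0.25), engines=("analytic", "ibm")),
    Preset("fig5", "selection-strength x plasticity-cost grid (IBM)",
           _FLUCT, EnvParams(scenario="sinusoid", f=0.5, sigma_xi2=0.01,
                             rho=0.5, tau=0.25), engines=("ibm",)),
    Preset("fig6", "developmental time-lag sweep, noiseless sinusoid",
           _FLUCT, EnvParams(scenario="sinusoid", f=0.5, sigma_xi2=0.0,
                             tau=0.25)),
    Preset("figS5", "stochastic AR(1) environment, strong selection (IBM)",
           _FLUCT.replace(omega_z2=0.7),
           EnvParams(scenario="stochastic", sigma_xi2=1.0, rho=0.5, tau=0.25),
           engines=("ibm",)),
    Preset("figS6", "two-patch spatial environment (IBM)",
           _FLUCT.replace(omega_z2=0.7),
           EnvParams(scenario="two_patch", dispersal_d=0.5, tau=0.0,
                     sigma_xi2=0.0), engines=("ibm",)),
]}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


def apply_variant(model: ModelParams, variant: str):
    """Return ``(model, frozen_loci, init_overrides)`` for a model variant."""
    if variant not in VARIANTS:
        raise ParameterError(f"unknown variant {variant!r}; one of {VARIANTS}")
    frozen: tuple = ()
    kw: dict = {}
    if variant in ("m_only", "neither"):
        model = model.replace(G_bb=0.0)
        frozen += ("b",)
        kw["b_bar"] = 0.0
    if variant in ("b_only", "neither"):
        model = model.replace(G_mm=0.0)
        frozen += ("m",)
        kw["m_bar"] = 0.0
    return model, frozen, kw


def run_analytic_variant(preset_or_model, env: EnvParams | None = None,
                         variant: str = "both", n_generations: int = 50_000,
                         seed: int = 0, **iterate_kw) -> Trajectory:
    """Run the recursion engine for one variant of a preset or parameter set."""
    if isinstance(preset_or_model, Preset):
        model, env = preset_or_model.model, preset_or_model.env
    else:
        model = preset_or_model
    model, _, kw = apply_variant(model, variant)
    proc = EnvironmentProcess(env, n_generations, seed=seed)
    init = TraitState.founder(model, **kw)
    return iterate(model, proc, init, n_generations, **iterate_kw)


def steady_cycle_mean(trajectory, period: float, n_periods: int = 10,
                      traits=("a_bar", "b_bar", "m_bar"),
                      discard_frac: float = 0.8) -> pd.Series:
    """Evolved trait values on the periodic attractor.

    Time-average over the last ``n_periods`` full periods after discarding
    the first ``discard_frac`` of the run.  In a constant regime
    (``period`` irrelevant) this is simply a trailing average.
    """
    frame = getattr(trajectory, "frame", trajectory)
    n = len(frame)
    k = int(np.ceil(n_periods * period))
    start = max(int(discard_frac * n), n - k)
    if n - start < 2 or k < 1:
        raise ParameterError(
            f"trajectory of length {n} too short for {n_periods} periods "
            f"of {period} generations")
    return frame.iloc[start:][list(traits)].mean()


def maternal_info_correlation(trajectory) -> float:
    """Correlation between the maternal phenotype and the offspring optimum.

    Pearson correlation of the after-selection mean phenotype of generation
    ``t-1`` against the optimum ``theta_t`` experienced by its offspring.
    Signals a degenerate series when the maternal phenotype is frozen
    (e.g. a non-evolving population in a constant environment).
    """
    frame = getattr(trajectory, "frame", trajectory)
    zstar = frame["z_bar_star"].to_numpy()
    theta = frame["theta"].to_numpy()
    return pearson(zstar[:-1], theta[1:])


def sign_changes(series, window: int = 25) -> int:
    """Number of sign changes of a trajectory after smoothing.

    Centered moving average over ``window`` generations removes the
    environmental-noise scale before counting zero crossings; exact zeros
    are ignored.
    """
    x = np.asarray(series, dtype=float)
    if window > 1:
        kernel = np.ones(window) / window
        x = np.convolve(x, kernel, mode="valid")
    s = np.sign(x)
    s = s[s != 0]
    return int(np.sum(s[1:] != s[:-1]))


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep specification."""

    parameter: str
    grid: tuple
    engine: str = "analytic"       # analytic | ibm | both
    n_replicates: int = 10         # per grid point, IBM only
    variant: str = "both"
    n_generations: int = 20_000
    ibm_n_generations: int = 5_000

    def __post_init__(self):
        if len(self.grid) == 0:
            raise ParameterError("sweep grid must be non-empty")
        if self.engine not in ("analytic", "ibm", "both"):
            raise ParameterError(f"unknown engine {self.engine!r}")
        if self.variant not in VARIANTS:
            raise ParameterError(f"unknown variant {self.variant!r}")


def _set_param(model: ModelParams, env: EnvParams, name: str, value):
    if hasattr(model, name):
        return model.replace(**{name: value}), env
    if hasattr(env, name):
        return model, env.replace(**{name: value})
    raise ParameterError(f"unknown sweep parameter {name!r}")


def _steady(traj, env: EnvParams, n_periods: int) -> pd.Series:
    period = 2 * np.pi / env.f if env.scenario == "sinusoid" and env.f > 0 \
        else 100.0
    return steady_cycle_mean(traj, period, n_periods=n_periods)


def frequency_sweep(spec: SweepSpec, model: ModelParams, env: EnvParams,
                    ibm: IBMParams | None = None, seed: int = 0,
                    n_periods: int = 10) -> pd.DataFrame:
    """Evolved steady-cycle trait means along a parameter grid.

    Returns a tidy long table with one row per grid point x engine x
    replicate x trait (column ``evolved``); per-point failures are recorded
    as NaN rows rather than aborting the sweep.
    """
    if ibm is None:
        ibm = IBMParams()
    rows = []
    for i, value in enumerate(spec.grid):
        mod_i, env_i = _set_param(model, env, spec.parameter, value)
        mod_v, frozen, kw = apply_variant(mod_i, spec.variant)
        if spec.engine in ("analytic", "both"):
            try:
                proc = EnvironmentProcess(env_i, spec.n_generations,
                                          seed=[seed, i])
                traj = iterate(mod_v, proc, TraitState.founder(mod_v, **kw),
                               spec.n_generations)
                means = _steady(traj, env_i, n_periods)
            except Exception:
                means = pd.Series({t: np.nan for t in
                                   ("a_bar", "b_bar", "m_bar")})
            for trait, val in means.items():
                rows.append((spec.parameter, value, "analytic", 0, trait, val))
        if spec.engine in ("ibm", "both"):
            for r in range(spec.n_replicates):
                try:
                    traj = run_ibm(mod_i, env_i, ibm,
                                   n_generations=spec.ibm_n_generations,
                                   frozen=frozen, seed=[seed, i, r],
                                   replicate=r)
                    means = _steady(traj, env_i, n_periods)
                except Exception:
                    means = pd.Series({t: np.nan for t in
                                       ("a_bar", "b_bar", "m_bar")})
                for trait, val in means.items():
                    rows.append((spec.parameter, value, "ibm", r, trait, val))
    return pd.DataFrame(rows, columns=["parameter", "value", "engine",
                                       "replicate", "trait", "evolved"])


def sweep_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Across-replicate mean and SD per grid point, engine and trait."""
    g = table.groupby(["parameter", "value", "engine", "trait"])["evolved"]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=0)).reset_index()
    return out


def selection_cost_grid(omega_z2_grid, omega_b2_grid, model: ModelParams,
                        env: EnvParams, ibm: IBMParams | None = None,
                        seed: int = 0, n_replicates: int = 3,
                        n_generations: int = 5_000,
                        n_periods: int = 10) -> pd.DataFrame:
    """Two-parameter IBM grid over selection strength and plasticity cost."""
    if ibm is None:
        ibm = IBMParams()
    rows = []
    for i, wz2 in enumerate(omega_z2_grid):
        for j, wb2 in enumerate(omega_b2_grid):
            mod = model.replace(omega_z2=wz2, omega_b2=wb2)
            for r in range(n_replicates):
                try:
                    traj = run_ibm(mod, env, ibm, n_generations=n_generations,
                                   seed=[seed, i, j, r], replicate=r)
                    means = _steady(traj, env, n_periods)
                except Exception:
                    means = pd.Series({t: np.nan for t in
                                       ("a_bar", "b_bar", "m_bar")})
                for trait, val in means.items():
                    rows.append((wz2, wb2, r, trait, val))
    return pd.DataFrame(rows, columns=["omega_z2", "omega_b2", "replicate",
                                       "trait", "evolved"])
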