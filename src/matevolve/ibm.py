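"""Individual-based forward simulator.

A population of ``N`` diploid hermaphrodites with discrete generations and
three unlinked loci coding for the reaction-norm elevation ``a``, plasticity
slope ``b`` and maternal-effect coefficient ``m`` (alleles additive within a
locus).  The life cycle is birth -> survival -> reproduction:

* birth: each individual develops ``z = a + b*cue + m*z*_mother + e`` with
  ``e ~ N(0, sigma_e2)`` and the cue sampled at ``t - tau``;
* survival: Bernoulli with probability
  ``w = w_min + (1 - w_min) * W(z, b, m)`` where ``W`` is the Gaussian
  fitness function with plasticity and maternal-effect costs (the floor
  ``w_min`` prevents premature extinction far from the optimum);
* reproduction: every offspring slot draws a mother uniformly from the
  survivors and a sperm donor uniformly from the other survivors (no
  selfing), inherits one allele per locus per parent independently
  (unlinked loci), and records its mother's phenotype as maternal input.
  Realized clutch sizes are thus multinomial with mean ``N / n_surv``.

Mutation follows a continuum-of-alleles model: each transmitted allele
mutates with probability ``mu_x``, adding a ``N(0, sigma_mut_x2)`` increment
to its value.  Genetic variances are emergent (mutation-selection balance)
rather than pinned to the analytic ``G_xx``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import EnvironmentProcess, optimum
from .errors import ExtinctionError
from .params import EnvParams, IBMParams, ModelParams
from .trajectory import Trajectory

__all__ = ["Population", "develop", "survival_probability", "reproduce",
           "mutate", "run_ibm", "run_replicates"]


@dataclass
class Population:
    """Arrays of per-individual state: allele pairs, phenotype, maternal input."""

    alleles_a: np.ndarray  # (N, 2)
    alleles_b: np.ndarray
    alleles_m: np.ndarray
    maternal_z_star: np.ndarray  # (N,)
    z: np.ndarray | None = None
    patch: np.ndarray | None = None  # two-patch scenario only
    frozen: frozenset = field(default_factory=frozenset)

    @classmethod
    def founders(cls, n: int, a0: float = 1e-4, b0: float = 1e-4,
                 m0: float = 1e-4, frozen=(), patches: bool = False,
                 rng: np.random.Generator | None = None) -> "Population":
        """Monomorphic founder cohort with trait values ``(a0, b0, m0)``.

        Loci named in ``frozen`` ('b' and/or 'm') are pinned to 0 and never
        mutate -- the "no plasticity" / "no maternal effect" variants.
        """
        frozen = frozenset(frozen)

        def init(x0, name):
            v = 0.0 if name in frozen else x0 / 2.0
            return np.full((n, 2), v)

        patch = None
        if patches:
            if rng is None:
                rng = np.random.default_rng()
            patch = rng.integers(0, 2, size=n)
        return cls(alleles_a=init(a0, "a"), alleles_b=init(b0, "b"),
                   alleles_m=init(m0, "m"),
                   maternal_z_star=np.zeros(n), patch=patch,
                   frozen=frozen)

    @property
    def n(self) -> int:
        return self.alleles_a.shape[0]

    def trait(self, name: str) -> np.ndarray:
        """Additive trait value (sum of the two allelic values)."""
        return getattr(self, f"alleles_{name}").sum(axis=1)


def develop(pop: Population, cue, sigma_e2: float,
            rng: np.random.Generator) -> np.ndarray:
    """Develop phenotypes ``z = a + b*cue + m*z*_mother + e`` for the cohort."""
    e = rng.normal(0.0, np.sqrt(sigma_e2), size=pop.n) if sigma_e2 > 0 \
        else np.zeros(pop.n)
    z = (pop.trait("a") + pop.trait("b") * np.asarray(cue)
         + pop.trait("m") * pop.maternal_z_star + e)
    pop.z = z
    return z


def survival_probability(z, b, m, theta, model: ModelParams,
                         w_min: float = 0.1) -> np.ndarray:
    """Floored Gaussian survival, ``w = w_min + (1 - w_min) W(z, b, m)``."""
    W = model.W_max * np.exp(
        -np.asarray(z - theta) ** 2 / (2.0 * model.omega_z2)
        - np.asarray(b) ** 2 / (2.0 * model.omega_b2)
        - np.asarray(m) ** 2 / (2.0 * model.omega_m2))
    return w_min + (1.0 - w_min) * W


def mutate(allele_values: np.ndarray, mu_x: float, sigma_x2: float,
           rng: np.random.Generator) -> np.ndarray:
    """Continuum-of-alleles mutation, in place.

    Each allele mutates with probability ``mu_x``; a mutation adds a
    ``N(0, sigma_x2)`` increment to the old allelic value.
    """
    if mu_x <= 0 or sigma_x2 <= 0:
        return allele_values
    mask = rng.random(allele_values.shape) < mu_x
    n_mut = int(mask.sum())
    if n_mut:
        allele_values[mask] += rng.normal(0.0, np.sqrt(sigma_x2), size=n_mut)
    return allele_values


def _inherit(alleles: np.ndarray, mothers: np.ndarray, fathers: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    n = len(mothers)
    out = np.empty((n, 2))
    out[:, 0] = alleles[mothers, rng.integers(0, 2, size=n)]
    out[:, 1] = alleles[fathers, rng.integers(0, 2, size=n)]
    return out


def reproduce(pop: Population, survivors: np.ndarray, ibm: IBMParams,
              rng: np.random.Generator, generation: int | None = None,
              within_patch: bool = False) -> Population:
    """Produce the next cohort of exactly ``N`` offspring from the survivors.

    Mothers are drawn uniformly with replacement across offspring slots;
    each mother's sperm donor is drawn uniformly from the other survivors
    (selfing excluded; in the two-patch scenario, from the survivors of her
    own patch when possible).  Offspring inherit one allele per locus per
    parent, loci independently, then alleles mutate; the maternal input of
    each offspring is its mother's developed phenotype (she survived
    selection, so this is an after-selection phenotype).
    """
    n_surv = len(survivors)
    if n_surv < 2:
        raise ExtinctionError(
            f"fewer than 2 survivors (generation {generation})",
            generation=generation)
    N = ibm.N
    mother_idx = rng.integers(0, n_surv, size=N)
    if within_patch and pop.patch is not None:
        father_idx = _fathers_within_patch(pop.patch[survivors], mother_idx, rng)
    else:
        father_idx = rng.integers(0, n_surv - 1, size=N)
        father_idx[father_idx >= mother_idx] += 1
    mothers = survivors[mother_idx]
    fathers = survivors[father_idx]

    mus = {"a": (ibm.mu_a, ibm.sigma_mut_a2),
           "b": (ibm.mu_b, ibm.sigma_mut_b2),
           "m": (ibm.mu_m, ibm.sigma_mut_m2)}
    new_alleles = {}
    for name in ("a", "b", "m"):
        if name in pop.frozen:
            new_alleles[name] = np.zeros((N, 2))
            continue
        alleles = _inherit(getattr(pop, f"alleles_{name}"), mothers, fathers, rng)
        mutate(alleles, *mus[name], rng)
        new_alleles[name] = alleles

    patch = pop.patch[mothers].copy() if pop.patch is not None else None
    return Population(alleles_a=new_alleles["a"], alleles_b=new_alleles["b"],
                      alleles_m=new_alleles["m"],
                      maternal_z_star=pop.z[mothers].copy(),
                      patch=patch, frozen=pop.frozen)


def _fathers_within_patch(surv_patch: np.ndarray, mother_idx: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Sperm donor from the mother's patch if possible, else any other survivor."""
    n_surv = len(surv_patch)
    father_idx = np.empty(len(mother_idx), dtype=int)
    for p in (0, 1):
        members = np.flatnonzero(surv_patch == p)
        slots = np.flatnonzero(surv_patch[mother_idx] == p)
        if len(members) < 2:  # fall back to global mating for this patch
            pick = rng.integers(0, n_surv - 1, size=len(slots))
            pick[pick >= mother_idx[slots]] += 1
            father_idx[slots] = pick
            continue
        pos_in_patch = np.searchsorted(members, mother_idx[slots])
        pick = rng.integers(0, len(members) - 1, size=len(slots))
        pick[pick >= pos_in_patch] += 1
        father_idx[slots] = members[pick]
    return father_idx


def run_ibm(model: ModelParams, env_params: EnvParams, ibm: IBMParams,
            *, n_generations: int | None = None, frozen=(),
            seed=None, record_every: int = 1,
            replicate: int = 0) -> Trajectory:
    """Run one replicate of the individual-based life cycle.

    Records per-generation cohort means of a, b, m and z (before selection),
    the phenotypic variance, the environment and the realized mean survival
    fitness.  Deterministic given ``seed``; loci in ``frozen`` are pinned to
    0 (variant runs without plasticity and/or maternal effects).
    """
    n_gen = ibm.n_generations if n_generations is None else int(n_generations)
    if seed is None:
        seed = ibm.seed
    rng = np.random.default_rng(seed)
    two_patch = env_params.scenario == "two_patch"
    if two_patch:
        env = None
    else:
        env = EnvironmentProcess(env_params, n_gen, rng=rng)

    pop = Population.founders(ibm.N, frozen=frozen, patches=two_patch, rng=rng)
    rec: dict[str, list] = {k: [] for k in
                            ("generation", "a_bar", "b_bar", "m_bar", "z_bar",
                             "z_bar_star", "sigma_z2", "theta", "epsilon",
                             "cue", "mean_fitness")}
    for t in range(n_gen):
        if two_patch:
            # migrate before development; the post-migration patch supplies
            # both the cue and the selection optimum (patch environments
            # are constant at eps = +/-1)
            mig = rng.random(ibm.N) < env_params.dispersal_d
            pop.patch = np.where(mig, 1 - pop.patch, pop.patch)
            eps_patch = np.where(pop.patch == 1, 1.0, -1.0)
            cue = eps_patch
            theta = np.asarray(optimum(eps_patch, env_params))
            eps_rec = float(eps_patch.mean())
            theta_rec = float(theta.mean())
            cue_rec = eps_rec
        else:
            s = env.sample(t)
            cue, theta = s.cue, s.theta
            eps_rec, theta_rec, cue_rec = s.env_at_selection, s.theta, s.cue

        z = develop(pop, cue, model.sigma_e2, rng)
        a_v, b_v, m_v = pop.trait("a"), pop.trait("b"), pop.trait("m")

        w = survival_probability(z, b_v, m_v, theta, model, ibm.w_min)
        survivors = np.flatnonzero(rng.random(ibm.N) < w)
        if len(survivors) < 2:
            raise ExtinctionError(
                f"population extinct at generation {t}", generation=t)
        if t % record_every == 0 or t == n_gen - 1:
            rec["generation"].append(t)
            rec["a_bar"].append(a_v.mean())
            rec["b_bar"].append(b_v.mean())
            rec["m_bar"].append(m_v.mean())
            rec["z_bar"].append(z.mean())
            rec["z_bar_star"].append(z[survivors].mean())
            rec["sigma_z2"].append(z.var())
            rec["theta"].append(theta_rec)
            rec["epsilon"].append(eps_rec)
            rec["cue"].append(cue_rec)
            rec["mean_fitness"].append(w.mean())
        pop = reproduce(pop, survivors, ibm, rng, generation=t,
                        within_patch=two_patch)
    return Trajectory.from_arrays(engine="ibm", replicate=replicate, **{
        k: np.asarray(v) for k, v in rec.items()})


def run_replicates(model: ModelParams, env_params: EnvParams, ibm: IBMParams,
                   *, n_generations: int | None = None, frozen=(),
                   base_seed: int | None = None, n_replicates: int | None = None,
                   record_every: int = 1) -> Trajectory:
    """Run ``n_replicates`` independent replicates and concatenate them.

    Replicate ``r`` uses the derived seed ``base_seed + r`` for exact
    reproducibility of any single replicate in isolation.
    """
    base = ibm.seed if base_seed is None else base_seed
    n_rep = ibm.n_replicates if n_replicates is None else int(n_replicates)
    runs = [run_ibm(model, env_params, ibm, n_generations=n_generations,
                    frozen=frozen, seed=base + r, record_every=record_every,
                    replicate=r)
            for r in range(n_rep)]
    return Trajectory.concat(runs)
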