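"""Synthetic paired-vial fecundity experiments with known ground truth.

The generator reproduces the design of the real assay — 20 mutation lines,
20-22 replicate vials per line, vials founded with 33 mutant + 33 wildtype
females plus 33 males, fecundity of 25 females per class measured over 24 h
at adult days 5, 19 and 33 — while drawing egg counts from an explicit
generative law so every downstream estimate can be checked against truth.

For mutation m, vial v with shared intercept u_v ~ Normal(0, vial_sd^2):

    wildtype count at age a ~ Count(mean = exp(mu + gamma_a + u_v))
    mutant  count at age a ~ Count(mean = exp(mu + gamma_a + u_v
                                   + delta_m + beta_m (a - a1) + kappa_m (a - a1)^2))

with a1 the first assay age and Count either Poisson or (with the
``overdispersion`` shape parameter set) negative binomial.  delta_m is the
log fecundity ratio at the first age (< 0 = deleterious), beta_m the per-day
change in the log ratio (< 0 = mutation-induced reproductive aging) and
kappa_m a quadratic term producing accelerating decline.  Because u_v is
shared by both classes within a vial, the mutant/wildtype contrast is a
within-vial comparison — the property that justifies the binomial
conditioning used by the aging models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import (
    FECUNDITY_COLUMNS,
    MUTANT,
    SURVIVAL_COLUMNS,
    WILDTYPE,
    FecundityDataset,
)

_DEFAULT_AGES = (5, 19, 33)
# wildtype trajectory: mild fecundity decline over the five assay weeks
_DEFAULT_AGE_EFFECTS = (0.0, -0.3, -0.8)
_BASELINE_SURVIVAL_LOGIT = 2.1972245773362196  # logit(0.9) at day 33


class ConfigError(ValueError):
    """The simulation configuration violates an invariant."""


@dataclass
class SimConfig:
    """Full generative parameterization of one synthetic experiment.

    Effect vectors (``delta``, ``beta``, ``kappa``, ``survival_logit``) have
    one entry per mutation; scalars are broadcast.  ``baseline_log_eggs`` is
    the expected log total eggs of 25 wildtype females over 24 h at day 5
    (default ln 600, i.e. ~24 eggs per female per day — a realistic figure
    for young, well-fed females); it is a free simulation parameter, not an
    estimate from any real dataset.
    """

    n_mutations: int = 20
    vials_per_mutation: tuple[int, int] = (20, 22)
    females_per_class: int = 25
    founding_females: int = 33
    assay_ages: tuple[int, ...] = _DEFAULT_AGES
    baseline_log_eggs: float = float(np.log(600.0))
    age_effects: tuple[float, ...] = _DEFAULT_AGE_EFFECTS
    vial_sd: float = 0.2
    delta: np.ndarray | float = 0.0
    beta: np.ndarray | float = 0.0
    kappa: np.ndarray | float = 0.0
    overdispersion: float | None = None
    #: (n_mutations, 2) logits of day-33 survival for [wildtype, mutant];
    #: a scalar is broadcast to both classes of every line
    survival_logit: np.ndarray | float = _BASELINE_SURVIVAL_LOGIT
    include_survival: bool = True
    attrition: bool = False
    seed: int = 0

    def _vector(self, value, name: str) -> np.ndarray:
        try:
            return np.broadcast_to(
                np.asarray(value, dtype=float), (self.n_mutations,)
            ).copy()
        except ValueError as exc:
            raise ConfigError(
                f"{name} must be scalar or have length n_mutations={self.n_mutations}"
            ) from exc

    def resolved_effects(self) -> dict[str, np.ndarray]:
        delta = self._vector(self.delta, "delta")
        beta = self._vector(self.beta, "beta")
        kappa = self._vector(self.kappa, "kappa")
        sl = np.asarray(self.survival_logit, dtype=float)
        if sl.ndim <= 1:
            sl = np.broadcast_to(sl, (self.n_mutations,))
            sl = np.stack([sl, sl], axis=1)
        sl = np.array(sl, dtype=float)
        if sl.shape != (self.n_mutations, 2):
            raise ConfigError("survival_logit must broadcast to (n_mutations, 2)")
        return {"delta": delta, "beta": beta, "kappa": kappa, "survival_logit": sl}

    def validate(self) -> None:
        if self.n_mutations < 1:
            raise ConfigError("n_mutations must be >= 1")
        lo, hi = self.vials_per_mutation
        if not (1 <= lo <= hi):
            raise ConfigError("vials_per_mutation must be an increasing positive range")
        if self.females_per_class < 1 or self.founding_females < self.females_per_class:
            raise ConfigError("need founding_females >= females_per_class >= 1")
        ages = list(self.assay_ages)
        if any(b <= a for a, b in zip(ages, ages[1:])) or len(ages) < 1:
            raise ConfigError("assay_ages must be strictly increasing and non-empty")
        if len(self.age_effects) != len(ages):
            raise ConfigError("age_effects must have one entry per assay age")
        if self.vial_sd < 0:
            raise ConfigError("vial_sd must be >= 0")
        if self.overdispersion is not None and self.overdispersion <= 0:
            raise ConfigError("overdispersion shape must be positive")
        self.resolved_effects()

    def mutation_labels(self) -> list[str]:
        width = len(str(self.n_mutations))
        return [f"m{i + 1:0{width}d}" for i in range(self.n_mutations)]


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, shape_param: float | None):
    if shape_param is None:
        return rng.poisson(mean)
    # negative binomial as gamma-mixed Poisson: var = mean + mean^2/shape
    lam = rng.gamma(shape_param, mean / shape_param)
    return rng.poisson(lam)


def simulate_experiment(config: SimConfig) -> FecundityDataset:
    """Draw one full experiment from the generative law; deterministic given seed."""
    config.validate()
    eff = config.resolved_effects()
    rng = np.random.default_rng(config.seed)
    ages = np.asarray(config.assay_ages, dtype=int)
    age_c = ages - ages[0]
    gamma = np.asarray(config.age_effects, dtype=float)
    labels = config.mutation_labels()
    lo, hi = config.vials_per_mutation

    rows: list[tuple] = []
    surv_rows: list[tuple] = []
    final_age = int(ages[-1])
    for m, label in enumerate(labels):
        n_vials = int(rng.integers(lo, hi + 1))
        log_ratio = eff["delta"][m] + eff["beta"][m] * age_c + eff["kappa"][m] * age_c**2
        for v in range(n_vials):
            vial = f"{label}_v{v + 1:02d}"
            u = rng.normal(0.0, config.vial_sd)
            p_wt = _expit(eff["survival_logit"][m, 0])
            p_mut = _expit(eff["survival_logit"][m, 1])
            alive_wt = int(rng.binomial(config.founding_females, p_wt))
            alive_mut = int(rng.binomial(config.founding_females, p_mut))
            for j, age in enumerate(ages):
                n_lay = config.females_per_class
                if config.attrition and age == final_age:
                    # matched-laying rule: the scarcer class sets both counts
                    n_lay = min(n_lay, alive_wt, alive_mut)
                    if n_lay < 1:
                        continue
                exposure = n_lay / config.females_per_class
                mean_wt = np.exp(config.baseline_log_eggs + gamma[j] + u) * exposure
                mean_mut = mean_wt * np.exp(log_ratio[j])
                wt_eggs = int(_draw_counts(rng, np.asarray(mean_wt), config.overdispersion))
                mut_eggs = int(_draw_counts(rng, np.asarray(mean_mut), config.overdispersion))
                rows.append((label, vial, int(age), WILDTYPE, n_lay, wt_eggs))
                rows.append((label, vial, int(age), MUTANT, n_lay, mut_eggs))
            if config.include_survival:
                surv_rows.append(
                    (label, vial, final_age, WILDTYPE, alive_wt, config.founding_females)
                )
                surv_rows.append(
                    (label, vial, final_age, MUTANT, alive_mut, config.founding_females)
                )

    obs = pd.DataFrame(rows, columns=FECUNDITY_COLUMNS)
    surv = pd.DataFrame(surv_rows, columns=SURVIVAL_COLUMNS) if surv_rows else None
    return FecundityDataset.from_frames(obs, survival=surv, assay_ages=[int(a) for a in ages])


def _expit(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_null(n_mutations: int, n_vials: int, seed: int, **overrides) -> FecundityDataset:
    """Experiment with every mutation effect zero; for type-I calibration."""
    cfg = SimConfig(
        n_mutations=n_mutations,
        vials_per_mutation=(n_vials, n_vials),
        delta=0.0,
        beta=0.0,
        kappa=0.0,
        seed=seed,
    )
    cfg = replace(cfg, **overrides)
    return simulate_experiment(cfg)


def paper_like_config(
    seed: int = 0,
    n_mutations: int = 20,
    n_deleterious: int = 16,
    vials_per_mutation: tuple[int, int] = (20, 22),
    aging_per_day5_effect: float = 1.0 / 30.0,
    acceleration_scale: float = 1.0 / 800.0,
    survival_coupling: float = 2.0,
) -> SimConfig:
    """Study-structured configuration: mostly-deleterious lines whose aging
    rate scales with their day-5 deleteriousness (effects "fan out" with age).

    The first ``n_deleterious`` lines get day-5 log-ratio effects spaced
    evenly from ln 0.95 down to ln 0.5 (fecundity reductions of 5-50%), an
    aging slope ``beta_m = aging_per_day5_effect * delta_m`` per day, a
    quadratic term ``kappa_m = acceleration_scale * delta_m`` and a mutant
    day-33 survival logit shifted by ``survival_coupling * delta_m``; the
    remaining lines are exactly neutral.  Line order is shuffled by seed so
    labels carry no information.
    """
    if not (0 <= n_deleterious <= n_mutations):
        raise ConfigError("need 0 <= n_deleterious <= n_mutations")
    rng = np.random.default_rng(seed)
    delta = np.zeros(n_mutations)
    if n_deleterious:
        delta[:n_deleterious] = np.linspace(np.log(0.95), np.log(0.5), n_deleterious)
    perm = rng.permutation(n_mutations)
    delta = delta[perm]
    beta = aging_per_day5_effect * delta
    kappa = acceleration_scale * delta
    surv = np.full((n_mutations, 2), _BASELINE_SURVIVAL_LOGIT)
    surv[:, 1] += survival_coupling * delta
    return SimConfig(
        n_mutations=n_mutations,
        vials_per_mutation=vials_per_mutation,
        delta=delta,
        beta=beta,
        kappa=kappa,
        survival_logit=surv,
        seed=seed,
    )
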