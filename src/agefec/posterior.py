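"""Posterior-derived estimands and tests for the fecundity analysis.

Every quantity here is a deterministic function applied draw-by-draw to the
MCMC output, summarized by its posterior mean, central 95% credibility
interval (2.5% and 97.5% quantiles, linear interpolation) and ``p_mcmc`` —
twice the smaller of the posterior tail fractions on either side of zero, a
Bayesian analogue of a two-tailed p value.

Estimands per mutation line:

* deleteriousness ``s = 1 - mut/wt`` fecundity (positive = harmful),
* the reproductive-aging coefficient (per-day change of the log
  mutant/wildtype ratio; negative = the mutant declines faster),
* interval-specific aging differences between pairs of assay ages,
* aging acceleration: the day 19-33 aging rate minus the day 5-19 rate on a
  common per-interval scale (negative = decline steepens late in life);

and per dataset the among-line variance of age-specific effects, whose
increase with age is the condition for mutations of this kind to respond to
an age-structured decline in the strength of selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .glmm import PosteriorDraws

ALPHA_DEFAULT = 0.05


class CodingError(TypeError):
    """Draws come from the wrong model or age coding for this estimand."""


def p_mcmc(draws_of_scalar) -> float:
    """Two times the smaller tail fraction of the draws around zero, capped at 1."""
    x = np.asarray(draws_of_scalar, dtype=float)
    if x.size == 0:
        raise ValueError("p_mcmc needs at least one draw")
    if not np.all(np.isfinite(x)):
        raise ValueError("p_mcmc requires finite draws")
    below = np.mean(x < 0)
    above = np.mean(x > 0)
    return float(min(1.0, 2.0 * min(below, above)))


def central_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Central posterior interval: the (1-level)/2 and 1-(1-level)/2 quantiles."""
    x = np.asarray(draws, dtype=float)
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [tail, 1.0 - tail])
    return float(lo), float(hi)


@dataclass
class Estimate:
    """A scalar posterior summary: mean, central 95% interval, p_mcmc."""

    mean: float
    ci_low: float
    ci_high: float
    p_mcmc: float

    @classmethod
    def from_draws(cls, draws, p_draws=None) -> "Estimate":
        """Summarize ``draws``; ``p_draws`` (default: same) feeds p_mcmc,
        for estimands reported on a transformed scale but tested on the
        model's linear scale."""
        x = np.asarray(draws, dtype=float)
        lo, hi = central_interval(x)
        return cls(float(x.mean()), lo, hi, p_mcmc(x if p_draws is None else p_draws))

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_mcmc": self.p_mcmc,
        }


# -- per-mutation estimands -----------------------------------------------


def _require(pd_: PosteriorDraws, model: str, age_coding: str | None = None) -> None:
    meta = pd_.parameterization
    if meta.get("model") != model:
        raise CodingError(f"draws are from model {meta.get('model')!r}, need {model!r}")
    if age_coding is not None and meta.get("age_coding") != age_coding:
        raise CodingError(
            f"draws use age coding {meta.get('age_coding')!r}, need {age_coding!r}"
        )


def log_ratio_draws(pd_: PosteriorDraws, mutation_id: str) -> np.ndarray:
    _require(pd_, "deleteriousness")
    return pd_.get(f"log_ratio[{mutation_id}]")


def deleteriousness(pd_: PosteriorDraws, mutation_id: str) -> Estimate:
    """Selection-style effect ``s = 1 - exp(log ratio)``; positive = deleterious.

    The significance test (p_mcmc) is on the log-scale mutant-class effect,
    where zero is the null.
    """
    theta = log_ratio_draws(pd_, mutation_id)
    return Estimate.from_draws(1.0 - np.exp(theta), p_draws=theta)


def aging_coefficient(pd_: PosteriorDraws, mutation_id: str) -> Estimate:
    """Per-day slope of the logit mutant fraction = per-day change of the
    log mutant/wildtype fecundity ratio.  Negative = faster mutant aging."""
    _require(pd_, "aging", "covariate")
    return Estimate.from_draws(pd_.get(f"aging_slope[{mutation_id}]"))


def _effect_at(pd_: PosteriorDraws, mutation_id: str, age: int) -> np.ndarray:
    return pd_.get(f"ratio_at[{mutation_id},{age}]")


def interval_aging(
    pd_: PosteriorDraws, mutation_id: str, age_pair: tuple[int, int]
) -> Estimate:
    """Change of the mutation effect between two assay ages (later - earlier)
    on the logit scale; negative = the mutant declined faster over the interval."""
    _require(pd_, "aging", "factor")
    early, late = age_pair
    ages = pd_.parameterization["assay_ages"]
    if early not in ages or late not in ages or not early < late:
        raise ValueError(f"age_pair must be an increasing pair of assay ages {ages}")
    return Estimate.from_draws(interval_aging_draws(pd_, mutation_id, age_pair))


def interval_aging_draws(pd_, mutation_id, age_pair) -> np.ndarray:
    early, late = age_pair
    return _effect_at(pd_, mutation_id, late) - _effect_at(pd_, mutation_id, early)


def aging_acceleration(pd_: PosteriorDraws, mutation_id: str) -> Estimate:
    """Late-interval aging rate minus early-interval rate, per draw.

    Rates are per-interval differences normalized to a common per-day scale,
    so unequal interval lengths compare fairly; with the default ages the
    intervals are both 14 days and the normalization cancels.  Negative
    values mean the decline steepens with age (acceleration)."""
    _require(pd_, "aging", "factor")
    ages = pd_.parameterization["assay_ages"]
    if len(ages) != 3:
        raise ValueError("acceleration contrast needs exactly three assay ages")
    a1, a2, a3 = ages
    early = interval_aging_draws(pd_, mutation_id, (a1, a2)) / (a2 - a1)
    late = interval_aging_draws(pd_, mutation_id, (a2, a3)) / (a3 - a2)
    return Estimate.from_draws((late - early) * (a2 - a1))


def among_line_variance(
    pd_: PosteriorDraws, age_day: int, mutation_subset: list[str] | None = None
) -> Estimate:
    """Variance (ddof=1) across mutation effects at one age, per draw."""
    _require(pd_, "aging", "factor")
    subset = _resolve_subset(pd_, mutation_subset)
    draws = np.stack([_effect_at(pd_, m, age_day) for m in subset])
    return Estimate.from_draws(draws.var(axis=0, ddof=1))


def variance_increase(
    pd_: PosteriorDraws, age_pair: tuple[int, int], mutation_subset: list[str] | None = None
) -> Estimate:
    """Difference of among-line variances between two ages (later - earlier),
    per draw, with p_mcmc on the difference."""
    _require(pd_, "aging", "factor")
    early, late = age_pair
    subset = _resolve_subset(pd_, mutation_subset)
    d_early = np.stack([_effect_at(pd_, m, early) for m in subset]).var(axis=0, ddof=1)
    d_late = np.stack([_effect_at(pd_, m, late) for m in subset]).var(axis=0, ddof=1)
    return Estimate.from_draws(d_late - d_early)


def _resolve_subset(pd_: PosteriorDraws, subset) -> list[str]:
    all_m = pd_.parameterization["mutations"]
    if subset is None:
        subset = all_m
    subset = [str(m) for m in subset]
    unknown = set(subset) - set(all_m)
    if unknown:
        raise KeyError(f"unknown mutations: {sorted(unknown)}")
    if len(subset) < 2:
        raise ValueError("among-line variance needs at least 2 mutations")
    return subset


# -- report assembly ------------------------------------------------------


@dataclass
class MutationResult:
    mutation_id: str
    s_first_age: Estimate
    s_summed: Estimate | None
    deleterious: bool
    deleterious_by: list[str]
    aging_coefficient: Estimate
    aging: bool
    interval_differences: dict[str, Estimate]
    acceleration: Estimate
    accelerating: bool

    def to_dict(self) -> dict:
        return {
            "mutation": self.mutation_id,
            "s_first_age": self.s_first_age.to_dict(),
            "s_summed": self.s_summed.to_dict() if self.s_summed else None,
            "deleterious": self.deleterious,
            "deleterious_by": self.deleterious_by,
            "aging_coefficient": self.aging_coefficient.to_dict(),
            "aging": self.aging,
            "interval_differences": {
                k: v.to_dict() for k, v in self.interval_differences.items()
            },
            "acceleration": self.acceleration.to_dict(),
            "accelerating": self.accelerating,
        }


@dataclass
class AgingReport:
    """All per-mutation and dataset-level estimands from the four model fits."""

    mutations: list[MutationResult]
    among_line_variance: dict[str, dict[str, Estimate]]
    variance_increases: dict[str, dict[str, Estimate]]
    alpha: float = ALPHA_DEFAULT
    provenance: dict = field(default_factory=dict)

    @property
    def deleterious_ids(self) -> list[str]:
        return [m.mutation_id for m in self.mutations if m.deleterious]

    @property
    def aging_ids(self) -> list[str]:
        return [m.mutation_id for m in self.mutations if m.aging]

    @property
    def accelerating_ids(self) -> list[str]:
        return [m.mutation_id for m in self.mutations if m.accelerating]

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "mutations": [m.to_dict() for m in self.mutations],
            "among_line_variance": {
                subset: {age: est.to_dict() for age, est in per_age.items()}
                for subset, per_age in self.among_line_variance.items()
            },
            "variance_increases": {
                subset: {pair: est.to_dict() for pair, est in per_pair.items()}
                for subset, per_pair in self.variance_increases.items()
            },
            "n_deleterious": len(self.deleterious_ids),
            "n_aging": len(self.aging_ids),
            "n_accelerating": len(self.accelerating_ids),
            "provenance": self.provenance,
        }


def build_report(
    draws_first_age: PosteriorDraws,
    draws_factor: PosteriorDraws,
    draws_covariate: PosteriorDraws,
    draws_summed: PosteriorDraws | None = None,
    alpha: float = ALPHA_DEFAULT,
) -> AgingReport:
    """Assemble the full analysis report from the individual model fits.

    Classification rules: a mutation is *deleterious* when its mutant-class
    effect is harmful (log ratio < 0) and significant (p_mcmc < alpha) in the
    first-age Poisson fit or, if provided, in the summed-ages fit (union
    rule, with the firing test(s) recorded); *aging* when the covariate
    slope is negative with p_mcmc < alpha; *accelerating* when it is aging
    and the late-minus-early rate contrast is negative with p_mcmc < alpha.
    """
    mutations = draws_first_age.parameterization["mutations"]
    ages = draws_factor.parameterization["assay_ages"]
    pairs = [(ages[i], ages[j]) for i in range(len(ages)) for j in range(i + 1, len(ages))]

    results = []
    for m in mutations:
        s1 = deleteriousness(draws_first_age, m)
        th1 = log_ratio_draws(draws_first_age, m)
        fired = []
        if s1.p_mcmc < alpha and th1.mean() < 0:
            fired.append("first-age")
        s_sum = None
        if draws_summed is not None:
            s_sum = deleteriousness(draws_summed, m)
            if s_sum.p_mcmc < alpha and log_ratio_draws(draws_summed, m).mean() < 0:
                fired.append("all-ages-summed")
        coeff = aging_coefficient(draws_covariate, m)
        aging = coeff.p_mcmc < alpha and coeff.mean < 0
        diffs = {f"{a}-{b}": interval_aging(draws_factor, m, (a, b)) for a, b in pairs}
        accel = aging_acceleration(draws_factor, m)
        results.append(
            MutationResult(
                mutation_id=m,
                s_first_age=s1,
                s_summed=s_sum,
                deleterious=bool(fired),
                deleterious_by=fired,
                aging_coefficient=coeff,
                aging=bool(aging),
                interval_differences=diffs,
                acceleration=accel,
                accelerating=bool(aging and accel.p_mcmc < alpha and accel.mean < 0),
            )
        )

    report = AgingReport(
        mutations=results,
        among_line_variance={},
        variance_increases={},
        alpha=alpha,
        provenance={
            "models": {
                "first_age": draws_first_age.parameterization,
                "factor": draws_factor.parameterization,
                "covariate": draws_covariate.parameterization,
                "summed": draws_summed.parameterization if draws_summed else None,
            }
        },
    )
    subsets = {"all": mutations}
    if len(report.deleterious_ids) >= 2:
        subsets["deleterious"] = report.deleterious_ids
    if len(report.aging_ids) >= 2:
        subsets["aging"] = report.aging_ids
    for name, ids in subsets.items():
        report.among_line_variance[name] = {
            str(a): among_line_variance(draws_factor, a, ids) for a in ages
        }
        report.variance_increases[name] = {
            f"{a}-{b}": variance_increase(draws_factor, (a, b), ids) for a, b in pairs
        }
    return report
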