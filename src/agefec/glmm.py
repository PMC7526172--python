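"""Bayesian hierarchical GLMMs for the paired fecundity assay.

Two model families, both with a per-vial random intercept:

* **Deleteriousness model** — vial-level egg counts per genotype class with a
  Poisson error distribution and log link, ``eggs ~ type * mutation + (1|vial)``,
  run either on day-5 counts only or on counts summed across the assay ages.
* **Aging models** — mutant eggs out of (mutant + wildtype) eggs per vial and
  age with a binomial error distribution and logit link,
  ``mut/(mut+wt) ~ age * mutation + (1|vial)``, with age either as a
  covariate in days (per-mutation slope) or as a factor (per-mutation
  per-age effect).  Under the paired-Poisson generative model, conditioning
  on the vial total makes the logit of the mutant fraction equal the log
  mutant/wildtype rate ratio, so the vial intercept shared by both classes
  cancels and the binomial effects are directly the relative-fecundity
  estimands.

Models are parameterized as cell means (one baseline/effect per mutation and
age or slope) so per-mutation estimands need no reference-level arithmetic.
Priors are weakly informative normals — SD 10 on baseline/level parameters,
SD 2.5 on slope parameters, the latter rescaled by the empirical SD of
non-binary predictor columns (autoscaling) — and Exponential(1) on the vial
intercept SD.  Sampling is HMC with four chains of 4000 iterations, the
first 1000 discarded as warmup, by default; convergence is assessed with the
Gelman-Rubin split potential scale reduction factor.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .dataset import FecundityDataset, PairingError
from .hmc import sample_hmc

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.05


class ConvergenceWarning(UserWarning):
    """An MCMC run finished with split-R-hat above the accepted threshold."""


@dataclass
class ModelSpec:
    """Sampler and prior settings shared by all model fits."""

    chains: int = 4
    iterations: int = 4000
    warmup: int = 1000
    prior_intercept_sd: float = 10.0
    prior_coefficient_sd: float = 2.5
    autoscale: bool = True
    vial_sd_prior_rate: float = 1.0  # Exponential prior on sigma_vial
    target_accept: float = 0.8
    rhat_threshold: float = RHAT_THRESHOLD

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("chains must be >= 2 (required by the convergence diagnostic)")
        if not (0 < self.warmup < self.iterations):
            raise ValueError("need 0 < warmup < iterations")

    @classmethod
    def fast(cls) -> "ModelSpec":
        """Short-chain settings for simulation studies and CI; not publication grade."""
        return cls(chains=2, iterations=700, warmup=250)


@dataclass
class PosteriorDraws:
    """Labelled MCMC output: (chains, post-warmup iterations, parameters)."""

    draws: np.ndarray
    parameter_names: list[str]
    parameterization: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.parameter_names) != self.draws.shape[2]:
            raise ValueError("parameter_names length must match draws axis 2")
        if len(set(self.parameter_names)) != len(self.parameter_names):
            raise ValueError("parameter_names must be unique")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("draws contain non-finite values")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        """Total post-warmup draws pooled over chains."""
        return self.draws.shape[0] * self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Pooled draws of one parameter as a flat vector."""
        try:
            j = self.parameter_names.index(name)
        except ValueError as exc:
            raise KeyError(f"unknown parameter {name!r}") from exc
        return self.draws[:, :, j].reshape(-1)

    def get_per_chain(self, name: str) -> np.ndarray:
        j = self.parameter_names.index(name)
        return self.draws[:, :, j]

    def save(self, path) -> None:
        """Persist as .npz with a JSON metadata sidecar array."""
        np.savez_compressed(
            path,
            draws=self.draws,
            parameter_names=np.array(self.parameter_names),
            parameterization=np.array(json.dumps(self.parameterization, sort_keys=True)),
        )

    @classmethod
    def load(cls, path) -> "PosteriorDraws":
        with np.load(path, allow_pickle=False) as f:
            return cls(
                draws=f["draws"],
                parameter_names=[str(s) for s in f["parameter_names"]],
                parameterization=json.loads(str(f["parameterization"])),
            )

    def to_arviz(self):
        """Convert to an arviz InferenceData (arviz must be importable)."""
        import arviz as az

        data = {name: self.get_per_chain(name) for name in self.parameter_names}
        return az.from_dict(posterior=data)


def gelman_rubin(pd_: PosteriorDraws) -> dict[str, float]:
    """Split potential scale reduction factor (split-R-hat) per parameter.

    Each chain is split in half; R-hat compares between- and within-half
    variances and approaches 1 for identically distributed stationary chains.
    """
    if pd_.n_chains < 2:
        raise ValueError("gelman_rubin requires >= 2 chains")
    return {
        name: split_rhat(pd_.get_per_chain(name)) for name in pd_.parameter_names
    }


def split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat for one parameter given a (chains, iterations) array."""
    c, n = chains.shape
    if n < 4:
        raise ValueError("need at least 4 iterations per chain")
    half = n // 2
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n2 = segs.shape
    within = segs.var(axis=1, ddof=1).mean()
    between = n2 * segs.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else np.inf
    var_plus = (n2 - 1) / n2 * within + between / n2
    return float(np.sqrt(var_plus / within))


# -- design assembly ------------------------------------------------------


def _index_of(values: pd.Series, levels: list) -> np.ndarray:
    lut = {v: i for i, v in enumerate(levels)}
    return values.map(lut).to_numpy(dtype=int)


def _one_hot(idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((idx.size, n))
    out[np.arange(idx.size), idx] = 1.0
    return out


def _autoscaled_sd(base_sd: float, column: np.ndarray, autoscale: bool) -> float:
    """Rescale a coefficient prior SD by 1/sd(x) for non-binary predictors."""
    uniq = np.unique(column)
    if not autoscale or set(uniq.tolist()) <= {0.0, 1.0}:
        return base_sd
    sd = float(np.std(column, ddof=1))
    return base_sd / sd if sd > 0 else base_sd


def _run(
    potential,
    init,
    spec: ModelSpec,
    seed: int,
    names: list[str],
    meta: dict,
    init_inv_mass=None,
) -> PosteriorDraws:
    res = sample_hmc(
        potential,
        init,
        iterations=spec.iterations,
        warmup=spec.warmup,
        seed=seed,
        target_accept=spec.target_accept,
        init_inv_mass=init_inv_mass,
    )
    pd_ = PosteriorDraws(draws=res.draws, parameter_names=names, parameterization=meta)
    rhats = gelman_rubin(pd_)
    max_rhat = max(rhats.values())
    pd_.parameterization["max_rhat"] = max_rhat
    pd_.parameterization["accept_rate"] = float(np.mean(res.accept_rate))
    if max_rhat > spec.rhat_threshold:
        worst = max(rhats, key=rhats.get)
        warnings.warn(
            f"split-R-hat {max_rhat:.3f} for {worst!r} exceeds "
            f"{spec.rhat_threshold}; chains may not have converged",
            ConvergenceWarning,
            stacklevel=3,
        )
    return pd_


# -- deleteriousness model (Poisson, log link) ----------------------------


def fit_deleteriousness_model(
    ds: FecundityDataset,
    ages_used: str = "first-age-only",
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Fit ``eggs ~ type * mutation + (1|vial)``, Poisson with log link.

    ``ages_used``: ``"first-age-only"`` uses counts from the first assay age;
    ``"all-ages-summed"`` sums each class's counts over the ages the vial was
    assayed at (vials missing an age are summed over available ages and
    flagged in the metadata).

    The per-mutation mutant-class effect (parameter ``log_ratio[m]``) is the
    log mutant/wildtype fecundity ratio; deleteriousness is ``1 - exp`` of it.
    """
    spec = spec or ModelSpec()
    if ages_used not in ("first-age-only", "all-ages-summed"):
        raise ValueError("ages_used must be 'first-age-only' or 'all-ages-summed'")
    wide = ds.paired_table()
    if ages_used == "first-age-only":
        sub = wide[wide["age_day"] == ds.assay_ages[0]]
        incomplete: list[str] = []
    else:
        counts = wide.groupby(["mutation", "vial"])["age_day"].count()
        incomplete = [f"{m}:{v}" for (m, v), k in counts.items() if k < len(ds.assay_ages)]
        sub = (
            wide.groupby(["mutation", "vial"], as_index=False)[["mut_eggs", "wt_eggs"]].sum()
        )
        if incomplete:
            logger.info("summed over available ages for %d incomplete vials", len(incomplete))
    if len(sub) == 0:
        raise PairingError("no paired vial counts available for the requested ages")

    # long format: one row per (vial, class); vial labels are only unique
    # within a mutation, so the random-intercept key is (mutation, vial)
    sub = sub.assign(vial_key=sub["mutation"] + ":" + sub["vial"])
    long = pd.concat(
        [
            sub[["mutation", "vial_key"]].assign(is_mut=0.0, eggs=sub["wt_eggs"]),
            sub[["mutation", "vial_key"]].assign(is_mut=1.0, eggs=sub["mut_eggs"]),
        ],
        ignore_index=True,
    )
    mutations = ds.mutation_ids
    vials = sorted(long["vial_key"].unique().tolist())
    midx = _index_of(long["mutation"], mutations)
    vidx = _index_of(long["vial_key"], vials)
    y = long["eggs"].to_numpy(dtype=float)
    t = long["is_mut"].to_numpy(dtype=float)
    n_mut, n_vial = len(mutations), len(vials)
    A_m = _one_hot(midx, n_mut)
    A_v = _one_hot(vidx, n_vial)

    sd_base = spec.prior_intercept_sd
    sd_theta = _autoscaled_sd(spec.prior_coefficient_sd, t, spec.autoscale)
    rate = spec.vial_sd_prior_rate

    # method-of-moments vial variance decides the parameterization: when
    # among-vial variance dominates Poisson count noise the vial means are
    # data-pinned and a centered (vial log-mean) parameterization mixes
    # well; when it does not, the non-centered form avoids the funnel
    vial_mut = pd.Series([v.split(":", 1)[0] for v in vials])
    totals = sub.set_index("vial_key").loc[vials, ["mut_eggs", "wt_eggs"]].sum(axis=1)
    log_tot = np.log(np.maximum(totals.to_numpy(dtype=float), 1.0))
    noise = float(np.mean(1.0 / np.maximum(totals.to_numpy(dtype=float), 1.0)))
    per_mut_var = pd.Series(log_tot).groupby(vial_mut.values).var(ddof=1).dropna()
    sigma2_mom = max(0.0, float(per_mut_var.mean()) - noise) if len(per_mut_var) else 0.0
    centered = sigma2_mom > 2.0 * noise
    sigma0 = float(np.sqrt(max(sigma2_mom, 0.0025)))

    vm = _index_of(pd.Series(vials).str.split(":", n=1).str[0], mutations)  # vial -> mutation
    A_vm = _one_hot(vm, n_mut)
    n_per_mut = A_vm.sum(axis=0)

    if centered:
        # parameters: alpha (per-mutation wildtype log mean), theta (log
        # ratio), w (per-vial wildtype log mean, prior N(alpha[m], sigma^2))
        def potential(q: np.ndarray):
            alpha = q[:, :n_mut]
            theta = q[:, n_mut : 2 * n_mut]
            w = q[:, 2 * n_mut : 2 * n_mut + n_vial]
            s = q[:, -1]
            sigma = np.exp(np.clip(s, -30, 10))
            inv_s2 = np.exp(np.clip(-2 * s, -20, 60))
            eta = w[:, vidx] + theta[:, midx] * t
            eta = np.clip(eta, -60, 60)
            lam = np.exp(eta)
            dev = w - alpha[:, vm]
            devsq = (dev**2).sum(axis=1)
            logp = (
                (y * eta - lam).sum(axis=1)
                - 0.5 * (alpha**2).sum(axis=1) / sd_base**2
                - 0.5 * (theta**2).sum(axis=1) / sd_theta**2
                - 0.5 * devsq * inv_s2
                - n_vial * s
                - rate * sigma
                + s
            )
            r = y - lam
            grad = np.empty_like(q)
            grad[:, :n_mut] = (dev @ A_vm) * inv_s2[:, None] - alpha / sd_base**2
            grad[:, n_mut : 2 * n_mut] = (r * t) @ A_m - theta / sd_theta**2
            grad[:, 2 * n_mut : 2 * n_mut + n_vial] = r @ A_v - dev * inv_s2[:, None]
            grad[:, -1] = devsq * inv_s2 - n_vial - rate * sigma + 1.0
            return logp, grad

    else:

        def potential(q: np.ndarray):
            alpha = q[:, :n_mut]
            theta = q[:, n_mut : 2 * n_mut]
            z = q[:, 2 * n_mut : 2 * n_mut + n_vial]
            s = q[:, -1]
            sigma = np.exp(np.clip(s, -30, 10))
            eta = alpha[:, midx] + theta[:, midx] * t + sigma[:, None] * z[:, vidx]
            eta = np.clip(eta, -60, 60)
            lam = np.exp(eta)
            logp = (
                (y * eta - lam).sum(axis=1)
                - 0.5 * (alpha**2).sum(axis=1) / sd_base**2
                - 0.5 * (theta**2).sum(axis=1) / sd_theta**2
                - 0.5 * (z**2).sum(axis=1)
                - rate * sigma
                + s
            )
            r = y - lam
            rv = r @ A_v
            grad = np.empty_like(q)
            grad[:, :n_mut] = r @ A_m - alpha / sd_base**2
            grad[:, n_mut : 2 * n_mut] = (r * t) @ A_m - theta / sd_theta**2
            grad[:, 2 * n_mut : 2 * n_mut + n_vial] = sigma[:, None] * rv - z
            grad[:, -1] = sigma * (z * rv).sum(axis=1) - rate * sigma + 1.0
            return logp, grad

    # data-informed, per-chain jittered initialization
    rng = np.random.default_rng(seed + 1)
    wt_mean = np.maximum(sub.groupby("mutation")["wt_eggs"].mean().reindex(mutations), 0.5)
    mut_mean = np.maximum(sub.groupby("mutation")["mut_eggs"].mean().reindex(mutations), 0.5)
    alpha0 = np.log(wt_mean.to_numpy())
    theta0 = np.log((mut_mean / wt_mean).to_numpy())
    if centered:
        w0 = np.log(np.maximum(sub.set_index("vial_key").loc[vials, "wt_eggs"].to_numpy(), 0.5))
        base = np.concatenate([alpha0, theta0, w0, [np.log(sigma0)]])
    else:
        base = np.concatenate([alpha0, theta0, np.zeros(n_vial), [np.log(sigma0)]])
    init = base[None, :] + rng.normal(0, 0.05, size=(spec.chains, base.size))
    init[:, -1] += rng.normal(0, 0.4, size=spec.chains)

    # Fisher-information diagonal at the starting point seeds the mass matrix
    lam0 = np.exp(np.clip(alpha0[midx] + theta0[midx] * t, -60, 60))
    if centered:
        curv = np.concatenate(
            [
                n_per_mut / sigma0**2 + 1.0 / sd_base**2,
                (lam0 * t) @ A_m + 1.0 / sd_theta**2,
                lam0 @ A_v + 1.0 / sigma0**2,
                [2.0 * n_vial + 1.0],
            ]
        )
    else:
        curv = np.concatenate(
            [
                lam0 @ A_m + 1.0 / sd_base**2,
                (lam0 * t) @ A_m + 1.0 / sd_theta**2,
                sigma0**2 * (lam0 @ A_v) + 1.0,
                [1.0],
            ]
        )

    vial_label = "w_vial" if centered else "z_vial"
    names = (
        [f"baseline[{m}]" for m in mutations]
        + [f"log_ratio[{m}]" for m in mutations]
        + [f"{vial_label}[{v}]" for v in vials]
        + ["vial_sd"]
    )
    meta = {
        "model": "deleteriousness",
        "family": "poisson-log",
        "formula": "eggs ~ type * mutation + (1|vial)",
        "parameterization": "cell-means",
        "ages_used": ages_used,
        "mutations": mutations,
        "vial_parameterization": "centered" if centered else "non-centered",
        "incomplete_vials": incomplete,
        "spec": asdict(spec),
        "seed": seed,
    }
    out = _run(potential, init, spec, seed, names, meta, init_inv_mass=1.0 / curv)
    # expose sigma on the natural scale
    j = names.index("vial_sd")
    out.draws[:, :, j] = np.exp(out.draws[:, :, j])
    return out


# -- aging models (binomial, logit link) ----------------------------------


def fit_aging_model(
    ds: FecundityDataset,
    age_coding: str = "covariate",
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Fit ``mut_eggs / (mut_eggs + wt_eggs) ~ age * mutation + (1|vial)``.

    ``age_coding="covariate"`` gives each mutation a day-5 level
    (``ratio_day5[m]``, the log ratio at the first assay age) and a per-day
    slope (``aging_slope[m]``); ``"factor"`` gives one effect per mutation
    and age (``ratio_at[m,a]``).  Vial-age rows whose two classes laid zero
    eggs in total carry no information about the ratio and are dropped with
    a logged notice.
    """
    spec = spec or ModelSpec()
    if age_coding not in ("covariate", "factor"):
        raise ValueError("age_coding must be 'covariate' or 'factor'")
    if len(ds.assay_ages) < 2:
        raise ValueError("aging models need paired counts at >= 2 assay ages")
    wide = ds.paired_table()
    total = wide["mut_eggs"] + wide["wt_eggs"]
    n_zero = int((total == 0).sum())
    if n_zero:
        logger.warning("dropping %d vial-age rows with zero total eggs", n_zero)
        wide = wide[total > 0]
        total = total[total > 0]

    wide = wide.assign(vial_key=wide["mutation"] + ":" + wide["vial"])
    mutations = ds.mutation_ids
    vials = sorted(wide["vial_key"].unique().tolist())
    ages = ds.assay_ages
    midx = _index_of(wide["mutation"], mutations)
    vidx = _index_of(wide["vial_key"], vials)
    aidx = _index_of(wide["age_day"], ages)
    y = wide["mut_eggs"].to_numpy(dtype=float)
    n = total.to_numpy(dtype=float)
    age_c = (wide["age_day"] - ages[0]).to_numpy(dtype=float)
    n_mut, n_vial, n_age = len(mutations), len(vials), len(ages)
    A_m = _one_hot(midx, n_mut)
    A_v = _one_hot(vidx, n_vial)

    sd_level = spec.prior_intercept_sd
    rate = spec.vial_sd_prior_rate
    rng = np.random.default_rng(seed + 1)

    # pooled empirical logits per (mutation, age) for initialization
    agg = wide.assign(tot=n, mut=y).groupby(["mutation", "age_day"])[["mut", "tot"]].sum()
    elogit = np.zeros((n_mut, n_age))
    for i, m in enumerate(mutations):
        for j, a in enumerate(ages):
            if (m, a) in agg.index:
                mu, to = agg.loc[(m, a)]
                p = np.clip((mu + 0.5) / (to + 1.0), 1e-6, 1 - 1e-6)
                elogit[i, j] = np.log(p / (1 - p))

    if age_coding == "covariate":
        sd_slope = _autoscaled_sd(spec.prior_coefficient_sd, age_c, spec.autoscale)

        def potential(q: np.ndarray):
            a = q[:, :n_mut]
            b = q[:, n_mut : 2 * n_mut]
            z = q[:, 2 * n_mut : 2 * n_mut + n_vial]
            s = q[:, -1]
            sigma = np.exp(np.clip(s, -30, 10))
            eta = a[:, midx] + b[:, midx] * age_c + sigma[:, None] * z[:, vidx]
            p = 0.5 * (1.0 + np.tanh(0.5 * eta))  # stable logistic
            ll = y * eta - n * np.logaddexp(0.0, eta)
            logp = (
                ll.sum(axis=1)
                - 0.5 * (a**2).sum(axis=1) / sd_level**2
                - 0.5 * (b**2).sum(axis=1) / sd_slope**2
                - 0.5 * (z**2).sum(axis=1)
                - rate * sigma
                + s
            )
            r = y - n * p
            rv = r @ A_v
            grad = np.empty_like(q)
            grad[:, :n_mut] = r @ A_m - a / sd_level**2
            grad[:, n_mut : 2 * n_mut] = (r * age_c) @ A_m - b / sd_slope**2
            grad[:, 2 * n_mut : 2 * n_mut + n_vial] = sigma[:, None] * rv - z
            grad[:, -1] = sigma * (z * rv).sum(axis=1) - rate * sigma + 1.0
            return logp, grad

        span = float(ages[-1] - ages[0])
        base = np.concatenate(
            [
                elogit[:, 0],
                (elogit[:, -1] - elogit[:, 0]) / span,
                np.zeros(n_vial),
                [np.log(0.1)],
            ]
        )
        names = (
            [f"ratio_day{ages[0]}[{m}]" for m in mutations]
            + [f"aging_slope[{m}]" for m in mutations]
            + [f"z_vial[{v}]" for v in vials]
            + ["vial_sd"]
        )
        eta0 = base[midx] + base[n_mut + midx] * age_c
        p0 = 0.5 * (1.0 + np.tanh(0.5 * eta0))
        w0 = n * p0 * (1.0 - p0)
        sigma0 = float(np.exp(base[-1]))
        curv = np.concatenate(
            [
                w0 @ A_m + 1.0 / sd_level**2,
                (w0 * age_c**2) @ A_m + 1.0 / sd_slope**2,
                sigma0**2 * (w0 @ A_v) + 1.0,
                [1.0],
            ]
        )
    else:
        n_fixed = n_mut * n_age
        cidx = midx * n_age + aidx  # flat (mutation, age) cell index
        A_c = _one_hot(cidx, n_fixed)

        def potential(q: np.ndarray):
            c = q[:, :n_fixed]
            z = q[:, n_fixed : n_fixed + n_vial]
            s = q[:, -1]
            sigma = np.exp(np.clip(s, -30, 10))
            eta = c[:, cidx] + sigma[:, None] * z[:, vidx]
            p = 0.5 * (1.0 + np.tanh(0.5 * eta))  # stable logistic
            ll = y * eta - n * np.logaddexp(0.0, eta)
            logp = (
                ll.sum(axis=1)
                - 0.5 * (c**2).sum(axis=1) / sd_level**2
                - 0.5 * (z**2).sum(axis=1)
                - rate * sigma
                + s
            )
            r = y - n * p
            rv = r @ A_v
            grad = np.empty_like(q)
            grad[:, :n_fixed] = r @ A_c - c / sd_level**2
            grad[:, n_fixed : n_fixed + n_vial] = sigma[:, None] * rv - z
            grad[:, -1] = sigma * (z * rv).sum(axis=1) - rate * sigma + 1.0
            return logp, grad

        base = np.concatenate([elogit.reshape(-1), np.zeros(n_vial), [np.log(0.1)]])
        names = (
            [f"ratio_at[{m},{a}]" for m in mutations for a in ages]
            + [f"z_vial[{v}]" for v in vials]
            + ["vial_sd"]
        )
        eta0 = base[cidx]
        p0 = 0.5 * (1.0 + np.tanh(0.5 * eta0))
        w0 = n * p0 * (1.0 - p0)
        sigma0 = float(np.exp(base[-1]))
        curv = np.concatenate(
            [w0 @ A_c + 1.0 / sd_level**2, sigma0**2 * (w0 @ A_v) + 1.0, [1.0]]
        )

    init = base[None, :] + rng.normal(0, 0.1, size=(spec.chains, base.size))
    init[:, -1] += rng.normal(0, 0.4, size=spec.chains)
    meta = {
        "model": "aging",
        "family": "binomial-logit",
        "formula": "(mut eggs | wt eggs) ~ age * mutation + (1|vial)",
        "parameterization": "cell-means",
        "age_coding": age_coding,
        "age_centering": f"days since day {ages[0]}",
        "assay_ages": list(map(int, ages)),
        "mutations": mutations,
        "dropped_zero_total_rows": n_zero,
        "spec": asdict(spec),
        "seed": seed,
    }
    out = _run(potential, init, spec, seed, names, meta, init_inv_mass=1.0 / curv)
    j = names.index("vial_sd")
    out.draws[:, :, j] = np.exp(out.draws[:, :, j])
    return out
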