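"""End-to-end orchestration: simulate/load -> fit -> analyze -> correlate.

``run_full_analysis`` composes the analysis stages in their natural order —
deleteriousness fits (first-age and summed Poisson), aging fits (binomial
with age as covariate and as factor), posterior report, rank-correlation
suite — and writes every artifact with the seed and settings recorded, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .dataset import FecundityDataset, load_fecundity_table, save_fecundity_table
from .glmm import ModelSpec, PosteriorDraws, fit_aging_model, fit_deleteriousness_model
from .pleiotropy import age_pleiotropy, aging_vs_deleteriousness, survival_pleiotropy
from .posterior import AgingReport, build_report
from .simulate import SimConfig, simulate_experiment

logger = logging.getLogger(__name__)

#: model stages: name -> (fit function kind, option)
ALL_MODELS = ("first_age", "summed", "covariate", "factor")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    outdir: str | Path = "agefec_run"
    data_path: str | Path | None = None
    survival_path: str | Path | None = None
    sim: SimConfig | None = None
    seed: int = 0
    fast: bool = False
    alpha: float = 0.05
    models: tuple[str, ...] = ALL_MODELS
    age_pairs: tuple[tuple[int, int], ...] = ((5, 19), (5, 33), (19, 33))
    save_draws: bool = True

    def model_spec(self) -> ModelSpec:
        return ModelSpec.fast() if self.fast else ModelSpec()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        rc = cls(**{k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            for key in ("delta", "beta", "kappa", "survival_logit"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = __import__("numpy").asarray(sim[key], dtype=float)
            for key in ("vials_per_mutation", "assay_ages", "age_effects"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            rc.sim = SimConfig(**sim)
        if isinstance(rc.models, list):
            rc.models = tuple(rc.models)
        if isinstance(rc.age_pairs, list):
            rc.age_pairs = tuple(tuple(p) for p in rc.age_pairs)
        return rc


@dataclass
class RunResult:
    dataset: FecundityDataset
    draws: dict[str, PosteriorDraws]
    report: AgingReport | None
    taus: dict[str, dict]
    outdir: Path
    seed: int
    artifacts: dict[str, str] = field(default_factory=dict)


def _fit_stage(name: str, ds, spec, seed: int) -> PosteriorDraws:
    if name == "first_age":
        return fit_deleteriousness_model(ds, "first-age-only", spec, seed=seed)
    if name == "summed":
        return fit_deleteriousness_model(ds, "all-ages-summed", spec, seed=seed + 1)
    if name == "covariate":
        return fit_aging_model(ds, "covariate", spec, seed=seed + 2)
    if name == "factor":
        return fit_aging_model(ds, "factor", spec, seed=seed + 3)
    raise ValueError(f"unknown model stage {name!r}")


def run_full_analysis(rc: RunConfig) -> RunResult:
    """Run every configured stage; artifacts land under ``rc.outdir``.

    Emits ``data.csv`` (and ``survival.csv``) when simulating, one
    ``draws_<model>.npz`` per fitted model, ``report.json``, ``tau.json``
    and ``run.json`` with seeds and R-hat summaries.  Any stage failure
    raises :class:`StageError` naming the stage.
    """
    outdir = Path(rc.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # -- data stage
    try:
        if rc.sim is not None:
            sim = dataclasses.replace(rc.sim, seed=rc.sim.seed if rc.sim.seed else rc.seed)
            ds = simulate_experiment(sim)
            data_path = outdir / "data.csv"
            surv_path = outdir / "survival.csv" if ds.survival is not None else None
            save_fecundity_table(ds, data_path, survival_path=surv_path)
            artifacts["data"] = str(data_path)
            if surv_path:
                artifacts["survival"] = str(surv_path)
        elif rc.data_path is not None:
            ds = load_fecundity_table(rc.data_path, survival_path=rc.survival_path)
        else:
            raise ValueError("RunConfig needs either sim or data_path")
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise StageError("data", exc) from exc

    # -- model fits
    spec = rc.model_spec()
    draws: dict[str, PosteriorDraws] = {}
    for name in rc.models:
        try:
            logger.info("fitting model %s", name)
            draws[name] = _fit_stage(name, ds, spec, rc.seed)
            if rc.save_draws:
                path = outdir / f"draws_{name}.npz"
                draws[name].save(path)
                artifacts[f"draws_{name}"] = str(path)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"fit:{name}", exc) from exc

    # -- posterior report
    report = None
    if {"first_age", "covariate", "factor"} <= set(draws):
        try:
            report = build_report(
                draws["first_age"],
                draws["factor"],
                draws["covariate"],
                draws_summed=draws.get("summed"),
                alpha=rc.alpha,
            )
            report.provenance["seed"] = rc.seed
            report.provenance["alpha"] = rc.alpha
            # file names only: keeps report content independent of where the
            # run directory lives, so equal-seed reruns are byte-identical
            report.provenance["artifacts"] = {
                k: Path(v).name for k, v in artifacts.items()
            }
            report.provenance["version"] = __version__
            rpath = outdir / "report.json"
            with open(rpath, "w") as fh:
                json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
            artifacts["report"] = str(rpath)
        except Exception as exc:  # noqa: BLE001
            raise StageError("analyze", exc) from exc

    # -- rank correlations
    taus: dict[str, dict] = {}
    try:
        subsets: dict[str, list[str] | None] = {"all": None}
        if report is not None:
            if len(report.deleterious_ids) >= 3:
                subsets["deleterious"] = report.deleterious_ids
            if len(report.aging_ids) >= 3:
                subsets["aging"] = report.aging_ids
        for sub_name, ids in subsets.items():
            entry: dict[str, dict] = {}
            for pair in rc.age_pairs:
                if set(pair) <= set(ds.assay_ages):
                    key = f"{pair[0]}-{pair[1]}"
                    entry[f"fecundity_{key}"] = age_pleiotropy(ds, ids, pair).to_dict()
                    entry[f"aging_vs_level_{key}"] = aging_vs_deleteriousness(
                        ds, ids, pair
                    ).to_dict()
            if ds.survival is not None:
                entry["survival_vs_first_age"] = survival_pleiotropy(ds, ids).to_dict()
            taus[sub_name] = entry
        tpath = outdir / "tau.json"
        with open(tpath, "w") as fh:
            json.dump(taus, fh, indent=1, sort_keys=True)
        artifacts["tau"] = str(tpath)
    except Exception as exc:  # noqa: BLE001
        raise StageError("pleiotropy", exc) from exc

    # -- run log
    run_info = {
        "seed": rc.seed,
        "fast": rc.fast,
        "alpha": rc.alpha,
        "models": list(rc.models),
        "version": __version__,
        "max_rhat": {k: v.parameterization.get("max_rhat") for k, v in draws.items()},
        "artifacts": artifacts,
    }
    with open(outdir / "run.json", "w") as fh:
        json.dump(run_info, fh, indent=1, sort_keys=True)
    artifacts["run"] = str(outdir / "run.json")

    return RunResult(
        dataset=ds,
        draws=draws,
        report=report,
        taus=taus,
        outdir=outdir,
        seed=rc.seed,
        artifacts=artifacts,
    )
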