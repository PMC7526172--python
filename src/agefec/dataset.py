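"""Data model for the paired mutant/wildtype fecundity assay.

The experimental unit is a vial housing mutant and wildtype females of one
mutation line together.  At each assay age a matched number of females of
each genotype class lays eggs for 24 h and the eggs are counted per class.
One :class:`VialObservation` is one (mutation, vial, age, class) egg count;
a validated collection of them, optionally with day-33 survival counts, is a
:class:`FecundityDataset` — the single input type of every downstream fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MUTANT = "mut"
WILDTYPE = "wt"
GENOTYPE_CLASSES = (MUTANT, WILDTYPE)

#: canonical CSV column order for fecundity tables
FECUNDITY_COLUMNS = ["mutation", "vial", "age_day", "class", "n_females", "eggs"]
#: canonical CSV column order for survival tables
SURVIVAL_COLUMNS = ["mutation", "vial", "age_day", "class", "n_alive", "n_start"]


class SchemaError(ValueError):
    """A required column is missing or has the wrong kind of content."""


class PairingError(ValueError):
    """A mutant record lacks its wildtype partner (or vice versa)."""


@dataclass(frozen=True)
class VialObservation:
    """One egg count: a genotype class in one vial at one assay age."""

    mutation_id: str
    vial_id: str
    age_day: int
    genotype_class: str
    n_females: int
    egg_count: int

    def __post_init__(self) -> None:
        if self.genotype_class not in GENOTYPE_CLASSES:
            raise ValueError(f"genotype_class must be one of {GENOTYPE_CLASSES}")
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")
        if self.egg_count < 0:
            raise ValueError("egg_count must be >= 0")


@dataclass(frozen=True)
class SurvivalObservation:
    """Survivor count for one genotype class in one vial at one age."""

    mutation_id: str
    vial_id: str
    age_day: int
    genotype_class: str
    n_alive: int
    n_start: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_alive <= self.n_start):
            raise ValueError("need 0 <= n_alive <= n_start")


def relative_fecundity(mut_eggs: int | np.ndarray, wt_eggs: int | np.ndarray):
    """Log ratio of mutant to wildtype egg counts, ln((mut+1)/(wt+1)).

    The +1 offset is applied to both counts unconditionally so the statistic
    is defined (and continuous) when either class laid no eggs.
    """
    mut = np.asarray(mut_eggs, dtype=float)
    wt = np.asarray(wt_eggs, dtype=float)
    if np.any(mut < 0) or np.any(wt < 0):
        raise ValueError("egg counts must be non-negative")
    out = np.log((mut + 1.0) / (wt + 1.0))
    return float(out) if out.ndim == 0 else out


@dataclass
class FecundityDataset:
    """Validated egg-count table plus optional survival records.

    ``observations`` holds one row per :class:`VialObservation` with columns
    ``mutation, vial, age_day, class, n_females, eggs``; ``survival`` (may be
    ``None``) one row per :class:`SurvivalObservation`.
    """

    observations: pd.DataFrame
    survival: pd.DataFrame | None = None
    assay_ages: list[int] = field(default_factory=list)
    mutation_ids: list[str] = field(default_factory=list)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_frames(
        cls,
        observations: pd.DataFrame,
        survival: pd.DataFrame | None = None,
        assay_ages: list[int] | None = None,
    ) -> "FecundityDataset":
        obs = observations.copy()
        for col in FECUNDITY_COLUMNS:
            if col not in obs.columns:
                raise SchemaError(f"missing required column: {col!r}")
        obs = obs[FECUNDITY_COLUMNS]
        obs["mutation"] = obs["mutation"].astype(str)
        obs["vial"] = obs["vial"].astype(str)
        for col in ("age_day", "n_females", "eggs"):
            try:
                obs[col] = obs[col].astype(int)
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"column {col!r} is not integer-valued") from exc
        surv = None
        if survival is not None and len(survival):
            surv = survival.copy()
            for col in SURVIVAL_COLUMNS:
                if col not in surv.columns:
                    raise SchemaError(f"missing required survival column: {col!r}")
            surv = surv[SURVIVAL_COLUMNS]
            surv["mutation"] = surv["mutation"].astype(str)
            surv["vial"] = surv["vial"].astype(str)
            for col in ("age_day", "n_alive", "n_start"):
                surv[col] = surv[col].astype(int)
        if assay_ages is None:
            assay_ages = sorted(obs["age_day"].unique().tolist())
        ds = cls(
            observations=obs.reset_index(drop=True),
            survival=surv.reset_index(drop=True) if surv is not None else None,
            assay_ages=[int(a) for a in assay_ages],
            mutation_ids=sorted(obs["mutation"].unique().tolist()),
        )
        ds.validate()
        return ds

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        """Enforce the dataset invariants; raise on the first violation."""
        obs = self.observations
        if len(obs) == 0:
            raise ValueError("dataset has no observations")
        if any(b <= a for a, b in zip(self.assay_ages, self.assay_ages[1:])):
            raise ValueError("assay_ages must be strictly increasing")
        if (obs["eggs"] < 0).any():
            bad = obs.loc[obs["eggs"] < 0].iloc[0]
            raise ValueError(
                f"negative egg count for ({bad['mutation']}, {bad['vial']}, "
                f"day {bad['age_day']})"
            )
        if (obs["n_females"] < 1).any():
            bad = obs.loc[obs["n_females"] < 1].iloc[0]
            raise ValueError(
                f"n_females < 1 for ({bad['mutation']}, {bad['vial']}, "
                f"day {bad['age_day']})"
            )
        unknown = set(obs["class"]) - set(GENOTYPE_CLASSES)
        if unknown:
            raise SchemaError(f"unknown genotype class labels: {sorted(unknown)}")
        extra_ages = set(obs["age_day"]) - set(self.assay_ages)
        if extra_ages:
            raise ValueError(f"ages outside assay_ages: {sorted(extra_ages)}")
        dup = obs.duplicated(subset=["mutation", "vial", "age_day", "class"])
        if dup.any():
            bad = obs.loc[dup].iloc[0]
            raise ValueError(
                f"duplicate record for ({bad['mutation']}, {bad['vial']}, "
                f"day {bad['age_day']}, {bad['class']})"
            )
        # mutant record exists iff wildtype record exists, with equal n_females
        for (mutation, vial, age), grp in obs.groupby(["mutation", "vial", "age_day"]):
            classes = set(grp["class"])
            if classes != set(GENOTYPE_CLASSES):
                missing = set(GENOTYPE_CLASSES) - classes
                raise PairingError(
                    f"({mutation}, {vial}, day {age}) lacks a "
                    f"{'/'.join(sorted(missing))} record"
                )
            nf = grp["n_females"].unique()
            if len(nf) != 1:
                raise PairingError(
                    f"({mutation}, {vial}, day {age}) has unequal n_females "
                    f"across classes: {sorted(nf.tolist())}"
                )
        if self.survival is not None:
            surv = self.survival
            if ((surv["n_alive"] < 0) | (surv["n_alive"] > surv["n_start"])).any():
                raise ValueError("survival records must satisfy 0 <= n_alive <= n_start")

    # -- views ------------------------------------------------------------

    def paired_table(self) -> pd.DataFrame:
        """Wide view: one row per (mutation, vial, age) with both class counts."""
        obs = self.observations
        wide = obs.pivot_table(
            index=["mutation", "vial", "age_day"],
            columns="class",
            values="eggs",
            aggfunc="first",
        ).reset_index()
        wide.columns.name = None
        wide = wide.rename(columns={MUTANT: "mut_eggs", WILDTYPE: "wt_eggs"})
        nf = obs.groupby(["mutation", "vial", "age_day"])["n_females"].first()
        wide = wide.merge(nf.rename("n_females").reset_index())
        wide["rel_fecundity"] = relative_fecundity(
            wide["mut_eggs"].to_numpy(), wide["wt_eggs"].to_numpy()
        )
        return wide.sort_values(["mutation", "vial", "age_day"]).reset_index(drop=True)

    def median_relative_fecundity(self, mutation_id: str, age_day: int) -> float:
        """Median over replicate vials of the per-vial ln((mut+1)/(wt+1))."""
        wide = self.paired_table()
        sel = wide[(wide["mutation"] == str(mutation_id)) & (wide["age_day"] == int(age_day))]
        if len(sel) == 0:
            raise KeyError(f"no paired vials for mutation {mutation_id!r} at day {age_day}")
        return float(sel["rel_fecundity"].median())

    def median_table(self, mutation_subset: list[str] | None = None) -> pd.DataFrame:
        """Per-mutation median relative fecundity at each assay age.

        Returns a frame indexed by mutation with one column per age.
        """
        wide = self.paired_table()
        med = wide.groupby(["mutation", "age_day"])["rel_fecundity"].median().unstack()
        if mutation_subset is not None:
            missing = set(map(str, mutation_subset)) - set(med.index)
            if missing:
                raise KeyError(f"unknown mutations: {sorted(missing)}")
            med = med.loc[[str(m) for m in mutation_subset]]
        return med

    def survival_log_ratio(
        self, mutation_id: str, age_day: int | None = None, pooled: bool = True
    ) -> float:
        """Relative survival ln((mut alive + 1)/(wt alive + 1)) for one line.

        Counts are pooled over vials by default; ``pooled=False`` takes the
        median of per-vial log ratios instead.
        """
        if self.survival is None or len(self.survival) == 0:
            raise ValueError("dataset has no survival records")
        if age_day is None:
            age_day = int(self.survival["age_day"].max())
        sel = self.survival[
            (self.survival["mutation"] == str(mutation_id))
            & (self.survival["age_day"] == int(age_day))
        ]
        if len(sel) == 0:
            raise KeyError(f"no survival records for {mutation_id!r} at day {age_day}")
        piv = sel.pivot_table(index="vial", columns="class", values="n_alive", aggfunc="first")
        if pooled:
            return float(math.log((piv[MUTANT].sum() + 1.0) / (piv[WILDTYPE].sum() + 1.0)))
        per_vial = np.log((piv[MUTANT].to_numpy() + 1.0) / (piv[WILDTYPE].to_numpy() + 1.0))
        return float(np.median(per_vial))

    def equals(self, other: "FecundityDataset") -> bool:
        key = ["mutation", "vial", "age_day", "class"]

        def canon(df: pd.DataFrame) -> pd.DataFrame:
            return df.sort_values(key).reset_index(drop=True)

        if not canon(self.observations).equals(canon(other.observations)):
            return False
        if (self.survival is None) != (other.survival is None):
            return False
        if self.survival is not None and not canon(self.survival).equals(canon(other.survival)):
            return False
        return self.assay_ages == other.assay_ages


def median_relative_fecundity(ds: FecundityDataset, mutation_id: str, age_day: int) -> float:
    """Functional form of :meth:`FecundityDataset.median_relative_fecundity`."""
    return ds.median_relative_fecundity(mutation_id, age_day)


# -- file I/O -------------------------------------------------------------


def load_fecundity_table(
    path,
    schema: dict[str, str] | None = None,
    survival_path=None,
    survival_schema: dict[str, str] | None = None,
) -> FecundityDataset:
    """Read a delimited fecundity table (and optional survival table).

    ``schema`` maps canonical column names (``mutation, vial, age_day, class,
    n_females, eggs``) to the file's actual headers, so externally produced
    files (e.g. a repository export with different headers) load without
    editing.  Raises :class:`SchemaError` for missing columns,
    :class:`PairingError` for unpaired records and ``ValueError`` for
    impossible counts.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    surv = None
    if survival_path is not None:
        surv = pd.read_csv(survival_path)
        if survival_schema:
            surv = surv.rename(columns={v: k for k, v in survival_schema.items()})
    return FecundityDataset.from_frames(df, survival=surv)


def save_fecundity_table(ds: FecundityDataset, path, survival_path=None) -> None:
    """Write the canonical CSV form (UTF-8, comma-separated, header row)."""
    ds.observations[FECUNDITY_COLUMNS].to_csv(path, index=False)
    if survival_path is not None and ds.survival is not None:
        ds.survival[SURVIVAL_COLUMNS].to_csv(survival_path, index=False)
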