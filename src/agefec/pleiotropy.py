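"""Rank-correlation tests for pleiotropy of mutation effects across ages.

Positive pleiotropy — a line that is bad young is also bad old — is assessed
with Kendall's tau on per-line median relative fecundities; the association
between a line's deleteriousness and the aging rate it induces uses the
change in median relative fecundity between two ages against the level at
the earlier age.  The latter test is conservative by construction: sampling
error in the earlier-age estimate enters the level positively and the
difference negatively, biasing the correlation toward negative values, so a
positive tau understates the true association.

The tau statistic is the tie-corrected tau-b (equal to tau-a when ties are
absent).  Two-tailed p values come from exact enumeration of the n!
permutation null for n <= 10 and from the tie-corrected normal approximation
(no continuity correction) otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import FecundityDataset

EXACT_MAX_N = 10


@dataclass
class TauResult:
    tau: float
    p_two_tailed: float
    n: int
    method: str  # "exact" or "approximation"
    degenerate: bool = False  # all pairs tied in x or y; tau undefined -> 0

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "p_two_tailed": self.p_two_tailed,
            "n": self.n,
            "method": self.method,
            "degenerate": self.degenerate,
        }


def _tau_b(x: np.ndarray, y: np.ndarray) -> float:
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic)


def _exact_perm_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-tailed permutation p for Kendall's tau, P(|tau*| >= |tau_obs|).

    The tie structure of both margins is permutation-invariant, so the tau-b
    denominator is constant across permutations and the comparison can be
    made on the integer concordant-minus-discordant statistic S — an exact
    integer test with no floating-point tolerance.  Permutations are
    processed in fixed-size blocks to bound memory at any n.
    """
    n = x.size
    iu, ju = np.triu_indices(n, k=1)
    # integer ranks preserve every pairwise ordering, enabling int8 arithmetic
    xr = np.unique(x, return_inverse=True)[1].astype(np.int8)
    yr = np.unique(y, return_inverse=True)[1].astype(np.int8)
    sx = np.sign(xr[ju] - xr[iu]).astype(np.int8)
    s_obs = abs(int((sx * np.sign(yr[ju] - yr[iu])).sum()))

    hits = total = 0
    block = 200_000
    perm_iter = itertools.permutations(yr.tolist())
    while True:
        flat = np.fromiter(
            itertools.chain.from_iterable(itertools.islice(perm_iter, block)),
            dtype=np.int8,
        )
        if flat.size == 0:
            break
        yp = flat.reshape(-1, n)
        s = (sx * np.sign(yp[:, ju] - yp[:, iu])).sum(axis=1, dtype=np.int32)
        hits += int(np.count_nonzero(np.abs(s) >= s_obs))
        total += yp.shape[0]
    return hits / total


def kendall_tau(x, y, exact_max_n: int = EXACT_MAX_N) -> TauResult:
    """Kendall rank correlation (tau-b) with a two-tailed p value.

    For n <= ``exact_max_n`` the p value is the exact permutation tail
    probability P(|tau| >= |tau_obs|) under the null of no association,
    enumerated over all n! orderings (ties handled by keeping the observed
    tie structure fixed); beyond that, the normal approximation with
    tie-corrected variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("kendall_tau needs at least 3 pairs")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("inputs must be finite")

    degenerate = np.unique(x).size == 1 or np.unique(y).size == 1
    if degenerate:
        method = "exact" if n <= exact_max_n else "approximation"
        return TauResult(tau=0.0, p_two_tailed=1.0, n=n, method=method, degenerate=True)

    tau = _tau_b(x, y)
    if n <= exact_max_n:
        return TauResult(tau=tau, p_two_tailed=_exact_perm_p(x, y), n=n, method="exact")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return TauResult(tau=tau, p_two_tailed=float(res.pvalue), n=n, method="approximation")


# -- dataset-level suites -------------------------------------------------


def age_pleiotropy(
    ds: FecundityDataset,
    mutation_subset: list[str] | None = None,
    age_pair: tuple[int, int] = (5, 33),
) -> TauResult:
    """Tau between per-line median relative fecundities at two ages."""
    early, late = age_pair
    med = ds.median_table(mutation_subset)
    _check_ages(med, early, late)
    return kendall_tau(med[early].to_numpy(), med[late].to_numpy())


def aging_vs_deleteriousness(
    ds: FecundityDataset,
    mutation_subset: list[str] | None = None,
    age_pair: tuple[int, int] = (5, 33),
) -> TauResult:
    """Tau between the change in median relative fecundity over an age
    interval and the level at the earlier age.

    A positive tau means more-deleterious lines (lower level) decline faster
    (more negative change).  Note the built-in conservative bias: estimation
    noise at the earlier age pushes tau negative under the null."""
    early, late = age_pair
    med = ds.median_table(mutation_subset)
    _check_ages(med, early, late)
    level = med[early].to_numpy()
    change = med[late].to_numpy() - level
    return kendall_tau(change, level)


def survival_pleiotropy(
    ds: FecundityDataset,
    mutation_subset: list[str] | None = None,
    pooled: bool = True,
) -> TauResult:
    """Tau between first-age median relative fecundity and final-age relative
    survival ln((mut alive + 1)/(wt alive + 1)), one value per line."""
    if ds.survival is None or len(ds.survival) == 0:
        raise ValueError("dataset has no survival records")
    med = ds.median_table(mutation_subset)
    first_age = ds.assay_ages[0]
    _check_ages(med, first_age, first_age)
    lines = med.index.tolist()
    fec = med[first_age].to_numpy()
    surv = np.array([ds.survival_log_ratio(m, pooled=pooled) for m in lines])
    return kendall_tau(fec, surv)


def _check_ages(med, early: int, late: int) -> None:
    for age in {early, late}:
        if age not in med.columns:
            raise KeyError(f"no medians available at day {age}")
    if med.isna().any().any():
        raise ValueError("medians missing for some (mutation, age) cells")
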