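import numpy as np
import pytest

import agefec
from agefec.glmm import PosteriorDraws
from agefec.posterior import (
    CodingError,
    Estimate,
    build_report,
    central_interval,
    p_mcmc,
)


class TestPMcmc:
    @pytest.mark.parametrize(
        "draws,expected",
        [
            ([1, 2, 3, -1], 0.5),
            ([1, 2, 3], 0.0),
            ([-1, -2, 1, 2], 1.0),
            ([-5, -6, -7, 8], 0.5),
        ],
    )
    def test_direct_counting(self, draws, expected):
        assert p_mcmc(draws) == pytest.approx(expected)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            p_mcmc([])

    def test_invariance_properties(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000) + 0.3
        base = p_mcmc(x)
        assert p_mcmc(10.0 * x) == base          # positive scaling
        assert p_mcmc(np.tanh(x)) == base        # sign-preserving monotone map
        assert p_mcmc(-x) == base                # sign flip leaves p unchanged
        assert 0.0 <= base <= 1.0


class TestEstimate:
    def test_central_interval_is_quantile_pair(self):
        x = np.arange(1000, dtype=float)
        lo, hi = central_interval(x)
        assert lo == pytest.approx(np.quantile(x, 0.025))
        assert hi == pytest.approx(np.quantile(x, 0.975))

    def test_transformed_scale_with_linear_scale_test(self):
        theta = np.array([-0.1, -0.2, -0.3, 0.05])
        est = Estimate.from_draws(1.0 - np.exp(theta), p_draws=theta)
        assert est.p_mcmc == p_mcmc(theta)


def _fake_factor_draws(effects: dict[str, np.ndarray], ages=(5, 19, 33)) -> PosteriorDraws:
    """Fabricate factor-model draws with given per-(mutation, age) vectors."""
    muts = sorted(effects)
    n = len(next(iter(effects.values()))[0])
    names, cols = [], []
    for m in muts:
        for j, a in enumerate(ages):
            names.append(f"ratio_at[{m},{a}]")
            cols.append(np.asarray(effects[m][j], dtype=float))
    draws = np.stack(cols, axis=1)[None, :, :]  # 1 chain
    draws = np.concatenate([draws, draws], axis=0)  # 2 identical chains
    return PosteriorDraws(
        draws,
        names,
        {"model": "aging", "age_coding": "factor", "assay_ages": list(ages), "mutations": muts},
    )


class TestFactorEstimands:
    def test_telescoping_identity_per_draw(self, mixed_effects_dataset, fast_spec):
        fac = agefec.fit_aging_model(mixed_effects_dataset, "factor", fast_spec, seed=4)
        for m in mixed_effects_dataset.mutation_ids[:3]:
            d_5_19 = agefec.posterior.interval_aging_draws(fac, m, (5, 19))
            d_19_33 = agefec.posterior.interval_aging_draws(fac, m, (19, 33))
            d_5_33 = agefec.posterior.interval_aging_draws(fac, m, (5, 33))
            np.testing.assert_allclose(d_5_19 + d_19_33, d_5_33, atol=1e-12)

    def test_acceleration_is_interval_difference_per_draw(self):
        rng = np.random.default_rng(1)
        eff = {"A": rng.standard_normal((3, 200))}
        pd_ = _fake_factor_draws(eff)
        accel = agefec.aging_acceleration(pd_, "A")
        d1 = agefec.posterior.interval_aging_draws(pd_, "A", (5, 19))
        d2 = agefec.posterior.interval_aging_draws(pd_, "A", (19, 33))
        expected = Estimate.from_draws(d2 - d1)
        assert accel.mean == pytest.approx(expected.mean, abs=1e-12)
        assert accel.p_mcmc == expected.p_mcmc

    def test_identical_effects_have_zero_variance(self):
        const = np.ones((3, 100))
        pd_ = _fake_factor_draws({"A": const, "B": const, "C": const})
        for age in (5, 19, 33):
            assert agefec.among_line_variance(pd_, age).mean == 0.0
        assert agefec.variance_increase(pd_, (5, 33)).mean == 0.0

    def test_variance_translation_invariance(self):
        rng = np.random.default_rng(2)
        eff = {m: rng.standard_normal((3, 150)) for m in "ABCD"}
        pd_ = _fake_factor_draws(eff)
        shifted = _fake_factor_draws({m: v + 7.5 for m, v in eff.items()})
        for age in (5, 19, 33):
            assert agefec.among_line_variance(pd_, age).mean == pytest.approx(
                agefec.among_line_variance(shifted, age).mean, rel=1e-12
            )

    def test_variance_matches_hand_computation(self):
        eff = {
            "A": np.tile([[0.0], [0.0], [0.0]], (1, 4)),
            "B": np.tile([[-0.2], [-0.4], [-0.8]], (1, 4)),
            "C": np.tile([[-0.1], [-0.3], [-0.9]], (1, 4)),
        }
        pd_ = _fake_factor_draws(eff)
        expected_day33 = np.var([0.0, -0.8, -0.9], ddof=1)
        assert agefec.among_line_variance(pd_, 33).mean == pytest.approx(expected_day33)

    def test_subset_and_pair_validation(self):
        eff = {m: np.zeros((3, 10)) for m in "AB"}
        pd_ = _fake_factor_draws(eff)
        with pytest.raises(ValueError, match="at least 2"):
            agefec.among_line_variance(pd_, 5, ["A"])
        with pytest.raises(KeyError):
            agefec.among_line_variance(pd_, 5, ["A", "Z"])
        with pytest.raises(ValueError, match="increasing pair"):
            agefec.interval_aging(pd_, "A", (33, 5))


class TestCodingGuards:
    def test_wrong_model_or_coding_rejected(self, mixed_effects_dataset, fast_spec):
        cov = agefec.fit_aging_model(mixed_effects_dataset, "covariate", fast_spec, seed=5)
        with pytest.raises(CodingError):
            agefec.interval_aging(cov, "m1", (5, 33))
        with pytest.raises(CodingError):
            agefec.deleteriousness(cov, "m1")

    def test_zero_draws_give_exactly_zero_s(self):
        names = ["log_ratio[A]", "baseline[A]"]
        draws = np.zeros((2, 10, 2))
        pd_ = PosteriorDraws(draws, names, {"model": "deleteriousness", "mutations": ["A"]})
        est = agefec.deleteriousness(pd_, "A")
        assert est.mean == 0.0 and est.ci_low == 0.0 and est.ci_high == 0.0


class TestReportClassification:
    @staticmethod
    def _poisson_like(theta: dict[str, np.ndarray]) -> PosteriorDraws:
        muts = sorted(theta)
        names = [f"log_ratio[{m}]" for m in muts]
        draws = np.stack([theta[m] for m in muts], axis=1)[None]
        draws = np.concatenate([draws, draws], axis=0)
        return PosteriorDraws(draws, names, {"model": "deleteriousness", "mutations": muts})

    @staticmethod
    def _covariate_like(slopes: dict[str, np.ndarray]) -> PosteriorDraws:
        muts = sorted(slopes)
        names = [f"aging_slope[{m}]" for m in muts]
        draws = np.stack([slopes[m] for m in muts], axis=1)[None]
        draws = np.concatenate([draws, draws], axis=0)
        return PosteriorDraws(
            draws, names, {"model": "aging", "age_coding": "covariate", "mutations": muts}
        )

    def test_union_rule_and_flags(self):
        rng = np.random.default_rng(3)
        n = 400
        harmful = rng.normal(-0.5, 0.05, n)
        null = rng.normal(0.0, 0.2, n)
        first = self._poisson_like({"A": harmful, "B": null})
        summed = self._poisson_like({"A": harmful, "B": rng.normal(-0.3, 0.03, n)})
        slopes = self._covariate_like(
            {"A": rng.normal(-0.02, 0.002, n), "B": rng.normal(0.0, 0.01, n)}
        )
        factor = _fake_factor_draws(
            {
                "A": np.stack([harmful, harmful - 0.3, harmful - 0.8]),
                "B": np.stack([null, null, null]),
            }
        )
        report = build_report(first, factor, slopes, draws_summed=summed)
        a, b = {m.mutation_id: m for m in report.mutations}["A"], {
            m.mutation_id: m for m in report.mutations
        }["B"]
        assert a.deleterious and "first-age" in a.deleterious_by
        assert a.aging and a.accelerating
        # B is harmless at day 5 but fires only through the summed test
        assert b.deleterious and b.deleterious_by == ["all-ages-summed"]
        assert not b.aging
        assert report.deleterious_ids == ["A", "B"]
        assert report.aging_ids == ["A"]
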