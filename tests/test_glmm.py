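import warnings

import numpy as np
import pandas as pd
import pytest

import agefec
from agefec.dataset import FecundityDataset
from agefec.glmm import (
    ConvergenceWarning,
    ModelSpec,
    PosteriorDraws,
    gelman_rubin,
    split_rhat,
)


class TestSplitRhat:
    def test_stationary_chain_split_in_half_is_near_one(self):
        rng = np.random.default_rng(0)
        long_run = rng.standard_normal(20_000)
        chains = long_run.reshape(2, 10_000)
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 500)) + np.array([[0.0], [10.0]])
        assert split_rhat(chains) > 3.0

    def test_single_chain_rejected(self):
        draws = np.zeros((1, 100, 2))
        pd_ = PosteriorDraws(draws, ["a", "b"])
        with pytest.raises(ValueError, match="2 chains"):
            gelman_rubin(pd_)

    def test_agrees_with_arviz_variant(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        stationary = rng.standard_normal((4, 2000))
        ours = split_rhat(stationary)
        theirs = float(az.rhat(az.convert_to_dataset(stationary[..., None]))["x"].values[0])
        assert ours == pytest.approx(theirs, abs=0.02)
        # both diagnostics flag clearly separated chains
        bad = stationary + np.arange(4)[:, None] * 5
        assert split_rhat(bad) > 1.5
        assert float(az.rhat(az.convert_to_dataset(bad[..., None]))["x"].values[0]) > 1.5


class TestPosteriorDrawsContainer:
    def _draws(self):
        rng = np.random.default_rng(3)
        return PosteriorDraws(rng.standard_normal((2, 50, 2)), ["a", "b"], {"k": 1})

    def test_bookkeeping_and_lookup(self):
        pd_ = self._draws()
        assert pd_.n_draws == 100
        assert pd_.get("a").shape == (100,)
        with pytest.raises(KeyError):
            pd_.get("missing")

    def test_invariants_enforced(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="unique"):
            PosteriorDraws(rng.standard_normal((2, 5, 2)), ["a", "a"])
        with pytest.raises(ValueError, match="match"):
            PosteriorDraws(rng.standard_normal((2, 5, 2)), ["a"])
        bad = rng.standard_normal((2, 5, 1))
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            PosteriorDraws(bad, ["a"])

    def test_save_load_roundtrip(self, tmp_path):
        pd_ = self._draws()
        path = tmp_path / "draws.npz"
        pd_.save(path)
        again = PosteriorDraws.load(path)
        np.testing.assert_array_equal(pd_.draws, again.draws)
        assert again.parameter_names == pd_.parameter_names
        assert again.parameterization == pd_.parameterization


class TestModelSpec:
    def test_contract_violations_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(chains=1)
        with pytest.raises(ValueError):
            ModelSpec(iterations=100, warmup=100)

    def test_default_draw_count_contract(self):
        spec = ModelSpec()
        assert spec.chains * (spec.iterations - spec.warmup) == 12_000


def _handmade_dataset(rows):
    obs = pd.DataFrame(
        rows, columns=["mutation", "vial", "age_day", "class", "n_females", "eggs"]
    )
    return FecundityDataset.from_frames(obs)


class TestDeleteriousnessModel:
    def test_recovers_known_log_ratio(self, fast_spec):
        cfg = agefec.SimConfig(
            n_mutations=1, vials_per_mutation=(200, 200), delta=np.log(0.8),
            vial_sd=0.0, seed=3,
        )
        ds = agefec.simulate_experiment(cfg)
        pd_ = agefec.fit_deleteriousness_model(ds, "first-age-only", fast_spec, seed=0)
        est = agefec.deleteriousness(pd_, "m1")
        assert est.ci_low < 0.2 < est.ci_high
        assert est.mean == pytest.approx(0.2, abs=0.02)
        assert est.p_mcmc < 0.01

    def test_symmetric_counts_give_zero_effect(self, tiny_spec):
        rows = []
        for v in range(12):
            eggs = 400 + 10 * v
            rows += [("A", str(v), 5, "mut", 25, eggs), ("A", str(v), 5, "wt", 25, eggs)]
        ds = _handmade_dataset(rows)
        pd_ = agefec.fit_deleteriousness_model(ds, "first-age-only", tiny_spec, seed=1)
        assert abs(float(pd_.get("log_ratio[A]").mean())) < 0.02

    def test_poisson_conjugate_limit(self, fast_spec):
        # single group, vague priors: posterior mean of exp(baseline)
        # approaches the sample mean of the wildtype counts
        ds = agefec.simulate_experiment(
            agefec.SimConfig(n_mutations=1, vials_per_mutation=(150, 150),
                             vial_sd=0.0, seed=9)
        )
        pd_ = agefec.fit_deleteriousness_model(ds, "first-age-only", fast_spec, seed=0)
        fitted = np.exp(pd_.get("baseline[m1]")).mean()
        observed = ds.paired_table().query("age_day == 5")["wt_eggs"].mean()
        assert fitted == pytest.approx(observed, rel=0.02)

    def test_summed_ages_equivalent_to_manual_sum(self, tiny_spec):
        ds = agefec.simulate_experiment(
            agefec.SimConfig(n_mutations=2, vials_per_mutation=(5, 5), seed=12)
        )
        pd_ = agefec.fit_deleteriousness_model(ds, "all-ages-summed", tiny_spec, seed=0)
        assert pd_.parameterization["ages_used"] == "all-ages-summed"
        assert pd_.parameterization["incomplete_vials"] == []

    def test_invalid_ages_used_rejected(self, mixed_effects_dataset, tiny_spec):
        with pytest.raises(ValueError, match="ages_used"):
            agefec.fit_deleteriousness_model(mixed_effects_dataset, "day-19", tiny_spec)

    def test_nonconvergence_warns_not_silent(self, tiny_spec):
        ds = agefec.simulate_experiment(
            agefec.SimConfig(n_mutations=1, vials_per_mutation=(4, 4), seed=5)
        )
        strict = ModelSpec(chains=2, iterations=220, warmup=100, rhat_threshold=0.5)
        with pytest.warns(ConvergenceWarning):
            pd_ = agefec.fit_deleteriousness_model(ds, "first-age-only", strict, seed=0)
        assert pd_.parameterization["max_rhat"] > 0.5  # diagnostics still attached


class TestAgingModels:
    def test_covariate_model_recovers_slope(self, fast_spec):
        cfg = agefec.SimConfig(
            n_mutations=1, vials_per_mutation=(150, 150), delta=np.log(0.9),
            beta=-0.02, vial_sd=0.2, seed=17,
        )
        ds = agefec.simulate_experiment(cfg)
        pd_ = agefec.fit_aging_model(ds, "covariate", fast_spec, seed=0)
        est = agefec.aging_coefficient(pd_, "m1")
        assert est.ci_low < -0.02 < est.ci_high
        assert est.p_mcmc < 0.01

    def test_null_slope_interval_covers_zero(self, fast_spec):
        ds = agefec.simulate_null(1, 100, seed=23, include_survival=False)
        pd_ = agefec.fit_aging_model(ds, "covariate", fast_spec, seed=0)
        est = agefec.aging_coefficient(pd_, "m1")
        assert est.ci_low < 0.0 < est.ci_high

    def test_factor_and_covariate_codings_agree(self, mixed_effects_dataset, fast_spec):
        cov = agefec.fit_aging_model(mixed_effects_dataset, "covariate", fast_spec, seed=2)
        fac = agefec.fit_aging_model(mixed_effects_dataset, "factor", fast_spec, seed=2)
        for m in mixed_effects_dataset.mutation_ids:
            slope = agefec.aging_coefficient(cov, m)
            diff = agefec.interval_aging(fac, m, (5, 33))
            # day-33 minus day-5 effect should match slope * 28 days
            se = (diff.ci_high - diff.ci_low) / 3.92
            assert diff.mean == pytest.approx(slope.mean * 28.0, abs=4 * se)

    def test_binomial_conditioning_equivalence(self):
        # paired Poisson counts conditioned on their total are binomial with
        # logit equal to the log rate ratio
        rng = np.random.default_rng(0)
        lam_m, lam_w = 240.0, 300.0
        mut = rng.poisson(lam_m, 40_000)
        wt = rng.poisson(lam_w, 40_000)
        tot = mut + wt
        phat = mut.sum() / tot.sum()
        logit = np.log(phat / (1 - phat))
        assert logit == pytest.approx(np.log(lam_m / lam_w), abs=0.02)

    def test_zero_total_rows_dropped_with_notice(self, tiny_spec):
        rows = []
        for v in range(6):
            for age in (5, 19):
                eggs_m, eggs_w = (0, 0) if (v == 0 and age == 19) else (40, 50)
                rows += [
                    ("A", str(v), age, "mut", 25, eggs_m),
                    ("A", str(v), age, "wt", 25, eggs_w),
                ]
        ds = _handmade_dataset(rows)
        pd_ = agefec.fit_aging_model(ds, "covariate", tiny_spec, seed=0)
        assert pd_.parameterization["dropped_zero_total_rows"] == 1

    def test_single_age_design_rejected(self, tiny_spec):
        rows = [("A", "1", 5, "mut", 25, 10), ("A", "1", 5, "wt", 25, 12),
                ("A", "2", 5, "mut", 25, 11), ("A", "2", 5, "wt", 25, 9)]
        ds = _handmade_dataset(rows)
        with pytest.raises(ValueError, match="2 assay ages"):
            agefec.fit_aging_model(ds, "covariate", tiny_spec)


class TestConvergenceOfStandardRuns:
    def test_fast_fits_reach_acceptable_rhat(self, mixed_effects_dataset, fast_spec):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for fit in (
                agefec.fit_deleteriousness_model(
                    mixed_effects_dataset, "first-age-only", fast_spec, seed=0
                ),
                agefec.fit_aging_model(mixed_effects_dataset, "factor", fast_spec, seed=0),
            ):
                assert fit.parameterization["max_rhat"] < 1.1
                assert fit.n_draws == fast_spec.chains * (
                    fast_spec.iterations - fast_spec.warmup
                )
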