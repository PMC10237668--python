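"""Participant filtering, prior predictive checks, model fits, summaries."""

import numpy as np
import pandas as pd
import pytest

from soprosody import choice_model as cm
from soprosody.errors import CapabilityError, SchemaError
from soprosody.simulate import GenerativeParams, gen_filler_accuracies, gen_responses


@pytest.fixture(scope="module")
def design():
    return gen_responses(40, GenerativeParams(seed=0))


@pytest.fixture(scope="module")
def small_m2_fit():
    params = GenerativeParams(seed=31)
    data = gen_responses(12, params)
    return cm.fit("m2", data, cm.PriorSpec(1.5), n_chains=2,
                  n_iterations=600, n_warmup=250, seed=6)


class TestFilterParticipants:
    def test_printed_distribution_retains_40_of_55(self):
        table = gen_filler_accuracies(seed=0)
        retained = cm.filter_participants(table)
        assert len(table) == 55
        assert retained.size == 40

    def test_all_perfect_all_retained(self):
        table = pd.DataFrame({"participant": [1, 2, 3],
                              "n_fillers": 20, "n_correct": 20})
        assert cm.filter_participants(table).size == 3

    def test_exactly_ten_percent_wrong_is_excluded(self):
        # the failure rule is "10% or more incorrect", so 2/20 wrong fails
        table = pd.DataFrame({"participant": [1, 2],
                              "n_fillers": [20, 20], "n_correct": [18, 19]})
        assert cm.filter_participants(table).tolist() == [2]

    def test_missing_filler_count_is_schema_error(self):
        with pytest.raises(SchemaError):
            cm.filter_participants(pd.DataFrame({"participant": [1],
                                                 "accuracy": [1.0]}))


class TestPriorPredictive:
    def test_narrow_prior_concentrates_at_half(self, design):
        p = cm.prior_predictive("m0", cm.PriorSpec(0.01), design, seed=1)
        assert np.all(np.abs(p - 0.5) < 0.15)
        assert abs(p.mean() - 0.5) < 0.01

    @pytest.mark.parametrize("sd", [1.5, 1.0, 0.5])
    def test_symmetric_priors_center_at_half(self, design, sd):
        p = cm.prior_predictive("m0", cm.PriorSpec(sd), design, seed=2)
        assert abs(p.mean() - 0.5) < 0.03

    def test_moderate_prior_mostly_inside(self, design):
        p = cm.prior_predictive("m0", cm.PriorSpec(0.5), design, seed=3)
        assert np.mean((p > 0.05) & (p < 0.95)) > 0.5

    def test_wide_prior_saturates_trial_probabilities(self, design):
        p = cm.prior_predictive("m0", cm.PriorSpec(10.0), design, seed=4,
                                statistic="trial_probability")
        assert np.mean((p < 0.05) | (p > 0.95)) >= 0.8

    def test_needs_enough_draws(self, design):
        with pytest.raises(ValueError):
            cm.prior_predictive("m0", cm.PriorSpec(1.0), design, n_draws=10)


class TestModelSpecs:
    def test_ladder_is_nested(self):
        chain = [cm.MODELS[m] for m in cm.MODEL_LADDER]
        for lo, hi in zip(chain, chain[1:]):
            assert lo in hi and hi not in lo

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            cm.PriorSpec(-1.0)


class TestFit:
    def test_constant_prosody_is_precondition_error(self):
        data = gen_responses(5, GenerativeParams(seed=1))
        data = data[data["prosody"] == 0]
        with pytest.raises(ValueError):
            cm.fit("m1", data, cm.PriorSpec(1.5), n_chains=1,
                   n_iterations=200, n_warmup=100)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cm.fit("m0", pd.DataFrame(columns=["participant", "pair",
                                               "prosody", "choice"]),
                   cm.PriorSpec(1.5))

    def test_label_invariance_of_population_summaries(self):
        # permuting participant ids must leave population-level posteriors
        # unchanged up to Monte-Carlo error
        params = GenerativeParams(seed=17)
        data = gen_responses(12, params)
        permuted = data.copy()
        ids = np.sort(data["participant"].unique())
        mapping = dict(zip(ids, np.roll(ids, 4)))
        permuted["participant"] = permuted["participant"].map(mapping)
        kw = dict(n_chains=2, n_iterations=800, n_warmup=300)
        fa = cm.fit("m0", data, cm.PriorSpec(1.5), seed=2, **kw)
        fb = cm.fit("m0", permuted, cm.PriorSpec(1.5), seed=2, **kw)
        a = fa.scalar_draws("b_intercept").mean()
        b = fb.scalar_draws("b_intercept").mean()
        assert abs(a - b) < 0.1

    def test_matches_glmer_oracle(self, small_m2_fit, tmp_path):
        # lme4's glmer as an independent GLMM oracle: its ML fixed-effect
        # estimates should track the posterior means on the same data
        import shutil
        import subprocess
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        data = gen_responses(12, GenerativeParams(seed=31))
        csv = tmp_path / "trials.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(choice ~ prosody + (1+prosody||participant) + (1|pair),\n"
            "           data=d, family=binomial)\n"
            "cat(fixef(m)['(Intercept)'], fixef(m)['prosody'], '\\n')\n")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True, timeout=300)
        ref_int, ref_slope = map(float, out.stdout.split())
        assert small_m2_fit.scalar_draws("b_intercept").mean() \
            == pytest.approx(ref_int, abs=0.25)
        assert small_m2_fit.scalar_draws("b_prosody").mean() \
            == pytest.approx(ref_slope, abs=0.25)

    def test_m2_recovery_and_summaries(self, small_m2_fit):
        s = cm.summarize_effects(small_m2_fit)
        # generating values: intercept -1.06, prosody slope 0.39
        assert s.table.loc["b_intercept", "mean"] == pytest.approx(-1.06, abs=0.6)
        assert s.table.loc["b_prosody", "q2.5"] < 0.39 < s.table.loc["b_prosody", "q97.5"]
        assert s.odds is not None and 0 < s.odds < 1
        assert s.odds_ratio == pytest.approx(s.odds_ratio_exp_of_mean, rel=0.25)
        for _, row in s.table.iterrows():
            assert row["q2.5"] <= row["q50"] <= row["q97.5"]
        assert s.participant_slopes is not None
        assert len(s.participant_slopes) == 12
        assert s.participant_slopes["cri95_excludes_zero"].dtype == bool


class TestSummaries:
    def test_participant_slopes_need_m2_or_m3(self, design):
        fr = cm.fit("m1", design.iloc[:240], cm.PriorSpec(1.5), n_chains=1,
                    n_iterations=300, n_warmup=150, seed=1)
        with pytest.raises(CapabilityError):
            fr.participant_slope_draws()

    def test_derived_quantities_match_reporting_conventions(self):
        assert round(cm.reciprocal_odds(0.34), 2) == 2.94
        assert round(cm.slope_variance(0.51), 2) == 0.26
        assert round(cm.slope_variance(0.42), 2) == 0.18

    def test_bf_bands(self):
        assert cm.interpret_bf(12.0) == "strong support"
        assert cm.interpret_bf(5.0) == "weak support"
        assert cm.interpret_bf(2.0) == "very weak support"
        assert cm.interpret_bf(0.05) == "favors the model without the term"


class TestCalibration:
    def test_cri_covers_generating_prosody_coefficient(self):
        # over 20 synthetic replicates at the defaults, the 95% CrI for the
        # prosody coefficient should cover the generating 0.39 in >= 17
        # (binomial tolerance around nominal 95% coverage)
        covered = 0
        for i in range(20):
            params = GenerativeParams(seed=7000 + i)
            data = gen_responses(40, params)
            fr = cm.fit("m3", data, cm.PriorSpec(1.5), n_chains=2,
                        n_iterations=600, n_warmup=250, seed=i,
                        on_fail="ignore")
            draws = fr.scalar_draws("b_prosody")
            lo, hi = np.quantile(draws, [0.025, 0.975])
            covered += lo <= 0.39 <= hi
        assert covered >= 17


class TestBayesFactorPlumbing:
    def test_non_nested_order_rejected(self, small_m2_fit):
        data = gen_responses(12, GenerativeParams(seed=31))
        f0 = cm.fit("m0", data, cm.PriorSpec(1.5), n_chains=2,
                    n_iterations=600, n_warmup=250, seed=8)
        with pytest.raises(ValueError):
            cm.bayes_factor_from_fits(f0, small_m2_fit)

    def test_prior_mismatch_rejected(self, small_m2_fit):
        data = gen_responses(12, GenerativeParams(seed=31))
        f0 = cm.fit("m0", data, cm.PriorSpec(1.0), n_chains=2,
                    n_iterations=600, n_warmup=250, seed=8)
        with pytest.raises(ValueError):
            cm.bayes_factor_from_fits(small_m2_fit, f0)
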