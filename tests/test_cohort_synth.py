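"""Synthetic cohort generation, imputation, design construction, descriptives."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from countsel import (
    DEFAULT_COHORT_SPEC,
    TABLE_FREQUENCIES,
    CohortSpec,
    FamilySpec,
    build_design,
    describe_counts,
    fit_mle,
    impute_simple,
    rate_ratios,
    run_study_pipeline,
    simulate_cohort,
)
from countsel.cohort_synth import _cat, _quant


class TestDescribeCounts:
    def test_published_frequency_table_reproduced(self):
        d = describe_counts(TABLE_FREQUENCIES)
        assert d["mean"] == pytest.approx(1.21, abs=0.01)
        assert d["sd"] == pytest.approx(2.18, abs=0.01)
        assert d["skewness"] == pytest.approx(4.49, abs=0.01)
        assert d["share_pct"][0] == pytest.approx(53.03, abs=0.01)

    def test_agrees_with_expanded_vector_oracle(self):
        freq = {0: 7, 1: 4, 2: 3, 5: 2, 9: 1}
        d = describe_counts(freq)
        y = np.repeat(list(freq), list(freq.values()))
        n = y.size
        assert d["mean"] == pytest.approx(y.mean(), rel=1e-12)
        assert d["sd"] == pytest.approx(y.std(ddof=1), rel=1e-12)
        m2, m3 = ((y - y.mean()) ** 2).mean(), ((y - y.mean()) ** 3).mean()
        g1 = m3 / m2**1.5
        G1 = g1 * np.sqrt(n * (n - 1)) / (n - 2)
        assert d["skewness"] == pytest.approx(G1, rel=1e-12)

    def test_unadjusted_skewness_option(self):
        freq = {0: 7, 1: 4, 2: 3, 5: 2, 9: 1}
        y = np.repeat(list(freq), list(freq.values()))
        m2, m3 = ((y - y.mean()) ** 2).mean(), ((y - y.mean()) ** 3).mean()
        assert describe_counts(freq, adjusted=False)["skewness"] == pytest.approx(
            m3 / m2**1.5, rel=1e-12
        )

    def test_degenerate_and_error_cases(self):
        assert describe_counts({4: 10})["sd"] == 0.0
        with pytest.raises(ValueError):
            describe_counts({})
        with pytest.raises(ValueError):
            describe_counts({0: 2})


class TestSimulateCohort:
    def test_zero_missingness_gives_complete_table(self):
        df = simulate_cohort(replace(DEFAULT_COHORT_SPEC, n=500).without_missingness())
        assert not df.isna().any().any()

    def test_fixed_seed_reproducible(self):
        spec = replace(DEFAULT_COHORT_SPEC, n=300, seed=8)
        pd.testing.assert_frame_equal(simulate_cohort(spec), simulate_cohort(spec))

    def test_missingness_rates_in_configured_range(self):
        spec = replace(DEFAULT_COHORT_SPEC, n=20000, seed=2)
        df = simulate_cohort(spec)
        for cov in spec.covariates:
            rate = df[cov.name].isna().mean()
            assert rate == pytest.approx(cov.missing_rate, abs=0.01)
        assert not df["y"].isna().any()

    def test_moments_converge_with_n(self):
        # theoretical mean of y is E[exp(eta)]; compare small vs large n
        small = simulate_cohort(replace(DEFAULT_COHORT_SPEC, n=1000, seed=3)
                                .without_missingness())
        big = simulate_cohort(replace(DEFAULT_COHORT_SPEC, n=100_000, seed=3)
                              .without_missingness())
        ref = big["y"].mean()
        assert abs(small["y"].mean() - ref) < 0.3
        # zero share in the published ballpark
        assert abs((big["y"] == 0).mean() - 0.53) < 0.05
        assert big["y"].mean() == pytest.approx(1.21, abs=0.15)

    def test_age_onset_correlation_near_target(self):
        df = simulate_cohort(replace(DEFAULT_COHORT_SPEC, n=50000, seed=4)
                             .without_missingness())
        r = np.corrcoef(df["age"], df["age_at_onset"])[0, 1]
        assert r == pytest.approx(0.7, abs=0.05)


class TestImputeSimple:
    def _spec(self):
        return CohortSpec(n=3, covariates=(
            _quant("q", 0, 1),
            _cat("c", ("A", "B"), (0.5, 0.5)),
        ))

    def test_quantitative_mean(self):
        df = pd.DataFrame({"q": [1.0, 2.0, np.nan], "c": ["A", "A", "B"], "y": [0, 1, 2]})
        out = impute_simple(df, self._spec())
        assert out["q"].tolist() == [1.0, 2.0, 1.5]

    def test_qualitative_level_median(self):
        df = pd.DataFrame({"q": [1.0, 2.0, 3.0, 4.0],
                           "c": ["A", "A", "B", np.nan], "y": [0, 1, 2, 0]})
        spec = CohortSpec(n=4, covariates=(
            _quant("q", 0, 1), _cat("c", ("A", "B"), (0.5, 0.5))))
        out = impute_simple(df, spec)
        assert out["c"].tolist() == ["A", "A", "B", "A"]

    def test_non_missing_cells_untouched(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"q": rng.standard_normal(10),
                           "c": ["A", "B"] * 5, "y": rng.poisson(1, 10)})
        df.loc[3, "q"] = np.nan
        out = impute_simple(df, self._spec())
        mask = df["q"].notna()
        np.testing.assert_array_equal(out.loc[mask, "q"].to_numpy(),
                                      df.loc[mask, "q"].to_numpy())

    def test_all_missing_column_rejected(self):
        df = pd.DataFrame({"q": [np.nan, np.nan, np.nan],
                           "c": ["A", "A", "B"], "y": [0, 1, 2]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute_simple(df, self._spec())


class TestBuildDesign:
    def test_three_level_factor_expands_to_two_dummies(self):
        spec = replace(DEFAULT_COHORT_SPEC, n=200, seed=1)
        df = simulate_cohort(spec.without_missingness())
        design, _ = build_design(df, spec, interactions=(), exclusions=())
        township = [c for c in design.columns if c.startswith("residence_township[")]
        assert len(township) == 2
        assert "residence_township[Hamadan]" not in township  # reference level

    def test_column_count_matches_dictionary(self):
        spec = replace(DEFAULT_COHORT_SPEC, n=400, seed=1)
        df = simulate_cohort(spec.without_missingness())
        design, forced = build_design(df, spec, exclusions=())
        mains = sum(1 if c.kind == "quantitative" else len(c.levels) - 1
                    for c in spec.covariates)
        inters = (3 * 1) + (1 * 1) + (1 * 1)  # gender x education/suicide/nonadherence
        assert design.p == mains + inters
        assert set(forced) == {"nonadherence[Yes]", "substance_history[Yes]",
                               "smoking_history[Yes]"}

    def test_perfectly_correlated_pair_triggers_exclusion(self):
        spec = replace(DEFAULT_COHORT_SPEC, n=200, seed=1)
        df = simulate_cohort(spec.without_missingness())
        df["age"] = df["age_at_onset"]  # correlation exactly 1
        design, _ = build_design(df, spec)
        assert "age" not in design.columns
        assert "age_at_onset" in design.columns

    def test_unknown_column_rejected(self):
        spec = replace(DEFAULT_COHORT_SPEC, n=100, seed=1)
        df = simulate_cohort(spec.without_missingness())
        with pytest.raises(KeyError):
            build_design(df, spec, forced_in=("no_such_column",))


class TestRateRatios:
    def test_published_arithmetic(self):
        assert np.exp(0.08) == pytest.approx(1.08, abs=0.01)
        assert np.exp(0.65) == pytest.approx(1.91, abs=0.01)
        assert np.exp(0.54) == pytest.approx(1.71, abs=0.01)

    def test_table_from_fit(self):
        from conftest import make_count_table

        tab = make_count_table(40, n=400, p=2, beta=[0.0], theta=1.0)
        fit = fit_mle(tab, FamilySpec("negbin"))
        rr = rate_ratios(fit)
        assert list(rr.columns) == ["term", "rate_ratio", "ci_low", "ci_high"]
        np.testing.assert_allclose(rr["rate_ratio"], np.exp(fit.estimates()))
        assert np.all(rr["ci_low"] <= rr["rate_ratio"])
        assert np.all(rr["rate_ratio"] <= rr["ci_high"])
        zero = rr[rr.term == "x1"]["rate_ratio"].item()
        assert zero == pytest.approx(1.0, abs=0.25)


@pytest.fixture(scope="module")
def report():
    spec = replace(DEFAULT_COHORT_SPEC, n=413, seed=6)
    return run_study_pipeline(spec, seed=6, folds=5, n_lambda=40,
                              compare_zip=False)


class TestStudyPipeline:
    def test_selection_contains_strongest_effect(self, report):
        # duration of illness carries the largest standardized effect
        assert "duration_illness" in report["selection"]["selected"]

    def test_final_model_reports_conventions(self, report):
        fm = report["final_model"]
        assert fm["theta"] > 0
        assert fm["aic"] == pytest.approx(-2 * fm["loglik"] + 2 * fm["n_params"])
        # forced-in clinical covariates appear even if unselected
        for term in ("nonadherence[Yes]", "substance_history[Yes]",
                     "smoking_history[Yes]"):
            assert term in fm["terms"]

    def test_vuong_block_present(self, report):
        assert set(report["vuong"]["comparator"]) >= {"P-MCP", "NB-full", "P-full"}

    def test_pipeline_deterministic(self, report):
        import json

        spec = replace(DEFAULT_COHORT_SPEC, n=413, seed=6)
        again = run_study_pipeline(spec, seed=6, folds=5, n_lambda=40,
                                   compare_zip=False)
        assert json.dumps(report, sort_keys=True, default=float) == \
            json.dumps(again, sort_keys=True, default=float)
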