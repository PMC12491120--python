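import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.formula.api as smf

from psmadyn.stats import (
    agreement_lme,
    anova_fixed,
    compute_fold_changes,
    concordance_correlation,
    fit_lme,
    fold_change,
    median_iqr,
    pivot_changes,
    summarize_trajectories,
)


class TestFoldChange:
    def test_serum_marker_examples(self):
        # stable patient: 3.4 -> 3.5 ng/mL; strong responder: 59.0 -> 6.9
        assert fold_change(3.4, 3.5) == pytest.approx(2.94, abs=0.005)
        assert fold_change(59.0, 6.9) == pytest.approx(-88.31, abs=0.005)

    def test_identity_is_zero(self):
        assert fold_change(7.7, 7.7) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 5.0)

    @given(b=st.floats(0.1, 1e3), p=st.floats(-99.0, 500.0))
    @settings(max_examples=100, deadline=None)
    def test_roundtrip_property(self, b, p):
        assert fold_change(b, b * (1 + p / 100.0)) == pytest.approx(p, abs=1e-7)


class TestMedianIqr:
    def test_hand_computed_convention(self):
        assert median_iqr([1, 2, 3]) == pytest.approx((2.0, 1.25, 2.75))

    def test_single_value(self):
        assert median_iqr([4.2]) == (4.2, 4.2, 4.2)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])

    def test_matches_sort_based_oracle(self):
        # midpoint plotting positions, checked against an explicit
        # sort-and-interpolate implementation on many small lists
        def oracle(vals, q):
            v = np.sort(np.asarray(vals, float))
            n = v.size
            pos = (np.arange(1, n + 1) - 0.5) / n
            if q <= pos[0]:
                return v[0]
            if q >= pos[-1]:
                return v[-1]
            return float(np.interp(q, pos, v))

        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(1, 13)
            vals = rng.normal(0, 10, n)
            med, q1, q3 = median_iqr(vals)
            assert med == pytest.approx(oracle(vals, 0.5), abs=1e-12)
            assert q1 == pytest.approx(oracle(vals, 0.25), abs=1e-12)
            assert q3 == pytest.approx(oracle(vals, 0.75), abs=1e-12)


def _toy_visits():
    rows = []
    for p, base in (("A", 10.0), ("B", 20.0)):
        for day, mult in ((0, 1.0), (7, 1.1), (28, 0.5)):
            rows.append((p, f"{p}-L1", day, "PSA", base * mult))
    return pd.DataFrame(rows, columns=["patient_id", "lesion_id", "day", "metric", "value"])


class TestFoldChangeTable:
    def test_fold_changes_from_visits(self):
        traj = compute_fold_changes(_toy_visits())
        d28 = traj[traj["day"] == 28]["pct_change"]
        assert np.allclose(d28, -50.0)

    def test_exclusions_are_explicit(self):
        traj = compute_fold_changes(_toy_visits(), exclude_patients=("A",))
        assert set(traj["patient_id"]) == {"B"}

    def test_missing_baseline_rejected(self):
        v = _toy_visits()
        v = v[~((v["patient_id"] == "A") & (v["day"] == 0))]
        with pytest.raises(ValueError, match="baseline"):
            compute_fold_changes(v)


def _synthetic_lme_frame(seed=0, n_groups=12, sigma_u=4.0, sigma_e=2.0,
                         beta=(1.0, 0.5)):
    rng = np.random.default_rng(seed)
    days = np.array([3.0, 7.0, 14.0, 21.0, 28.0])
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, sigma_u)
        for d in days:
            y = beta[0] + beta[1] * d + u + rng.normal(0, sigma_e)
            rows.append((f"G{g}", d, y))
    return pd.DataFrame(rows, columns=["patient_id", "day", "pct_change"])


class TestFitLme:
    def test_exact_fit_data_recovers_ols_closed_form(self):
        # zero-noise polynomial data: estimates equal the generating
        # coefficients to numerical identity
        days = np.array([0.0, 7.0, 14.0, 21.0, 28.0])
        rows = []
        for g in ("A", "B", "C"):
            for d in days:
                rows.append((g, d, -5.63 * d + 1.11 * d**2 - 0.03 * d**3))
        df = pd.DataFrame(rows, columns=["patient_id", "day", "pct_change"])
        fit = fit_lme(df, fixed_terms=("day", "day2", "day3"))
        assert fit.degenerate
        assert fit.params["day"] == pytest.approx(-5.63, abs=1e-8)
        assert fit.params["I(day ** 2)"] == pytest.approx(1.11, abs=1e-8)
        assert fit.params["I(day ** 3)"] == pytest.approx(-0.03, abs=1e-8)
        assert fit.variance_components["residual_var"] == 0.0

    def test_estimates_match_statsmodels_reference(self):
        df = _synthetic_lme_frame()
        fit = fit_lme(df, fixed_terms=("day",))
        ref = smf.mixedlm("pct_change ~ day", df, groups=df["patient_id"]).fit(reml=True)
        assert fit.params["day"] == pytest.approx(ref.fe_params["day"], rel=1e-8)
        assert fit.variance_components["group_var"] == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=1e-6)

    def test_missing_rows_dropped_and_counted(self):
        df = _synthetic_lme_frame()
        df.loc[df.index[:4], "pct_change"] = np.nan
        fit = fit_lme(df, fixed_terms=("day",))
        assert fit.n_dropped == 4
        assert fit.n_obs == len(df) - 4

    def test_singular_design_names_terms(self):
        # only two distinct days cannot identify a cubic
        df = _synthetic_lme_frame()
        df = df[df["day"].isin([7.0, 14.0])]
        with pytest.raises(ValueError, match="collinear"):
            fit_lme(df, fixed_terms=("day", "day2", "day3"))

    def test_ci_brackets_estimate(self):
        fe = fit_lme(_synthetic_lme_frame(), fixed_terms=("day",)).fixed_effects
        assert (fe["ci_low"] <= fe["estimate"]).all()
        assert (fe["estimate"] <= fe["ci_high"]).all()


class TestAnova:
    def test_f_equals_squared_t_for_single_df_terms(self):
        fit = fit_lme(_synthetic_lme_frame(), fixed_terms=("day",))
        an = anova_fixed(fit)
        fe = fit.fixed_effects
        t2 = (fe["estimate"] / fe["se"]) ** 2
        assert np.allclose(an["F"], t2, rtol=1e-12)

    def test_null_term_rejection_rate_near_nominal(self):
        # slope truly zero: ~5% of replicates should reject at alpha = .05
        rejections = 0
        reps = 500
        for r in range(reps):
            df = _synthetic_lme_frame(seed=1000 + r, beta=(1.0, 0.0))
            an = anova_fixed(fit_lme(df, fixed_terms=("day",)))
            rejections += an.loc["day", "p"] < 0.05
        assert 0.03 <= rejections / reps <= 0.07

    def test_degenerate_intercept_infinitely_significant(self):
        rows = [(g, d, 5.0) for g in "ABC" for d in (7.0, 21.0)]
        df = pd.DataFrame(rows, columns=["patient_id", "day", "pct_change"])
        fit = fit_lme(df, fixed_terms=("1",))
        an = anova_fixed(fit)
        assert an.loc["Intercept", "p"] == pytest.approx(0.0, abs=1e-12)


class TestAgreement:
    def _pairs(self, diffs, lesions=None):
        n = len(diffs)
        lesions = lesions or [f"L{i % 4}" for i in range(n)]
        base = np.linspace(-30, 40, n)
        return pd.DataFrame({
            "lesion_id": lesions,
            "bpnd_pct": base,
            "suv_pct": base + np.asarray(diffs, float),
        })

    def test_identical_series_zero_bias_zero_width(self):
        res = agreement_lme(self._pairs(np.zeros(8)))
        assert res.bias == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    def test_constant_offset_recovered_exactly(self):
        res = agreement_lme(self._pairs(np.full(8, 12.5)))
        assert res.bias == pytest.approx(12.5)
        assert res.loa_high - res.loa_low == pytest.approx(0.0, abs=1e-9)

    def test_variance_components_recovered(self):
        # known lesion-level and residual variance: recovered bias and LoA
        # width should match the generating values within Monte-Carlo error
        rng = np.random.default_rng(12)
        sd_lesion, sd_resid, bias = 8.0, 5.0, 25.0
        reps, biases, widths = 200, [], []
        for _ in range(reps):
            rows = []
            for les in range(10):
                u = rng.normal(0, sd_lesion)
                for _v in range(3):
                    rows.append((f"L{les}", 0.0, bias + u + rng.normal(0, sd_resid)))
            df = pd.DataFrame(rows, columns=["lesion_id", "bpnd_pct", "_d"])
            df["suv_pct"] = df["bpnd_pct"] + df["_d"]
            res = agreement_lme(df)
            biases.append(res.bias)
            widths.append(res.loa_high - res.loa_low)
        true_width = 2 * 1.96 * np.hypot(sd_lesion, sd_resid)
        assert np.mean(biases) == pytest.approx(bias, abs=3 * sd_lesion / np.sqrt(10 * reps) * 3)
        assert np.mean(widths) == pytest.approx(true_width, rel=0.08)

    def test_single_lesion_rejected(self):
        with pytest.raises(ValueError):
            agreement_lme(self._pairs(np.zeros(4), lesions=["L0"] * 4))


class TestConcordance:
    def test_perfect_agreement(self):
        y = np.array([1.0, 3.0, -2.0, 4.0, 0.5])
        ccc, est = concordance_correlation(y, y)
        assert ccc == pytest.approx(1.0)

    def test_anticorrelated_is_negative(self):
        y = np.array([1.0, 3.0, -2.0, 4.0, 0.5])
        ccc, _ = concordance_correlation(y, -y + 3.0)
        assert ccc < 0

    def test_matches_published_formula_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 20, 30)
        b = a + 10 + rng.normal(0, 8, 30)
        ccc, est = concordance_correlation(a, b)
        lin = 2 * np.cov(a, b, ddof=1)[0, 1] / (
            np.var(a, ddof=1) + np.var(b, ddof=1) + (a.mean() - b.mean()) ** 2
        )
        assert ccc == pytest.approx(lin, rel=1e-12)
        assert est == "variance-components"

    def test_offset_strictly_degrades_concordance(self):
        y = np.linspace(-20, 20, 12)
        cccs = [concordance_correlation(y, y + off)[0] for off in (0.0, 5.0, 15.0, 40.0)]
        assert np.all(np.diff(cccs) < 0)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_correlation([1.0, 2.0], [1.0, 2.0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            concordance_correlation(np.full(5, 3.0), np.full(5, 3.0))


class TestSummaries:
    def test_permutation_invariance(self):
        traj = compute_fold_changes(_toy_visits())
        a = summarize_trajectories(traj)
        b = summarize_trajectories(traj.sample(frac=1.0, random_state=4))
        pd.testing.assert_frame_equal(a, b)

    def test_pivot_broadcasts_psa_to_lesions(self):
        traj = compute_fold_changes(_toy_visits())
        wide = pivot_changes(traj)
        assert "psa_pct" in wide.columns
        assert len(wide) == traj[traj["metric"] == "PSA"].shape[0]
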