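"""ROI-wise group tests, severity regression, demographics."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import aslreg as ar


def _wide(values, prefix="s"):
    """participants x parcels wide table from a dict parcel -> list."""
    df = pd.DataFrame(values)
    df.index = [f"{prefix}{i}" for i in range(len(df))]
    df.index.name = "participant_id"
    df.columns.name = "parcel"
    return df


class TestROIGroupTTest:
    def test_hand_computed_3v3_toy(self):
        """Pooled two-sample t on {1,2,3} vs {4,5,6} matches the textbook
        formula to 1e-10."""
        a = _wide({1: [1.0, 2.0, 3.0]})
        b = _wide({1: [4.0, 5.0, 6.0]}, prefix="t")
        res = ar.roi_group_ttest(a, b, n_tests=1)[0]
        xa, xb = np.array([1.0, 2, 3]), np.array([4.0, 5, 6])
        sp = np.sqrt((2 * xa.var(ddof=1) + 2 * xb.var(ddof=1)) / 4)
        t_expect = (xa.mean() - xb.mean()) / (sp * np.sqrt(2 / 3))
        assert abs(res.t_statistic - t_expect) < 1e-10
        assert res.df == 4
        assert res.direction == "lower_in_group1"

    def test_swapping_groups_negates_t_preserves_p(self):
        rng = np.random.default_rng(0)
        a = _wide({1: rng.normal(60, 5, 8), 2: rng.normal(55, 5, 8)})
        b = _wide({1: rng.normal(50, 5, 10), 2: rng.normal(55, 5, 10)}, prefix="t")
        fwd = ar.roi_group_ttest(a, b, n_tests=2)
        rev = ar.roi_group_ttest(b, a, n_tests=2)
        for f, r in zip(fwd, rev):
            assert f.t_statistic == pytest.approx(-r.t_statistic)
            assert f.p_raw == pytest.approx(r.p_raw)

    def test_bonferroni_identity(self):
        rng = np.random.default_rng(1)
        a = _wide({i: rng.normal(60, 5, 6) for i in range(1, 6)})
        b = _wide({i: rng.normal(58, 5, 6) for i in range(1, 6)}, prefix="t")
        for res in ar.roi_group_ttest(a, b, n_tests=219):
            assert res.p_bonferroni == pytest.approx(min(1.0, res.p_raw * 219))
            assert res.significant_fwe == (res.p_bonferroni < 0.05)

    def test_welch_option_changes_df(self):
        rng = np.random.default_rng(2)
        a = _wide({1: rng.normal(60, 1, 5)})
        b = _wide({1: rng.normal(60, 15, 30)}, prefix="t")
        pooled = ar.roi_group_ttest(a, b, n_tests=1, equal_var=True)[0]
        welch = ar.roi_group_ttest(a, b, n_tests=1, equal_var=False)[0]
        assert pooled.df == 33
        assert welch.df != pooled.df

    def test_fwer_controlled_under_global_null(self):
        """Over 100 replicate null cohorts with 219 ROIs each, the fraction
        with ANY Bonferroni-significant ROI stays at or below 0.05 + 2*SE."""
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            a = _wide({p: rng.normal(60, 8, 8) for p in range(1, 220)})
            b = _wide({p: rng.normal(60, 8, 8) for p in range(1, 220)}, prefix="t")
            res = ar.roi_group_ttest(a, b, n_tests=219)
            hits += any(r.significant_fwe for r in res)
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert hits / n_rep <= 0.05 + 2 * se

    def test_injected_effects_detected_at_d2(self):
        """Cohen's d = 2 reductions in 5 of 219 parcels, n = 14 vs 50: all
        five flagged, direction lower in the patient group."""
        rng = np.random.default_rng(4)
        sd = 6.0
        injected = {101, 102, 103, 104, 105}
        b = _wide({p: rng.normal(60, sd, 50) for p in range(1, 220)}, prefix="c")
        a = _wide(
            {p: rng.normal(60 - (2 * sd if p in injected else 0), sd, 14)
             for p in range(1, 220)},
            prefix="p",
        )
        res = {r.parcel: r for r in ar.roi_group_ttest(a, b, n_tests=219)}
        for p in injected:
            assert res[p].significant_fwe
            assert res[p].direction == "lower_in_group1"


class TestSeverityRegression:
    def test_noise_free_slope_recovered_exactly(self):
        sev = pd.Series([0.0, 2.0, 4.0, 6.0, 8.0],
                        index=[f"s{i}" for i in range(5)])
        cbf = _wide({1: (70.0 - 2.0 * sev.to_numpy()), 2: np.full(5, 55.0)})
        res = {r.parcel: r for r in ar.severity_regression(cbf, sev)}
        assert abs(res[1].slope - (-2.0)) < 1e-8
        assert abs(res[2].slope) < 1e-8

    def test_participants_without_severity_excluded(self):
        sev = pd.Series([1.0, 2.0, 3.0, np.nan, 4.0],
                        index=[f"s{i}" for i in range(5)])
        cbf = _wide({1: [60.0, 58, 56, 999.0, 54]})
        res = ar.severity_regression(cbf, sev)[0]
        assert abs(res.slope - (-2.0)) < 1e-8  # the 999 row never entered

    def test_zero_severity_variance_rejected(self):
        sev = pd.Series([2.0, 2.0, 2.0], index=["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="variance"):
            ar.severity_regression(_wide({1: [1.0, 2, 3]}), sev)

    def test_slope_recovery_and_null_calibration(self):
        """200 replicates at n = 14, injected slope -2, noise sd 5: the mean
        recovered slope is within 2*SE of -2, and a null parcel is flagged
        (uncorrected p < .05) about 5% of the time."""
        rng = np.random.default_rng(5)
        slopes, null_hits = [], 0
        n_rep = 200
        for _ in range(n_rep):
            sev = np.clip(rng.normal(6.5, 2.5, 14), 0, None)
            while np.var(sev) == 0:  # pragma: no cover
                sev = np.clip(rng.normal(6.5, 2.5, 14), 0, None)
            sev_s = pd.Series(sev, index=[f"s{i}" for i in range(14)])
            cbf = _wide({
                1: 70.0 - 2.0 * sev + rng.normal(0, 5, 14),
                2: 60.0 + rng.normal(0, 5, 14),
            })
            res = {r.parcel: r for r in ar.severity_regression(cbf, sev_s)}
            slopes.append(res[1].slope)
            null_hits += res[2].significant_uncorrected
        se = np.std(slopes, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(slopes) - (-2.0)) < 2 * se
        assert 0.01 <= null_hits / n_rep <= 0.10


class TestDemographics:
    def _manifest(self, n_a=21, n_b=14, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, n in (("tau_like", n_a), ("tdp_like", n_b)):
            for i in range(n):
                rows.append({"participant_id": f"{g}{i}", "group": g,
                             "age": rng.normal(65, 7),
                             "severity": abs(rng.normal(6.5, 2.5)),
                             "sex": "F" if rng.random() < 0.5 else "M"})
        return pd.DataFrame(rows)

    def test_ordinal_df_is_33_for_21_vs_14(self):
        out = ar.compare_demographics(self._manifest(), "tau_like", "tdp_like")
        t_rows = out[out["test"] == "t"]
        assert (t_rows["df"] == 33).all()

    def test_identical_groups_null_results(self):
        m = self._manifest(n_a=10, n_b=10, seed=1)
        m.loc[m["group"] == "tdp_like", ["age", "severity", "sex"]] = (
            m.loc[m["group"] == "tau_like", ["age", "severity", "sex"]].to_numpy()
        )
        out = ar.compare_demographics(m, "tau_like", "tdp_like")
        t_rows = out[out["test"] == "t"]
        assert np.allclose(t_rows["statistic"], 0.0, atol=1e-12)
        chi_rows = out[out["test"] == "chi2"]
        assert (chi_rows["p_value"] > 0.99).all()

    def test_chi_squared_matches_closed_form_2x2(self):
        """Hand-built 2x2 sex table: X^2 = N(ad-bc)^2 / (row/col margins)."""
        rows = (
            [{"participant_id": f"a{i}", "group": "tau_like", "sex": "F"} for i in range(8)]
            + [{"participant_id": f"b{i}", "group": "tau_like", "sex": "M"} for i in range(13)]
            + [{"participant_id": f"c{i}", "group": "tdp_like", "sex": "F"} for i in range(6)]
            + [{"participant_id": f"d{i}", "group": "tdp_like", "sex": "M"} for i in range(8)]
        )
        m = pd.DataFrame(rows)
        out = ar.compare_demographics(m, "tau_like", "tdp_like", ordinal=())
        a, b, c, d = 8, 13, 6, 8
        n = a + b + c + d
        expect = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        chi_row = out[out["test"] == "chi2"].iloc[0]
        assert abs(chi_row["statistic"] - expect) < 1e-9
        assert chi_row["df"] == 1
        assert chi_row["p_value"] == pytest.approx(stats.chi2.sf(expect, 1))
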