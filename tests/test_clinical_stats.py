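"""OLS edge-outcome fits, sex-stratified age correlations, confounder screens."""
import numpy as np
import pandas as pd
import pytest

from painconn import (
    ClinicalTable,
    ConnectivityMatrix,
    ValidationError,
    age_outcome_by_sex,
    confounder_check,
    correlate_edges_with_outcome,
    ols_fit,
)


def brute_force_ols(x, y):
    """Normal equations solved directly."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    A = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
    resid = y - (intercept + slope * x)
    sst = np.sum((y - y.mean()) ** 2)
    return slope, intercept, 1 - np.sum(resid**2) / sst


class TestOlsFit:
    def test_exact_line_recovered(self):
        x = np.arange(10.0)
        fit = ols_fit(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_constant_outcome(self):
        fit = ols_fit(np.arange(5.0), np.full(5, 3.0))
        assert fit.slope == 0.0
        assert fit.r_squared == 0.0

    def test_hand_computed_example(self):
        # normal equations: slope 2, intercept -1/3, SSR=8, SST=26/3 -> R^2=12/13
        fit = ols_fit([0.0, 1.0, 2.0], [0.0, 1.0, 4.0])
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.intercept == pytest.approx(-1 / 3, abs=1e-12)
        assert fit.r_squared == pytest.approx(12 / 13, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(41)
        for _ in range(30):
            x = rng.normal(size=rng.integers(3, 12))
            y = rng.normal(size=x.size)
            if np.ptp(y) == 0:
                continue
            fit = ols_fit(x, y)
            slope, intercept, r2 = brute_force_ols(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_r_squared_invariant_to_x_rescaling(self):
        rng = np.random.default_rng(43)
        x = rng.normal(size=20)
        y = 3 * x + rng.normal(size=20)
        f1 = ols_fit(x, y)
        f2 = ols_fit(10 * x + 5, y)
        assert f2.r_squared == pytest.approx(f1.r_squared, abs=1e-12)
        assert f2.slope == pytest.approx(f1.slope / 10, abs=1e-12)

    def test_constant_predictor_raises(self):
        with pytest.raises(ValidationError, match="degenerate"):
            ols_fit(np.full(5, 2.0), np.arange(5.0))


def _clinical_frame(n_pat=8, n_ctl=4, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pat + n_ctl
    frame = pd.DataFrame(
        {
            "subject_id": [f"p{i}" for i in range(n_pat)] + [f"c{i}" for i in range(n_ctl)],
            "group": ["patient"] * n_pat + ["control"] * n_ctl,
            "age": rng.normal(58, 7, n),
            "sex": np.where(np.arange(n) % 2 == 0, "F", "M"),
            "vas_pct": np.concatenate([rng.normal(17, 30, n_pat), np.full(n_ctl, np.nan)]),
            "womac_pct": np.concatenate([rng.normal(17, 30, n_pat), np.full(n_ctl, np.nan)]),
            "mean_fd": np.abs(rng.normal(0.15, 0.05, n)),
        }
    )
    return frame


class TestEdgeOutcome:
    def _matrices(self, values):
        return [
            ConnectivityMatrix(f"p{i}", np.array([[v]]), "fisher_z")
            for i, v in enumerate(values)
        ]

    def test_noiseless_coupling_recovered(self):
        x = np.linspace(0.1, 0.6, 8)
        frame = _clinical_frame()
        frame.loc[frame["group"] == "patient", "vas_pct"] = 8.71 + 67.87 * x
        fits = correlate_edges_with_outcome(
            self._matrices(x), [(0, 0)], ClinicalTable(frame)
        )
        row = fits.iloc[0]
        assert row["slope"] == pytest.approx(67.87, abs=1e-9)
        assert row["intercept"] == pytest.approx(8.71, abs=1e-9)
        assert row["r_squared"] == pytest.approx(1.0, abs=1e-12)
        assert bool(row["flagged"])

    def test_shuffled_outcome_rarely_flagged(self):
        rng = np.random.default_rng(47)
        n_flagged = 0
        for rep in range(20):
            x = rng.normal(0.3, 0.1, 56)
            frame = _clinical_frame(n_pat=56, n_ctl=3, seed=rep)
            fits = correlate_edges_with_outcome(
                self._matrices(x), [(0, 0)], ClinicalTable(frame)
            )
            n_flagged += int(fits["flagged"].iloc[0])
        assert n_flagged <= 3  # R^2 >= 0.10 is rare under independence at n=56

    def test_low_r2_not_flagged(self):
        x = np.linspace(0, 1, 8)
        frame = _clinical_frame(seed=2)
        fits = correlate_edges_with_outcome(
            self._matrices(x), [(0, 0)], ClinicalTable(frame), r2_threshold=0.999
        )
        assert not fits["flagged"].any()

    def test_missing_outcomes_excluded_with_warning(self):
        x = np.linspace(0.1, 0.6, 8)
        frame = _clinical_frame(seed=3)
        frame.loc[frame["subject_id"] == "p0", "vas_pct"] = np.nan
        with pytest.warns(UserWarning, match="excluded"):
            fits = correlate_edges_with_outcome(
                self._matrices(x), [(0, 0)], ClinicalTable(frame)
            )
        assert fits["n"].iloc[0] == 7
        assert fits["n_excluded"].iloc[0] == 1


class TestAgeOutcome:
    def test_perfect_negative_correlation_in_females(self):
        frame = _clinical_frame(n_pat=10, seed=4)
        mask = (frame["group"] == "patient") & (frame["sex"] == "F")
        frame.loc[mask, "vas_pct"] = -frame.loc[mask, "age"]
        out = age_outcome_by_sex(ClinicalTable(frame))
        assert out["F"]["r"] == pytest.approx(-1.0, abs=1e-12)
        assert out["F"]["p"] < 1e-6

    def test_small_stratum_skipped(self):
        frame = _clinical_frame(n_pat=7, seed=5)
        frame.loc[frame["group"] == "patient", "sex"] = ["F"] * 6 + ["M"]
        with pytest.warns(UserWarning, match="skipped"):
            out = age_outcome_by_sex(ClinicalTable(frame))
        assert "M" not in out
        assert "F" in out

    def test_independent_outcome_gives_moderate_r(self):
        rng = np.random.default_rng(53)
        n_large = 0
        n_strata = 0
        for rep in range(20):
            frame = _clinical_frame(n_pat=60, seed=100 + rep)
            out = age_outcome_by_sex(ClinicalTable(frame))
            n_large += sum(abs(v["r"]) > 0.5 for v in out.values())
            n_strata += len(out)
        assert n_large <= 0.05 * n_strata  # |r| > 0.5 is rare at n=30 per stratum


class TestConfounders:
    def test_identical_groups_pass(self):
        frame = _clinical_frame(n_pat=6, n_ctl=6, seed=6)
        vals = np.array([50.0, 55, 60, 58, 62, 57])
        frame.loc[frame["group"] == "patient", "age"] = vals
        frame.loc[frame["group"] == "control", "age"] = vals
        report = confounder_check(ClinicalTable(frame))
        age_row = report[report["variable"] == "age"].iloc[0]
        assert age_row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert age_row["p_value"] == pytest.approx(1.0, abs=1e-12)

    def test_large_age_shift_detected(self):
        frame = _clinical_frame(n_pat=56, n_ctl=20, seed=7)
        frame.loc[frame["group"] == "patient", "age"] += 20.0
        report = confounder_check(ClinicalTable(frame))
        age_row = report[report["variable"] == "age"].iloc[0]
        assert age_row["p_value"] < 1e-3
        assert not age_row["passes"]

    def test_null_groups_usually_pass(self):
        n_pass = 0
        for rep in range(20):
            frame = _clinical_frame(n_pat=56, n_ctl=20, seed=200 + rep)
            report = confounder_check(ClinicalTable(frame))
            n_pass += int(report[report["variable"] == "age"]["passes"].iloc[0])
        assert n_pass >= 14  # ~90% expected at the 0.1 screen

    def test_empty_group_raises(self):
        frame = _clinical_frame(n_pat=5, n_ctl=0, seed=8)
        with pytest.raises(ValidationError):
            confounder_check(ClinicalTable(frame))

    def test_reports_all_three_confounders(self):
        frame = _clinical_frame(seed=9)
        report = confounder_check(ClinicalTable(frame))
        assert set(report["variable"]) == {"age", "sex", "mean_fd"}
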