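"""Clinical-outcome correlation and group confounder checks.

Edge strengths (on the same scale used for testing) are regressed against
percent-change pain outcomes (VAS, WOMAC) with ordinary least squares;
age-outcome correlations are computed per sex stratum; and age, sex, and mean
framewise displacement are screened for patient/control differences.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ClinicalTable, ConnectivityMatrix
from .errors import ValidationError

__all__ = [
    "OlsFit",
    "ols_fit",
    "correlate_edges_with_outcome",
    "age_outcome_by_sex",
    "confounder_check",
]


@dataclass(frozen=True)
class OlsFit:
    """Simple-regression fit y = intercept + slope * x."""

    slope: float
    intercept: float
    r_squared: float
    n: int


def ols_fit(x: np.ndarray, y: np.ndarray) -> OlsFit:
    """Least-squares line with R^2 = 1 - SSE/SST.

    A constant outcome is reported as slope 0, R^2 = 0 (nothing to explain);
    a constant predictor is a degenerate design and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValidationError("degenerate design: predictor x is constant")
    if np.ptp(y) == 0:
        return OlsFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, n=x.size)
    res = stats.linregress(x, y)
    return OlsFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=x.size,
    )


def correlate_edges_with_outcome(
    patient_matrices: list[ConnectivityMatrix],
    edges: list[tuple[int, int]],
    clinical: ClinicalTable,
    outcome: str = "vas_pct",
    r2_threshold: float = 0.10,
) -> pd.DataFrame:
    """Fit outcome ~ edge strength across patients, one OLS fit per edge.

    Patients with a missing outcome are excluded (a warning reports how
    many). Rows are sorted by R^2 descending; ``flagged`` marks fits with
    R^2 >= ``r2_threshold``.
    """
    pat = clinical.patients().set_index("subject_id")
    if outcome not in pat.columns:
        raise ValidationError(f"unknown outcome column {outcome!r}")
    by_id = {m.subject_id: m for m in patient_matrices}
    missing_ids = [sid for sid in by_id if sid not in pat.index]
    if missing_ids:
        raise ValidationError(f"patients without clinical rows: {sorted(missing_ids)}")

    y_all = pat.loc[list(by_id), outcome].to_numpy(dtype=float)
    keep = ~np.isnan(y_all)
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} patient(s) excluded: missing {outcome}", stacklevel=2
        )
    ids = [sid for sid, k in zip(by_id, keep) if k]
    y = y_all[keep]

    rows = []
    for si, ai in edges:
        x = np.array([by_id[sid].values[si, ai] for sid in ids])
        fit = ols_fit(x, y)
        rows.append(
            {
                "seed_index": si,
                "atlas_index": ai,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "n": fit.n,
                "n_excluded": n_excluded,
                "flagged": fit.r_squared >= r2_threshold,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "seed_index", "atlas_index", "slope", "intercept",
            "r_squared", "n", "n_excluded", "flagged",
        ],
    )
    return frame.sort_values(
        ["r_squared", "seed_index", "atlas_index"],
        ascending=[False, True, True],
        ignore_index=True,
    )


def age_outcome_by_sex(
    clinical: ClinicalTable, outcome: str = "vas_pct", min_stratum: int = 3
) -> dict[str, dict[str, float]]:
    """Pearson correlation of age with an outcome, per sex stratum.

    Returns ``{sex: {"r": ..., "p": ..., "n": ...}}``; strata with fewer than
    ``min_stratum`` complete observations are skipped with a warning.
    """
    pat = clinical.patients()
    if outcome not in pat.columns:
        raise ValidationError(f"unknown outcome column {outcome!r}")
    out: dict[str, dict[str, float]] = {}
    for sex, sub in pat.groupby("sex"):
        sub = sub.dropna(subset=["age", outcome])
        if len(sub) < min_stratum:
            warnings.warn(f"sex stratum {sex!r} skipped: n={len(sub)}", stacklevel=2)
            continue
        r, p = stats.pearsonr(sub["age"], sub[outcome])
        out[str(sex)] = {"r": float(r), "p": float(p), "n": int(len(sub))}
    return out


def confounder_check(clinical: ClinicalTable, screen_p: float = 0.1) -> pd.DataFrame:
    """Screen age, sex, and mean framewise displacement for group differences.

    Continuous variables use a two-sample Welch t-test; sex uses a chi-square
    test with continuity correction, replaced by Fisher's exact test when any
    expected cell count is below 5. ``passes`` marks p > ``screen_p`` (no
    evidence of confounding at the screening level).
    """
    pat, ctl = clinical.patients(), clinical.controls()
    if len(pat) == 0 or len(ctl) == 0:
        raise ValidationError("both patient and control groups must be non-empty")

    rows = []
    for col in ("age", "mean_fd"):
        a = pat[col].dropna().to_numpy(dtype=float)
        b = ctl[col].dropna().to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"variable": col, "test": "welch_t", "statistic": float(stat),
                     "p_value": float(p)})

    table = pd.crosstab(clinical.frame["group"], clinical.frame["sex"])
    expected = stats.contingency.expected_freq(table.to_numpy())
    if table.shape == (2, 2) and (expected < 5).any():
        stat, p = stats.fisher_exact(table.to_numpy())
        test = "fisher_exact"
    else:
        stat, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=True)
        test = "chi2"
    rows.append({"variable": "sex", "test": test, "statistic": float(stat),
                 "p_value": float(p)})

    frame = pd.DataFrame(rows)
    frame["passes"] = frame["p_value"] > screen_p
    return frame
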