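"""Statistical machinery for the paired-cohort device comparison.

Group contrasts use the two-sample t-test (pooled-variance Student by
default, Welch as an option).  Familial resemblance uses Pearson correlation
within daughter-mother pairs.  Device agreement uses partial correlation
adjusted for age and BMI, computed by the residual method: regress both
measures on the covariates (with intercept) by least squares and correlate
the residuals; the t reference has n - 2 - k degrees of freedom.  An
influential-point sensitivity recomputes after dropping observations whose
standardized value exceeds a threshold (default |z| > 2) on either measure.
All p-values are two-sided; significance is declared at 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .records import StatResult


def standardize(values) -> np.ndarray:
    """z-scores with sample SD (ddof=1): mean 0, SD 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant vector cannot be standardized")
    return (x - x.mean()) / sd


def two_sample_t(mean1=None, sd1=None, n1=None, mean2=None, sd2=None, n2=None,
                 *, x=None, y=None, equal_var: bool = True) -> StatResult:
    """Two-sample t-test from summary statistics or raw vectors.

    Summaries (mean, SD, n per group) suffice to reproduce printed-table
    p-values; raw vectors are accepted via ``x``/``y``.  ``equal_var=True``
    gives the pooled-variance Student test (df = n1 + n2 - 2); False gives
    Welch.
    """
    if x is not None or y is not None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        mean1, sd1, n1 = x.mean(), x.std(ddof=1), x.size
        mean2, sd2, n2 = y.mean(), y.std(ddof=1), y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be >= 0")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return StatResult(0.0, 0.0, n1 + n2 - 2, 1.0, n1 + n2, kind="t")
        raise ValueError("zero variance with unequal means: t undefined")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                     equal_var=equal_var)
    df = n1 + n2 - 2 if equal_var else _welch_df(sd1, n1, sd2, n2)
    return StatResult(mean1 - mean2, float(res.statistic), float(df),
                      float(res.pvalue), int(n1 + n2), kind="t")


def _welch_df(sd1, n1, sd2, n2) -> float:
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    return (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))


def pearson_with_p(x, y) -> StatResult:
    """Pearson r with two-sided p from the t reference (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise ValueError("constant input has no defined correlation")
    r, p = stats.pearsonr(x, y)
    n = x.size
    t = _r_to_t(r, n - 2)
    return StatResult(float(r), t, n - 2, float(p), n, kind="pearson")


def _r_to_t(r: float, df: float) -> float:
    one_minus = 1.0 - r * r
    if one_minus < 1e-15:
        return float(np.sign(r)) * float("inf")
    return float(r * np.sqrt(df / one_minus))


def partial_correlation(x, y, covariates=None) -> StatResult:
    """Partial correlation of x and y given covariates, by the residual method.

    With no covariates this reduces exactly to :func:`pearson_with_p`.
    ``covariates`` is an (n, k) matrix; an intercept is always included in
    the projection.  p is two-sided from t with df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (np.asarray(covariates).size == 0):
        return pearson_with_p(x, y)
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != x.size:
        Z = Z.T
    n, k = Z.shape
    if x.size != y.size or x.size != n:
        raise ValueError("x, y and covariates must have matching length")
    if n < k + 3:
        raise ValueError(f"need n >= k + 3 observations, got n={n}, k={k}")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank-deficient (collinear)")
    coef, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ coef
    rx, ry = resid[:, 0], resid[:, 1]
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("a variable is fully explained by the covariates")
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - k
    t = _r_to_t(r, df)
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return StatResult(r, t, df, p, n, kind="partial")


def sensitivity_excluding_outliers(x, y, covariates=None, threshold: float = 2.0):
    """Partial correlation before and after removing influential points.

    A point is removed when its standardized value exceeds ``threshold`` in
    absolute value on x or on y (z-scores from the full sample; a single
    pass, no iteration).  Returns (full result, reduced result, n_removed).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    full = partial_correlation(x, y, covariates)
    keep = (np.abs(standardize(x)) <= threshold) & (np.abs(standardize(y)) <= threshold)
    n_removed = int((~keep).sum())
    if n_removed == 0:
        return full, full, 0
    Z = None
    if covariates is not None and np.asarray(covariates).size:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != x.size:
            Z = Z.T
        k = Z.shape[1]
        if keep.sum() < k + 3:
            raise ValueError("too few observations remain after outlier removal")
        Z = Z[keep]
    reduced = partial_correlation(x[keep], y[keep], Z)
    return full, reduced, n_removed


# --------------------------------------------------------------------------
# Report tables

#: Measures summarized per group (label, column, daughters available?).
TABLE1_MEASURES = [
    ("BDI from OS, %", "pct_bdi", True),
    ("FGV from DXA, %", "pct_fgv", True),
    ("MBD from mammograms, %", "pct_mbd", False),
    ("FGV from DXA, cm3", "afgv_cm3", True),
    ("MBD from mammograms, cm3", "ambd_cm3", False),
    ("Optical index", "optical_index", True),
    ("Lipid, %", "lipid_pct", True),
    ("Water, %", "water_pct", True),
    ("Collagen, %", "collagen_pct", True),
    ("Total hemoglobin, %", "total_hb_pct", True),
    ("Scattering amplitude, mm-1", "amplitude", True),
    ("Scattering power", "power", True),
]

#: Device-comparison pairs (Table-2 layout): relative then absolute measures.
TABLE2_PAIRS = [
    ("relative", "pct_bdi", "pct_fgv"),
    ("relative", "pct_bdi", "pct_mbd"),
    ("relative", "pct_fgv", "pct_mbd"),
    ("absolute", "pct_collagen_water", "afgv_cm3"),
    ("absolute", "pct_collagen_water", "ambd_cm3"),
    ("absolute", "afgv_cm3", "ambd_cm3"),
]

#: OS components compared against imaging density (Table-3 layout).
TABLE3_OS_COMPONENTS = [
    "water_pct", "lipid_pct", "collagen_pct", "total_hb_pct",
    "amplitude", "power", "optical_index",
]
TABLE3_IMAGING = ["pct_fgv", "pct_mbd"]

#: Imaging columns that exist only for mothers.
_MOTHER_ONLY = {"pct_mbd", "ambd_cm3"}


def _complete(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    sub = df[cols].apply(pd.to_numeric, errors="coerce")
    return sub.dropna()


def _pair_frame(measures: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Wide per-pair frame: one row per pair_id with <col>_daughter/_mother."""
    merged = measures.merge(covariates, on="participant_id", validate="1:1")
    wide = merged.pivot(index="pair_id", columns="group")
    wide.columns = [f"{c}_{g}" for c, g in wide.columns]
    return wide


def build_report(measures: pd.DataFrame, covariates: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Assemble the three analysis tables from a measures and covariate table.

    ``measures``: per participant, the density indices plus fitted
    composition columns.  ``covariates``: participant_id, pair_id, group
    (daughter|mother), age, bmi.  Missing data are handled complete-case per
    comparison; comparisons unavailable for a group (mammography in
    daughters) are reported as NA.  Returns {'table1', 'table2', 'table3'}.
    """
    required = {"participant_id", "pair_id", "group", "age", "bmi"}
    if missing := required - set(covariates.columns):
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    if "participant_id" not in measures.columns:
        raise ValueError("measures table missing column: participant_id")
    df = measures.merge(covariates, on="participant_id", validate="1:1")
    df = df.sort_values("participant_id").reset_index(drop=True)
    daughters = df[df["group"] == "daughter"]
    mothers = df[df["group"] == "mother"]
    wide = _pair_frame(measures, covariates)

    t1_rows = []
    for label, col, in_daughters in TABLE1_MEASURES:
        if col not in df.columns:
            continue
        d = daughters[col].dropna() if in_daughters else pd.Series(dtype=float)
        m = mothers[col].dropna()
        row = {"measure": label,
               "daughters_mean": d.mean() if len(d) else np.nan,
               "daughters_sd": d.std(ddof=1) if len(d) > 1 else np.nan,
               "daughters_n": len(d),
               "mothers_mean": m.mean() if len(m) else np.nan,
               "mothers_sd": m.std(ddof=1) if len(m) > 1 else np.nan,
               "mothers_n": len(m),
               "ttest_p": np.nan, "pair_r": np.nan, "pair_r_p": np.nan}
        if len(d) >= 2 and len(m) >= 2 and (d.std(ddof=1) > 0 or m.std(ddof=1) > 0):
            row["ttest_p"] = two_sample_t(x=d.to_numpy(), y=m.to_numpy()).p_two_sided
        pd_cols = [f"{col}_daughter", f"{col}_mother"]
        if all(c in wide.columns for c in pd_cols):
            pairs = wide[pd_cols].dropna()
            if len(pairs) >= 3:
                pr = pearson_with_p(pairs.iloc[:, 0], pairs.iloc[:, 1])
                row["pair_r"], row["pair_r_p"] = pr.estimate, pr.p_two_sided
        t1_rows.append(row)
    table1 = pd.DataFrame(t1_rows)

    def partial_row(sub: pd.DataFrame, xcol: str, ycol: str) -> tuple[float, float, int]:
        cc = _complete(sub, [xcol, ycol, "age", "bmi"])
        if len(cc) < 5:
            return np.nan, np.nan, len(cc)
        res = partial_correlation(standardize(cc[xcol]), standardize(cc[ycol]),
                                  cc[["age", "bmi"]].to_numpy())
        return res.estimate, res.p_two_sided, res.n

    t2_rows = []
    for kind, xcol, ycol in TABLE2_PAIRS:
        row = {"kind": kind, "measure_x": xcol, "measure_y": ycol}
        for grp, sub in (("daughters", daughters), ("mothers", mothers)):
            if grp == "daughters" and (xcol in _MOTHER_ONLY or ycol in _MOTHER_ONLY):
                row[f"{grp}_r_partial"] = np.nan
                row[f"{grp}_p"] = np.nan
                row[f"{grp}_n"] = 0
                continue
            r, p, n = partial_row(sub, xcol, ycol)
            row[f"{grp}_r_partial"], row[f"{grp}_p"], row[f"{grp}_n"] = r, p, n
        t2_rows.append(row)
    table2 = pd.DataFrame(t2_rows)

    t3_rows = []
    for comp_col in TABLE3_OS_COMPONENTS:
        if comp_col not in df.columns:
            continue
        for img in TABLE3_IMAGING:
            row = {"os_component": comp_col, "imaging_measure": img}
            for grp, sub in (("daughters", daughters), ("mothers", mothers)):
                if grp == "daughters" and img in _MOTHER_ONLY:
                    row[f"{grp}_r_partial"] = np.nan
                    row[f"{grp}_p"] = np.nan
                    row[f"{grp}_n"] = 0
                    continue
                r, p, n = partial_row(sub, comp_col, img)
                row[f"{grp}_r_partial"], row[f"{grp}_p"], row[f"{grp}_n"] = r, p, n
            t3_rows.append(row)
    table3 = pd.DataFrame(t3_rows)

    return {"table1": table1, "table2": table2, "table3": table3}
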