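"""Cohort statistics: paired-eye mixed models, correlations, contingency.

Two eyes of one patient are correlated, so group comparisons use a
two-level random-intercept model

    y_ij = b0 + b1 * group_ij + u_i + e_ij,   u_i ~ N(0, s_u^2),  e_ij ~ N(0, s_e^2)

with patient ``i`` as the random effect. The model is fitted by restricted
maximum likelihood, profiling the single variance ratio
``lambda = s_u^2 / s_e^2`` by one-dimensional bounded optimization; the
fixed-effect p-value is a Wald z test on ``b1``. Structure-function
associations are Pearson correlations; the GA x VA split is a Pearson
chi-square on the 2x2 table without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ezquant.errors import DomainError
from ezquant.va_function import VAGroups, classify_va_change, classify_va_group

# (metric column base, region) rows of the comparison/correlation tables,
# in presentation order
TABLE_METRICS: list[tuple[str, str]] = [
    ("partial_attenuation_pct", "central_subfield"),
    ("partial_attenuation_pct", "central_macula"),
    ("partial_attenuation_pct", "panmacular"),
    ("total_attenuation_pct", "central_subfield"),
    ("total_attenuation_pct", "central_macula"),
    ("total_attenuation_pct", "panmacular"),
    ("mean_ez_rpe_um", "central_subfield"),
    ("mean_ez_rpe_um", "central_macula"),
    ("ez_rpe_volume_mm3", "panmacular"),
    ("ez_intensity_index", "central_subfield"),
    ("ez_intensity_index", "central_macula"),
    ("ez_intensity_index", "panmacular"),
]


def metric_column(base: str, region: str) -> str:
    if base == "ez_rpe_volume_mm3":
        return "ez_rpe_volume_mm3"
    return f"{base}_{region}"


@dataclass(frozen=True)
class LMMResult:
    fixed_effect_estimate: float
    standard_error: float
    p_value: float
    random_intercept_variance: float
    residual_variance: float
    n_eyes: int
    n_patients: int
    converged: bool = True


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    statistic: float
    p_value: float


def proportion_pct(k: int, n: int, decimals: int = 1) -> float:
    """Percentage ``100*k/n`` rounded half away from zero to ``decimals``."""
    if n <= 0:
        raise DomainError("denominator must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100) * Decimal(k) / Decimal(n)).quantize(q, ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# random-intercept LMM (REML, profiled variance ratio)


@dataclass
class _GroupedDesign:
    """Per-patient sufficient statistics for the profiled REML criterion.

    With block covariance ``V_i = I + lam * J`` the Woodbury identity gives
    ``V_i^{-1} = I - c_i J`` with ``c_i = lam / (1 + lam * m_i)``, so every
    GLS cross-product reduces to totals minus c-weighted group-sum outer
    products — no per-block linear algebra is needed.
    """

    n: int
    p: int
    XtX: np.ndarray   # (p, p) total cross-product
    Xty: np.ndarray   # (p,)
    yty: float
    sx: np.ndarray    # (G, p) per-group column sums of X
    sy: np.ndarray    # (G,) per-group sums of y
    m: np.ndarray     # (G,) group sizes

    @classmethod
    def build(cls, y: np.ndarray, X: np.ndarray, pid: np.ndarray) -> "_GroupedDesign":
        order = np.argsort(pid, kind="stable")
        y, X, pid = y[order], X[order], pid[order]
        starts = np.flatnonzero(np.r_[True, pid[1:] != pid[:-1]])
        m = np.diff(np.r_[starts, len(pid)])
        sx = np.add.reduceat(X, starts, axis=0)
        sy = np.add.reduceat(y, starts)
        return cls(n=len(y), p=X.shape[1], XtX=X.T @ X, Xty=X.T @ y,
                   yty=float(y @ y), sx=sx, sy=sy, m=m.astype(np.float64))

    def pieces(self, lam: float) -> tuple[np.ndarray, np.ndarray, float, float]:
        c = lam / (1.0 + lam * self.m)
        XtVX = self.XtX - np.einsum("g,gi,gj->ij", c, self.sx, self.sx)
        XtVy = self.Xty - (c * self.sy) @ self.sx
        ytVy = self.yty - float(c @ (self.sy ** 2))
        logdetV = float(np.log1p(lam * self.m).sum())
        return XtVX, XtVy, ytVy, logdetV


def _neg_reml(log_lam: float, d: _GroupedDesign) -> float:
    lam = np.exp(log_lam)
    XtVX, XtVy, ytVy, logdetV = d.pieces(lam)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = ytVy - 2 * beta @ XtVy + beta @ XtVX @ beta
    rss = max(rss, 1e-300)
    sigma_e2 = rss / (d.n - d.p)
    sign, logdetXtVX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    return 0.5 * (logdetV + (d.n - d.p) * np.log(sigma_e2) + logdetXtVX)


def fit_random_intercept_lmm(outcome, group, patient,
                             groups_labels: tuple = (0, 1)) -> LMMResult:
    """Fit ``y = b0 + b1*group + u_patient + e`` by REML.

    Parameters
    ----------
    outcome:
        Per-eye metric values.
    group:
        Binary label per eye (0/1, bool, or two distinct labels).
    patient:
        Patient identifier per eye; eyes sharing it share a random intercept.

    Returns
    -------
    LMMResult
        ``fixed_effect_estimate`` is the adjusted group mean difference;
        ``p_value`` comes from a Wald z test on it.
    """
    y = np.asarray(outcome, dtype=np.float64)
    g_raw = np.asarray(group)
    pid = np.asarray(patient)
    if y.ndim != 1 or y.shape != g_raw.shape or y.shape != pid.shape:
        raise DomainError("outcome, group and patient must be equal-length 1-D")
    if not np.isfinite(y).all():
        raise DomainError("outcome contains non-finite values")
    levels = pd.unique(g_raw)
    if len(levels) != 2:
        raise DomainError(f"group must have exactly 2 levels, got {len(levels)}")
    if set(levels.tolist()) == {0, 1} or set(levels.tolist()) == {False, True}:
        g = g_raw.astype(float)
    else:
        order = [l for l in groups_labels if l in levels] or sorted(levels.tolist(), key=str)
        g = (g_raw == order[1]).astype(float)
    for lv in (0.0, 1.0):
        if len(np.unique(pid[g == lv])) < 2:
            raise DomainError("need >= 2 patients per group")

    X = np.column_stack([np.ones_like(y), g])
    design = _GroupedDesign.build(y, X, pid)
    n, p = design.n, design.p

    res = optimize.minimize_scalar(
        _neg_reml, bounds=(np.log(1e-8), np.log(1e8)), method="bounded",
        args=(design,), options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    # the boundary lam -> 0 (pure OLS) can beat the interior optimum
    if _neg_reml(np.log(1e-12), design) < res.fun:
        lam = 0.0
    converged = bool(res.success)

    XtVX, XtVy, ytVy, _ = design.pieces(lam)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(ytVy - 2 * beta @ XtVy + beta @ XtVX @ beta, 0.0)
    sigma_e2 = rss / (n - p)
    cov = sigma_e2 * np.linalg.inv(XtVX)
    se = float(np.sqrt(cov[1, 1]))
    z = beta[1] / se if se > 0 else np.inf
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    p_value = max(p_value, np.finfo(float).tiny)
    return LMMResult(
        fixed_effect_estimate=float(beta[1]),
        standard_error=se,
        p_value=p_value,
        random_intercept_variance=float(lam * sigma_e2),
        residual_variance=float(sigma_e2),
        n_eyes=int(n),
        n_patients=len(design.m),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# correlation and contingency


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson r with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D")
    if x.size < 3:
        raise DomainError("need n >= 3 for a p-value")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DomainError("zero variance in x or y")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), p_value=float(p), n=int(x.size))


def chi_square_2x2(table, fisher: bool = False) -> ContingencyResult:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table.

    With ``fisher=True`` returns Fisher's exact test instead (the odds-ratio
    statistic with its exact p).
    """
    t = np.asarray(table, dtype=np.float64)
    if t.shape != (2, 2) or (t < 0).any():
        raise DomainError("table must be 2x2 with non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DomainError("zero marginal in the 2x2 table")
    if fisher:
        odds, p = stats.fisher_exact(t)
        return ContingencyResult(table=t, statistic=float(odds), p_value=float(p))
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return ContingencyResult(table=t, statistic=float(chi2), p_value=float(p))


# ---------------------------------------------------------------------------
# report builders


STRATA = ("all", "foveal_ga", "no_ga")


def _stratum_filter(df: pd.DataFrame, stratum: str) -> pd.DataFrame:
    if stratum == "all":
        return df
    if stratum == "foveal_ga":
        return df[df["ga_status"] == "foveal"]
    if stratum == "no_ga":
        return df[df["ga_status"] == "none"]
    raise DomainError(f"unknown stratum {stratum!r}")


def build_group_comparison_table(df: pd.DataFrame, stratum: str = "all",
                                 groups: VAGroups = VAGroups(),
                                 year: int = 0) -> pd.DataFrame:
    """Excellent-vs-worse VA comparison of every metric in one stratum.

    ``df`` is a tidy per-(eye, visit) frame holding the cohort columns
    (patient_id, eye_id, year, va_letters, ga_status, ...) plus the flat
    metric columns of :meth:`EyeMetrics.to_row`. Intermediate-acuity eyes
    are excluded; p-values come from the random-intercept model. Rows where
    a group is empty are flagged instead of raising.
    """
    base = _stratum_filter(df[df["year"] == year], stratum).copy()
    base["va_group"] = base["va_letters"].map(lambda l: classify_va_group(l, groups))
    sub = base[base["va_group"].isin(["excellent", "worse"])]
    rows = []
    for metric, region in TABLE_METRICS:
        col = metric_column(metric, region)
        exc = sub[sub["va_group"] == "excellent"][col].dropna()
        wor = sub[sub["va_group"] == "worse"][col].dropna()
        row = {
            "stratum": stratum, "metric": metric, "region": region,
            "mean_excellent": exc.mean() if len(exc) else np.nan,
            "mean_worse": wor.mean() if len(wor) else np.nan,
            "n_excellent": len(exc), "n_worse": len(wor),
            "p_value": np.nan, "flag": "",
        }
        if len(exc) == 0 or len(wor) == 0:
            row["flag"] = "empty_group"
        else:
            valid = sub.dropna(subset=[col])
            try:
                fit = fit_random_intercept_lmm(
                    valid[col].to_numpy(),
                    (valid["va_group"] == "worse").to_numpy(),
                    valid["patient_id"].to_numpy())
                row["p_value"] = fit.p_value
            except DomainError:
                row["flag"] = "unfittable"
        rows.append(row)
    return pd.DataFrame(rows)


def build_correlation_table(df: pd.DataFrame, stratum: str = "all",
                            year: int = 0) -> pd.DataFrame:
    """Pearson correlation of VA letters with every metric in one stratum.

    Uses all eyes of the stratum (no acuity-subgroup exclusion)."""
    base = _stratum_filter(df[df["year"] == year], stratum)
    rows = []
    for metric, region in TABLE_METRICS:
        col = metric_column(metric, region)
        valid = base.dropna(subset=[col])
        row = {"stratum": stratum, "metric": metric, "region": region,
               "r": np.nan, "p_value": np.nan, "n": len(valid), "flag": ""}
        try:
            res = pearson_correlation(valid[col].to_numpy(),
                                      valid["va_letters"].to_numpy())
            row.update(r=res.r, p_value=res.p_value)
        except DomainError:
            row["flag"] = "degenerate"
        rows.append(row)
    return pd.DataFrame(rows)


def _paired_visits(df: pd.DataFrame, year0: int, year1: int) -> pd.DataFrame:
    y0 = df[df["year"] == year0].set_index("eye_id")
    y1 = df[df["year"] == year1].set_index("eye_id")
    common = y0.index.intersection(y1.index)
    merged = y0.loc[common].join(y1.loc[common][["va_letters"]], rsuffix="_y5")
    return merged.reset_index()


def build_longitudinal_table(df: pd.DataFrame, year0: int = 0, year1: int = 5,
                             restrict_excellent_baseline: bool = False,
                             groups: VAGroups = VAGroups()) -> pd.DataFrame:
    """Baseline metric means by visual-acuity change group.

    Default grouping: eyes losing >= 2 lines between the two visits vs eyes
    worsening by less than one line (improvement included). With
    ``restrict_excellent_baseline`` the comparison conditions on excellent
    baseline acuity: "worsened" eyes fall to worse acuity by the second
    visit, "stable" eyes keep excellent acuity. Eyes missing the second
    visit are excluded.
    """
    paired = _paired_visits(df, year0, year1)
    if restrict_excellent_baseline:
        paired = paired[paired["va_letters"].map(
            lambda l: classify_va_group(l, groups)) == "excellent"]
        grp5 = paired["va_letters_y5"].map(lambda l: classify_va_group(l, groups))
        labels = pd.Series(np.where(grp5 == "worse", "worsened",
                           np.where(grp5 == "excellent", "stable", "intermediate")),
                           index=paired.index)
        worse_label, stable_label = "worsened", "stable"
    else:
        labels = paired.apply(
            lambda r: classify_va_change(r["va_letters"], r["va_letters_y5"], groups),
            axis=1) if len(paired) else pd.Series(dtype=object)
        worse_label, stable_label = "loss_ge_2_lines", "stable_le_1_line"
    paired = paired.assign(change_group=labels)
    sub = paired[paired["change_group"].isin([worse_label, stable_label])]
    rows = []
    for metric, region in TABLE_METRICS:
        col = metric_column(metric, region)
        wor = sub[sub["change_group"] == worse_label][col].dropna()
        sta = sub[sub["change_group"] == stable_label][col].dropna()
        row = {
            "metric": metric, "region": region,
            "mean_worsened": wor.mean() if len(wor) else np.nan,
            "mean_stable": sta.mean() if len(sta) else np.nan,
            "n_worsened": len(wor), "n_stable": len(sta),
            "p_value": np.nan, "flag": "",
        }
        if len(wor) == 0 or len(sta) == 0:
            row["flag"] = "empty_group"
        else:
            valid = sub.dropna(subset=[col])
            try:
                fit = fit_random_intercept_lmm(
                    valid[col].to_numpy(),
                    (valid["change_group"] == worse_label).to_numpy(),
                    valid["patient_id"].to_numpy())
                row["p_value"] = fit.p_value
            except DomainError:
                row["flag"] = "unfittable"
        rows.append(row)
    return pd.DataFrame(rows)


def ga_va_contingency(df: pd.DataFrame, year: int = 0,
                      groups: VAGroups = VAGroups()) -> ContingencyResult:
    """2x2 foveal-GA x acuity-group contingency at one visit.

    Rows: foveal GA / no GA; columns: excellent / worse acuity.
    """
    base = df[df["year"] == year]
    grp = base["va_letters"].map(lambda l: classify_va_group(l, groups))
    tab = np.array([
        [int(((base["ga_status"] == "foveal") & (grp == "excellent")).sum()),
         int(((base["ga_status"] == "foveal") & (grp == "worse")).sum())],
        [int(((base["ga_status"] == "none") & (grp == "excellent")).sum()),
         int(((base["ga_status"] == "none") & (grp == "worse")).sum())],
    ])
    return chi_square_2x2(tab)
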