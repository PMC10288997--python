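"""Case-control statistics for biomarker cohorts.

Implements the comparison machinery used on per-eye metric tables:
two-sample t-tests (from raw samples or from printed summary
statistics), covariate-adjusted logistic regression fitted by
iteratively reweighted least squares with Wald odds-ratio confidence
intervals, and three-category sector significance maps thresholded at
p <= 0.001 and p <= 0.05.

The default t-test variant is Welch (unequal variances,
Welch-Satterthwaite degrees of freedom); the pooled-variance Student
form is available.  Predictors are z-scored before the logistic fit by
default so odds ratios are per standard deviation — without
standardization a predictor spanning ~1e5 raw units produces the
degenerate-looking OR = 1.000 (1.000-1.000).
No multiple-testing correction is applied by default; an optional
Benjamini-Hochberg flag adjusts the p-values fed to the significance
categories.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

# ---------------------------------------------------------------------------
# t-tests

@dataclass
class GroupComparisonResult:
    metric: str
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int
    t: float
    df: float
    p: float
    variant: str
    degenerate: bool = False


def t_test_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: Literal["welch", "pooled"] = "welch",
    metric: str = "",
) -> GroupComparisonResult:
    """Two-sample t-test from group summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        equal = mean1 == mean2
        return GroupComparisonResult(
            metric, mean1, sd1, n1, mean2, sd2, n2,
            t=0.0 if equal else math.inf,
            df=float(n1 + n2 - 2),
            p=1.0 if equal else 0.0,
            variant=variant,
            degenerate=not equal,
        )
    v1, v2 = sd1**2, sd2**2
    if variant == "welch":
        se2 = v1 / n1 + v2 / n2
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    elif variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = float(n1 + n2 - 2)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    t = (mean1 - mean2) / math.sqrt(se2)
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupComparisonResult(metric, mean1, sd1, n1, mean2, sd2, n2, t, df, float(p), variant)


def t_test_samples(
    x1: Sequence[float],
    x2: Sequence[float],
    variant: Literal["welch", "pooled"] = "welch",
    metric: str = "",
) -> GroupComparisonResult:
    """Two-sample t-test from raw samples (ddof = 1 SDs)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("need at least 2 observations per group")
    return t_test_summary(
        float(x1.mean()), float(x1.std(ddof=1)), x1.size,
        float(x2.mean()), float(x2.std(ddof=1)), x2.size,
        variant=variant, metric=metric,
    )


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)

@dataclass
class LogisticResult:
    metric: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    coef: float
    se: float
    covariates: tuple[str, ...]
    standardized: bool
    converged: bool = True
    separated: bool = False


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Newton/IRLS maximum-likelihood logistic fit.

    Returns (beta, cov, converged, separated).  Perfect separation shows
    up as diverging coefficients with vanishing score; it is flagged
    rather than raised.
    """
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    separated = False
    cov = np.full((k, k), np.nan)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        H = (X * w[:, None]).T @ X
        H.flat[:: k + 1] += 1e-10
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(step)) > 50:
            step = step * (50 / np.max(np.abs(step)))
        beta = beta + step
        if np.max(np.abs(beta)) > 30:
            separated = True
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        pass
    return beta, cov, converged, separated


def logistic_adjusted(
    table: pd.DataFrame,
    metric: str,
    covariates: Iterable[str] = ("age",),
    outcome: str = "is_case",
    standardized: bool = True,
) -> LogisticResult:
    """Covariate-adjusted logistic regression of case status on one metric.

    ``table[outcome]`` must be 0/1 with both classes present.  With
    ``standardized`` the metric (and continuous covariates) are z-scored,
    so the odds ratio is per 1 SD.  Constant covariates (e.g. gender in a
    single-sex cohort) are dropped with a warning.
    """
    covariates = tuple(covariates)
    y = table[outcome].to_numpy(dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("outcome must contain both classes coded 0/1")
    cols = [metric, *covariates]
    data = table[cols].to_numpy(dtype=float)
    if np.isnan(data).any():
        raise ValueError("missing values in metric or covariates")
    kept_cov = []
    design = [np.ones(len(table))]
    for j, name in enumerate(cols):
        col = data[:, j]
        if np.ptp(col) == 0:
            import warnings

            warnings.warn(f"covariate {name!r} is constant; dropped from the fit")
            continue
        if standardized:
            col = (col - col.mean()) / col.std(ddof=1)
        design.append(col)
        if j > 0:
            kept_cov.append(name)
    X = np.column_stack(design)
    beta, cov, converged, separated = _irls_logistic(X, y)
    b = beta[1]
    se = math.sqrt(max(cov[1, 1], 0.0)) if np.isfinite(cov[1, 1]) else float("nan")
    if separated or not np.isfinite(se) or se == 0:
        return LogisticResult(
            metric=metric, odds_ratio=math.inf if b > 0 else 0.0,
            ci_low=0.0, ci_high=math.inf, p=float("nan"), coef=b, se=se,
            covariates=tuple(kept_cov), standardized=standardized,
            converged=converged, separated=True,
        )
    z = b / se
    p = 2.0 * sps.norm.sf(abs(z))
    lo, hi = b - 1.959963984540054 * se, b + 1.959963984540054 * se
    return LogisticResult(
        metric=metric, odds_ratio=math.exp(b), ci_low=math.exp(lo), ci_high=math.exp(hi),
        p=float(p), coef=float(b), se=float(se), covariates=tuple(kept_cov),
        standardized=standardized, converged=converged,
    )


# ---------------------------------------------------------------------------
# Significance maps

class SignificanceCategory(str, enum.Enum):
    STRONG = "P<=0.001"  # rendered yellow
    SIGNIFICANT = "P<=0.05"  # rendered red
    NONE = "P>0.05"  # rendered green


def classify_p(p: float, thresholds: tuple[float, float] = (0.001, 0.05)) -> SignificanceCategory:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p <= thresholds[0]:
        return SignificanceCategory.STRONG
    if p <= thresholds[1]:
        return SignificanceCategory.SIGNIFICANT
    return SignificanceCategory.NONE


def significance_map(
    p_values: Mapping[str, float], thresholds: tuple[float, float] = (0.001, 0.05)
) -> dict[str, SignificanceCategory]:
    """Three-category map of per-sector p-values (closed on the boundaries)."""
    return {sector: classify_p(p, thresholds) for sector, p in p_values.items()}


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


# ---------------------------------------------------------------------------
# Cohort driver

_CONTRASTS = {
    "nmosd-vs-hc": ("NMOSD", "HC"),
    "on-vs-hc": ("ON", "HC"),
    "non-on-vs-hc": ("NON_ON", "HC"),
}


@dataclass
class CohortReport:
    contrast: str
    t_tests: pd.DataFrame
    logistic: pd.DataFrame
    sector_categories: Optional[pd.DataFrame]


def run_cohort_analysis(
    table: pd.DataFrame,
    contrast: str = "nmosd-vs-hc",
    covariates: Iterable[str] = ("age",),
    t_variant: Literal["welch", "pooled"] = "welch",
    bh_correction: bool = False,
    thresholds: tuple[float, float] = (0.001, 0.05),
) -> CohortReport:
    """t-test + adjusted logistic per metric column; significance categories
    for any per-sector columns (named ``{plexus}_{sector}_{metric}``).

    ``table`` is tidy, one row per eye, with a ``group`` column.  Metric
    columns are ``{plexus}_{metric}``.
    """
    case_label, control_label = _resolve_contrast(table, contrast)
    cases = table[table["group"] == case_label]
    controls = table[table["group"] == control_label]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError(f"contrast {contrast!r}: empty group "
                         f"({case_label}: {len(cases)}, {control_label}: {len(controls)})")

    id_cols = {"subject", "eye", "group", "age", "bmi", "bcva"}
    metric_cols = [c for c in table.columns if c not in id_cols]
    sector_cols = [c for c in metric_cols if len(c.split("_", 2)) == 3 and c.split("_")[1] in
                   {"SI", "TI", "II", "NI", "SE", "TE", "IE", "NE"}]
    full_cols = [c for c in metric_cols if c not in sector_cols]

    sub = pd.concat([cases, controls], ignore_index=True)
    sub = sub.assign(is_case=(sub["group"] == case_label).astype(int))

    t_rows = []
    logit_rows = []
    for col in full_cols:
        res = t_test_samples(cases[col], controls[col], variant=t_variant, metric=col)
        t_rows.append(
            dict(metric=col, case_mean=res.mean1, case_sd=res.sd1, n_case=res.n1,
                 control_mean=res.mean2, control_sd=res.sd2, n_control=res.n2,
                 t=res.t, df=res.df, p=res.p)
        )
        lr = logistic_adjusted(sub, col, covariates=covariates)
        logit_rows.append(
            dict(metric=col, OR=lr.odds_ratio, ci_low=lr.ci_low, ci_high=lr.ci_high,
                 p=lr.p, converged=lr.converged, separated=lr.separated)
        )
    t_frame = pd.DataFrame(t_rows)
    logit_frame = pd.DataFrame(logit_rows)

    sector_frame = None
    if sector_cols:
        rows = []
        ps = []
        for col in sector_cols:
            res = t_test_samples(cases[col], controls[col], variant=t_variant, metric=col)
            ps.append(res.p)
        ps = np.asarray(ps)
        shown = benjamini_hochberg(ps) if bh_correction else ps
        for col, p_raw, p_use in zip(sector_cols, ps, shown):
            plexus, sector, metric = col.split("_", 2)
            rows.append(
                dict(plexus=plexus, sector=sector, metric=metric, p=p_raw,
                     category=classify_p(float(p_use), thresholds).value)
            )
        sector_frame = pd.DataFrame(rows)
    return CohortReport(contrast=contrast, t_tests=t_frame, logistic=logit_frame,
                        sector_categories=sector_frame)


def _resolve_contrast(table: pd.DataFrame, contrast: str) -> tuple[str, str]:
    if contrast not in _CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; options: {sorted(_CONTRASTS)}")
    case, control = _CONTRASTS[contrast]
    present = set(table["group"].unique())
    if case == "NMOSD" and "NMOSD" not in present:
        # an ON/non-ON table still supports the pooled contrast
        if {"ON", "NON_ON"} & present:
            return case, control
    return case, control


_CATEGORY_COLORS = {
    "P<=0.001": "#f5d515",
    "P<=0.05": "#d62728",
    "P>0.05": "#2ca02c",
}


def render_significance_grid(sector_frame: pd.DataFrame, path: str) -> None:
    """Three-color per-sector significance grid (metric rows x sector columns),
    one panel per plexus."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    order = ["SI", "TI", "II", "NI", "SE", "TE", "IE", "NE"]
    plexuses = sorted(sector_frame["plexus"].unique())
    fig, axes = plt.subplots(1, len(plexuses), figsize=(4 * len(plexuses), 3), squeeze=False)
    cmap = ListedColormap([_CATEGORY_COLORS[k] for k in ("P>0.05", "P<=0.05", "P<=0.001")])
    code = {"P>0.05": 0, "P<=0.05": 1, "P<=0.001": 2}
    for ax, plexus in zip(axes[0], plexuses):
        block = sector_frame[sector_frame["plexus"] == plexus]
        metrics = sorted(block["metric"].unique())
        img = np.zeros((len(metrics), len(order)))
        for i, m in enumerate(metrics):
            for j, s in enumerate(order):
                sel = block[(block["metric"] == m) & (block["sector"] == s)]
                if len(sel):
                    img[i, j] = code[sel["category"].iloc[0]]
        ax.imshow(img, cmap=cmap, vmin=0, vmax=2, aspect="auto")
        ax.set_xticks(range(len(order)), order)
        ax.set_yticks(range(len(metrics)), metrics)
        ax.set_title(plexus)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
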