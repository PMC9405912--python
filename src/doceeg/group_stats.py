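"""Step-1 biomarker screening: between-group and mixed-design statistics.

Scalar qEEG measures are compared between groups with a one-way ANOVA
(or ANCOVA when a covariate such as age is supplied). Connectivity
measures, which carry a five-level within-subject ROI structure, go
through a split-plot (mixed) model: the between-subjects stratum is an
OLS (AN)COVA on subject means; the within-subject stratum tests ROI and
ROI x group with Greenhouse–Geisser-corrected degrees of freedom.
Planned contrasts use Student t-tests with bootstrap p-values, and
effect sizes are partial eta squared and Cohen's d.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core import ConfigurationError


@dataclass
class StatResult:
    effect_name: str
    statistic: float  # F or t
    df: tuple[float, float]
    p_value: float
    partial_eta_sq: float | None = None
    cohens_d: float | None = None
    gg_epsilon: float | None = None
    bootstrap_p: float | None = None

    def as_dict(self) -> dict:
        return {
            "effect": self.effect_name,
            "statistic": round(float(self.statistic), 4),
            "df": [round(float(d), 3) for d in self.df],
            "p_value": round(float(self.p_value), 5),
            "partial_eta_sq": None if self.partial_eta_sq is None
            else round(float(self.partial_eta_sq), 4),
            "cohens_d": None if self.cohens_d is None
            else round(float(self.cohens_d), 4),
            "gg_epsilon": None if self.gg_epsilon is None
            else round(float(self.gg_epsilon), 4),
            "bootstrap_p": None if self.bootstrap_p is None
            else round(float(self.bootstrap_p), 5),
        }


# ---------------------------------------------------------------------------
# summary-statistic helpers (desk-scale reproductions)
# ---------------------------------------------------------------------------

def pooled_t_from_summary(m1: float, se1: float, n1: int,
                          m2: float, se2: float, n2: int
                          ) -> tuple[float, int]:
    """Two-sample pooled-variance Student t from group means and SEMs.

    SEMs are converted to SDs (sd = se * sqrt(n)); df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("need n >= 2 per group")
    if se1 <= 0 or se2 <= 0:
        raise ConfigurationError("standard errors must be positive")
    sd1, sd2 = se1 * np.sqrt(n1), se2 * np.sqrt(n2)
    df = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    t = (m1 - m2) / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    return float(t), df


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """eta_p^2 = F*df1 / (F*df1 + df2) for a reported F effect."""
    if df1 <= 0 or df2 <= 0:
        raise ConfigurationError("degrees of freedom must be positive")
    return float(F * df1 / (F * df1 + df2))


def cohens_d_from_summary(m1: float, sd1: float, n1: int,
                          m2: float, sd2: float, n2: int) -> float:
    """Cohen's d with the pooled-SD denominator."""
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    return float((m1 - m2) / sp)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return cohens_d_from_summary(a.mean(), a.std(ddof=1), len(a),
                                 b.mean(), b.std(ddof=1), len(b))


# ---------------------------------------------------------------------------
# bootstrap t-test
# ---------------------------------------------------------------------------

def _pooled_t(a: np.ndarray, b: np.ndarray) -> float:
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 <= 0:
        return 0.0
    return (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))


def bootstrap_ttest(a, b, n_boot: int = 1000,
                    seed: int | None = 0) -> float:
    """Two-sided bootstrap p-value for the pooled two-sample t statistic.

    Groups are recentered to a common null before resampling with
    replacement within each group; p is the add-one-smoothed fraction of
    resampled |t*| at least as large as the observed |t|.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("need >= 2 values per group")
    if n_boot < 100:
        raise ConfigurationError("n_boot must be >= 100")
    t_obs = _pooled_t(a, b)
    a0, b0 = a - a.mean(), b - b.mean()
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    ra, rb = a0[ia], b0[ib]
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * ra.var(axis=1, ddof=1)
           + (n2 - 1) * rb.var(axis=1, ddof=1)) / (n1 + n2 - 2)
    sp2 = np.maximum(sp2, 1e-300)
    t_star = (ra.mean(axis=1) - rb.mean(axis=1)) / np.sqrt(
        sp2 * (1.0 / n1 + 1.0 / n2))
    exceed = int((np.abs(t_star) >= abs(t_obs)).sum())
    return float((exceed + 1) / (n_boot + 1))


def bootstrap_mean_diff_ci(a, b, n_boot: int = 1000, ci: float = 0.95,
                           seed: int | None = 0) -> tuple[float, float]:
    """Percentile bootstrap CI of the group mean difference."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    rng = np.random.default_rng(seed)
    diffs = (a[rng.integers(0, len(a), size=(n_boot, len(a)))].mean(axis=1)
             - b[rng.integers(0, len(b), size=(n_boot, len(b)))].mean(axis=1))
    lo, hi = np.quantile(diffs, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# one-way AN(C)OVA on scalar measures
# ---------------------------------------------------------------------------

def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def one_way_anova(values: np.ndarray, groups: np.ndarray,
                  covariate: np.ndarray | None = None,
                  name: str = "group") -> StatResult:
    """Between-group F test on a scalar measure, optionally age-adjusted.

    With a covariate this is the classic one-way ANCOVA (common slope,
    Type III group effect).
    """
    y = np.asarray(values, float)
    g = np.asarray(groups)
    levels = np.unique(g)
    if len(levels) < 2:
        raise ConfigurationError("between factor needs at least 2 levels")
    n = len(y)
    dummies = np.column_stack([(g == lv).astype(float) for lv in levels[1:]])
    base = [np.ones(n)]
    if covariate is not None:
        base.append(np.asarray(covariate, float))
    X0 = np.column_stack(base)
    X1 = np.column_stack(base + [dummies])
    rss0, rss1 = _rss(y, X0), _rss(y, X1)
    df1 = len(levels) - 1
    df2 = n - X1.shape[1]
    ss_eff = max(rss0 - rss1, 0.0)
    F = (ss_eff / df1) / (rss1 / df2) if rss1 > 0 else np.inf
    p = float(scipy.stats.f.sf(F, df1, df2))
    return StatResult(effect_name=name, statistic=float(F), df=(df1, df2),
                      p_value=p,
                      partial_eta_sq=ss_eff / (ss_eff + rss1)
                      if (ss_eff + rss1) > 0 else 0.0)


# ---------------------------------------------------------------------------
# split-plot mixed model with ROI as the within factor
# ---------------------------------------------------------------------------

def greenhouse_geisser_epsilon(Y: np.ndarray, groups: np.ndarray) -> float:
    """GG sphericity epsilon from the pooled within-group covariance."""
    g = np.asarray(groups)
    k = Y.shape[1]
    S = np.zeros((k, k))
    dof = 0
    for lv in np.unique(g):
        sub = Y[g == lv]
        if len(sub) > 1:
            S += (len(sub) - 1) * np.cov(sub, rowvar=False)
            dof += len(sub) - 1
    S /= max(dof, 1)
    # double-center
    Sc = S - S.mean(axis=0) - S.mean(axis=1)[:, None] + S.mean()
    num = np.trace(Sc) ** 2
    den = (k - 1) * np.sum(Sc * Sc)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def mixed_model(
    roi_values: pd.DataFrame | np.ndarray,
    groups: np.ndarray,
    covariate: np.ndarray | None = None,
) -> dict[str, StatResult]:
    """Split-plot model: between-subject group, within-subject ROI.

    Parameters
    ----------
    roi_values : (n_subjects, n_roi) measure values, one column per ROI.
    groups : between-subject factor (2+ levels).
    covariate : optional per-subject covariate (e.g. age); enters the
        between stratum as an ANCOVA adjustment and the within stratum as
        ROI x covariate regressors.

    Returns effects ``group``, ``roi`` and ``roi_x_group``; the two
    within-subject p-values carry Greenhouse–Geisser-corrected degrees of
    freedom, reported alongside the epsilon used.
    """
    Y = np.asarray(roi_values, float)
    g = np.asarray(groups)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ConfigurationError("need a subjects x ROI matrix (>= 2 ROIs)")
    if np.isnan(Y).any():
        raise ConfigurationError("missing ROI cells are not allowed")
    levels = np.unique(g)
    if len(levels) < 2:
        raise ConfigurationError("between factor needs at least 2 levels")
    for lv in levels:
        if (g == lv).sum() < 2:
            raise ConfigurationError(f"group {lv!r} has fewer than 2 subjects")
    n, k = Y.shape

    # --- between-subjects stratum: AN(C)OVA on subject means -------------
    between = one_way_anova(Y.mean(axis=1), g, covariate=covariate,
                            name="group")

    # --- within-subject stratum ------------------------------------------
    y_long = Y.ravel()  # subject-major
    subj = np.repeat(np.arange(n), k)
    roi = np.tile(np.arange(k), n)
    S = np.column_stack([(subj == i).astype(float) for i in range(n)])
    R = np.column_stack([(roi == j).astype(float) for j in range(1, k)])
    RG = np.column_stack([
        R[:, j] * (g[subj] == lv).astype(float)
        for j in range(k - 1) for lv in levels[1:]
    ])
    extra_cols = 0
    base = [S]
    if covariate is not None:
        cov = np.asarray(covariate, float)
        RC = R * cov[subj][:, None]
        base.append(RC)
        extra_cols = k - 1
    X0 = np.column_stack(base)
    X1 = np.column_stack(base + [R])
    X2 = np.column_stack(base + [R, RG])
    rss0, rss1, rss2 = _rss(y_long, X0), _rss(y_long, X1), _rss(y_long, X2)
    df_roi = k - 1
    df_inter = (k - 1) * (len(levels) - 1)
    df_resid = (n - len(levels)) * (k - 1) - extra_cols
    if df_resid <= 0:
        raise ConfigurationError("not enough subjects for the within stratum")
    ms_resid = rss2 / df_resid
    eps = greenhouse_geisser_epsilon(Y, g)

    def within(name: str, ss: float, df1: int) -> StatResult:
        ss = max(ss, 0.0)
        F = (ss / df1) / ms_resid if ms_resid > 0 else np.inf
        p = float(scipy.stats.f.sf(F, df1 * eps, df_resid * eps))
        return StatResult(effect_name=name, statistic=float(F),
                          df=(df1 * eps, df_resid * eps), p_value=p,
                          partial_eta_sq=ss / (ss + rss2) if (ss + rss2) > 0
                          else 0.0, gg_epsilon=eps)

    return {
        "group": between,
        "roi": within("roi", rss0 - rss1, df_roi),
        "roi_x_group": within("roi_x_group", rss1 - rss2, df_inter),
    }


# ---------------------------------------------------------------------------
# normality and nonparametric checks
# ---------------------------------------------------------------------------

def shapiro_normality(values) -> tuple[float, float]:
    """Shapiro–Wilk W and p; undefined for all-identical samples."""
    x = np.asarray(values, float)
    if len(x) < 3:
        raise ConfigurationError("Shapiro-Wilk needs >= 3 values")
    if np.ptp(x) == 0:
        raise ConfigurationError("Shapiro-Wilk undefined for identical values")
    w, p = scipy.stats.shapiro(x)
    return float(w), float(p)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann–Whitney U (two-sided): exact for small tie-free samples,
    tie-corrected normal approximation otherwise."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 25 and not has_ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# screening report
# ---------------------------------------------------------------------------

#: Scalar qEEG columns screened with one-way AN(C)OVA.
QEEG_MEASURES = ("dominant_freq_hz", "zpsd_delta", "zpsd_theta",
                 "zpsd_alpha", "zpsd_beta", "peen_mean", "amp_mean_uv")
#: Connectivity estimators screened with the mixed (ROI within) model.
CONNECTIVITY_MEASURES = ("wpli", "pcoh", "mi")


def screen_features(
    features: pd.DataFrame,
    factor: str,
    covariate: str | None = None,
    alpha: float = 0.05,
    roi_names: tuple[str, ...] | None = None,
) -> dict:
    """Step-1 biomarker screening over a per-subject feature table.

    ``features`` must hold one row per subject with the qEEG columns, the
    per-ROI connectivity columns (``<estimator>_<roi>``), the grouping
    column ``factor`` and optionally the covariate column. A measure is
    flagged as a biomarker when its group effect is significant at
    ``alpha``.
    """
    from .montage import ROI_NAMES

    roi_names = roi_names or ROI_NAMES
    g = features[factor].to_numpy()
    cov = features[covariate].to_numpy(float) if covariate else None
    report: dict = {"factor": factor, "covariate": covariate, "alpha": alpha,
                    "measures": {}}
    for measure in QEEG_MEASURES:
        if measure not in features:
            continue
        res = one_way_anova(features[measure].to_numpy(float), g,
                            covariate=cov, name=f"{measure}:group")
        report["measures"][measure] = {**res.as_dict(),
                                       "selected": bool(res.p_value < alpha)}
    for est in CONNECTIVITY_MEASURES:
        cols = [f"{est}_{roi}" for roi in roi_names]
        if not all(c in features for c in cols):
            continue
        effects = mixed_model(features[cols], g, covariate=cov)
        entry = {name: r.as_dict() for name, r in effects.items()}
        entry["selected"] = bool(effects["group"].p_value < alpha)
        report["measures"][est] = entry
    report["selected"] = sorted(
        m for m, v in report["measures"].items() if v["selected"]
    )
    return report
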