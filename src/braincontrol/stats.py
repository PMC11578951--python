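"""Cohort statistics: enrolment cascade, demographics, region screening,
and delta-controllability → outcome correlations.

Conventions chosen to match how such cohort tables are typically reported:
two-sample demographic t-tests use pooled variance and report |t|; 2×2
chi-square tests use no continuity correction; the region screen runs an
ANCOVA (metric ~ group + age + sex) for the patient-off vs control contrast
and a paired t-test (on − off) for the medication contrast, and calls a
region "responsive" when both are significant at the (uncorrected) α.  An
optional Benjamini–Hochberg switch exists but is off by default.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict

import numpy as np
import pandas as pd
import scipy.stats

from .atlas import MOTOR_STRUCTURES, split_label
from .control import DeltaProfile

__all__ = [
    "cohort_filter",
    "improvement_rate",
    "pooled_t_from_summary",
    "chisq_2x2",
    "ancova_region",
    "ancova_table",
    "paired_t_region",
    "paired_t_table",
    "select_responsive_regions",
    "correlate_delta_outcome",
]

#: order in which exclusion reasons are applied and tallied
EXCLUSION_ORDER = ("no_surgery", "unilateral_dbs", "rf_lesion", "missing_data")


def cohort_filter(candidates: list) -> tuple[list, "OrderedDict[str, int]"]:
    """Apply the enrolment exclusion cascade.

    Removes candidates whose ``exclusion_reason`` is set, in the canonical
    reason order, and returns the retained list plus a ledger of counts per
    reason (reasons outside the canonical order are appended).
    """
    ledger: OrderedDict[str, int] = OrderedDict((r, 0) for r in EXCLUSION_ORDER)
    kept = []
    for rec in candidates:
        reason = getattr(rec, "exclusion_reason", None)
        if reason is None:
            kept.append(rec)
        else:
            ledger[reason] = ledger.get(reason, 0) + 1
    for r in list(ledger):
        if ledger[r] == 0:
            del ledger[r]
    return kept, ledger


def improvement_rate(pre_off: float, post_off_stim_on: float) -> float:
    """Percent motor improvement: (pre − post) / pre × 100.

    ``pre_off`` is the preoperative medication-off score, ``post`` the
    postoperative medication-off/stimulation-on score; negative improvement
    (worsening) is allowed.
    """
    if pre_off <= 0:
        raise ValueError("preoperative score must be positive")
    return (pre_off - post_off_stim_on) / pre_off * 100.0


def pooled_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from summary statistics.

    Returns (|t|, df, two-sided p) with df = n1 + n2 − 2, matching the
    unsigned convention of demographic tables.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0.0:
        if m1 == m2:
            return 0.0, df, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = abs(m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * scipy.stats.t.sf(t, df)
    return float(t), df, float(p)


def chisq_2x2(counts) -> tuple[float, int, float]:
    """Pearson chi-square on a 2×2 table, no continuity correction."""
    tab = np.asarray(counts)
    if tab.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(tab < 0) or tab.dtype.kind not in "iu" and np.any(tab != tab.astype(int)):
        raise ValueError("counts must be nonnegative integers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError("zero margin: chi-square undefined")
    chi2, p, dof, _ = scipy.stats.chi2_contingency(tab, correction=False)
    return float(chi2), int(dof), float(p)


def ancova_region(
    pd_values: np.ndarray,
    hc_values: np.ndarray,
    ages: np.ndarray,
    sexes: np.ndarray,
) -> tuple[float, float, str]:
    """Group contrast for one region, adjusted for age and sex.

    Fits metric ~ group + age + sex by OLS (statsmodels) over the pooled
    sample; returns the F statistic and p for the group term (1 df, so
    F = t²) and the direction of the adjusted patient − control difference
    as "+"/"−".  ``sexes`` may be strings or 0/1 codes; collinear covariates
    are dropped with a warning.
    """
    import statsmodels.api as sm

    y = np.concatenate([np.asarray(pd_values, float), np.asarray(hc_values, float)])
    group = np.concatenate(
        [np.ones(len(pd_values)), np.zeros(len(hc_values))]
    )
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes)
    if sexes.dtype.kind in "OUS":
        sexes = (sexes == "male").astype(float)
    X = np.column_stack([group, ages, sexes.astype(float)])
    keep = [0]
    for j in (1, 2):
        if np.linalg.matrix_rank(
            np.column_stack([np.ones(len(y)), X[:, keep + [j]]])
        ) > np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X[:, keep]])):
            keep.append(j)
        else:
            warnings.warn("dropping collinear covariate column", stacklevel=2)
    X = sm.add_constant(X[:, keep])
    fit = sm.OLS(y, X).fit()
    t = fit.tvalues[1]
    direction = "+" if fit.params[1] >= 0 else "-"
    return float(t**2), float(fit.pvalues[1]), direction


def ancova_table(
    pd_values: np.ndarray,
    hc_values: np.ndarray,
    ages: np.ndarray,
    sexes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized group ANCOVA across many regions at once.

    ``pd_values`` (n1 × R) and ``hc_values`` (n2 × R) share a region axis;
    returns (F, p, direction) arrays of length R.  F compares the residual
    sums of squares of the full (intercept+group+age+sex) and reduced
    (intercept+age+sex) designs, which equals the squared group-coefficient
    t of the single-region route.
    """
    y = np.vstack([np.asarray(pd_values, float), np.asarray(hc_values, float)])
    n1, n2 = len(pd_values), len(hc_values)
    n = n1 + n2
    group = np.concatenate([np.ones(n1), np.zeros(n2)])
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes)
    if sexes.dtype.kind in "OUS":
        sexes = (sexes == "male").astype(float)
    X_full = np.column_stack([np.ones(n), group, ages, sexes.astype(float)])
    X_red = X_full[:, [0, 2, 3]]

    beta_f, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_f = np.sum((y - X_full @ beta_f) ** 2, axis=0)
    beta_r, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    rss_r = np.sum((y - X_red @ beta_r) ** 2, axis=0)
    df_resid = n - X_full.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (rss_r - rss_f) / (rss_f / df_resid)
    F = np.where(np.isfinite(F), np.maximum(F, 0.0), 0.0)
    p = scipy.stats.f.sf(F, 1, df_resid)
    direction = np.where(beta_f[1] >= 0, "+", "-")
    return F, p, direction


def paired_t_region(on_values: np.ndarray, off_values: np.ndarray) -> tuple[float, float]:
    """Paired t-test of the medication contrast, sign convention on − off."""
    on = np.asarray(on_values, dtype=float)
    off = np.asarray(off_values, dtype=float)
    if on.shape != off.shape:
        raise ValueError("on/off value vectors must be paired")
    if len(on) < 3:
        raise ValueError("need at least 3 pairs")
    d = on - off
    if np.ptp(d) == 0.0:
        if d[0] == 0.0:
            return 0.0, 1.0
        raise ValueError(
            "all paired differences identical and nonzero: t undefined "
            f"(constant difference {d[0]:.6g})"
        )
    t, p = scipy.stats.ttest_rel(on, off)
    return float(t), float(p)


def paired_t_table(on_values: np.ndarray, off_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized paired t across regions (columns)."""
    res = scipy.stats.ttest_rel(on_values, off_values, axis=0)
    return np.asarray(res.statistic), np.asarray(res.pvalue)


def select_responsive_regions(
    ancova_frame: pd.DataFrame,
    paired_frame: pd.DataFrame,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Intersection rule: regions abnormal vs controls AND changed by medication.

    Both inputs need columns (region, hemisphere, metric) plus the test
    columns (group_F, group_p, direction) and (med_t, med_p).  Returns the
    merged table restricted to rows significant in both tests at ``alpha``
    (uncorrected by default; ``fdr=True`` applies Benjamini–Hochberg to each
    test family first).
    """
    merged = ancova_frame.merge(
        paired_frame, on=["region", "hemisphere", "metric"], how="inner"
    )
    gp = merged["group_p"].to_numpy(copy=True)
    mp = merged["med_p"].to_numpy(copy=True)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        gp = multipletests(gp, method="fdr_bh")[1]
        mp = multipletests(mp, method="fdr_bh")[1]
    merged["responsive"] = (gp < alpha) & (mp < alpha)
    return merged[merged["responsive"]].reset_index(drop=True)


def _default_roi_labels(node_labels: list[str]) -> list[str]:
    wanted = {f"{s}_{h}" for s in MOTOR_STRUCTURES for h in ("L", "R")}
    return [lab for lab in node_labels if lab in wanted]


def correlate_delta_outcome(
    deltas: dict[str, DeltaProfile],
    improvements: dict[str, float],
    roi_labels: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of per-region delta controllability with improvement.

    Defaults to the eight a-priori motor structures, both hemispheres, both
    metrics.  Rows with zero-variance deltas are emitted with NaN r and
    ``undefined=True`` rather than dropped.
    """
    common = sorted(set(deltas) & set(improvements))
    if len(common) < 5:
        raise ValueError(
            f"need >= 5 subjects with both sessions and outcomes, got {len(common)}"
        )
    any_profile = deltas[common[0]]
    labels = any_profile.node_labels or []
    if roi_labels is None:
        roi_labels = _default_roi_labels(labels)
    y = np.array([improvements[s] for s in common], dtype=float)
    rows = []
    for lab in roi_labels:
        region, hemi = split_label(lab)
        for metric in ("ac", "mc"):
            x = np.array([deltas[s].value(lab, metric) for s in common])
            if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
                rows.append(
                    dict(region=region, hemisphere=hemi, metric=metric,
                         r=np.nan, p=np.nan, n=len(common),
                         significant=False, undefined=True)
                )
                continue
            r, p = scipy.stats.pearsonr(x, y)
            rows.append(
                dict(region=region, hemisphere=hemi, metric=metric,
                     r=float(r), p=float(p), n=len(common),
                     significant=bool(p < alpha), undefined=False)
            )
    return pd.DataFrame(rows)
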