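"""Case-control inference: covariate adjustment, FDR, effect sizes, ROC.

The discriminability comparison rests on a small set of classical tools:
ANCOVA with age and sex as covariates (adjustment applied only when a
covariate is itself significant), Benjamini-Hochberg q-values within each
measurement family, Cohen's d with pooled standard deviation and a
1,000-resample bootstrap CI, the trapezoidal (Mann-Whitney) ROC area with
DeLong variance, and DeLong's test for two correlated ROC curves measured
on the same subjects.  Utilities for reconstructing effect sizes directly
from printed group means/CIs are included so the published tables can be
re-derived without subject-level data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import reconstruct_sd_from_ci
from .composites import CompositeModel, fit_composite


# ---------------------------------------------------------------------------
# ANCOVA with gated covariate adjustment

@dataclass
class AncovaResult:
    f_group: float
    p: float
    adjusted_values: np.ndarray
    covariates_adjusted: tuple[str, ...]       # which covariates passed the gate
    q: float | None = None


def ancova_adjust(values: np.ndarray, group: np.ndarray, age: np.ndarray,
                  sex: np.ndarray) -> AncovaResult:
    """Linear model value ~ group + age + sex with type-II group F.

    Covariate adjustment (removal of the centred age/sex contribution from
    the values) is applied only for covariates whose own effect is
    significant at unadjusted p < 0.05; the gate decision is recorded.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need n >= 10")
    df = pd.DataFrame({"value": values, "group": np.asarray(group),
                       "age": np.asarray(age, dtype=float),
                       "sex": np.asarray(sex)})
    if df[["value", "age"]].isna().any().any():
        raise ValueError("covariates and values must be complete")
    fit = smf.ols("value ~ C(group) + age + C(sex)", data=df).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("rank-deficient design")
    table = sm.stats.anova_lm(fit, typ=2)
    f_group = float(table.loc["C(group)", "F"])
    p_group = float(table.loc["C(group)", "PR(>F)"])

    gated = []
    adjusted = values.copy()
    if float(table.loc["age", "PR(>F)"]) < 0.05:
        b = float(fit.params["age"])
        adjusted = adjusted - b * (df["age"].to_numpy() - df["age"].mean())
        gated.append("age")
    sex_terms = [p for p in fit.params.index if p.startswith("C(sex)")]
    if float(table.loc["C(sex)", "PR(>F)"]) < 0.05 and sex_terms:
        term = sex_terms[0]
        level = term.split("T.")[1].rstrip("]")
        ind = (df["sex"].to_numpy() == level).astype(float)
        b = float(fit.params[term])
        adjusted = adjusted - b * (ind - ind.mean())
        gated.append("sex")
    return AncovaResult(f_group, p_group, adjusted, tuple(gated))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# effect sizes

@dataclass
class EffectSizeResult:
    d: float
    ci_low: float
    ci_high: float
    n_boot: int


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    return float(np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                         / (na + nb - 2)))


def cohens_d(group_a: np.ndarray, group_b: np.ndarray, n_boot: int = 1000,
             seed: int | None = None) -> EffectSizeResult:
    """Cohen's d = (mean_b - mean_a) / pooled sd, positive when b is higher.

    `group_b` is conventionally the clinical group.  The CI is the
    percentile interval of `n_boot` within-group resampled estimates.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    sd = _pooled_sd(a, b)
    if sd == 0:
        raise ValueError("zero pooled standard deviation")
    d = float((b.mean() - a.mean()) / sd)
    rng = np.random.default_rng(seed)
    ra = a[rng.integers(0, a.size, size=(n_boot, a.size))]
    rb = b[rng.integers(0, b.size, size=(n_boot, b.size))]
    na, nb = a.size, b.size
    var_a = ra.var(axis=1, ddof=1) if na > 1 else np.zeros(n_boot)
    var_b = rb.var(axis=1, ddof=1) if nb > 1 else np.zeros(n_boot)
    psd = np.sqrt(((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2))
    diff = rb.mean(axis=1) - ra.mean(axis=1)
    boots = np.where(psd > 0, diff / np.where(psd > 0, psd, 1.0), 0.0)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return EffectSizeResult(d, float(lo), float(hi), n_boot)


def cohens_d_from_summary(mean_a: float, ci_a: tuple[float, float], n_a: int,
                          mean_b: float, ci_b: tuple[float, float],
                          n_b: int) -> float:
    """Cohen's d from printed means and 95% CIs (sds reconstructed)."""
    sd_a = reconstruct_sd_from_ci(mean_a, ci_a[0], ci_a[1], n_a)
    sd_b = reconstruct_sd_from_ci(mean_b, ci_b[0], ci_b[1], n_b)
    pooled = np.sqrt(((n_a - 1) * sd_a ** 2 + (n_b - 1) * sd_b ** 2)
                     / (n_a + n_b - 2))
    if pooled == 0:
        return 0.0
    return float((mean_b - mean_a) / pooled)


def welch_t_from_summary(mean_a: float, sd_a: float, n_a: int,
                         mean_b: float, sd_b: float, n_b: int
                         ) -> tuple[float, float]:
    """Welch two-sample t statistic and df from group summaries."""
    va, vb = sd_a ** 2 / n_a, sd_b ** 2 / n_b
    t = (mean_b - mean_a) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    return float(t), float(df)


# ---------------------------------------------------------------------------
# ROC machinery (trapezoidal AUC, DeLong variance and paired test)

@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    orientation: str = "case_high"


@dataclass
class DeLongComparison:
    z: float
    p: float
    auc_difference: float
    degenerate: bool = False


def _placements(cases: np.ndarray, controls: np.ndarray
                ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong structural components via midranks (ties get 1/2)."""
    m, n = cases.size, controls.size
    combined = np.concatenate([cases, controls])
    mid = sps.rankdata(combined, method="average")
    rank_cases = sps.rankdata(cases, method="average")
    rank_controls = sps.rankdata(controls, method="average")
    v10 = (mid[:m] - rank_cases) / n              # P(score > random control)
    v01 = 1.0 - (mid[m:] - rank_controls) / m     # P(random case > this control)
    auc = float(v10.mean())
    return auc, v10, v01


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Trapezoidal ROC area with a DeLong-variance 95% CI.

    Equivalent to the Mann-Whitney U statistic with half credit for ties:
    the probability that a randomly chosen case scores above a randomly
    chosen control.  Scores are oriented case-high by convention; areas
    below 0.5 are reported as-is.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    cases, controls = scores[y == 1], scores[y == 0]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    auc, v10, v01 = _placements(cases, controls)
    var = (v10.var(ddof=1) / cases.size if cases.size > 1 else 0.0) \
        + (v01.var(ddof=1) / controls.size if controls.size > 1 else 0.0)
    se = float(np.sqrt(var))
    lo = max(0.0, auc - 1.96 * se)
    hi = min(1.0, auc + 1.96 * se)
    return RocResult(auc, lo, hi, se)


def delong_test(scores_1: np.ndarray, scores_2: np.ndarray,
                labels: np.ndarray) -> DeLongComparison:
    """DeLong's test for two correlated ROC curves on the same subjects."""
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    y = np.asarray(labels).astype(int)
    if s1.size != s2.size or s1.size != y.size:
        raise ValueError("scores must cover the same subjects")
    case, ctrl = y == 1, y == 0
    if not case.any() or not ctrl.any():
        raise ValueError("both classes must be present")
    auc1, v10_1, v01_1 = _placements(s1[case], s1[ctrl])
    auc2, v10_2, v01_2 = _placements(s2[case], s2[ctrl])
    m, n = int(case.sum()), int(ctrl.sum())
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc1 - auc2
    if var_diff <= 0:
        return DeLongComparison(0.0, 1.0, float(diff), degenerate=True)
    z = diff / np.sqrt(var_diff)
    p = 2.0 * sps.norm.sf(abs(z))
    return DeLongComparison(float(z), float(max(p, np.finfo(float).tiny)),
                            float(diff))


def binormal_auc(d: float) -> float:
    """Closed-form AUC for equal-variance normal groups separated by d."""
    return float(sps.norm.cdf(d / np.sqrt(2.0)))


# ---------------------------------------------------------------------------
# correlations

@dataclass
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def correlation_ci(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson r with a Fisher-z 95% confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    r, p = sps.pearsonr(x, y)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(x.size - 3)
    lo, hi = np.tanh(z - 1.96 * se), np.tanh(z + 1.96 * se)
    return CorrelationResult(float(r), float(lo), float(hi), float(p), x.size)


def correlation_ci_from_summary(r: float, n: int) -> tuple[float, float]:
    """Fisher-z CI for a printed correlation at sample size n."""
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    return float(np.tanh(z - 1.96 * se)), float(np.tanh(z + 1.96 * se))


# ---------------------------------------------------------------------------
# combined activity + attention discriminative index

def fit_discriminative_index(features: pd.DataFrame, is_case: np.ndarray,
                             feature_keys: list[str],
                             C: float = 1.0) -> CompositeModel:
    """Ridge-stabilized logistic regression over the combined feature block.

    Unlike the instrument composites (pre-fit on calibration data), this
    index is optimized on the analysis sample itself, mirroring how the
    original combined index was built.
    """
    return fit_composite(features, is_case, feature_keys,
                         name="discriminative_index", C=C)
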