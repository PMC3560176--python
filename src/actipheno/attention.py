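"""Attention-task scoring: core metrics, epoch states, signal detection.

Two continuous-performance tasks are scored here.  The high-target-density
star task ("No-4's": respond to everything except 4-pointed stars) yields
accuracy, omission and commission errors and latency statistics, and its
high response rate supports classifying each 30-second epoch into one of
five attention states (fully attentive, distracted, impulsive, random,
minimally responsive) with a Fisher linear discriminant.  The letter CPT
(respond to everything except 'X', 6 blocks x 3 ISI sub-blocks) yields the
standard 12-measure battery including signal-detection d' and beta,
perseverations (anticipatory RT < 100 ms) and the four RT/RT-SE slopes
across blocks and ISI levels, plus a discriminant-based confidence index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from . import reference_tables as ref
from .composites import CompositeModel, fit_composite

STATES = ("attentive", "distracted", "impulsive", "random", "minimal")
EPOCH_FEATURES = ("hit_rate", "fa_rate", "rt_mean", "rt_sd", "n_responses")
PERSEVERATION_RT_MS = 100.0


@dataclass
class No4sMetrics:
    accuracy: float          # %
    eom: int
    eoc: int
    latency: float           # ms, correct target responses
    latency_sd: float
    latency_cov: float       # % = 100 * sd / mean
    attention_shifts: int | None = None
    pct_time: dict[str, float] | None = None
    latency_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        d = {"no4s_accuracy": self.accuracy, "no4s_eom": self.eom,
             "no4s_eoc": self.eoc, "no4s_latency": self.latency,
             "no4s_latency_sd": self.latency_sd,
             "no4s_latency_cov": self.latency_cov}
        if self.attention_shifts is not None:
            d["no4s_attention_shifts"] = self.attention_shifts
        if self.pct_time is not None:
            for s in STATES:
                d[f"no4s_pct_{s}"] = self.pct_time[s]
        return d


@dataclass
class CptMetrics:
    eom: int
    eoc: int
    rt: float
    rt_se: float
    rt_block_variability: float
    d_prime: float
    beta: float
    perseverations: int
    rt_slope_blocks: float
    rt_se_slope_blocks: float
    rt_slope_isi: float
    rt_se_slope_isi: float
    signal_detection_defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {"cpt_eom": self.eom, "cpt_eoc": self.eoc, "cpt_rt": self.rt,
                "cpt_rt_se": self.rt_se,
                "cpt_rt_block_var": self.rt_block_variability,
                "cpt_dprime": self.d_prime, "cpt_beta": self.beta,
                "cpt_perseverations": self.perseverations,
                "cpt_rt_slope_blocks": self.rt_slope_blocks,
                "cpt_rt_se_slope_blocks": self.rt_se_slope_blocks,
                "cpt_rt_slope_isi": self.rt_slope_isi,
                "cpt_rt_se_slope_isi": self.rt_se_slope_isi}


# ---------------------------------------------------------------------------
# No-4's core scoring

def score_no4s_core(responses: pd.DataFrame) -> No4sMetrics:
    """Accuracy, omissions, commissions and latency statistics.

    `responses` carries one row per trial with `is_target`, `responded`
    and `rt_ms`.  Latency statistics are computed over correct target
    responses only; with no correct responses they are NaN and flagged.
    """
    is_target = responses["is_target"].to_numpy(dtype=bool)
    responded = responses["responded"].to_numpy(dtype=bool)
    rt = responses["rt_ms"].to_numpy(dtype=float)

    eom = int((is_target & ~responded).sum())
    eoc = int((~is_target & responded).sum())
    correct = (is_target & responded) | (~is_target & ~responded)
    accuracy = 100.0 * correct.sum() / len(responses)

    hit_rt = rt[is_target & responded]
    if hit_rt.size == 0:
        return No4sMetrics(accuracy, eom, eoc, np.nan, np.nan, np.nan,
                           latency_defined=False)
    mean = float(hit_rt.mean())
    sd = float(hit_rt.std(ddof=1)) if hit_rt.size > 1 else 0.0
    cov = 100.0 * sd / mean if mean > 0 else np.nan
    return No4sMetrics(accuracy, eom, eoc, mean, sd, cov)


# ---------------------------------------------------------------------------
# 30-s epoch features and the five-state discriminant

def build_epoch_features(responses: pd.DataFrame,
                         epoch_length: float = ref.EPOCH_LENGTH_S
                         ) -> pd.DataFrame:
    """One feature row per 30-s epoch: hit/FA rates, RT mean/sd, responses.

    Trials belong to the epoch containing their onset; a trailing partial
    epoch shorter than half the epoch length is dropped.  Epochs with no
    trials are zero-filled and flagged ``empty``.
    """
    onset = responses["onset_ms"].to_numpy(dtype=float)
    if onset.size == 0:
        raise ValueError("no trials")
    epoch_ms = epoch_length * 1000.0
    session_end = onset.max()
    n_epochs = int(session_end // epoch_ms) + 1
    tail = session_end - (n_epochs - 1) * epoch_ms
    if n_epochs > 1 and tail < epoch_ms / 2.0:
        n_epochs -= 1

    idx = (onset // epoch_ms).astype(int)
    rows = []
    for e in range(n_epochs):
        sub = responses[idx == e]
        if sub.empty:
            rows.append({"epoch": e, "hit_rate": 0.0, "fa_rate": 0.0,
                         "rt_mean": 0.0, "rt_sd": 0.0, "n_responses": 0,
                         "empty": True})
            continue
        tgt = sub["is_target"].to_numpy(dtype=bool)
        resp = sub["responded"].to_numpy(dtype=bool)
        rt = sub["rt_ms"].to_numpy(dtype=float)[resp]
        hit_rate = float(resp[tgt].mean()) if tgt.any() else 0.0
        fa_rate = float(resp[~tgt].mean()) if (~tgt).any() else 0.0
        rows.append({"epoch": e,
                     "hit_rate": hit_rate,
                     "fa_rate": fa_rate,
                     "rt_mean": float(rt.mean()) if rt.size else 0.0,
                     "rt_sd": float(rt.std(ddof=1)) if rt.size > 1 else 0.0,
                     "n_responses": int(resp.sum()),
                     "empty": False})
    return pd.DataFrame(rows)


@dataclass
class StateClassifier:
    """Fisher linear discriminant over epoch features, five states."""

    lda: LinearDiscriminantAnalysis
    feature_names: tuple[str, ...] = EPOCH_FEATURES

    def classify(self, series: pd.DataFrame) -> pd.DataFrame:
        X = series[list(self.feature_names)].to_numpy(dtype=float)
        scores = self.lda.decision_function(X)
        if scores.ndim == 1:
            scores = np.column_stack([-scores, scores])
        # align classifier columns to the canonical priority order so that
        # exact ties resolve attentive > distracted > ... > minimal
        order = [list(self.lda.classes_).index(s) for s in STATES]
        ordered = scores[:, order]
        labels = np.asarray(STATES, dtype=object)[np.argmax(ordered, axis=1)]
        out = series.copy()
        out["state"] = labels
        for j, s in enumerate(STATES):
            out[f"score_{s}"] = ordered[:, j]
        return out


def fit_state_lda(features: pd.DataFrame, labels: np.ndarray) -> StateClassifier:
    """Fit the multiclass Fisher discriminant (pooled within-class covariance)."""
    present = set(np.unique(labels))
    missing = set(STATES) - present
    if missing:
        raise ValueError(f"training data missing states: {sorted(missing)}")
    X = features[list(EPOCH_FEATURES)].to_numpy(dtype=float)
    # uniform priors: the classical Fisher rule scores class separation
    # only, and empirical priors would bias occupancy toward the
    # attentive-heavy training mixture
    lda = LinearDiscriminantAnalysis(solver="svd",
                                     priors=np.full(len(STATES), 0.2))
    lda.fit(X, np.asarray(labels, dtype=object))
    return StateClassifier(lda)


def classify_epochs(classifier: StateClassifier,
                    series: pd.DataFrame) -> pd.DataFrame:
    return classifier.classify(series)


def summarize_states(labels: np.ndarray) -> tuple[dict[str, float], int]:
    """Percent time per state and the count of adjacent-epoch label changes."""
    labels = np.asarray(labels, dtype=object)
    n = labels.size
    if n == 0:
        raise ValueError("no epochs")
    pct = {s: 100.0 * float((labels == s).sum()) / n for s in STATES}
    shifts = int((labels[1:] != labels[:-1]).sum())
    return pct, shifts


def score_no4s_session(responses: pd.DataFrame,
                       classifier: StateClassifier,
                       epoch_length: float = ref.EPOCH_LENGTH_S) -> No4sMetrics:
    """Full No-4's battery: core metrics plus state percentages and shifts."""
    core = score_no4s_core(responses)
    series = build_epoch_features(responses, epoch_length)
    labeled = classifier.classify(series)
    pct, shifts = summarize_states(labeled["state"].to_numpy())
    core.attention_shifts = shifts
    core.pct_time = pct
    return core


# ---------------------------------------------------------------------------
# distraction severity composite

def fit_distraction_composite(features: pd.DataFrame, is_case: np.ndarray,
                              C: float = 1.0) -> CompositeModel:
    """Logistic composite over the 12 No-4's measures (calibration cohort)."""
    return fit_composite(features, is_case, list(ref.NO4S_KEYS),
                         name="distraction_composite", C=C)


def distraction_composite(model: CompositeModel,
                          features: pd.DataFrame) -> np.ndarray:
    if model is None:
        raise ValueError("distraction composite model not fitted")
    return model.score(features)


# ---------------------------------------------------------------------------
# letter CPT scoring

def _clipped_rate(k: int, n: int) -> float:
    """Log-linear guard: rates clipped to [1/(2n), 1 - 1/(2n)]."""
    if n == 0:
        return np.nan
    return float(np.clip(k / n, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n)))


def _slope(xs: np.ndarray, ys: np.ndarray) -> float:
    ok = np.isfinite(ys)
    if ok.sum() < 2:
        return np.nan
    return float(np.polyfit(xs[ok], ys[ok], 1)[0])


def score_cptii(responses: pd.DataFrame) -> CptMetrics:
    """The 12-measure CPT battery from a block/ISI-labelled response log."""
    for col in ("block", "sub_block", "isi_ms"):
        if responses[col].isna().any():
            raise ValueError("CPT stream requires block/sub_block/isi labels")
    is_target = responses["is_target"].to_numpy(dtype=bool)
    responded = responses["responded"].to_numpy(dtype=bool)
    rt = responses["rt_ms"].to_numpy(dtype=float)

    n_targets = int(is_target.sum())
    n_nontargets = int((~is_target).sum())
    hits = int((is_target & responded).sum())
    eom = n_targets - hits
    eoc = int((~is_target & responded).sum())

    correct_rt = rt[is_target & responded]
    defined = correct_rt.size > 0
    rt_mean = float(correct_rt.mean()) if defined else np.nan
    rt_sd = float(correct_rt.std(ddof=1)) if correct_rt.size > 1 else 0.0
    rt_se = rt_sd / np.sqrt(correct_rt.size) if defined else np.nan

    if responded.any():
        hr = _clipped_rate(hits, n_targets)
        far = _clipped_rate(eoc, n_nontargets)
        z_hit, z_fa = norm.ppf(hr), norm.ppf(far)
        d_prime = float(z_hit - z_fa)
        beta = float(np.exp((z_fa ** 2 - z_hit ** 2) / 2.0))
        sd_defined = True
    else:
        d_prime, beta, sd_defined = np.nan, np.nan, False

    perseverations = int((responded & (rt < PERSEVERATION_RT_MS)).sum())

    df = responses.assign(_hit_rt=np.where(is_target & responded, rt, np.nan))
    sub = df.groupby(["block", "sub_block"], sort=True)["_hit_rt"]
    sub_sds = sub.std(ddof=1).to_numpy(dtype=float)
    block_var = float(np.nanstd(sub_sds, ddof=1)) if np.isfinite(sub_sds).sum() > 1 else np.nan

    by_block = df.groupby("block", sort=True)["_hit_rt"]
    blocks = np.asarray(sorted(df["block"].unique()), dtype=float)
    rt_by_block = by_block.mean().to_numpy(dtype=float)
    se_by_block = (by_block.std(ddof=1) / np.sqrt(by_block.count())).to_numpy(dtype=float)

    isi_levels = np.sort(df["isi_ms"].unique())
    level_index = np.arange(1, isi_levels.size + 1, dtype=float)
    by_isi = df.groupby("isi_ms", sort=True)["_hit_rt"]
    rt_by_isi = by_isi.mean().to_numpy(dtype=float)
    se_by_isi = (by_isi.std(ddof=1) / np.sqrt(by_isi.count())).to_numpy(dtype=float)

    return CptMetrics(
        eom=eom, eoc=eoc, rt=rt_mean, rt_se=float(rt_se),
        rt_block_variability=block_var, d_prime=d_prime, beta=beta,
        perseverations=perseverations,
        rt_slope_blocks=_slope(blocks, rt_by_block),
        rt_se_slope_blocks=_slope(blocks, se_by_block),
        rt_slope_isi=_slope(level_index, rt_by_isi),
        rt_se_slope_isi=_slope(level_index, se_by_isi),
        signal_detection_defined=sd_defined,
    )


# ---------------------------------------------------------------------------
# CPT confidence index

CONFIDENCE_PREDICTORS = ("cpt_eom", "sex_code", "age", "cpt_beta",
                         "cpt_rt_slope_isi")


@dataclass
class ConfidenceIndexModel:
    """Two-class discriminant over (omissions, sex, age, beta, RT-ISI slope)."""

    lda: LinearDiscriminantAnalysis
    predictors: tuple[str, ...] = CONFIDENCE_PREDICTORS

    def index(self, features: pd.DataFrame) -> np.ndarray:
        """Posterior probability of the clinical class, scaled to [0, 100]."""
        X = self._design(features)
        case_col = int(np.nonzero(self.lda.classes_ == 1)[0][0])
        return 100.0 * self.lda.predict_proba(X)[:, case_col]

    def _design(self, features: pd.DataFrame) -> np.ndarray:
        df = features.copy()
        if "sex_code" not in df.columns:
            df["sex_code"] = (df["sex"] == "male").astype(float)
        return df[list(self.predictors)].to_numpy(dtype=float)


def fit_confidence_index(features: pd.DataFrame,
                         is_case: np.ndarray) -> ConfidenceIndexModel:
    y = np.asarray(is_case).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("calibration cohort must contain both groups")
    model = ConfidenceIndexModel(LinearDiscriminantAnalysis(solver="svd"))
    model.lda.fit(model._design(features), y)
    return model


def apply_confidence_index(model: ConfidenceIndexModel,
                           features: pd.DataFrame) -> np.ndarray:
    return model.index(features)
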