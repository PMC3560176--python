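"""Synthetic study cohort: subjects, feature tables, trajectories and task streams.

The original subject-level data were never deposited, so every downstream
stage of the pipeline is exercised on synthetic data with the statistical
structure the analysis assumes:

* a summary-level feature generator calibrated to the published per-group
  means and 95% CIs (standard deviations reconstructed from the CI
  half-widths), with a latent severity factor that makes activity and
  attention deficits correlate positively within the ADHD group;
* a mechanistic marker-trajectory generator (bouts of correlated 2-D walk
  separated by heavy-tailed still periods, quantized to the camera
  resolution) for validating the movement-feature extractors;
* stimulus-stream and response generators for the two attention tasks,
  with a hidden five-state attention process evolving over 30-s epochs
  that the epoch classifier must recover.

All generators are deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import reference_tables as ref
from .motion import Trajectory

STATES = ("attentive", "distracted", "impulsive", "random", "minimal")

_Z95 = 1.96   # normal multiplier for the printed 95% CIs


# ---------------------------------------------------------------------------
# summary-statistic reconstruction

def reconstruct_sd_from_ci(mean: float, ci_low: float, ci_high: float,
                           n: int) -> float:
    """Standard deviation implied by a printed mean with 95% CI at size n.

    sd = (ci_high - ci_low) / 2 / 1.96 * sqrt(n).  Uses the normal
    multiplier rather than a t quantile; at n >= 40 the difference is
    negligible and the published intervals are z-style.
    """
    if not (ci_low <= mean <= ci_high):
        raise ValueError("CI bounds must bracket the mean")
    if n < 2:
        raise ValueError("need n >= 2")
    half = (ci_high - ci_low) / 2.0
    return float(half / _Z95 * np.sqrt(n))


# ---------------------------------------------------------------------------
# parameter containers

def _stochastic_round(x: np.ndarray, quantum: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Round to the grid `quantum` with mean-preserving randomization."""
    b = x / quantum
    f = np.floor(b)
    return (f + (rng.random(x.shape) < (b - f))) * quantum


@dataclass(frozen=True)
class MeasureParams:
    """Per-measure sampling parameters for both groups.

    Measures are generated through a Gaussian copula: a standard-normal
    latent value (carrying the factor structure) is mapped through the
    group's moment-matched marginal — identity for `normal`, a gamma
    quantile map for strictly positive skewed measures (`gamma`, optionally
    reflected around `reflect_at` for bounded-above measures such as
    accuracy), or a log-normal map.  Discrete measures are then rounded
    stochastically to their natural grid (counts, 2.5%-time steps), which
    keeps group means exact while reproducing the ties at zero that hold
    the rare-event measures' ROC areas near chance.
    """

    key: str
    domain: str                      # activity | no4s | cptii
    family: str                      # normal | gamma | reflected_gamma | lognormal
    mean_control: float
    sd_control: float
    mean_adhd: float
    sd_adhd: float
    reflect_at: float | None = None
    quantum: float | None = None     # natural grid of a discrete measure

    def __post_init__(self) -> None:
        if self.sd_control < 0 or self.sd_adhd < 0:
            raise ValueError(f"{self.key}: sd must be >= 0")
        if self.family != "normal":
            for m in (self._inner(self.mean_control), self._inner(self.mean_adhd)):
                if m <= 0:
                    raise ValueError(f"{self.key}: skewed family needs a "
                                     "strictly positive mean")

    def _inner(self, mean: float) -> float:
        # scale on which the skewed marginal lives (deficit for reflected)
        return mean if self.reflect_at is None else self.reflect_at - mean

    def _group_moments(self, group: str) -> tuple[float, float]:
        if group == "control":
            return self.mean_control, self.sd_control
        return self.mean_adhd, self.sd_adhd

    def _inner_sample(self, z: np.ndarray, group: str) -> np.ndarray:
        """Marginal value on the inner scale from standard-normal latents."""
        mean, sd = self._group_moments(group)
        if self.family == "normal":
            return mean + sd * z
        m = self._inner(mean)
        if sd == 0:
            return np.full_like(z, m)
        if self.family == "lognormal":
            s2 = np.log1p((sd / m) ** 2)
            return np.exp(np.log(m) - s2 / 2.0 + np.sqrt(s2) * z)
        shape = (m / sd) ** 2
        scale = sd ** 2 / m
        return sps.gamma.ppf(sps.norm.cdf(z), a=shape, scale=scale)

    def transform(self, z: np.ndarray, group: str,
                  rng: np.random.Generator) -> np.ndarray:
        x = self._inner_sample(np.asarray(z, dtype=float), group)
        if self.quantum:
            x = _stochastic_round(x, self.quantum, rng)
        if self.reflect_at is not None:
            x = self.reflect_at - x
        return x

    def latent_effect(self, n_mc: int = 100_000) -> float:
        """Severity-oriented separation: sqrt(2) * probit of the group AUC.

        The AUC between the two marginals (on the inner scale, ties counted
        half) summarizes separation for any family; for two normals it
        reduces to (mean_A - mean_C) / sqrt((sd_A^2 + sd_C^2) / 2).  A fixed
        internal seed keeps the Monte-Carlo branch deterministic.
        """
        mc, sc = self._group_moments("control")
        ma, sa = self._group_moments("adhd")
        if self.family == "normal":
            denom = np.sqrt((sa ** 2 + sc ** 2) / 2.0)
            return float((ma - mc) / denom) if denom > 0 else 0.0
        rng = np.random.default_rng(1234)
        za = rng.standard_normal(n_mc)
        zc = rng.standard_normal(n_mc)
        xa = self._inner_sample(za, "adhd")
        xc = self._inner_sample(zc, "control")
        if self.quantum:
            xa = _stochastic_round(xa, self.quantum, rng)
            xc = _stochastic_round(xc, self.quantum, rng)
        auc = float((xa > xc).mean() + 0.5 * (xa == xc).mean())
        auc = min(max(auc, 1e-6), 1 - 1e-6)
        return float(np.sqrt(2.0) * sps.norm.ppf(auc))


@dataclass
class GroupParameterSet:
    """Sampling parameters for every measure plus cohort-level settings."""

    measures: dict[str, MeasureParams]
    n_adhd: int = ref.N_ADHD
    n_control: int = ref.N_CONTROL
    domain_factor_corr: float = 0.3    # inter-domain correlation via severity
    loading_cap: float = 0.95          # max |loading| on the domain factor
    _loading_cache: dict[str, float] | None = field(
        default=None, init=False, repr=False, compare=False)

    @classmethod
    def from_reference_tables(cls, n_adhd: int = ref.N_ADHD,
                              n_control: int = ref.N_CONTROL,
                              **kw) -> "GroupParameterSet":
        # sd reconstruction always uses the published sample sizes; the
        # n_adhd/n_control arguments only set the synthetic cohort size
        measures = {}
        for m in ref.ALL_MEASURES:
            sd_c = reconstruct_sd_from_ci(*m.control, ref.N_CONTROL)
            sd_a = reconstruct_sd_from_ci(*m.adhd, ref.N_ADHD)
            measures[m.key] = MeasureParams(
                m.key, m.domain, m.family, m.control[0], sd_c,
                m.adhd[0], sd_a, m.reflect_at,
                quantum=ref.MEASURE_QUANTUM.get(m.key))
        return cls(measures, n_adhd=n_adhd, n_control=n_control, **kw)

    def loadings(self) -> dict[str, float]:
        """Factor loading per measure: proportional to its latent effect.

        Within each domain the loading is the latent-scale standardized
        group difference divided by the domain maximum, capped at
        `loading_cap`, so the group shift of every measure is mediated by
        the domain factor and no linear contrast of measures carries
        spurious extra signal.
        """
        if getattr(self, "_loading_cache", None) is not None:
            return self._loading_cache
        effects = {k: p.latent_effect() for k, p in self.measures.items()}
        lam = {}
        for domain in ("activity", "no4s", "cptii"):
            keys = [k for k, p in self.measures.items() if p.domain == domain]
            if not keys:
                continue
            peak = max(abs(effects[k]) for k in keys)
            scale = (self.loading_cap / peak) if peak > 0 else 0.0
            for k in keys:
                lam[k] = effects[k] * scale
        self._loading_cache = lam
        return lam


# ---------------------------------------------------------------------------
# cohort feature table

_SUBTYPE_SPLIT = {"inattentive": ref.N_INATTENTIVE, "combined": 20,
                  "hyperactive_impulsive": 3}

_PCT_STATE_KEYS = ["no4s_pct_attentive", "no4s_pct_distracted",
                   "no4s_pct_impulsive", "no4s_pct_random", "no4s_pct_minimal"]


def _sample_ages(rng: np.random.Generator, n: int, mean: float,
                 sd: float) -> np.ndarray:
    lo, hi = ref.AGE_RANGE
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_feature_cohort(params: GroupParameterSet, seed: int) -> pd.DataFrame:
    """One row per subject: covariates plus all 36 calibrated measures.

    Within each group, a standard-normal latent severity factor and three
    correlated domain factors (activity, No-4's, CPT-II) drive every
    measure through its loading; group mean differences enter through the
    per-group calibrated distributions, so sample means converge to the
    published means as n grows.  Identical seeds reproduce the table
    bit-for-bit.
    """
    expected = {m.key for m in ref.ALL_MEASURES}
    missing = sorted(expected - set(params.measures))
    if missing:
        raise ValueError(f"missing measure parameterization: {missing}")

    rng = np.random.default_rng(seed)
    lam = params.loadings()
    rho = params.domain_factor_corr
    rows = {}
    groups = [("control", params.n_control), ("ADHD", params.n_adhd)]
    n_total = params.n_adhd + params.n_control

    severity = rng.standard_normal(n_total)
    domain_noise = {d: rng.standard_normal(n_total)
                    for d in ("activity", "no4s", "cptii")}
    factors = {d: np.sqrt(rho) * severity + np.sqrt(1 - rho) * domain_noise[d]
               for d in ("activity", "no4s", "cptii")}

    group_col = np.array(["control"] * params.n_control + ["ADHD"] * params.n_adhd)
    values: dict[str, np.ndarray] = {}
    for key, mp in params.measures.items():
        lam_k = lam[key]
        z = (lam_k * factors[mp.domain]
             + np.sqrt(max(0.0, 1.0 - lam_k ** 2)) * rng.standard_normal(n_total))
        x = np.empty(n_total)
        for g, _ in groups:
            mask = group_col == g
            x[mask] = mp.transform(z[mask],
                                   "control" if g == "control" else "adhd", rng)
        values[key] = x

    # The five attention-state shares are calibrated marginally and sum to
    # 100 only in expectation (the published group means themselves sum to
    # 99.4/100.8).  Percentages that sum to exactly 100 arise only in the
    # epoch-level scoring path, not in this summary-level generator.

    ages = np.concatenate([
        _sample_ages(rng, params.n_control, ref.CONTROL_AGE_MEAN, ref.CONTROL_AGE_SD),
        _sample_ages(rng, params.n_adhd, ref.ADHD_AGE_MEAN, ref.ADHD_AGE_SD),
    ])

    def _sex_vector(n: int, n_male_ref: int, n_ref: int) -> np.ndarray:
        n_male = int(round(n * n_male_ref / n_ref))
        v = np.array(["male"] * n_male + ["female"] * (n - n_male))
        rng.shuffle(v)
        return v

    sex = np.concatenate([
        _sex_vector(params.n_control, ref.CONTROL_MALES, ref.N_CONTROL),
        _sex_vector(params.n_adhd, ref.ADHD_MALES, ref.N_ADHD),
    ])

    n_adhd = params.n_adhd
    sub_counts = {k: int(round(v * n_adhd / ref.N_ADHD))
                  for k, v in _SUBTYPE_SPLIT.items()}
    while sum(sub_counts.values()) < n_adhd:
        sub_counts["combined"] += 1
    while sum(sub_counts.values()) > n_adhd:
        sub_counts[max(sub_counts, key=sub_counts.get)] -= 1
    subtype_adhd = np.concatenate([np.array([k] * v)
                                   for k, v in sub_counts.items()])
    rng.shuffle(subtype_adhd)
    subtype = np.concatenate([np.array(["none"] * params.n_control), subtype_adhd])

    rows = {
        "subject_id": [f"S{i:04d}" for i in range(n_total)],
        "group": group_col,
        "sex": sex,
        "age": ages,
        "subtype": subtype,
        "latent_severity": severity,
    }
    rows.update(values)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trajectory generator

@dataclass
class MovementModelParams:
    """Mechanistic bout/still model behind a marker trajectory."""

    bout_rate: float = 10.0                 # bouts per minute
    bout_amplitude_scale: float = 15.0      # mm of path per second of bout
    immobility_tail_exponent: float = 1.5   # Pareto tail of still durations
    path_roughness: float = 0.5             # 0 straight .. 1 maximally jittered
    sampling_rate: float = ref.SAMPLING_RATE_HZ
    resolution: float = ref.RESOLUTION_MM
    session_duration: float = ref.NO4S_SESSION_S

    def __post_init__(self) -> None:
        if self.bout_rate < 0:
            raise ValueError("bout_rate must be >= 0")
        if self.sampling_rate <= 0 or self.resolution <= 0:
            raise ValueError("sampling_rate and resolution must be positive")
        if not 0.0 <= self.path_roughness <= 1.0:
            raise ValueError("path_roughness must be in [0, 1]")


def simulate_trajectory(params: MovementModelParams, seed: int,
                        marker_id: str = "head") -> Trajectory:
    """Alternating still periods and movement bouts, quantized to resolution.

    Still durations are heavy tailed (Pareto with the configured tail
    index, renormalized to fill the session); bouts are correlated 2-D
    walks whose turning-angle dispersion grows with `path_roughness`.  The
    generator's own bout log is stored in ``traj.meta["bouts"]``.
    """
    if params.session_duration <= 0:
        raise ValueError("session_duration must be positive")
    rng = np.random.default_rng(seed)
    fs = params.sampling_rate
    n = int(round(params.session_duration * fs))
    time = np.arange(n) / fs
    x = np.zeros(n)
    y = np.zeros(n)

    k_bouts = rng.poisson(params.bout_rate * params.session_duration / 60.0)
    bouts = []
    if k_bouts > 0:
        durations = rng.lognormal(mean=np.log(0.8), sigma=0.5, size=k_bouts)
        total_bout = durations.sum()
        budget = params.session_duration
        if total_bout > 0.8 * budget:
            durations *= 0.8 * budget / total_bout
            total_bout = durations.sum()
        gaps = rng.pareto(params.immobility_tail_exponent, k_bouts + 1) + 0.1
        gaps *= (budget - total_bout) / gaps.sum()

        # quadratic map keeps the top of the roughness range from
        # saturating at an effectively uniform turning-angle distribution
        heading_sd = np.pi * params.path_roughness ** 2
        t_cursor = 0.0
        cx, cy = 0.0, 0.0
        for i in range(k_bouts):
            t_cursor += gaps[i]
            start = int(round(t_cursor * fs))
            dur_frames = max(1, int(round(durations[i] * fs)))
            stop = min(start + dur_frames, n)
            if start >= n:
                break
            m = stop - start
            step_len = rng.rayleigh(scale=params.bout_amplitude_scale / fs
                                    / np.sqrt(np.pi / 2.0), size=m)
            heading = rng.uniform(0, 2 * np.pi) + np.cumsum(
                rng.normal(0.0, heading_sd, size=m))
            dx = step_len * np.cos(heading)
            dy = step_len * np.sin(heading)
            px = cx + np.cumsum(dx)
            py = cy + np.cumsum(dy)
            x[start:stop] = px
            y[start:stop] = py
            x[stop:] = px[-1]
            y[stop:] = py[-1]
            cx, cy = px[-1], py[-1]
            bouts.append({"start_s": start / fs, "end_s": stop / fs,
                          "path_mm": float(step_len.sum())})
            t_cursor = stop / fs

    res = params.resolution
    x = np.round(x / res) * res
    y = np.round(y / res) * res
    return Trajectory(marker_id, time, x, y, np.ones(n, dtype=bool),
                      meta={"bouts": bouts, "params": params})


def inject_frame_loss(traj: Trajectory, loss_fraction: float,
                      seed: int, mean_run: float = 10.0) -> Trajectory:
    """Mark frames invalid in geometric runs (mean length `mean_run`).

    Emulates marker occlusion: losses are temporally contiguous and the
    expected invalid share equals `loss_fraction`.  Valid positions are
    unchanged.
    """
    if not 0.0 <= loss_fraction < 1.0:
        raise ValueError("loss_fraction must be in [0, 1)")
    out = traj.copy()
    if loss_fraction == 0.0:
        return out
    rng = np.random.default_rng(seed)
    n = out.n_frames
    mean_valid_run = mean_run * (1.0 - loss_fraction) / loss_fraction
    valid = np.ones(n, dtype=bool)
    pos = 0
    state_invalid = rng.random() < loss_fraction
    while pos < n:
        mean_len = mean_run if state_invalid else mean_valid_run
        run = rng.geometric(1.0 / max(mean_len, 1.0))
        if state_invalid:
            valid[pos:pos + run] = False
        pos += run
        state_invalid = not state_invalid
    out.valid = valid
    return out


# ---------------------------------------------------------------------------
# task streams

def simulate_no4s_stream(session_duration: float = ref.NO4S_SESSION_S,
                         seed: int = 0) -> pd.DataFrame:
    """Star stimuli at 240 ms with shifted-exponential ISIs (mean 2500 ms).

    Stimuli are 16/8/5-pointed stars (targets, 90%) and 4-pointed stars
    (non-targets); the ISI is 1000 ms plus an exponential with mean
    1500 ms, matching the stated mean cycle of roughly 2.74 s.
    """
    if session_duration <= 0:
        raise ValueError("session_duration must be positive")
    rng = np.random.default_rng(seed)
    end_ms = session_duration * 1000.0
    onsets, codes, isis = [], [], []
    t = 0.0
    while t + ref.NO4S_STIM_MS <= end_ms:
        onsets.append(t)
        if rng.random() < ref.NO4S_TARGET_FRACTION:
            codes.append(int(rng.choice([16, 8, 5])))
        else:
            codes.append(4)
        isi = 1000.0 + rng.exponential(ref.NO4S_MEAN_ISI_MS - 1000.0)
        isis.append(isi)
        t += ref.NO4S_STIM_MS + isi
    df = pd.DataFrame({
        "task": "no4s",
        "trial_index": np.arange(len(onsets)),
        "onset_ms": np.asarray(onsets),
        "stimulus_code": [str(c) for c in codes],
        "is_target": np.asarray(codes) != 4,
        "block": pd.NA,
        "sub_block": pd.NA,
        "isi_ms": np.asarray(isis),
    })
    return df


def simulate_cptii_stream(seed: int = 0) -> pd.DataFrame:
    """Letter stream: 6 blocks x 3 ISI sub-blocks (1, 2, 4 s), 250 ms stimuli.

    Within each block the three ISI sub-blocks appear in random order;
    each sub-block has the conventional 20 trials with ~10% non-target 'X'.
    """
    rng = np.random.default_rng(seed)
    letters = [c for c in "ABCDEFGHIJKLMNOPQRSTUVWYZ"]   # no X
    rows = []
    t = 0.0
    trial = 0
    for block in range(1, ref.CPT_N_BLOCKS + 1):
        order = rng.permutation(ref.CPT_ISI_LEVELS_MS)
        for sub, isi in enumerate(order, start=1):
            for _ in range(ref.CPT_TRIALS_PER_SUBBLOCK):
                is_x = rng.random() < ref.CPT_NONTARGET_RATE
                code = "X" if is_x else str(rng.choice(letters))
                rows.append((trial, t, code, not is_x, block, sub, isi))
                t += ref.CPT_STIM_MS + isi
                trial += 1
    df = pd.DataFrame(rows, columns=["trial_index", "onset_ms", "stimulus_code",
                                     "is_target", "block", "sub_block", "isi_ms"])
    df.insert(0, "task", "cptii")
    return df


# ---------------------------------------------------------------------------
# responses with a hidden attention-state process

@dataclass(frozen=True)
class StateParams:
    hit_prob: float
    fa_prob: float
    rt_mean: float     # ms
    rt_sd: float       # ms

    def __post_init__(self) -> None:
        for p in (self.hit_prob, self.fa_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.rt_sd < 0:
            raise ValueError("rt_sd must be >= 0")


@dataclass
class ResponseModelParams:
    """Hidden five-state response model at 30-s epoch granularity."""

    states: dict[str, StateParams]
    transition: np.ndarray          # 5x5, rows sum to 1, order = STATES
    initial: np.ndarray             # length 5
    epoch_length: float = ref.EPOCH_LENGTH_S

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if set(self.states) != set(STATES):
            raise ValueError(f"states must be exactly {STATES}")
        if self.transition.shape != (5, 5) or not np.allclose(
                self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0):
            raise ValueError("initial distribution must sum to 1")

    def stationary(self) -> np.ndarray:
        """Leading left eigenvector of the transition matrix."""
        vals, vecs = np.linalg.eig(self.transition.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, i])
        return v / v.sum()

    @classmethod
    def default(cls) -> "ResponseModelParams":
        states = {
            "attentive":  StateParams(0.98, 0.05, 440.0, 70.0),
            "distracted": StateParams(0.72, 0.15, 680.0, 190.0),
            "impulsive":  StateParams(0.96, 0.70, 215.0, 65.0),
            "random":     StateParams(0.50, 0.50, 420.0, 260.0),
            "minimal":    StateParams(0.06, 0.02, 750.0, 200.0),
        }
        transition = np.array([
            [0.85, 0.06, 0.06, 0.01, 0.02],
            [0.35, 0.45, 0.12, 0.04, 0.04],
            [0.30, 0.15, 0.50, 0.03, 0.02],
            [0.25, 0.15, 0.10, 0.45, 0.05],
            [0.20, 0.10, 0.05, 0.05, 0.60],
        ])
        initial = np.array([0.60, 0.15, 0.15, 0.05, 0.05])
        return cls(states, transition, initial)


_MIN_RT = {"attentive": 100.0, "distracted": 100.0, "minimal": 100.0,
           "impulsive": 20.0, "random": 20.0}


def simulate_responses(stream: pd.DataFrame, params: ResponseModelParams,
                       seed: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-trial responses plus the hidden per-epoch state labels.

    The hidden state is constant within each 30-s epoch and evolves by the
    transition matrix across epochs.  Response latencies are normal within
    state, floored at 100 ms except for the impulsive and random states
    (which may emit anticipatory sub-100-ms presses).
    """
    if stream.empty:
        raise ValueError("stream must be non-empty")
    rng = np.random.default_rng(seed)
    onset = stream["onset_ms"].to_numpy(dtype=float)
    epoch_ms = params.epoch_length * 1000.0
    epoch_idx = (onset // epoch_ms).astype(int)
    n_epochs = int(epoch_idx.max()) + 1

    labels = np.empty(n_epochs, dtype=object)
    state = int(rng.choice(5, p=params.initial))
    for e in range(n_epochs):
        labels[e] = STATES[state]
        state = int(rng.choice(5, p=params.transition[state]))

    responded = np.zeros(len(stream), dtype=bool)
    rt = np.full(len(stream), np.nan)
    for i, (e, target) in enumerate(zip(epoch_idx, stream["is_target"])):
        sp = params.states[labels[e]]
        p = sp.hit_prob if target else sp.fa_prob
        if rng.random() < p:
            responded[i] = True
            rt[i] = max(_MIN_RT[labels[e]],
                        rng.normal(sp.rt_mean, sp.rt_sd))
    out = stream.copy()
    out["responded"] = responded
    out["rt_ms"] = rt
    return out, labels


# ---------------------------------------------------------------------------
# executive-function ratings

def sample_ratings(cohort: pd.DataFrame, target_correlations: dict[str, float],
                   composite_col: str, seed: int) -> pd.DataFrame:
    """Rating columns whose population correlation with a composite is fixed.

    Each rating is r * z(composite) + sqrt(1 - r^2) * noise, scaled to a
    T-score-like range; since the composite is itself driven by the latent
    severity factor, ratings inherit the severity structure.
    """
    rng = np.random.default_rng(seed)
    z = cohort[composite_col].to_numpy(dtype=float)
    z = (z - z.mean()) / z.std(ddof=0)
    out = {}
    for name, r in target_correlations.items():
        if not abs(r) < 1:
            raise ValueError("|target_correlation| must be < 1")
        val = r * z + np.sqrt(1 - r ** 2) * rng.standard_normal(z.size)
        out[f"rating_{name.lower().replace(' ', '_')}"] = 50.0 + 15.0 * val
    return pd.DataFrame(out, index=cohort.index)


DEFAULT_RATING_TARGETS = dict(ref.TABLE4_R["activity_composite"])
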