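"""Movement-pattern measures from infrared marker trajectories.

A seated subject's head and shin markers are tracked at 50 Hz with 0.04 mm
spatial resolution while they perform a computerized attention task.  This
module turns one marker trajectory into the six hyperactivity measures used
in the case-control analysis:

* mean immobility duration (s) — mean length of still periods between
  movement events;
* microevents — number of movements larger than 1 mm, counted as
  threshold crossings of accumulated path length;
* total displacement (m) — summed inter-frame path length;
* movement area (cm^2) — convex hull of the visited positions;
* spatial complexity — divider (compass) fractal dimension of the path,
  1 for a straight path, approaching 2 for a plane-filling one;
* temporal scaling — box-counting exponent of the movement event times,
  0 for a single burst of activity, 1 for activity at every time scale.

Extensive counts (microevents, displacement) are rescaled for lost frames;
the exponents, area and immobility mean are intensive and left unscaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
from scipy.spatial import ConvexHull, QhullError

MARKERS = ("head", "left_shin", "right_shin")

#: default movement-event threshold (mm)
MICROEVENT_THRESHOLD_MM = 1.0
_EPS = 1e-9

#: temporal box-count widths (s): 0.5 s doubling up to 64 s
TEMPORAL_WIDTHS_S = tuple(0.5 * 2 ** k for k in range(8))

#: divider-ruler ladder base (mm) and maximal fraction of the path extent
RULER_BASE_MM = 0.5
RULER_MAX_FRACTION = 0.25


@dataclass
class Trajectory:
    """Time-stamped 2-D marker positions with per-frame validity flags."""

    marker_id: str
    time: np.ndarray          # s, strictly increasing
    x: np.ndarray             # mm
    y: np.ndarray             # mm
    valid: np.ndarray         # bool
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.time.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.time.size
        if not (self.x.size == self.y.size == self.valid.size == n):
            raise ValueError("trajectory arrays must have equal length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        if self.n_frames < 2:
            return 0.0
        return float(self.time[-1] - self.time[0])

    def copy(self) -> "Trajectory":
        return Trajectory(self.marker_id, self.time.copy(), self.x.copy(),
                          self.y.copy(), self.valid.copy(), dict(self.meta))


@dataclass
class MotionFeatureSet:
    """The six per-marker movement measures plus the frame-loss share."""

    immobility_duration: float    # s
    microevents: float            # count (float after loss adjustment)
    displacement: float           # m
    area: float                   # cm^2
    spatial_complexity: float     # exponent in [1, 2]
    temporal_scaling: float       # exponent in [0, 1]
    loss_fraction: float = 0.0
    loss_adjusted: bool = False

    def as_dict(self) -> dict[str, float]:
        return {
            "immobility_duration": self.immobility_duration,
            "microevents": self.microevents,
            "displacement": self.displacement,
            "area": self.area,
            "spatial_complexity": self.spatial_complexity,
            "temporal_scaling": self.temporal_scaling,
            "loss_fraction": self.loss_fraction,
        }


# ---------------------------------------------------------------------------
# preprocessing

def preprocess_trajectory(traj: Trajectory) -> tuple[Trajectory, float]:
    """Fill invalid frames by linear interpolation between valid neighbours.

    Leading/trailing gaps are held at the nearest valid position.  Returns
    the cleaned trajectory and the fraction of frames that were invalid.
    """
    valid = traj.valid
    n = valid.size
    n_valid = int(valid.sum())
    if n_valid < 2:
        raise ValueError("need at least 2 valid frames to interpolate")
    loss_fraction = 1.0 - n_valid / n
    if n_valid == n:
        out = traj.copy()
        return out, 0.0
    idx = np.arange(n)
    x = np.interp(idx, idx[valid], traj.x[valid])
    y = np.interp(idx, idx[valid], traj.y[valid])
    meta = dict(traj.meta)
    meta["interpolated"] = ~valid.copy()
    out = Trajectory(traj.marker_id, traj.time.copy(), x, y,
                     np.ones(n, dtype=bool), meta)
    return out, float(loss_fraction)


def observed_step_mask(traj: Trajectory) -> np.ndarray:
    """True for inter-frame steps whose both endpoints were truly observed.

    Steps bridging interpolated frames carry reconstructed, not measured,
    displacement; extensive measures exclude them and are rescaled by the
    observed-step share instead (see :func:`extract_motion_features`).
    """
    interp = traj.meta.get("interpolated")
    if interp is None:
        return np.ones(max(traj.n_frames - 1, 0), dtype=bool)
    interp = np.asarray(interp, dtype=bool)
    return ~(interp[:-1] | interp[1:])


# ---------------------------------------------------------------------------
# movement events

def microevent_times(traj: Trajectory,
                     threshold: float = MICROEVENT_THRESHOLD_MM,
                     observed_only: bool = False) -> np.ndarray:
    """Times (s) at which accumulated path length crosses `threshold`.

    The accumulator resets to zero at each event, so one large excursion
    registers a single event regardless of its amplitude, while sustained
    drift registers floor(path / threshold) events.  With `observed_only`
    the steps bridging interpolated frames contribute no path.
    """
    if traj.n_frames < 2:
        return np.empty(0)
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    if observed_only:
        steps = steps * observed_step_mask(traj)
    cum = np.cumsum(steps)            # cum[i] = path length through frame i+1
    total = cum[-1]
    events = []
    target = threshold
    pos = 0
    while True:
        pos = int(np.searchsorted(cum, target - _EPS, side="left"))
        if pos >= cum.size:
            break
        events.append(pos + 1)        # event lands on frame pos+1
        target = cum[pos] + threshold
    return traj.time[np.asarray(events, dtype=int)] if events else np.empty(0)


def count_microevents(traj: Trajectory,
                      threshold: float = MICROEVENT_THRESHOLD_MM,
                      observed_only: bool = False) -> int:
    """Number of movements exceeding `threshold` mm."""
    return int(microevent_times(traj, threshold, observed_only).size)


def total_displacement(traj: Trajectory, observed_only: bool = False) -> float:
    """Total distance moved, in metres."""
    if traj.n_frames < 2:
        return 0.0
    steps = np.hypot(np.diff(traj.x), np.diff(traj.y))
    if observed_only:
        steps = steps * observed_step_mask(traj)
    return float(steps.sum() / 1000.0)


def movement_area(traj: Trajectory) -> float:
    """Area (cm^2) of the convex hull of visited positions; 0 if degenerate."""
    pts = np.column_stack([traj.x, traj.y])
    pts = np.unique(pts, axis=0)
    if pts.shape[0] < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return 0.0          # collinear point set
    return float(hull.volume / 100.0)     # mm^2 -> cm^2 (2-D "volume" is area)


def immobility_statistics(traj: Trajectory,
                          threshold: float = MICROEVENT_THRESHOLD_MM) -> float:
    """Mean still-period duration (s): runs between consecutive microevents.

    With no events the whole session counts as one still period.
    """
    events = microevent_times(traj, threshold)
    if traj.n_frames < 2:
        return 0.0
    bounds = np.concatenate([[traj.time[0]], events, [traj.time[-1]]])
    durations = np.diff(bounds)
    return float(durations.mean())


# ---------------------------------------------------------------------------
# scaling exponents

def _ruler_ladder(extent: float) -> np.ndarray:
    rulers = []
    r = RULER_BASE_MM
    while r <= extent * RULER_MAX_FRACTION:
        rulers.append(r)
        r *= 2.0
    return np.asarray(rulers)


def _divider_length(x: np.ndarray, y: np.ndarray, r: float) -> float:
    """Apparent path length at ruler size r (compass walk along the path)."""
    steps = np.hypot(np.diff(x), np.diff(y))
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    n = x.size
    anchor = 0
    count = 0
    r2 = (r - _EPS) ** 2
    chunk = 512
    while True:
        # the next compass point is at least ruler-r of arc length ahead
        lo = int(np.searchsorted(arc, arc[anchor] + r - _EPS, side="left"))
        if lo >= n:
            break
        found = -1
        while lo < n:
            hi = min(lo + chunk, n)
            dx = x[lo:hi] - x[anchor]
            dy = y[lo:hi] - y[anchor]
            hit = np.nonzero(dx * dx + dy * dy >= r2)[0]
            if hit.size:
                found = lo + int(hit[0])
                break
            lo = hi
        if found < 0:
            break
        anchor = found
        count += 1
    residual = float(np.hypot(x[-1] - x[anchor], y[-1] - y[anchor]))
    return count * r + residual


def spatial_complexity(traj: Trajectory) -> float:
    """Divider (compass) dimension of the movement path, clamped to [1, 2].

    Measures apparent length L(r) over a geometric ruler ladder
    (0.5 mm doublings up to a quarter of the bounding-box diagonal) and
    returns 1 - slope of log L(r) vs log r.  Returns nan for paths too
    short or too small to support at least two rulers.
    """
    steps_total = total_displacement(traj) * 1000.0
    if steps_total <= 0:
        return float("nan")
    extent = float(np.hypot(traj.x.max() - traj.x.min(),
                            traj.y.max() - traj.y.min()))
    rulers = _ruler_ladder(extent)
    if rulers.size < 2:
        return float("nan")
    lengths = np.array([_divider_length(traj.x, traj.y, r) for r in rulers])
    ok = lengths > 0
    if ok.sum() < 2:
        return float("nan")
    slope = np.polyfit(np.log(rulers[ok]), np.log(lengths[ok]), 1)[0]
    return float(np.clip(1.0 - slope, 1.0, 2.0))


def temporal_scaling(traj: Trajectory,
                     threshold: float = MICROEVENT_THRESHOLD_MM) -> float:
    """Temporal box-count exponent of the microevent point process.

    Counts occupied time boxes N(w) at widths 0.5 s ... 64 s and returns
    -slope of log N(w) vs log w, clamped to [0, 1].  Zero events return 0
    by convention.
    """
    events = microevent_times(traj, threshold)
    return event_time_scaling(events)


def event_time_scaling(event_times: np.ndarray,
                       widths: tuple[float, ...] = TEMPORAL_WIDTHS_S) -> float:
    """Box-count exponent for an explicit set of event times (s)."""
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        return 0.0
    w = np.asarray(widths, dtype=float)
    counts = np.array([np.unique(np.floor(events / wi)).size for wi in w])
    slope = np.polyfit(np.log(w), np.log(counts), 1)[0]
    return float(np.clip(-slope, 0.0, 1.0))


# ---------------------------------------------------------------------------
# frame-loss adjustment and the full feature set

def adjust_for_loss(features: MotionFeatureSet,
                    loss_fraction: float) -> MotionFeatureSet:
    """Rescale extensive measures by 1/(1 - loss_fraction).

    Microevents and displacement accumulate over time and scale with the
    observed share of the session; the exponents, hull area and mean
    immobility are intensive and are left alone.
    """
    if not 0.0 <= loss_fraction < 1.0:
        raise ValueError("loss_fraction must be in [0, 1)")
    if loss_fraction >= 0.5:
        warnings.warn(f"frame loss {loss_fraction:.0%} exceeds 50%: "
                      "adjusted measures are low quality", stacklevel=2)
    scale = 1.0 / (1.0 - loss_fraction)
    return replace(features,
                   microevents=features.microevents * scale,
                   displacement=features.displacement * scale,
                   loss_fraction=loss_fraction,
                   loss_adjusted=True)


def fit_activity_composite(features, is_case, C: float = 1.0):
    """Activity severity composite: logistic weights over the 12 head and
    shin movement measures, standardized against control statistics.

    Fit on a calibration cohort containing both groups; the returned model
    serializes to JSON and applies unchanged to later cohorts.  Higher
    scores are more ADHD-like.
    """
    from . import reference_tables as ref
    from .composites import fit_composite
    return fit_composite(features, is_case, list(ref.ACTIVITY_KEYS),
                         name="activity_composite", C=C)


def apply_activity_composite(model, features) -> np.ndarray:
    """Score rows of a feature table with a fitted activity composite."""
    if model is None:
        raise ValueError("activity composite model not fitted")
    return model.score(features)


def extract_motion_features(traj: Trajectory,
                            threshold: float = MICROEVENT_THRESHOLD_MM,
                            adjust_loss: bool = True) -> MotionFeatureSet:
    """Preprocess a raw trajectory and compute all six movement measures.

    Extensive measures (microevents, displacement) accumulate over truly
    observed steps only and are then rescaled by the observed-step share,
    so reconstructed bridges across occlusions are neither counted twice
    nor silently dropped.  Intensive measures (exponents, area, immobility
    mean) use the interpolated geometry.
    """
    clean, loss = preprocess_trajectory(traj)
    mask = observed_step_mask(clean)
    step_loss = 1.0 - float(mask.mean()) if mask.size else 0.0
    feats = MotionFeatureSet(
        immobility_duration=immobility_statistics(clean, threshold),
        microevents=float(count_microevents(clean, threshold,
                                            observed_only=True)),
        displacement=total_displacement(clean, observed_only=True),
        area=movement_area(clean),
        spatial_complexity=spatial_complexity(clean),
        temporal_scaling=temporal_scaling(clean, threshold),
        loss_fraction=loss,
    )
    if adjust_loss and step_loss > 0:
        feats = adjust_for_loss(feats, step_loss)
        feats.loss_fraction = loss
    return feats
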