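"""Bolus landmark detection: arrival, aortic extrema, renal peak, time shift.

All detections run on smoothed curves.  Times are reported in the curve's own
time base; downstream integration re-references them to the detected arrival
(t = 0).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    BolusNotFoundError,
    BoundaryPeakWarning,
    FlatCurveError,
    NegativeDeltaTWarning,
    RecirculationNotFoundError,
    UnsmoothedCurveWarning,
)

__all__ = [
    "BolusLandmarks",
    "detect_bolus_arrival",
    "detect_aorta_landmarks",
    "detect_kidney_peak",
    "compute_delta_t",
]

#: Minimum separation between candidate peaks, in frames.
MIN_PEAK_SEPARATION = 5
#: First-peak qualification threshold as a fraction of the global maximum.
PEAK_HEIGHT_FRACTION = 0.5
#: Minimum peak prominence as a fraction of the curve's post-arrival range,
#: rejecting residual noise dimples on the bolus limbs.
PEAK_PROMINENCE_FRACTION = 0.05


@dataclass
class BolusLandmarks:
    """Times (s) and concentrations (mmol/L) of the characteristic bolus extrema."""

    t_arrival: float
    t_aorta_max1: float
    c_aorta_max1: float
    t_aorta_min1: float
    c_aorta_min1: float
    t_aorta_max2: float
    c_aorta_max2: float
    t_kidney_max1: float | None = None
    c_kidney_max1: float | None = None
    delta_t: float | None = None

    def __post_init__(self) -> None:
        if not (self.t_arrival <= self.t_aorta_max1 < self.t_aorta_min1 < self.t_aorta_max2):
            raise ValueError(
                "landmark ordering violated: need "
                "t_arrival <= t_aorta_max1 < t_aorta_min1 < t_aorta_max2"
            )
        if self.delta_t is not None and self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BolusLandmarks":
        return cls(**json.loads(Path(path).read_text()))


def _require_smoothed(curve) -> None:
    if not getattr(curve, "smoothed", False):
        warnings.warn(
            "landmark detection expects a smoothed curve",
            UnsmoothedCurveWarning,
            stacklevel=3,
        )


def detect_bolus_arrival(
    curve,
    *,
    k: float = 5.0,
    baseline_frames: int = 20,
    min_rise_frames: int = 3,
) -> float:
    """Time of the last frame before the contrast-driven signal ascent.

    The curve first exceeding ``baseline_mean + k * baseline_sd`` and staying
    above it while rising for at least ``min_rise_frames`` frames marks the
    ascent; the detector then backtracks down the rising limb to the last
    frame still within one baseline standard deviation of the baseline mean.
    """
    _require_smoothed(curve)
    v = curve.values
    if len(v) < baseline_frames + min_rise_frames + 1:
        raise BolusNotFoundError("curve too short for arrival detection")
    base = v[:baseline_frames]
    mean = float(base.mean())
    sd = float(base.std(ddof=0))
    span = float(v.max() - mean)
    if span <= 0:
        raise BolusNotFoundError("curve never rises above its baseline")
    # relative floor keeps noiseless (sd ~ 0) curves from triggering on the
    # smoothing filter's sub-frame onset leak; irrelevant once real noise
    # dominates the baseline sd
    sd_eff = max(sd, 3e-3 * span)
    threshold = mean + k * sd_eff

    crossing = None
    for i in range(1, len(v) - min_rise_frames):
        if v[i] > threshold and np.all(np.diff(v[i : i + min_rise_frames + 1]) >= 0):
            crossing = i
            break
    if crossing is None:
        raise BolusNotFoundError(
            f"no sustained crossing of baseline + {k}*sd found"
        )
    j = crossing - 1
    while j > 0 and v[j] - mean > sd_eff and v[j] <= v[j + 1]:
        j -= 1
    return float(curve.times[j])


#: Half-width (frames) of the quadratic vertex refinement around a detected
#: extremum.  Spans roughly one breathing cycle so residual periodic ripple
#: the smoothing filter passes does not pin extrema to a ripple crest.
REFINE_HALF_WIDTH = 7


def _refine_extremum(times: np.ndarray, values: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-frame extremum location via a local quadratic least-squares fit.

    Falls back to the grid point when the fit is degenerate or the vertex
    strays more than the fit half-width from the grid extremum.
    """
    lo = max(i - REFINE_HALF_WIDTH, 0)
    hi = min(i + REFINE_HALF_WIDTH + 1, len(values))
    if hi - lo < 6:
        return float(times[i]), float(values[i])
    tt = times[lo:hi] - times[i]
    # cubic rather than quadratic: captures limb asymmetry, so the vertex is
    # not dragged toward the flatter side of the extremum
    coeffs = np.polyfit(tt, values[lo:hi], 3)
    roots = np.roots(np.polyder(coeffs))
    roots = roots[np.isreal(roots)].real
    if len(roots) == 0:
        return float(times[i]), float(values[i])
    vertex = float(roots[np.argmin(np.abs(roots))])
    if abs(vertex) > (times[1] - times[0]) * REFINE_HALF_WIDTH:
        return float(times[i]), float(values[i])
    return float(times[i] + vertex), float(np.polyval(coeffs, vertex))


def _peaks(values: np.ndarray, height: float | None = None) -> np.ndarray:
    prominence = PEAK_PROMINENCE_FRACTION * float(np.ptp(values))
    idx, _ = find_peaks(
        values, height=height, distance=MIN_PEAK_SEPARATION, prominence=prominence
    )
    return idx


def detect_aorta_landmarks(curve, t_arrival: float) -> BolusLandmarks:
    """First maximum, first minimum and (lower) second maximum of the AIF.

    The first maximum is the first local maximum after arrival exceeding 50%
    of the global post-arrival maximum; the first minimum is the global
    minimum between the first maximum and the next qualifying local maximum;
    the second maximum is the highest local maximum after that minimum within
    a 60 s horizon (ties broken by earliest time).
    """
    _require_smoothed(curve)
    t = curve.times
    v = curve.values
    after = t >= t_arrival
    if not after.any():
        raise BolusNotFoundError("arrival time outside curve")
    offset = int(np.argmax(after))
    seg = v[offset:]
    gmax = float(seg.max())
    peak_idx = _peaks(seg, height=PEAK_HEIGHT_FRACTION * gmax)
    if len(peak_idx) == 0:
        raise FlatCurveError("no qualifying first aortic maximum found")
    i_max1 = offset + int(peak_idx[0])

    horizon = t_arrival + 60.0
    # all local maxima after the first peak (no height threshold: the
    # recirculation peak is lower), within the search horizon
    later = _peaks(v[i_max1:]) + i_max1
    later = later[t[later] <= horizon]
    if len(later) == 0:
        raise RecirculationNotFoundError(
            "no second aortic maximum within the search horizon"
        )
    i_next = int(later[0])
    i_min1 = i_max1 + int(np.argmin(v[i_max1 : i_next + 1]))
    after_min = later[later > i_min1]
    if len(after_min) == 0:
        raise RecirculationNotFoundError("no local maximum after the first minimum")
    vals = v[after_min]
    i_max2 = int(after_min[int(np.argmax(vals))])  # argmax returns earliest tie

    t_max1, c_max1 = _refine_extremum(t, v, i_max1)
    t_min1, c_min1 = _refine_extremum(t, v, i_min1)
    t_max2, c_max2 = _refine_extremum(t, v, i_max2)
    if not (t_arrival <= t_max1 < t_min1 < t_max2):  # refinement crossed over
        t_max1, c_max1 = float(t[i_max1]), float(v[i_max1])
        t_min1, c_min1 = float(t[i_min1]), float(v[i_min1])
        t_max2, c_max2 = float(t[i_max2]), float(v[i_max2])

    return BolusLandmarks(
        t_arrival=float(t_arrival),
        t_aorta_max1=t_max1,
        c_aorta_max1=c_max1,
        t_aorta_min1=t_min1,
        c_aorta_min1=c_min1,
        t_aorta_max2=t_max2,
        c_aorta_max2=c_max2,
    )


def detect_kidney_peak(curve, t_arrival: float) -> tuple[float, float]:
    """First local maximum of a renal curve after arrival (>=50% of global max)."""
    _require_smoothed(curve)
    t = curve.times
    v = curve.values
    after = t >= t_arrival
    if not after.any():
        raise BolusNotFoundError("arrival time outside curve")
    offset = int(np.argmax(after))
    seg = v[offset:]
    if np.ptp(seg) == 0:
        raise FlatCurveError("kidney curve is constant after arrival")
    gmax = float(seg.max())
    peak_idx = _peaks(seg, height=PEAK_HEIGHT_FRACTION * gmax)
    if len(peak_idx) == 0:
        # monotone rise to the final frame: report the boundary maximum
        i = offset + int(np.argmax(seg))
        if i == len(v) - 1:
            warnings.warn(
                "kidney peak sits on the final frame",
                BoundaryPeakWarning,
                stacklevel=2,
            )
            return float(t[i]), float(v[i])
        raise FlatCurveError("no qualifying kidney maximum found")
    i = offset + int(peak_idx[0])
    return _refine_extremum(t, v, i)


def compute_delta_t(t_aorta_max1: float, t_kidney_max1: float) -> float:
    """Aorta-to-kidney peak delay; negative values floored at 0 with a warning."""
    dt = t_kidney_max1 - t_aorta_max1
    if dt < 0:
        warnings.warn(
            f"kidney peak precedes aortic peak by {-dt:.3g} s; delta_t floored at 0",
            NegativeDeltaTWarning,
            stacklevel=2,
        )
        return 0.0
    return float(dt)
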