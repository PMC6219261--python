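"""Time-shift-modified Rutland-Patlak plot and GFR conversion.

The two-compartment graphical model plots, for each frame t inside the
evaluation window,

    y = c_kidney(t + dt) * V_kidney / c_aorta(t)
    x = integral_0^t c_aorta(t') dt' / c_aorta(t)

so that y = V_vas + p*V_vas * x: the slope p*V_vas (mL/s) is the whole-blood
clearance of the kidney and the intercept its vascular volume.  The slope is
converted to plasma GFR in mL/min/m^2 body surface via
``slope * 60 / BS * (1 - hct)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import linregress

from .calibration import CalibrationModel, default_model
from .errors import (
    DegenerateDenominatorError,
    GridMismatchError,
    NonPaperFallbackWarning,
    PipelineStageError,
    TruncatedWindowWarning,
    WindowTooShortError,
)
from .landmarks import (
    BolusLandmarks,
    compute_delta_t,
    detect_aorta_landmarks,
    detect_bolus_arrival,
    detect_kidney_peak,
)
from .preprocessing import (
    CORRECTION_FOR,
    ConcentrationCurve,
    DynamicSeries,
    RoiSet,
    SignalCurve,
    Subject,
    TissueGeometry,
    correct_residual_tissue,
    curve_to_concentration,
    extract_roi_mean,
    smooth_curve,
    subtract_baseline,
)

__all__ = [
    "PatlakPoints",
    "PatlakFit",
    "GfrResult",
    "PipelineConfig",
    "cumulative_aif_integral",
    "evaluation_window",
    "build_patlak_points",
    "fit_patlak",
    "gfr_from_slope",
    "run_subject_pipeline",
]

MIN_FIT_POINTS = 10


@dataclass
class PatlakPoints:
    """Patlak plot coordinates inside the evaluation window."""

    x: np.ndarray  # s: cumulative AIF integral / instantaneous AIF
    y: np.ndarray  # mL: shifted kidney content / instantaneous AIF
    t: np.ndarray  # s, curve time base
    window: tuple[float, float]
    v_kidney: float
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class PatlakFit:
    """Ordinary-least-squares line through the Patlak points."""

    slope_m: float  # mL/s, = p * V_vas
    intercept_b: float  # mL, = V_vas
    r_squared: float
    n_points: int


@dataclass
class GfrResult:
    """Per-kidney and total GFR (mL/min/m^2 BS) with fit diagnostics."""

    subject_id: str
    gfr_left: float
    gfr_right: float
    fit_left: PatlakFit | None = None
    fit_right: PatlakFit | None = None
    landmarks_left: BolusLandmarks | None = None
    landmarks_right: BolusLandmarks | None = None
    warnings: list[str] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    points_left: PatlakPoints | None = None
    points_right: PatlakPoints | None = None

    @property
    def gfr_total(self) -> float:
        return self.gfr_left + self.gfr_right


@dataclass
class PipelineConfig:
    """Tunable knobs of the end-to-end pipeline (defaults follow the method)."""

    smooth_window: int = 15
    smooth_poly: int = 2
    arrival_k: float = 5.0
    baseline_frames: int = 20
    window_duration: float = 60.0
    eps_frac: float = 0.01
    integral_from: str = "arrival"  # or "window_start"
    delta_t_source: str = "kidney"  # or "cortex"
    clip_out_of_range: bool = False
    subtract_zero_offset: bool = False
    fallback_window_offset: float | None = None  # s after arrival, non-paper


def cumulative_aif_integral(aorta: ConcentrationCurve, t_arrival: float) -> np.ndarray:
    """Cumulative trapezoidal integral of the AIF from arrival (mmol*s/L).

    Returned aligned to the curve's time grid; identically zero before
    arrival.
    """
    t = aorta.times
    if not (t[0] - 1e-9 <= t_arrival <= t[-1] + 1e-9):
        raise ValueError("arrival time lies outside the aortic curve")
    out = np.zeros_like(aorta.values)
    after = t >= t_arrival - 1e-9
    i0 = int(np.argmax(after))
    out[i0:] = cumulative_trapezoid(aorta.values[i0:], t[i0:], initial=0.0)
    return out


def evaluation_window(
    landmarks: BolusLandmarks,
    duration: float = 60.0,
    *,
    curve: ConcentrationCurve | None = None,
) -> tuple[float, float]:
    """Regression window ``[t_aorta_max2, t_aorta_max2 + duration]``.

    If ``curve`` is given and ends before the window does, the window is
    truncated with a warning; fewer than :data:`MIN_FIT_POINTS` surviving
    frames raise :class:`WindowTooShortError`.
    """
    t_start = landmarks.t_aorta_max2
    t_end = t_start + duration
    if curve is not None:
        if curve.times[-1] < t_end - 1e-9:
            warnings.warn(
                f"series ends at {curve.times[-1]:.2f} s; evaluation window "
                f"truncated from {t_end:.2f} s",
                TruncatedWindowWarning,
                stacklevel=2,
            )
            t_end = float(curve.times[-1])
        n_in = int(np.sum((curve.times >= t_start - 1e-9) & (curve.times <= t_end + 1e-9)))
        if n_in < MIN_FIT_POINTS:
            raise WindowTooShortError(
                f"evaluation window holds {n_in} frames; need >= {MIN_FIT_POINTS}"
            )
    return float(t_start), float(t_end)


def build_patlak_points(
    aorta: ConcentrationCurve,
    kidney: ConcentrationCurve,
    delta_t: float,
    v_kidney: float,
    t_arrival: float,
    window: tuple[float, float],
    *,
    eps_frac: float = 0.01,
    integral_from: str = "arrival",
) -> PatlakPoints:
    """Patlak coordinates for each in-window frame.

    The kidney curve is shifted by ``delta_t`` via linear interpolation in
    time.  Frames whose aortic concentration falls below ``eps_frac`` of the
    post-arrival aortic peak are dropped (count recorded).
    """
    if aorta.times.shape != kidney.times.shape or not np.allclose(
        aorta.times, kidney.times, rtol=1e-9, atol=1e-9
    ):
        raise GridMismatchError("aorta and kidney curves must share a time grid")
    if v_kidney <= 0:
        raise ValueError("v_kidney must be > 0")
    if integral_from == "arrival":
        integral = cumulative_aif_integral(aorta, t_arrival)
    elif integral_from == "window_start":
        integral = cumulative_aif_integral(aorta, window[0])
    else:
        raise ValueError("integral_from must be 'arrival' or 'window_start'")

    t = aorta.times
    in_win = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    peak = float(aorta.values[t >= t_arrival - 1e-9].max())
    eps = eps_frac * peak
    keep = in_win & (aorta.values > eps)
    n_dropped = int(in_win.sum() - keep.sum())
    if not keep.any():
        raise DegenerateDenominatorError(
            "all in-window frames dropped by the aortic denominator guard"
        )
    c_a = aorta.values[keep]
    c_k = np.interp(t[keep] + delta_t, kidney.times, kidney.values)
    return PatlakPoints(
        x=integral[keep] / c_a,
        y=c_k * v_kidney / c_a,
        t=t[keep],
        window=(float(window[0]), float(window[1])),
        v_kidney=float(v_kidney),
        n_dropped=n_dropped,
    )


def fit_patlak(points: PatlakPoints) -> PatlakFit:
    """OLS line through the Patlak points; slope p*V_vas, intercept V_vas."""
    n = len(points)
    if n < MIN_FIT_POINTS:
        raise WindowTooShortError(f"need >= {MIN_FIT_POINTS} Patlak points, have {n}")
    if np.ptp(points.x) == 0:
        raise ValueError("zero variance in Patlak x coordinates")
    res = linregress(points.x, points.y)
    return PatlakFit(
        slope_m=float(res.slope),
        intercept_b=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=n,
    )


def gfr_from_slope(slope_m: float, subject: Subject) -> float:
    """Plasma GFR in mL/min/m^2 BS: ``slope * 60 / BS * (1 - hct)``."""
    return slope_m * 60.0 / subject.body_surface * (1.0 - subject.hematocrit)


def _smoothed_concentration(
    si_curve: SignalCurve, calibration: CalibrationModel, cfg: PipelineConfig
) -> ConcentrationCurve:
    sm = smooth_curve(si_curve, cfg.smooth_window, cfg.smooth_poly)
    return curve_to_concentration(
        sm,
        calibration,
        clip_out_of_range=cfg.clip_out_of_range,
        subtract_zero_offset=cfg.subtract_zero_offset,
    )


def run_subject_pipeline(
    *,
    curves: dict[str, SignalCurve] | None = None,
    series: DynamicSeries | None = None,
    rois: RoiSet | None = None,
    geometry: dict[str, TissueGeometry],
    subject: Subject,
    calibration: CalibrationModel | None = None,
    config: PipelineConfig | None = None,
) -> GfrResult:
    """End-to-end GFR estimation for one subject.

    Accepts either precomputed per-ROI signal curves (``curves``) or a raw
    dynamic ``series`` with an ROI mask set.  Stages: baseline subtraction,
    ROI extraction, Savitzky-Golay smoothing, concentration conversion,
    residual-tissue correction, landmark detection, evaluation-window
    placement, Patlak regression and GFR conversion — run independently for
    the left and right kidney.
    """
    calibration = calibration or default_model()
    cfg = config or PipelineConfig()
    captured: list[str] = []

    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")

        if curves is None:
            if series is None or rois is None:
                raise ValueError("provide either curves or series + rois")
            try:
                sub = subtract_baseline(series)
                curves = {
                    name: extract_roi_mean(sub, rois[name], roi_label=name)
                    for name in rois.names()
                }
            except Exception as exc:  # noqa: BLE001 - re-raised with stage label
                raise PipelineStageError("extract", exc) from exc

        def corrected(label: str) -> ConcentrationCurve:
            conc = _smoothed_concentration(curves[label], calibration, cfg)
            corr_label = CORRECTION_FOR[label]
            if corr_label in curves and label in geometry:
                corr = _smoothed_concentration(curves[corr_label], calibration, cfg)
                return correct_residual_tissue(conc, corr, geometry[label])
            return conc

        try:
            aorta = corrected("aorta_all")
            renal_src = {
                "left": "kidney_left" if cfg.delta_t_source == "kidney" else "cortex_left",
                "right": "kidney_right" if cfg.delta_t_source == "kidney" else "cortex_right",
            }
            kidney = {
                "left": corrected("kidney_left"),
                "right": corrected("kidney_right"),
            }
            peak_curve = {
                side: kidney[side] if renal_src[side].startswith("kidney") else corrected(renal_src[side])
                for side in ("left", "right")
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("preprocess", exc) from exc

        try:
            t_arrival = detect_bolus_arrival(
                aorta, k=cfg.arrival_k, baseline_frames=cfg.baseline_frames
            )
            aortic = detect_aorta_landmarks(aorta, t_arrival)
        except Exception as exc:  # noqa: BLE001
            if cfg.fallback_window_offset is not None and not isinstance(
                exc, PipelineStageError
            ):
                warnings.warn(
                    "aortic recirculation not found; anchoring evaluation window "
                    f"at arrival + {cfg.fallback_window_offset:g} s (non-paper fallback)",
                    NonPaperFallbackWarning,
                    stacklevel=2,
                )
                t_arrival = detect_bolus_arrival(
                    aorta, k=cfg.arrival_k, baseline_frames=cfg.baseline_frames
                )
                aortic = None
            else:
                raise PipelineStageError("landmarks", exc) from exc

        results: dict[str, tuple] = {}
        for side in ("left", "right"):
            try:
                t_k, c_k = detect_kidney_peak(peak_curve[side], t_arrival)
                if aortic is not None:
                    dt = compute_delta_t(aortic.t_aorta_max1, t_k)
                    lm = BolusLandmarks(
                        t_arrival=aortic.t_arrival,
                        t_aorta_max1=aortic.t_aorta_max1,
                        c_aorta_max1=aortic.c_aorta_max1,
                        t_aorta_min1=aortic.t_aorta_min1,
                        c_aorta_min1=aortic.c_aorta_min1,
                        t_aorta_max2=aortic.t_aorta_max2,
                        c_aorta_max2=aortic.c_aorta_max2,
                        t_kidney_max1=t_k,
                        c_kidney_max1=c_k,
                        delta_t=dt,
                    )
                    window = evaluation_window(lm, cfg.window_duration, curve=aorta)
                else:
                    dt = 0.0
                    lm = None
                    t0 = t_arrival + cfg.fallback_window_offset
                    window = (t0, min(t0 + cfg.window_duration, float(aorta.times[-1])))
                points = build_patlak_points(
                    aorta,
                    kidney[side],
                    dt,
                    geometry[f"kidney_{side}"].v_tissue,
                    t_arrival,
                    window,
                    eps_frac=cfg.eps_frac,
                    integral_from=cfg.integral_from,
                )
                fit = fit_patlak(points)
                gfr = gfr_from_slope(fit.slope_m, subject)
                results[side] = (gfr, fit, lm, points)
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001
                raise PipelineStageError(f"patlak_{side}", exc) from exc

        captured = [f"{w.category.__name__}: {w.message}" for w in wlist]

    return GfrResult(
        subject_id=subject.id,
        gfr_left=results["left"][0],
        gfr_right=results["right"][0],
        fit_left=results["left"][1],
        fit_right=results["right"][1],
        landmarks_left=results["left"][2],
        landmarks_right=results["right"][2],
        warnings=captured,
        diagnostics={
            "t_arrival": t_arrival,
            "config": cfg.__dict__.copy(),
            "n_dropped": {side: results[side][3].n_dropped for side in results},
        },
        points_left=results["left"][3],
        points_right=results["right"][3],
    )
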