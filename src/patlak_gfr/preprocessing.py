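"""Baseline subtraction, ROI extraction, smoothing and partial-volume correction.

Turns a dynamic bolus-track series (or precomputed ROI signal curves) into
smoothed, residual-tissue-corrected concentration-time curves ready for
landmark detection and the Patlak regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import savgol_filter

from .calibration import CalibrationModel, si_to_concentration
from .errors import (
    AlreadySubtractedWarning,
    GridMismatchError,
    NegativeValueWarning,
)

__all__ = [
    "DynamicSeries",
    "RoiSet",
    "SignalCurve",
    "ConcentrationCurve",
    "TissueGeometry",
    "Subject",
    "subtract_baseline",
    "extract_roi_mean",
    "smooth_curve",
    "curve_to_concentration",
    "correct_residual_tissue",
    "body_surface_area",
    "contrast_volume_per_kg",
    "smoothing_window_span",
    "ORGAN_ROIS",
    "CORRECTION_FOR",
]

#: Organ ROIs processed by the full pipeline, and the correction ROI paired
#: with each for residual-tissue removal.
ORGAN_ROIS = ("aorta_all", "kidney_left", "kidney_right", "cortex_left", "cortex_right")
CORRECTION_FOR = {
    "aorta_all": "correction_aorta",
    "kidney_left": "correction_left",
    "kidney_right": "correction_right",
    "cortex_left": "correction_left",
    "cortex_right": "correction_right",
}


def _check_uniform(times: np.ndarray) -> None:
    if len(times) >= 2:
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("curve time grid must be uniform")
        if dt[0] <= 0:
            raise ValueError("curve times must be strictly increasing")


@dataclass
class SignalCurve:
    """Uniformly sampled mean-SI time course of one ROI (arbitrary units)."""

    times: np.ndarray
    values: np.ndarray
    roi_label: str = ""
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1D arrays")
        _check_uniform(self.times)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class ConcentrationCurve:
    """Uniformly sampled concentration time course (mmol/L = umol/mL)."""

    times: np.ndarray
    values: np.ndarray
    roi_label: str = ""
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1D arrays")
        _check_uniform(self.times)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class DynamicSeries:
    """Time-ordered stack of 2D/3D frames from the bolus-track sequence."""

    frames: np.ndarray  # shape (t, ...) with >= 20 frames
    frame_interval: float = 0.58
    baseline_index: int = 2  # third frame, zero-based
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (t, y, x) or (t, z, y, x)")
        if self.frames.shape[0] < 20:
            raise ValueError("dynamic series needs at least 20 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class RoiSet:
    """Named boolean masks over the spatial grid of a :class:`DynamicSeries`."""

    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            if not mask.any():
                raise ValueError(f"ROI mask '{name}' is empty")
            self.masks[name] = mask
        # organ masks must not overlap their own correction masks
        for organ, corr in CORRECTION_FOR.items():
            if organ in self.masks and corr in self.masks:
                if np.any(self.masks[organ] & self.masks[corr]):
                    raise ValueError(f"ROI '{organ}' overlaps its correction ROI '{corr}'")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.masks

    def names(self) -> list[str]:
        return list(self.masks)


@dataclass
class TissueGeometry:
    """Voxel/organ/residual volumes of one thick-slice ROI (all in mL)."""

    v_voxel: float
    v_tissue: float

    def __post_init__(self) -> None:
        if self.v_voxel <= 0:
            raise ValueError("v_voxel must be > 0")
        if not (0 < self.v_tissue <= self.v_voxel):
            raise ValueError("v_tissue must satisfy 0 < v_tissue <= v_voxel")

    @property
    def v_residual(self) -> float:
        return self.v_voxel - self.v_tissue


@dataclass
class Subject:
    """Per-subject metadata entering the GFR normalisation."""

    id: str = "subject"
    body_weight: float = 17.5  # kg
    hematocrit: float = 0.47
    body_surface: float | None = None  # m^2; derived from weight when None

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body weight must be > 0")
        if not (0 < self.hematocrit < 1):
            raise ValueError("hematocrit must lie in (0, 1)")
        if self.body_surface is None:
            self.body_surface = body_surface_area(self.body_weight)
        elif self.body_surface <= 0:
            raise ValueError("body surface must be > 0")


def subtract_baseline(series: DynamicSeries) -> DynamicSeries:
    """Subtract the reference frame (default: third image) from later frames.

    Frames up to and including the baseline are zeroed.  A second application
    is a no-op with an :class:`AlreadySubtractedWarning`.
    """
    if series.baseline_subtracted:
        warnings.warn(
            "series already baseline-subtracted; returning unchanged",
            AlreadySubtractedWarning,
            stacklevel=2,
        )
        return series
    idx = series.baseline_index
    if not (0 <= idx < series.n_frames):
        raise ValueError(f"baseline index {idx} outside series of {series.n_frames} frames")
    out = series.frames - series.frames[idx]
    out[: idx + 1] = 0.0
    return DynamicSeries(
        frames=out,
        frame_interval=series.frame_interval,
        baseline_index=idx,
        baseline_subtracted=True,
    )


def extract_roi_mean(series: DynamicSeries, mask: np.ndarray, roi_label: str = "") -> SignalCurve:
    """Per-frame arithmetic mean of the series over the mask voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.frames.shape[1:]:
        raise ValueError(
            f"mask shape {mask.shape} incompatible with frames {series.frames.shape[1:]}"
        )
    if not mask.any():
        raise ValueError("ROI mask is empty")
    values = series.frames[:, mask].mean(axis=1)
    return SignalCurve(times=series.times, values=values, roi_label=roi_label)


def smooth_curve(curve, window_frames: int = 15, poly_order: int = 2):
    """Savitzky-Golay smoothing with mirror-padded edges; length preserved."""
    if window_frames % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if window_frames < poly_order + 2:
        raise ValueError("smoothing window must be >= poly_order + 2")
    if window_frames > len(curve):
        raise ValueError(
            f"smoothing window {window_frames} exceeds curve length {len(curve)}"
        )
    smoothed = savgol_filter(curve.values, window_frames, poly_order, mode="mirror")
    return replace(curve, values=smoothed, smoothed=True)


def curve_to_concentration(
    curve: SignalCurve,
    model: CalibrationModel,
    *,
    clip_out_of_range: bool = False,
    subtract_zero_offset: bool = False,
) -> ConcentrationCurve:
    """Element-wise SI-to-concentration conversion of a signal curve.

    Negative post-subtraction SI values are clipped to 0 with a warning.  With
    ``subtract_zero_offset`` the small concentration the map assigns to SI = 0
    is removed from the whole curve.
    """
    values = curve.values
    if np.any(values < 0):
        warnings.warn(
            f"{int(np.sum(values < 0))} negative SI value(s) clipped to 0 "
            "before concentration conversion",
            NegativeValueWarning,
            stacklevel=2,
        )
        values = np.clip(values, 0.0, None)
    conc = si_to_concentration(values, model, clip_out_of_range=clip_out_of_range)
    if subtract_zero_offset:
        conc = conc - model.conc_at_zero_si
    return ConcentrationCurve(
        times=curve.times, values=conc, roi_label=curve.roi_label, smoothed=curve.smoothed
    )


def correct_residual_tissue(
    organ_curve: ConcentrationCurve,
    correction_curve: ConcentrationCurve,
    geom: TissueGeometry,
) -> ConcentrationCurve:
    """Remove the residual-tissue contribution from a thick-slice voxel curve.

    Applies pointwise::

        c_tissue = c_voxel * (V_voxel / V_tissue) - c_residual * (V_residual / V_tissue)

    Negative results are retained (not clipped) with a warning so downstream
    regression sees unbiased noise.
    """
    if organ_curve.times.shape != correction_curve.times.shape or not np.allclose(
        organ_curve.times, correction_curve.times, rtol=1e-9, atol=1e-9
    ):
        raise GridMismatchError("organ and correction curves must share a time grid")
    corrected = (
        organ_curve.values * (geom.v_voxel / geom.v_tissue)
        - correction_curve.values * (geom.v_residual / geom.v_tissue)
    )
    if np.any(corrected < 0):
        warnings.warn(
            f"residual-tissue correction produced {int(np.sum(corrected < 0))} "
            f"negative value(s) in '{organ_curve.roi_label}'; retained",
            NegativeValueWarning,
            stacklevel=2,
        )
    return ConcentrationCurve(
        times=organ_curve.times,
        values=corrected,
        roi_label=organ_curve.roi_label,
        smoothed=organ_curve.smoothed,
    )


def body_surface_area(bw: float) -> float:
    """Allometric canine body surface, ``0.1 * BW[kg]^0.667`` in m^2."""
    if bw <= 0:
        raise ValueError("body weight must be > 0")
    return 0.1 * bw**0.667


def contrast_volume_per_kg(
    dose_mmol_per_kg: float = 0.1, stock_mmol_per_ml: float = 0.5
) -> float:
    """Injected contrast volume per kg implied by molar dose and stock strength (mL/kg)."""
    if stock_mmol_per_ml <= 0:
        raise ValueError("stock concentration must be > 0")
    return dose_mmol_per_kg / stock_mmol_per_ml


def smoothing_window_span(window_frames: int = 15, frame_interval: float = 0.58) -> float:
    """Temporal span (s) covered by a smoothing window of ``window_frames`` frames."""
    return window_frames * frame_interval
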