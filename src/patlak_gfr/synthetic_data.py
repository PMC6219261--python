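"""Ground-truth synthetic subjects: AIF, two-compartment kidneys, noise, images.

No scan data accompany the method, so every pipeline stage is validated
against subjects generated here.  The arterial input is a gamma-variate first
pass plus a delayed, broadened recirculation pass and a slow distribution
tail; kidney curves follow the forward two-compartment model

    c_kidney(t) = [V_vas * c_aorta(t - dt) + p*V_vas * int_0^{t-dt} c_aorta] / V_kidney

whose Patlak slope is exactly p*V_vas.  Observed signal curves are produced
by voxel-mixing each tissue curve with a residual-tissue curve, inverting the
calibration map, and (optionally) adding Gaussian plus breathing noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .calibration import CalibrationModel, concentration_to_si, default_model
from .errors import NegativeValueWarning
from .preprocessing import (
    ConcentrationCurve,
    DynamicSeries,
    RoiSet,
    SignalCurve,
    Subject,
    TissueGeometry,
    body_surface_area,
)

__all__ = [
    "KidneyTruth",
    "NoiseModel",
    "SyntheticTruth",
    "SyntheticSubject",
    "default_truth",
    "default_noise",
    "generate_aif",
    "generate_kidney_curve",
    "add_measurement_noise",
    "make_subject",
    "render_dynamic_series",
    "generate_dilution_table",
    "true_landmarks",
    "expected_slope",
    "expected_gfr",
]

#: Fraction of each thick-slice ROI voxel actually occupied by organ tissue.
TISSUE_FRACTION = {"aorta": 0.35, "kidney": 0.55, "cortex": 0.50}


@dataclass
class KidneyTruth:
    """Forward-model parameters of one kidney (or cortex) compartment."""

    v_vas: float  # mL, vascular volume inside the ROI
    v_kidney: float  # mL, organ volume inside the ROI
    p: float  # 1/s, proportionality (filtration) constant
    delta_t: float = 4.8  # s, aorta-to-organ bolus delay

    def __post_init__(self) -> None:
        if self.p < 0 or self.delta_t < 0:
            raise ValueError("p and delta_t must be >= 0")
        if not (0 < self.v_vas < self.v_kidney):
            raise ValueError("need 0 < v_vas < v_kidney")


@dataclass
class NoiseModel:
    """Measurement-noise parameters applied to rendered signal curves."""

    gaussian_sd_frac: float = 0.0  # sd as fraction of the curve's peak value
    breathing_amplitude_frac: float = 0.0  # multiplicative sinusoid amplitude
    breathing_period_s: float = 4.0

    def __post_init__(self) -> None:
        if self.gaussian_sd_frac < 0 or self.breathing_amplitude_frac < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if self.breathing_period_s <= 0:
            raise ValueError("breathing period must be > 0")


@dataclass
class SyntheticTruth:
    """Complete parameter set of one synthetic subject."""

    # arterial input
    arrival_s: float = 12.0
    peak_time_s: float = 8.43  # s after arrival
    peak_concentration: float = 70.0  # mmol/L; observed range 17-125
    gamma_shape: float = 3.3
    recirc_delay_s: float = 24.0  # first-pass to second-pass peak delay
    recirc_fraction: float = 0.32  # second max relative to first (< 1)
    recirc_shape: float = 2.6  # broader second pass
    tail_fraction: float = 0.10  # slow distribution-phase plateau
    tail_rise_s: float = 15.0
    washout_rate: float = 0.008  # 1/s
    # sampling
    frame_interval: float = 0.58
    duration_s: float = 180.0
    # organs
    left: KidneyTruth = field(
        default_factory=lambda: KidneyTruth(v_vas=6.0, v_kidney=45.0, p=0.044910)
    )
    right: KidneyTruth = field(
        default_factory=lambda: KidneyTruth(v_vas=6.0, v_kidney=45.0, p=0.042433)
    )
    cortex_left: KidneyTruth = field(
        default_factory=lambda: KidneyTruth(v_vas=1.8, v_kidney=20.0, p=0.09)
    )
    cortex_right: KidneyTruth = field(
        default_factory=lambda: KidneyTruth(v_vas=1.8, v_kidney=20.0, p=0.09)
    )
    # residual-tissue enhancement: a small, delayed, heavily damped AIF copy
    residual_fraction: float = 0.05
    residual_delay_s: float = 3.0
    residual_peak_time_s: float = 25.0
    residual_shape: float = 1.2
    # subject metadata
    body_weight_kg: float = 17.5
    hematocrit: float = 0.47
    # noise
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.recirc_fraction < 1):
            raise ValueError("recirculation fraction must lie in [0, 1)")
        if self.peak_concentration <= 0 or self.peak_time_s <= 0:
            raise ValueError("AIF peak parameters must be positive")
        if self.frame_interval <= 0 or self.duration_s <= 0:
            raise ValueError("sampling parameters must be positive")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.duration_s / self.frame_interval)) + 1
        return np.arange(n) * self.frame_interval

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticTruth":
        payload = dict(payload)
        for key in ("left", "right", "cortex_left", "cortex_right"):
            if key in payload and isinstance(payload[key], dict):
                payload[key] = KidneyTruth(**payload[key])
        if "noise" in payload and isinstance(payload["noise"], dict):
            payload["noise"] = NoiseModel(**payload["noise"])
        return cls(**payload)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SyntheticSubject:
    """A generated subject: truth, observable curves, geometry and metadata."""

    truth: SyntheticTruth
    subject: Subject
    geometry: dict[str, TissueGeometry]
    si_curves: dict[str, SignalCurve]  # observed (noisy) baseline-subtracted SI
    conc_truth: dict[str, ConcentrationCurve]  # noiseless tissue concentrations
    calibration: CalibrationModel


def default_truth(**overrides) -> SyntheticTruth:
    """Default truth targeting the published mean landmark times and GFRs."""
    return replace(SyntheticTruth(), **overrides) if overrides else SyntheticTruth()


def default_noise() -> NoiseModel:
    """Reference noise level: 3% Gaussian, 5% breathing at 4 s period."""
    return NoiseModel(
        gaussian_sd_frac=0.03, breathing_amplitude_frac=0.05, breathing_period_s=4.0
    )


def _gamma_variate(t: np.ndarray, t_peak: float, shape: float) -> np.ndarray:
    """Gamma-variate bolus shape normalised to peak 1 at ``t_peak``; 0 for t <= 0."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    z = t[pos] / t_peak
    out[pos] = z**shape * np.exp(shape * (1.0 - z))
    return out


def _aif_shape(truth: SyntheticTruth, t_rel: np.ndarray) -> np.ndarray:
    """Unnormalised AIF shape on times relative to arrival."""
    first = _gamma_variate(t_rel, truth.peak_time_s, truth.gamma_shape)
    second = truth.recirc_fraction * _gamma_variate(
        t_rel - truth.recirc_delay_s, truth.peak_time_s, truth.recirc_shape
    )
    pos = np.clip(t_rel, 0.0, None)
    tail = (
        truth.tail_fraction
        * (1.0 - np.exp(-pos / truth.tail_rise_s))
        * np.exp(-truth.washout_rate * pos)
    )
    tail[t_rel <= 0] = 0.0
    return first + second + tail


def aif_values(truth: SyntheticTruth, times: np.ndarray) -> np.ndarray:
    """AIF concentration at arbitrary times, scaled so the max equals the peak parameter."""
    fine = np.arange(0.0, truth.recirc_delay_s + 3 * truth.peak_time_s, 0.005)
    scale = truth.peak_concentration / _aif_shape(truth, fine).max()
    return scale * _aif_shape(truth, np.asarray(times, dtype=float) - truth.arrival_s)


def generate_aif(truth: SyntheticTruth, times: np.ndarray | None = None) -> ConcentrationCurve:
    """Arterial input on the subject's sampling grid (or a supplied grid)."""
    times = truth.times if times is None else np.asarray(times, dtype=float)
    return ConcentrationCurve(times=times, values=aif_values(truth, times), roi_label="aorta_all")


def generate_kidney_curve(
    aif: ConcentrationCurve, organ: KidneyTruth, roi_label: str = "kidney"
) -> ConcentrationCurve:
    """Forward two-compartment organ curve from the AIF (trapezoidal integral)."""
    t = aif.times
    shifted = np.interp(t - organ.delta_t, t, aif.values, left=0.0)
    integral = cumulative_trapezoid(aif.values, t, initial=0.0)
    shifted_integral = np.interp(t - organ.delta_t, t, integral, left=0.0)
    values = (organ.v_vas * shifted + organ.p * organ.v_vas * shifted_integral) / organ.v_kidney
    return ConcentrationCurve(times=t, values=values, roi_label=roi_label)


def _residual_curve(truth: SyntheticTruth, times: np.ndarray, roi_label: str) -> ConcentrationCurve:
    t_rel = np.asarray(times, dtype=float) - truth.arrival_s - truth.residual_delay_s
    values = (
        truth.residual_fraction
        * truth.peak_concentration
        * _gamma_variate(t_rel, truth.residual_peak_time_s, truth.residual_shape)
    )
    return ConcentrationCurve(times=times, values=values, roi_label=roi_label)


def add_measurement_noise(curve, noise: NoiseModel, seed, *, breathing_phase: float = 0.0):
    """Gaussian noise (sd = fraction of the curve's peak) plus breathing sinusoid.

    The breathing artefact is multiplicative on the local signal.  ``seed``
    may be an integer or a ``numpy.random.Generator``; fixed seeds give
    bitwise-identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.array(curve.values, dtype=float)
    peak = float(np.max(np.abs(values))) if len(values) else 0.0
    if noise.breathing_amplitude_frac > 0:
        osc = np.sin(2 * np.pi * curve.times / noise.breathing_period_s + breathing_phase)
        values = values * (1.0 + noise.breathing_amplitude_frac * osc)
    if noise.gaussian_sd_frac > 0:
        values = values + rng.normal(0.0, noise.gaussian_sd_frac * peak, size=values.shape)
    return replace(curve, values=values)


def _default_geometry(truth: SyntheticTruth) -> dict[str, TissueGeometry]:
    def geom(v_tissue: float, kind: str) -> TissueGeometry:
        return TissueGeometry(v_voxel=v_tissue / TISSUE_FRACTION[kind], v_tissue=v_tissue)

    return {
        "aorta_all": geom(8.0, "aorta"),
        "kidney_left": geom(truth.left.v_kidney, "kidney"),
        "kidney_right": geom(truth.right.v_kidney, "kidney"),
        "cortex_left": geom(truth.cortex_left.v_kidney, "cortex"),
        "cortex_right": geom(truth.cortex_right.v_kidney, "cortex"),
    }


def _mix_voxel(
    tissue: ConcentrationCurve, residual: ConcentrationCurve, geom: TissueGeometry
) -> ConcentrationCurve:
    values = (
        tissue.values * geom.v_tissue + residual.values * geom.v_residual
    ) / geom.v_voxel
    return replace(tissue, values=values)


def _to_si(curve: ConcentrationCurve, model: CalibrationModel) -> SignalCurve:
    floor = model.conc_at_zero_si
    values = curve.values
    if np.any(values < floor):
        warnings.warn(
            f"{int(np.sum(values < floor))} concentration value(s) below the "
            "calibration domain clamped to its minimum during rendering",
            NegativeValueWarning,
            stacklevel=2,
        )
        values = np.clip(values, floor, None)
    return SignalCurve(
        times=curve.times,
        values=concentration_to_si(values, model),
        roi_label=curve.roi_label,
    )


def make_subject(
    truth: SyntheticTruth,
    *,
    seed: int | None = None,
    calibration: CalibrationModel | None = None,
) -> SyntheticSubject:
    """Generate a full subject: tissue truth curves plus observed SI curves.

    The observed curves are baseline-subtracted mean-SI traces per ROI, built
    by voxel-mixing each tissue curve with its residual-tissue neighbour,
    inverting the calibration, and applying the truth's noise model.
    """
    calibration = calibration or default_model()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    geometry = _default_geometry(truth)
    times = truth.times

    aif = generate_aif(truth)
    conc_truth: dict[str, ConcentrationCurve] = {
        "aorta_all": aif,
        "kidney_left": generate_kidney_curve(aif, truth.left, "kidney_left"),
        "kidney_right": generate_kidney_curve(aif, truth.right, "kidney_right"),
        "cortex_left": generate_kidney_curve(aif, truth.cortex_left, "cortex_left"),
        "cortex_right": generate_kidney_curve(aif, truth.cortex_right, "cortex_right"),
    }
    residuals = {
        "correction_aorta": _residual_curve(truth, times, "correction_aorta"),
        "correction_left": _residual_curve(truth, times, "correction_left"),
        "correction_right": _residual_curve(truth, times, "correction_right"),
    }

    si_curves: dict[str, SignalCurve] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeValueWarning)
        for label in sorted(conc_truth):
            mixed = _mix_voxel(conc_truth[label], residuals[_correction_label(label)], geometry[label])
            si_curves[label] = _to_si(mixed, calibration)
        for label in sorted(residuals):
            si_curves[label] = _to_si(residuals[label], calibration)

    breathing_phase = float(rng.uniform(0.0, 2 * np.pi))
    for label in sorted(si_curves):
        si_curves[label] = add_measurement_noise(
            si_curves[label], truth.noise, rng, breathing_phase=breathing_phase
        )

    subject = Subject(
        id=f"synthetic-{truth.seed if seed is None else seed}",
        body_weight=truth.body_weight_kg,
        hematocrit=truth.hematocrit,
    )
    return SyntheticSubject(
        truth=truth,
        subject=subject,
        geometry=geometry,
        si_curves=si_curves,
        conc_truth=conc_truth,
        calibration=calibration,
    )


def _correction_label(organ_label: str) -> str:
    if organ_label == "aorta_all":
        return "correction_aorta"
    return "correction_left" if organ_label.endswith("left") else "correction_right"


# --------------------------------------------------------------------------
# image rendering


def _ellipse(shape: tuple[int, int], center: tuple[float, float], semi: tuple[float, float]) -> np.ndarray:
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return ((yy - center[0]) / semi[0]) ** 2 + ((xx - center[1]) / semi[1]) ** 2 <= 1.0


def _box(shape: tuple[int, int], r0: int, c0: int, h: int, w: int) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[r0 : r0 + h, c0 : c0 + w] = True
    return m


def build_roi_masks(shape: tuple[int, int] = (64, 64)) -> dict[str, np.ndarray]:
    """Simple geometric ROI layout: aortic band, kidney ellipses, cortex rims."""
    aorta = _box(shape, 6, 30, 48, 4)
    kid_l_outer = _ellipse(shape, (26.0, 14.0), (11.0, 7.0))
    kid_r_outer = _ellipse(shape, (26.0, 49.0), (11.0, 7.0))
    kid_l_inner = _ellipse(shape, (26.0, 14.0), (7.0, 4.5))
    kid_r_inner = _ellipse(shape, (26.0, 49.0), (7.0, 4.5))
    return {
        "aorta_all": aorta,
        "kidney_left": kid_l_inner,
        "kidney_right": kid_r_inner,
        "cortex_left": kid_l_outer & ~kid_l_inner,
        "cortex_right": kid_r_outer & ~kid_r_inner,
        "correction_aorta": _box(shape, 6, 36, 4, 4),
        "correction_left": _box(shape, 44, 10, 4, 4),
        "correction_right": _box(shape, 44, 50, 4, 4),
        "a_renalis_dexter": _box(shape, 44, 30, 5, 3),
        "highest_si": _box(shape, 24, 30, 5, 3),
    }


def render_dynamic_series(
    subject: SyntheticSubject,
    calibration: CalibrationModel | None = None,
    *,
    shape: tuple[int, int] = (64, 64),
    baseline_offset: float = 100.0,
    seed: int | None = None,
) -> tuple[DynamicSeries, RoiSet]:
    """Paint the subject's voxel-mixed SI curves into a 2D dynamic series.

    Frames carry a constant baseline offset so the subtraction procedure is
    exercised; per-voxel Gaussian noise and a global breathing modulation are
    added according to the subject's noise model.
    """
    calibration = calibration or subject.calibration
    truth = subject.truth
    times = truth.times
    masks = build_roi_masks(shape)
    rng = np.random.default_rng(truth.seed if seed is None else seed)

    # noiseless per-region enhancement curves (aorta variants share the lumen curve)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NegativeValueWarning)
        region_si: dict[str, np.ndarray] = {}
        residuals = {
            label: _residual_curve(truth, times, label)
            for label in ("correction_aorta", "correction_left", "correction_right")
        }
        for label in ("aorta_all", "kidney_left", "kidney_right", "cortex_left", "cortex_right"):
            mixed = _mix_voxel(
                subject.conc_truth[label], residuals[_correction_label(label)], subject.geometry[label]
            )
            region_si[label] = _to_si(mixed, calibration).values
        for label, res in residuals.items():
            region_si[label] = _to_si(res, calibration).values

    n_t = len(times)
    enhancement = np.zeros((n_t,) + shape)
    paint_order = [
        "cortex_left",
        "cortex_right",
        "kidney_left",
        "kidney_right",
        "aorta_all",
        "correction_aorta",
        "correction_left",
        "correction_right",
    ]
    for label in paint_order:
        enhancement[:, masks[label]] = region_si[label][:, None]
    # the small aorta variants sample the same lumen signal
    for label in ("a_renalis_dexter", "highest_si"):
        enhancement[:, masks[label]] = region_si["aorta_all"][:, None]

    noise = truth.noise
    if noise.breathing_amplitude_frac > 0:
        phase = float(rng.uniform(0.0, 2 * np.pi))
        osc = 1.0 + noise.breathing_amplitude_frac * np.sin(
            2 * np.pi * times / noise.breathing_period_s + phase
        )
        enhancement *= osc[:, None, None]
    if noise.gaussian_sd_frac > 0:
        sd = noise.gaussian_sd_frac * float(region_si["aorta_all"].max())
        enhancement += rng.normal(0.0, sd, size=enhancement.shape)

    frames = baseline_offset + enhancement
    frames[: 3] = baseline_offset  # pre-contrast reference frames
    series = DynamicSeries(frames=frames, frame_interval=truth.frame_interval)
    return series, RoiSet(masks=masks)


# --------------------------------------------------------------------------
# dilution emulation and truth summaries


def generate_dilution_table(
    model: CalibrationModel,
    concentrations,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    replicates: int = 4,
):
    """Emulated serial dilution: render SI per tube, average replicate reads."""
    from .calibration import DilutionTable

    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= model.a):
        raise ValueError("concentration outside the calibration domain")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    si_true = concentration_to_si(conc, model)
    reads = si_true[None, :] + rng.normal(0.0, noise_sd, size=(replicates, len(conc)))
    return DilutionTable(concentration=conc, mean_si=reads.mean(axis=0))


def true_landmarks(truth: SyntheticTruth, dt: float = 0.005) -> dict[str, float]:
    """Noiseless landmark times/values computed on a fine grid (generator truth)."""
    t_end = truth.arrival_s + truth.recirc_delay_s + 4 * truth.peak_time_s
    fine = np.arange(0.0, t_end, dt)
    aif = generate_aif(truth, fine)
    v = aif.values
    i_max1 = int(np.argmax(v))
    # search the recirculation peak after the inter-pass minimum
    i_lo = i_max1 + int(np.argmin(v[i_max1 : i_max1 + int(truth.recirc_delay_s / dt)]))
    i_max2 = i_lo + int(np.argmax(v[i_lo:]))
    out = {
        "t_arrival": truth.arrival_s,
        "t_aorta_max1": float(fine[i_max1]),
        "c_aorta_max1": float(v[i_max1]),
        "t_aorta_min1": float(fine[i_lo]),
        "c_aorta_min1": float(v[i_lo]),
        "t_aorta_max2": float(fine[i_max2]),
        "c_aorta_max2": float(v[i_max2]),
    }
    from scipy.signal import find_peaks

    for side in ("left", "right"):
        organ: KidneyTruth = getattr(truth, side)
        curve = generate_kidney_curve(aif, organ)
        # first local maximum above half the global max (same rule as detection)
        peaks, _ = find_peaks(
            curve.values, height=0.5 * curve.values.max(), distance=max(int(1.0 / dt), 1)
        )
        j = int(peaks[0]) if len(peaks) else int(np.argmax(curve.values))
        out[f"t_kidney_max1_{side}"] = float(fine[j])
        out[f"c_kidney_max1_{side}"] = float(curve.values[j])
    return out


def roi_sensitivity_study(
    n_seeds: int = 20,
    *,
    truth: SyntheticTruth | None = None,
    voxel_noise_frac: float = 0.10,
    variants: tuple[str, ...] = ("aorta_all", "a_renalis_dexter", "highest_si"),
) -> dict[str, list[float]]:
    """Total-GFR estimates per aortic-ROI variant across seeded noisy renders.

    Mirrors the in-vivo comparison of a full-lumen aortic ROI against two
    small 3x5-voxel boxes (one distal, one at the highest-signal point): with
    independent per-voxel noise, larger ROIs average more voxels and the
    spread of the GFR estimates shrinks.
    """
    from .patlak import run_subject_pipeline
    from .preprocessing import extract_roi_mean, subtract_baseline

    base = truth or replace(default_truth(), noise=default_noise())
    base = replace(base, noise=replace(base.noise, gaussian_sd_frac=voxel_noise_frac))
    out: dict[str, list[float]] = {v: [] for v in variants}
    needed = (
        "kidney_left",
        "kidney_right",
        "correction_aorta",
        "correction_left",
        "correction_right",
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seed in range(n_seeds):
            subj = make_subject(replace(base, seed=seed), seed=seed)
            series, rois = render_dynamic_series(subj, seed=seed)
            sub = subtract_baseline(series)
            curves = {n: extract_roi_mean(sub, rois[n], roi_label=n) for n in needed}
            for variant in variants:
                curves_v = dict(curves)
                curves_v["aorta_all"] = extract_roi_mean(
                    sub, rois[variant], roi_label="aorta_all"
                )
                result = run_subject_pipeline(
                    curves=curves_v,
                    geometry=subj.geometry,
                    subject=subj.subject,
                    calibration=subj.calibration,
                )
                out[variant].append(result.gfr_total)
    return out


def expected_slope(organ: KidneyTruth) -> float:
    """Ground-truth Patlak slope p*V_vas (mL/s)."""
    return organ.p * organ.v_vas


def expected_gfr(truth: SyntheticTruth, side: str) -> float:
    """Ground-truth plasma GFR of one kidney (mL/min/m^2 BS)."""
    organ: KidneyTruth = getattr(truth, side)
    bs = body_surface_area(truth.body_weight_kg)
    return expected_slope(organ) * 60.0 / bs * (1.0 - truth.hematocrit)
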