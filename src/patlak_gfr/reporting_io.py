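"""File formats, cohort summaries and result plots.

Curve CSVs use the schema ``time_s, value, roi_label`` with a leading
``# units: si`` or ``# units: mmol_per_L`` comment; reports are written as
schema-versioned JSON or one flat CSV row per kidney.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError, UnknownRoiWarning
from .landmarks import BolusLandmarks
from .patlak import GfrResult, PatlakFit, PatlakPoints
from .preprocessing import ConcentrationCurve, SignalCurve

__all__ = [
    "CohortSummary",
    "KNOWN_ROI_LABELS",
    "load_curves_csv",
    "write_curves_csv",
    "summarize_cohort",
    "write_report",
    "plot_rpp",
    "plot_landmark_boxplots",
]

REPORT_SCHEMA_VERSION = "1.0"

KNOWN_ROI_LABELS = {
    "aorta_all",
    "kidney_left",
    "kidney_right",
    "cortex_left",
    "cortex_right",
    "correction_aorta",
    "correction_left",
    "correction_right",
    "a_renalis_dexter",
    "highest_si",
}


@dataclass
class CohortSummary:
    """Cohort means and sample standard deviations over successful subjects."""

    n_subjects: int
    gfr_mean: dict[str, float]  # keys: left, right, total
    gfr_sd: dict[str, float | None]
    r_squared_mean: float
    r_squared_sd: float | None
    landmark_time_mean: dict[str, float] = field(default_factory=dict)
    landmark_time_sd: dict[str, float | None] = field(default_factory=dict)
    landmark_conc_mean: dict[str, float] = field(default_factory=dict)
    landmark_conc_sd: dict[str, float | None] = field(default_factory=dict)
    paired_t_p_value: float | None = None
    subject_ids: list[str] = field(default_factory=list)


def write_curves_csv(curves: dict, path: str | Path, units: str = "si") -> None:
    """Write per-ROI curves to CSV with a units comment header."""
    if units not in ("si", "mmol_per_L"):
        raise ValueError("units must be 'si' or 'mmol_per_L'")
    rows = []
    for label, curve in curves.items():
        rows.append(
            pd.DataFrame(
                {"time_s": curve.times, "value": curve.values, "roi_label": label}
            )
        )
    df = pd.concat(rows, ignore_index=True)
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, index=False)


def load_curves_csv(path: str | Path) -> tuple[dict, str]:
    """Read per-ROI curves grouped by label; returns (curves, units)."""
    path = Path(path)
    units = "si"
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#"):
        if "mmol_per_L" in first:
            units = "mmol_per_L"
        elif "si" not in first:
            raise SchemaError(f"unrecognised units comment: {first.strip()}")
    # round_trip parsing: the default C float parser can be off by one ulp
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    value_col = "value" if "value" in df.columns else "mean_si"
    required = {"time_s", value_col, "roi_label"}
    if not required.issubset(df.columns):
        raise SchemaError(
            f"curves CSV needs columns (time_s, value|mean_si, roi_label); got {list(df.columns)}"
        )
    cls = ConcentrationCurve if units == "mmol_per_L" else SignalCurve
    curves = {}
    for label, grp in df.groupby("roi_label", sort=False):
        if label not in KNOWN_ROI_LABELS:
            warnings.warn(f"unknown ROI label '{label}'", UnknownRoiWarning, stacklevel=2)
        times = grp["time_s"].to_numpy()
        dt = np.diff(times)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise SchemaError(f"non-uniform time grid for ROI '{label}'")
        curves[label] = cls(times=times, values=grp[value_col].to_numpy(), roi_label=label)
    return curves, units


def _mean_sd(values: list[float]) -> tuple[float, float | None]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None  # sample sd; n=1 -> n/a
    return mean, sd


def summarize_cohort(
    results: list[GfrResult],
    landmarks: list[BolusLandmarks] | None = None,
    *,
    paired_t_test: bool = False,
) -> CohortSummary:
    """Arithmetic means and sample standard deviations across subjects."""
    if not results:
        raise ValueError("need at least one subject result")
    left = [r.gfr_left for r in results]
    right = [r.gfr_right for r in results]
    total = [r.gfr_total for r in results]
    r2 = [f.r_squared for r in results for f in (r.fit_left, r.fit_right) if f is not None]

    gfr_mean, gfr_sd = {}, {}
    for key, vals in (("left", left), ("right", right), ("total", total)):
        gfr_mean[key], gfr_sd[key] = _mean_sd(vals)
    r2_mean, r2_sd = _mean_sd(r2)

    lt_mean: dict[str, float] = {}
    lt_sd: dict[str, float | None] = {}
    lc_mean: dict[str, float] = {}
    lc_sd: dict[str, float | None] = {}
    if landmarks:
        time_keys = ("t_aorta_max1", "t_aorta_min1", "t_aorta_max2", "t_kidney_max1")
        conc_keys = ("c_aorta_max1", "c_aorta_min1", "c_aorta_max2", "c_kidney_max1")
        for key in time_keys:
            vals = [
                getattr(lm, key) - lm.t_arrival
                for lm in landmarks
                if getattr(lm, key) is not None
            ]
            if vals:
                lt_mean[key], lt_sd[key] = _mean_sd(vals)
        for key in conc_keys:
            vals = [getattr(lm, key) for lm in landmarks if getattr(lm, key) is not None]
            if vals:
                lc_mean[key], lc_sd[key] = _mean_sd(vals)
        dts = [lm.delta_t for lm in landmarks if lm.delta_t is not None]
        if dts:
            lt_mean["delta_t"], lt_sd["delta_t"] = _mean_sd(dts)

    p_value = None
    if paired_t_test and len(results) > 1:
        from scipy.stats import ttest_rel

        p_value = float(ttest_rel(left, right).pvalue)

    return CohortSummary(
        n_subjects=len(results),
        gfr_mean=gfr_mean,
        gfr_sd=gfr_sd,
        r_squared_mean=r2_mean,
        r_squared_sd=r2_sd,
        landmark_time_mean=lt_mean,
        landmark_time_sd=lt_sd,
        landmark_conc_mean=lc_mean,
        landmark_conc_sd=lc_sd,
        paired_t_p_value=p_value,
        subject_ids=[r.subject_id for r in results],
    )


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_report(result, path: str | Path, format: str = "json") -> Path:
    """Write a :class:`GfrResult` or :class:`CohortSummary` to JSON or CSV."""
    path = Path(path)
    if format == "json":
        payload = {"schema_version": REPORT_SCHEMA_VERSION, **_jsonify(asdict(result))}
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif format == "csv":
        if isinstance(result, GfrResult):
            rows = []
            for side in ("left", "right"):
                fit: PatlakFit | None = getattr(result, f"fit_{side}")
                row = {
                    "subject_id": result.subject_id,
                    "kidney": side,
                    "gfr_ml_min_m2": getattr(result, f"gfr_{side}"),
                    "gfr_total_ml_min_m2": result.gfr_total,
                }
                if fit is not None:
                    row.update(
                        slope_ml_s=fit.slope_m,
                        intercept_ml=fit.intercept_b,
                        r_squared=fit.r_squared,
                        n_points=fit.n_points,
                    )
                rows.append(row)
            pd.DataFrame(rows).to_csv(path, index=False)
        else:
            pd.json_normalize(_jsonify(asdict(result))).to_csv(path, index=False)
    else:
        raise ValueError("format must be 'json' or 'csv'")
    return path


def plot_rpp(points: PatlakPoints, fit: PatlakFit, path: str | Path, title: str = "") -> Path:
    """Scatter of the Patlak points with the fitted trend line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(points.x, points.y, "o", ms=3, alpha=0.6, label="RPP points")
    xs = np.array([points.x.min(), points.x.max()])
    ax.plot(xs, fit.intercept_b + fit.slope_m * xs, "k-", label=f"fit (R$^2$={fit.r_squared:.3f})")
    ax.set_xlabel("$\\int c_{aorta}\\,dt' / c_{aorta}(t)$  [s]")
    ax.set_ylabel("$c_{kidney}(t+\\Delta t)\\,V_{kidney} / c_{aorta}(t)$  [mL]")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_landmark_boxplots(landmarks: list[BolusLandmarks], path: str | Path) -> Path:
    """Boxplots of landmark times (relative to arrival) across subjects."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = ("t_aorta_max1", "t_aorta_min1", "t_aorta_max2", "t_kidney_max1")
    data, labels = [], []
    for key in keys:
        vals = [
            getattr(lm, key) - lm.t_arrival for lm in landmarks if getattr(lm, key) is not None
        ]
        if vals:
            data.append(vals)
            labels.append(key.replace("t_", ""))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(data, tick_labels=labels)
    ax.set_ylabel("time after arrival [s]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
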