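"""Signal-intensity / contrast-concentration calibration from serial dilutions.

A dilution series of the gadolinium agent measured at known concentrations
yields a monotone map from MRI signal intensity (SI, arbitrary units) to
concentration (mmol/L).  Within the usable low-concentration range the map is
well described by an ascending exponential

    c(S) = a + b * exp(x * S)

which this module fits, compares against a cubic-polynomial alternative via
AIC, inverts, and applies element-wise.  The package ships a built-in default
parameter set (``default_model``) for use when no dilution data are at hand.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    CalibrationDomainError,
    CalibrationRangeWarning,
    InsufficientDataError,
    NonMonotoneWarning,
)

__all__ = [
    "DilutionTable",
    "CalibrationModel",
    "default_model",
    "fit_si_concentration_models",
    "aic_relative_likelihood",
    "si_to_concentration",
    "concentration_to_si",
]

# Gaussian-residual AIC: n*ln(RSS/n) + 2k, with k counting the fitted curve
# parameters plus the residual variance.
_K_EXPONENTIAL = 4  # a, b, x + sigma^2
_K_CUBIC = 5  # 4 polynomial coefficients + sigma^2


@dataclass
class DilutionTable:
    """Serial-dilution measurements: one mean SI per known concentration.

    Parameters
    ----------
    concentration : array-like
        Tube concentrations in mmol/L, strictly increasing, non-negative.
    mean_si : array-like
        Mean signal intensity per tube (averaged over replicate reads),
        arbitrary units.
    """

    concentration: np.ndarray
    mean_si: np.ndarray

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.mean_si = np.asarray(self.mean_si, dtype=float)
        if self.concentration.ndim != 1 or self.mean_si.ndim != 1:
            raise ValueError("dilution columns must be one-dimensional")
        if self.concentration.shape != self.mean_si.shape:
            raise ValueError("concentration and mean_si must have equal length")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be non-negative")
        if np.any(np.diff(self.concentration) <= 0):
            raise ValueError("concentrations must be strictly increasing")

    def __len__(self) -> int:
        return len(self.concentration)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DilutionTable":
        """Read a two-column CSV (concentration_mmol_per_L, mean_si)."""
        df = pd.read_csv(path, comment="#")
        required = {"concentration_mmol_per_L", "mean_si"}
        if not required.issubset(df.columns):
            from .errors import SchemaError

            raise SchemaError(
                f"dilution CSV needs columns {sorted(required)}, got {list(df.columns)}"
            )
        return cls(df["concentration_mmol_per_L"].to_numpy(), df["mean_si"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"concentration_mmol_per_L": self.concentration, "mean_si": self.mean_si}
        ).to_csv(path, index=False)


@dataclass
class CalibrationModel:
    """Parameters of the exponential SI-to-concentration map and its validity range."""

    a: float  # mmol/L, offset
    b: float  # mmol/L, scale (> 0)
    x: float  # 1/a.u., rate (> 0)
    si_valid_max: float = 1200.0
    conc_valid_max: float = 15.0
    aic_exponential: float | None = None
    aic_cubic: float | None = None
    cubic_coeffs: tuple[float, float, float, float] | None = field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("calibration scale b must be > 0")
        if self.x <= 0:
            raise ValueError("calibration rate x must be > 0")
        if self.si_valid_max <= 0:
            raise ValueError("si_valid_max must be > 0")

    @property
    def conc_at_zero_si(self) -> float:
        """Concentration the map assigns to SI = 0 (a + b, small but non-zero)."""
        return self.a + self.b

    def to_json(self, path: str | Path) -> None:
        payload = {
            "a": self.a,
            "b": self.b,
            "x": self.x,
            "si_valid_max": self.si_valid_max,
            "conc_valid_max": self.conc_valid_max,
        }
        if self.aic_exponential is not None:
            payload["aic_exponential"] = self.aic_exponential
        if self.aic_cubic is not None:
            payload["aic_cubic"] = self.aic_cubic
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            a=payload["a"],
            b=payload["b"],
            x=payload["x"],
            si_valid_max=payload.get("si_valid_max", 1200.0),
            conc_valid_max=payload.get("conc_valid_max", 15.0),
            aic_exponential=payload.get("aic_exponential"),
            aic_cubic=payload.get("aic_cubic"),
        )


def default_model() -> CalibrationModel:
    """The package's built-in calibration constants (not refittable without tubes)."""
    with resources.files("patlak_gfr.data").joinpath("calibration_default.json").open() as fh:
        payload = json.load(fh)
    return CalibrationModel(**payload)


def _exponential(si: np.ndarray, a: float, b: float, x: float) -> np.ndarray:
    return a + b * np.exp(x * si)


def _inverse_exponential(conc: np.ndarray, a: float, b: float, x: float) -> np.ndarray:
    return np.log((conc - a) / b) / x


def fit_si_concentration_models(
    table: DilutionTable, si_max: float = 1200.0
) -> CalibrationModel:
    """Fit concentration-on-SI models to the dilution rows with SI <= ``si_max``.

    The exponential ``c = a + b*exp(x*S)`` is fitted by nonlinear least
    squares minimising residuals in SI (measurement noise enters through the
    SI reads, so this is the consistent direction; the returned object is
    still the concentration-from-SI map).  A cubic polynomial in SI is fitted
    to the same points for comparison, and both AICs are recorded on the
    returned model using the identical Gaussian-residual formula
    ``n*ln(RSS/n) + 2k`` on concentration residuals.

    Raises
    ------
    InsufficientDataError
        Fewer than 5 in-range rows, or no concentration variation at all.
    """
    mask = table.mean_si <= si_max
    si = table.mean_si[mask]
    conc = table.concentration[mask]
    if np.ptp(conc) == 0:
        raise InsufficientDataError(
            "degenerate dilution: constant concentration carries no signal"
        )
    # SI must increase with concentration in the fit range; if it turns over
    # (T2* decline) keep the longest monotone prefix and warn.
    diffs = np.diff(si)
    if np.any(diffs <= 0):
        cut = int(np.argmax(diffs <= 0)) + 1
        warnings.warn(
            f"SI not monotone in concentration; fitting the {cut}-row monotone prefix",
            NonMonotoneWarning,
            stacklevel=2,
        )
        si, conc = si[:cut], conc[:cut]
    if len(si) < 5:
        raise InsufficientDataError(
            f"need >= 5 dilution rows with SI <= {si_max}, have {len(si)}"
        )

    a0 = float(conc.min()) - 1.0
    b0 = 1.0
    x0 = math.log(max(conc.max() - a0, 1e-9) / b0) / max(si.max(), 1.0)
    p0 = (a0, b0, x0)
    # 'a' must stay below min(conc) for the SI-residual objective to be defined
    bounds = ([-np.inf, 1e-12, 1e-12], [float(conc.min()) - 1e-9, np.inf, np.inf])
    params = None
    rng = np.random.default_rng(0)
    for attempt in range(6):
        try:
            params, _ = curve_fit(
                _inverse_exponential,
                conc,
                si,
                p0=p0,
                bounds=bounds,
                maxfev=20000,
                xtol=1e-14,
                ftol=1e-14,
            )
            if params[1] > 0 and params[2] > 0:
                break
        except (RuntimeError, ValueError):
            pass
        # restart from a jittered initial guess
        p0 = (
            a0 * (1 + 0.3 * rng.standard_normal()),
            b0 * math.exp(0.5 * rng.standard_normal()),
            abs(x0) * math.exp(0.5 * rng.standard_normal()),
        )
        params = None
    if params is None or params[1] <= 0 or params[2] <= 0:
        raise InsufficientDataError("exponential calibration fit did not converge")
    a, b, x = (float(v) for v in params)

    n = len(si)
    rss_exp = float(np.sum((conc - _exponential(si, a, b, x)) ** 2))
    cubic = np.polyfit(si, conc, 3)
    rss_cub = float(np.sum((conc - np.polyval(cubic, si)) ** 2))
    tiny = 1e-300
    aic_exp = n * math.log(max(rss_exp, tiny) / n) + 2 * _K_EXPONENTIAL
    aic_cub = n * math.log(max(rss_cub, tiny) / n) + 2 * _K_CUBIC

    return CalibrationModel(
        a=a,
        b=b,
        x=x,
        si_valid_max=si_max,
        conc_valid_max=float(conc.max()),
        aic_exponential=aic_exp,
        aic_cubic=aic_cub,
        cubic_coeffs=tuple(float(c) for c in cubic),
    )


def aic_relative_likelihood(aic_low: float, aic_high: float) -> float:
    """Evidence ratio exp((aic_high - aic_low)/2) of the lower-AIC model."""
    if not (math.isfinite(aic_low) and math.isfinite(aic_high)):
        raise ValueError("AIC values must be finite")
    return math.exp((aic_high - aic_low) / 2.0)


def si_to_concentration(
    si, model: CalibrationModel, *, clip_out_of_range: bool = False
):
    """Map signal intensity to concentration, ``a + b*exp(x*S)`` (mmol/L).

    SI above ``model.si_valid_max`` is evaluated by extrapolation with a
    :class:`CalibrationRangeWarning` (optionally clipped to the boundary).
    Negative SI raises.
    """
    si_arr = np.asarray(si, dtype=float)
    if np.any(si_arr < 0):
        raise ValueError("signal intensity must be non-negative")
    if np.any(si_arr > model.si_valid_max):
        n_over = int(np.sum(si_arr > model.si_valid_max))
        warnings.warn(
            f"{n_over} SI value(s) exceed the calibrated range "
            f"(max {model.si_valid_max:g}); "
            + ("clipped" if clip_out_of_range else "extrapolated"),
            CalibrationRangeWarning,
            stacklevel=2,
        )
        if clip_out_of_range:
            si_arr = np.minimum(si_arr, model.si_valid_max)
    out = model.a + model.b * np.exp(model.x * si_arr)
    return float(out) if np.isscalar(si) else out


def concentration_to_si(c, model: CalibrationModel):
    """Strict inverse of :func:`si_to_concentration`: ``ln((c - a)/b)/x``.

    Defined for ``c > a``; note concentrations below ``a + b`` map to negative
    SI (below the map's value at SI = 0).
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr <= model.a):
        raise CalibrationDomainError(
            f"concentration must exceed the calibration offset a = {model.a:g}"
        )
    out = np.log((c_arr - model.a) / model.b) / model.x
    return float(out) if np.isscalar(c) else out
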