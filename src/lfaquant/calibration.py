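"""Calibration of the T/C ratio against log analyte quantity.

The assay response is linear in the decimal log of analyte mass: with
x = log10(quantity / 10 fg) the five standard classes (10 fg .. 100 pg) map
to x = 0..4, and ordinary least squares of T/C on x gives the calibration
line y = m x + b. From the fit:

    sigma = sqrt( sum (Y - Y')^2 / N )        standard error of detection
    R^2   = 1 - SS_res / SS_tot               coefficient of determination
    LOD   = LOB + 1.645 sigma / m             limit of detection (x scale)
    LOQ   = 10 sigma / m                      limit of quantification (x scale)
    CV    = 100 s / mu                        per-class coefficient of variation (%)

Note sigma deliberately uses divisor N (not N - 2): it is the RMS prediction
error of the calibration line, not an unbiased regression variance estimate.
LOB defaults to 0 in the absence of blank readings; given blanks it is their
mean + 1.645 x std. Unknown quantities are predicted by inverting the line:
quantity = 10 fg x 10^((T/C - b) / m).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from os import PathLike
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

__all__ = [
    "Reading",
    "CalibrationModel",
    "FitDiagnostics",
    "ClassStats",
    "fit_calibration",
    "r_squared",
    "std_error",
    "lod",
    "loq",
    "class_stats",
    "predict_quantity",
    "read_readings_csv",
    "write_readings_csv",
    "concentration_from_quantity",
    "quantity_from_concentration",
    "molarity_from_concentration",
]

REFERENCE_QUANTITY_FG = 10.0  # the lowest standard class; x = 0


@dataclass(frozen=True)
class Reading:
    """One T/C reading of a strip with known analyte quantity."""

    set_id: int
    quantity_fg: float
    tc_ratio: float
    reading_index: int = 0

    def __post_init__(self) -> None:
        if self.quantity_fg <= 0:
            raise ValueError(f"quantity must be > 0 fg, got {self.quantity_fg}")
        if self.tc_ratio < 0:
            raise ValueError(f"T/C ratio must be >= 0, got {self.tc_ratio}")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted line T/C = m x + b with x = log10(quantity / reference)."""

    slope: float
    intercept: float
    sigma: float = 0.0
    r2: float = 1.0
    lob: float = 0.0
    lod_x: float = 0.0
    loq_x: float = 0.0
    n: int = 0
    reference_quantity_fg: float = REFERENCE_QUANTITY_FG

    def x_from_quantity(self, quantity_fg: float) -> float:
        return float(np.log10(quantity_fg / self.reference_quantity_fg))

    def quantity_from_x(self, x: float) -> float:
        return float(self.reference_quantity_fg * 10.0**x)

    def predict_tc(self, quantity_fg: float) -> float:
        return self.slope * self.x_from_quantity(quantity_fg) + self.intercept

    def to_json(self) -> str:
        return json.dumps(
            {
                "slope": self.slope,
                "intercept": self.intercept,
                "sigma": self.sigma,
                "r2": self.r2,
                "lob": self.lob,
                "lod_x": self.lod_x,
                "loq_x": self.loq_x,
                "n": self.n,
                "reference_quantity_fg": self.reference_quantity_fg,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "CalibrationModel":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class FitDiagnostics:
    residuals: np.ndarray
    n: int
    ss_residual: float
    ss_total: float


@dataclass(frozen=True)
class ClassStats:
    """Mean, sample standard deviation and CV of one quantity class."""

    quantity_fg: float
    mean: float
    std: float
    cv_percent: Optional[float]  # None when the mean is zero (CV undefined)
    n: int


def fit_calibration(
    readings: Iterable[Reading],
    lob: float = 0.0,
    reference_quantity_fg: float = REFERENCE_QUANTITY_FG,
) -> Tuple[CalibrationModel, FitDiagnostics]:
    """Ordinary least squares of T/C on log10(quantity / reference).

    Returns the model (with sigma, R^2, LOD and LOQ populated) and the fit
    diagnostics. Requires at least two distinct quantities.
    """
    readings = list(readings)
    x = np.array([np.log10(r.quantity_fg / reference_quantity_fg) for r in readings])
    y = np.array([r.tc_ratio for r in readings])
    if len(np.unique(x)) < 2:
        raise DegenerateInputError("need >= 2 distinct quantities to fit a line")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    n = len(readings)
    diag = FitDiagnostics(residuals=resid, n=n, ss_residual=ss_res, ss_total=ss_tot)
    sigma = std_error(resid, n)
    model = CalibrationModel(
        slope=float(slope),
        intercept=float(intercept),
        sigma=sigma,
        r2=r_squared(diag),
        lob=lob,
        lod_x=lod(lob, sigma, float(slope)),
        loq_x=loq(sigma, float(slope)),
        n=n,
        reference_quantity_fg=reference_quantity_fg,
    )
    return model, diag


def r_squared(diag: FitDiagnostics) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    if diag.ss_total <= 0:
        raise DegenerateInputError("SS_total is zero; R^2 undefined")
    return 1.0 - diag.ss_residual / diag.ss_total


def std_error(residuals: Sequence[float], n: int) -> float:
    """Standard error of detection: RMS of residuals with divisor N."""
    if n < 1:
        raise ValueError("N must be >= 1")
    resid = np.asarray(residuals, dtype=np.float64)
    return float(np.sqrt((resid @ resid) / n))


def lod(lob: float, sigma: float, slope: float) -> float:
    """Limit of detection on the log-quantity axis: LOB + 1.645 sigma / m."""
    if slope == 0:
        raise ValueError("calibration slope is zero; LOD undefined")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return lob + 1.645 * sigma / slope


def loq(sigma: float, slope: float) -> float:
    """Limit of quantification on the log-quantity axis: 10 sigma / m."""
    if slope == 0:
        raise ValueError("calibration slope is zero; LOQ undefined")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return 10.0 * sigma / slope


def class_stats(readings: Iterable[Reading]) -> List[ClassStats]:
    """Per-quantity mean, sample (n-1) standard deviation and CV in percent.

    Classes are returned in descending quantity order (the order assay tables
    are conventionally printed in). Singleton classes raise, since the sample
    standard deviation is undefined.
    """
    df = pd.DataFrame(
        {"quantity_fg": [r.quantity_fg for r in readings],
         "tc_ratio": [r.tc_ratio for r in readings]}
    )
    if df.empty:
        raise DegenerateInputError("no readings")
    out: List[ClassStats] = []
    for q, grp in sorted(df.groupby("quantity_fg"), key=lambda kv: -kv[0]):
        vals = grp["tc_ratio"].to_numpy()
        if len(vals) < 2:
            raise DegenerateInputError(
                f"class {q} fg has a single reading; sample std undefined"
            )
        mu = float(vals.mean())
        s = float(vals.std(ddof=1))
        cv = 100.0 * s / mu if mu > 0 else None
        out.append(ClassStats(quantity_fg=float(q), mean=mu, std=s, cv_percent=cv, n=len(vals)))
    return out


def predict_quantity(tc: float, model: CalibrationModel) -> float:
    """Invert the calibration line: quantity (fg) whose calibrated T/C is ``tc``.

    Extrapolation beyond the calibrated range is permitted; callers should
    flag predictions outside the standard classes.
    """
    if model.slope <= 0:
        raise ValueError(f"calibration slope must be > 0, got {model.slope}")
    x = (tc - model.intercept) / model.slope
    return model.quantity_from_x(x)


# --- unit conversions ------------------------------------------------------
# Masses are carried in fg; concentrations in pg/mL. 1 pg/mL x 1 uL = 1 fg.


def concentration_from_quantity(quantity_fg: float, volume_ul: float) -> float:
    """Concentration (pg/mL) of ``quantity_fg`` dissolved in ``volume_ul``."""
    if volume_ul <= 0:
        raise ValueError(f"volume must be > 0 uL, got {volume_ul}")
    return quantity_fg / volume_ul


def quantity_from_concentration(concentration_pg_ml: float, volume_ul: float) -> float:
    """Analyte mass (fg) in ``volume_ul`` of a ``concentration_pg_ml`` solution."""
    if volume_ul <= 0:
        raise ValueError(f"volume must be > 0 uL, got {volume_ul}")
    return concentration_pg_ml * volume_ul


def molarity_from_concentration(concentration_pg_ml: float, molecular_weight_g_mol: float) -> float:
    """Molar concentration (nM) of a mass concentration given the molecular weight."""
    if molecular_weight_g_mol <= 0:
        raise ValueError("molecular weight must be > 0")
    # pg/mL = ng/L; ng/L / (g/mol) = nmol/L / 1e9 ... work in SI: g/L / (g/mol) = mol/L
    grams_per_liter = concentration_pg_ml * 1e-9
    molar = grams_per_liter / molecular_weight_g_mol
    return molar * 1e9  # nM


def read_readings_csv(path: Union[str, PathLike]) -> List[Reading]:
    """Load readings from a CSV with columns set_id, quantity_fg, reading_index, tc_ratio."""
    df = pd.read_csv(path)
    required = {"set_id", "quantity_fg", "reading_index", "tc_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"readings CSV missing columns: {sorted(missing)}")
    return [
        Reading(
            set_id=int(row.set_id),
            quantity_fg=float(row.quantity_fg),
            tc_ratio=float(row.tc_ratio),
            reading_index=int(row.reading_index),
        )
        for row in df.itertuples()
    ]


def write_readings_csv(readings: Iterable[Reading], path: Union[str, PathLike]) -> None:
    pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "quantity_fg": r.quantity_fg,
                "reading_index": r.reading_index,
                "tc_ratio": r.tc_ratio,
            }
            for r in readings
        ]
    ).to_csv(path, index=False)
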