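"""Beer-Lambert quantification: absorbance in, concentrations and amounts out.

A single measurement gives the stock molar concentration directly,

    c_stock = A260 / (MAC260 * l) * dilution,

reported in nM, with the mass concentration (ng/uL) following from the
molecular weight.  A serial-dilution series is fitted instead by ordinary
least squares of the mean replicate A260 against 1/dilution (with
intercept); the slope is the stock absorbance at the measurement path
length, which damps per-handling pipetting error, and a fitted intercept
beyond +/-0.005 AU flags a blank/baseline problem.

``fit_beer_lambert`` is the calibration direction: absorbance regressed on
known molar concentration, slope / path length as the molar absorption
coefficient estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, ValidationError
from .photometry import MacResult

__all__ = [
    "Measurement",
    "DilutionSeries",
    "FitDiagnostics",
    "QuantReport",
    "concentration_from_a260",
    "fit_dilution_series",
    "fit_beer_lambert",
    "totals",
    "INTERCEPT_WARN_AU",
]

#: Fitted intercepts beyond this magnitude (absorbance units) flag a
#: blank/baseline problem in a dilution series.
INTERCEPT_WARN_AU = 0.005


@dataclass(frozen=True)
class Measurement:
    """One absorbance reading of a diluted stock."""

    a260: float
    dilution: float = 1.0
    path_length: float = 1.0

    def __post_init__(self) -> None:
        if self.a260 < 0:
            raise ValidationError(f"a260 must be non-negative, got {self.a260}")
        if self.dilution < 1:
            raise ValidationError(f"dilution factor must be >= 1, got {self.dilution}")
        if self.path_length <= 0:
            raise ValidationError(f"path length must be positive, got {self.path_length}")


@dataclass(frozen=True)
class DilutionSeries:
    """Replicated absorbance readings at distinct fold-dilutions."""

    points: tuple[tuple[float, tuple[float, ...]], ...]
    path_length: float = 1.0

    def __post_init__(self) -> None:
        pts = tuple(
            (float(d), tuple(float(a) for a in reps)) for d, reps in self.points
        )
        object.__setattr__(self, "points", pts)
        if not pts:
            raise ValidationError("a dilution series needs at least one point")
        dils = [d for d, _ in pts]
        if len(set(dils)) != len(dils):
            raise DegenerateDesignError("dilution factors must be distinct")
        for d, reps in pts:
            if d < 1:
                raise ValidationError(f"dilution factor must be >= 1, got {d}")
            if not reps:
                raise ValidationError(f"dilution {d}: at least one replicate required")
            if any(a < 0 for a in reps):
                raise ValidationError(f"dilution {d}: negative absorbance")
        if self.path_length <= 0:
            raise ValidationError(f"path length must be positive, got {self.path_length}")

    @classmethod
    def from_csv(
        cls, source: Union[str, Path, IO[str]], path_length: float = 1.0
    ) -> "DilutionSeries":
        """Read the ``dilution,a260`` CSV dialect (header required, one row
        per replicate)."""
        df = pd.read_csv(source)
        missing = {"dilution", "a260"} - set(df.columns)
        if missing:
            raise ValidationError(
                f"series CSV must have columns 'dilution' and 'a260'; missing {sorted(missing)}"
            )
        points = [
            (float(d), tuple(grp["a260"].astype(float)))
            for d, grp in df.groupby("dilution", sort=True)
        ]
        return cls(tuple(points), path_length=path_length)


@dataclass(frozen=True)
class FitDiagnostics:
    slope: float
    intercept: float
    r: float
    residuals: tuple[float, ...]
    intercept_warning: bool = False


@dataclass(frozen=True)
class QuantReport:
    """Stock concentrations and, after ``totals``, total amounts.

    Units: molar concentration in nM, mass concentration in ng/uL,
    totals in umol and ug.
    """

    molar_concentration: float
    mass_concentration: float
    mac: MacResult
    total_amount_mol: Optional[float] = None
    total_amount_mass: Optional[float] = None
    stock_volume: Optional[float] = None
    fit: Optional[FitDiagnostics] = None

    def to_dict(self) -> dict:
        out = {
            "molar_concentration_nM": self.molar_concentration,
            "mass_concentration_ng_per_uL": self.mass_concentration,
            "mac_260_per_M_cm": self.mac.mac_260,
            "mol_weight_g_per_mol": self.mac.mol_weight,
        }
        if self.stock_volume is not None:
            out.update(
                stock_volume_uL=self.stock_volume,
                total_amount_umol=self.total_amount_mol,
                total_amount_ug=self.total_amount_mass,
            )
        if self.fit is not None:
            out["fit"] = {
                "slope_AU": self.fit.slope,
                "intercept_AU": self.fit.intercept,
                "pearson_r": self.fit.r,
                "intercept_warning": self.fit.intercept_warning,
            }
        return out


def _report_from_stock_a260(
    stock_a260: float, path_length: float, mac: MacResult, fit: Optional[FitDiagnostics]
) -> QuantReport:
    if mac.mac_260 <= 0:
        raise ValidationError(
            "MAC260 must be positive to quantify (empty sequence has no absorption)"
        )
    molar = stock_a260 / (mac.mac_260 * path_length)  # mol/L
    molar_nM = molar * 1e9
    mass_ng_uL = molar_nM * mac.mol_weight * 1e-6  # nM * g/mol -> ng/uL
    return QuantReport(
        molar_concentration=molar_nM,
        mass_concentration=mass_ng_uL,
        mac=mac,
        fit=fit,
    )


def concentration_from_a260(m: Measurement, mac: MacResult) -> QuantReport:
    """Stock concentration from a single Beer-Lambert measurement."""
    return _report_from_stock_a260(m.a260 * m.dilution, m.path_length, mac, fit=None)


def fit_dilution_series(
    series: DilutionSeries,
    mac: MacResult,
    *,
    pooled: bool = False,
) -> QuantReport:
    """Stock concentration from an OLS fit of A260 against 1/dilution.

    Replicates are averaged per dilution point unless ``pooled`` regresses
    every replicate individually.  A single-point series falls back to the
    direct Beer-Lambert calculation on that point's mean.
    """
    if len(series.points) == 1:
        d, reps = series.points[0]
        m = Measurement(
            a260=float(np.mean(reps)), dilution=d, path_length=series.path_length
        )
        return concentration_from_a260(m, mac)

    if pooled:
        x = np.array([1.0 / d for d, reps in series.points for _ in reps])
        y = np.array([a for _, reps in series.points for a in reps])
    else:
        x = np.array([1.0 / d for d, _ in series.points])
        y = np.array([np.mean(reps) for _, reps in series.points])

    if np.ptp(x) == 0:
        raise DegenerateDesignError("all dilution factors identical; cannot regress")

    fit = stats.linregress(x, y)
    residuals = tuple(float(r) for r in y - (fit.intercept + fit.slope * x))
    warn = bool(abs(fit.intercept) > INTERCEPT_WARN_AU)
    if warn:
        warnings.warn(
            f"fitted intercept {fit.intercept:.4f} AU exceeds "
            f"+/-{INTERCEPT_WARN_AU} AU: check blanks/baseline",
            stacklevel=2,
        )
    diagnostics = FitDiagnostics(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        residuals=residuals,
        intercept_warning=warn,
    )
    # slope = A260 of the undiluted stock at this path length
    return _report_from_stock_a260(float(fit.slope), series.path_length, mac, diagnostics)


def fit_beer_lambert(
    known_concentrations: Sequence[float],
    absorbances: Sequence[float],
    path_length: float = 1.0,
) -> tuple[float, float]:
    """Estimate a molar absorption coefficient from a calibration line.

    Ordinary least squares of absorbance on known molar concentration;
    returns ``(epsilon_hat, pearson_r)`` with epsilon in M^-1 cm^-1.
    Readings above 1.0 AU draw a linear-range warning.
    """
    c = np.asarray(known_concentrations, dtype=float)
    a = np.asarray(absorbances, dtype=float)
    if c.shape != a.shape or c.ndim != 1:
        raise ValidationError(
            f"concentration and absorbance lists must match 1-D shapes, "
            f"got {c.shape} and {a.shape}"
        )
    if c.size < 2 or np.ptp(c) == 0:
        raise DegenerateDesignError(
            "calibration needs >= 2 distinct concentrations"
        )
    if path_length <= 0:
        raise ValidationError(f"path length must be positive, got {path_length}")
    if np.any(a > 1.0):
        warnings.warn(
            "absorbance readings above 1.0 AU may leave the instrument's "
            "linear range",
            stacklevel=2,
        )
    fit = stats.linregress(c, a)
    return float(fit.slope) / path_length, float(fit.rvalue)


def totals(report: QuantReport, stock_volume: float) -> QuantReport:
    """Add total amounts for a stock of ``stock_volume`` microliters.

    nM * uL = 1e-9 umol; (ng/uL) * uL = ng = 1e-3 ug.
    """
    if stock_volume <= 0:
        raise ValidationError(f"stock volume must be positive, got {stock_volume}")
    return replace(
        report,
        stock_volume=stock_volume,
        total_amount_mol=report.molar_concentration * stock_volume * 1e-9,
        total_amount_mass=report.mass_concentration * stock_volume * 1e-3,
    )
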