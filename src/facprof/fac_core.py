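"""Frontal affinity chromatography (FAC) quantitation.

In FAC an analyte solution at initial concentration [A]0 is continuously
infused through a miniature column carrying an immobilized lectin with
effective ligand content Bt.  Binding retards the analyte's elution front
relative to a non-binding standard; the retardation V - V0 obeys

    Kd = Bt / (V - V0) - [A]0

for a single-site equilibrium.  Unit convention throughout: Bt in nmol,
volumes in uL, concentrations in mol/L.  The hidden factor of 10^3 comes
from the identity nmol/uL == mmol/L, so ``Bt_nmol / (conc_M * 1e3)`` is a
volume in uL.

Column calibration uses a concentration-dependence series and the
Woolf-Hofstee linearization: plotting (V - V0) against (V - V0)*[A]0 gives
a line with slope -1/Kd and intercept Bt/Kd, fitted by ordinary least
squares exactly as run on the instrument data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import InsufficientDataError, NoSaturableBindingError, ValidationError

#: uL * (mmol/L) = nmol; equivalently mol/L -> mmol/L.
_MMOL_PER_MOL = 1e3


@dataclass(frozen=True)
class ColumnCalibration:
    """Calibrated lectin column: effective ligand content and reference Kd.

    Parameters
    ----------
    lectin_name : str
        Label of the immobilized lectin.
    bt_nmol : float
        Effective ligand content Bt, nmol. Must be positive.
    kd_ref_M : float
        Dissociation constant of the calibration ligand, mol/L.
    bed_volume_uL : float, optional
        Geometric bed volume of the miniature column.
    r2 : float, optional
        Coefficient of determination of the Woolf-Hofstee line.
    """

    lectin_name: str
    bt_nmol: float
    kd_ref_M: float
    bed_volume_uL: Optional[float] = None
    r2: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.bt_nmol > 0:
            raise ValidationError(f"Bt must be positive, got {self.bt_nmol}")
        if not self.kd_ref_M > 0:
            raise ValidationError(f"Kd must be positive, got {self.kd_ref_M}")
        if self.bed_volume_uL is not None and not self.bed_volume_uL > 0:
            raise ValidationError("bed volume must be positive when given")


@dataclass(frozen=True)
class CalibrationPoint:
    """One point of a concentration-dependence series."""

    a0_M: float
    v_minus_v0_uL: float

    def __post_init__(self) -> None:
        if not self.a0_M > 0:
            raise ValidationError(f"A0 must be positive, got {self.a0_M}")


@dataclass(frozen=True)
class RetardationMeasurement:
    """Per-glycan elution-front retardation at known analyte concentration."""

    glycan_id: str
    a0_M: float
    v_minus_v0_uL: float
    below_detection: bool = False

    def __post_init__(self) -> None:
        if not self.a0_M > 0:
            raise ValidationError(f"A0 must be positive, got {self.a0_M}")
        if not math.isfinite(self.v_minus_v0_uL):
            raise ValidationError("V-V0 must be finite")
        if self.v_minus_v0_uL <= 0 and not self.below_detection:
            raise ValidationError(
                f"non-positive V-V0 ({self.v_minus_v0_uL}) requires below_detection"
            )


def bed_volume_uL(diameter_mm: float, length_mm: float) -> float:
    """Cylindrical bed volume in uL (1 mm^3 == 1 uL).

    The standard miniature FAC column (diameter 2 mm x 10 mm) has
    pi * 1^2 * 10 = 31.4 uL.
    """
    if diameter_mm <= 0 or length_mm <= 0:
        raise ValidationError("column dimensions must be positive")
    return math.pi * (diameter_mm / 2.0) ** 2 * length_mm


def retardation_forward(bt_nmol: float, kd_M: float, a0_M: float) -> float:
    """Predicted front retardation V - V0 in uL for a single-site column.

    V - V0 = Bt / (Kd + [A]0), with the nmol / (mmol/L) = uL conversion.
    Strictly increasing in Bt, strictly decreasing in Kd and [A]0.
    """
    if bt_nmol < 0:
        raise ValidationError(f"Bt must be non-negative, got {bt_nmol}")
    if kd_M <= 0 or a0_M < 0:
        raise ValidationError("require Kd > 0 and A0 >= 0")
    denom = (kd_M + a0_M) * _MMOL_PER_MOL
    if denom == 0:
        raise ValidationError("Kd + A0 must be positive")
    return bt_nmol / denom


def kd_from_retardation(
    bt_nmol: float, v_minus_v0_uL: float, a0_M: float
) -> Optional[float]:
    """Kd in mol/L from retardation: Bt/(V-V0) - [A]0.

    Returns ``None`` when the measurement carries no information:
    V-V0 <= 0 (below detection; not an exception, the caller flags the
    measurement) or a non-positive result (noise exceeded the model).
    Exact algebraic inverse of :func:`retardation_forward`.
    """
    if bt_nmol <= 0:
        raise ValidationError(f"Bt must be positive, got {bt_nmol}")
    if v_minus_v0_uL <= 0:
        return None
    kd = bt_nmol / (v_minus_v0_uL * _MMOL_PER_MOL) - a0_M
    if kd <= 0:
        return None
    return kd


def kd_simplified(bt_nmol: float, v_minus_v0_uL: float) -> Optional[float]:
    """Kd neglecting [A]0: Bt/(V-V0).

    Valid when [A]0 is negligibly small (e.g. < 1e-8 M) against Kd; the
    relative error versus :func:`kd_from_retardation` is exactly A0/Kd.
    """
    if bt_nmol <= 0:
        raise ValidationError(f"Bt must be positive, got {bt_nmol}")
    if v_minus_v0_uL <= 0:
        return None
    return bt_nmol / (v_minus_v0_uL * _MMOL_PER_MOL)


def ka_from_kd(kd_M: float) -> float:
    """Association constant Ka = 1/Kd, L/mol."""
    if kd_M <= 0:
        raise ValidationError(f"Kd must be positive, got {kd_M}")
    return 1.0 / kd_M


def woolf_hofstee_fit(
    points: Sequence[CalibrationPoint], lectin_name: str = "column"
) -> ColumnCalibration:
    """Calibrate Bt and Kd from a concentration-dependence series.

    Ordinary least squares of y = V-V0 (uL) on x = (V-V0)*[A]0 (uL*M):
    Kd = -1/slope (M) and Bt = intercept * Kd * 1e3 (nmol, via the
    uL * mmol/L identity).  On noiseless model data this recovers the
    generating parameters to machine precision.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 points, fewer than 2 distinct A0 values, or a
        degenerate (zero-variance) design.
    NoSaturableBindingError
        Non-negative slope: the data show no saturable binding.
    ValidationError
        Any non-positive retardation in the series.
    """
    if len(points) < 3:
        raise InsufficientDataError(
            f"need at least 3 calibration points, got {len(points)}"
        )
    if len({p.a0_M for p in points}) < 2:
        raise InsufficientDataError("need at least 2 distinct A0 values")
    v = np.array([p.v_minus_v0_uL for p in points], dtype=float)
    if np.any(v <= 0):
        raise ValidationError("all V-V0 values must be positive for calibration")
    a0 = np.array([p.a0_M for p in points], dtype=float)
    x = v * a0
    y = v
    if np.ptp(x) == 0:
        raise InsufficientDataError("degenerate design: no spread in (V-V0)*A0")
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise NoSaturableBindingError(
            f"no saturable binding: Woolf-Hofstee slope {slope:.3g} >= 0"
        )
    kd = -1.0 / slope
    bt = intercept * kd * _MMOL_PER_MOL
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ColumnCalibration(lectin_name=lectin_name, bt_nmol=bt, kd_ref_M=kd, r2=r2)
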