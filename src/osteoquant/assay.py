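"""Fluorescent AGE quantification normalized to collagen.

Bone hydrolysate fluorescence (excitation 360 nm / emission 460 nm) is
converted to quinine equivalents against a serially diluted quinine
standard curve; collagen mass is derived from a chloramine-T
hydroxyproline absorbance assay (570 nm) using the constant that collagen
is 14% hydroxyproline by mass.  The result is reported as
ng quinine fluorescence per mg collagen.

Both standard curves are ordinary least-squares lines (with intercept,
since plate readers carry background signal) and must reach R^2 >= 0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PlateAssay",
    "StandardCurve",
    "FAGEResult",
    "HYDROXYPROLINE_COLLAGEN_FRACTION",
    "fit_standard_curve",
    "quantify_hydroxyproline",
    "compute_fage",
    "quinine_dilution_series",
]

HYDROXYPROLINE_COLLAGEN_FRACTION = 0.14

#: quinine stock: 10 ug quinine per mL of 0.1 N H2SO4, i.e. 10000 ng/mL
QUININE_STOCK_NG_ML = 10000.0
#: hydroxyproline stock: 2 mg per mL of 0.001 N HCl
HYDROXYPROLINE_STOCK_MG_ML = 2.0


def quinine_dilution_series(
    stock: float = QUININE_STOCK_NG_ML, n_steps: int = 7, include_blank: bool = True
) -> np.ndarray:
    """Two-fold serial dilution grid of the quinine stock (plus a blank)."""
    conc = stock / (2.0 ** np.arange(n_steps))
    return np.append(conc, 0.0) if include_blank else conc


@dataclass
class PlateAssay:
    """One plate read-out: standards (conc, reading) and sample rows."""

    standards: list[tuple[float, float]]
    samples: list[tuple[str, float, float]]  # (id, reading, dilution factor)
    mode: str = "fluorescence_360_460"

    def __post_init__(self) -> None:
        if len(self.standards) < 3:
            raise ValueError("need at least 3 standards")
        conc = np.array([c for c, _ in self.standards], float)
        if np.ptp(conc) <= 0:
            raise ValueError("standard concentrations are degenerate")
        if self.mode not in ("fluorescence_360_460", "absorbance_570"):
            raise ValueError("unknown plate mode")


@dataclass
class StandardCurve:
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("standard curve slope must be positive")

    def invert(self, reading: float) -> float:
        """Back-calculated concentration for one reading."""
        return (reading - self.intercept) / self.slope


@dataclass
class FAGEResult:
    fage: float  # ng quinine / mg collagen
    quinine_eq_ng: float
    hydroxyproline_mg: float
    collagen_mg: float
    flags: list[str] = field(default_factory=list)


def fit_standard_curve(
    standards: list[tuple[float, float]], r2_min: float = 0.95
) -> StandardCurve:
    """OLS line reading = slope * concentration + intercept, with QC."""
    conc = np.array([c for c, _ in standards], float)
    reading = np.array([r for _, r in standards], float)
    if conc.size < 3 or np.ptp(conc) <= 0:
        raise ValueError("need >= 3 standards over a non-degenerate range")
    fit = sps.linregress(conc, reading)
    r2 = float(fit.rvalue**2)
    if r2 < r2_min:
        raise ValueError(f"standard curve failed QC: R^2 = {r2:.4f} < {r2_min}")
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        conc_range=(float(conc.min()), float(conc.max())),
    )


def quantify_hydroxyproline(
    absorbance: float,
    curve: StandardCurve,
    dilution: float = 1.0,
    hydrolysate_volume_mL: float = 1.0,
) -> tuple[float, float, list[str]]:
    """Hydroxyproline and collagen mass (mg) from one 570 nm reading.

    Concentration (mg/mL) is back-calculated from the standard curve and
    scaled by the dilution factor and hydrolysate volume; collagen follows
    from the 14% hydroxyproline mass fraction.
    """
    flags = []
    conc = curve.invert(absorbance) * dilution
    raw = curve.invert(absorbance)
    if not (curve.conc_range[0] <= raw <= curve.conc_range[1]):
        flags.append("reading outside standard range (extrapolated)")
    if conc < 0:
        flags.append("negative back-calculated concentration clamped to 0")
        conc = 0.0
    hyp = conc * hydrolysate_volume_mL
    return hyp, hyp / HYDROXYPROLINE_COLLAGEN_FRACTION, flags


def compute_fage(
    fluorescence: float,
    quinine_curve: StandardCurve,
    collagen_mg: float,
    dilution: float = 10.0,
    hydrolysate_volume_mL: float = 1.0,
    hydroxyproline_mg: float | None = None,
) -> FAGEResult:
    """Total fluorescent AGEs (ng quinine / mg collagen) for one sample.

    The hydrolysate is read after a ``dilution``-fold dilution (10x with
    deionized water in the reference protocol); quinine equivalents are the
    back-calculated concentration times dilution times hydrolysate volume.
    """
    if collagen_mg <= 0:
        raise ValueError("collagen mass must be positive")
    flags = []
    conc = quinine_curve.invert(fluorescence)  # ng/mL in the diluted read
    if not (quinine_curve.conc_range[0] <= conc <= quinine_curve.conc_range[1]):
        flags.append("reading outside standard range (extrapolated)")
    if conc < 0:
        flags.append("negative back-calculated concentration clamped to 0")
        conc = 0.0
    quinine_eq = conc * dilution * hydrolysate_volume_mL
    return FAGEResult(
        fage=quinine_eq / collagen_mg,
        quinine_eq_ng=quinine_eq,
        hydroxyproline_mg=(
            hydroxyproline_mg
            if hydroxyproline_mg is not None
            else collagen_mg * HYDROXYPROLINE_COLLAGEN_FRACTION
        ),
        collagen_mg=collagen_mg,
        flags=flags,
    )
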