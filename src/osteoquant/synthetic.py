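"""Forward models of raw instrument outputs for a two-group rat cohort.

Every analysis stage in this package consumes raw artifacts (traces,
spectra, plate readings, voxel volumes).  This module synthesizes those
artifacts from latent per-animal parameters so the whole pipeline runs
with known ground truth: a control group and a diabetic (T2D) group, each
parameter drawn from an independent normal (truncated at zero for strictly
positive quantities) with group means and SDs taken from the study
conditions this package emulates — endpoint metabolic covariates, bending,
indentation, spectroscopic, assay and morphometric group summaries.

Within the T2D group a single shared latent "glycation severity" factor
induces the reported cross-parameter correlations (e.g. NE-xLR with
post-yield displacement); control-group draws are independent.

All forward models are exact inverses of the corresponding analysis
routines at zero noise.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from . import io as oio
from .assay import (
    HYDROXYPROLINE_COLLAGEN_FRACTION,
    HYDROXYPROLINE_STOCK_MG_ML,
    PlateAssay,
    quinine_dilution_series,
)
from .indentation import IndentationCycleSet, NanoPHCurve
from .mechanics import LoadDisplacementTrace
from .microct import VoxelVolume, local_thickness
from .spectra import AMIDE_I_CENTERS, Spectrum

__all__ = [
    "CohortConfig",
    "PARAMETER_DEFAULTS",
    "NOISE_DEFAULTS",
    "GLYCATION_LOADINGS",
    "forward_bending",
    "forward_rpi",
    "forward_nano",
    "forward_ftir",
    "forward_xrd",
    "forward_plate",
    "forward_volume",
    "ftir_band_library",
    "generate_cohort",
    "FAGEPlateSet",
]

#: parameter -> (control mean, control SD, T2D mean, T2D SD).
#: Metabolic covariates, nanoindentation, crystallite sizes, fAGE and the
#: morphometric entries carry the study's printed group summaries; bending,
#: cRPI and FTIR absolute levels are not printed (figures only) so typical
#: rat-femur values are used with the groups' printed percent differences.
PARAMETER_DEFAULTS: dict[str, tuple[float, float, float, float]] = {
    "body_weight_g": (252.8, 30.67, 247.8, 13.92),
    "fasting_glucose_mg_dl": (97.9, 10.46, 292.5, 45.69),
    "hba1c_pct": (6.08, 0.39, 7.89, 0.52),
    "plasma_insulin_miu_l": (2.82, 0.588, 2.216, 0.197),
    "triglyceride_mg_dl": (64.21, 8.39, 213.66, 29.06),
    "cholesterol_mg_dl": (63.68, 7.78, 130.64, 26.53),
    # three-point bending (T2D lower by 36.9% / 57% / 36.8%)
    "f_max_n": (130.0, 12.0, 82.03, 9.0),
    "stiffness_n_mm": (320.0, 35.0, 137.6, 20.0),
    "pyd_mm": (0.38, 0.06, 0.2402, 0.05),
    "f_yield_frac": (0.85, 0.02, 0.85, 0.02),
    # cRPI (T2D: ID-1st +4.1%, IDI +14.7%, US-1st -9.1%, Avg-ED +11.3%)
    "id_first_um": (70.0, 3.0, 72.87, 3.0),
    "idi_um": (15.0, 1.5, 17.205, 1.8),
    "us_first_n_um": (0.55, 0.04, 0.49995, 0.04),
    "avg_ed_uj": (30.0, 3.0, 33.39, 3.0),
    # nanoindentation
    "er_gpa": (20.6, 1.04, 16.22, 0.78),
    "hardness_gpa": (0.577, 0.039, 0.387, 0.039),
    # XRD crystallite sizes
    "crystal_length_nm": (18.29, 0.73, 16.67, 0.85),
    "crystal_width_nm": (4.64, 0.11, 5.18, 0.19),
    # FTIR (T2D: M/M -33.46%, C/P -22.22%, cryst -9.93%, acid P -6.94%,
    # NE-xLR +85.65%, maturity unchanged)
    "mineral_to_matrix": (3.50, 0.30, 2.3289, 0.25),
    "carbonate_to_phosphate": (0.0090, 0.0009, 0.0070, 0.0009),
    "crystallinity": (1.25, 0.06, 1.1259, 0.06),
    "acid_phosphate": (0.72, 0.05, 0.6700, 0.05),
    "ne_xlr": (1.50, 0.15, 2.7848, 0.28),
    "collagen_maturity": (3.00, 0.30, 3.00, 0.30),
    # fAGE assay
    "fage_ng_mg": (288.6, 33.5, 412.4, 36.6),
    "collagen_mg": (1.5, 0.15, 1.5, 0.15),
    "bone_mass_mg": (6.0, 0.5, 6.0, 0.5),
    # morphometry
    "bv_tv_pct": (46.14, 2.10, 38.54, 6.05),
    "tb_th_mm": (0.095, 0.017, 0.089, 0.011),
    "ct_ar_mm2": (6.76, 0.28, 5.72, 0.85),
    "ct_th_mm": (0.70, 0.02, 0.61, 0.05),
    "ct_tmd_mg_cc": (1594.7, 50.0, 1604.1, 114.0),
}

#: latent draws are truncated at zero (all parameters here are amounts,
#: ratios or displacements that cannot be negative)
_POSITIVE = set(PARAMETER_DEFAULTS)

#: dimensionless relative noise amplitudes per modality
NOISE_DEFAULTS: dict[str, float] = {
    "bending": 0.002,
    "rpi": 0.001,
    "nano": 0.0,
    "ftir": 0.0005,
    "xrd": 0.5,
    "plate": 0.005,
    "volume": 0.0,
}

#: loadings of the shared T2D glycation-severity factor; chosen so the
#: induced within-group correlations match the study's reported values
#: (r(NE-xLR, PYD) = -0.697, r(fAGE, width) = 0.833, r(HbA1c, NE-xLR) ~ 0.69)
GLYCATION_LOADINGS: dict[str, float] = {
    "ne_xlr": 0.835,
    "pyd_mm": -0.835,
    "fage_ng_mg": 0.913,
    "crystal_width_nm": 0.913,
    "hba1c_pct": 0.80,
    "f_max_n": -0.885,
    "bv_tv_pct": -0.90,
    "ct_th_mm": -0.85,
}

ALL_MODALITIES = ("bending", "rpi", "nano", "ftir", "xrd", "fage", "microct")


@dataclass
class CohortConfig:
    """Latent-parameter and noise configuration for one synthetic cohort."""

    n_per_group: int = 10
    seed: int = 0
    parameter_table: dict = field(
        default_factory=lambda: copy.deepcopy(PARAMETER_DEFAULTS)
    )
    noise: dict = field(default_factory=lambda: dict(NOISE_DEFAULTS))
    glycation_loadings: dict = field(
        default_factory=lambda: dict(GLYCATION_LOADINGS)
    )
    modalities: tuple = ALL_MODALITIES
    rpi_sites: int = 6
    nano_indents: int = 8
    site_cv: float = 0.02  # relative indent-site scatter within an animal
    # scaled-down default volume geometry (full-size scans are unnecessary
    # for parameter recovery and dominate runtime)
    trabecular_edge_mm: float = 0.6
    trabecular_voxel_um: float = 10.0
    cortical_voxel_um: float = 20.0
    cortical_slices: int = 12

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name, row in self.parameter_table.items():
            if len(row) != 4:
                raise ValueError(f"parameter {name!r} needs 4 entries")
            if row[1] < 0 or row[3] < 0:
                raise ValueError(f"parameter {name!r} has a negative SD")


@dataclass
class FAGEPlateSet:
    """The two plates of one fAGE work-up plus the shared dilution bookkeeping."""

    quinine: PlateAssay
    hydroxyproline: PlateAssay
    dilution: float
    hydrolysate_volume_mL: float


# ----------------------------------------------------------------- bending


def forward_bending(
    stiffness: float,
    F_yield: float,
    F_max: float,
    PYD: float,
    span: float = 19.0,
    rate: float = 10.0,
    noise: float = 0.0,
    offset_fraction: float = 0.002,
    sample_hz: float = 100.0,
    preload: float = 10.0,
    rng: np.random.Generator | None = None,
) -> LoadDisplacementTrace:
    """Synthetic load-displacement trace of one three-point-bending test.

    The trace is linear with the given slope up to a proportional limit,
    then follows a quadratic Bezier hardening arc that (a) passes exactly
    through the 0.2%-offset yield point ``(F_yield/k + offset, F_yield)``
    and (b) peaks at ``F_max`` at the fracture displacement
    ``D_fx = D_yield + PYD``; a sharp terminal load drop marks fracture.
    At zero noise the analysis stage inverts the trace exactly.
    """
    if not (0 < F_yield <= F_max):
        raise ValueError("need 0 < F_yield <= F_max")
    if stiffness <= 0:
        raise ValueError("stiffness must be positive")
    if PYD < 0:
        raise ValueError("PYD must be non-negative")
    k = stiffness
    step = rate / 60.0 / sample_hz  # mm per sample at the crosshead speed

    if PYD == 0.0:
        # purely elastic: single linear ramp to the fracture load
        d_end = F_max / k
        d = np.arange(0.0, d_end + step / 2, step)
        d[-1] = d_end
        f = k * d
        work = 0.5 * F_max * d_end
        d_yield = d_fx = d_end
    else:
        c = offset_fraction * span
        d_yield = F_yield / k + c
        d_fx = d_yield + PYD
        if F_max > F_yield and (F_max - F_yield) / PYD >= k:
            raise ValueError(
                "hardening from F_yield to F_max over the given PYD would "
                "need a post-yield slope >= the elastic slope; "
                "increase PYD or reduce F_max - F_yield"
            )
        # post-yield tangent at the yield point: geometric mean of the
        # elastic slope and the mean hardening slope (keeps both Bezier
        # control points interior, hence the arc smooth and monotone)
        s_mean = (F_max - F_yield) / PYD
        s_y = np.sqrt(k * s_mean) if s_mean > 0 else 0.5 * k
        # control point of the elastic->yield arc: tangent intersection
        c1_d = (F_yield - s_y * d_yield) / (k - s_y)
        if c1_d <= 0:
            raise ValueError(
                "offset yield point incompatible with the elastic slope"
            )
        d_p = min(0.9 * F_yield / k, 0.97 * c1_d)  # proportional limit
        p0 = np.array([d_p, k * d_p])
        c1 = np.array([c1_d, k * c1_d])
        yld = np.array([d_yield, F_yield])
        c2 = np.array(
            [d_yield + (F_max - F_yield) / s_y if s_y > 0 else d_yield, F_max]
        )
        end = np.array([d_fx, F_max])

        def bezier(t, a, b, cc):
            t = np.asarray(t)[:, None]
            return (1 - t) ** 2 * a + 2 * t * (1 - t) * b + t**2 * cc

        t = np.linspace(0.0, 1.0, 4001)
        seg1 = bezier(t, p0, c1, yld)
        seg2 = bezier(t, yld, c2, end)
        dd = np.concatenate([seg1[:, 0], seg2[1:, 0]])
        ff = np.concatenate([seg1[:, 1], seg2[1:, 1]])
        d_lin = np.arange(0.0, d_p, step)
        d_arc = np.arange(d_p, d_fx + step / 2, step)
        d_arc[-1] = min(d_arc[-1], d_fx)
        if d_arc[-1] < d_fx:
            d_arc = np.append(d_arc, d_fx)
        f_arc = np.interp(d_arc, dd, ff)
        d = np.concatenate([d_lin, d_arc])
        f = np.concatenate([k * d_lin, f_arc])
        # analytic area: triangle + the two Bezier integrals; each
        # integrand F(t) d'(t) is a cubic in t, exact under 4-point GL
        gt, gw = np.polynomial.legendre.leggauss(4)
        tq = 0.5 * (gt + 1.0)

        def bezier_area(a, b, cc):
            dp = 2 * (1 - tq) * (b[0] - a[0]) + 2 * tq * (cc[0] - b[0])
            fq = (1 - tq) ** 2 * a[1] + 2 * tq * (1 - tq) * b[1] + tq**2 * cc[1]
            return 0.5 * float(np.sum(gw * fq * dp))

        work = (
            0.5 * k * d_p**2
            + bezier_area(p0, c1, yld)
            + bezier_area(yld, c2, end)
        )

    # terminal fracture drop (negligible displacement, below 50% of F_max)
    eps = 1e-6
    d = np.concatenate([d, [d[-1] + eps, d[-1] + 2 * eps]])
    f = np.concatenate([f, [0.3 * F_max, 0.02 * F_max]])
    if noise > 0:
        rng = np.random.default_rng() if rng is None else rng
        f = f + rng.normal(0.0, noise * F_max, size=f.size)
    time = np.arange(f.size) / sample_hz
    return LoadDisplacementTrace(
        time=time,
        load=f,
        displacement=d,
        span=span,
        preload=preload,
        rate=rate,
        truth={
            "stiffness": k,
            "F_yield": F_yield,
            "F_max": F_max,
            "PYD": PYD,
            "D_yield": d_yield,
            "D_fx": d_fx,
            "work_to_failure": work,
        },
    )


# -------------------------------------------------------------------- cRPI


def forward_rpi(
    first_depth: float,
    creep_per_cycle: float,
    unload_slope: float,
    loop_area: float,
    n_cycles: int = 10,
    F_max: float = 8.0,
    noise: float = 0.0,
    samples_per_branch: int = 40,
    rng: np.random.Generator | None = None,
) -> IndentationCycleSet:
    """Synthetic cRPI cycle set with exactly controlled metrics.

    Peak-force depth of cycle ``c`` is ``first_depth + (c-1) *
    creep_per_cycle``; the unloading branches are straight lines of slope
    ``unload_slope`` (N/um) and the loading branch start is placed so every
    cycle's enclosed hysteresis area equals ``loop_area`` (uJ).
    """
    if n_cycles < 2:
        raise ValueError("need at least 2 cycles")
    if creep_per_cycle < 0:
        raise ValueError("creep must be non-negative")
    if loop_area < 0:
        raise ValueError("loop area must be non-negative")
    if unload_slope <= 0:
        raise ValueError("unloading slope must be positive")
    cycles = []
    for c in range(n_cycles):
        peak = first_depth + c * creep_per_cycle
        start = peak - F_max / unload_slope - 2.0 * loop_area / F_max
        end = peak - F_max / unload_slope
        f_up = np.linspace(0.0, F_max, samples_per_branch)
        d_up = np.linspace(start, peak, samples_per_branch)
        f_dn = np.linspace(F_max, 0.0, samples_per_branch)[1:]
        d_dn = np.linspace(peak, end, samples_per_branch)[1:]
        f = np.concatenate([f_up, f_dn])
        d = np.concatenate([d_up, d_dn])
        if noise > 0:
            rng = np.random.default_rng() if rng is None else rng
            d = d + rng.normal(0.0, noise * first_depth, size=d.size)
            d[np.argmax(f)] = peak  # keep the controlled peak depth exact
        cycles.append((f, d))
    return IndentationCycleSet(cycles=cycles, F_target=F_max)


# ---------------------------------------------------------- nanoindentation


def forward_nano(
    Er: float,
    H: float,
    P_max: float = 1000.0,
    epsilon: float = 0.75,
    m: float = 1.5,
    area_coeff: float = 24.5,
    samples_per_segment: int = 500,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> NanoPHCurve:
    """Self-consistent Berkovich load-depth curve for given (Er, H) in GPa.

    The curve is built so Oliver-Pharr analysis returns (Er, H) exactly:
    ``A = P_max/H``, ``h_c = sqrt(A/area_coeff)``,
    ``S = (2/sqrt(pi)) Er sqrt(A)``, ``h_max = h_c + eps P_max/S``, loading
    ``P = P_max (h/h_max)^2``, 10-s hold, unloading
    ``P = alpha (h - h_f)^m`` with ``h_f = h_max - m P_max/S``.
    """
    if Er <= 0 or H <= 0:
        raise ValueError("Er and H must be positive")
    A = P_max / (H / 1000.0)  # nm^2 (H in uN/nm^2)
    h_c = np.sqrt(A / area_coeff)
    S = (2.0 / np.sqrt(np.pi)) * (Er / 1000.0) * np.sqrt(A)  # uN/nm
    h_max = h_c + epsilon * P_max / S
    h_f = h_max - m * P_max / S
    if h_f < 0:
        raise ValueError(
            f"residual depth h_f = {h_f:.1f} nm < 0 for Er={Er}, H={H}: "
            "unloading exponent/stiffness combination is unphysical"
        )
    alpha = P_max / (h_max - h_f) ** m
    n = samples_per_segment
    p_load = np.linspace(0.0, P_max, n)
    h_load = h_max * np.sqrt(p_load / P_max)
    p_hold = np.full(n, P_max)
    h_hold = np.full(n, h_max)
    p_unld = np.linspace(P_max, 0.0, n)
    h_unld = h_f + (p_unld / alpha) ** (1.0 / m)
    load = np.concatenate([p_load, p_hold, p_unld])
    depth = np.concatenate([h_load, h_hold, h_unld])
    if noise > 0:
        rng = np.random.default_rng() if rng is None else rng
        depth = depth + rng.normal(0.0, noise * h_max, size=depth.size)
    segment = np.array(["load"] * n + ["hold"] * n + ["unload"] * n)
    return NanoPHCurve(load=load, depth=depth, segment=segment, P_max=P_max)


# -------------------------------------------------------------------- FTIR


def ftir_band_library(
    mineral_to_matrix: float,
    carbonate_to_phosphate: float,
    crystallinity: float,
    acid_phosphate: float,
    ne_xlr: float,
    collagen_maturity: float,
) -> list[tuple[float, float, float]]:
    """Gaussian band set (center cm^-1, sigma cm^-1, area) realizing the
    requested compositional ratios.

    The phosphate envelope is built from sub-components at 960, 1020, 1030,
    1096 and 1127 cm^-1 whose amplitudes solve a small linear system so the
    baseline-corrected intensity ratios at 1030/1020 and 1127/1096 match
    the requested crystallinity and acid-phosphate values; the whole
    mineral block is then scaled to the requested mineral-to-matrix area
    ratio against the six-Gaussian amide I envelope, whose 1678/1692 and
    1660/1692 sub-band areas encode NE-xLR and collagen maturity.
    """
    # amide I sub-bands, areas relative to the 1692 cm^-1 band
    sigma_a = 5.0  # FWHM ~11.8 cm^-1, typical amide I sub-band width
    rel = {
        1610.0: 0.35,
        1630.0: 1.4,
        1645.0: 2.2,
        1660.0: collagen_maturity,
        1678.0: ne_xlr,
        1692.0: 1.0,
    }
    amide = [(c, sigma_a, rel[c]) for c in AMIDE_I_CENTERS]
    amide_total = sum(a for _, _, a in amide)

    centers = np.array([1020.0, 1030.0, 1096.0, 1127.0])
    sigmas = np.array([12.0, 10.0, 14.0, 14.0])
    # target intensities (arbitrary scale) at the four probe wavenumbers
    target = np.array([1.0, crystallinity, 0.45, 0.45 * acid_phosphate])
    base_c, base_s, base_amp = 960.0, 16.0, 0.25
    M = np.exp(
        -0.5 * ((centers[:, None] - centers[None, :]) / sigmas[None, :]) ** 2
    )
    rhs = target - base_amp * np.exp(-0.5 * ((centers - base_c) / base_s) ** 2)
    amps = np.linalg.solve(M, rhs)
    if np.any(amps <= 0):
        raise ValueError(
            "requested crystallinity/acid-phosphate ratios are outside the "
            "range realizable by the phosphate sub-band model"
        )
    mineral = [(base_c, base_s, base_amp * base_s * np.sqrt(2 * np.pi))]
    mineral += [
        (c, s, a * s * np.sqrt(2 * np.pi)) for c, s, a in zip(centers, sigmas, amps)
    ]
    mineral_area = sum(a for _, _, a in mineral)
    scale = mineral_to_matrix * amide_total / mineral_area
    mineral = [(c, s, a * scale) for c, s, a in mineral]
    phosphate_area = sum(a for _, _, a in mineral)
    carbonate = [(871.0, 5.5, carbonate_to_phosphate * phosphate_area)]
    return mineral + carbonate + amide


def forward_ftir(
    band_library: list[tuple[float, float, float]],
    baseline: tuple[float, float] = (0.0, 0.0),
    noise: float = 0.0,
    grid: tuple[float, float, float] = (400.0, 1800.0, 2.0),
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Sum-of-Gaussians absorbance spectrum on a uniform wavenumber grid.

    ``band_library`` entries are (center, sigma, area); ``baseline`` is a
    linear drift (offset, slope per cm^-1); ``noise`` is an absolute
    absorbance SD.
    """
    lo, hi, step = grid
    x = np.arange(lo, hi + step / 2, step)
    y = baseline[0] + baseline[1] * (x - lo)
    for center, sigma, area in band_library:
        if not (lo <= center <= hi):
            raise ValueError(f"band center {center} outside the grid")
        if sigma <= 0 or area < 0:
            raise ValueError("bands need sigma > 0 and area >= 0")
        y = y + area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((x - center) / sigma) ** 2
        )
    if noise > 0:
        rng = np.random.default_rng() if rng is None else rng
        y = y + rng.normal(0.0, noise, size=y.size)
    return Spectrum(x=x, y=y, kind="ftir")


# --------------------------------------------------------------------- XRD


def forward_xrd(
    length_nm: float,
    width_nm: float,
    background: tuple[float, ...] = (30.0,),
    noise: float = 0.0,
    wavelength_nm: float = 0.15406,
    amplitudes: tuple[float, float] = (1000.0, 400.0),
    grid: tuple[float, float, float] = (20.0, 45.0, 0.0334),
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Synthetic bone XRD pattern with Scherrer-consistent peak widths.

    Gaussian peaks at 26 deg (002, crystallite length) and 40 deg (310,
    width); each FWHM is set by inverting the Scherrer relation
    ``FWHM_rad = lambda / (size * cos(theta))`` at Cu K-alpha.
    ``background`` holds polynomial coefficients (low order first) in
    (2theta - 20); ``noise`` scales Poisson-like counting noise.
    """
    if length_nm <= 0 or width_nm <= 0:
        raise ValueError("crystallite sizes must be positive")
    lo, hi, step = grid
    x = np.arange(lo, hi + step / 2, step)
    y = np.polynomial.polynomial.polyval(x - lo, background)
    y = np.broadcast_to(y, x.shape).astype(float).copy()
    for (center, size), amp in zip(
        ((26.0, length_nm), (40.0, width_nm)), amplitudes
    ):
        theta = np.deg2rad(center / 2.0)
        fwhm_deg = np.rad2deg(wavelength_nm / (size * np.cos(theta)))
        sigma = fwhm_deg / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        y = y + amp * np.exp(-0.5 * ((x - center) / sigma) ** 2)
    if noise > 0:
        rng = np.random.default_rng() if rng is None else rng
        y = y + rng.normal(0.0, noise * np.sqrt(np.maximum(y, 1.0)))
    return Spectrum(x=x, y=y, kind="xrd")


# ------------------------------------------------------------------- plate


def forward_plate(
    true_fage: float,
    collagen_mg: float,
    bone_mass_mg: float = 6.0,
    dilution: float = 10.0,
    fluor_response: tuple[float, float] = (1.0, 80.0),
    abs_response: tuple[float, float] = (0.9, 0.04),
    noise: float = 0.0,
    sample_id: str = "sample",
    standards_steps: int = 10,
    rng: np.random.Generator | None = None,
) -> FAGEPlateSet:
    """Synthetic fluorescence + absorbance plates for one bone hydrolysate.

    The hydrolysate volume follows the 100 uL-per-mg-bone digestion ratio;
    the fluorescence read uses the stated 10x dilution.  Standards are the
    quinine two-fold series from the 10 ug/mL stock and a hydroxyproline
    two-fold series from the 2 mg/mL stock; both respond linearly
    (slope, intercept) with optional relative read noise.  A zero-noise
    plate set round-trips exactly through the assay analysis.
    """
    if true_fage < 0 or collagen_mg <= 0 or bone_mass_mg <= 0:
        raise ValueError("need true_fage >= 0 and positive masses")
    volume_mL = 0.1 * bone_mass_mg  # 100 uL of 6 N HCl per mg bone
    rng = np.random.default_rng() if rng is None else rng

    def read(conc, slope, intercept):
        r = slope * conc + intercept
        if noise > 0:
            r = r * (1.0 + rng.normal(0.0, noise, size=np.shape(r)))
        return r

    fs, fi = fluor_response
    # enough two-fold steps that the standards bracket the low sample
    # concentrations; otherwise intercept noise dominates back-calculation
    q_conc = quinine_dilution_series(n_steps=standards_steps)
    q_std = list(zip(q_conc, read(q_conc, fs, fi)))
    quinine_eq = true_fage * collagen_mg  # total ng in the hydrolysate
    sample_conc = quinine_eq / (dilution * volume_mL)
    q_samples = [(sample_id, float(read(sample_conc, fs, fi)), dilution)]

    hs, hi_ = abs_response
    h_conc = HYDROXYPROLINE_STOCK_MG_ML / (2.0 ** np.arange(7))
    h_conc = np.append(h_conc, 0.0)
    h_std = list(zip(h_conc, read(h_conc, hs, hi_)))
    hyp_mg = collagen_mg * HYDROXYPROLINE_COLLAGEN_FRACTION
    h_samples = [(sample_id, float(read(hyp_mg / volume_mL, hs, hi_)), 1.0)]

    return FAGEPlateSet(
        quinine=PlateAssay(q_std, q_samples, mode="fluorescence_360_460"),
        hydroxyproline=PlateAssay(h_std, h_samples, mode="absorbance_570"),
        dilution=dilution,
        hydrolysate_volume_mL=volume_mL,
    )


# ------------------------------------------------------------------ volume


def forward_volume(
    kind: str,
    geometry: dict,
    voxel_um: float,
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
) -> VoxelVolume:
    """Synthetic voxel volume: cortical annulus, plate stack or random field.

    * ``cortical`` — hollow cylinder; geometry: outer_radius_mm,
      thickness_mm, n_slices, optionally gray_bone (emitting a gray volume
      with zero background for density work).
    * ``plates`` — parallel plates along axis 0; geometry: edge_mm,
      plate_mm, gap_mm.
    * ``field`` — thresholded smoothed Gaussian random field; geometry:
      edge_mm, bv_tv_pct and either sigma_vox or tb_th_mm (in which case
      the smoothing scale is self-calibrated until the mean local
      thickness is within 3% of the target).
    """
    vox_mm = voxel_um / 1000.0
    rng = np.random.default_rng() if rng is None else rng
    if kind == "cortical":
        R = geometry["outer_radius_mm"]
        t = geometry["thickness_mm"]
        n_slices = int(geometry.get("n_slices", 10))
        r = R - t
        if not (0 <= r < R):
            raise ValueError("need 0 <= inner radius < outer radius")
        half = int(np.ceil(R / vox_mm)) + 2
        coord = (np.arange(2 * half + 1) - half) * vox_mm
        xx, yy = np.meshgrid(coord, coord, indexing="ij")
        rho2 = xx**2 + yy**2
        ring = (rho2 <= R**2) & (rho2 > r**2)
        mask = np.broadcast_to(ring, (n_slices, *ring.shape)).copy()
        gray = geometry.get("gray_bone")
        if gray is None:
            return VoxelVolume(mask, voxel_um, roi={"kind": kind, **geometry})
        vol = np.where(mask, float(gray), 0.0).astype(np.float32)
        if noise > 0:
            vol = vol + rng.normal(0.0, noise * gray, size=vol.shape).astype(
                np.float32
            )
        return VoxelVolume(
            vol, voxel_um, threshold=0.5 * gray, roi={"kind": kind, **geometry}
        )
    if kind == "plates":
        edge = geometry["edge_mm"]
        plate = geometry["plate_mm"]
        gap = geometry["gap_mm"]
        n = int(round(edge / vox_mm))
        z = (np.arange(n) + 0.5) * vox_mm
        # half-gap phase offset keeps the plates off the volume boundary
        profile = np.mod(z - gap / 2.0, plate + gap) < plate
        mask = np.broadcast_to(profile[:, None, None], (n, n, n)).copy()
        return VoxelVolume(mask, voxel_um, roi={"kind": kind, **geometry})
    if kind == "field":
        edge = geometry["edge_mm"]
        bvtv = geometry["bv_tv_pct"] / 100.0
        if not 0 < bvtv < 1:
            raise ValueError("field BV/TV must be strictly between 0 and 100%")
        n = int(round(edge / vox_mm))
        target_th = geometry.get("tb_th_mm")
        sigma = geometry.get("sigma_vox")
        if sigma is None:
            if target_th is None:
                raise ValueError("field volume needs sigma_vox or tb_th_mm")
            sigma = 0.6 * (target_th / vox_mm)
        base = rng.normal(size=(n, n, n))
        from scipy.ndimage import gaussian_filter

        def realize(sig):
            smooth = gaussian_filter(base, sig, mode="wrap")
            thr = np.quantile(smooth, 1.0 - bvtv)
            return smooth >= thr

        mask = realize(sigma)
        if target_th is not None:
            for _ in range(3):
                th = float(local_thickness(mask, vox_mm)[mask].mean())
                if abs(th - target_th) <= 0.03 * target_th:
                    break
                sigma *= target_th / th
                mask = realize(sigma)
        return VoxelVolume(mask, voxel_um, roi={"kind": kind, **geometry})
    raise ValueError(f"unknown volume kind {kind!r}")


# ------------------------------------------------------------------ cohort


def _draw_latents(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-animal latent parameter table for both groups."""
    rows = []
    for group, (im, isd) in (("control", (0, 1)), ("t2d", (2, 3))):
        loadings = config.glycation_loadings if group == "t2d" else {}
        for i in range(config.n_per_group):
            severity = float(rng.standard_normal())
            row = {"id": f"{group}_{i+1:02d}", "group": group,
                   "glycation_severity": severity}
            for name, entry in config.parameter_table.items():
                mean, sd = entry[im], entry[isd]
                lam = loadings.get(name, 0.0)
                for attempt in range(100):
                    z = rng.standard_normal()
                    val = mean + sd * (
                        lam * severity + np.sqrt(1.0 - lam**2) * z
                    )
                    if name not in _POSITIVE or val > 0 or sd == 0:
                        break
                    if attempt == 0:
                        warnings.warn(
                            f"negative draw for {name}; redrawing truncated",
                            stacklevel=2,
                        )
                else:  # pragma: no cover - essentially unreachable
                    val = mean
                row[name] = float(val)
            rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig, out_dir) -> pd.DataFrame:
    """Write one file set per animal per enabled modality; return the
    cohort table linking animals to artifact paths (relative to
    ``out_dir``, so re-runs are byte-identical) and latent truths.

    Deterministic for a fixed (config, seed): running twice produces
    byte-identical artifacts and tables.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    latents = _draw_latents(config, rng)
    noise = config.noise

    records = []
    for _, row in latents.iterrows():
        animal_dir = out / row["id"]
        animal_dir.mkdir(exist_ok=True)
        rec = {"id": row["id"], "group": row["group"]}
        rec.update({f"true_{k}": row[k] for k in config.parameter_table})
        rec["true_glycation_severity"] = row["glycation_severity"]

        if "bending" in config.modalities:
            trace = forward_bending(
                stiffness=row["stiffness_n_mm"],
                F_yield=row["f_yield_frac"] * row["f_max_n"],
                F_max=row["f_max_n"],
                PYD=row["pyd_mm"],
                noise=noise.get("bending", 0.0),
                rng=rng,
            )
            path = animal_dir / "bending.csv"
            oio.write_trace(path, trace)
            rec["bending_path"] = str(path.relative_to(out))
            rec["true_work_to_failure_n_mm"] = trace.truth["work_to_failure"]

        if "rpi" in config.modalities:
            paths = []
            for s in range(config.rpi_sites):
                jit = 1.0 + config.site_cv * rng.standard_normal(4)
                cyc = forward_rpi(
                    first_depth=row["id_first_um"] * jit[0],
                    creep_per_cycle=max(row["idi_um"], 0.0) / 9.0 * jit[1],
                    unload_slope=row["us_first_n_um"] * jit[2],
                    loop_area=row["avg_ed_uj"] * jit[3],
                    noise=noise.get("rpi", 0.0),
                    rng=rng,
                )
                force = np.concatenate([f for f, _ in cyc.cycles])
                depth = np.concatenate([d for _, d in cyc.cycles])
                idx = np.concatenate(
                    [np.full(f.size, i + 1) for i, (f, _) in enumerate(cyc.cycles)]
                )
                path = animal_dir / f"rpi_site{s+1}.csv"
                oio.write_rpi(path, force, depth, idx)
                paths.append(str(path.relative_to(out)))
            rec["rpi_paths"] = ";".join(paths)

        if "nano" in config.modalities:
            paths = []
            for s in range(config.nano_indents):
                jit = 1.0 + 0.25 * config.site_cv * rng.standard_normal(2)
                curve = forward_nano(
                    Er=row["er_gpa"] * jit[0],
                    H=row["hardness_gpa"] * jit[1],
                    noise=noise.get("nano", 0.0),
                    rng=rng,
                )
                path = animal_dir / f"nano_{s+1}.csv"
                oio.write_nano(path, curve)
                paths.append(str(path.relative_to(out)))
            rec["nano_paths"] = ";".join(paths)

        if "ftir" in config.modalities:
            bands = ftir_band_library(
                mineral_to_matrix=row["mineral_to_matrix"],
                carbonate_to_phosphate=row["carbonate_to_phosphate"],
                crystallinity=row["crystallinity"],
                acid_phosphate=row["acid_phosphate"],
                ne_xlr=row["ne_xlr"],
                collagen_maturity=row["collagen_maturity"],
            )
            spec = forward_ftir(bands, noise=noise.get("ftir", 0.0), rng=rng)
            path = animal_dir / "ftir.txt"
            oio.write_spectrum(path, spec)
            rec["ftir_path"] = str(path.relative_to(out))

        if "xrd" in config.modalities:
            spec = forward_xrd(
                length_nm=row["crystal_length_nm"],
                width_nm=row["crystal_width_nm"],
                noise=noise.get("xrd", 0.0),
                rng=rng,
            )
            path = animal_dir / "xrd.txt"
            oio.write_spectrum(path, spec)
            rec["xrd_path"] = str(path.relative_to(out))

        if "fage" in config.modalities:
            plates = forward_plate(
                true_fage=row["fage_ng_mg"],
                collagen_mg=row["collagen_mg"],
                bone_mass_mg=row["bone_mass_mg"],
                noise=noise.get("plate", 0.0),
                sample_id=row["id"],
                rng=rng,
            )
            qp = animal_dir / "plate_quinine.csv"
            hp = animal_dir / "plate_hydroxyproline.csv"
            oio.write_plate(qp, plates.quinine)
            oio.write_plate(hp, plates.hydroxyproline)
            rec["plate_quinine_path"] = str(qp.relative_to(out))
            rec["plate_hydroxyproline_path"] = str(hp.relative_to(out))
            rec["hydrolysate_volume_ml"] = plates.hydrolysate_volume_mL

        if "microct" in config.modalities:
            mid_r = row["ct_ar_mm2"] / (2.0 * np.pi * row["ct_th_mm"])
            outer = mid_r + row["ct_th_mm"] / 2.0
            inner = outer - row["ct_th_mm"]
            gray = row["ct_tmd_mg_cc"] * 5.0  # phantom map: density = gray/5
            cort = forward_volume(
                "cortical",
                {
                    "outer_radius_mm": outer,
                    "thickness_mm": row["ct_th_mm"],
                    "n_slices": config.cortical_slices,
                    "gray_bone": gray,
                },
                voxel_um=config.cortical_voxel_um,
                noise=noise.get("volume", 0.0),
                rng=rng,
            )
            rec["true_j_mm4"] = float(np.pi / 2.0 * (outer**4 - inner**4))
            cpath = animal_dir / "cortical.tif"
            oio.write_volume(cpath, cort)
            trab = forward_volume(
                "field",
                {
                    "edge_mm": config.trabecular_edge_mm,
                    "bv_tv_pct": row["bv_tv_pct"],
                    "tb_th_mm": row["tb_th_mm"],
                },
                voxel_um=config.trabecular_voxel_um,
                rng=rng,
            )
            tpath = animal_dir / "trabecular.tif"
            oio.write_volume(tpath, trab)
            rec["cortical_path"] = str(cpath.relative_to(out))
            rec["trabecular_path"] = str(tpath.relative_to(out))
            # phantom gray means for the two-point density calibration
            rec["phantom_gray_200"] = 1000.0
            rec["phantom_gray_800"] = 4000.0
        records.append(rec)

    table = pd.DataFrame(records)
    table.to_csv(out / "cohort.csv", index=False, float_format="%.10g")
    return table
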