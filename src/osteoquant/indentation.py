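"""Tissue-level indentation analysis.

Two instruments are covered:

* **Cyclic reference-point indentation (cRPI)** — a probe is driven into
  cortical bone to a fixed peak force (8 N) for 10 cycles at 2 Hz.  The
  metrics are the first-cycle indentation depth (ID-1st), total indentation
  distance (TID, depth at peak force of the last cycle), indentation
  distance increase (IDI = TID - ID-1st), first-cycle unloading slope
  (US-1st) and the mean per-cycle hysteresis-loop energy (Avg-ED).

* **Nanoindentation** — reduced modulus ``Er`` and hardness ``H`` are
  extracted from the unloading branch of a Berkovich load-depth curve by
  the Oliver-Pharr method: a power law ``P = alpha * (h - h_f)**m`` is fit
  to the upper unloading branch, the contact stiffness ``S = dP/dh`` is
  evaluated at ``h_max``, the contact depth is ``h_c = h_max -
  eps * P_max / S``, the projected contact area ``A = 24.5 * h_c**2``
  (ideal Berkovich), ``H = P_max / A`` and
  ``Er = sqrt(pi) / 2 * S / sqrt(A)``.

Units: cRPI force N, depth um (so loop areas are in uJ); nanoindentation
load uN, depth nm, with moduli reported in GPa (1 uN/nm^2 == 1000 GPa).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "IndentationCycleSet",
    "RPIResult",
    "NanoPHCurve",
    "NanoResult",
    "segment_cycles",
    "analyze_rpi",
    "analyze_nanoindentation",
]

GPA_PER_UN_NM2 = 1000.0  # 1 uN/nm^2 = 10^12 Pa


@dataclass
class IndentationCycleSet:
    """Per-cycle (force N, depth um) arrays for one cRPI indent site."""

    cycles: list[tuple[np.ndarray, np.ndarray]]
    F_target: float = 8.0
    frequency: float = 2.0
    site_id: str = ""

    def __post_init__(self) -> None:
        self.cycles = [
            (np.asarray(f, float), np.asarray(d, float)) for f, d in self.cycles
        ]
        if len(self.cycles) < 2:
            raise ValueError("need at least 2 cycles")
        for f, _ in self.cycles:
            if abs(f.max() - self.F_target) > 0.02 * self.F_target:
                raise ValueError(
                    f"cycle peak force {f.max():.3f} N deviates >2% from "
                    f"target {self.F_target} N"
                )


@dataclass
class RPIResult:
    ID_1st: float
    TID: float
    IDI: float
    US_1st: float
    Avg_ED: float
    n_sites: int
    flags: list[str] = field(default_factory=list)


@dataclass
class NanoPHCurve:
    """Nanoindentation load (uN) - depth (nm) record with segment labels."""

    load: np.ndarray
    depth: np.ndarray
    segment: np.ndarray  # 'load' | 'hold' | 'unload'
    P_max: float = 1000.0

    def __post_init__(self) -> None:
        self.load = np.asarray(self.load, float)
        self.depth = np.asarray(self.depth, float)
        self.segment = np.asarray(self.segment)
        if abs(self.load.max() - self.P_max) > 0.01 * self.P_max:
            raise ValueError("peak load deviates >1% from P_max")


@dataclass
class NanoResult:
    Er: float
    H: float
    S: float
    h_c: float
    h_max: float
    A: float
    m: float
    h_f: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (self.h_c < self.h_max):
            raise ValueError("contact depth must be below maximum depth")
        if self.Er <= 0 or self.H <= 0:
            raise ValueError("modulus and hardness must be positive")


def segment_cycles(
    force: np.ndarray,
    depth: np.ndarray,
    n_expected: int = 10,
    F_target: float = 8.0,
    site_id: str = "",
) -> IndentationCycleSet:
    """Split an interleaved cRPI force record at the minima between peaks."""
    force = np.asarray(force, float)
    depth = np.asarray(depth, float)
    peak_level = 0.9 * force.max()
    above = force >= peak_level
    # contiguous runs above 90% of peak mark the cycle apices
    edges = np.flatnonzero(np.diff(above.astype(int)))
    runs = edges.reshape(-1, 2) if edges.size % 2 == 0 else edges[:-1].reshape(-1, 2)
    peaks = [int(a + np.argmax(force[a:b + 1])) for a, b in runs]
    # split at the force minimum between consecutive peaks
    bounds = [0]
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        bounds.append(p0 + int(np.argmin(force[p0:p1])))
    bounds.append(force.size - 1)
    # boundary samples are shared so each cycle's loop closes
    cycles = [
        (force[a:b + 1], depth[a:b + 1])
        for a, b in zip(bounds[:-1], bounds[1:])
        if b - a >= 3
    ]
    if len(cycles) != n_expected:
        warnings.warn(
            f"detected {len(cycles)} cycles, expected {n_expected}; proceeding",
            stacklevel=2,
        )
    return IndentationCycleSet(cycles=cycles, F_target=F_target, site_id=site_id)


def _loop_area(force: np.ndarray, depth: np.ndarray) -> float:
    """Enclosed hysteresis area (uJ) of one cycle by the shoelace formula.

    The polygon is closed from the last sample back to the first; the sign
    is discarded so a reversed traversal gives the same energy.
    """
    x, y = depth, force
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _unloading_slope(force: np.ndarray, depth: np.ndarray, fit_range=(0.40, 0.95)):
    """Linear-fit slope (N/um) of the upper unloading branch of a cycle."""
    i_peak = int(np.argmax(force))
    f, d = force[i_peak:], depth[i_peak:]
    fmax = force[i_peak]
    sel = (f >= fit_range[0] * fmax) & (f <= fit_range[1] * fmax)
    if sel.sum() < 2:
        sel = slice(None)
    return float(np.polyfit(d[sel], f[sel], 1)[0])


def analyze_rpi(
    sites: list[IndentationCycleSet],
    unload_fit_range: tuple[float, float] = (0.40, 0.95),
    include_first_cycle_energy: bool = True,
) -> RPIResult:
    """Average cRPI metrics over indent sites (unweighted mean per sample).

    Whether the first cycle's hysteresis energy enters Avg-ED is
    configurable; by default all cycles are averaged.
    """
    if not sites:
        raise ValueError("need at least one indent site")
    per_site = []
    flags: list[str] = []
    for site in sites:
        first_f, first_d = site.cycles[0]
        last_f, last_d = site.cycles[-1]
        id1 = float(first_d[np.argmax(first_f)])
        tid = float(last_d[np.argmax(last_f)])
        us1 = _unloading_slope(first_f, first_d, unload_fit_range)
        cyc = site.cycles if include_first_cycle_energy else site.cycles[1:]
        if abs(last_f[-1] - last_f[0]) > 0.05 * site.F_target:
            flags.append(f"{site.site_id}: final cycle not closed")
        eds = [_loop_area(f, d) for f, d in cyc]
        per_site.append((id1, tid, tid - id1, us1, float(np.mean(eds))))
    id1, tid, idi, us1, ed = np.mean(np.array(per_site), axis=0)
    return RPIResult(
        ID_1st=float(id1),
        TID=float(tid),
        IDI=float(idi),
        US_1st=float(us1),
        Avg_ED=float(ed),
        n_sites=len(sites),
        flags=flags,
    )


def analyze_nanoindentation(
    curve: NanoPHCurve,
    epsilon: float = 0.75,
    unload_fit_range: tuple[float, float] = (0.40, 0.95),
    area_coeff: float = 24.5,
    beta: float = 1.0,
) -> NanoResult:
    """Oliver-Pharr reduced modulus (GPa) and hardness (GPa) from one curve.

    ``epsilon`` is the indenter geometry constant (0.75 for the paraboloid
    approximation of a Berkovich tip); ``area_coeff`` the ideal-tip area
    function coefficient in A = c * h_c**2; ``beta`` an optional stiffness
    geometry correction divided out of S before use.
    """
    unload = curve.segment == "unload"
    P = curve.load[unload]
    h = curve.depth[unload]
    P_max = curve.P_max
    h_max = float(curve.depth.max())
    sel = (P >= unload_fit_range[0] * P_max) & (P <= unload_fit_range[1] * P_max)
    if sel.sum() < 10:
        raise ValueError("unloading segment has <10 samples in the fit range")
    Pf, hf_ = P[sel], h[sel]

    def model(hh, alpha, h_f, m):
        return alpha * np.clip(hh - h_f, 0.0, None) ** m

    h_lo = float(hf_.min())
    p0 = (P_max / max(h_max - 0.9 * h_lo, 1.0) ** 1.5, 0.9 * h_lo, 1.5)
    try:
        popt, _ = curve_fit(
            model,
            hf_,
            Pf,
            p0=p0,
            bounds=([0.0, -np.inf, 1.0], [np.inf, h_lo, 3.0]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological input
        raise RuntimeError(f"unloading power-law fit failed: {exc}") from exc
    alpha, h_f, m = popt
    if not (1.0 <= m <= 3.0):
        raise RuntimeError(f"unloading exponent m={m:.3f} outside [1, 3]")
    resid = Pf - model(hf_, *popt)
    ss_tot = float(np.sum((Pf - Pf.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    S = alpha * m * (h_max - h_f) ** (m - 1.0) / beta  # uN/nm
    h_c = h_max - epsilon * P_max / S
    if h_c <= 0:
        raise RuntimeError("non-positive contact depth; curve not indenter-like")
    A = area_coeff * h_c**2  # nm^2
    H = P_max / A * GPA_PER_UN_NM2
    Er = (np.sqrt(np.pi) / 2.0) * S / np.sqrt(A) * GPA_PER_UN_NM2
    return NanoResult(
        Er=float(Er),
        H=float(H),
        S=float(S),
        h_c=float(h_c),
        h_max=h_max,
        A=float(A),
        m=float(m),
        h_f=float(h_f),
        r_squared=r2,
    )
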