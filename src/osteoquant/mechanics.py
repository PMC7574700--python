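"""Whole-bone mechanics from three-point-bending load-displacement traces.

A femur loaded to failure in three-point bending yields a load-displacement
record from which four structural-level parameters are extracted:

* ``F_max`` — greatest load before fracture (whole-bone strength),
* ``stiffness`` — slope of the linear (elastic) portion of the curve,
* ``work_to_failure`` — area under the curve to fracture (whole-bone
  toughness surrogate),
* ``PYD`` — post-yield displacement, the displacement between the
  0.2%-offset yield point and fracture; a ductility surrogate.

The yield point follows the 0.2% offset convention: the elastic fit line is
translated along the displacement axis by ``offset_fraction * span`` and its
first intersection with the trace defines ``(D_yield, F_yield)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LoadDisplacementTrace",
    "BendingResult",
    "LinearRegionNotFound",
    "analyze_bending",
]


class LinearRegionNotFound(RuntimeError):
    """No candidate window of the trace fits a line at the required R^2."""


@dataclass
class LoadDisplacementTrace:
    """One bending test: sampled time (s), load (N), displacement (mm).

    ``span`` is the support span in mm, ``preload`` the contact preload in N
    and ``rate`` the crosshead speed in mm/min.  ``truth`` optionally carries
    the generating parameters when the trace is synthetic.
    """

    time: np.ndarray
    load: np.ndarray
    displacement: np.ndarray
    span: float = 19.0
    preload: float = 10.0
    rate: float = 10.0
    truth: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        n = self.load.size
        if not (self.time.size == n == self.displacement.size):
            raise ValueError("time, load and displacement must have equal length")
        if n < 10:
            raise ValueError("trace needs at least 10 samples")
        # displacement must be monotone once the preload is exceeded
        above = np.flatnonzero(self.load >= self.preload)
        if above.size:
            d = self.displacement[above[0]:]
            if np.any(np.diff(d) < -1e-9):
                raise ValueError("displacement decreases after preload crossing")


@dataclass
class BendingResult:
    F_max: float
    stiffness: float
    work_to_failure: float
    D_yield: float
    F_yield: float
    D_fx: float
    PYD: float
    r_squared: float
    yield_flagged: bool = False

    def __post_init__(self) -> None:
        if self.D_fx < self.D_yield - 1e-9:
            raise ValueError("fracture displacement precedes yield")


def _window_regressions(x: np.ndarray, y: np.ndarray, length: int):
    """Slope, intercept and R^2 of every contiguous window of ``length``.

    Vectorized over window starts with prefix sums; O(n) per length.
    """
    n = x.size
    cx, cy = np.concatenate(([0.0], np.cumsum(x))), np.concatenate(([0.0], np.cumsum(y)))
    cxx = np.concatenate(([0.0], np.cumsum(x * x)))
    cyy = np.concatenate(([0.0], np.cumsum(y * y)))
    cxy = np.concatenate(([0.0], np.cumsum(x * y)))
    s = np.arange(0, n - length + 1)
    e = s + length
    sx = cx[e] - cx[s]
    sy = cy[e] - cy[s]
    sxx = cxx[e] - cxx[s]
    syy = cyy[e] - cyy[s]
    sxy = cxy[e] - cxy[s]
    m = float(length)
    varx = sxx - sx * sx / m
    vary = syy - sy * sy / m
    cov = sxy - sx * sy / m
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(varx > 0, cov / varx, np.nan)
        r2 = np.where((varx > 0) & (vary > 0), cov * cov / (varx * vary), np.nan)
        # a flat-in-y window fits y = const exactly
        r2 = np.where((varx > 0) & (vary <= 1e-30), 1.0, r2)
        rss = np.clip(vary - np.where(varx > 0, cov * cov / varx, 0.0), 0.0, None)
    intercept = (sy - slope * sx) / m
    rms = np.sqrt(rss / m)
    return s, slope, intercept, r2, rms


def _linear_region(d, f, f_lo, f_hi, min_points, r2_min, rel_tol=1e-4):
    """Best linear window within the force band [f_lo, f_hi].

    The region is the longest sliding window whose RMS residual about its
    own fit stays at the trace's noise floor (estimated robustly from
    first differences, with a small absolute floor of ``rel_tol`` times
    the band top), so the fit does not creep into the post-proportional
    curvature; the window must also reach R^2 >= ``r2_min``.  If no window
    passes the noise criterion the max-R^2 window is used; if every
    window's R^2 is below ``r2_min`` the trace has no linear region.
    """
    mask = (f >= f_lo) & (f <= f_hi)
    idx = np.flatnonzero(mask)
    if idx.size < min_points:
        raise LinearRegionNotFound(
            f"only {idx.size} samples between {f_lo:.3g} N and {f_hi:.3g} N"
        )
    # the candidate force band is traversed once on loading; use its span
    lo, hi = idx[0], idx[-1] + 1
    x, y = d[lo:hi], f[lo:hi]
    # noise floor from first differences with the ramp rise removed
    dy = np.diff(y)
    noise_sd = 1.4826 * float(np.median(np.abs(dy - np.median(dy)))) / np.sqrt(2.0)
    tol = np.hypot(1.2 * noise_sd, rel_tol * f_hi)
    fallback = None
    candidates = []  # (slope, intercept, r2) of noise-consistent windows
    max_len = None
    for length in range(x.size, min_points - 1, -1):
        if max_len is not None and length < 0.8 * max_len:
            break
        s, slope, intercept, r2, rms = _window_regressions(x, y, length)
        ok = (rms <= tol) & (np.nan_to_num(r2, nan=-1.0) >= r2_min)
        if np.any(ok):
            if max_len is None:
                max_len = length
            best = np.flatnonzero(ok)[np.argmin(rms[ok])]
            candidates.append(
                (float(slope[best]), float(intercept[best]), float(r2[best]))
            )
        elif max_len is None:
            j = int(np.nanargmax(np.where(np.isfinite(r2), r2, -np.inf)))
            if np.isfinite(r2[j]) and r2[j] >= r2_min:
                if fallback is None or r2[j] > fallback[2]:
                    fallback = (
                        float(slope[j]), float(intercept[j]), float(r2[j])
                    )
    if candidates:
        # the elastic portion is the steepest of the near-maximal linear
        # windows (post-yield plateaus can be equally linear but shallower)
        return max(candidates, key=lambda c: c[0])
    if fallback is not None:
        return fallback
    raise LinearRegionNotFound(
        f"no window of >= {min_points} points reaches R^2 {r2_min}"
    )


def analyze_bending(
    trace: LoadDisplacementTrace,
    offset_fraction: float = 0.002,
    r2_min: float = 0.98,
    min_points: int = 20,
    fracture_drop: float = 0.5,
) -> BendingResult:
    """Extract F_max, stiffness, work-to-failure and PYD from one trace.

    The linear region is the longest sliding window between the preload and
    80% of F_max whose fit reaches ``r2_min``; the yield point is the first
    intersection of the trace with that fit line displaced by
    ``offset_fraction * span`` along the displacement axis; fracture is the
    last sample before the load falls below ``fracture_drop * F_max`` (or the
    final sample).  Work is the trapezoidal area under the curve from the
    start of the record to fracture.
    """
    d, f = trace.displacement, trace.load
    i_peak = int(np.argmax(f))
    F_max = float(f[i_peak])
    # fracture: first post-peak sample below the drop threshold
    post = np.flatnonzero(f[i_peak:] < fracture_drop * F_max)
    i_fx = i_peak + post[0] - 1 if post.size else f.size - 1
    i_fx = max(i_fx, i_peak)
    D_fx = float(d[i_fx])

    stiffness, intercept, r2 = _linear_region(
        d[: i_peak + 1], f[: i_peak + 1], trace.preload, 0.8 * F_max, min_points, r2_min
    )

    # 0.2% offset line: F = stiffness * (d - c) + intercept
    c = offset_fraction * trace.span
    gap = f[: i_fx + 1] - (stiffness * (d[: i_fx + 1] - c) + intercept)
    # first +->- crossing after the trace has risen above the preload
    start = int(np.flatnonzero(f >= trace.preload)[0]) if np.any(f >= trace.preload) else 0
    cross = np.flatnonzero((gap[start:-1] > 0) & (gap[start + 1:] <= 0))
    if cross.size:
        i = start + int(cross[0])
        w = gap[i] / (gap[i] - gap[i + 1])
        D_yield = float(d[i] + w * (d[i + 1] - d[i]))
        F_yield = float(f[i] + w * (f[i + 1] - f[i]))
        flagged = False
    else:  # fully linear trace: no intersection before fracture
        D_yield, F_yield, flagged = D_fx, float(f[i_fx]), True

    work = float(np.trapezoid(f[: i_fx + 1], d[: i_fx + 1]))
    return BendingResult(
        F_max=F_max,
        stiffness=stiffness,
        work_to_failure=work,
        D_yield=D_yield,
        F_yield=F_yield,
        D_fx=D_fx,
        PYD=max(D_fx - D_yield, 0.0),
        r_squared=r2,
        yield_flagged=flagged,
    )
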