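"""Density calibration and cortical/trabecular voxel morphometry.

Cortical analysis works slice-by-slice on a cylindrical mid-diaphyseal ROI:
cross-sectional area Ct.Ar (foreground voxels times voxel area), polar
moment of inertia J about the section centroid (sum of r^2 dA), and mean
cortical thickness Ct.Th (twice the mean Euclidean distance transform
sampled on the medial skeleton of each slice).

Trabecular analysis works on a cubical ROI: bone volume fraction BV/TV,
trabecular thickness Tb.Th as the mean local (largest-inscribed-sphere)
thickness of the foreground, separation Tb.Sp as the same measure on the
background, and trabecular number Tb.N = (BV/TV) / Tb.Th.

Tissue mineral density maps gray values through a two-point hydroxyapatite
phantom calibration (200 and 800 mg/cc in the reference protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "VoxelVolume",
    "DensityCalibration",
    "MorphometryResult",
    "calibrate_density",
    "cortical_morphometry",
    "trabecular_morphometry",
    "local_thickness",
]


@dataclass
class VoxelVolume:
    """3D scalar grid with isotropic voxel size in micrometres.

    ``threshold`` segments gray volumes; boolean arrays are used as-is.
    ``roi`` is a free-form descriptor carried through for provenance.
    """

    values: np.ndarray
    voxel_size_um: float
    threshold: float | None = None
    roi: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError("volume must be 3D")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel size must be positive")

    @property
    def mask(self) -> np.ndarray:
        if self.values.dtype == bool:
            return self.values
        if self.threshold is None:
            raise ValueError("gray volume requires a segmentation threshold")
        return self.values >= self.threshold

    def smoothed(self, sigma: float = 1.0) -> "VoxelVolume":
        """Optional Gaussian noise-removal filter (sigma in voxels)."""
        return VoxelVolume(
            ndimage.gaussian_filter(self.values.astype(float), sigma),
            self.voxel_size_um,
            self.threshold,
            self.roi,
        )


@dataclass
class DensityCalibration:
    """Linear gray-value to mg/cc hydroxyapatite map."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration must be strictly increasing")

    def __call__(self, gray) -> np.ndarray:
        return self.slope * np.asarray(gray, float) + self.intercept


@dataclass
class MorphometryResult:
    bv_tv_pct: float | None = None
    tb_th_mm: float | None = None
    tb_sp_mm: float | None = None
    tb_n_per_mm: float | None = None
    ct_ar_mm2: float | None = None
    ct_th_mm: float | None = None
    j_mm4: float | None = None
    tmd_mg_cc: float | None = None
    flags: list[str] = field(default_factory=list)


def calibrate_density(
    phantom_grays: tuple[float, float],
    known_densities: tuple[float, float] = (200.0, 800.0),
) -> DensityCalibration:
    """Exact two-point line through the phantom (gray, density) pairs."""
    g1, g2 = phantom_grays
    d1, d2 = known_densities
    if g1 == g2:
        raise ValueError("phantom gray values must be distinct")
    slope = (d2 - d1) / (g2 - g1)
    return DensityCalibration(slope=slope, intercept=d1 - slope * g1)


def tissue_mineral_density(
    v: VoxelVolume, calibration: DensityCalibration
) -> float:
    """Mean calibrated density (mg/cc) over the segmented bone mask."""
    mask = v.mask
    if not mask.any():
        raise ValueError("empty bone mask")
    return float(calibration(v.values[mask]).mean())


def local_thickness(
    mask: np.ndarray, voxel_size: float, radius_step: float = 0.5
) -> np.ndarray:
    """Local thickness map by the inscribed-sphere (distance-ridge) method.

    The Euclidean distance transform is evaluated on the phase and its
    ridge (voxels whose distance is a local maximum) extracted; each ridge
    voxel carries a sphere of its own diameter, and the thickness at a
    voxel is the diameter of the largest sphere covering it — the standard
    model-independent thickness definition of bone histomorphometry.

    Ridge radii are processed in bins of ``radius_step`` voxels; the
    spheres of one bin are painted in a single pass as a distance
    transform of the bin's ridge set, so the cost is one EDT per bin.
    """
    mask = np.asarray(mask, bool)
    out = np.zeros(mask.shape, float)
    if not mask.any():
        return out
    edt = ndimage.distance_transform_edt(mask)
    ridge = (edt >= ndimage.maximum_filter(edt, size=3)) & mask
    radii = edt[ridge]
    bins = np.unique(np.floor(radii / radius_step))
    for b in bins[::-1]:
        sel = np.floor(edt / radius_step) == b
        pts = ridge & sel
        if not pts.any():
            continue
        r = float(edt[pts].max())  # largest true radius in the bin
        dist = ndimage.distance_transform_edt(~pts)
        np.maximum(out, np.where(dist <= r + 1e-9, 2.0 * r, 0.0), out=out)
    uncovered = mask & (out == 0)
    out[uncovered] = 2.0 * edt[uncovered]
    out[~mask] = 0.0
    return out * voxel_size


def cortical_morphometry(
    v: VoxelVolume, calibration: DensityCalibration | None = None
) -> MorphometryResult:
    """Slice-averaged Ct.Ar (mm^2), Ct.Th (mm) and J (mm^4).

    Slices are taken along axis 0 (the diaphyseal axis).  Empty slices are
    skipped with a flag; an all-empty ROI is an error.
    """
    mask = v.mask
    vox_mm = v.voxel_size_um / 1000.0
    voxel_area = vox_mm**2
    areas, js, thicknesses = [], [], []
    flags = []
    for k in range(mask.shape[0]):
        sl = mask[k]
        n = int(sl.sum())
        if n == 0:
            flags.append(f"slice {k} empty, skipped")
            continue
        areas.append(n * voxel_area)
        yy, xx = np.nonzero(sl)
        cy, cx = yy.mean(), xx.mean()
        r2 = ((yy - cy) ** 2 + (xx - cx) ** 2) * voxel_area  # voxel^2 -> mm^2
        js.append(float(np.sum(r2) * voxel_area))
        # medial skeleton as the distance ridge (local maxima of the EDT);
        # less voxelization bias than a thinning skeleton on thick rings
        edt = ndimage.distance_transform_edt(sl)
        skel = (edt >= ndimage.maximum_filter(edt, size=3)) & sl
        if skel.any():
            thicknesses.append(2.0 * float(edt[skel].mean()) * vox_mm)
    if not areas:
        raise ValueError("all slices of the cortical ROI are empty")
    result = MorphometryResult(
        ct_ar_mm2=float(np.mean(areas)),
        ct_th_mm=float(np.mean(thicknesses)) if thicknesses else None,
        j_mm4=float(np.mean(js)),
        flags=flags,
    )
    if calibration is not None and v.values.dtype != bool:
        result.tmd_mg_cc = tissue_mineral_density(v, calibration)
    return result


def trabecular_morphometry(
    v: VoxelVolume, calibration: DensityCalibration | None = None
) -> MorphometryResult:
    """BV/TV (%), Tb.Th (mm), Tb.Sp (mm) and Tb.N (1/mm) of a cubical ROI."""
    mask = v.mask
    vox_mm = v.voxel_size_um / 1000.0
    bvtv = 100.0 * float(mask.mean())
    flags = []
    tb_th = tb_sp = tb_n = None
    if 0.0 < bvtv < 100.0:
        th_map = local_thickness(mask, vox_mm)
        tb_th = float(th_map[mask].mean())
        sp_map = local_thickness(~mask, vox_mm)
        tb_sp = float(sp_map[~mask].mean())
        tb_n = (bvtv / 100.0) / tb_th if tb_th > 0 else None
    else:
        flags.append("single-phase volume: thickness of the empty phase undefined")
    result = MorphometryResult(
        bv_tv_pct=bvtv, tb_th_mm=tb_th, tb_sp_mm=tb_sp, tb_n_per_mm=tb_n, flags=flags
    )
    if calibration is not None and v.values.dtype != bool:
        result.tmd_mg_cc = tissue_mineral_density(v, calibration)
    return result
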