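"""Preprocessing of paired HU volumes into the dual-channel model input.

Covers HU-to-fraction rescaling calibrated on trachea/aorta medians,
isotropic resampling, the Jacobian determinant of a displacement field,
fraction-based parametric response mapping (PRM), and ROI extraction
(random and sliding-window).

Conventions: voxel indices are 0-based; ROI windows are half-open
``[origin, origin + size)``; intensity fractions are NOT clipped to [0, 1]
so PRM thresholds remain monotone for out-of-range HU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

EMPH_THRESHOLD_HU = -950.0  # emphysema: TLC intensity below this
TRAP_THRESHOLD_HU = -856.0  # air trapping: RV intensity below this


class ExtractionError(RuntimeError):
    pass


@dataclass(frozen=True)
class RescaleCalibration:
    """HU anchors: trachea median (air) and descending-aorta median (tissue)."""

    air_hu: float = -1000.0
    tissue_hu: float = 55.0

    def __post_init__(self):
        if self.tissue_hu <= self.air_hu:
            raise ValueError("tissue_hu must exceed air_hu")

    def fraction(self, hu):
        """Affine HU -> tissue-fraction map: 0 at air, 1 at tissue."""
        return (np.asarray(hu, np.float64) - self.air_hu) / (self.tissue_hu - self.air_hu)


def rescale_intensity(hu_volume: np.ndarray, calib: RescaleCalibration) -> np.ndarray:
    return calib.fraction(hu_volume)


@dataclass
class DualChannelVolume:
    """Registered tissue-fraction + Jacobian channels with spacing and lung mask."""

    intensity_fraction: np.ndarray
    jacobian: np.ndarray
    spacing_mm: tuple[float, float, float]
    lung_mask: np.ndarray

    def __post_init__(self):
        if not (self.intensity_fraction.shape == self.jacobian.shape == self.lung_mask.shape):
            raise ValueError("channels and mask must share one shape")
        m = self.lung_mask.astype(bool)
        if m.any():
            if not np.isfinite(self.intensity_fraction[m]).all():
                raise ValueError("intensity_fraction must be finite on the lung mask")
            if not (self.jacobian[m] > 0).all():
                raise ValueError("jacobian must be positive on the lung mask")

    @property
    def shape(self):
        return self.intensity_fraction.shape


@dataclass
class PRMMap:
    """Voxel PRM labels (0 normal, 1 fSAD, 2 Emph, -1 outside) and lung metrics."""

    labels: np.ndarray
    emph_pct: float
    fsad_pct: float
    airt_pct: float
    tissue_pct_median: float
    rv_tlc_ratio: float
    median_jacobian: float = float("nan")

    def as_row(self, subject_id: str) -> dict:
        return {"subject_id": subject_id, "emph_pct": self.emph_pct,
                "fsad_pct": self.fsad_pct, "airt_pct": self.airt_pct,
                "tissue_pct_median": self.tissue_pct_median,
                "rv_tlc_ratio": self.rv_tlc_ratio,
                "median_jacobian": self.median_jacobian}


@dataclass
class ROI:
    """A size^3 x 2 patch: channel 0 intensity fraction, channel 1 Jacobian."""

    values: np.ndarray  # (2, size, size, size)
    origin_vox: tuple[int, int, int]
    subject_id: str = ""

    def __post_init__(self):
        if self.values.ndim != 4 or self.values.shape[0] != 2:
            raise ValueError("ROI values must have shape (2, s, s, s)")
        if not np.isfinite(self.values).all():
            raise ValueError("ROI channels must be finite")


def resample_isotropic(volume: np.ndarray, spacing_mm, target_spacing_mm: float,
                       is_mask: bool = False):
    """Resample onto an isotropic grid spanning the same physical node extent.

    Trilinear interpolation for images, nearest-neighbour for masks.  Output
    axis length is ``round((n-1) * spacing / target) + 1`` so the original
    grid nodes are reproduced exactly whenever they land on the new grid.
    Returns ``(resampled, (target,) * 3)``.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    spacing = np.asarray(spacing_mm, float)
    if (spacing <= 0).any():
        raise ValueError("spacing must be positive")
    shape = volume.shape
    out_shape = tuple(int(round((n - 1) * s / target_spacing_mm)) + 1
                      for n, s in zip(shape, spacing))
    axes = [np.arange(m) * target_spacing_mm / s for m, s in zip(out_shape, spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    order = 0 if is_mask else 1
    out = map_coordinates(volume.astype(np.float64), np.array(coords), order=order,
                          mode="nearest")
    if is_mask:
        out = out.astype(volume.dtype)
    return out, (target_spacing_mm,) * 3


def jacobian_determinant(displacement_mm: np.ndarray, spacing_mm) -> np.ndarray:
    """det(I + grad u) per voxel; central differences inside, one-sided at edges."""
    u = np.asarray(displacement_mm, np.float64)
    if u.ndim != 4 or u.shape[-1] != 3:
        raise ValueError("displacement must have shape (D, H, W, 3)")
    if any(n < 3 for n in u.shape[:3]):
        raise ValueError("each spatial axis must have length >= 3")
    spacing = [float(s) for s in spacing_mm]
    jac = np.empty(u.shape[:3] + (3, 3))
    for i in range(3):
        grads = np.gradient(u[..., i], *spacing, axis=(0, 1, 2))
        for j in range(3):
            jac[..., i, j] = grads[j]
    jac[..., 0, 0] += 1.0
    jac[..., 1, 1] += 1.0
    jac[..., 2, 2] += 1.0
    return np.linalg.det(jac)


def prm_classify(tlc_fraction: np.ndarray, rv_fraction: np.ndarray, mask: np.ndarray,
                 calib: RescaleCalibration, emph_hu: float = EMPH_THRESHOLD_HU,
                 trap_hu: float = TRAP_THRESHOLD_HU,
                 jacobian: np.ndarray | None = None) -> PRMMap:
    """Fraction-based PRM: Emph if TLC < emph threshold, else fSAD if RV < trap.

    HU thresholds are mapped into fraction space with the same calibration that
    rescaled the volumes, so the rule is invariant to consistent affine HU
    recalibration.  Both threshold comparisons are strict.  ``airt_pct`` counts
    all lung voxels below the trapping threshold on the RV image, regardless of
    emphysema.  ``rv_tlc_ratio`` is the mean Jacobian over the lung (RV volume
    as the integral of local volume change), NaN when no Jacobian is given.
    """
    if tlc_fraction.shape != rv_fraction.shape or tlc_fraction.shape != mask.shape:
        raise ValueError("tlc, rv and mask shapes must match")
    m = mask.astype(bool)
    n = int(m.sum())
    if n == 0:
        raise ValueError("empty lung mask")
    emph_thr = float(calib.fraction(emph_hu))
    trap_thr = float(calib.fraction(trap_hu))
    emph = m & (tlc_fraction < emph_thr)
    trapped = m & (rv_fraction < trap_thr)
    fsad = trapped & ~emph
    labels = np.full(mask.shape, -1, np.int8)
    labels[m] = 0
    labels[fsad] = 1
    labels[emph] = 2
    med_jac = float(np.median(jacobian[m])) if jacobian is not None else float("nan")
    rv_tlc = float(np.mean(jacobian[m])) if jacobian is not None else float("nan")
    return PRMMap(
        labels=labels,
        emph_pct=100.0 * emph.sum() / n,
        fsad_pct=100.0 * fsad.sum() / n,
        airt_pct=100.0 * trapped.sum() / n,
        tissue_pct_median=100.0 * float(np.median(tlc_fraction[m])),
        rv_tlc_ratio=rv_tlc,
        median_jacobian=med_jac,
    )


def _coverage_table(mask: np.ndarray) -> np.ndarray:
    """3D summed-area table (padded by one leading zero per axis)."""
    sat = mask.astype(np.int64)
    for ax in range(3):
        sat = sat.cumsum(axis=ax)
    return np.pad(sat, [(1, 0)] * 3)


def _window_sum(sat: np.ndarray, origin, size: int) -> int:
    z, y, x = origin
    z2, y2, x2 = z + size, y + size, x + size
    return int(sat[z2, y2, x2] - sat[z, y2, x2] - sat[z2, y, x2] - sat[z2, y2, x]
               + sat[z, y, x2] + sat[z, y2, x] + sat[z2, y, x] - sat[z, y, x])


def _cut_roi(volume: DualChannelVolume, origin, size: int) -> ROI:
    z, y, x = origin
    sl = (slice(z, z + size), slice(y, y + size), slice(x, x + size))
    vals = np.stack([volume.intensity_fraction[sl], volume.jacobian[sl]]).astype(np.float32)
    return ROI(values=vals, origin_vox=(int(z), int(y), int(x)))


def extract_random_rois(volume: DualChannelVolume, n: int, size_vox: int = 32,
                        min_lung_fraction: float = 0.5, seed: int = 0) -> list[ROI]:
    """Rejection-sample n window origins with lung coverage >= min_lung_fraction.

    Origins are uniform over all in-bounds window positions; positions failing
    the coverage test are rejected.  Deterministic per seed; the attempt budget
    is 100 * n, and exhausting it raises naming the shortfall.
    """
    shape = volume.shape
    if any(dim < size_vox for dim in shape):
        raise ExtractionError(f"volume {shape} smaller than ROI size {size_vox}")
    sat = _coverage_table(volume.lung_mask)
    need = min_lung_fraction * size_vox ** 3
    max_origin = [dim - size_vox for dim in shape]
    rng = np.random.default_rng(seed)
    rois: list[ROI] = []
    budget = 100 * n
    attempts = 0
    while len(rois) < n and attempts < budget:
        attempts += 1
        origin = tuple(int(rng.integers(0, m + 1)) for m in max_origin)
        if _window_sum(sat, origin, size_vox) >= need:
            rois.append(_cut_roi(volume, origin, size_vox))
    if len(rois) < n:
        # Distinguish "nothing admissible" from "budget exhausted".
        admissible = False
        for z in range(0, max_origin[0] + 1):
            for y in range(0, max_origin[1] + 1):
                for x in range(0, max_origin[2] + 1):
                    if _window_sum(sat, (z, y, x), size_vox) >= need:
                        admissible = True
                        break
                if admissible:
                    break
            if admissible:
                break
        if not admissible:
            raise ExtractionError(
                f"no window position reaches lung coverage {min_lung_fraction}")
        raise ExtractionError(
            f"attempt budget exhausted: {len(rois)} of {n} ROIs extracted")
    return rois


def sliding_window_rois(volume: DualChannelVolume, size_vox: int = 32,
                        overlap_vox: int = 16, min_lung_fraction: float = 0.5) -> list[ROI]:
    """Regular-grid windows (stride = size - overlap) fully inside the volume,
    filtered by lung coverage, in lexicographic (z, y, x) order."""
    if not 0 <= overlap_vox < size_vox:
        raise ValueError("overlap must satisfy 0 <= overlap < size")
    shape = volume.shape
    if any(dim < size_vox for dim in shape):
        raise ExtractionError(f"volume {shape} smaller than ROI size {size_vox}")
    stride = size_vox - overlap_vox
    sat = _coverage_table(volume.lung_mask)
    need = min_lung_fraction * size_vox ** 3
    rois = []
    for z in range(0, shape[0] - size_vox + 1, stride):
        for y in range(0, shape[1] - size_vox + 1, stride):
            for x in range(0, shape[2] - size_vox + 1, stride):
                if _window_sum(sat, (z, y, x), size_vox) >= need:
                    rois.append(_cut_roi(volume, (z, y, x), size_vox))
    return rois


def prm_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["subject_id", "emph_pct", "fsad_pct", "airt_pct",
                                       "tissue_pct_median", "rv_tlc_ratio",
                                       "median_jacobian"])
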