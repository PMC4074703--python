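"""Mask volumetry, ICV correction, lesion partitions, and coregistration.

Quantities follow the measurement chain of the vein/WMH study design:
WMHV is the segmented lesion volume in ml; CWMHV normalizes it by head
size, CWMHV = WMHV * meanICV / ICV, where meanICV is the cohort mean
intracranial volume; PVH vs DWMH is partitioned by a full 3D
anisotropy-aware Euclidean distance from the lateral ventricles (<= 10 mm
is periventricular, inclusive at exactly 10 mm); the periventricular slab
is the five consecutive axial slices starting at the first
ventricle-containing slice strictly above the top of the basal ganglia
(10 mm at 2.0 mm slices); regional WMH volume restricts the coregistered
lesion mask to that slab before the same ICV correction.

Coregistration is rigid and intensity-based. The phase volume is always
the fixed reference; a FLAIR-like moving volume is resampled onto it. The
optimizer is deterministic: a coarse multi-start grid over +/-5 deg and
+/-5 mm followed by Powell refinement with fixed iteration caps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import minimize

from .volumes import ImageVolume

__all__ = [
    "SubjectMeasurements",
    "RigidTransform",
    "RegistrationError",
    "mask_volume_ml",
    "corrected_volume",
    "compute_icv",
    "partition_pvh_dwmh",
    "select_periventricular_slab",
    "rigid_coregister",
    "resample_volume",
    "resample_mask",
    "regional_wmh_volume",
]

logger = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    """Registration failed: non-overlapping volumes or no improvement."""


@dataclass
class SubjectMeasurements:
    """One subject's derived quantities. Corrected volumes are filled once
    the cohort mean ICV is bound (the correction is cohort-relative)."""

    subject_id: str
    wmhv_ml: float
    icv_ml: float
    pvh_ml: float
    dwmh_ml: float
    regional_wmh_ml: float
    dmv_count_total: int
    dmv_count_left: int | None = None
    dmv_count_right: int | None = None
    slab_slices: tuple[int, ...] = ()
    cwmhv_ml: float | None = None
    pvh_corrected_ml: float | None = None
    dwmh_corrected_ml: float | None = None
    regional_wmh_corrected_ml: float | None = None

    def bind_mean_icv(self, mean_icv_ml: float) -> "SubjectMeasurements":
        """Fill corrected volumes given the cohort mean ICV."""
        self.cwmhv_ml = corrected_volume(self.wmhv_ml, self.icv_ml, mean_icv_ml)
        self.pvh_corrected_ml = corrected_volume(self.pvh_ml, self.icv_ml, mean_icv_ml)
        self.dwmh_corrected_ml = corrected_volume(self.dwmh_ml, self.icv_ml, mean_icv_ml)
        self.regional_wmh_corrected_ml = corrected_volume(
            self.regional_wmh_ml, self.icv_ml, mean_icv_ml
        )
        return self

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "wmhv_ml": self.wmhv_ml,
            "icv_ml": self.icv_ml,
            "cwmhv_ml": self.cwmhv_ml,
            "pvh_ml": self.pvh_ml,
            "dwmh_ml": self.dwmh_ml,
            "pvh_corrected_ml": self.pvh_corrected_ml,
            "dwmh_corrected_ml": self.dwmh_corrected_ml,
            "regional_wmh_ml": self.regional_wmh_ml,
            "regional_wmh_corrected_ml": self.regional_wmh_corrected_ml,
            "dmv_count_total": self.dmv_count_total,
            "dmv_count_left": self.dmv_count_left,
            "dmv_count_right": self.dmv_count_right,
            "slab_slices": list(self.slab_slices),
        }


# ------------------------------------------------------------- volumetry

def mask_volume_ml(mask: np.ndarray, spacing) -> float:
    """Voxel count times voxel volume (mm^3), in ml."""
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    return float(np.count_nonzero(mask)) * float(np.prod(spacing)) / 1000.0


def corrected_volume(wmhv_ml: float, icv_ml: float, mean_icv_ml: float) -> float:
    """Head-size-corrected volume: wmhv * meanICV / ICV."""
    if icv_ml <= 0 or mean_icv_ml <= 0:
        raise ValueError(
            f"ICV and mean ICV must be positive, got {icv_ml}, {mean_icv_ml}"
        )
    return wmhv_ml * mean_icv_ml / icv_ml


def compute_icv(
    intracranial: np.ndarray, spacing, parenchyma_ml: float | None = None
) -> float:
    """Intracranial volume from a supplied intracranial mask.

    The mask delineation itself is an input (phantom truth or external
    preprocessing). If a parenchyma volume is given, an ICV smaller than it
    triggers a validation warning — ICV must include CSF.
    """
    if not np.any(intracranial):
        raise ValueError("intracranial mask is empty")
    icv = mask_volume_ml(intracranial, spacing)
    if parenchyma_ml is not None and icv < parenchyma_ml:
        logger.warning(
            "ICV %.2f ml is smaller than parenchyma volume %.2f ml; "
            "the intracranial mask should include CSF", icv, parenchyma_ml,
        )
    return icv


def partition_pvh_dwmh(
    wmh: np.ndarray,
    ventricles: np.ndarray,
    spacing,
    distance_mm: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split a WMH mask into periventricular (<= distance_mm from the
    ventricles, inclusive) and deep components by a 3D anisotropy-aware
    Euclidean distance transform in mm."""
    if wmh.shape != ventricles.shape:
        raise ValueError("WMH and ventricle masks are on different grids")
    if distance_mm <= 0:
        raise ValueError("distance must be positive")
    wmh = wmh.astype(bool)
    if not np.any(ventricles):
        logger.warning("empty ventricle mask: all WMH classed as deep")
        return np.zeros_like(wmh), wmh.copy()
    dist = ndimage.distance_transform_edt(~ventricles.astype(bool), sampling=spacing)
    pvh = wmh & (dist <= distance_mm)
    return pvh, wmh & ~pvh


def select_periventricular_slab(
    ventricles: np.ndarray,
    basal_ganglia_top_slice: int,
    n_slices: int = 5,
) -> tuple[int, ...]:
    """The n_slices consecutive axial slice indices starting at the first
    ventricle-containing slice strictly above the basal ganglia top.

    At 2.0 mm slices the default five slices span the 10 mm slab over
    which vein voxels are counted. Every selected slice must contain
    ventricle; otherwise the availability is reported in the error.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be at least 1")
    has_vent = np.where(ventricles.any(axis=(0, 1)))[0]
    above = has_vent[has_vent > basal_ganglia_top_slice]
    if len(above) == 0:
        raise ValueError(
            f"no ventricle-containing slices above slice {basal_ganglia_top_slice} "
            f"(ventricles span {has_vent.tolist() or 'nothing'})"
        )
    start = int(above[0])
    slab = tuple(range(start, start + n_slices))
    missing = [z for z in slab if z not in set(has_vent.tolist())]
    if missing:
        raise ValueError(
            f"slab {slab} needs ventricle on every slice but slices {missing} "
            f"have none (ventricle-containing slices: {has_vent.tolist()})"
        )
    return slab


# --------------------------------------------------------- coregistration

@dataclass
class RigidTransform:
    """Rigid map from reference-space mm coordinates (about the reference
    grid center) to moving-space mm coordinates: x_mov = R @ x_ref + t.

    Angles are degrees about the x, y, z axes, applied as Rz @ Ry @ Rx.
    """

    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    reference_shape: tuple[int, int, int] | None = None
    reference_spacing: tuple[float, float, float] | None = None

    def matrix(self) -> np.ndarray:
        ax, ay, az = np.deg2rad(self.rotation_deg)
        cx, sx = np.cos(ax), np.sin(ax)
        cy, sy = np.cos(ay), np.sin(ay)
        cz, sz = np.cos(az), np.sin(az)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return rz @ ry @ rx

    @property
    def params(self) -> np.ndarray:
        return np.array([*self.rotation_deg, *self.translation_mm], dtype=float)

    @classmethod
    def from_params(cls, p, reference: ImageVolume | None = None) -> "RigidTransform":
        ref_shape = reference.shape if reference is not None else None
        ref_spacing = reference.spacing if reference is not None else None
        return cls(tuple(p[:3]), tuple(p[3:6]), ref_shape, ref_spacing)


def _grid_coords_mm(shape, spacing):
    """Centered voxel-center mm coordinate arrays for a grid."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]


def _sample_coords(transform: RigidTransform, ref_shape, ref_spacing, mov_shape, mov_spacing):
    """Moving-grid index coordinates at which to sample, for every
    reference voxel."""
    xs, ys, zs = _grid_coords_mm(ref_shape, ref_spacing)
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()])
    mov_mm = transform.matrix() @ pts + np.asarray(transform.translation_mm)[:, None]
    centers = [(n - 1) / 2.0 for n in mov_shape]
    idx = [
        mov_mm[i] / mov_spacing[i] + centers[i] for i in range(3)
    ]
    return np.stack(idx)


def resample_volume(
    moving: ImageVolume,
    transform: RigidTransform,
    reference: ImageVolume,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample a moving volume onto the reference grid under the transform."""
    idx = _sample_coords(
        transform, reference.shape, reference.spacing, moving.shape, moving.spacing
    )
    out = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float), idx, order=order,
        mode="constant", cval=cval, prefilter=(order > 1),
    )
    return out.reshape(reference.shape)


def resample_mask(
    mask: np.ndarray,
    transform: RigidTransform,
    reference: ImageVolume,
    moving_spacing,
) -> np.ndarray:
    """Nearest-neighbour resampling of a binary mask onto the target grid."""
    moving = ImageVolume(mask.astype(np.float32), moving_spacing)
    out = resample_volume(moving, transform, reference, order=0) > 0.5
    if mask.any() and not out.any():
        logger.warning("mask resampled to empty output despite nonempty input")
    return out


def _overlap_fraction(idx, mov_shape) -> float:
    ok = np.ones(idx.shape[1], dtype=bool)
    for i, n in enumerate(mov_shape):
        ok &= (idx[i] >= 0) & (idx[i] <= n - 1)
    return float(ok.mean())


def _neg_similarity(ref_data, mov_resampled, metric: str) -> float:
    if metric == "mse":
        return float(np.mean((ref_data - mov_resampled) ** 2))
    if metric == "nmi":
        hist, _, _ = np.histogram2d(
            ref_data.ravel(), mov_resampled.ravel(), bins=32
        )
        pxy = hist / hist.sum()
        px = pxy.sum(axis=1)
        py = pxy.sum(axis=0)
        nz = pxy > 0
        hxy = -float((pxy[nz] * np.log(pxy[nz])).sum())
        hx = -float((px[px > 0] * np.log(px[px > 0])).sum())
        hy = -float((py[py > 0] * np.log(py[py > 0])).sum())
        if hxy == 0:
            return 0.0
        return -(hx + hy) / hxy  # negative normalized mutual information
    raise ValueError(f"unknown metric {metric!r}")


def rigid_coregister(
    moving: ImageVolume,
    reference: ImageVolume,
    init: RigidTransform | None = None,
    metric: str = "nmi",
    grid_extent: float = 5.0,
    grid_steps: int = 3,
    max_iter: int = 200,
    tol: float = 1e-5,
) -> RigidTransform:
    """Recover the rigid transform aligning ``moving`` to ``reference``.

    The reference grid is never modified (the phase volume is the fixed
    reference in the subject pipeline). Similarity is normalized mutual
    information by default; ``metric="mse"`` suits same-modality phantom
    tests. Deterministic optimization: coarse multi-start over a
    ``grid_steps``-per-axis grid spanning +/-``grid_extent`` (degrees and
    mm, rotations and in-plane translations) around the init, evaluated on
    a 2x-downsampled grid, then Powell refinement at full resolution.
    """
    if init is None:
        init = RigidTransform()
    ref_data = np.asarray(reference.data, dtype=float)

    # downsampled reference grid for the coarse sweep (in-plane only)
    step = (2, 2, 1)
    coarse = ImageVolume(
        ref_data[:: step[0], :: step[1], :: step[2]],
        tuple(s * t for s, t in zip(reference.spacing, step)),
    )

    def objective(p, ref_vol, ref_arr):
        t = RigidTransform.from_params(p)
        idx = _sample_coords(
            t, ref_vol.shape, ref_vol.spacing, moving.shape, moving.spacing
        )
        if _overlap_fraction(idx, moving.shape) == 0.0:
            return np.inf
        mov = ndimage.map_coordinates(
            np.asarray(moving.data, dtype=float), idx, order=1,
            mode="constant", cval=0.0,
        ).reshape(ref_vol.shape)
        return _neg_similarity(ref_arr, mov, metric)

    coarse_arr = np.asarray(coarse.data, dtype=float)
    p0 = init.params
    idx0 = _sample_coords(
        init, reference.shape, reference.spacing, moving.shape, moving.spacing
    )
    if _overlap_fraction(idx0, moving.shape) == 0.0:
        raise RegistrationError(
            "volumes do not overlap at the initial transform "
            f"(init rotation {init.rotation_deg}, translation {init.translation_mm})"
        )

    offsets = np.linspace(-grid_extent, grid_extent, grid_steps)
    best_p, best_f = p0.copy(), objective(p0, coarse, coarse_arr)
    # axis-wise coarse sweep keeps the start set small but deterministic
    for axis in range(6):
        for off in offsets:
            if off == 0:
                continue
            p = best_p.copy()
            p[axis] = p0[axis] + off
            f = objective(p, coarse, coarse_arr)
            if f < best_f:
                best_f, best_p = f, p
    # joint in-plane sweep (rotation about z with x/y shifts) — the dominant
    # modes for axial acquisitions
    for rz in offsets:
        for tx in offsets:
            for ty in offsets:
                p = p0.copy()
                p[2], p[3], p[4] = p0[2] + rz, p0[3] + tx, p0[4] + ty
                f = objective(p, coarse, coarse_arr)
                if f < best_f:
                    best_f, best_p = f, p

    res = minimize(
        objective, best_p, args=(reference, ref_data), method="Powell",
        options={"maxiter": max_iter, "xtol": tol, "ftol": tol},
    )
    f_init = objective(p0, reference, ref_data)
    if not np.isfinite(res.fun) or res.fun > f_init + abs(f_init) * 1e-12:
        raise RegistrationError(
            f"optimization did not improve on the initial transform "
            f"(init {metric} objective {f_init:.6g}, final {res.fun:.6g})"
        )
    return RigidTransform.from_params(res.x, reference)


def regional_wmh_volume(
    wmh_on_phase_grid: np.ndarray,
    slab_slices,
    icv_ml: float,
    mean_icv_ml: float,
    spacing,
) -> float:
    """ICV-corrected WMH volume restricted to the periventricular slab
    slices of the phase grid (the coregistered regional measure)."""
    nz = wmh_on_phase_grid.shape[2]
    slab = tuple(int(z) for z in slab_slices)
    if any(z < 0 or z >= nz for z in slab):
        raise ValueError(f"slab slices {slab} outside grid with {nz} slices")
    sub = np.zeros_like(wmh_on_phase_grid, dtype=bool)
    sub[:, :, list(slab)] = wmh_on_phase_grid[:, :, list(slab)].astype(bool)
    raw = mask_volume_ml(sub, spacing)
    return corrected_volume(raw, icv_ml, mean_icv_ml)
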