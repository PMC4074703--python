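"""Parenchyma intensity modelling and threshold segmentation.

Both lesion and vein segmentation reduce to the same primitive: fit a
Gaussian to the brain-parenchyma intensity distribution and threshold at a
fixed multiple of its SD — mu + 3*sigma above the mean for white-matter
hyperintensities on FLAIR, mu - 2*sigma below the mean for deep medullary
veins on corrected SWI phase.

The default fit is robust: a scaled Gaussian is least-squares fitted to
the intensity histogram restricted to a percentile band of the region, so
that the contaminated tail (lesions above on FLAIR, veins below on phase)
does not inflate the SD. A pure moments estimator is available for
comparison. Voxels exactly at the threshold are not segmented (strict
inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit

from .volumes import FilteredPhaseVolume, ImageVolume

__all__ = [
    "IntensityModel",
    "SegmentationResult",
    "FalseVeinRules",
    "fit_parenchyma_distribution",
    "compute_threshold",
    "segment_wmh",
    "segment_dmv",
    "flag_false_dmv_candidates",
    "hemisphere_counts",
]

#: 26-neighbourhood structuring element for 3D connected components
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class IntensityModel:
    """Fitted parenchyma intensity distribution."""

    mu: float
    sigma: float
    method: str
    n_voxels: int
    goodness_of_fit: float  # R^2 of the histogram fit (1.0 for moments)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"fitted sigma must be positive, got {self.sigma}")


@dataclass
class SegmentationResult:
    """Binary segmentation with its threshold provenance and bilateral counts."""

    mask: np.ndarray
    threshold: float
    direction: str  # "above" | "below"
    k: float
    model: IntensityModel
    count_total: int
    count_left: int | None = None
    count_right: int | None = None

    def to_report(self) -> dict:
        return {
            "threshold": self.threshold,
            "direction": self.direction,
            "k": self.k,
            "mu": self.model.mu,
            "sigma": self.model.sigma,
            "fit_method": self.model.method,
            "count_total": self.count_total,
            "count_left": self.count_left,
            "count_right": self.count_right,
        }


def _freedman_diaconis_bins(values: np.ndarray) -> int:
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return 64
    width = 2.0 * iqr / len(values) ** (1.0 / 3.0)
    n = int(np.ceil((values.max() - values.min()) / width))
    return int(np.clip(n, 16, 4096))


def fit_parenchyma_distribution(
    vol: ImageVolume | FilteredPhaseVolume,
    region: np.ndarray,
    method: str = "robust",
    pct_range: tuple[float, float] = (2.0, 90.0),
    bins: int | None = None,
    min_voxels: int = 100,
) -> IntensityModel:
    """Fit a Gaussian (mu, sigma) to the intensities of ``vol`` inside ``region``.

    ``method="robust"`` (default) least-squares fits a scaled Gaussian to
    the histogram of values between the ``pct_range`` percentiles; the
    amplitude is free, so truncating a contaminated tail does not bias the
    body fit. ``method="moments"`` uses the plain sample mean/SD of the
    whole region and is provided for comparison — heavy lesion tails
    visibly inflate it.

    ``pct_range`` should clip the tail the pathology lives in: the default
    (2, 90) suits FLAIR, where lesions are the far upper tail; for phase,
    where veins occupy the lower tail, pass e.g. (10, 98).
    """
    if vol.data.shape != region.shape:
        raise ValueError("volume and region grids differ")
    values = np.asarray(vol.data)[region.astype(bool)]
    if values.size < min_voxels:
        raise ValueError(
            f"region has {values.size} voxels, below the floor of {min_voxels}"
        )
    if np.ptp(values) == 0:
        raise ValueError("region intensities have zero variance; cannot fit")

    if method == "moments":
        return IntensityModel(
            mu=float(values.mean()),
            sigma=float(values.std(ddof=1)),
            method="moments",
            n_voxels=int(values.size),
            goodness_of_fit=1.0,
        )
    if method != "robust":
        raise ValueError(f"unknown fit method {method!r}")

    lo, hi = np.percentile(values, pct_range)
    body = values[(values >= lo) & (values <= hi)]
    if body.size < min_voxels or np.ptp(body) == 0:
        raise ValueError("percentile band leaves too few distinct values to fit")

    def gauss(x, a, mu, sd):
        return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)

    def lsq_fit(sample, p0):
        nbins = bins if bins is not None else _freedman_diaconis_bins(sample)
        counts, edges = np.histogram(sample, bins=nbins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        try:
            popt, _ = curve_fit(
                gauss, centers, counts.astype(float), p0=p0, maxfev=20000
            )
        except RuntimeError:  # pragma: no cover - pathological inputs
            return p0[1], p0[2], 0.0
        resid = counts - gauss(centers, *popt)
        ss_tot = float(((counts - counts.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
        return float(popt[1]), abs(float(popt[2])), r2

    mu0 = float(np.median(body))
    q75, q25 = np.percentile(body, [75, 25])
    sd0 = max((q75 - q25) / 1.349, 1e-12 * max(abs(mu0), 1.0),
              np.ptp(body) / max(_freedman_diaconis_bins(body), 1))
    counts0, _ = np.histogram(body, bins=_freedman_diaconis_bins(body))
    mu, sd, r2 = lsq_fit(body, (float(counts0.max()), mu0, sd0))
    if sd <= 0:
        raise ValueError("histogram fit collapsed to zero width")
    return IntensityModel(
        mu=float(mu), sigma=float(sd), method="robust",
        n_voxels=int(values.size), goodness_of_fit=r2,
    )


def compute_threshold(model: IntensityModel, k: float, direction: str) -> float:
    """Threshold at mu + k*sigma (``above``) or mu - k*sigma (``below``)."""
    if k <= 0:
        raise ValueError(f"SD multiplier k must be positive, got {k}")
    if direction == "above":
        return model.mu + k * model.sigma
    if direction == "below":
        return model.mu - k * model.sigma
    raise ValueError(f"direction must be 'above' or 'below', got {direction!r}")


def hemisphere_counts(mask: np.ndarray, midline_x: float) -> tuple[int, int]:
    """Split a mask's voxel count at the mid-sagittal plane (x index axis).

    Voxels with x index < midline are counted left, >= midline right, so
    left + right always equals the total.
    """
    xs = np.nonzero(mask)[0]
    left = int((xs < midline_x).sum())
    return left, int(len(xs) - left)


def _build_result(
    mask: np.ndarray, threshold: float, direction: str, k: float,
    model: IntensityModel, midline_x: float | None,
) -> SegmentationResult:
    total = int(mask.sum())
    left = right = None
    if midline_x is not None:
        left, right = hemisphere_counts(mask, midline_x)
    return SegmentationResult(
        mask=mask, threshold=threshold, direction=direction, k=k,
        model=model, count_total=total, count_left=left, count_right=right,
    )


def segment_wmh(
    flair: ImageVolume,
    brain: np.ndarray,
    model: IntensityModel,
    k: float = 3.0,
    midline_x: float | None = None,
) -> SegmentationResult:
    """Segment white-matter hyperintensities: brain voxels strictly above
    mu + k*sigma (default k = 3). The supplied brain mask must already
    exclude ventricles/CSF."""
    if flair.data.shape != brain.shape:
        raise ValueError("FLAIR volume and brain mask grids differ")
    thr = compute_threshold(model, k, "above")
    mask = brain.astype(bool) & (np.asarray(flair.data) > thr)
    return _build_result(mask, thr, "above", k, model, midline_x)


def segment_dmv(
    fphase: FilteredPhaseVolume,
    slab: np.ndarray,
    model: IntensityModel,
    k: float = 2.0,
    exclusion: np.ndarray | None = None,
    midline_x: float | None = None,
) -> SegmentationResult:
    """Segment deep medullary veins: slab voxels strictly below
    mu - k*sigma (default k = 2) on the corrected phase, minus an optional
    exclusion mask (manually identified or rule-flagged false veins)."""
    if fphase.data.shape != slab.shape:
        raise ValueError("filtered phase and slab mask grids differ")
    if not slab.any():
        raise ValueError("slab mask is empty")
    if exclusion is not None and exclusion.shape != slab.shape:
        raise ValueError("exclusion mask is not on the phase grid")
    thr = compute_threshold(model, k, "below")
    mask = slab.astype(bool) & (np.asarray(fphase.data) < thr)
    if exclusion is not None:
        mask = mask & ~exclusion.astype(bool)
    return _build_result(mask, thr, "below", k, model, midline_x)


@dataclass(frozen=True)
class FalseVeinRules:
    """Shape rules flagging segmented components unlikely to be veins.

    A component is flagged when any enabled rule fires: its volume exceeds
    ``max_component_mm3`` (veins are thin — a large blob is a bleed or
    artifact); it is near-spherical (principal-axis elongation below
    ``min_elongation`` with at least ``min_blob_voxels`` voxels); or it
    touches the outer boundary of the slab's analysis region (cortical rim
    vessels, sinus edges). Disabled rules never fire; the returned mask is
    advisory and never auto-applied.
    """

    max_component_mm3: float | None = 500.0
    min_elongation: float | None = 2.0
    min_blob_voxels: int = 8
    flag_boundary: bool = False


def _elongation_ratio(coords_mm: np.ndarray) -> float:
    """Ratio of the largest to smallest principal spatial extents (in mm).

    A thin tube has a large ratio; a sphere is near 1. Degenerate
    components (fewer than 3 voxels) are treated as maximally elongated.
    """
    if len(coords_mm) < 3:
        return np.inf
    c = coords_mm - coords_mm.mean(axis=0)
    cov = c.T @ c / len(c)
    ev = np.sort(np.linalg.eigvalsh(cov))
    # voxels are points; add a hair so single-plane components stay finite
    lo = max(ev[0], 1e-6)
    return float(np.sqrt(ev[-1] / lo))


def flag_false_dmv_candidates(
    seg: SegmentationResult,
    spacing: tuple[float, float, float],
    rules: FalseVeinRules = FalseVeinRules(),
    region: np.ndarray | None = None,
) -> np.ndarray:
    """Flag connected components of a DMV segmentation that violate
    vein-like shape rules, returning a candidate exclusion mask.

    This automates the screening step that is done visually on patient
    data; the caller decides whether to pass the result to
    :func:`segment_dmv` as ``exclusion``.
    """
    out = np.zeros(seg.mask.shape, dtype=bool)
    if not seg.mask.any():
        return out
    labels, n = ndimage.label(seg.mask, structure=STRUCT_26)
    voxvol = float(np.prod(spacing))
    boundary = None
    if rules.flag_boundary and region is not None:
        eroded = ndimage.binary_erosion(region.astype(bool), structure=STRUCT_26)
        boundary = region.astype(bool) & ~eroded
    sp = np.asarray(spacing)
    for lab in range(1, n + 1):
        comp = labels == lab
        size = int(comp.sum())
        flag = False
        if rules.max_component_mm3 is not None and size * voxvol > rules.max_component_mm3:
            flag = True
        if (
            not flag
            and rules.min_elongation is not None
            and size >= rules.min_blob_voxels
        ):
            coords = np.argwhere(comp) * sp
            if _elongation_ratio(coords) < rules.min_elongation:
                flag = True
        if not flag and boundary is not None and (comp & boundary).any():
            flag = True
        if flag:
            out |= comp
    return out
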