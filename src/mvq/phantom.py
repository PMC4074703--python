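"""Seeded synthetic brain phantoms and cohort tables with known ground truth.

The structural phantom emulates an axial FLAIR acquisition: an ellipsoidal
brain of Gaussian-intensity parenchyma inside a larger intracranial
envelope, lateral-ventricle ellipsoids at CSF-like intensity, and spherical
hyperintense lesions whose offset is expressed in multiples of the
parenchyma SD. The SWI phantom emulates the phase channel of a
gradient-echo acquisition: a smooth low-order polynomial background field
plus narrow tubular veins carrying a negative phase dip, wrapped to
(-pi, pi]. Geometry is evaluated in mm so anisotropic voxels are handled
exactly; all randomness is driven by the spec's seed, so a given spec is
bit-reproducible.

The cohort generator draws covariates mirroring a small-vessel-disease
baseline table and builds log lesion volume and vein voxel count from a
latent bivariate residual whose correlation equals the requested partial
correlation given the covariates — the construction makes the population
partial correlation exactly the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .volumes import ComplexGREVolume, ImageVolume

__all__ = [
    "LesionSpec",
    "VeinSpec",
    "PhantomSpec",
    "PhantomBundle",
    "CohortSpec",
    "GeometryError",
    "generate_structural_phantom",
    "generate_swi_phantom",
    "generate_subject_phantom",
    "generate_cohort_table",
    "radial_vein_fan",
    "wrap_phase",
    "default_structural_spec",
    "default_swi_spec",
    "default_subject_specs",
    "COHORT_COLUMNS",
]


class GeometryError(ValueError):
    """A lesion or vein extends outside the brain, or geometry is infeasible."""


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap angles to the acquired-phase convention (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phase, dtype=np.float64)))


@dataclass(frozen=True)
class LesionSpec:
    """Spherical hyperintense lesion: center (mm, relative to grid center),
    radius (mm), intensity offset in units of the parenchyma SD."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    offset_sd: float = 6.0


@dataclass(frozen=True)
class VeinSpec:
    """Tubular vein: piecewise-linear centerline (mm points, relative to grid
    center), radius (mm), phase dip depth in radians (positive number; the
    dip applied is -depth)."""

    polyline_mm: tuple[tuple[float, float, float], ...]
    radius_mm: float = 0.5
    phase_depth_rad: float = 0.6


@dataclass
class PhantomSpec:
    """Full description of one phantom volume.

    Spatial defaults follow a 3-T axial protocol: 0.4688 mm in-plane pitch
    with 5.0 mm slices for the FLAIR-like volume and 2.0 mm slices for the
    gradient-echo volume. Grid extents are scaled down from a full head so
    phantoms build in well under a second; intensity statistics are
    arbitrary choices stated here, not measured values.
    """

    shape: tuple[int, int, int] = (128, 128, 16)
    spacing: tuple[float, float, float] = (0.4688, 0.4688, 5.0)
    parenchyma_mean: float = 100.0
    parenchyma_sd: float = 10.0
    csf_intensity: float = 30.0
    brain_radii_mm: tuple[float, float, float] = (24.0, 24.0, 24.0)
    intracranial_margin_mm: float = 3.0
    ventricle_radii_mm: tuple[float, float, float] = (4.0, 10.0, 10.0)
    ventricle_offset_mm: float = 7.0
    lesions: tuple[LesionSpec, ...] = ()
    veins: tuple[VeinSpec, ...] = ()
    # background phase polynomial: {(i, j, k): coeff} over normalized
    # coordinates u, v, w in [-1, 1]; total order <= 2 is typical
    background_coeffs: dict = field(default_factory=dict)
    phase_noise_sd: float = 0.0
    magnitude_noise_sd: float = 0.0
    allow_wrap: bool = True
    basal_ganglia_top_slice: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) < 2 for n in self.shape):
            raise ValueError("grid shape must be at least 2 voxels per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        if self.parenchyma_sd <= 0:
            raise ValueError("parenchyma SD must be positive")
        for les in self.lesions:
            if les.radius_mm <= 0:
                raise ValueError("lesion radius must be positive")
        for v in self.veins:
            if v.radius_mm <= 0:
                raise ValueError("vein radius must be positive")
            if not (0.0 < v.phase_depth_rad <= np.pi):
                raise ValueError(
                    f"vein phase depth must lie in (0, pi], got {v.phase_depth_rad}"
                )

    def to_yaml(self) -> str:
        d = {
            "shape": list(self.shape),
            "spacing": list(self.spacing),
            "parenchyma_mean": self.parenchyma_mean,
            "parenchyma_sd": self.parenchyma_sd,
            "csf_intensity": self.csf_intensity,
            "brain_radii_mm": list(self.brain_radii_mm),
            "intracranial_margin_mm": self.intracranial_margin_mm,
            "ventricle_radii_mm": list(self.ventricle_radii_mm),
            "ventricle_offset_mm": self.ventricle_offset_mm,
            "lesions": [
                {"center_mm": [float(x) for x in l.center_mm],
                 "radius_mm": float(l.radius_mm),
                 "offset_sd": float(l.offset_sd)}
                for l in self.lesions
            ],
            "veins": [
                {"polyline_mm": [[float(x) for x in p] for p in v.polyline_mm],
                 "radius_mm": float(v.radius_mm),
                 "phase_depth_rad": float(v.phase_depth_rad)}
                for v in self.veins
            ],
            "background_coeffs": {
                ",".join(map(str, k)): float(c) for k, c in self.background_coeffs.items()
            },
            "phase_noise_sd": self.phase_noise_sd,
            "magnitude_noise_sd": self.magnitude_noise_sd,
            "allow_wrap": self.allow_wrap,
            "basal_ganglia_top_slice": self.basal_ganglia_top_slice,
            "seed": self.seed,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        d = yaml.safe_load(text)
        d["shape"] = tuple(d["shape"])
        d["spacing"] = tuple(d["spacing"])
        d["brain_radii_mm"] = tuple(d["brain_radii_mm"])
        d["ventricle_radii_mm"] = tuple(d["ventricle_radii_mm"])
        d["lesions"] = tuple(
            LesionSpec(tuple(l["center_mm"]), l["radius_mm"], l["offset_sd"])
            for l in d.get("lesions", [])
        )
        d["veins"] = tuple(
            VeinSpec(tuple(tuple(p) for p in v["polyline_mm"]),
                     v["radius_mm"], v["phase_depth_rad"])
            for v in d.get("veins", [])
        )
        d["background_coeffs"] = {
            tuple(int(x) for x in k.split(",")): float(c)
            for k, c in d.get("background_coeffs", {}).items()
        }
        return cls(**d)


@dataclass
class PhantomBundle:
    """Ground-truthed phantom volumes and masks; either side may be absent."""

    spec: PhantomSpec
    flair: ImageVolume | None = None
    gre: ComplexGREVolume | None = None
    brain_mask: np.ndarray | None = None
    ventricle_mask: np.ndarray | None = None
    intracranial_mask: np.ndarray | None = None
    wmh_truth: np.ndarray | None = None
    vein_truth: np.ndarray | None = None
    basal_ganglia_top_slice: int | None = None
    midline_x: float | None = None


# ---------------------------------------------------------------- geometry

def _coords_mm(shape, spacing):
    """Per-axis voxel-center coordinates in mm, origin at grid center."""
    return [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]


def _ellipsoid_mask(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    xs, ys, zs = _coords_mm(shape, spacing)
    u = (xs - center_mm[0]) / radii_mm[0]
    v = (ys - center_mm[1]) / radii_mm[1]
    w = (zs - center_mm[2]) / radii_mm[2]
    return (
        u[:, None, None] ** 2 + v[None, :, None] ** 2 + w[None, None, :] ** 2
    ) <= 1.0


def _tube_mask(shape, spacing, polyline_mm, radius_mm) -> np.ndarray:
    """Rasterize a piecewise-linear tube by exact distance-to-segment in mm."""
    xs, ys, zs = _coords_mm(shape, spacing)
    pts = np.asarray(polyline_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("vein polyline needs at least two 3D points")
    mask = np.zeros(shape, dtype=bool)
    for a, b in zip(pts[:-1], pts[1:]):
        lo = np.minimum(a, b) - radius_mm
        hi = np.maximum(a, b) + radius_mm
        # bounding-box subgrid keeps rasterization cheap
        idx = [
            np.where((c >= l) & (c <= h))[0]
            for c, l, h in zip((xs, ys, zs), lo, hi)
        ]
        if any(len(i) == 0 for i in idx):
            continue
        gx, gy, gz = np.meshgrid(xs[idx[0]], ys[idx[1]], zs[idx[2]], indexing="ij")
        p = np.stack([gx, gy, gz], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d2 = ((p - a) ** 2).sum(-1)
        else:
            t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
            proj = a + t[..., None] * ab
            d2 = ((p - proj) ** 2).sum(-1)
        sub = d2 <= radius_mm**2
        mask[np.ix_(idx[0], idx[1], idx[2])] |= sub
    return mask


def _base_masks(spec: PhantomSpec):
    icv_radii = tuple(r + spec.intracranial_margin_mm for r in spec.brain_radii_mm)
    intracranial = _ellipsoid_mask(spec.shape, spec.spacing, (0, 0, 0), icv_radii)
    brain_full = _ellipsoid_mask(spec.shape, spec.spacing, (0, 0, 0), spec.brain_radii_mm)
    off = spec.ventricle_offset_mm
    vent = _ellipsoid_mask(spec.shape, spec.spacing, (-off, 0, 0), spec.ventricle_radii_mm)
    vent |= _ellipsoid_mask(spec.shape, spec.spacing, (off, 0, 0), spec.ventricle_radii_mm)
    vent &= brain_full
    brain = brain_full & ~vent  # parenchyma only; CSF rim and ventricles excluded
    return intracranial, brain_full, brain, vent


def _default_bg_top(spec: PhantomSpec, vent: np.ndarray) -> int:
    if spec.basal_ganglia_top_slice is not None:
        return int(spec.basal_ganglia_top_slice)
    zs = np.where(vent.any(axis=(0, 1)))[0]
    if len(zs) == 0:
        return 0
    # by convention the basal ganglia top sits in the lower third of the
    # ventricle extent, leaving room for the periventricular slab above it
    return int(zs[0] + max(0, (len(zs) // 4) - 1))


# ------------------------------------------------------------- generators

def generate_structural_phantom(spec: PhantomSpec) -> PhantomBundle:
    """FLAIR-side phantom: Gaussian parenchyma, CSF-like ventricles/rim,
    spherical hyperintense lesions, and the matching truth masks."""
    rng = np.random.default_rng(spec.seed)
    intracranial, brain_full, brain, vent = _base_masks(spec)

    wmh = np.zeros(spec.shape, dtype=bool)
    lesion_offsets = np.zeros(spec.shape)
    for les in spec.lesions:
        m = _ellipsoid_mask(spec.shape, spec.spacing, les.center_mm,
                            (les.radius_mm,) * 3)
        if not m.any():
            raise GeometryError(f"lesion at {les.center_mm} rasterizes to no voxels")
        if (m & ~brain).any():
            raise GeometryError(
                f"lesion at {les.center_mm} mm extends outside the parenchyma"
            )
        wmh |= m
        lesion_offsets[m] = les.offset_sd * spec.parenchyma_sd

    data = np.zeros(spec.shape)
    noise = rng.normal(0.0, spec.parenchyma_sd, size=spec.shape)
    data[brain] = spec.parenchyma_mean + noise[brain]
    data += lesion_offsets
    csf = intracranial & ~brain
    data[csf] = spec.csf_intensity

    flair = ImageVolume(data, spec.spacing, modality="FLAIR")
    nx = spec.shape[0]
    return PhantomBundle(
        spec=spec,
        flair=flair,
        brain_mask=brain,
        ventricle_mask=vent,
        intracranial_mask=intracranial,
        wmh_truth=wmh,
        basal_ganglia_top_slice=_default_bg_top(spec, vent),
        midline_x=(nx - 1) / 2.0,
    )


def generate_swi_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Gradient-echo-side phantom: complex volume whose phase is a smooth
    polynomial background plus negative tubular vein dips plus noise,
    wrapped to (-pi, pi); magnitude is near-uniform inside the brain."""
    rng = np.random.default_rng(spec.seed)
    intracranial, brain_full, brain, vent = _base_masks(spec)

    vein = np.zeros(spec.shape, dtype=bool)
    dips = np.zeros(spec.shape)
    for v in spec.veins:
        m = _tube_mask(spec.shape, spec.spacing, v.polyline_mm, v.radius_mm)
        if not m.any():
            raise GeometryError("vein polyline rasterizes to no voxels")
        if (m & ~brain).any():
            raise GeometryError("vein extends outside the parenchyma")
        vein |= m
        dips[m] = np.minimum(dips[m], -v.phase_depth_rad)

    phase = np.zeros(spec.shape)
    if spec.background_coeffs:
        xs, ys, zs = _coords_mm(spec.shape, spec.spacing)
        half = [max(abs(c[0]), abs(c[-1]), 1e-12) for c in (xs, ys, zs)]
        u, v_, w = (c / h for c, h in zip((xs, ys, zs), half))
        for (i, j, k), coeff in spec.background_coeffs.items():
            phase += coeff * np.multiply.outer(
                np.multiply.outer(u**i, v_**j), w**k
            )
    phase += dips
    if spec.phase_noise_sd > 0:
        phase += rng.normal(0.0, spec.phase_noise_sd, size=spec.shape)
    if not spec.allow_wrap and np.abs(phase).max() > np.pi:
        raise ValueError(
            "summed phase exceeds +/-pi and wrapping is disabled for this spec"
        )
    phase = wrap_phase(phase)

    magnitude = np.zeros(spec.shape)
    magnitude[intracranial] = 1.0
    if spec.magnitude_noise_sd > 0:
        magnitude[intracranial] += rng.normal(
            0.0, spec.magnitude_noise_sd, size=int(intracranial.sum())
        )
        magnitude = np.clip(magnitude, 1e-6, None)

    gre = ComplexGREVolume(magnitude * np.exp(1j * phase), spec.spacing)
    nx = spec.shape[0]
    return PhantomBundle(
        spec=spec,
        gre=gre,
        brain_mask=brain,
        ventricle_mask=vent,
        intracranial_mask=intracranial,
        vein_truth=vein,
        basal_ganglia_top_slice=_default_bg_top(spec, vent),
        midline_x=(nx - 1) / 2.0,
    )


def generate_subject_phantom(
    flair_spec: PhantomSpec, swi_spec: PhantomSpec
) -> tuple[PhantomBundle, PhantomBundle]:
    """Paired FLAIR and SWI phantoms for one synthetic subject.

    When the two specs share grid shape and spacing the pair exercises the
    identity-transform path; different slice thicknesses exercise
    coregistration and resampling.
    """
    structural = generate_structural_phantom(flair_spec)
    swi = generate_swi_phantom(swi_spec)
    return structural, swi


def radial_vein_fan(
    n_veins: int,
    slice_indices: Sequence[int],
    inner_mm: float,
    outer_mm: float,
    spacing_z: float,
    nz: int,
    radius_mm: float = 0.5,
    phase_depth_rad: float = 0.6,
) -> tuple[VeinSpec, ...]:
    """Build an in-plane radial fan of straight veins across the given axial
    slices, emulating medullary veins converging toward the ventricles."""
    veins = []
    zs = [(z - (nz - 1) / 2.0) * spacing_z for z in slice_indices]
    per_slice = max(1, n_veins // max(1, len(slice_indices)))
    for si, z in enumerate(zs):
        for i in range(per_slice):
            # evenly spaced around the ring, staggered between slices
            ang = 2.0 * np.pi * i / per_slice + 0.13 + 0.37 * si
            d = np.array([np.cos(ang), np.sin(ang)])
            p0 = (inner_mm * d[0], inner_mm * d[1], z)
            p1 = (outer_mm * d[0], outer_mm * d[1], z)
            veins.append(VeinSpec((p0, p1), radius_mm, phase_depth_rad))
    return tuple(veins)


def default_subject_specs(
    seed: int = 0, same_grid: bool = True
) -> tuple[PhantomSpec, PhantomSpec]:
    """Paired FLAIR/SWI specs for one synthetic subject.

    ``same_grid=True`` puts the FLAIR phantom on the gradient-echo grid
    (identity coregistration path); otherwise the FLAIR side uses 5.0 mm
    slices and exercises resampling.
    """
    swi = default_swi_spec(seed=seed)
    lesion = LesionSpec((0.0, 15.0, 0.0), 7.0, 6.0)
    if same_grid:
        flair = PhantomSpec(
            shape=swi.shape, spacing=swi.spacing,
            brain_radii_mm=swi.brain_radii_mm,
            intracranial_margin_mm=swi.intracranial_margin_mm,
            lesions=(lesion,), seed=seed + 1,
        )
    else:
        flair = PhantomSpec(
            shape=(128, 128, 10), spacing=(0.4688, 0.4688, 5.0),
            brain_radii_mm=swi.brain_radii_mm,
            intracranial_margin_mm=swi.intracranial_margin_mm,
            lesions=(lesion,), seed=seed + 1,
        )
    return flair, swi


def default_structural_spec(seed: int = 0) -> PhantomSpec:
    """Scaled-down FLAIR phantom with one detectable lesion."""
    return PhantomSpec(
        shape=(100, 100, 12),
        spacing=(0.4688, 0.4688, 5.0),
        brain_radii_mm=(20.0, 20.0, 16.0),
        intracranial_margin_mm=2.0,
        lesions=(LesionSpec((0.0, 13.0, 0.0), 7.0, 6.0),),
        seed=seed,
    )


def default_swi_spec(seed: int = 0) -> PhantomSpec:
    """Scaled-down SWI phantom: polynomial background field, phase noise,
    and a fan of veins across the mid slices."""
    shape = (128, 128, 20)
    spacing = (0.4688, 0.4688, 2.0)
    veins = radial_vein_fan(
        165, slice_indices=range(7, 12), inner_mm=14.0, outer_mm=19.5,
        spacing_z=spacing[2], nz=shape[2],
        radius_mm=0.7, phase_depth_rad=1.6,
    )
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        brain_radii_mm=(22.0, 22.0, 16.0),
        intracranial_margin_mm=2.0,
        background_coeffs={(1, 0, 0): 0.8, (0, 1, 0): -0.5, (2, 0, 0): 0.6,
                           (0, 2, 0): 0.4, (1, 1, 0): 0.3, (0, 0, 1): 0.2},
        phase_noise_sd=0.1,
        veins=veins,
        seed=seed,
    )


# ---------------------------------------------------------------- cohort

#: column dictionary for generated cohort tables
COHORT_COLUMNS = {
    "subject_id": "unique subject identifier",
    "age": "age in years",
    "sex": "0 = male, 1 = female",
    "education_years": "years of formal education",
    "hypertension": "0 = no, 1 = treated, 2 = untreated",
    "diabetes": "0/1",
    "hyperlipidemia": "0/1",
    "sbp": "systolic blood pressure, mm Hg",
    "dbp": "diastolic blood pressure, mm Hg",
    "glucose": "serum glucose, mmol/l",
    "tc": "total cholesterol, mmol/l",
    "thcy": "total homocysteine, umol/l",
    "hscrp": "high-sensitivity C-reactive protein, mg/l",
    "mmse": "mini-mental state examination score",
    "n_microbleeds": "microbleed count",
    "n_lacunes": "lacune count",
    "dmv_voxel_count": "deep-medullary-vein voxel count (bilateral)",
    "cwmhv_ml": "ICV-corrected white-matter-hyperintensity volume, ml",
}

#: covariates entering the generating partial-correlation structure
COHORT_ADJUST_COVARIATES = (
    "age", "sex", "education_years", "n_microbleeds", "n_lacunes",
)


@dataclass
class CohortSpec:
    """Synthetic cohort with a tunable partial correlation between
    log-corrected-WMH-volume and DMV voxel count given the adjustment
    covariates (age, sex, education, microbleed count, lacune count).

    Covariate means/SDs default to values typical of an elderly
    small-vessel-disease cohort; counts are Poisson (real counts are
    overdispersed — see the package docs). `wmh_loadings` / `dmv_loadings`
    give each standardized covariate's direct effect on the two outcomes;
    the residual correlation is set to the target so the population partial
    correlation given the covariates equals the target exactly.
    """

    n_subjects: int = 158
    target_partial_correlation: float = 0.5
    age_mean: float = 66.5
    age_sd: float = 12.8
    female_fraction: float = 0.494
    education_mean: float = 7.3
    education_sd: float = 4.6
    sbp_mean: float = 144.0
    sbp_sd: float = 19.0
    dbp_mean: float = 82.8
    dbp_sd: float = 10.8
    glucose_mean: float = 5.5
    glucose_sd: float = 1.9
    tc_mean: float = 4.45
    tc_sd: float = 1.17
    thcy_mean: float = 14.0
    thcy_sd: float = 6.0
    hscrp_mean: float = 9.4
    hscrp_sd: float = 7.5
    mmse_mean: float = 25.8
    mmse_sd: float = 3.5
    lacune_rate: float = 1.9
    microbleed_rate: float = 8.3
    log_cwmhv_mean: float = 3.22  # ln ml; median ~25 ml
    log_cwmhv_sd: float = 0.83
    dmv_mean: float = 3676.0
    dmv_sd: float = 1071.0
    wmh_loadings: dict = field(
        default_factory=lambda: {"age": 0.10, "n_lacunes": 0.30, "n_microbleeds": 0.20}
    )
    dmv_loadings: dict = field(
        default_factory=lambda: {"n_lacunes": 0.25, "n_microbleeds": 0.25}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-1.0 < self.target_partial_correlation < 1.0):
            raise ValueError("target partial correlation must lie in (-1, 1)")
        n_cov = len(COHORT_ADJUST_COVARIATES)
        if self.n_subjects < n_cov + 3:
            raise ValueError(
                f"need at least {n_cov + 3} subjects for {n_cov} covariates "
                f"(df = n - covariates - 2 must be positive), got {self.n_subjects}"
            )
        for name, loadings in (("wmh", self.wmh_loadings), ("dmv", self.dmv_loadings)):
            bad = set(loadings) - set(COHORT_ADJUST_COVARIATES)
            if bad:
                raise ValueError(f"{name}_loadings refer to unknown covariates {bad}")
            if sum(v * v for v in loadings.values()) >= 1.0:
                raise ValueError(
                    f"{name}_loadings have squared norm >= 1; the implied "
                    "correlation matrix is not positive definite "
                    f"(target {self.target_partial_correlation} unreachable)"
                )

    def population_partial_correlation(self) -> float:
        """Partial correlation of log-CWMHV and DMV count given the
        adjustment covariates implied by the generating model.

        Both outcomes are linear in the standardized covariates plus a
        residual, and the residual pair has correlation equal to the
        target, so this is exactly the target by construction.
        """
        return self.target_partial_correlation


def _standardize(col: np.ndarray) -> np.ndarray:
    sd = col.std(ddof=0)
    if sd == 0:
        return np.zeros_like(col, dtype=float)
    return (col - col.mean()) / sd


def generate_cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table whose partial correlation between log-CWMHV and
    DMV voxel count, given age/sex/education/microbleeds/lacunes, equals the
    spec target in the population."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    cov = {
        "age": rng.normal(spec.age_mean, spec.age_sd, n),
        "sex": (rng.random(n) < spec.female_fraction).astype(int),
        "education_years": np.clip(rng.normal(spec.education_mean, spec.education_sd, n), 0, None),
        "n_microbleeds": rng.poisson(spec.microbleed_rate, n),
        "n_lacunes": rng.poisson(spec.lacune_rate, n),
    }
    z = {k: _standardize(np.asarray(v, dtype=float)) for k, v in cov.items()}

    rho = spec.target_partial_correlation
    e = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)

    def latent(loadings, resid):
        lin = np.zeros(n)
        ss = 0.0
        for name, a in loadings.items():
            lin += a * z[name]
            ss += a * a
        return lin + np.sqrt(1.0 - ss) * resid

    x = latent(spec.wmh_loadings, e[:, 0])   # standardized log-CWMHV
    y = latent(spec.dmv_loadings, e[:, 1])   # standardized DMV count

    cwmhv = np.exp(spec.log_cwmhv_mean + spec.log_cwmhv_sd * x)
    dmv = np.clip(np.rint(spec.dmv_mean + spec.dmv_sd * y), 1, None).astype(int)

    table = pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        **cov,
        "hypertension": rng.choice([0, 1, 2], size=n, p=[0.24, 0.56, 0.20]),
        "diabetes": (rng.random(n) < 0.24).astype(int),
        "hyperlipidemia": (rng.random(n) < 0.335).astype(int),
        "sbp": rng.normal(spec.sbp_mean, spec.sbp_sd, n),
        "dbp": rng.normal(spec.dbp_mean, spec.dbp_sd, n),
        "glucose": rng.normal(spec.glucose_mean, spec.glucose_sd, n),
        "tc": rng.normal(spec.tc_mean, spec.tc_sd, n),
        "thcy": rng.normal(spec.thcy_mean, spec.thcy_sd, n),
        "hscrp": np.clip(rng.normal(spec.hscrp_mean, spec.hscrp_sd, n), 0.1, None),
        "mmse": np.clip(np.rint(rng.normal(spec.mmse_mean, spec.mmse_sd, n)), 0, 30).astype(int),
        "dmv_voxel_count": dmv,
        "cwmhv_ml": cwmhv,
    })
    return table[list(COHORT_COLUMNS)]
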