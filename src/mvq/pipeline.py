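"""Subject-level and cohort-level orchestration.

``run_subject`` composes the measurement chain for one subject: homodyne
phase filtering, periventricular slab selection, parenchyma distribution
fits, vein and lesion threshold segmentation, coregistration of the FLAIR
lesion mask onto the phase grid (the phase volume is always the fixed
reference), and volumetry. ``run_cohort`` binds the cohort mean ICV,
computes corrected volumes, and executes the statistical plan: median
dichotomization with group descriptives, partial correlations of
log-corrected lesion volume with the vein voxel count given age, sex,
education and microbleed/lacune counts, and univariate plus backward
stepwise logistic models of large lesion burden with age forced in.

Vein voxel counts enter the regression models in units of 10^3 voxels, so
odds ratios read "per thousand vein voxels".
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats
from .phase import homodyne_highpass_filter
from .segmentation import (
    fit_parenchyma_distribution,
    segment_dmv,
    segment_wmh,
)
from .volumes import ComplexGREVolume, ImageVolume
from .volumetrics import (
    RigidTransform,
    SubjectMeasurements,
    compute_icv,
    mask_volume_ml,
    partition_pvh_dwmh,
    resample_mask,
    rigid_coregister,
    select_periventricular_slab,
)

__all__ = [
    "PipelineConfig",
    "SubjectInputs",
    "StageError",
    "run_subject",
    "run_cohort",
    "subject_inputs_from_phantom",
]

logger = logging.getLogger(__name__)

#: covariates adjusted for in the partial-correlation analyses
ADJUST_COVARIATES = ("age", "sex", "education_years", "n_microbleeds", "n_lacunes")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Run-time constants of the measurement chain.

    Defaults are the protocol constants: k = 3 SD above the mean for WMH,
    k = 2 SD below for veins, a 32 x 32 central filter matrix, a 5-slice
    periventricular slab, and a 10 mm periventricular distance.
    """

    wmh_k: float = 3.0
    dmv_k: float = 2.0
    central_matrix: int = 32
    n_slab_slices: int = 5
    pvh_distance_mm: float = 10.0
    wmh_fit_pct: tuple[float, float] = (2.0, 90.0)
    dmv_fit_pct: tuple[float, float] = (30.0, 70.0)
    fit_method: str = "robust"
    coregister: str = "auto"  # "auto" | "identity" | "register"
    registration_metric: str = "nmi"
    min_cohort_size: int = 10
    stepwise_p_remove: float = 0.10
    univariate_screen_p: float = 0.1
    seed: int = 0

    def to_yaml(self) -> str:
        d = asdict(self)
        d["wmh_fit_pct"] = list(self.wmh_fit_pct)
        d["dmv_fit_pct"] = list(self.dmv_fit_pct)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        for k in ("wmh_fit_pct", "dmv_fit_pct"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def write_resolved(self, out_dir: str | Path) -> None:
        """Every run records its resolved configuration next to its outputs."""
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "resolved_config.yaml").write_text(self.to_yaml())


@dataclass
class SubjectInputs:
    """Per-subject volumes and masks, each on its acquisition grid."""

    subject_id: str
    flair: ImageVolume
    flair_brain_mask: np.ndarray
    flair_ventricle_mask: np.ndarray
    intracranial_mask: np.ndarray
    gre: ComplexGREVolume
    gre_brain_mask: np.ndarray
    gre_ventricle_mask: np.ndarray
    basal_ganglia_top_slice: int
    midline_x: float | None = None
    exclusion_mask: np.ndarray | None = None

    def input_hashes(self) -> dict:
        def h(a):
            return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]

        return {
            "flair": h(self.flair.data),
            "gre": h(self.gre.data),
            "flair_brain_mask": h(self.flair_brain_mask),
            "gre_brain_mask": h(self.gre_brain_mask),
        }


def subject_inputs_from_phantom(
    structural, swi, subject_id: str = "phantom", exclusion: np.ndarray | None = None
) -> SubjectInputs:
    """Assemble pipeline inputs from a paired phantom bundle."""
    return SubjectInputs(
        subject_id=subject_id,
        flair=structural.flair,
        flair_brain_mask=structural.brain_mask,
        flair_ventricle_mask=structural.ventricle_mask,
        intracranial_mask=structural.intracranial_mask,
        gre=swi.gre,
        gre_brain_mask=swi.brain_mask,
        gre_ventricle_mask=swi.ventricle_mask,
        basal_ganglia_top_slice=swi.basal_ganglia_top_slice,
        midline_x=swi.midline_x,
        exclusion_mask=exclusion,
    )


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except StageError:
                raise
            except Exception as e:
                raise StageError(name, str(e)) from e

        return wrapped

    return deco


def run_subject(
    config: PipelineConfig, inputs: SubjectInputs
) -> tuple[SubjectMeasurements, dict]:
    """Execute the full per-subject measurement chain.

    Returns the subject's measurements (corrected volumes unbound until the
    cohort mean ICV is known) and an artifact dict holding the segmentation
    masks, fitted models and reports. Deterministic given config + inputs.
    """
    logger.info("subject %s: inputs %s", inputs.subject_id, inputs.input_hashes())
    artifacts: dict = {}

    fphase = _stage("phase_filter")(homodyne_highpass_filter)(
        inputs.gre, central_matrix=config.central_matrix
    )
    artifacts["filtered_phase"] = fphase

    if inputs.gre_ventricle_mask is None or not np.any(inputs.gre_ventricle_mask):
        raise StageError(
            "slab_selection",
            "a nonempty ventricle mask on the phase grid is required to "
            "select the periventricular slab",
        )
    slab = _stage("slab_selection")(select_periventricular_slab)(
        inputs.gre_ventricle_mask,
        inputs.basal_ganglia_top_slice,
        config.n_slab_slices,
    )
    slab_mask = np.zeros_like(inputs.gre_brain_mask, dtype=bool)
    slab_mask[:, :, list(slab)] = inputs.gre_brain_mask[:, :, list(slab)].astype(bool)
    artifacts["slab_slices"] = slab

    phase_model = _stage("dmv_fit")(fit_parenchyma_distribution)(
        fphase, slab_mask, method=config.fit_method, pct_range=config.dmv_fit_pct
    )
    seg_dmv = _stage("dmv_segmentation")(segment_dmv)(
        fphase,
        slab_mask,
        phase_model,
        k=config.dmv_k,
        exclusion=inputs.exclusion_mask,
        midline_x=inputs.midline_x,
    )
    artifacts["dmv_segmentation"] = seg_dmv

    flair_model = _stage("wmh_fit")(fit_parenchyma_distribution)(
        inputs.flair, inputs.flair_brain_mask,
        method=config.fit_method, pct_range=config.wmh_fit_pct,
    )
    seg_wmh = _stage("wmh_segmentation")(segment_wmh)(
        inputs.flair, inputs.flair_brain_mask, flair_model, k=config.wmh_k
    )
    artifacts["wmh_segmentation"] = seg_wmh

    wmhv = mask_volume_ml(seg_wmh.mask, inputs.flair.spacing)
    parenchyma_ml = mask_volume_ml(inputs.flair_brain_mask, inputs.flair.spacing)
    icv = _stage("volumetry")(compute_icv)(
        inputs.intracranial_mask, inputs.flair.spacing, parenchyma_ml=parenchyma_ml
    )
    pvh, dwmh = _stage("pvh_partition")(partition_pvh_dwmh)(
        seg_wmh.mask, inputs.flair_ventricle_mask, inputs.flair.spacing,
        distance_mm=config.pvh_distance_mm,
    )

    phase_ref = ImageVolume(np.abs(inputs.gre.data), inputs.gre.spacing, "magnitude")
    same_grid = inputs.flair.shape == inputs.gre.shape and np.allclose(
        inputs.flair.spacing, inputs.gre.spacing
    )
    if config.coregister == "identity" or (config.coregister == "auto" and same_grid):
        if not same_grid:
            raise StageError(
                "coregistration",
                "identity coregistration requires FLAIR and phase on one grid",
            )
        transform = RigidTransform(reference_shape=phase_ref.shape,
                                   reference_spacing=phase_ref.spacing)
        wmh_on_phase = seg_wmh.mask.astype(bool)
    else:
        transform = _stage("coregistration")(rigid_coregister)(
            inputs.flair, phase_ref, metric=config.registration_metric
        )
        wmh_on_phase = _stage("coregistration")(resample_mask)(
            seg_wmh.mask, transform, phase_ref, inputs.flair.spacing
        )
    artifacts["flair_to_phase_transform"] = transform
    artifacts["wmh_on_phase_grid"] = wmh_on_phase

    regional_mask = np.zeros_like(wmh_on_phase, dtype=bool)
    regional_mask[:, :, list(slab)] = wmh_on_phase[:, :, list(slab)]
    regional_raw = mask_volume_ml(regional_mask, inputs.gre.spacing)

    meas = SubjectMeasurements(
        subject_id=inputs.subject_id,
        wmhv_ml=wmhv,
        icv_ml=icv,
        pvh_ml=mask_volume_ml(pvh, inputs.flair.spacing),
        dwmh_ml=mask_volume_ml(dwmh, inputs.flair.spacing),
        regional_wmh_ml=regional_raw,
        dmv_count_total=seg_dmv.count_total,
        dmv_count_left=seg_dmv.count_left,
        dmv_count_right=seg_dmv.count_right,
        slab_slices=tuple(slab),
    )
    artifacts["report"] = {
        "subject_id": inputs.subject_id,
        "dmv": seg_dmv.to_report(),
        "wmh": seg_wmh.to_report(),
        "measurements": meas.to_dict(),
        "input_hashes": inputs.input_hashes(),
    }
    return meas, artifacts


# ---------------------------------------------------------------- cohort

#: Table-1-style descriptive variables: (column, kind)
DESCRIPTIVE_VARS = [
    ("age", "continuous"),
    ("sex", "dichotomous"),
    ("education_years", "continuous"),
    ("mmse", "continuous"),
    ("hypertension", "categorical"),
    ("diabetes", "dichotomous"),
    ("hyperlipidemia", "dichotomous"),
    ("sbp", "continuous"),
    ("dbp", "continuous"),
    ("glucose", "continuous"),
    ("tc", "continuous"),
    ("thcy", "continuous"),
    ("hscrp", "continuous"),
    ("n_microbleeds", "continuous"),
    ("n_lacunes", "continuous"),
]

#: stepwise candidates screened at univariate p < 0.1 (MMSE excluded by
#: design: it is a consequence of lesion severity, not a candidate cause)
SCREENED_CANDIDATES = ("sbp", "dbp", "glucose", "tc", "thcy", "hscrp",
                       "n_microbleeds", "n_lacunes")


def _descriptives_by_group(table: pd.DataFrame, labels: np.ndarray) -> pd.DataFrame:
    rows = []
    lo, hi = labels == "low", labels == "high"
    for col, kind in DESCRIPTIVE_VARS:
        if col not in table.columns:
            continue
        v = table[col].to_numpy(dtype=float)
        if kind == "continuous":
            t, df, p = stats.two_sample_t_test(v[lo], v[hi])
            rows.append({
                "variable": col, "kind": kind,
                "low_mean": v[lo].mean(), "low_sd": v[lo].std(ddof=1),
                "high_mean": v[hi].mean(), "high_sd": v[hi].std(ddof=1),
                "p": p,
            })
        else:
            levels = np.unique(v)
            counts = np.array([
                [(v[g] == lev).sum() for lev in levels] for g in (lo, hi)
            ])
            keep = counts.sum(axis=0) > 0
            p = stats.fisher_exact(counts[:, keep])
            rows.append({
                "variable": col, "kind": kind,
                "low_mean": v[lo].mean(), "low_sd": np.nan,
                "high_mean": v[hi].mean(), "high_sd": np.nan,
                "p": p,
            })
    return pd.DataFrame(rows)


def run_cohort(
    config: PipelineConfig,
    table: pd.DataFrame | None = None,
    measurements: list[SubjectMeasurements] | None = None,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Cohort-level analysis.

    Either pass a ready cohort ``table`` (one row per subject with
    ``cwmhv_ml``, ``dmv_voxel_count`` and covariate columns), or pass
    per-subject ``measurements`` plus a ``covariates`` table keyed by
    ``subject_id`` — in that case the cohort mean ICV is bound here and
    corrected volumes are (re)computed before analysis. Rows with missing
    values in analysis columns are dropped with a logged count.
    """
    if table is None:
        if measurements is None or covariates is None:
            raise ValueError("need either a cohort table or measurements + covariates")
        mean_icv = float(np.mean([m.icv_ml for m in measurements]))
        for m in measurements:
            m.bind_mean_icv(mean_icv)
        meas_df = pd.DataFrame([m.to_dict() for m in measurements])
        meas_df = meas_df.rename(columns={"dmv_count_total": "dmv_voxel_count"})
        table = meas_df.merge(covariates, on="subject_id", how="inner")
    else:
        table = table.copy()
        mean_icv = float(table["icv_ml"].mean()) if "icv_ml" in table else None

    needed = ["cwmhv_ml", "dmv_voxel_count", *ADJUST_COVARIATES]
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks required columns {missing_cols}")
    before = len(table)
    table = table.dropna(subset=[c for c in needed if c in table.columns])
    dropped = before - len(table)
    if dropped:
        logger.warning("dropped %d rows with missing analysis values", dropped)
    if len(table) < config.min_cohort_size:
        raise ValueError(
            f"cohort has {len(table)} usable subjects, below the floor of "
            f"{config.min_cohort_size}"
        )

    log_cwmhv = stats.natural_log_transform(table["cwmhv_ml"].to_numpy())
    labels, cutoff = stats.dichotomize_at_median(table["cwmhv_ml"].to_numpy())
    y_large = (labels == "high").astype(float)

    descriptives = _descriptives_by_group(table, labels)

    cov_df = table[list(ADJUST_COVARIATES)].astype(float)
    dmv = table["dmv_voxel_count"].to_numpy(dtype=float)
    partials = {}
    targets = {"log_cwmhv": log_cwmhv}
    for extra in ("pvh_corrected_ml", "dwmh_corrected_ml", "regional_wmh_corrected_ml"):
        if extra in table.columns and table[extra].notna().all() and (table[extra] > 0).all():
            targets[f"log_{extra}"] = stats.natural_log_transform(
                table[extra].to_numpy()
            )
    for name, vec in targets.items():
        partials[name] = stats.partial_pearson(vec, dmv, cov_df)
    raw_p = [a.p_value for a in partials.values()]
    adj_p = stats.bonferroni_adjust(raw_p)
    partial_table = pd.DataFrame({
        "target": list(partials),
        "r_plain": [a.r_plain for a in partials.values()],
        "r_partial": [a.r_partial for a in partials.values()],
        "df": [a.df for a in partials.values()],
        "p_raw": raw_p,
        "p_bonferroni": adj_p,
    })

    # regression candidates; vein count in 10^3 voxels
    cand = pd.DataFrame({
        "age": table["age"].astype(float),
        "sex": table["sex"].astype(float),
        "education_years": table["education_years"].astype(float),
        "dmv_voxels_k": dmv / 1000.0,
    })
    for c in SCREENED_CANDIDATES:
        if c in table.columns and c not in cand.columns:
            cand[c] = table[c].astype(float)

    univariate = {}
    for c in cand.columns:
        m = stats.fit_logistic(y_large, cand[[c]])
        row = m.table.loc[c]
        univariate[c] = {
            "or": float(row["or"]), "ci_low": float(row["ci_low"]),
            "ci_high": float(row["ci_high"]), "p": float(row["p"]),
        }

    stepwise = stats.backward_stepwise_logistic(
        y_large,
        cand,
        forced=("age",),
        always_include=("sex", "education_years", "dmv_voxels_k"),
        p_remove=config.stepwise_p_remove,
        screen_p=config.univariate_screen_p,
        outcome=f"cwmhv > {cutoff:.2f} ml",
    )

    return {
        "n_subjects": int(len(table)),
        "mean_icv_ml": mean_icv,
        "median_cwmhv_ml": cutoff,
        "group_sizes": {
            "low": int((labels == "low").sum()),
            "high": int((labels == "high").sum()),
        },
        "descriptives": descriptives,
        "partial_correlations": partial_table,
        "univariate_or": univariate,
        "stepwise_model": stepwise,
        "table": table,
    }


def cohort_report_json(report: dict) -> str:
    """Serialize a cohort report to JSON (DataFrames become records)."""
    out = {}
    for k, v in report.items():
        if isinstance(v, pd.DataFrame):
            out[k] = v.to_dict(orient="records")
        elif isinstance(v, stats.LogisticModel):
            out[k] = {
                "outcome": v.outcome,
                "coefficients": v.table.reset_index(names="term").to_dict(orient="records"),
                "forced": list(v.forced),
                "removal_trace": [
                    {"term": t, "step": s, "removal_p": p} for t, s, p in v.removal_trace
                ],
                "log_likelihood": v.log_likelihood,
                "n": v.n,
            }
        else:
            out[k] = v
    return json.dumps(out, indent=2, default=lambda o: float(o) if np.isscalar(o) else str(o))
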