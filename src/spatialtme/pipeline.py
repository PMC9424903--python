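"""End-to-end orchestration: fields in, biomarkers and survival fits out.

``profile_cohort`` runs, for every patient field: lineage gating against
FMO-derived thresholds, tumor-mask segmentation into IF / TN / ISA,
region assignment, and region-wise density computation. Per-field values
are averaged into patient values, from which it derives the MMP14+
CAF/CAF ratio class (median split), both Immunoscore variants, and the
four risk groups. ``fit_survival`` then fits the multivariable Cox model
and the group-C contrast on the resulting patient table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import scoring, survival
from .gating import GatingConfig, default_gating_config, derive_thresholds, gate_lineages
from .segmentation import SegmentationParams, assign_regions, segment_field

__all__ = ["profile_cohort", "fit_survival", "run_pipeline"]

DENSITY_POPULATIONS = ("CD3", "CD8", "CAF", "M1_TAM", "M2_TAM", "TIL", "MDSC", "tumor")


def profile_cohort(
    fields_by_patient: dict[str, list],
    gating_config: GatingConfig,
    seg_params: SegmentationParams | None = None,
    ratio_mode: str = "mean_of_fields",
) -> pd.DataFrame:
    """Measure per-patient biomarkers from raw per-field cell tables.

    ``fields_by_patient`` maps patient id to a list of cell tables (or
    ``(cells, nests)`` tuples as produced by the simulator); cells need
    coordinate and marker-intensity columns only — gating and
    segmentation are performed here, with the gated panCK+ (tumor)
    lineage defining the tumor mask.

    Returns one row per patient: ``mmp14_caf_ratio``, per-region T-cell
    densities, Immunoscore classes for both variants (``is_high``,
    ``conventional_high`` as 0/1 indicators), the ratio class, and the
    risk group.
    """
    if seg_params is None:
        seg_params = SegmentationParams()

    density_rows = []
    ratio_fields: dict[str, list[pd.DataFrame]] = {}
    for pid, fields in fields_by_patient.items():
        ratio_fields[pid] = []
        for k, item in enumerate(fields):
            cells = item[0] if isinstance(item, tuple) else item
            gated = gate_lineages(cells, gating_config)
            field_size = _infer_field_size(gated, seg_params)
            masks = segment_field(
                gated,
                field_size_um=field_size,
                params=seg_params,
                tumor_flag=(gated["lineage"] == "tumor").to_numpy(),
            )
            labeled = assign_regions(gated, masks)
            dens = scoring.field_densities(labeled, masks.areas_mm2, DENSITY_POPULATIONS)
            dens["patient_id"] = pid
            dens["field_id"] = k
            density_rows.append(dens)
            ratio_fields[pid].append(labeled)

    per_field = pd.concat(density_rows, ignore_index=True)
    per_patient = scoring.patient_densities(per_field)

    patients = sorted(fields_by_patient)
    ratio = pd.Series(
        {
            pid: scoring.patient_positive_fraction(ratio_fields[pid], mode=ratio_mode)
            for pid in patients
        },
        name="mmp14_caf_ratio",
    )
    ratio_klass = scoring.dichotomize_by_median(ratio)

    is_score = scoring.immunoscore(per_patient, variant="is").set_index("patient_id")
    conv_score = scoring.immunoscore(per_patient, variant="conventional").set_index("patient_id")

    out = pd.DataFrame({"patient_id": patients}).set_index("patient_id", drop=False)
    out["mmp14_caf_ratio"] = ratio
    out["ratio_klass"] = ratio_klass
    out["is_total"] = is_score["total"]
    out["is_klass"] = is_score["klass"]
    out["conventional_total"] = conv_score["total"]
    out["conventional_klass"] = conv_score["klass"]
    out["group"] = scoring.risk_groups(out["is_klass"], out["ratio_klass"])
    out["is_high"] = (out["is_klass"] == "high").astype(int)
    out["ratio_high"] = (out["ratio_klass"] == "high").astype(int)
    return out.reset_index(drop=True)


def _infer_field_size(cells: pd.DataFrame, seg_params: SegmentationParams) -> float:
    """Field side length: smallest multiple of the grid resolution
    covering the observed coordinates, defaulting to 1884 µm."""
    extent = float(max(cells["x_um"].max(), cells["y_um"].max(), 0.0))
    default = 1884.0
    if extent <= default:
        return default
    res = seg_params.grid_resolution_um
    return float(np.ceil(extent / res) * res)


def fit_survival(patient_table: pd.DataFrame) -> dict:
    """Multivariable Cox model plus the group-C contrast.

    ``patient_table`` must hold the clinical covariates, ``rfs_months``
    and ``event``, and the measured biomarker indicators (``is_high``,
    ``ratio_high``, ``group``). Returns a dict with the tidy fit tables
    and the four-group Kaplan-Meier curves.
    """
    covariates = survival.TABLE_COVARIATES + survival.BIOMARKER_TERMS
    multivariable = survival.cox_fit(patient_table, covariates)
    contrast, curves = survival.group_c_contrast(patient_table)
    return {
        "multivariable": multivariable,
        "group_c": contrast,
        "km_curves": curves,
    }


def run_pipeline(
    clinical: pd.DataFrame,
    fields_by_patient: dict[str, list],
    fmo_samples: dict[str, np.ndarray],
    positivity_quantile: float = 0.99,
    seg_params: SegmentationParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Convenience wrapper: thresholds -> profiling -> survival fits.

    Returns the merged patient table (clinical + measured biomarkers) and
    the survival-fit dict from :func:`fit_survival`.
    """
    thresholds = derive_thresholds(fmo_samples, positivity_quantile)
    config = default_gating_config(thresholds, positivity_quantile)
    biomarkers = profile_cohort(fields_by_patient, config, seg_params)
    merged = clinical.merge(biomarkers, on="patient_id")
    fits = fit_survival(merged)
    return merged, fits
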