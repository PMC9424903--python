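"""Region-wise densities, Immunoscore variants, marker-positive fractions,
and the two-biomarker risk groups.

Conventions used throughout (they interlock, so they are stated once):

* A patient-level value is the arithmetic mean of that patient's
  per-field values; missing fields are skipped, and a patient with no
  usable field gets a missing value, never a zero.
* Median dichotomization is uniform: values less than or equal to the
  cohort median are ``low``, values strictly above it are ``high``. The
  same tie rule gives the Immunoscore components (density at the median
  scores 0).
* The Immunoscore sums four binary components — CD3+ and CD8+ T-cell
  density, each scored against the cohort median in two regions — and is
  ``high`` iff the total is at least 2. The conventional variant scores
  the center of tumor (CT = TN plus ISA) and the invasive front (IF);
  the IS variant replaces CT with the intratumoral stromal area (ISA),
  excluding tumor nests where T-cell density carries no prognostic
  signal.
* The MMP14+ CAF/CAF ratio is the fraction of intratumoral (TN and ISA;
  the invasive front is excluded because peritumoral smooth muscle also
  stains for aSMA) CAFs positive for MMP14. A field with no CAF in the
  denominator contributes a missing value, not a zero.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IMMUNOSCORE_REGIONS",
    "compute_density",
    "field_densities",
    "patient_densities",
    "dichotomize_by_median",
    "immunoscore",
    "positive_fraction",
    "patient_positive_fraction",
    "risk_groups",
]

#: Region pairs scored by each Immunoscore variant.
IMMUNOSCORE_REGIONS = {"conventional": ("CT", "IF"), "is": ("ISA", "IF")}

#: Populations whose densities feed the Immunoscore.
T_CELL_POPULATIONS = ("CD3", "CD8")


def compute_density(n_cells: int, region_area_mm2: float) -> float:
    """Cell density (cells/mm²) for one lineage in one region."""
    if region_area_mm2 <= 0 or np.isnan(region_area_mm2):
        raise ValueError("region area must be positive; a missing region is a missing value")
    return n_cells / region_area_mm2


def _population_mask(cells: pd.DataFrame, population: str) -> np.ndarray:
    """Cells belonging to a named population.

    Populations are lineage labels plus the derived T-cell sets: ``CD3``
    (all T cells) and ``CD8`` (cytotoxic subset, TILs with a positive CD8
    flag).
    """
    lineage = cells["lineage"].to_numpy()
    if population == "CD3":
        return lineage == "TIL"
    if population == "CD8":
        return (lineage == "TIL") & cells["CD8_pos"].to_numpy(dtype=bool)
    return lineage == population


def field_densities(
    cells: pd.DataFrame,
    areas_mm2: Mapping[str, float],
    populations: Sequence[str],
    regions: Sequence[str] = ("IF", "TN", "ISA", "CT"),
) -> pd.DataFrame:
    """Tidy per-field density table for one region-labeled field.

    ``areas_mm2`` comes from the field's RegionMaskSet; a region with zero
    area yields missing densities for that region (the field does not
    contain it).
    """
    region_col = cells["region"].to_numpy()
    rows = []
    for population in populations:
        pop = _population_mask(cells, population)
        for region in regions:
            if region == "CT":
                in_region = (region_col == "TN") | (region_col == "ISA")
            else:
                in_region = region_col == region
            area = areas_mm2.get(region, 0.0)
            if area > 0:
                dens = compute_density(int((pop & in_region).sum()), area)
            else:
                dens = np.nan
            rows.append({"population": population, "region": region, "density": dens})
    return pd.DataFrame(rows)


def patient_densities(per_field: pd.DataFrame) -> pd.DataFrame:
    """Average per-field densities into patient values.

    Expects a tidy table with columns ``patient_id, field_id, population,
    region, density``; returns ``patient_id, population, region, density``
    where the patient value is the mean over fields, ignoring missing
    fields (all-missing stays missing).
    """
    return (
        per_field.groupby(["patient_id", "population", "region"], as_index=False)["density"]
        .mean()
    )


def dichotomize_by_median(values: pd.Series) -> pd.Series:
    """Median split: value <= cohort median -> ``low``, above -> ``high``.

    Missing values stay missing; the median is taken over non-missing
    values and at least two are required.
    """
    clean = values.dropna()
    if len(clean) < 2:
        raise ValueError("need at least 2 non-missing values to dichotomize")
    median = clean.median()
    out = pd.Series(
        np.where(values > median, "high", "low"), index=values.index, dtype=object
    )
    out[values.isna()] = np.nan
    return out


def immunoscore(
    densities: pd.DataFrame,
    variant: str = "is",
    medians: Mapping[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Per-patient Immunoscore for one variant.

    ``densities`` is the tidy patient-level table from
    :func:`patient_densities` and must cover the CD3 and CD8 populations
    in the variant's two regions. Each of the four components scores 1
    when the patient's density is strictly above the cohort median of
    that (population, region) and 0 otherwise, including exact ties.
    A missing density leaves that component missing; the total is the sum
    of the available components and the class is ``high`` iff total >= 2.

    ``medians`` may supply pre-computed cohort medians keyed by
    ``(population, region)``; by default they are computed from
    ``densities`` itself.
    """
    if variant not in IMMUNOSCORE_REGIONS:
        raise ValueError(f"unknown Immunoscore variant {variant!r}")
    regions = IMMUNOSCORE_REGIONS[variant]

    wide = densities.set_index(["patient_id", "population", "region"])["density"]
    patients = densities["patient_id"].unique()
    rows = []
    for pid in patients:
        components = {}
        for population in T_CELL_POPULATIONS:
            for region in regions:
                key = (population, region)
                try:
                    value = wide.loc[(pid, population, region)]
                except KeyError:
                    value = np.nan
                if medians is not None:
                    med = medians[key]
                else:
                    med = (
                        densities.query("population == @population and region == @region")[
                            "density"
                        ].median()
                    )
                comp = np.nan if np.isnan(value) else int(value > med)
                components[f"{population}_{region}"] = comp
        vals = np.array(list(components.values()), dtype=float)
        n_avail = int(np.sum(~np.isnan(vals)))
        total = np.nan if n_avail == 0 else int(np.nansum(vals))
        klass = np.nan if n_avail == 0 else ("high" if total >= 2 else "low")
        rows.append(
            {
                "patient_id": pid,
                **components,
                "n_components": n_avail,
                "total": total,
                "klass": klass,
                "variant": variant,
            }
        )
    return pd.DataFrame(rows)


def positive_fraction(
    cells: pd.DataFrame,
    lineage: str,
    flag_col: str,
    regions: Iterable[str] = ("TN", "ISA"),
) -> tuple[int, int, float]:
    """Marker-positive fraction of a lineage within a region set.

    Returns ``(numerator, denominator, ratio)``; the ratio is missing
    (NaN) when the denominator is zero.
    """
    region_set = set(regions)
    sel = (cells["lineage"] == lineage) & cells["region"].isin(region_set)
    denominator = int(sel.sum())
    numerator = int((sel & cells[flag_col].astype(bool)).sum())
    if denominator == 0:
        logger.warning("no %s cells in regions %s; ratio is missing", lineage, sorted(region_set))
        return numerator, denominator, float("nan")
    return numerator, denominator, numerator / denominator


def patient_positive_fraction(
    fields: Iterable[pd.DataFrame],
    lineage: str = "CAF",
    flag_col: str = "MMP14_pos",
    regions: Iterable[str] = ("TN", "ISA"),
    mode: str = "mean_of_fields",
) -> float:
    """Patient-level positive fraction over multiple fields.

    ``mean_of_fields`` (default) averages per-field ratios, consistent
    with the field-averaging rule for densities; ``pooled`` sums counts
    across fields before dividing.
    """
    if mode not in ("mean_of_fields", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    nums, dens, ratios = [], [], []
    for cells in fields:
        n, d, r = positive_fraction(cells, lineage, flag_col, regions)
        nums.append(n)
        dens.append(d)
        ratios.append(r)
    if mode == "pooled":
        total = sum(dens)
        return float("nan") if total == 0 else sum(nums) / total
    ratios = [r for r in ratios if not np.isnan(r)]
    return float("nan") if not ratios else float(np.mean(ratios))


def risk_groups(is_klass: pd.Series, ratio_klass: pd.Series) -> pd.Series:
    """Four-group stratification from the IS-Immunoscore class and the
    MMP14+ CAF/CAF ratio class.

    A: high score, high ratio; B: high score, low ratio; C: low score,
    high ratio (the poor-prognosis group); D: low score, low ratio.
    Missing inputs give a missing group.
    """
    mapping = {
        ("high", "high"): "A",
        ("high", "low"): "B",
        ("low", "high"): "C",
        ("low", "low"): "D",
    }
    out = pd.Series(np.nan, index=is_klass.index, dtype=object)
    for idx in is_klass.index:
        key = (is_klass.loc[idx], ratio_klass.loc[idx])
        if key in mapping:
            out.loc[idx] = mapping[key]
    return out
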