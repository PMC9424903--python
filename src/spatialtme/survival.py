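"""Kaplan-Meier estimation, log-rank tests, and Cox proportional-hazards
fits for dichotomized clinical and biomarker covariates.

The Cox model surface mirrors the cohort analysis this package supports:
all covariates are binary indicators (age >= 67, female sex, left-sided
or rectal location, stage IIIC, unfavorable histology, 5-FU-only adjuvant
chemotherapy) plus the two biomarkers (IS-Immunoscore class and MMP14+
CAF/CAF ratio class). Ties use Efron's partial likelihood and confidence
intervals are Wald intervals on the log-hazard scale (the lifelines
defaults); all p-values are two-sided.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

logger = logging.getLogger(__name__)

__all__ = [
    "TABLE_COVARIATES",
    "BIOMARKER_TERMS",
    "km_logrank",
    "cox_fit",
    "group_c_contrast",
    "cohort_characteristics",
]

#: Clinical covariates retained in the multivariable model.
TABLE_COVARIATES = [
    "age_ge_67",
    "female",
    "left_or_rectum",
    "stage_iiic",
    "histology_unfavorable",
    "chemo_5fu_only",
]

#: Biomarker indicator columns (1 = high).
BIOMARKER_TERMS = ["is_high", "ratio_high"]


def km_logrank(
    times: pd.Series | np.ndarray,
    events: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
) -> tuple[dict, float, float]:
    """Kaplan-Meier curves per group plus the log-rank test.

    Returns ``(curves, statistic, p)`` where ``curves`` maps each group
    label to a step-function DataFrame (columns ``time`` and
    ``survival``). Requires at least two non-empty groups.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise ValueError("log-rank test needs at least two groups")
    if (counts == 0).any():
        raise ValueError("every group must contain at least one subject")

    curves = {}
    for label in labels:
        sel = groups == label
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(label))
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )

    result = multivariate_logrank_test(times, groups, events)
    return curves, float(result.test_statistic), float(result.p_value)


def cox_fit(
    data: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "rfs_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Cox proportional-hazards fit over binary covariates.

    Returns a tidy table with one row per term: hazard ratio, Wald 95%
    confidence bounds, and two-sided p-value. Zero-variance terms are an
    error; fewer events than terms triggers a warning, not an error.
    """
    for term in covariates:
        if data[term].nunique(dropna=True) < 2:
            raise ValueError(f"covariate {term!r} has zero variance")
    n_events = int(data[event_col].sum())
    if n_events < len(covariates):
        warnings.warn(
            f"only {n_events} events for {len(covariates)} terms; estimates may be unstable",
            stacklevel=2,
        )
    cph = CoxPHFitter()
    cph.fit(
        data[covariates + [duration_col, event_col]],
        duration_col=duration_col,
        event_col=event_col,
    )
    summary = cph.summary
    return pd.DataFrame(
        {
            "term": summary.index,
            "hr": summary["exp(coef)"].to_numpy(),
            "ci_lower": summary["exp(coef) lower 95%"].to_numpy(),
            "ci_upper": summary["exp(coef) upper 95%"].to_numpy(),
            "p": summary["p"].to_numpy(),
        }
    ).reset_index(drop=True)


def group_c_contrast(
    data: pd.DataFrame,
    group_col: str = "group",
    duration_col: str = "rfs_months",
    event_col: str = "event",
) -> tuple[pd.DataFrame, dict]:
    """Univariable contrast of risk group C against groups A, B and D
    combined, plus Kaplan-Meier curves for all four groups.

    Returns ``(fit, curves)``: the one-term Cox fit for the group-C
    indicator and the per-group survival step functions.
    """
    groups = data[group_col]
    if not (groups == "C").any():
        raise ValueError("group C is empty")
    work = data[[duration_col, event_col]].copy()
    work["group_c"] = (groups == "C").astype(int)
    fit = cox_fit(work, ["group_c"], duration_col=duration_col, event_col=event_col)
    curves, _, _ = km_logrank(data[duration_col], data[event_col], groups)
    return fit, curves


def cohort_characteristics(
    clinical: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Characteristics table: per-level patient counts with percentages
    of the cohort (rounded half-up to whole percent).

    Accepts binary or categorical columns; the output is tidy with one
    row per (characteristic, level).
    """
    if columns is None:
        columns = [c for c in clinical.columns if c != "patient_id"]
    n = len(clinical)
    rows = []
    for col in columns:
        counts = clinical[col].value_counts(dropna=False)
        for level, count in counts.items():
            rows.append(
                {
                    "characteristic": col,
                    "level": level,
                    "n": int(count),
                    "pct": int(np.floor(100.0 * count / n + 0.5)),
                }
            )
    return pd.DataFrame(rows)
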