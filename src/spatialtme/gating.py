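"""Marker gating: FMO thresholds and rule-based lineage calls.

Positivity thresholds are derived from fluorescence-minus-one (FMO) null
samples as empirical quantiles (nearest-rank convention: the
``ceil(q * n)``-th order statistic). A cell is positive for a marker iff
its intensity is strictly greater than the threshold, so ties with the
threshold count as negative.

Lineages are assigned by an ordered list of rules, each requiring a set
of positive and a set of negative markers; the first matching rule wins
and unmatched cells are ``UNCLASSIFIED``. The default rule set encodes
the usual mIHC lineage definitions: tumor cells are panCK+; CAFs are
aSMA+ cells negative for panCK, CD45 and CD31; macrophages are
CD45+CD68+ (M2 if additionally CD163+, else M1); T cells are CD45+CD3+
with CD8 recorded as a sub-flag; MDSCs are CD45+ myeloid-marker+ CD68-
(the myeloid marker is configurable, CD33 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "UNCLASSIFIED",
    "LineageRule",
    "GatingConfig",
    "derive_threshold_fmo",
    "derive_thresholds",
    "default_gating_config",
    "gate_lineages",
    "mark_positive",
]

UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class LineageRule:
    """One gate: ``lineage`` requires all ``positive`` markers above and
    all ``negative`` markers at or below their thresholds."""

    lineage: str
    positive: tuple[str, ...] = ()
    negative: tuple[str, ...] = ()

    @property
    def markers(self) -> tuple[str, ...]:
        return self.positive + self.negative


@dataclass
class GatingConfig:
    """Thresholds plus an ordered rule list (first match wins)."""

    thresholds: dict[str, float]
    rules: list[LineageRule]
    positivity_quantile: float = 0.99

    def __post_init__(self) -> None:
        missing = {
            m for rule in self.rules for m in rule.markers if m not in self.thresholds
        }
        if missing:
            raise ValueError(f"rules reference markers without thresholds: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path: str) -> "GatingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rules = [
            LineageRule(
                lineage=r["lineage"],
                positive=tuple(r.get("positive", [])),
                negative=tuple(r.get("negative", [])),
            )
            for r in raw["rules"]
        ]
        return cls(
            thresholds={k: float(v) for k, v in raw["thresholds"].items()},
            rules=rules,
            positivity_quantile=float(raw.get("positivity_quantile", 0.99)),
        )

    def to_yaml(self, path: str) -> None:
        raw = {
            "positivity_quantile": self.positivity_quantile,
            "thresholds": {k: float(v) for k, v in self.thresholds.items()},
            "rules": [
                {
                    "lineage": r.lineage,
                    "positive": list(r.positive),
                    "negative": list(r.negative),
                }
                for r in self.rules
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def derive_threshold_fmo(
    null_intensities: Iterable[float], positivity_quantile: float = 0.99
) -> float:
    """FMO positivity threshold: nearest-rank empirical quantile of the
    null sample (the ``ceil(q * n)``-th order statistic)."""
    values = np.sort(np.asarray(list(null_intensities), dtype=float))
    if values.size == 0:
        raise ValueError("empty FMO null sample")
    if not (0.0 < positivity_quantile < 1.0):
        raise ValueError("positivity_quantile must lie in (0, 1)")
    k = math.ceil(positivity_quantile * values.size)
    return float(values[k - 1])


def derive_thresholds(
    fmo_samples: Mapping[str, Iterable[float]], positivity_quantile: float = 0.99
) -> dict[str, float]:
    """Per-marker FMO thresholds for a panel of null samples."""
    return {
        marker: derive_threshold_fmo(sample, positivity_quantile)
        for marker, sample in fmo_samples.items()
    }


def default_gating_config(
    thresholds: Mapping[str, float],
    positivity_quantile: float = 0.99,
    mdsc_marker: str = "CD33",
) -> GatingConfig:
    """The default lineage tree. The tumor gate is evaluated first so that
    panCK dominates double-positive conflicts; M2 precedes M1 so that
    CD163 splits the macrophage gate."""
    rules = [
        LineageRule("tumor", positive=("panCK",)),
        LineageRule("CAF", positive=("aSMA",), negative=("panCK", "CD45", "CD31")),
        LineageRule("M2_TAM", positive=("CD45", "CD68", "CD163")),
        LineageRule("M1_TAM", positive=("CD45", "CD68")),
        LineageRule("TIL", positive=("CD45", "CD3")),
        LineageRule("MDSC", positive=("CD45", mdsc_marker), negative=("CD68",)),
    ]
    return GatingConfig(
        thresholds=dict(thresholds), rules=rules, positivity_quantile=positivity_quantile
    )


def mark_positive(
    cells: pd.DataFrame, marker: str, threshold: float
) -> pd.Series:
    """Per-cell positivity flag: intensity strictly above the threshold."""
    if marker not in cells.columns:
        raise KeyError(f"marker column {marker!r} not in cell table")
    return cells[marker] > threshold


def gate_lineages(cells: pd.DataFrame, config: GatingConfig) -> pd.DataFrame:
    """Assign a lineage to every cell (first matching rule wins).

    Returns a copy of ``cells`` with a ``lineage`` column and one boolean
    ``<marker>_pos`` column per thresholded marker.
    """
    missing = [
        m for rule in config.rules for m in rule.markers if m not in cells.columns
    ]
    if missing:
        raise ValueError(f"cell table lacks marker columns: {sorted(set(missing))}")

    out = cells.copy()
    flags: dict[str, np.ndarray] = {}
    for marker, thr in config.thresholds.items():
        if marker in cells.columns:
            flags[marker] = (cells[marker].to_numpy(dtype=float) > thr)
            out[f"{marker}_pos"] = flags[marker]

    lineage = np.full(len(cells), UNCLASSIFIED, dtype=object)
    unassigned = np.ones(len(cells), dtype=bool)
    for rule in config.rules:
        match = unassigned.copy()
        for m in rule.positive:
            match &= flags[m]
        for m in rule.negative:
            match &= ~flags[m]
        lineage[match] = rule.lineage
        unassigned &= ~match
    out["lineage"] = lineage
    return out
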