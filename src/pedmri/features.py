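"""First-order radiomic features.

For each quantitative map (ADC, UCBV, K2, CCBV) and each region (tumour ROI,
whole brain) the four histogram moments mean / SD / skewness / kurtosis are
computed over the in-mask voxels, plus the tumour volume in cm^3 — 33
features per subject in total.  Conventions follow common radiomics usage:
sample SD (n-1 denominator), population-moment skewness m3/m2^1.5 and
Pearson (non-excess) kurtosis m4/m2^2, switchable via flags.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MAPS",
    "REGIONS",
    "STATS",
    "FEATURE_COLUMNS",
    "VOLUME_COLUMN",
    "histogram_features",
    "tumour_volume",
    "build_feature_table",
    "grade_of",
]

MAPS = ("ADC", "UCBV", "K2", "CCBV")
REGIONS = ("ROI", "WB")
STATS = ("mean", "sd", "skewness", "kurtosis")
VOLUME_COLUMN = "tumour_volume_cm3"

#: Deterministic column order of the 33-feature table.
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{m}_{r}_{s}" for m in MAPS for r in REGIONS for s in STATS
) + (VOLUME_COLUMN,)

#: Map units recorded in the table's sidecar schema.
FEATURE_UNITS = {
    "ADC": "1e-3 mm^2/s",
    "UCBV": "NAWM-normalised CBV",
    "CCBV": "NAWM-normalised CBV",
    "K2": "leakage rate (arbitrary, 1/s-scaled)",
    VOLUME_COLUMN: "cm^3",
}

LOW_GRADE_LABEL = "pilocytic_astrocytoma"


def grade_of(label: str) -> str:
    """Tumour grade dichotomy: pilocytic astrocytoma is low grade,
    medulloblastoma and ependymoma high grade."""
    known = {"pilocytic_astrocytoma", "medulloblastoma", "ependymoma"}
    if label not in known:
        raise ValueError(f"unknown tumour label {label!r}")
    return "low" if label == LOW_GRADE_LABEL else "high"


def histogram_features(
    volume: np.ndarray,
    region_mask: np.ndarray,
    qc_mask: np.ndarray | None = None,
    min_voxels: int = 8,
    sample_sd: bool = True,
    excess_kurtosis: bool = False,
) -> tuple[float, float, float, float]:
    """(mean, sd, skewness, kurtosis) of the in-mask voxel values.

    NaN voxels and voxels failing QC are excluded.  A region with fewer than
    ``min_voxels`` usable voxels returns all-NaN (the subject should be
    dropped with a warning); a zero-variance region has defined mean/sd but
    undefined shape moments.
    """
    mask = region_mask.astype(bool)
    if qc_mask is not None:
        mask = mask & qc_mask.astype(bool)
    vals = volume[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < min_voxels:
        warnings.warn(
            f"region has only {vals.size} usable voxels (< {min_voxels})",
            stacklevel=2,
        )
        return (np.nan,) * 4

    mean = float(vals.mean())
    m2 = float(np.mean((vals - mean) ** 2))
    sd = float(vals.std(ddof=1 if sample_sd else 0))
    if m2 <= 0:
        return mean, sd, np.nan, np.nan
    m3 = float(np.mean((vals - mean) ** 3))
    m4 = float(np.mean((vals - mean) ** 4))
    skew = m3 / m2**1.5
    kurt = m4 / m2**2
    if excess_kurtosis:
        kurt -= 3.0
    return mean, sd, skew, kurt


def tumour_volume(roi_mask: np.ndarray, voxel_size_mm: Iterable[float]) -> float:
    """ROI volume in cm^3: voxel count times physical voxel volume / 1000."""
    voxel_size_mm = np.asarray(tuple(voxel_size_mm), dtype=float)
    if (voxel_size_mm <= 0).any():
        raise ValueError("voxel sizes must be positive")
    n = int(np.count_nonzero(roi_mask))
    if n == 0:
        warnings.warn("empty tumour ROI; volume is 0", stacklevel=2)
    return n * float(np.prod(voxel_size_mm)) / 1000.0


def build_feature_table(
    subject_maps: Mapping[str, Mapping[str, np.ndarray]],
    subject_masks: Mapping[str, Mapping[str, np.ndarray]],
    labels: Mapping[str, str],
    voxel_size_mm: Iterable[float],
    min_voxels: int = 8,
    wb_excludes_roi: bool = False,
    sample_sd: bool = True,
    excess_kurtosis: bool = False,
) -> pd.DataFrame:
    """Assemble the subjects x 33-features table with label and grade columns.

    Parameters
    ----------
    subject_maps:
        ``{subject_id: {"ADC": vol, "UCBV": vol, "K2": vol, "CCBV": vol}}``.
    subject_masks:
        ``{subject_id: {"roi": m, "brain": m, "qc": m}}`` (qc optional).
    labels:
        ``{subject_id: tumour type}``.
    wb_excludes_roi:
        If True, whole-brain statistics exclude the tumour ROI; the default
        computes them over the full brain mask, tumour included.

    Subjects missing a map or with an unusably small QC'd region are
    excluded with a warning.
    """
    voxel_size_mm = tuple(voxel_size_mm)
    rows = {}
    for sid, maps in subject_maps.items():
        missing = [m for m in MAPS if m not in maps]
        if missing:
            warnings.warn(f"subject {sid} missing maps {missing}; excluded",
                          stacklevel=2)
            continue
        masks = subject_masks[sid]
        roi = masks["roi"].astype(bool)
        brain = masks["brain"].astype(bool)
        qc = masks.get("qc")
        wb = brain & ~roi if wb_excludes_roi else brain
        row: dict[str, float] = {}
        for map_name in MAPS:
            vol = maps[map_name]
            # ADC maps carry their own NaN-based QC; perfusion maps use qc_mask
            map_qc = qc if map_name != "ADC" else None
            for region_name, region in (("ROI", roi), ("WB", wb)):
                stats = histogram_features(
                    vol, region, map_qc, min_voxels=min_voxels,
                    sample_sd=sample_sd, excess_kurtosis=excess_kurtosis,
                )
                for stat_name, value in zip(STATS, stats):
                    row[f"{map_name}_{region_name}_{stat_name}"] = value
        row[VOLUME_COLUMN] = tumour_volume(roi, voxel_size_mm)
        if any(np.isnan(v) for v in row.values()):
            warnings.warn(
                f"subject {sid} has undefined features after QC; excluded",
                stacklevel=2,
            )
            continue
        row["label"] = labels[sid]
        row["grade"] = grade_of(labels[sid])
        rows[sid] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    if len(table):
        table = table[list(FEATURE_COLUMNS) + ["label", "grade"]]
    table.index.name = "subject_id"
    return table


def feature_schema() -> dict:
    """Sidecar schema describing units and moment conventions."""
    return {
        "columns": list(FEATURE_COLUMNS),
        "units": FEATURE_UNITS,
        "sd": "sample (n-1)",
        "kurtosis": "Pearson m4/m2^2 (non-excess)",
        "skewness": "m3/m2^1.5",
    }
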