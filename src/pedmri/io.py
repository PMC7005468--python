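"""Cohort manifests, NIfTI readers/writers, YAML configuration and the
end-to-end pipeline driver (simulate -> quantify -> features -> stats ->
classify).

Volumes travel as NIfTI (.nii.gz), tables as CSV, reports as JSON.  Every
artefact written here carries the cohort-config hash and seed, either in
the NIfTI header ``descrip`` field or in a ``*.meta.json`` sidecar, so any
output can be traced to the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .adc import DWIPair, compute_adc
from .classify import CVReport, ExperimentConfig, train_and_evaluate
from .dsc import DSCSeries, quantify_subject
from .features import FEATURE_COLUMNS, build_feature_table, feature_schema
from .stats import univariate_battery
from .synthetic import ClassProfile, CohortConfig, SyntheticSubject, iter_cohort

__all__ = [
    "config_hash",
    "save_cohort_config",
    "load_cohort_config",
    "load_experiment_config",
    "write_volume",
    "read_volume",
    "save_subject",
    "load_subject",
    "write_manifest",
    "load_manifest",
    "quantify_to_maps",
    "run_full_pipeline",
    "PipelineError",
]

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "subject_id", "label", "dsc", "dwi_b0", "dwi_b1",
    "roi_mask", "nawm_mask", "brain_mask",
    "b_low", "b_high", "TR_s", "TE_s",
    "voxel_x_mm", "voxel_y_mm", "voxel_z_mm",
]


class PipelineError(RuntimeError):
    """A pipeline stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def config_hash(config) -> str:
    """Stable short hash of a dataclass configuration."""
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# YAML configuration


def save_cohort_config(config: CohortConfig, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config)))


def load_cohort_config(path: Path) -> CohortConfig:
    data = yaml.safe_load(Path(path).read_text())
    for key in ("n_per_class", "grid_shape", "voxel_size_mm", "b_values_s_per_mm2"):
        if key in data:
            data[key] = tuple(data[key])
    return CohortConfig(**data)


def load_experiment_config(path: Path) -> ExperimentConfig:
    return ExperimentConfig(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# NIfTI volumes


def write_volume(
    data: np.ndarray,
    path: Path,
    voxel_size_mm=(1.0, 1.0, 1.0),
    descrip: str = "",
) -> None:
    affine = np.diag(list(voxel_size_mm[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header["descrip"] = descrip.encode()[:79]
    zooms = list(voxel_size_mm[:3]) + ([1.0] if data.ndim == 4 else [])
    img.header.set_zooms(zooms[: data.ndim])
    nib.save(img, str(path))


def read_volume(path: Path) -> np.ndarray:
    try:
        return np.asarray(nib.load(str(path)).get_fdata())
    except Exception as exc:  # corrupt or unreadable file
        raise PipelineError("load", f"cannot read NIfTI {path}: {exc}") from exc


def save_subject(subject: SyntheticSubject, out_dir: Path, descrip: str = "") -> dict:
    """Write one subject's volumes; returns its manifest row."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vs = subject.voxel_size_mm
    paths = {}
    vols = {
        "dsc": subject.dsc_series.signal,
        "dwi_b0": subject.dwi_b0,
        "dwi_b1": subject.dwi_b1,
        "roi_mask": subject.roi_mask.astype(np.float32),
        "nawm_mask": subject.nawm_mask.astype(np.float32),
        "brain_mask": subject.brain_mask.astype(np.float32),
    }
    for name, vol in vols.items():
        p = out_dir / f"{subject.subject_id}_{name}.nii.gz"
        write_volume(vol, p, vs, descrip=descrip)
        paths[name] = str(p)
    return {
        "subject_id": subject.subject_id,
        "label": subject.label,
        **paths,
        "b_low": subject.b_values[0],
        "b_high": subject.b_values[1],
        "TR_s": float(subject.dsc_series.t[1] - subject.dsc_series.t[0]),
        "TE_s": subject.dsc_series.TE_s,
        "voxel_x_mm": vs[0], "voxel_y_mm": vs[1], "voxel_z_mm": vs[2],
    }


def load_subject(row) -> SyntheticSubject:
    """Rebuild a subject from one manifest row (mapping or Series).

    The returned subject carries no voxel-wise ground truth
    (``ground_truth={}``): quantification never sees the truth, whether the
    volumes came from the simulator or from disk.
    """
    signal = read_volume(row["dsc"])
    n_t = signal.shape[-1]
    t = np.arange(n_t) * float(row["TR_s"])
    series = DSCSeries(signal, t, TE_s=float(row["TE_s"]))
    return SyntheticSubject(
        subject_id=str(row["subject_id"]),
        label=str(row["label"]),
        dsc_series=series,
        dwi_b0=read_volume(row["dwi_b0"]),
        dwi_b1=read_volume(row["dwi_b1"]),
        roi_mask=read_volume(row["roi_mask"]) > 0.5,
        nawm_mask=read_volume(row["nawm_mask"]) > 0.5,
        brain_mask=read_volume(row["brain_mask"]) > 0.5,
        ground_truth={},
        b_values=(float(row["b_low"]), float(row["b_high"])),
        voxel_size_mm=(
            float(row["voxel_x_mm"]), float(row["voxel_y_mm"]),
            float(row["voxel_z_mm"]),
        ),
    )


# ---------------------------------------------------------------------------
# manifest


def write_manifest(rows: list[dict], path: Path) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def load_manifest(path: Path, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a cohort manifest CSV."""
    path = Path(path)
    if not path.exists():
        raise PipelineError("manifest", f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise PipelineError("manifest", f"missing columns: {missing}")
    dup = df["subject_id"][df["subject_id"].duplicated()].tolist()
    if dup:
        raise PipelineError("manifest", f"duplicated subject ids: {dup}")
    if (df["b_high"] <= df["b_low"]).any():
        raise PipelineError("manifest", "b_high must exceed b_low for all subjects")
    if check_files:
        file_cols = ["dsc", "dwi_b0", "dwi_b1", "roi_mask", "nawm_mask", "brain_mask"]
        absent = [
            p for col in file_cols for p in df[col] if not Path(p).exists()
        ]
        if absent:
            raise PipelineError("manifest", f"referenced files do not exist: {absent[:5]}")
    return df


# ---------------------------------------------------------------------------
# pipeline


def quantify_to_maps(subject: SyntheticSubject, **quant_kwargs) -> dict[str, np.ndarray]:
    """Run ADC and DSC quantification for one subject; returns the four
    feature maps plus the QC mask."""
    pair = DWIPair(subject.dwi_b0, subject.dwi_b1,
                   subject.b_values[0], subject.b_values[1])
    adc = compute_adc(pair, subject.brain_mask)
    maps = quantify_subject(
        subject.dsc_series, subject.brain_mask, subject.roi_mask,
        subject.nawm_mask, **quant_kwargs,
    )
    return {
        "ADC": adc, "UCBV": maps.ucbv, "K2": maps.k2, "CCBV": maps.ccbv,
        "qc": maps.qc_mask,
    }


def run_full_pipeline(
    config: CohortConfig,
    profile: ClassProfile | None = None,
    out_dir: Path | None = None,
    experiments: list[ExperimentConfig] | None = None,
) -> dict:
    """Simulate a cohort, quantify every subject, build the feature table,
    run the univariate battery and the configured classification
    experiments.  Deterministic (byte-identical feature CSV) under a fixed
    config and seed.

    Returns a dict with the feature table, the univariate results and one
    :class:`~pedmri.classify.CVReport` per experiment; when ``out_dir`` is
    given, all artefacts are also written there.
    """
    tag = f"pedmri cfg={config_hash(config)} seed={config.seed}"
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    subject_maps, subject_masks, labels, manifest_rows = {}, {}, {}, []
    stage = "simulate"
    try:
        for subject in iter_cohort(config, profile):
            stage = "quantify"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                maps = quantify_to_maps(subject)
            sid = subject.subject_id
            subject_maps[sid] = {k: maps[k] for k in ("ADC", "UCBV", "K2", "CCBV")}
            subject_masks[sid] = {
                "roi": subject.roi_mask, "brain": subject.brain_mask,
                "qc": maps["qc"],
            }
            labels[sid] = subject.label
            if out_dir is not None:
                sub_dir = out_dir / "volumes"
                manifest_rows.append(save_subject(subject, sub_dir, descrip=tag))
                for name in ("ADC", "UCBV", "K2", "CCBV"):
                    write_volume(
                        np.nan_to_num(maps[name]),
                        sub_dir / f"{sid}_{name.lower()}.nii.gz",
                        subject.voxel_size_mm, descrip=tag,
                    )
            stage = "simulate"
    except (ValueError, RuntimeError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = build_feature_table(
                subject_maps, subject_masks, labels, config.voxel_size_mm
            )
    except (ValueError, KeyError) as exc:
        raise PipelineError("features", str(exc)) from exc
    if table.empty:
        raise PipelineError("features", "no subject survived QC")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stats_table = univariate_battery(table, list(FEATURE_COLUMNS))

    if experiments is None:
        experiments = [
            ExperimentConfig(task="grade", reduction="univariate",
                             classifier="adaboost", seed=config.seed),
            ExperimentConfig(task="type", reduction="univariate",
                             classifier="adaboost", seed=config.seed),
        ]
    reports: dict[str, CVReport] = {}
    for exp in experiments:
        key = f"{exp.task}_{exp.reduction}_{exp.classifier}"
        try:
            reports[key] = train_and_evaluate(table, exp)
        except ValueError as exc:
            raise PipelineError("classify", str(exc)) from exc

    if out_dir is not None:
        meta = {"config_hash": config_hash(config), "seed": config.seed}
        write_manifest(manifest_rows, out_dir / "manifest.csv")
        table.to_csv(out_dir / "features.csv")
        (out_dir / "features.meta.json").write_text(
            json.dumps({**meta, "schema": feature_schema()}, indent=2)
        )
        stats_out = stats_table.copy()
        stats_out["pairwise_p"] = stats_out["pairwise_p"].apply(
            lambda d: json.dumps({f"{a}|{b}": p for (a, b), p in d.items()})
        )
        stats_out["auc"] = stats_out["auc"].apply(
            lambda d: json.dumps({f"{a}|{b}": v for (a, b), v in d.items()})
        )
        stats_out.to_csv(out_dir / "univariate.csv")
        for key, rep in reports.items():
            payload = {
                **meta,
                "bar": rep.bar, "f_stat": rep.f_stat,
                "precision_macro": rep.precision_macro,
                "per_class": rep.per_class,
                "fold_details": rep.fold_details,
            }
            (out_dir / f"cv_report_{key}.json").write_text(
                json.dumps(payload, indent=2, default=str)
            )
            rep.confusion.to_csv(out_dir / f"confusion_{key}.csv")

    return {"features": table, "univariate": stats_table, "reports": reports}
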