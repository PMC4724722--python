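"""Formats and reporting: NIfTI-1 volumes, covariate CSVs, YAML configs,
run manifests, and the tabular reports of an experiment.

Volumes are reoriented to RAS canonical axes on load so a single internal
coordinate convention holds everywhere; header scaling (slope/intercept) is
applied by nibabel's ``get_fdata``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fprharness import ExperimentConfig, ExperimentResult
from .synthdata import BrainMask, CohortSpec, SubjectImage

__all__ = [
    "RunManifest",
    "load_volume",
    "save_volume",
    "save_mask",
    "load_covariates",
    "save_covariates",
    "save_cohort",
    "config_from_yaml",
    "write_report",
]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: config echo, seeds, checksums."""

    config: dict
    software_version: str = __version__
    master_seed: int | None = None
    stage_seeds: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def load_volume(path, age: float = 0.0, gender: int = 0, subject_id: str | None = None) -> SubjectImage:
    """Read a 3D NIfTI-1 volume as a :class:`SubjectImage`.

    Reorients to RAS canonical axes; header slope/intercept scaling is applied.
    Rejects non-3D files and volumes containing NaNs.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise ValueError(f"{path}: not a readable NIfTI file ({exc})") from exc
    img = nib.as_closest_canonical(img)
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        pass  # single-frame 4D files are accepted and squeezed
    elif len(shape) != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {len(shape)}D with shape {shape}")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    data = data.reshape(shape[:3])
    if np.isnan(data).any():
        raise ValueError(f"{path}: volume contains NaN values")
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return SubjectImage(
        values=data,
        voxel_size=voxel_size,
        age=age,
        gender=gender,
        subject_id=subject_id or path.name.split(".")[0],
    )


def save_volume(image: SubjectImage | np.ndarray, path, voxel_size=None) -> None:
    """Write a volume as NIfTI-1 with the voxel size on the affine diagonal."""
    if isinstance(image, SubjectImage):
        data, vs = image.values, image.voxel_size
    else:
        data, vs = np.asarray(image), voxel_size
        if vs is None:
            raise ValueError("voxel_size required when saving a bare array")
    affine = np.diag(list(vs) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def save_mask(mask: BrainMask, path, voxel_size) -> None:
    save_volume(mask.include.astype(np.uint8), path, voxel_size)


def load_covariates(path) -> pd.DataFrame:
    """Covariate CSV with columns subject_id, age, gender."""
    df = pd.read_csv(path)
    missing = {"subject_id", "age", "gender"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: covariate CSV missing columns {sorted(missing)}")
    return df


def save_covariates(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, index=False)


def save_cohort(images, covariates: pd.DataFrame, out_dir) -> None:
    """Write a cohort as per-subject .nii.gz volumes plus covariates.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for im in images:
        save_volume(im, out / f"{im.subject_id}.nii.gz")
    save_covariates(covariates, out / "covariates.csv")


def config_from_yaml(path) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a YAML file mirroring its fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cohort_kwargs = raw.pop("cohort_spec", {})
    for key in ("grid_shape", "voxel_size"):
        if key in cohort_kwargs:
            cohort_kwargs[key] = tuple(cohort_kwargs[key])
    if "conditions" in raw:
        raw["conditions"] = tuple((float(f), str(t)) for f, t in raw["conditions"])
    return ExperimentConfig(cohort_spec=CohortSpec(**cohort_kwargs), **raw)


def _fmt_pct(x: float) -> str:
    return f"{x:.1f}"


def write_report(result: ExperimentResult, out_dir) -> dict:
    """Write the experiment's tables and JSON summary.

    Produces ``table1.csv`` (per-condition "count (peaks)" cells per
    direction), ``table2.csv`` (localization), ``logistic.csv``,
    ``results.json`` (full numeric summary; percentages to one decimal in the
    tables) and ``manifest.json``. Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    ct = result.condition_table
    t1_rows = []
    for (fwhm, tag), grp in ct.groupby(["smoothing_fwhm", "condition_tag"], sort=True):
        row = {"condition_tag": tag, "smoothing_fwhm": fwhm}
        for _, r in grp.iterrows():
            row[r["direction"]] = f"{int(r['fwe_count'])} ({int(r['n_peaks'])})"
            row[f"{r['direction']}_fwer_pct"] = _fmt_pct(r["fwer_pct"])
        t1_rows.append(row)
    table1 = pd.DataFrame(
        t1_rows,
        columns=[
            "condition_tag", "smoothing_fwhm",
            "increase", "increase_fwer_pct", "decrease", "decrease_fwer_pct",
        ],
    )
    paths["table1"] = out / "table1.csv"
    table1.to_csv(paths["table1"], index=False)

    table2 = result.localization.copy()
    for col in ("volume_pct", "count_pct"):
        table2[col] = table2[col].map(lambda v: float(_fmt_pct(v)) if pd.notna(v) else v)
    paths["table2"] = out / "table2.csv"
    table2.to_csv(paths["table2"], index=False)

    logi_rows = []
    for name, fit in (
        ("smoothing_direction", result.logistic_smoothing),
        ("modulation_direction", result.logistic_modulation),
    ):
        if fit is None:
            continue
        for factor, p in fit.wald_p.items():
            logi_rows.append(
                {
                    "model": name,
                    "factor": factor,
                    "wald_p": p,
                    "hl_statistic": fit.hl_statistic,
                    "hl_p": fit.hl_p,
                    "n_obs": fit.n_obs,
                }
            )
    paths["logistic"] = out / "logistic.csv"
    pd.DataFrame(
        logi_rows, columns=["model", "factor", "wald_p", "hl_statistic", "hl_p", "n_obs"]
    ).to_csv(paths["logistic"], index=False)

    summary = {
        "engine": result.config.engine,
        "m_comparisons": result.config.m_comparisons,
        "alpha": result.config.alpha,
        "conditions": [
            {
                "smoothing_fwhm": r["smoothing_fwhm"],
                "condition_tag": r["condition_tag"],
                "direction": r["direction"],
                "fwe_count": int(r["fwe_count"]),
                "n_peaks": int(r["n_peaks"]),
                "fwer_pct": round(r["fwer_pct"], 1),
                "ci_pct": [round(r["ci_lo_pct"], 1), round(r["ci_hi_pct"], 1)],
            }
            for _, r in ct.iterrows()
        ],
        "spearman": {
            "rho": result.spearman_rho,
            "p": result.spearman_p,
            "degenerate": result.spearman_degenerate,
        },
        "n_failures": len(result.failures),
    }
    paths["results"] = out / "results.json"
    paths["results"].write_text(json.dumps(summary, indent=2) + "\n")

    manifest = RunManifest(
        config={
            **{k: getattr(result.config, k) for k in (
                "m_comparisons", "pool_size", "control_group_size", "alpha", "engine", "seed"
            )},
            "conditions": list(map(list, result.config.conditions)),
            "cohort_spec": asdict(result.config.cohort_spec),
        },
        master_seed=result.config.seed,
    )
    paths["manifest"] = out / "manifest.json"
    manifest.write(paths["manifest"])
    return paths
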