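"""File formats and configuration.

Washout traces travel as CSV (``time_s, flow_L_per_s, n2_frac`` — units
encoded in the column names), image stacks as paired NIfTI files or as a
``.npz`` archive with a JSON geometry sidecar, cohorts as CSV.  All
readers validate and reject out-of-contract values rather than coercing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .fld import AcquisitionParams, MultiEchoStack
from .mbw import WashoutTrace

WASHOUT_COLUMNS = ("time_s", "flow_L_per_s", "n2_frac")

#: minimum cohort schema for the statistical surface
COHORT_REQUIRED_COLUMNS = (
    "id",
    "group",
    "lci",
    "scond_star",
    "sacin_star",
    "central_mfld_frc",
    "central_mfld_tlc",
    "central_mfld_ratio",
    "peripheral_mfld_frc",
    "peripheral_mfld_tlc",
    "peripheral_mfld_ratio",
)


class SchemaError(ValueError):
    """A file does not match its documented column contract."""


def load_washout_csv(path) -> WashoutTrace:
    """Read a washout trace, validating columns, time order and bounds."""
    df = pd.read_csv(path)
    missing = [c for c in WASHOUT_COLUMNS if c not in df.columns]
    if missing:
        extra = [c for c in df.columns if c not in WASHOUT_COLUMNS]
        raise SchemaError(
            f"missing column(s) {missing} (found {extra}); units are encoded "
            "in the column names and must match exactly"
        )
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("non-monotone time")
    n2 = df["n2_frac"].to_numpy(float)
    if np.any((n2 < 0) | (n2 > 1)):
        raise ValueError("n2_frac out of range [0, 1]")
    dt = np.median(np.diff(t))
    return WashoutTrace(
        time_s=t,
        flow_L_per_s=df["flow_L_per_s"].to_numpy(float),
        n2_frac=n2,
        sample_rate_hz=1.0 / dt,
        meta={"path": str(path)},
    )


def save_washout_csv(trace: WashoutTrace, path) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "flow_L_per_s": trace.flow_L_per_s,
            "n2_frac": trace.n2_frac,
        }
    ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# image stacks


def save_stack_npz(stack: MultiEchoStack, path) -> None:
    """Write a stack as .npz with a JSON geometry/acquisition sidecar."""
    path = Path(path)
    np.savez(
        path,
        image_te1=stack.image_te1,
        image_te2=stack.image_te2,
        lung_mask=stack.lung_mask,
        phantom_mask=stack.phantom_mask,
    )
    sidecar = {
        "voxel_dims_mm": list(stack.voxel_dims_mm),
        "volume_state": stack.volume_state,
        "acq": dataclasses.asdict(stack.acq),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_stack_npz(path) -> MultiEchoStack:
    path = Path(path)
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    sidecar = json.loads(path.with_suffix(".json").read_text())
    acq = sidecar["acq"]
    acq["matrix"] = tuple(acq["matrix"])
    return MultiEchoStack(
        image_te1=arrays["image_te1"],
        image_te2=arrays["image_te2"],
        lung_mask=arrays["lung_mask"].astype(bool),
        phantom_mask=arrays["phantom_mask"].astype(bool),
        voxel_dims_mm=tuple(sidecar["voxel_dims_mm"]),
        volume_state=sidecar["volume_state"],
        acq=AcquisitionParams(**acq),
    )


def save_stack_nifti(stack: MultiEchoStack, prefix) -> None:
    """Write the two echo images and masks as NIfTI files.

    Files: ``<prefix>_te1.nii.gz``, ``<prefix>_te2.nii.gz``,
    ``<prefix>_lungmask.nii.gz``, ``<prefix>_phantommask.nii.gz``; a
    JSON sidecar carries volume state and acquisition parameters.
    """
    import nibabel as nib

    prefix = Path(prefix)
    dx, dy, dz = stack.voxel_dims_mm
    affine = np.diag([dx, dy, dz, 1.0])
    for name, arr in (
        ("te1", stack.image_te1),
        ("te2", stack.image_te2),
        ("lungmask", np.asarray(stack.lung_mask, np.uint8)),
        ("phantommask", np.asarray(stack.phantom_mask, np.uint8)),
    ):
        a = np.asarray(arr)
        if a.ndim == 2:
            a = a[..., None]
        nib.save(
            nib.Nifti1Image(a.astype(np.float32), affine),
            str(prefix.parent / f"{prefix.name}_{name}.nii.gz"),
        )
    sidecar = {
        "volume_state": stack.volume_state,
        "acq": dataclasses.asdict(stack.acq),
        "voxel_dims_mm": list(stack.voxel_dims_mm),
    }
    (prefix.parent / f"{prefix.name}_stack.json").write_text(
        json.dumps(sidecar, indent=2)
    )


def load_stack_nifti(prefix) -> MultiEchoStack:
    import nibabel as nib

    prefix = Path(prefix)
    sidecar = json.loads((prefix.parent / f"{prefix.name}_stack.json").read_text())
    acq = sidecar["acq"]
    acq["matrix"] = tuple(acq["matrix"])

    def _read(name):
        img = nib.load(str(prefix.parent / f"{prefix.name}_{name}.nii.gz"))
        return np.squeeze(np.asarray(img.dataobj))

    return MultiEchoStack(
        image_te1=_read("te1"),
        image_te2=_read("te2"),
        lung_mask=_read("lungmask").astype(bool),
        phantom_mask=_read("phantommask").astype(bool),
        voxel_dims_mm=tuple(sidecar["voxel_dims_mm"]),
        volume_state=sidecar["volume_state"],
        acq=AcquisitionParams(**acq),
    )


# --------------------------------------------------------------------------
# cohorts and configuration


def load_cohort_csv(path, required: Sequence[str] = COHORT_REQUIRED_COLUMNS) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing column(s): {missing}")
    if df["id"].duplicated().any():
        raise ValueError("duplicated subject ids")
    groups = set(df["group"].unique())
    if not groups <= {"CF", "control"}:
        raise ValueError(f"unknown group label(s): {sorted(groups - {'CF', 'control'})}")
    counts = df["group"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError(f"need >= 2 subjects in each of two groups, got {dict(counts)}")
    return df


@dataclass
class PipelineConfig:
    """Resolved options of an end-to-end run; logged verbatim by the CLI."""

    seed: int = 0
    anchor: str = "centered"
    s3_window: Tuple[float, float] = (0.50, 0.95)
    to_window: Tuple[float, float] = (1.5, 3.0)
    r2_min: float = 0.5
    interpolate_lci: bool = False
    calibration_mode: str = "te0"
    correction_factor: float = 1.0
    fld_cap: float = 1.2
    welch: bool = False
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("s3_window", "to_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["s3_window"] = list(d["s3_window"])
        d["to_window"] = list(d["to_window"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))
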