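"""File I/O and run configuration.

NIfTI (.nii / .nii.gz, 3-D with time as the third axis) is the canonical
container for image and mask series; flat binary arrays with a JSON sidecar
(``<file>.raw`` + ``<file>.json`` holding shape and dtype) are supported as a
fallback.  Masks are binarized on read, with a warning when non-binary values
are found (e.g. {0, 255} exports).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .hitl import ExpertPolicy, HitlConfig
from .patch_ops import ImageSeries, MaskSeries

__all__ = [
    "FormatError",
    "read_series",
    "write_series",
    "read_mask",
    "write_mask",
    "RunConfig",
]

logger = logging.getLogger("dynqc")


class FormatError(ValueError):
    """An input file could not be interpreted as a dynamic series."""


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_array(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=np.float64)
    elif path.suffix == ".raw":
        meta_path = _sidecar(path)
        if not meta_path.exists():
            raise FormatError(f"raw array {path} has no JSON sidecar {meta_path}")
        meta = json.loads(meta_path.read_text())
        arr = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
        arr = arr.astype(np.float64)
    else:
        raise FormatError(f"unsupported format: {path} (expected .nii, .nii.gz or .raw)")
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected 3 axes (row, col, time), got {arr.ndim} axes {arr.shape}"
        )
    return arr


def read_series(path: str | Path) -> ImageSeries:
    """Read a dynamic image series (M, N, T) from NIfTI or raw+sidecar."""
    return ImageSeries(_read_array(path))


def write_series(series: ImageSeries | np.ndarray, path: str | Path) -> None:
    """Write a dynamic series as NIfTI (identity affine) or raw+sidecar."""
    data = series.data if isinstance(series, ImageSeries) else np.asarray(series, float)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(data, np.eye(4)), str(path))
    elif path.suffix == ".raw":
        data.tofile(path)
        _sidecar(path).write_text(
            json.dumps({"shape": list(data.shape), "dtype": str(data.dtype)})
        )
    else:
        raise FormatError(f"unsupported output format: {path}")


def read_mask(path: str | Path, role: str = "prediction") -> MaskSeries:
    """Read a binary mask series; non-binary values are binarized with a warning."""
    arr = _read_array(path)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        warnings.warn(
            f"{path}: mask contains non-binary values {vals[:5]}...; binarizing at > 0",
            stacklevel=2,
        )
        arr = arr > 0
    return MaskSeries(np.asarray(arr, dtype=np.uint8), role=role)


def write_mask(mask: MaskSeries, path: str | Path) -> None:
    """Write a mask series (values {0, 1})."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(mask.data.astype(np.uint8), np.eye(4)), str(path))
    elif path.suffix == ".raw":
        mask.data.astype(np.uint8).tofile(path)
        _sidecar(path).write_text(
            json.dumps({"shape": list(mask.data.shape), "dtype": "uint8"})
        )
    else:
        raise FormatError(f"unsupported output format: {path}")


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a pipeline run; round-trips through YAML/JSON.

    Geometry (``K``, ``w_S``, ``w_M``) and referral settings mirror
    :class:`~dynqc.hitl.HitlConfig`; seeds drive every random component.
    """

    K: int = 64
    w_S: int = 16
    w_M: int = 2
    fraction: float = 0.1
    per_slice: bool = False
    policy: str = "reluctant"
    tau: float = 0.6
    bp_overlap_threshold: float = 0.1
    n_mc: int = 100
    seed: int = 0
    n_slices: int = 5
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.w_S < 1 or self.w_M < 1:
            raise ValueError("strides must be >= 1")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")
        if self.policy not in ("oracle", "reluctant"):
            raise ValueError(f"unknown policy {self.policy!r}")

    def to_hitl_config(self) -> HitlConfig:
        return HitlConfig(
            K=self.K,
            w_S=self.w_S,
            w_M=self.w_M,
            fraction=self.fraction,
            policy=ExpertPolicy(
                kind=self.policy,
                dice_threshold=self.tau,
                bp_overlap_threshold=self.bp_overlap_threshold,
            ),
            n_mc=self.n_mc,
            seed=self.seed,
            per_slice=self.per_slice,
        )

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        payload = asdict(self)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(payload, sort_keys=True))
        elif path.suffix == ".json":
            path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        else:
            raise FormatError(f"config format must be .yaml/.yml/.json, got {path.suffix}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            payload = yaml.safe_load(text)
        elif path.suffix == ".json":
            payload = json.loads(text)
        else:
            raise FormatError(f"config format must be .yaml/.yml/.json, got {path.suffix}")
        return cls(**payload)

    def digest(self) -> str:
        """Short hash of the canonical config, for run logs."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)
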