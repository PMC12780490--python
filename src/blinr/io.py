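"""NIfTI I/O and run configuration.

Volumes are read and written with nibabel.  Only 3-D NIfTI-1 images are
accepted; 4-D acquisitions must be split per b-value upstream.  The source
header and affine are carried opaquely on the volume so outputs can be written
back with byte-identical geometry fields; output data is stored as 32-bit
float.

Run configuration is a YAML mapping with three known sections (``encoding``,
``training``) plus top-level ``patch_size``/``seed``; unknown keys are rejected
by name to catch typos early.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, fields as dc_fields

import nibabel as nib
import numpy as np
import yaml

from .encoding import EncodingConfig
from .train import TrainingConfig
from .volume import GridSpec, Volume3D

__all__ = ["read_volume", "write_volume", "RunConfig", "load_config",
           "parse_b_label", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file problem, naming the offending key."""


def read_volume(path: str, role: str = "target_noisy") -> Volume3D:
    """Load a 3-D NIfTI volume, keeping its header for round-tripping."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(path)
    if img.ndim != 3:
        raise ValueError(
            f"{path} is {img.ndim}-D; split 4-D series into one file per b-value"
        )
    data = np.asanyarray(img.dataobj).astype(np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    grid = GridSpec(shape=data.shape, spacing=zooms)
    return Volume3D(grid, data, role=role, meta=(img.affine, img.header))


def write_volume(vol: Volume3D, path: str, template: Volume3D | None = None,
                 clip_negative: bool = False) -> None:
    """Write a volume as float32 NIfTI, copying geometry from the template.

    ``template`` (or the volume's own retained metadata) supplies the affine
    and header; without either, an axis-aligned affine is built from the
    spacing.  ``clip_negative`` floors exported intensities at zero — used for
    denoised magnitudes, which are physically nonnegative.
    """
    data = vol.data.astype(np.float32)
    if clip_negative:
        data = np.maximum(data, 0.0)
    meta = template.meta if template is not None else vol.meta
    if meta is not None:
        affine, header = meta
        header = header.copy()
        header.set_data_dtype(np.float32)
        img = nib.Nifti1Image(data, affine, header)
    else:
        affine = np.diag(list(vol.grid.spacing) + [1.0])
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(vol.grid.spacing)
    nib.save(img, path)


def parse_b_label(label: str) -> float:
    """Parse a b-value label like ``b500`` or ``500`` into a float."""
    s = label.strip().lower()
    if s.startswith("b"):
        s = s[1:]
    try:
        b = float(s)
    except ValueError:
        raise ConfigError(f"malformed b-value label: {label!r}") from None
    if b < 0:
        raise ConfigError(f"b-value must be nonnegative: {label!r}")
    return b


@dataclass
class RunConfig:
    """Everything a pipeline run needs: encodings, training, patch size, seed."""

    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    patch_size: int = 3
    seed: int = 0


def _build_section(cls, raw: dict, section: str):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {section!r}: {sorted(unknown)}")
    return cls(**raw)


def load_config(path: str | None) -> RunConfig:
    """Load a YAML run configuration; missing keys take the defaults
    (omega_max 20, patch_size 3, lr 4e-4, epochs 20)."""
    raw = {}
    if path is not None:
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known_top = {"encoding", "training", "patch_size", "seed"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    enc = _build_section(EncodingConfig, raw.get("encoding", {}) or {}, "encoding")
    trn_raw = dict(raw.get("training", {}) or {})
    patch_size = int(raw.get("patch_size", 3))
    seed = int(raw.get("seed", trn_raw.get("seed", 0)))
    trn_raw.setdefault("seed", seed)
    trn_raw.setdefault("patch_size", patch_size)
    trn = _build_section(TrainingConfig, trn_raw, "training")
    if enc.type not in ("bandlimited", "fourier", "identity"):
        raise ConfigError(f"unknown encoding.type: {enc.type!r}")
    return RunConfig(encoding=enc, training=trn, patch_size=patch_size, seed=seed)
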