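"""File-format helpers: mask PNGs, model checkpoints, cohort folders.

Masks are single-channel 8-bit PNGs (0 background, 255 breast). Model
checkpoints are NumPy ``.npz`` archives of the flat state dict plus a JSON
sidecar describing the architecture, so a checkpoint can be rebuilt without
unpickling anything.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .dicom_io import write_dicom
from .nn import Module, SmallCNN, UNet
from .synthetic import Cohort


def save_mask_png(mask: np.ndarray, path: str | os.PathLike) -> None:
    iio.imwrite(str(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def load_mask_png(path: str | os.PathLike) -> np.ndarray:
    return np.asarray(iio.imread(str(path))) > 127


def save_model(model: Module, path: str | os.PathLike, config: dict) -> None:
    """Write ``<path>.npz`` (weights) and ``<path>.json`` (architecture)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    path.with_suffix(".json").write_text(json.dumps(config, indent=2))


def load_model(path: str | os.PathLike) -> Module:
    """Rebuild a model from its ``.npz`` + ``.json`` checkpoint pair."""
    path = Path(path)
    config = json.loads(path.with_suffix(".json").read_text())
    kind = config.pop("kind")
    if kind == "unet":
        model: Module = UNet(**config)
    elif kind == "cnn":
        model = SmallCNN(**config)
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


def save_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write a cohort as DICOM files + mask PNGs + manifest CSV.

    Returns the manifest with the ``path`` column filled in.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    manifest = cohort.manifest.copy()
    paths = []
    for i, rec in enumerate(cohort.records):
        rel = f"images/{rec.patient_id}_{i:05d}.dcm"
        write_dicom(rec, out / rel)
        if rec.mask is not None:
            save_mask_png(rec.mask, out / "masks" / f"{rec.patient_id}_{i:05d}.png")
        paths.append(rel)
    manifest["path"] = paths
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
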