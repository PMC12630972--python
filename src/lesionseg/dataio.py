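"""Readers/writers for images, masks, manifests and run configuration."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = ["load_manifest", "read_image", "read_mask", "write_mask",
           "write_image", "write_probability_map", "load_run_config",
           "save_json"]

log = logging.getLogger("lesionseg")

_REQUIRED_COLUMNS = ("image", "mask")
_CONFIG_SECTIONS = {"schema_version", "preprocess", "model", "training",
                    "evaluation", "seed"}


def load_manifest(path) -> pd.DataFrame:
    """Load and validate a dataset manifest CSV (image, mask[, split])."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty manifest: {path}") from None
    if len(df) == 0:
        raise ValueError(f"empty manifest: {path}")
    missing_cols = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest {path} lacks columns: {missing_cols}")
    root = path.parent
    problems = []
    for i, row in df.iterrows():
        for col in _REQUIRED_COLUMNS:
            p = root / str(row[col])
            if not p.exists():
                problems.append(f"row {i + 1}: missing {col} file {p}")
    if problems:
        raise FileNotFoundError("; ".join(problems))
    if "split" not in df.columns:
        df["split"] = "train"
    df["image"] = [str(root / p) for p in df["image"]]
    df["mask"] = [str(root / p) for p in df["mask"]]
    return df


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG image as H x W x 3 uint8 (16-bit inputs are rescaled)."""
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.dtype == np.uint16:
        log.warning("16-bit image %s rescaled to 8-bit", path)
        arr = (arr / 257.0).round().astype(np.uint8)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[2] == 4:
        arr = arr[..., :3]
    return arr.astype(np.uint8)


def read_mask(path) -> np.ndarray:
    """Read a single-channel mask PNG as {0,255} uint8."""
    arr = np.asarray(Image.open(path).convert("L"))
    return np.where(arr > 127, 255, 0).astype(np.uint8)


def write_mask(path, mask: np.ndarray):
    """Write a binary mask as single-channel {0,255} PNG (bit-exact round trip)."""
    mask = np.asarray(mask)
    out = np.where(mask > 0, 255, 0).astype(np.uint8)
    Image.fromarray(out, mode="L").save(path)


def write_image(path, image: np.ndarray):
    Image.fromarray(np.asarray(image).astype(np.uint8)).save(path)


def write_probability_map(path, probs: np.ndarray):
    """Export probabilities as 8-bit PNG, value = round(255 * p)."""
    p8 = np.rint(np.clip(probs, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(p8, mode="L").save(path)


def load_run_config(path) -> dict:
    """Load a YAML/JSON run configuration; unknown top-level keys rejected."""
    path = Path(path)
    text = path.read_text()
    cfg = (json.loads(text) if path.suffix == ".json"
           else yaml.safe_load(text))
    if not isinstance(cfg, dict):
        raise ValueError(f"run config {path} is not a mapping")
    unknown = set(cfg) - _CONFIG_SECTIONS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def save_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
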