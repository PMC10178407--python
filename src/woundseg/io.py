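"""File formats and run configuration.

Masks live on disk as single-channel 8-bit PNG with values {0, 255} and in
memory as {0, 1} uint8 arrays; write→read round-trips are bit-exact.
Probability maps are stored as 16-bit PNG (value = round(p · 65535)).
Dataset directories follow the ``images/`` + ``masks/`` matching-basename
layout with an optional ``manifest.csv``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import fields as dc_fields

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "DataError",
    "read_image",
    "read_mask",
    "write_mask",
    "read_probability_map",
    "write_probability_map",
    "load_dataset_dir",
    "load_run_config",
    "setup_logging",
]

log = logging.getLogger("woundseg")


class DataError(ValueError):
    """Malformed input data (CLI exit code 3)."""


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def read_image(path: str) -> np.ndarray:
    """RGB uint8 (H, W, 3)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def read_mask(path: str, coerce: bool = False) -> np.ndarray:
    """Read a binary mask PNG into {0, 1} uint8.

    Strict mode requires a single-channel 8-bit image with values {0, 255};
    ``coerce=True`` converts other inputs to grayscale and thresholds at 128.
    """
    with Image.open(path) as im:
        if coerce:
            arr = np.asarray(im.convert("L"))
            return (arr >= 128).astype(np.uint8)
        if im.mode != "L":
            raise DataError(
                f"{path}: expected single-channel 8-bit mask (mode L), got {im.mode}; "
                "use coerce to convert"
            )
        arr = np.asarray(im)
    bad = np.setdiff1d(np.unique(arr), [0, 255])
    if bad.size:
        raise DataError(
            f"{path}: mask values must be 0/255, found {bad[:8]}; use coerce to threshold"
        )
    return (arr // 255).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str) -> None:
    arr = np.asarray(mask)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise DataError("in-memory masks must be binary 0/1")
    Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(path)


def write_probability_map(prob: np.ndarray, path: str) -> None:
    arr = np.clip(np.asarray(prob, dtype=np.float64), 0.0, 1.0)
    Image.fromarray(np.round(arr * 65535).astype(np.uint16), mode="I;16").save(path)


def read_probability_map(path: str) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im, dtype=np.float64) / 65535.0


def load_dataset_dir(root: str, coerce_masks: bool = False):
    """Load an ``images/`` + ``masks/`` directory into (image, mask) pairs."""
    img_dir, mask_dir = os.path.join(root, "images"), os.path.join(root, "masks")
    if not os.path.isdir(img_dir) or not os.path.isdir(mask_dir):
        raise DataError(f"{root}: expected images/ and masks/ subdirectories")
    pairs = []
    for name in sorted(os.listdir(img_dir)):
        mask_path = os.path.join(mask_dir, name)
        if not os.path.exists(mask_path):
            raise DataError(f"mask missing for {name}")
        pairs.append((read_image(os.path.join(img_dir, name)),
                      read_mask(mask_path, coerce=coerce_masks)))
    if not pairs:
        raise DataError(f"{root}: no images found")
    return pairs


# -- run configuration ---------------------------------------------------------

_SECTIONS = {"network", "training", "augmentation", "calibration", "synthetic"}


def load_run_config(path: str, overrides: dict | None = None) -> dict:
    """Load a YAML run config, rejecting unknown sections and keys.

    Returns a dict of dataclass-ready keyword sections; the fully resolved
    config is logged so every run records its settings.
    """
    from .segnet import NetworkConfig
    from .training import AugmentationSpec, TrainConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise DataError(f"unknown config sections: {sorted(unknown)}")
    known_keys = {
        "network": {f.name for f in dc_fields(NetworkConfig)},
        "training": {f.name for f in dc_fields(TrainConfig)},
        "augmentation": {f.name for f in dc_fields(AugmentationSpec)},
        "calibration": {"degree", "model", "prior_area_cm2"},
        "synthetic": {"n", "seed", "area_range_cm2", "height_range_mm",
                      "focal_mm", "pixel_pitch_mm", "resolution"},
    }
    for section, content in raw.items():
        if not isinstance(content, dict):
            raise DataError(f"config section {section} must be a mapping")
        bad = set(content) - known_keys[section]
        if bad:
            raise DataError(f"unknown keys in [{section}]: {sorted(bad)}")
    if overrides:
        for dotted, value in overrides.items():
            section, key = dotted.split(".", 1)
            if section not in _SECTIONS or key not in known_keys[section]:
                raise DataError(f"unknown override {dotted}")
            raw.setdefault(section, {})[key] = value
    log.info("resolved run config: %s", raw)
    return raw
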