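"""Image and configuration I/O.

Grayscale magnitude images travel as PNG (8- or 16-bit) or single-slice
NIfTI-1 volumes; in memory they are always float64 arrays in [0, 1].
Configs are YAML or JSON files parsed into plain dicts.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from PIL import Image

from .phantoms import validate_image


def write_png(img: np.ndarray, path, bit_depth: int = 16) -> None:
    """Write a [0, 1] image as 8- or 16-bit grayscale PNG."""
    arr = validate_image(img)
    if bit_depth == 8:
        data = np.round(arr * 255).astype(np.uint8)
        Image.fromarray(data, mode="L").save(path)
    elif bit_depth == 16:
        data = np.round(arr * 65535).astype(np.uint16)
        Image.fromarray(data).save(path)
    else:
        raise ValueError("bit_depth must be 8 or 16")


def read_png(path) -> np.ndarray:
    """Read a grayscale PNG back to a float64 [0, 1] image."""
    with Image.open(path) as im:
        if im.mode == "I;16":
            arr = np.asarray(im, dtype=np.float64) / 65535.0
        elif im.mode == "L":
            arr = np.asarray(im, dtype=np.float64) / 255.0
        else:
            arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
    return arr


def write_nifti(img: np.ndarray, path) -> None:
    """Write a 2-D image as a single-slice NIfTI-1 volume."""
    arr = validate_image(img)
    vol = arr[:, :, None].astype(np.float32)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def read_nifti(path) -> np.ndarray:
    """Read a single-slice NIfTI-1 volume as a 2-D float image."""
    vol = np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)
    if vol.ndim == 3:
        if vol.shape[2] != 1:
            raise ValueError(f"expected a single-slice volume, got shape {vol.shape}")
        vol = vol[:, :, 0]
    return np.clip(vol, 0.0, 1.0)


def read_image(path) -> np.ndarray:
    """Dispatch on extension: .png, .nii or .nii.gz."""
    p = Path(path)
    if p.suffix == ".png":
        return read_png(p)
    if p.suffix == ".nii" or p.name.endswith(".nii.gz"):
        return read_nifti(p)
    raise ValueError(f"unsupported image format: {p.name}")


def write_image(img: np.ndarray, path) -> None:
    p = Path(path)
    if p.suffix == ".png":
        write_png(img, p)
    elif p.suffix == ".nii" or p.name.endswith(".nii.gz"):
        write_nifti(img, p)
    else:
        raise ValueError(f"unsupported image format: {p.name}")


def load_config(path) -> dict:
    """Load a YAML or JSON config file into a dict."""
    p = Path(path)
    if p.suffix in (".yaml", ".yml"):
        return yaml.safe_load(p.read_text()) or {}
    if p.suffix == ".json":
        return json.loads(p.read_text())
    raise ValueError(f"unsupported config format: {p.name}")
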