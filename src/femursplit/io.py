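"""Reading and writing images and manifests.

Normalized images are saved as 16-bit grayscale PNG by default (values in
[0, 1] scaled by 65535) so no quantization precedes training; 8-bit is
optional.  DICOM input is supported through pydicom when available, applying
RescaleSlope/Intercept and MONOCHROME1 inversion before any normalization.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np
import pandas as pd


def save_png(pixels, path: str, bit_depth: int = 16) -> str:
    """Save a [0, 1] (or raw non-negative, auto-scaled) image as grayscale PNG."""
    a = np.asarray(pixels, dtype=np.float64)
    if a.size and a.max() > 1.0:
        a = a / a.max()
    a = np.clip(a, 0.0, 1.0)
    if bit_depth == 16:
        out = np.round(a * 65535.0).astype(np.uint16)
    elif bit_depth == 8:
        out = np.round(a * 255.0).astype(np.uint8)
    else:
        raise ValueError(f"bit_depth: must be 8 or 16, got {bit_depth}")
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    iio.imwrite(path, out)
    return path


def load_image(path: str) -> np.ndarray:
    """Load a grayscale PNG/TIFF (or DICOM by extension) as a float array.

    Integer images are returned on their native scale (0..255 / 0..65535);
    min-max normalization is a separate, explicit step.
    """
    if path.lower().endswith((".dcm", ".dicom")):
        return load_dicom(path)
    a = iio.imread(path)
    if a.ndim == 3:   # collapse an RGB(A) scan to luminance
        a = a[..., :3].mean(axis=-1)
    return np.asarray(a, dtype=np.float64)


def load_dicom(path: str) -> np.ndarray:
    import pydicom

    ds = pydicom.dcmread(path)
    a = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    a = a * slope + intercept
    if getattr(ds, "PhotometricInterpretation", "") == "MONOCHROME1":
        a = a.max() - a
    a -= a.min()
    return a


def load_manifest(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def save_manifest(df: pd.DataFrame, path: str) -> str:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    df.to_csv(path, index=False)
    return path
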