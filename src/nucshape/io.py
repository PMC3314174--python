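"""File interchange: images, contour JSON, metrics CSV, exclusion lists."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from nucshape.contour import Contour
from nucshape.preprocess import GrayImage

FORMAT_VERSION = 1

IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


def read_image(path: str | Path, channel: int | None = None) -> GrayImage:
    """Read a single-page grayscale TIFF or PNG as a GrayImage.

    Multi-channel images require ``channel`` (index of the lamin channel);
    8- and 16-bit inputs are kept at native depth.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path.name} has {arr.shape} channels; pass --channel to "
                "select the lamin channel"
            )
        axis = int(np.argmin(arr.shape))  # channel axis is the smallest
        arr = np.take(arr, channel, axis=axis)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2-D grayscale image")
    if arr.dtype == np.uint8 or arr.dtype == np.uint16:
        return GrayImage(arr)
    if np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 65535:
        return GrayImage(arr.astype(np.uint16))
    raise ValueError(f"{path.name}: unsupported dtype {arr.dtype}")


def write_image(img: GrayImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels)
    else:
        iio.imwrite(path, img.pixels)


def write_contours(contours: list[Contour], path: str | Path) -> None:
    records = [
        {
            "image": c.image_id,
            "nucleus_id": c.nucleus_id,
            "vertices": c.vertices.tolist(),
        }
        for c in contours
    ]
    with open(path, "w") as fh:
        json.dump({"version": FORMAT_VERSION, "contours": records}, fh)


def read_contours(path: str | Path) -> list[Contour]:
    with open(path) as fh:
        data = json.load(fh)
    return [
        Contour(np.asarray(r["vertices"], float), r["image"], int(r["nucleus_id"]))
        for r in data["contours"]
    ]


def read_exclusions(path: str | Path) -> list[tuple[str, tuple[float, float]]]:
    """Exclusion file: JSON list of {"image": id, "point": [x, y]}."""
    with open(path) as fh:
        data = json.load(fh)
    items = data["exclusions"] if isinstance(data, dict) else data
    return [(r["image"], (float(r["point"][0]), float(r["point"][1])))
            for r in items]


METRIC_COLUMNS = [
    "image_id", "nucleus_id", "group", "mnc", "neg_curv_std",
    "max_neg_curvature", "mean_pos_curvature", "invaginations", "area",
    "perimeter", "equivalent_diameter", "convex_area", "solidity",
    "tortuosity", "eccentricity", "intensity_mean", "intensity_std",
]


def write_metrics(df: pd.DataFrame, path: str | Path) -> None:
    """Write the metrics table with a stable column order and full float
    precision (reruns on identical inputs give byte-identical files)."""
    cols = [c for c in METRIC_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, index=False, float_format="%.12g")


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def list_images(directory: str | Path) -> list[Path]:
    directory = Path(directory)
    return sorted(p for p in directory.iterdir()
                  if p.suffix.lower() in IMAGE_SUFFIXES)
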