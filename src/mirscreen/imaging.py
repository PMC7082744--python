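"""Scratch-wound quantification and per-object shape features.

Images are 2-D grayscale intensity grids (row-major, origin top-left,
pixel units).  Segmentation is threshold-based (Otsu by default, as
GFP-channel images are thresholding-dominated) with 8-connected
objects and 4-connected background, the standard duality that keeps
the Euler number consistent.  Wound area is the largest background
component spanning the image top-to-bottom after morphologically
closing the foreground.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import filters, measure, morphology

MIN_OBJECT_SIZE = 50     # px, debris filter at a 10X-like scale
MAX_OBJECT_SIZE = 5000   # px, clump/artifact filter


@dataclass
class LabeledObjects:
    """Connected-component labelling restricted to the size-filtered objects."""

    label_map: np.ndarray          # 0 = background
    object_ids: tuple[int, ...]
    areas: dict[int, int]


# the ten per-object descriptors written to the features table
ALL_FEATURES = (
    "Area",
    "Perimeter",
    "MajorAxisLength",
    "MinorAxisLength",
    "Eccentricity",
    "Compactness",
    "EulerNumber",
    "Extent",
    "FormFactor",
    "Solidity",
)


def _threshold(image: np.ndarray, method: str | float) -> np.ndarray:
    if isinstance(method, (int, float)) and not isinstance(method, bool):
        return image > method
    if method == "otsu":
        return image > filters.threshold_otsu(image)
    raise ValueError(f"unknown threshold method {method!r}")


def segment_and_measure(
    image: np.ndarray,
    threshold_method: str | float = "otsu",
    min_size: int = MIN_OBJECT_SIZE,
    max_size: int = MAX_OBJECT_SIZE,
) -> tuple[LabeledObjects, pd.DataFrame]:
    """Segment objects and measure shape descriptors.

    Foreground = pixels above threshold; 8-connected components outside
    ``[min_size, max_size]`` pixels are discarded.  Feature definitions:
    axis lengths are 4*sqrt(eigenvalue) of the second central moment
    matrix, Eccentricity = sqrt(1 - (minor/major)^2), FormFactor =
    4*pi*Area/Perimeter^2 (1 for a disc), Compactness its reciprocal,
    Extent = Area / bounding-box area, Solidity = Area / convex-hull
    area, EulerNumber = 1 - holes.  An empty foreground yields an empty
    result, not an error.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={image.ndim}")
    if min_size >= max_size:
        raise ValueError("min_size must be < max_size")
    mask = _threshold(image, threshold_method)
    labels = measure.label(mask, connectivity=2)
    rows = []
    keep = np.zeros_like(labels)
    kept_ids: list[int] = []
    areas: dict[int, int] = {}
    for prop in measure.regionprops(labels):
        if not (min_size <= prop.area <= max_size):
            continue
        new_id = len(kept_ids) + 1
        kept_ids.append(new_id)
        areas[new_id] = int(prop.area)
        keep[labels == prop.label] = new_id
        perimeter = float(prop.perimeter)
        area = float(prop.area)
        form = 4 * math.pi * area / perimeter**2 if perimeter > 0 else math.nan
        rows.append(
            {
                "object_id": new_id,
                "Area": area,
                "Perimeter": perimeter,
                "MajorAxisLength": float(prop.axis_major_length),
                "MinorAxisLength": float(prop.axis_minor_length),
                "Eccentricity": float(prop.eccentricity),
                "Compactness": 1.0 / form if form and form > 0 else math.nan,
                "EulerNumber": int(prop.euler_number),
                "Extent": float(prop.extent),
                "FormFactor": form,
                "Solidity": float(prop.solidity),
            }
        )
    features = pd.DataFrame(rows, columns=["object_id", *ALL_FEATURES])
    return LabeledObjects(keep, tuple(kept_ids), areas), features


def wound_area(
    image: np.ndarray, closing_radius: int = 4, threshold_method: str | float = "otsu"
) -> int:
    """Pixel area of the scratch: the largest background component
    touching both the top and bottom borders (falling back to the
    largest background component overall), after closing the foreground
    with a disc of ``closing_radius`` to bridge inter-cell gaps."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if not image.any():
        warnings.warn("fully-background image: wound area equals the whole frame", stacklevel=2)
        return int(image.size)
    fg = _threshold(image, threshold_method)
    if closing_radius > 0:
        fg = morphology.closing(fg, morphology.disk(closing_radius))
    bg_labels = measure.label(~fg, connectivity=1)
    if bg_labels.max() == 0:
        return 0
    spanning = []
    sizes = {}
    top, bottom = bg_labels[0, :], bg_labels[-1, :]
    for prop in measure.regionprops(bg_labels):
        sizes[prop.label] = prop.area
        if (top == prop.label).any() and (bottom == prop.label).any():
            spanning.append(prop.label)
    if spanning:
        return int(max(sizes[l] for l in spanning))
    return int(max(sizes.values()))


@dataclass
class WoundSeries:
    """Wound areas over time for one well; migration(t) = area(0) - area(t)."""

    well: str
    timepoints: tuple[float, ...]
    areas: tuple[int, ...]

    @property
    def migration(self) -> tuple[float, ...]:
        return tuple(self.areas[0] - a for a in self.areas)


def migration_series(
    images_by_timepoint: Mapping[float, np.ndarray],
    well: str = "",
    closing_radius: int = 4,
) -> WoundSeries:
    """Wound areas across sorted timepoints; requires the t=0 reference."""
    times = sorted(images_by_timepoint)
    if not times or times[0] != 0:
        raise ValueError("missing t=0 reference image")
    areas = tuple(wound_area(images_by_timepoint[t], closing_radius) for t in times)
    return WoundSeries(well=well, timepoints=tuple(float(t) for t in times), areas=areas)


def aggregate_well(features: pd.DataFrame, statistic: str = "mean") -> pd.Series:
    """Element-wise aggregate of per-object features into a well vector.

    Zero objects yield an all-NaN record flagged via the ``n_objects``
    entry so the caller can exclude the well.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    cols = [c for c in ALL_FEATURES if c in features.columns]
    if len(features) == 0:
        out = pd.Series({c: math.nan for c in cols})
        out["n_objects"] = 0
        return out
    agg = features[cols].mean() if statistic == "mean" else features[cols].median()
    agg["n_objects"] = len(features)
    return agg


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF image as a 2-D array."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(str(path)))
    if img.ndim == 3:  # collapse identical channels
        img = img[..., 0]
    return img


def write_image(image: np.ndarray, path: str | Path) -> None:
    import imageio.v3 as iio

    iio.imwrite(str(path), np.asarray(image, dtype=np.uint8))
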