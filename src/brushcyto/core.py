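"""Shared containers for the brush-cytology morphometry pipeline.

The unit of analysis throughout the package is the *cell cluster*: a connected
group of epithelial cells cropped from a 40x Papanicolaou-stained brushing
slide.  A cluster travels through the pipeline as a :class:`ClusterImage`
(pixels + calibration + foreground mask), acquires a :class:`NuclearLabelMap`
from watershed segmentation, and ends up as a named 536-dimensional
:class:`FeatureVector` (495 aggregate texture + 41 nuclear shape features).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

#: default physical calibration, typical for 40x scans (micrometres per pixel)
DEFAULT_PIXEL_SIZE_UM: float = 0.25

#: minimum object area retained anywhere in the pipeline (micrometres squared)
DEFAULT_MIN_AREA_UM2: float = 100.0

N_TEXTURE_FEATURES = 495
N_SHAPE_FEATURES = 41
N_FEATURES = N_TEXTURE_FEATURES + N_SHAPE_FEATURES

PROVENANCES = ("annotated", "auto_detected", "synthetic")


@dataclass
class ClusterImage:
    """A single cell-cluster crop.

    Parameters
    ----------
    pixels
        2-D grayscale or RGB 8-bit array.
    pixel_size_um
        Physical side length of one pixel in micrometres; must be positive.
    foreground_mask
        Optional boolean array marking cluster (non-background) pixels;
        must match the spatial dimensions of ``pixels``.
    provenance
        One of ``annotated``, ``auto_detected`` or ``synthetic``.
    id
        Free-form identifier used in manifests and feature tables.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    foreground_mask: Optional[np.ndarray] = None
    provenance: str = "annotated"
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")
        if self.foreground_mask is not None:
            self.foreground_mask = np.asarray(self.foreground_mask, dtype=bool)
            if self.foreground_mask.shape != self.pixels.shape[:2]:
                raise ValueError("foreground_mask must match pixel dimensions")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape[:2]


@dataclass
class NuclearLabelMap:
    """Integer-labelled nucleus mask aligned to a cluster crop.

    ``labels`` uses 0 for non-nucleus pixels and 1..n_nuclei for individual
    nuclei; each positive label is a single connected component.
    """

    labels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())


@dataclass
class FeatureVector:
    """Named, ordered morphometric vector for one cluster.

    The full pipeline produces 536 entries (495 texture + 41 shape) named
    ``family.descriptor.statistic``; partial vectors (texture-only or
    shape-only) are permitted so that the feature banks compose.
    """

    names: list
    values: np.ndarray
    cluster_id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return self.values.size

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.cluster_id)


def feature_frame(vectors: list) -> pd.DataFrame:
    """Stack FeatureVectors into a table (one row per cluster).

    Adds ``cluster_id`` and ``label`` columns; feature ordering is taken from
    the first vector and must agree across vectors.
    """
    if not vectors:
        raise ValueError("no feature vectors given")
    names = vectors[0].names
    for v in vectors[1:]:
        if v.names != names:
            raise ValueError("inconsistent feature ordering across clusters")
    frame = pd.DataFrame([v.values for v in vectors], columns=names)
    frame.insert(0, "cluster_id", [v.cluster_id for v in vectors])
    frame.insert(1, "label", [v.label for v in vectors])
    return frame
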