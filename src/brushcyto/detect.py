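"""Automatic cell-cluster detection on slide-scale images.

Unannotated slides are decomposed into 1000x1000-pixel patches on a
non-overlapping grid; patches dominated by slide background (over 40% by
area) are discarded, and connected dark components above a 100 um^2 area
floor in the surviving patches become candidate cluster crops.  Coordinates
are 0-based with half-open boxes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .core import DEFAULT_MIN_AREA_UM2, DEFAULT_PIXEL_SIZE_UM, ClusterImage
from .preprocess import background_threshold


@dataclass
class PatchSpec:
    """Tiling and filtering parameters for slide decomposition."""

    patch_px: int = 1000
    max_background_fraction: float = 0.40
    min_cluster_area_um2: float = DEFAULT_MIN_AREA_UM2
    background_intensity_threshold: Union[float, str] = "auto"

    def __post_init__(self) -> None:
        if self.patch_px < 64:
            raise ValueError("patch_px must be >= 64")
        if not (0.0 < self.max_background_fraction < 1.0):
            raise ValueError("max_background_fraction must lie in (0, 1)")
        if self.min_cluster_area_um2 <= 0:
            raise ValueError("min_cluster_area_um2 must be positive")


@dataclass
class Patch:
    """One tile of a slide image with its offset in slide coordinates."""

    pixels: np.ndarray
    row0: int
    col0: int

    @property
    def box(self) -> Tuple[int, int, int, int]:
        h, w = self.pixels.shape[:2]
        return (self.row0, self.col0, self.row0 + h, self.col0 + w)


def tile(image: np.ndarray, spec: Optional[PatchSpec] = None) -> List[Patch]:
    """Cut a slide-scale image into a row-major non-overlapping patch grid.

    Right/bottom remainders smaller than a full patch are dropped.  Raises
    ``ValueError`` if the image is smaller than one patch in either
    dimension.
    """
    spec = spec or PatchSpec()
    image = np.asarray(image)
    H, W = image.shape[:2]
    s = spec.patch_px
    if H < s or W < s:
        raise ValueError("image smaller than one patch")
    patches = []
    for r0 in range(0, H - s + 1, s):
        for c0 in range(0, W - s + 1, s):
            patches.append(Patch(image[r0:r0 + s, c0:c0 + s], r0, c0))
    return patches


def _resolve_threshold(patch_pixels: np.ndarray, spec: PatchSpec) -> float:
    if spec.background_intensity_threshold == "auto":
        return background_threshold(patch_pixels)
    return float(spec.background_intensity_threshold)


def background_fraction(patch_pixels: np.ndarray, threshold: float) -> float:
    """Fraction of patch pixels at or above the background threshold."""
    patch_pixels = np.asarray(patch_pixels, dtype=float)
    return float((patch_pixels >= threshold).mean())


def filter_patches(
    patches: Sequence[Patch], spec: Optional[PatchSpec] = None
) -> List[Patch]:
    """Keep patches whose background fraction does not exceed the cap."""
    spec = spec or PatchSpec()
    kept = []
    for p in patches:
        thr = _resolve_threshold(p.pixels, spec)
        if background_fraction(p.pixels, thr) <= spec.max_background_fraction:
            kept.append(p)
    return kept


def extract_clusters(
    patch: Patch,
    spec: Optional[PatchSpec] = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> List[ClusterImage]:
    """Candidate clusters from one retained patch.

    Foreground = pixels below the background threshold; connected components
    with area >= ``min_cluster_area_um2`` become tight bounding-box crops
    carrying their own foreground mask, ``provenance='auto_detected'``.
    Components touching the patch edge are clipped to patch bounds.
    """
    spec = spec or PatchSpec()
    thr = _resolve_threshold(patch.pixels, spec)
    fg = np.asarray(patch.pixels, dtype=float) < thr
    fg = ndi.binary_fill_holes(fg)
    labels, n = ndi.label(fg)
    min_px = spec.min_cluster_area_um2 / (pixel_size_um ** 2)
    clusters: List[ClusterImage] = []
    if n == 0:
        return clusters
    slices = ndi.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        if comp.sum() < min_px:
            continue
        crop = np.asarray(patch.pixels)[sl]
        cid = (f"p{patch.row0}_{patch.col0}"
               f"_c{patch.row0 + sl[0].start}_{patch.col0 + sl[1].start}")
        clusters.append(
            ClusterImage(
                pixels=crop.copy(),
                pixel_size_um=pixel_size_um,
                foreground_mask=comp,
                provenance="auto_detected",
                id=cid,
            )
        )
    return clusters


def detect_clusters(
    image: np.ndarray,
    spec: Optional[PatchSpec] = None,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> Tuple[List[ClusterImage], pd.DataFrame]:
    """Full detection chain: tile -> patch filter -> cluster extraction.

    Returns the clusters and a manifest (patch offset, cluster box in patch
    coordinates, area in um^2).
    """
    spec = spec or PatchSpec()
    patches = filter_patches(tile(image, spec), spec)
    clusters: List[ClusterImage] = []
    rows = []
    for p in patches:
        for cl in extract_clusters(p, spec, pixel_size_um):
            clusters.append(cl)
            area_um2 = float(cl.foreground_mask.sum()) * pixel_size_um ** 2
            rows.append(
                {
                    "cluster_id": cl.id,
                    "patch_row0": p.row0,
                    "patch_col0": p.col0,
                    "area_um2": area_um2,
                }
            )
    manifest = pd.DataFrame(
        rows, columns=["cluster_id", "patch_row0", "patch_col0", "area_um2"]
    )
    return clusters, manifest
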