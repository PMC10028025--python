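"""Cluster crop preprocessing.

A raw crop contains the cluster of interest plus bright slide background and
small debris (stain artifacts, pen markings, bile residue, single cells).
The cleaning sequence applied here is: background removal by an intensity
threshold derived from the crop's own background plateau, removal of objects
below a physical area threshold, then histogram equalization restricted to
the retained foreground.  Texture extraction additionally subtracts a local
mean (15x15 window) to cancel slowly varying illumination.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .core import DEFAULT_MIN_AREA_UM2, ClusterImage

#: Rec. 709 luminance weights used for RGB -> gray conversion
LUMINANCE_WEIGHTS = np.array([0.2125, 0.7154, 0.0721])

#: default window (pixels, odd) for local-mean illumination normalization
ILLUMINATION_WINDOW = 15


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to 8-bit gray by Rec. 709 luminance.

    Single-channel input passes through unchanged.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[-1] == 3:
        gray = image.astype(float) @ LUMINANCE_WEIGHTS
        return np.clip(np.round(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"expected 2-D gray or HxWx3 RGB, got shape {image.shape}")


def background_threshold(image: np.ndarray) -> float:
    """Estimate the background intensity threshold of a crop.

    The bright slide background is estimated as the pixels above the Otsu
    split of the crop; the threshold is placed at the lower edge of that
    mode (mean minus three standard deviations) so that essentially all
    background pixels sit above it.  For a (near-)uniform crop the whole
    image is treated as background.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    lo, hi = image.min(), image.max()
    if hi - lo < 1e-9:
        return float(lo)
    split = threshold_otsu(image)
    bg = image[image > split]
    if bg.size == 0:
        return float(image.mean())
    # the bright side may still mix cytoplasm with slide background when
    # nuclei dominate the first split; re-split while it stays heterogeneous
    for _ in range(2):
        if bg.std() <= 10.0 or np.unique(bg).size < 2:
            break
        split = threshold_otsu(bg)
        upper = bg[bg > split]
        if upper.size == 0:
            break
        bg = upper
    return float(bg.mean() - 3.0 * bg.std())


def remove_background(image: np.ndarray, threshold: Optional[float] = None
                      ) -> np.ndarray:
    """Foreground mask: pixels strictly below the background threshold.

    ``threshold`` defaults to :func:`background_threshold` of the crop.  A
    uniformly bright crop yields an empty mask (flagged with a warning, not
    an error).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("remove_background expects a 2-D gray image")
    if image.size == 0:
        raise ValueError("empty image")
    lo, hi = float(image.min()), float(image.max())
    if hi - lo < 1e-9:
        warnings.warn("uniform image: empty foreground mask", stacklevel=2)
        return np.zeros(image.shape, dtype=bool)
    if threshold is None:
        threshold = background_threshold(image)
    return image.astype(float) < threshold


def remove_small_objects_um2(
    mask: np.ndarray,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    pixel_size_um: float = 0.25,
) -> np.ndarray:
    """Drop connected components smaller than ``min_area_um2``.

    The pixel-count threshold is ``min_area_um2 / pixel_size_um**2``;
    components with strictly fewer pixels are removed.
    """
    if min_area_um2 <= 0:
        raise ValueError("min_area_um2 must be positive")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    mask = np.asarray(mask, dtype=bool)
    min_px = min_area_um2 / (pixel_size_um ** 2)
    labels, n = ndi.label(mask)
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = np.zeros(n + 1, dtype=bool)
    keep[1:] = areas[1:] >= min_px
    return keep[labels]


def equalize_contrast(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Histogram-equalize the crop using only mask (cluster) pixels.

    The mapping is the 256-bin CDF of the masked intensities stretched to
    [0, 255]; it is monotone, so intensity rank order is preserved.  Pixels
    outside the mask are mapped through the same curve so the image stays
    coherent.  A constant masked region is returned unchanged.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.ndim != 2:
        raise ValueError("equalize_contrast expects a 2-D gray image")
    if mask.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    if not mask.any():
        raise ValueError("empty mask: nothing to equalize")
    vals = image[mask].astype(np.intp)
    hist = np.bincount(vals, minlength=256).astype(float)
    cdf = np.cumsum(hist)
    cdf /= cdf[-1]
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if cdf_min >= 1.0:  # single gray level under the mask
        return image.copy()
    lut = np.round(255.0 * (cdf - cdf_min) / (1.0 - cdf_min))
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return lut[image.astype(np.intp)]


def normalize_illumination(
    image: np.ndarray, window: int = ILLUMINATION_WINDOW
) -> np.ndarray:
    """Subtract the local mean in an odd square window (reflect borders).

    Output is float and signed; on a slowly varying image the interior is
    close to zero.  The operation is linear in the input.
    """
    image = np.asarray(image, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > min(image.shape):
        raise ValueError("window larger than image")
    local_mean = ndi.uniform_filter(image, size=window, mode="reflect")
    return image - local_mean


def preprocess_cluster(
    cluster: ClusterImage,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
) -> ClusterImage:
    """Full cleaning chain on one crop.

    Order: grayscale -> background removal -> small-object removal ->
    hole filling -> mask-restricted histogram equalization.  Returns a new
    ClusterImage whose ``pixels`` are equalized gray and whose
    ``foreground_mask`` is the cleaned cluster mask.  If the crop already
    carries a foreground mask (e.g. synthetic truth) it is used as the
    starting mask instead of re-thresholding.
    """
    gray = to_grayscale(cluster.pixels)
    if cluster.foreground_mask is not None:
        mask = cluster.foreground_mask.copy()
    else:
        mask = remove_background(gray)
    mask = remove_small_objects_um2(mask, min_area_um2, cluster.pixel_size_um)
    mask = ndi.binary_fill_holes(mask)
    if not mask.any():
        warnings.warn(f"cluster {cluster.id!r}: empty foreground after "
                      "cleaning", stacklevel=2)
        eq = gray
    else:
        eq = equalize_contrast(gray, mask)
    return ClusterImage(
        pixels=eq,
        pixel_size_um=cluster.pixel_size_um,
        foreground_mask=mask,
        provenance=cluster.provenance,
        id=cluster.id,
    )
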