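"""Aggregate cluster texture features.

Four families of per-pixel response maps are computed on the
illumination-normalized crop and each map is summarized over the cluster
foreground with five statistics (mean, median, standard deviation,
skewness, kurtosis):

* 13 Haralick maps — the classical second-order statistics of a symmetric,
  direction-averaged gray-level co-occurrence matrix accumulated inside a
  5x5 window around each pixel, on a 64-level quantization;
* 13 CoLlAGe maps — the same second-order statistics, but of the
  co-occurrence of locally dominant gradient orientations (the dominant
  singular direction of the stacked window gradients);
* 48 Gabor magnitude maps — a DC-free complex Gabor bank over 6 frequencies
  x 8 orientations;
* 25 Law's maps — responses to the outer products of the L5/E5/S5/W5/R5
  line kernels.

99 maps x 5 statistics = 495 texture features per cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numba import njit
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel

from .core import ClusterImage, FeatureVector
from .preprocess import normalize_illumination

HARALICK_NAMES = (
    "energy",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "info_measure_1",
    "info_measure_2",
)

STAT_NAMES = ("mean", "median", "std", "skewness", "kurtosis")

#: classical five-tap Law's line kernels
LAWS_VECTORS: Dict[str, np.ndarray] = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}

#: symmetric co-occurrence offsets: 0, 45, 90, 135 degrees at distance 1
GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def _default_frequencies() -> Tuple[float, ...]:
    return tuple(np.geomspace(0.05, 0.4, 6))


def _default_orientations() -> Tuple[float, ...]:
    return tuple(np.arange(8) * np.pi / 8.0)


@dataclass
class TextureConfig:
    """Parameters of the texture banks."""

    haralick_window: int = 5
    gray_levels: int = 64
    collage_window: int = 5
    collage_orientation_bins: int = 64
    gabor_frequencies: Tuple[float, ...] = field(
        default_factory=_default_frequencies
    )
    gabor_orientations: Tuple[float, ...] = field(
        default_factory=_default_orientations
    )
    laws_vectors: Dict[str, np.ndarray] = field(
        default_factory=lambda: dict(LAWS_VECTORS)
    )

    def validate(self) -> None:
        for w in (self.haralick_window, self.collage_window):
            if w < 3 or w % 2 == 0:
                raise ValueError("windows must be odd and >= 3")
        if self.gray_levels < 2 or self.collage_orientation_bins < 2:
            raise ValueError("quantization levels must be >= 2")
        n_gabor = len(self.gabor_frequencies) * len(self.gabor_orientations)
        if n_gabor != 48:
            raise ValueError(
                f"gabor grid must have 48 filters, got {n_gabor}"
            )
        for f in self.gabor_frequencies:
            if not (0 < f < 0.5):
                raise ValueError("gabor frequencies must lie below Nyquist")
        for name, v in self.laws_vectors.items():
            v = np.asarray(v, dtype=float)
            if v.size != 5:
                raise ValueError(f"laws vector {name} must have 5 taps")
        for name in ("E5", "S5", "R5"):
            if abs(float(np.sum(self.laws_vectors[name]))) > 1e-9:
                raise ValueError(f"laws vector {name} must sum to zero")
        if abs(float(np.sum(self.laws_vectors["L5"])) - 16.0) > 1e-9:
            raise ValueError("laws vector L5 must sum to 16")


@dataclass
class ResponseMap:
    """One per-pixel texture response map."""

    values: np.ndarray
    family: str
    descriptor_name: str

    @property
    def name(self) -> str:
        return f"{self.family}.{self.descriptor_name}"


def quantize(
    image: np.ndarray, foreground: np.ndarray, levels: int
) -> np.ndarray:
    """Quantize an image to ``levels`` bins over the foreground min-max range.

    Values outside the range (background pixels) are clipped to the end
    bins.  A constant foreground maps everything to bin 0.
    """
    image = np.asarray(image, dtype=float)
    fg = np.asarray(foreground, dtype=bool)
    vals = image[fg] if fg.any() else image.ravel()
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-12:
        return np.zeros(image.shape, dtype=np.int32)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


# ---------------------------------------------------------------------------
# windowed co-occurrence statistics (shared by Haralick and CoLlAGe)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cooccurrence_stats_maps(q, window, n_levels):  # pragma: no cover
    """13 co-occurrence statistics of the windowed, symmetric,
    direction-averaged GLCM around every pixel.

    ``q`` is an int32 level image.  Pairs are counted for the four standard
    distance-1 offsets when both endpoints fall inside the window and the
    image; each pair is entered twice (symmetry).  The information measures
    use the symmetric-matrix identities HXY1 = HX + HY = 2 HX and
    HXY2 = 2 HX.
    """
    H, W = q.shape
    half = window // 2
    out = np.zeros((13, H, W), dtype=np.float64)
    # scratch
    cmat = np.zeros((n_levels, n_levels), dtype=np.float64)
    max_pairs = 4 * window * window * 2
    ta = np.empty(max_pairs, dtype=np.int32)
    tb = np.empty(max_pairs, dtype=np.int32)
    px = np.zeros(n_levels, dtype=np.float64)
    psum = np.zeros(2 * n_levels - 1, dtype=np.float64)
    pdiff = np.zeros(n_levels, dtype=np.float64)
    offs = ((0, 1), (1, 0), (1, 1), (1, -1))

    for y in range(H):
        for x in range(W):
            y0 = max(y - half, 0)
            y1 = min(y + half, H - 1)
            x0 = max(x - half, 0)
            x1 = min(x + half, W - 1)
            nt = 0
            total = 0.0
            for dy, dx in offs:
                for wy in range(y0, y1 + 1):
                    ny = wy + dy
                    if ny < y0 or ny > y1:
                        continue
                    for wx in range(x0, x1 + 1):
                        nx = wx + dx
                        if nx < x0 or nx > x1:
                            continue
                        a = q[wy, wx]
                        b = q[ny, nx]
                        if cmat[a, b] == 0.0:
                            ta[nt] = a
                            tb[nt] = b
                            nt += 1
                        cmat[a, b] += 1.0
                        if cmat[b, a] == 0.0:
                            ta[nt] = b
                            tb[nt] = a
                            nt += 1
                        cmat[b, a] += 1.0
                        total += 2.0
            if total == 0.0:
                continue
            # normalize touched entries; build marginals
            for k in range(nt):
                a = ta[k]
                b = tb[k]
                p = cmat[a, b] / total
                cmat[a, b] = p
                px[a] += p
                psum[a + b] += p
                pdiff[abs(a - b)] += p
            energy = 0.0
            contrast = 0.0
            corr_num = 0.0
            idm = 0.0
            entropy = 0.0
            for k in range(nt):
                a = ta[k]
                b = tb[k]
                p = cmat[a, b]
                energy += p * p
                d = a - b
                contrast += p * d * d
                corr_num += p * a * b
                idm += p / (1.0 + d * d)
                entropy -= p * np.log(p)
            mu = 0.0
            hx = 0.0
            for i in range(n_levels):
                if px[i] > 0.0:
                    mu += i * px[i]
                    hx -= px[i] * np.log(px[i])
            var = 0.0
            for i in range(n_levels):
                if px[i] > 0.0:
                    var += (i - mu) * (i - mu) * px[i]
            if var > 1e-12:
                correlation = (corr_num - mu * mu) / var
            else:
                correlation = 0.0
            sum_avg = 0.0
            sum_ent = 0.0
            for k in range(2 * n_levels - 1):
                if psum[k] > 0.0:
                    sum_avg += k * psum[k]
                    sum_ent -= psum[k] * np.log(psum[k])
            sum_var = 0.0
            for k in range(2 * n_levels - 1):
                if psum[k] > 0.0:
                    sum_var += (k - sum_avg) * (k - sum_avg) * psum[k]
            mud = 0.0
            diff_ent = 0.0
            for k in range(n_levels):
                if pdiff[k] > 0.0:
                    mud += k * pdiff[k]
                    diff_ent -= pdiff[k] * np.log(pdiff[k])
            diff_var = 0.0
            for k in range(n_levels):
                if pdiff[k] > 0.0:
                    diff_var += (k - mud) * (k - mud) * pdiff[k]
            # information measures of correlation (symmetric identities)
            if hx > 1e-12:
                imc1 = (entropy - 2.0 * hx) / hx
            else:
                imc1 = 0.0
            arg = 1.0 - np.exp(-2.0 * (2.0 * hx - entropy))
            if arg < 0.0:
                arg = 0.0
            imc2 = np.sqrt(arg)

            out[0, y, x] = energy
            out[1, y, x] = contrast
            out[2, y, x] = correlation
            out[3, y, x] = var
            out[4, y, x] = idm
            out[5, y, x] = sum_avg
            out[6, y, x] = sum_var
            out[7, y, x] = sum_ent
            out[8, y, x] = entropy
            out[9, y, x] = diff_var
            out[10, y, x] = diff_ent
            out[11, y, x] = imc1
            out[12, y, x] = imc2

            # reset scratch
            for k in range(nt):
                cmat[ta[k], tb[k]] = 0.0
            for i in range(n_levels):
                px[i] = 0.0
                pdiff[i] = 0.0
            for k in range(2 * n_levels - 1):
                psum[k] = 0.0
    return out


def haralick_maps(
    image: np.ndarray,
    foreground: np.ndarray,
    cfg: Optional[TextureConfig] = None,
) -> List[ResponseMap]:
    """13 windowed Haralick statistic maps of the normalized image."""
    cfg = cfg or TextureConfig()
    cfg.validate()
    image = np.asarray(image, dtype=float)
    if cfg.haralick_window > min(image.shape):
        raise ValueError("haralick window exceeds image size")
    q = quantize(image, foreground, cfg.gray_levels)
    stack = _cooccurrence_stats_maps(q, cfg.haralick_window, cfg.gray_levels)
    return [
        ResponseMap(stack[i], "haralick", HARALICK_NAMES[i])
        for i in range(13)
    ]


def dominant_orientations(
    image: np.ndarray, window: int = 5
) -> np.ndarray:
    """Locally dominant gradient orientation (radians, [0, pi)) per pixel.

    The orientation is the dominant right singular direction of the matrix
    stacking the (gx, gy) gradient vectors of the window, computed via the
    2x2 windowed structure tensor.  Zero-gradient windows yield 0.
    """
    image = np.asarray(image, dtype=float)
    gy, gx = np.gradient(image)
    sxx = ndi.uniform_filter(gx * gx, size=window, mode="reflect")
    sxy = ndi.uniform_filter(gx * gy, size=window, mode="reflect")
    syy = ndi.uniform_filter(gy * gy, size=window, mode="reflect")
    theta = 0.5 * np.arctan2(2.0 * sxy, sxx - syy)
    theta = np.mod(theta, np.pi)
    degenerate = (sxx + syy) < 1e-15
    if degenerate.any():
        theta = np.where(degenerate, 0.0, theta)
    return theta


def collage_maps(
    image: np.ndarray,
    foreground: np.ndarray,
    cfg: Optional[TextureConfig] = None,
) -> List[ResponseMap]:
    """13 CoLlAGe maps: co-occurrence statistics of binned dominant
    gradient orientations within the window around each pixel."""
    cfg = cfg or TextureConfig()
    cfg.validate()
    image = np.asarray(image, dtype=float)
    if cfg.collage_window > min(image.shape):
        raise ValueError("collage window exceeds image size")
    theta = dominant_orientations(image, cfg.collage_window)
    bins = cfg.collage_orientation_bins
    q = np.clip(
        np.floor(theta / np.pi * bins).astype(np.int32), 0, bins - 1
    )
    stack = _cooccurrence_stats_maps(q, cfg.collage_window, bins)
    return [
        ResponseMap(stack[i], "collage", HARALICK_NAMES[i])
        for i in range(13)
    ]


def gabor_bank(
    image: np.ndarray,
    cfg: Optional[TextureConfig] = None,
) -> List[ResponseMap]:
    """48 Gabor magnitude response maps (DC-free complex filters)."""
    cfg = cfg or TextureConfig()
    cfg.validate()
    image = np.asarray(image, dtype=float)
    maps: List[ResponseMap] = []
    for f in cfg.gabor_frequencies:
        for t in cfg.gabor_orientations:
            kern = gabor_kernel(frequency=f, theta=t)
            kern = kern - kern.real.mean()  # remove DC so flat regions -> 0
            resp = fftconvolve(image, kern, mode="same")
            mag = np.abs(resp)
            deg = int(round(np.degrees(t)))
            maps.append(
                ResponseMap(mag, "gabor", f"f{f:.3f}_t{deg:03d}")
            )
    return maps


def laws_kernels(
    cfg: Optional[TextureConfig] = None,
) -> Dict[str, np.ndarray]:
    """The 25 ordered outer-product kernels, keyed e.g. ``L5E5``
    (= outer(L5, E5): rows weighted by L5, columns by E5)."""
    cfg = cfg or TextureConfig()
    names = ("L5", "E5", "S5", "W5", "R5")
    out: Dict[str, np.ndarray] = {}
    for u in names:
        for v in names:
            out[u + v] = np.outer(
                np.asarray(cfg.laws_vectors[u], dtype=float),
                np.asarray(cfg.laws_vectors[v], dtype=float),
            )
    return out


def laws_bank(
    image: np.ndarray,
    cfg: Optional[TextureConfig] = None,
) -> List[ResponseMap]:
    """25 Law's response maps: sliding dot product (correlation, reflect
    borders) with each 5x5 outer-product kernel."""
    cfg = cfg or TextureConfig()
    cfg.validate()
    image = np.asarray(image, dtype=float)
    maps = []
    for name, kern in laws_kernels(cfg).items():
        resp = ndi.correlate(image, kern, mode="reflect")
        maps.append(ResponseMap(resp, "laws", name))
    return maps


def response_maps(
    image: np.ndarray,
    foreground: np.ndarray,
    cfg: Optional[TextureConfig] = None,
) -> List[ResponseMap]:
    """All 99 maps in canonical order: Haralick, CoLlAGe, Gabor, Law's."""
    cfg = cfg or TextureConfig()
    return (
        haralick_maps(image, foreground, cfg)
        + collage_maps(image, foreground, cfg)
        + gabor_bank(image, cfg)
        + laws_bank(image, cfg)
    )


def five_statistics(values: np.ndarray) -> np.ndarray:
    """mean, median, population sd, skewness, kurtosis (Gaussian = 3).

    A degenerate (zero-variance) sample reports skewness = kurtosis = 0.
    """
    values = np.asarray(values, dtype=float).ravel()
    mean = values.mean()
    median = float(np.median(values))
    centered = values - mean
    m2 = np.mean(centered**2)
    sd = np.sqrt(m2)
    if sd < 1e-12:
        return np.array([mean, median, 0.0, 0.0, 0.0])
    skew = np.mean(centered**3) / sd**3
    kurt = np.mean(centered**4) / m2**2
    return np.array([mean, median, sd, skew, kurt])


def summarize(
    maps: Sequence[ResponseMap],
    foreground: np.ndarray,
    cluster_id: str = "",
    label: Optional[str] = None,
) -> FeatureVector:
    """Summarize each response map over the cluster foreground.

    Returns a FeatureVector with ``len(maps) * 5`` entries named
    ``family.descriptor.statistic``; the full bank yields 495.
    Requires at least 4 foreground pixels (kurtosis needs them).
    """
    fg = np.asarray(foreground, dtype=bool)
    if fg.sum() < 4:
        raise ValueError("need at least 4 foreground pixels to summarize")
    names: List[str] = []
    values: List[float] = []
    degenerate = []
    for m in maps:
        stats = five_statistics(m.values[fg])
        if stats[2] == 0.0 and np.ptp(m.values[fg]) == 0.0:
            degenerate.append(m.name)
        for stat_name, v in zip(STAT_NAMES, stats):
            names.append(f"{m.name}.{stat_name}")
            values.append(float(v))
    if degenerate:
        warnings.warn(
            f"constant response maps (skew/kurt set to 0): {degenerate[:5]}",
            stacklevel=2,
        )
    return FeatureVector(names=names, values=np.array(values),
                         cluster_id=cluster_id, label=label)


def texture_features(
    cluster: ClusterImage,
    cfg: Optional[TextureConfig] = None,
) -> FeatureVector:
    """495 texture features of a preprocessed cluster.

    Applies illumination normalization (15x15 local-mean subtraction) and
    summarizes all 99 response maps over the cluster foreground.
    """
    cfg = cfg or TextureConfig()
    if cluster.foreground_mask is None:
        raise ValueError("cluster must carry a foreground mask")
    # clamp the 15x15 local-mean window for unusually small crops
    win = min(15, min(cluster.shape) - (1 - min(cluster.shape) % 2))
    win = max(win - (1 - win % 2), 3)
    normalized = normalize_illumination(
        np.asarray(cluster.pixels, float), window=win
    )
    maps = response_maps(normalized, cluster.foreground_mask, cfg)
    return summarize(maps, cluster.foreground_mask,
                     cluster_id=cluster.id)
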