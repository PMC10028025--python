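"""Nuclear shape features.

Eight descriptors are measured per segmented nucleus (area, perimeter,
major/minor ellipse-equivalent axis lengths, eccentricity, solidity,
circularity, equivalent diameter), aggregated to cluster level with the
same five statistics used for texture (8 x 5 = 40), and complemented by the
cluster nuclear-to-cytoplasmic (N:C) ratio for a total of 41 shape
features.  Lengths are reported in micrometres, areas in square
micrometres.
"""

from __future__ import annotations

from typing import List

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import regionprops_table

from .core import ClusterImage, FeatureVector, NuclearLabelMap
from .texture import STAT_NAMES, five_statistics


def solidity_of(mask: np.ndarray) -> float:
    """Region area over the area of the convex hull of its pixel centres.

    Using the hull polygon (not a re-rasterized hull image) keeps the
    estimate nearly unbiased for small regions; values may exceed 1 by a
    raster epsilon for convex shapes.  Degenerate regions (fewer than three
    non-collinear pixels) report 1.
    """
    pts = np.argwhere(mask)
    if len(pts) < 3:
        return 1.0
    try:
        hull = ConvexHull(pts.astype(float))
    except QhullError:
        return 1.0
    return float(len(pts) / hull.volume) if hull.volume > 0 else 1.0

#: descriptor order used in aggregation (8 descriptors x 5 statistics = 40)
SHAPE_DESCRIPTORS = (
    "area_um2",
    "perimeter_um",
    "major_axis_um",
    "minor_axis_um",
    "eccentricity",
    "solidity",
    "circularity",
    "equivalent_diameter_um",
)


def nucleus_descriptors(
    labels: NuclearLabelMap, pixel_size_um: float
) -> pd.DataFrame:
    """Per-nucleus shape table (one row per label, physical units).

    Axis lengths come from the ellipse with matching second moments;
    solidity is area over convex-hull area; perimeter uses the Crofton
    estimator; circularity is 4*pi*A/P^2 (1 for a disc).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if labels.n_nuclei < 1:
        raise ValueError("empty label map: no nuclei to measure")
    props = regionprops_table(
        labels.labels,
        properties=(
            "label",
            "area",
            "perimeter_crofton",
            "axis_major_length",
            "axis_minor_length",
            "eccentricity",
            "equivalent_diameter_area",
        ),
    )
    t = pd.DataFrame(props)
    from scipy import ndimage as ndi

    slices = ndi.find_objects(labels.labels)
    solidities = []
    for lab in t["label"]:
        sl = slices[int(lab) - 1]
        solidities.append(solidity_of(labels.labels[sl] == lab))
    t["solidity"] = solidities
    px = pixel_size_um
    out = pd.DataFrame(
        {
            "label": t["label"],
            "area_px": t["area"],
            "area_um2": t["area"] * px**2,
            "perimeter_um": t["perimeter_crofton"] * px,
            "major_axis_um": t["axis_major_length"] * px,
            "minor_axis_um": t["axis_minor_length"] * px,
            "eccentricity": t["eccentricity"],
            "solidity": t["solidity"],
            "equivalent_diameter_um": t["equivalent_diameter_area"] * px,
        }
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        circ = 4 * np.pi * t["area"] / t["perimeter_crofton"] ** 2
    out["circularity"] = np.where(t["perimeter_crofton"] > 0, circ, 0.0)
    return out


def aggregate_shape(table: pd.DataFrame) -> FeatureVector:
    """Cluster-level aggregation: 8 descriptors x 5 statistics = 40 values.

    Single-nucleus clusters report sd = skewness = kurtosis = 0 (degenerate
    sample convention, shared with the texture summarizer).
    """
    if len(table) < 1:
        raise ValueError("empty shape table")
    names: List[str] = []
    values: List[float] = []
    for desc in SHAPE_DESCRIPTORS:
        stats = five_statistics(table[desc].to_numpy())
        for stat_name, v in zip(STAT_NAMES, stats):
            names.append(f"shape.{desc}.{stat_name}")
            values.append(float(v))
    return FeatureVector(names=names, values=np.array(values))


def nc_ratio(labels: NuclearLabelMap, foreground: np.ndarray) -> float:
    """Nuclear-to-cytoplasmic ratio: total nuclear area over non-nuclear
    foreground area.  Errors when the cluster has no cytoplasm pixels."""
    fg = np.asarray(foreground, dtype=bool)
    nuclear = int((labels.labels > 0).sum())
    non_nuclear = int(fg.sum()) - int((fg & (labels.labels > 0)).sum())
    if non_nuclear <= 0:
        raise ValueError("degenerate cluster: no non-nuclear foreground area")
    return nuclear / non_nuclear


def shape_features(
    cluster: ClusterImage,
    labels: NuclearLabelMap,
) -> FeatureVector:
    """All 41 shape features (40 aggregates + N:C ratio) for one cluster."""
    if cluster.foreground_mask is None:
        raise ValueError("cluster must carry a foreground mask")
    table = nucleus_descriptors(labels, cluster.pixel_size_um)
    agg = aggregate_shape(table)
    names = list(agg.names) + ["shape.nc_ratio"]
    values = np.concatenate(
        [agg.values, [nc_ratio(labels, cluster.foreground_mask)]]
    )
    return FeatureVector(names=names, values=values, cluster_id=cluster.id)
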