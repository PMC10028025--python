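"""End-to-end feature extraction: crop -> 536-dimensional vector."""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import ClusterImage, FeatureVector, feature_frame
from .preprocess import preprocess_cluster
from .segment import segment_nuclei
from .shape import shape_features
from .synthetic import Cohort
from .texture import TextureConfig, texture_features


def extract_features(
    cluster: ClusterImage,
    cfg: Optional[TextureConfig] = None,
    label: Optional[str] = None,
) -> FeatureVector:
    """Full morphometric profile of one cluster crop.

    Runs preprocessing (background removal, cleanup, equalization),
    watershed nuclear segmentation, the four texture banks on the
    illumination-normalized crop, and the nuclear shape bank; returns the
    495 texture + 41 shape features in canonical order.
    """
    clean = preprocess_cluster(cluster)
    labels = segment_nuclei(clean)
    tex = texture_features(clean, cfg)
    if labels.n_nuclei < 1:
        raise ValueError(
            f"cluster {cluster.id!r}: no nuclei segmented; "
            "shape features undefined"
        )
    shp = shape_features(clean, labels)
    return FeatureVector(
        names=list(tex.names) + list(shp.names),
        values=np.concatenate([tex.values, shp.values]),
        cluster_id=cluster.id,
        label=label,
    )


def extract_cohort(
    cohort: Cohort,
    cfg: Optional[TextureConfig] = None,
) -> Tuple[pd.DataFrame, List[str]]:
    """Feature table for a synthetic cohort.

    Returns (frame, patient_ids) where the frame has one row per cluster
    with ``cluster_id``/``label`` columns followed by the 536 features;
    clusters whose segmentation finds no nuclei are skipped with their
    patient kept in ``patient_ids`` alignment dropped too.
    """
    vectors: List[FeatureVector] = []
    kept_patients: List[str] = []
    for pid, cl in zip(cohort.patient_ids, cohort.clusters):
        try:
            vec = extract_features(cl.as_cluster_image(), cfg, label=cl.label)
        except ValueError:
            continue
        vectors.append(vec)
        kept_patients.append(pid)
    return feature_frame(vectors), kept_patients
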