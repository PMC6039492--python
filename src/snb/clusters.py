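"""High-intensity cluster analysis of mean-intensity maps.

The brightest pixels of a cell's mean-intensity map (top decile by default)
tend to form spatially segregated clusters.  The question this module
answers is whether receptors inside those clusters are more oligomerized
than receptors elsewhere at comparable surface density: cluster pixels are
selected by intensity quantile, labeled by connected components, and their
mean molecular brightness is compared with out-of-cluster pixels restricted
to the same intensity deciles (expression matching).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label

__all__ = ["ClusterReport", "top_intensity_clusters", "compare_cluster_brightness"]


@dataclass
class ClusterReport:
    """Result of selecting and labeling the top-intensity pixels.

    ``selected_mask`` is the full top-fraction pixel set; ``cluster_label_map``
    labels its connected components (0 = none), with components smaller than
    ``min_size`` dropped from the cluster count but retained in the set.
    """

    cluster_label_map: np.ndarray
    selected_mask: np.ndarray
    n_clusters: int
    intensity_decile_edges: np.ndarray
    fraction: float
    in_cluster_brightness: float = float("nan")
    matched_out_brightness: float = float("nan")
    analysis_mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def top_intensity_clusters(
    mean_map: np.ndarray,
    mask: np.ndarray,
    fraction: float = 0.10,
    connectivity: int = 8,
    min_size: int = 4,
) -> ClusterReport:
    """Select the top-``fraction`` intensity pixels within ``mask`` and label
    their spatial clusters.

    The threshold is the (1 - fraction) quantile of masked intensities; ties
    at the threshold are included, so the selection may slightly exceed the
    nominal fraction.  ``connectivity`` is 4 or 8 (pixel neighbourhoods);
    components smaller than ``min_size`` pixels do not count as clusters.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mean_map = np.asarray(mean_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != mean_map.shape:
        raise ValueError("mask and map shapes differ")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    values = mean_map[mask]
    decile_edges = np.quantile(values, np.linspace(0.0, 1.0, 11))
    if np.ptp(values) == 0:
        warnings.warn(
            "all masked intensities are equal; selecting the whole mask",
            RuntimeWarning,
            stacklevel=2,
        )
        selected = mask.copy()
    else:
        threshold = np.quantile(values, 1.0 - fraction)
        selected = mask & (mean_map >= threshold)
    labels = label(selected, connectivity=1 if connectivity == 4 else 2)
    n_clusters = 0
    relabeled = np.zeros_like(labels)
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        if comp.sum() >= min_size:
            n_clusters += 1
            relabeled[comp] = n_clusters
    return ClusterReport(
        cluster_label_map=relabeled,
        selected_mask=selected,
        n_clusters=n_clusters,
        intensity_decile_edges=decile_edges,
        fraction=fraction,
        analysis_mask=mask,
    )


def compare_cluster_brightness(
    brightness_map: np.ndarray,
    mean_map: np.ndarray,
    report: ClusterReport,
) -> tuple[float, float]:
    """Mean brightness inside clusters versus expression-matched outside.

    "Inside" means pixels belonging to counted clusters (components of at
    least ``min_size``).  Out-of-cluster pixels — including selected pixels
    that did not form a cluster — are binned by the intensity deciles of the
    analysis mask, and the comparison value is their mean brightness
    restricted to the deciles occupied by cluster pixels, so both groups
    sample similar surface densities.  Updates the report in place and
    returns the two means.
    """
    brightness_map = np.asarray(brightness_map, dtype=float)
    mean_map = np.asarray(mean_map, dtype=float)
    selected = report.cluster_label_map > 0
    mask = report.analysis_mask
    if not selected.any():
        raise ValueError("cluster report selects no pixels")
    edges = report.intensity_decile_edges.copy()
    edges[0] = -np.inf
    edges[-1] = np.inf
    decile_of = np.digitize(mean_map, edges[1:-1])
    occupied = np.unique(decile_of[selected])
    out = mask & ~selected & np.isin(decile_of, occupied)
    if not out.any():
        raise ValueError("no expression-matched out-of-cluster pixels")
    in_vals = brightness_map[selected]
    out_vals = brightness_map[out]
    in_mean = float(np.nanmean(in_vals))
    out_mean = float(np.nanmean(out_vals))
    report.in_cluster_brightness = in_mean
    report.matched_out_brightness = out_mean
    return in_mean, out_mean
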