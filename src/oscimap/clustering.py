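"""Grouping of thresholded oscillating pixels into spatial clusters with
OPTICS, morphology-derived minimum cluster sizes, and per-cluster traces
and geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import OPTICS

from .errors import ConfigurationError
from .preprocess import Movie
from .spectral import PSDImage

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterInfo",
    "PixelClusterSet",
    "neuron_footprint_pixels",
    "cluster_pixels",
    "cluster_trace",
    "cluster_geometry",
]


def neuron_footprint_pixels(diameter_um: float, pixel_pitch_um: float) -> int:
    """Number of pixels covering one neuron footprint of the given diameter.

    ``round(pi * (d/2)^2 / pitch^2)``, clamped to at least 1 pixel. With a
    110 um dendritic-ellipse diameter at 18 um/pixel this yields 29.
    """
    if diameter_um <= 0 or pixel_pitch_um <= 0:
        raise ConfigurationError("diameter and pixel pitch must be > 0")
    n = round(np.pi * (diameter_um / 2.0) ** 2 / pixel_pitch_um**2)
    return max(int(n), 1)


@dataclass(frozen=True)
class ClusterInfo:
    id: int
    pixels: np.ndarray  # (n, 2) row/col
    centroid: tuple[float, float]
    size: int
    mean_band_power: float


@dataclass(frozen=True)
class PixelClusterSet:
    """A labelling of masked pixels into clusters (-1 = noise)."""

    labels: np.ndarray
    clusters: tuple[ClusterInfo, ...]
    params: dict

    def __len__(self) -> int:
        return len(self.clusters)


def cluster_pixels(image: PSDImage, min_cluster_size: int = 5,
                   max_eps: float = 5.0, method: str = "dbscan",
                   xi: float = 0.05, use_power_feature: bool = False,
                   ) -> PixelClusterSet:
    """Density-cluster the masked pixels of a PSD image in (row, col) space.

    OPTICS builds the density ordering; cluster extraction defaults to the
    DBSCAN cut at ``eps = max_eps`` (robust on small pixel sets), with the
    xi-steepness method available via ``method='xi'``. Every reported
    cluster has at least ``min_cluster_size`` members and clusters need not
    be spatially contiguous. Fewer masked pixels than the minimum yields an
    empty cluster set, not an error. Clusters are sorted by descending mean
    band power and numbered from 0. ``use_power_feature=True`` appends the
    normalised band power as a third clustering feature (off by default:
    the mask already encodes oscillation strength).
    """
    if method not in ("dbscan", "xi"):
        raise ConfigurationError(f"unknown extraction method {method!r}")
    if min_cluster_size < 2:
        raise ConfigurationError("min_cluster_size must be >= 2")
    coords = np.argwhere(image.mask)
    # lexicographic processing order makes tie-breaking deterministic
    order = np.lexsort((coords[:, 1], coords[:, 0]))
    coords = coords[order]
    labels_map = np.full(image.band_power.shape, -1, dtype=np.int32)
    if coords.shape[0] < min_cluster_size:
        logger.info("only %d masked pixels (< %d); empty cluster set",
                    coords.shape[0], min_cluster_size)
        return PixelClusterSet(labels=labels_map, clusters=(), params={
            "min_cluster_size": min_cluster_size, "max_eps": max_eps,
            "method": method, "xi": xi})

    features = coords.astype(float)
    if use_power_feature:
        power = image.band_power[coords[:, 0], coords[:, 1]]
        pmax = np.nanmax(power)
        if pmax > 0:
            features = np.column_stack([features, power / pmax])

    if method == "dbscan":
        model = OPTICS(min_samples=min_cluster_size, max_eps=max_eps,
                       cluster_method="dbscan", eps=max_eps)
    else:
        model = OPTICS(min_samples=min_cluster_size, max_eps=max_eps,
                       cluster_method="xi", xi=xi,
                       min_cluster_size=min_cluster_size)
    raw = model.fit_predict(features)

    infos = []
    for label in np.unique(raw):
        if label == -1:
            continue
        members = coords[raw == label]
        if members.shape[0] < min_cluster_size:
            continue
        power = image.band_power[members[:, 0], members[:, 1]]
        infos.append((float(np.nanmean(power)), members))
    infos.sort(key=lambda item: -item[0])

    clusters = []
    for new_id, (mean_power, members) in enumerate(infos):
        labels_map[members[:, 0], members[:, 1]] = new_id
        clusters.append(ClusterInfo(
            id=new_id, pixels=members,
            centroid=(float(members[:, 0].mean()), float(members[:, 1].mean())),
            size=int(members.shape[0]), mean_band_power=mean_power))
    return PixelClusterSet(labels=labels_map, clusters=tuple(clusters),
                           params={"min_cluster_size": min_cluster_size,
                                   "max_eps": max_eps, "method": method,
                                   "xi": xi})


def cluster_trace(movie: Movie, cluster: ClusterInfo | np.ndarray) -> np.ndarray:
    """Unweighted per-frame mean over a cluster's member pixels.

    ``cluster`` may be a :class:`ClusterInfo` or an ``(n, 2)`` array of
    row/col pixel coordinates. The movie is expected to carry dF/F.
    """
    pixels = cluster.pixels if isinstance(cluster, ClusterInfo) else np.asarray(cluster)
    if pixels.size == 0:
        raise ConfigurationError("cannot extract a trace from an empty cluster")
    nrows, ncols = movie.frame_shape
    if (pixels[:, 0].min() < 0 or pixels[:, 1].min() < 0
            or pixels[:, 0].max() >= nrows or pixels[:, 1].max() >= ncols):
        raise ConfigurationError("cluster pixels outside the movie frame")
    return movie.data[:, pixels[:, 0], pixels[:, 1]].mean(axis=1)


def cluster_geometry(cluster_set: PixelClusterSet,
                     reference_point: tuple[float, float],
                     pixel_pitch_um: float) -> pd.DataFrame:
    """Per-cluster geometry in micrometres.

    Columns: centroid distance to the reference point, mean pairwise
    inter-pixel Euclidean distance, and area (n_pixels * pitch^2).
    """
    if pixel_pitch_um <= 0:
        raise ConfigurationError("pixel pitch must be > 0")
    rows = []
    for cl in cluster_set.clusters:
        if cl.size > 1:
            mean_pair = float(pdist(cl.pixels.astype(float)).mean()) * pixel_pitch_um
        else:
            mean_pair = 0.0
        dist = np.hypot(cl.centroid[0] - reference_point[0],
                        cl.centroid[1] - reference_point[1]) * pixel_pitch_um
        rows.append({
            "cluster_id": cl.id,
            "n_pixels": cl.size,
            "centroid_row": cl.centroid[0],
            "centroid_col": cl.centroid[1],
            "centroid_dist_um": float(dist),
            "mean_pairwise_um": mean_pair,
            "area_um2": cl.size * pixel_pitch_um**2,
            "mean_band_power": cl.mean_band_power,
        })
    return pd.DataFrame(rows, columns=[
        "cluster_id", "n_pixels", "centroid_row", "centroid_col",
        "centroid_dist_um", "mean_pairwise_um", "area_um2", "mean_band_power"])
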