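"""Measurement extraction: amygdala norm time courses, z-scored cortical
maps, ROI definition, and windowed mean amplitudes.

The analysis windows are the early-peak window 130–170 ms and four
consecutive 40-ms windows spanning 190–350 ms.  Windows are half-open
[start, end) in seconds and are mapped to samples by index flooring, so the
sample counts per window are exact at 1250 Hz.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from sklearn.cluster import KMeans

from .anatomy import SurfaceSourceSpace, VolumeSourceSpace
from .errors import InvalidConfigError
from .inverse import SourceEstimate

logger = logging.getLogger(__name__)

#: The five analysis windows (seconds, half-open).
ANALYSIS_WINDOWS = {
    "130-170": (0.130, 0.170),
    "190-230": (0.190, 0.230),
    "230-270": (0.230, 0.270),
    "270-310": (0.270, 0.310),
    "310-350": (0.310, 0.350),
}
EARLY_WINDOWS = ("130-170",)
LATE_WINDOWS = ("190-230", "230-270", "270-310", "310-350")

#: Default peak-ROI sizes (vertex counts) for the ventral (fusiform) and
#: lateral occipito-temporal search regions.
DEFAULT_ROI_SIZES = {"fusiform": 77, "lateral_occipital": 82}


# ---------------------------------------------------------------------------
# amygdala norm time course


def node_norm_timecourses(
    estimate: SourceEstimate, volume_space: VolumeSourceSpace, hemisphere: str
) -> np.ndarray:
    """Per-node Euclidean norms of the trihedral components: (n_nodes, n_times)."""
    cols = estimate.columns_of(volume_space.structure_label, hemisphere)
    if cols.size == 0:
        raise InvalidConfigError(f"no {volume_space.structure_label}/{hemisphere} components")
    comp = estimate.data[cols].reshape(-1, 3, estimate.data.shape[1])
    return np.linalg.norm(comp, axis=1)


def amygdala_timecourse(
    estimate: SourceEstimate, volume_space: VolumeSourceSpace
) -> dict[str, np.ndarray]:
    """Per-hemisphere mean-of-node-norms amygdala activity time course.

    At every node the amplitude is the Euclidean norm of the three trihedral
    component estimates; the hemisphere trace is the node-mean of the norms.
    """
    return {
        hemi: node_norm_timecourses(estimate, volume_space, hemi).mean(axis=0)
        for hemi in ("left", "right")
        if np.any(volume_space.hemisphere == hemi)
    }


# ---------------------------------------------------------------------------
# z-scored maps


@dataclass
class ZMap:
    """Per-vertex z-scored current amplitudes relative to the baseline."""

    data: np.ndarray  # (n_vertices, n_times), dimensionless
    times: np.ndarray
    baseline: tuple
    flagged: np.ndarray  # vertices with zero baseline sd (z forced to 0)


def zscore_map(
    data: np.ndarray, times: np.ndarray, baseline_window: tuple = (-0.2, 0.0)
) -> ZMap:
    """z(t) = (x(t) − baseline mean) / baseline sd, per vertex.

    Vertices with zero baseline standard deviation are flagged and set to 0.
    """
    data = np.asarray(data, float)
    mask = (times >= baseline_window[0]) & (times < baseline_window[1])
    if not mask.any():
        raise InvalidConfigError("baseline window contains no samples")
    mean = data[:, mask].mean(axis=1, keepdims=True)
    sd = data[:, mask].std(axis=1, ddof=0, keepdims=True)
    flagged = sd[:, 0] == 0.0
    if flagged.any():
        logger.warning("%d vertices with zero baseline sd; z set to 0", flagged.sum())
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (data - mean) / safe_sd
    z[flagged] = 0.0
    return ZMap(z, times, baseline_window, flagged)


# ---------------------------------------------------------------------------
# ROIs


@dataclass
class RoiDefinition:
    name: str
    members: np.ndarray  # vertex or node ids, unique
    center: int
    defining_window: tuple | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.members = np.asarray(self.members, int)
        if len(np.unique(self.members)) != len(self.members):
            raise InvalidConfigError("ROI members must be unique")
        if self.center not in self.members:
            raise InvalidConfigError("ROI center must be a member")

    @property
    def size(self) -> int:
        return len(self.members)

    def to_json_dict(self) -> dict:
        return {
            "name": self.name,
            "members": self.members.tolist(),
            "center": int(self.center),
            "defining_window": self.defining_window,
        }


def geodesic_distances(surface: SurfaceSourceSpace, source_vertex: int) -> np.ndarray:
    """Graph-geodesic distance from one vertex along mesh edges (metres)."""
    tris = surface.triangles
    edges = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    lengths = np.linalg.norm(
        surface.vertices[edges[:, 0]] - surface.vertices[edges[:, 1]], axis=1
    )
    n = surface.n_sources
    graph = csr_matrix(
        (np.r_[lengths, lengths], (np.r_[edges[:, 0], edges[:, 1]], np.r_[edges[:, 1], edges[:, 0]])),
        shape=(n, n),
    )
    return dijkstra(graph, indices=source_vertex)


def define_peak_roi(
    zmap: ZMap,
    window: tuple,
    size: int,
    surface: SurfaceSourceSpace,
    search_vertices: np.ndarray | None = None,
    name: str = "roi",
) -> RoiDefinition:
    """Fixed-size ROI centred on the window-mean z maximum.

    The center is the vertex maximizing the mean z over the window within
    the search region; the ROI is the ``size`` nearest vertices to the
    center by geodesic graph distance (ties broken by lowest vertex id).
    """
    if size < 1:
        raise InvalidConfigError("ROI size must be >= 1")
    tmask = (zmap.times >= window[0]) & (zmap.times < window[1])
    if not tmask.any():
        raise InvalidConfigError("ROI window outside the epoch")
    wmean = zmap.data[:, tmask].mean(axis=1)
    search = (
        np.arange(surface.n_sources) if search_vertices is None else np.asarray(search_vertices, int)
    )
    center = int(search[np.argmax(wmean[search])])
    dist = geodesic_distances(surface, center)
    dist = dist[search]
    order = np.lexsort((search, dist))  # distance, then lowest vertex id
    members = np.sort(search[order[: min(size, len(search))]])
    return RoiDefinition(name, members, center, defining_window=tuple(window))


def cluster_volume_rois(
    node_coordinates: np.ndarray, k: int, seed: int = 0, name_prefix: str = "cluster"
) -> list[RoiDefinition]:
    """k-means partition of node coordinates into control ROIs.

    Deterministic for a fixed seed (k-means++ initialization, 10 restarts).
    Each ROI's center is the member node nearest its cluster centroid.
    """
    coords = np.asarray(node_coordinates, float)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(coords)
    rois = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        d = np.linalg.norm(coords[members] - km.cluster_centers_[c], axis=1)
        center = int(members[np.argmin(d)])
        rois.append(RoiDefinition(f"{name_prefix}{c}", members, center))
    return rois


def roi_timecourse(data: np.ndarray, roi: RoiDefinition) -> np.ndarray:
    """Mean over ROI members of per-source time series (n_sources, n_times)."""
    return data[roi.members].mean(axis=0)


# ---------------------------------------------------------------------------
# windowed measurements


def window_mean(trace: np.ndarray, times: np.ndarray, window: tuple) -> float:
    """Time-sample mean over the half-open window [start, end)."""
    mask = (times >= window[0]) & (times < window[1])
    if not mask.any():
        raise InvalidConfigError(f"window {window} contains no samples")
    return float(np.asarray(trace)[..., mask].mean())

def window_means(
    trace: np.ndarray,
    times: np.ndarray,
    windows: dict | None = None,
    **row_labels,
) -> pd.DataFrame:
    """Tidy rows of per-window means of one time course."""
    if windows is None:
        windows = ANALYSIS_WINDOWS
    rows = [
        {**row_labels, "window": label, "value": window_mean(trace, times, win)}
        for label, win in windows.items()
    ]
    return pd.DataFrame(rows)


def measurement_table(
    traces: dict,
    times: np.ndarray,
    windows: dict | None = None,
) -> pd.DataFrame:
    """MeasurementTable from {(subject, roi, hemisphere, emotion, gaze): trace}.

    Long tidy format: subject, roi, hemisphere, emotion, gaze, window, value.
    """
    frames = [
        window_means(
            trace,
            times,
            windows,
            subject=subject,
            roi=roi,
            hemisphere=hemisphere,
            emotion=emotion,
            gaze=gaze,
        )
        for (subject, roi, hemisphere, emotion, gaze), trace in traces.items()
    ]
    return pd.concat(frames, ignore_index=True)
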