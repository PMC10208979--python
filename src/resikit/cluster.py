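"""Clustering of DNA-PAINT localizations into per-target groups.

The clusterer exploits two properties of DNA-PAINT data: localizations of a
single target are Gaussian-distributed around the true position, and true
repetitive blinking is spread uniformly across the acquisition whereas
sticking artifacts are temporally compact.

Spatial stage (gradient-ascent style):

1. count neighbours within radius ``r`` of each localization (ellipsoidal
   scaled norm ``sqrt(dx^2 + dy^2 + (dz * r / r_z)^2) <= r`` in 3D);
2. a localization is a local maximum if no neighbour within ``r`` has a
   higher count (ties broken toward the lowest index so a flat-topped cloud
   still yields exactly one maximum);
3. processing maxima in decreasing-count order, all not-yet-assigned
   localizations within ``r`` of a maximum form its cluster; clusters with
   ``<= n_min`` members are dissolved.

Temporal filters, applied per kept cluster:

* mean-frame filter: reject clusters whose mean frame falls in the first or
  last ``edge_fraction`` (default 20%) of the acquisition;
* window filter: split the acquisition into ``n_windows`` (default 20) equal
  windows; reject if any single window holds more than
  ``window_max_fraction`` (default 80%) of the cluster's localizations.

A rule of thumb for ``r`` is about twice the localization precision; a
suitable ``n_min`` separates the single-target mode from background in a
histogram of per-pick localization counts (:func:`suggest_n_min`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError
from .io import LocalizationTable

STATUS_KEPT = "kept"
STATUS_MEAN_FRAME = "rejected_mean_frame"
STATUS_WINDOW = "rejected_window"


@dataclass
class ClusterParams:
    """Clustering and artifact-filter parameters.

    ``r`` (nm) sets the cluster radius; ``r_z`` the axial radius for 3D data
    (z spread is roughly twofold larger than lateral, so ``r_z ~ 2 r``);
    ``n_min`` is the strict lower bound on members per cluster (clusters need
    more than ``n_min`` localizations to survive).
    """

    r: float
    n_min: int = 10
    r_z: float | None = None
    edge_fraction: float = 0.20
    n_windows: int = 20
    window_max_fraction: float = 0.80

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValidationError("r must be > 0")
        if self.r_z is not None and self.r_z <= 0:
            raise ValidationError("r_z must be > 0")
        if self.n_min < 1:
            raise ValidationError("n_min must be >= 1")
        if not 0.0 <= self.edge_fraction < 0.5:
            raise ValidationError("edge_fraction must be in [0, 0.5)")
        if self.n_windows < 1:
            raise ValidationError("n_windows must be >= 1")
        if not 0.0 < self.window_max_fraction <= 1.0:
            raise ValidationError("window_max_fraction must be in (0, 1]")


@dataclass
class ClusterResult:
    """Cluster assignment plus per-cluster diagnostics.

    ``assignment`` maps each localization to a cluster id (-1 = unassigned,
    including members of dissolved clusters); ``clusters`` is a DataFrame
    indexed by cluster id with member count ``n``, centroid, ``mean_frame``,
    ``max_window_fraction`` and ``status``. Members of temporally rejected
    clusters keep their id; use ``kept_ids`` / ``kept_mask`` to restrict to
    surviving clusters.
    """

    assignment: np.ndarray
    clusters: pd.DataFrame

    @property
    def kept_ids(self) -> np.ndarray:
        return self.clusters.index[self.clusters["status"] == STATUS_KEPT].to_numpy()

    def kept_mask(self) -> np.ndarray:
        """Boolean mask over localizations belonging to kept clusters."""
        kept = set(self.kept_ids.tolist())
        return np.fromiter(
            (a in kept for a in self.assignment), dtype=bool, count=len(self.assignment)
        )

    @property
    def n_kept(self) -> int:
        return len(self.kept_ids)


def _scaled_coords(table: LocalizationTable, params: ClusterParams) -> np.ndarray:
    """Coordinates with z scaled by r/r_z so the ellipsoidal neighbourhood
    becomes a Euclidean ball of radius r."""
    coords = table.coords()
    if table.is_3d:
        if params.r_z is None:
            raise ValidationError("3D clustering requires r_z")
        coords = coords.copy()
        coords[:, 2] *= params.r / params.r_z
    return coords


def neighbor_counts(table: LocalizationTable, params: ClusterParams) -> np.ndarray:
    """Number of other localizations within distance r of each localization."""
    if len(table) == 0:
        raise ValidationError("cannot cluster an empty table")
    coords = _scaled_coords(table, params)
    tree = cKDTree(coords)
    # counts include self; subtract it
    counts = tree.query_ball_point(coords, params.r, return_length=True) - 1
    return counts.astype(np.int64)


def find_local_maxima(
    table: LocalizationTable,
    counts: np.ndarray,
    params: ClusterParams,
) -> np.ndarray:
    """Indices of localizations that dominate their r-neighbourhood.

    Index i is a maximum iff no j within r has ``counts[j] > counts[i]``, nor
    an equal count with ``j < i`` (lowest-index tie-break). Isolated points
    (count 0) are maxima by definition. Sorted ascending.
    """
    coords = _scaled_coords(table, params)
    tree = cKDTree(coords)
    maxima = []
    for i, nbrs in enumerate(tree.query_ball_point(coords, params.r)):
        ci = counts[i]
        is_max = True
        for j in nbrs:
            if j == i:
                continue
            if counts[j] > ci or (counts[j] == ci and j < i):
                is_max = False
                break
        if is_max:
            maxima.append(i)
    return np.asarray(maxima, dtype=np.int64)


def cluster(table: LocalizationTable, params: ClusterParams) -> ClusterResult:
    """Full clustering pipeline: assign, size-threshold, temporal filters."""
    counts = neighbor_counts(table, params)
    maxima = find_local_maxima(table, counts, params)
    coords = _scaled_coords(table, params)
    tree = cKDTree(coords)
    n = len(table)
    assignment = np.full(n, -1, dtype=np.int64)

    # higher neighbour count processed first; ties by index (deterministic)
    order = maxima[np.lexsort((maxima, -counts[maxima]))]
    next_id = 0
    for m in order:
        if assignment[m] != -1:
            continue
        members = [j for j in tree.query_ball_point(coords[m], params.r) if assignment[j] == -1]
        if len(members) > params.n_min:
            assignment[members] = next_id
            next_id += 1
        # else: leave unassigned; too small to be a cluster seed

    n_frames = table.meta.n_frames
    if n_frames is None or n_frames < 1:
        raise ValidationError("metadata n_frames required for temporal filters")
    frames = table.locs["frame"].to_numpy(float)
    window_len = n_frames / params.n_windows

    records = []
    coord_cols = ["x", "y", "z"] if table.is_3d else ["x", "y"]
    raw = table.locs[coord_cols].to_numpy(float)
    for cid in range(next_id):
        mask = assignment == cid
        k = int(mask.sum())
        centroid = raw[mask].mean(axis=0)
        mean_frame = float(frames[mask].mean())
        widx = np.minimum((frames[mask] / window_len).astype(int), params.n_windows - 1)
        occupancy = np.bincount(widx, minlength=params.n_windows)
        max_window_fraction = float(occupancy.max() / k)

        lo = params.edge_fraction * n_frames
        hi = (1.0 - params.edge_fraction) * n_frames
        if mean_frame <= lo or mean_frame >= hi:
            status = STATUS_MEAN_FRAME
        elif max_window_fraction > params.window_max_fraction:
            status = STATUS_WINDOW
        else:
            status = STATUS_KEPT
        rec = {"n": k, "mean_frame": mean_frame,
               "max_window_fraction": max_window_fraction, "status": status}
        for c, v in zip(coord_cols, centroid):
            rec[c] = v
        records.append(rec)

    columns = ["n", *coord_cols, "mean_frame", "max_window_fraction", "status"]
    clusters = pd.DataFrame(records, columns=columns)
    clusters.index.name = "cluster_id"
    return ClusterResult(assignment=assignment, clusters=clusters)


def suggest_n_min(pick_counts, bins: "int | str" = "auto") -> dict:
    """Suggest an n_min threshold from a histogram of per-pick counts.

    When the histogram is bimodal (background mode vs single-target mode),
    returns the antimode between the two largest modes as the suggested
    threshold. Returns a dict with keys ``bimodal``, ``threshold``,
    ``hist``, ``edges`` and ``flag``.
    """
    pick_counts = np.asarray(list(pick_counts), dtype=float)
    if pick_counts.size == 0:
        raise ValidationError("pick_counts must be non-empty")
    if pick_counts.size < 10:
        return {"bimodal": False, "threshold": None, "hist": None, "edges": None,
                "flag": "insufficient data"}
    hist, edges = np.histogram(pick_counts, bins=bins)
    # light smoothing stabilizes mode detection on sparse histograms
    kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
    kernel /= kernel.sum()
    smooth = np.convolve(hist.astype(float), kernel, mode="same")
    from scipy.signal import find_peaks

    # prominence filter keeps only substantial modes, not histogram noise
    peaks, _ = find_peaks(smooth, prominence=0.1 * smooth.max())
    if smooth.argmax() not in peaks:  # plateau/edge-located main mode
        peaks = np.sort(np.append(peaks, smooth.argmax()))
    modes = peaks.tolist()
    if len(modes) < 2:
        return {"bimodal": False, "threshold": None, "hist": hist, "edges": edges,
                "flag": "unimodal"}
    top = sorted(sorted(modes, key=lambda i: -smooth[i])[:2])
    valley = top[0] + int(np.argmin(smooth[top[0]: top[1] + 1]))
    # a genuine antimode separates the modes; a shallow dip is binning noise
    if smooth[valley] > 0.5 * min(smooth[top[0]], smooth[top[1]]):
        return {"bimodal": False, "threshold": None, "hist": hist, "edges": edges,
                "flag": "unimodal"}
    threshold = float(0.5 * (edges[valley] + edges[valley + 1]))
    return {"bimodal": True, "threshold": threshold, "hist": hist, "edges": edges,
            "flag": None}
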