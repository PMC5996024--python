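"""Centriolar-patch geometry: density-based patch boundary, convex-hull area
and nearest-neighbour spacing.

All computations are performed in the apical xy plane: the centriolar patch is
an essentially planar structure at the apical surface, so z is ignored here by
design.  The patch of a cell is formalised as the largest density-connected
subset of its centriole positions (a DBSCAN-style rule standing in for a
manual boundary), its size as the area of the minimum convex polygon
containing the member positions, and its internal spacing as each centriole's
distance to its nearest neighbour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .detection import SpotSet

__all__ = [
    "PatchModel",
    "patch_boundary",
    "hull_area",
    "nearest_neighbour_distances",
    "build_patch",
]


@dataclass
class PatchModel:
    """Per-cell centriolar patch summary.

    ``member_indices`` index into the cell's SpotSet; ``hull_vertices`` are the
    xy hull polygon vertices (counter-clockwise, micrometres); ``nn_distances``
    has one entry per member when the count is >= 2 (empty otherwise).
    """

    cell_id: int
    member_indices: np.ndarray
    hull_vertices: np.ndarray
    area: float
    nn_distances: np.ndarray
    centriole_count: int
    excluded_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    low_confidence: bool = False


def patch_boundary(
    spots: SpotSet,
    density_radius: float = 1.5,
    min_density: int = 3,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Largest density-connected subset of a cell's spots (DBSCAN-style).

    A spot is *core* when it has at least ``min_density`` other spots within
    ``density_radius`` (xy, micrometres).  Clusters are the connected
    components of core spots under the radius graph, plus any non-core spot
    within the radius of a cluster core (density-reachable).  The returned
    cluster is chosen by (size, summed score) descending, with a final
    lexicographic tie-break on the cluster centroid, so the result is
    deterministic.

    Returns ``(member_indices, excluded_indices, low_confidence)``; when no
    spot is core, the patch degenerates to the single highest-scoring spot and
    is flagged ``low_confidence``.
    """
    n = len(spots)
    if n == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int), True
    xy = spots.xy
    tree = cKDTree(xy)
    neighbours = [np.asarray(nb, dtype=int) for nb in tree.query_ball_point(xy, density_radius)]
    core = np.array([len(nb) - 1 >= min_density for nb in neighbours])

    if not core.any():
        best = int(np.lexsort((xy[:, 1], xy[:, 0], -spots.scores))[0])
        members = np.array([best], dtype=int)
        excluded = np.setdiff1d(np.arange(n), members)
        return members, excluded, True

    # Connected components over core spots, then attach reachable border spots.
    labels = np.full(n, -1, dtype=int)
    current = 0
    for seed in np.nonzero(core)[0]:
        if labels[seed] != -1:
            continue
        stack = [seed]
        labels[seed] = current
        while stack:
            i = stack.pop()
            for j in neighbours[i]:
                if labels[j] == -1:
                    labels[j] = current
                    if core[j]:
                        stack.append(j)
        current += 1

    clusters = [np.nonzero(labels == c)[0] for c in range(current)]

    def sort_key(members: np.ndarray):
        centroid = xy[members].mean(axis=0)
        return (-len(members), -float(spots.scores[members].sum()), centroid[0], centroid[1])

    clusters.sort(key=sort_key)
    members = clusters[0]
    excluded = np.setdiff1d(np.arange(n), members)
    return members, excluded, False


def hull_area(points_xy: np.ndarray) -> float:
    """Area (um^2) of the xy convex hull; 0 for fewer than 3 or collinear points."""
    pts = np.asarray(points_xy, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        return 0.0
    try:
        hull = ConvexHull(pts)
    except QhullError:  # collinear / degenerate input
        return 0.0
    return float(hull.volume)  # in 2D, .volume is the area


def hull_vertices(points_xy: np.ndarray) -> np.ndarray:
    """Counter-clockwise hull vertices; the input points themselves if < 3 or degenerate."""
    pts = np.asarray(points_xy, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        return pts.copy()
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return pts.copy()
    return pts[hull.vertices]


def nearest_neighbour_distances(points_xy: np.ndarray) -> np.ndarray:
    """For each point, the xy distance (um) to its closest other point, in input order.

    Duplicate positions yield distance 0 with a warning (they usually indicate
    a detection artefact upstream).
    """
    pts = np.asarray(points_xy, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("nearest-neighbour distances need at least 2 points")
    dists, _ = cKDTree(pts).query(pts, k=2)
    nn = dists[:, 1]
    if np.any(nn == 0):
        warnings.warn("duplicate positions found: nearest-neighbour distance 0", stacklevel=2)
    return nn


def build_patch(
    spots: SpotSet,
    cell_id: int,
    density_radius: float = 1.5,
    min_density: int = 3,
) -> PatchModel:
    """Assemble the full PatchModel for one cell's SpotSet."""
    members, excluded, low_conf = patch_boundary(spots, density_radius, min_density)
    xy = spots.xy[members]
    nn = nearest_neighbour_distances(xy) if len(xy) >= 2 else np.empty(0)
    return PatchModel(
        cell_id=cell_id,
        member_indices=members,
        hull_vertices=hull_vertices(xy),
        area=hull_area(xy),
        nn_distances=nn,
        centriole_count=len(members),
        excluded_indices=excluded,
        low_confidence=low_conf,
    )
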