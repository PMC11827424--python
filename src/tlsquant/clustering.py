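"""Density-based detection of lymphoid aggregates from cell centroids.

Aggregates are found by DBSCAN-style density clustering over the positions
of the four lymphocyte subsets jointly (TLS cross-sections can present as
T-cell-only planes, so detection is not restricted to B cells).  A core
cell has at least ``min_neighbours`` lymphocytes — counting itself —
within ``neighbour_radius_um``; clusters are maximal density-connected
sets and everything else is noise.

Aggregates that sit close together and are connected by thin strands of
lymphocytes are biologically one structure sectioned through several
lobes, so a second pass merges clusters linked by such strands: a strand
is a connected chain of at least ``strand_min_path_cells`` unclustered
lymphocytes with consecutive gaps at most ``strand_link_radius_um``,
touching both clusters within that same radius.  Merging is transitive
and never adds the strand cells themselves to the merged membership.

Each cluster is polygonized with an alpha shape (concave hull) of its
member positions so that non-convex and multi-lobular outlines get a
faithful area; the polygon always covers every member cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError, cKDTree
from shapely.geometry import MultiPoint
from shapely.ops import unary_union
from sklearn.cluster import DBSCAN


@dataclass(frozen=True)
class ClusteringParams:
    """Detection and merging parameters (all distances in µm).

    Defaults reflect lymphocyte packing in dense aggregates (~10 µm
    nearest-neighbour spacing): a 30 µm neighbourhood holding ≥10 cells
    marks aggregate-level density, strands are followed at up to 40 µm
    gaps, and the 50 µm alpha radius closes the hull over that packing.
    """

    neighbour_radius_um: float = 30.0
    min_neighbours: int = 10
    strand_link_radius_um: float = 40.0
    strand_min_path_cells: int = 5
    hull_alpha_um: float = 50.0

    def __post_init__(self) -> None:
        for name in (
            "neighbour_radius_um",
            "min_neighbours",
            "strand_link_radius_um",
            "strand_min_path_cells",
            "hull_alpha_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.strand_link_radius_um < self.neighbour_radius_um:
            raise ValueError("strand_link_radius_um must be >= neighbour_radius_um")


@dataclass
class AggregateCluster:
    """A detected lymphoid aggregate.

    ``member_cell_ids`` holds the lymphocytes assigned to the cluster (a
    sorted tuple); ``boundary`` is the alpha-shape geometry (Polygon, or
    MultiPolygon for merged multi-lobe aggregates) covering all members.
    """

    member_cell_ids: tuple[str, ...]
    boundary: shapely.Geometry
    centroid: tuple[float, float]
    degenerate: bool = False
    merged_from: int = 1

    @property
    def n_cells(self) -> int:
        return len(self.member_cell_ids)

    @property
    def area_um2(self) -> float:
        return 0.0 if self.degenerate else float(self.boundary.area)


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    cross = (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (b[:, 1] - a[:, 1]) * (
        c[:, 0] - a[:, 0]
    )
    area2 = np.abs(cross)  # twice the triangle area
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


def alpha_shape(points: np.ndarray, alpha_um: float):
    """Concave hull of a 2-D point set via the alpha complex.

    Unions the Delaunay triangles whose circumradius is at most
    ``alpha_um``; any member point left uncovered (possible for stragglers
    at very small alpha) is patched in with a 1 µm disc so that the result
    always covers the full point set.

    Returns ``(geometry, degenerate)``; fewer than 3 points or a collinear
    set is degenerate (empty geometry, zero area).
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        return shapely.Polygon(), True
    try:
        tri = Delaunay(points)
    except QhullError:
        return shapely.Polygon(), True  # collinear
    radii = _circumradii(points, tri.simplices)
    keep = tri.simplices[radii <= alpha_um]
    parts = [shapely.polygons(points[s]) for s in keep]
    geom = unary_union(parts) if parts else shapely.Polygon()
    covered = shapely.intersects_xy(geom, points[:, 0], points[:, 1])
    if not covered.all():
        extras = MultiPoint(points[~covered]).buffer(1.0)
        geom = unary_union([geom, extras])
    if geom.is_empty or geom.area == 0:
        return geom, True
    return geom, False


def polygonize(points: np.ndarray, hull_alpha_um: float) -> tuple[shapely.Geometry, float]:
    """Alpha-shape polygon and its area (µm²) for a set of member positions."""
    geom, degenerate = alpha_shape(points, hull_alpha_um)
    return geom, (0.0 if degenerate else float(geom.area))


def _make_cluster(ids: np.ndarray, xy: np.ndarray, alpha_um: float, merged_from: int = 1) -> AggregateCluster:
    order = np.argsort(ids)
    ids = ids[order]
    xy = xy[order]
    geom, degenerate = alpha_shape(xy, alpha_um)
    centroid = (float(xy[:, 0].mean()), float(xy[:, 1].mean()))
    return AggregateCluster(
        member_cell_ids=tuple(ids.tolist()),
        boundary=geom,
        centroid=centroid,
        degenerate=degenerate,
        merged_from=merged_from,
    )


def detect_aggregates(
    lymphocytes: pd.DataFrame, params: ClusteringParams | None = None
) -> list[AggregateCluster]:
    """Density-cluster lymphocyte positions into candidate aggregates.

    ``lymphocytes`` needs columns ``cell_id, x, y`` (lymphocyte cells
    only).  Cells are processed in ascending ``cell_id`` order so border
    cells attach to the first core cluster reached in that order,
    making the result independent of input row order.  Returns clusters
    sorted by their smallest member id; noise cells belong to none.
    """
    params = params or ClusteringParams()
    if len(lymphocytes) == 0:
        return []
    df = lymphocytes.sort_values("cell_id", kind="mergesort").reset_index(drop=True)
    xy = df[["x", "y"]].to_numpy(dtype=float)
    ids = df["cell_id"].to_numpy(dtype=object)
    labels = DBSCAN(
        eps=params.neighbour_radius_um, min_samples=params.min_neighbours
    ).fit_predict(xy)
    clusters: list[AggregateCluster] = []
    for lab in sorted(set(labels) - {-1}):
        mask = labels == lab
        clusters.append(_make_cluster(ids[mask], xy[mask], params.hull_alpha_um))
    clusters.sort(key=lambda c: c.member_cell_ids[0])
    return clusters


def merge_connected(
    clusters: list[AggregateCluster],
    lymphocytes: pd.DataFrame,
    params: ClusteringParams | None = None,
) -> list[AggregateCluster]:
    """Merge clusters joined by strands of unclustered lymphocytes.

    Builds connected components of the unclustered (noise) lymphocytes in
    the ``strand_link_radius_um`` neighbourhood graph; a noise component of
    at least ``strand_min_path_cells`` cells that touches two or more
    clusters (some cell within the link radius of a member of each) fuses
    them.  Merging is transitive; memberships are unions of the original
    member sets, so the total clustered-cell count is conserved.
    """
    params = params or ClusteringParams()
    if len(clusters) <= 1:
        return list(clusters)

    df = lymphocytes.sort_values("cell_id", kind="mergesort").reset_index(drop=True)
    xy = df[["x", "y"]].to_numpy(dtype=float)
    ids = df["cell_id"].to_numpy(dtype=object)
    id_to_row = {cid: i for i, cid in enumerate(ids)}

    cluster_of = np.full(len(df), -1, dtype=int)
    for ci, cl in enumerate(clusters):
        for cid in cl.member_cell_ids:
            cluster_of[id_to_row[cid]] = ci

    noise_rows = np.flatnonzero(cluster_of == -1)
    parent = list(range(len(clusters)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    if len(noise_rows) >= params.strand_min_path_cells:
        tree = cKDTree(xy)
        pairs = tree.query_pairs(params.strand_link_radius_um, output_type="ndarray")
        is_noise = cluster_of == -1
        # components over noise-noise edges
        nn = pairs[is_noise[pairs[:, 0]] & is_noise[pairs[:, 1]]]
        noise_index = np.full(len(df), -1, dtype=int)
        noise_index[noise_rows] = np.arange(len(noise_rows))
        if len(nn):
            adj = coo_matrix(
                (np.ones(len(nn)), (noise_index[nn[:, 0]], noise_index[nn[:, 1]])),
                shape=(len(noise_rows), len(noise_rows)),
            )
            _, comp = connected_components(adj, directed=False)
        else:
            comp = np.arange(len(noise_rows))
        comp_sizes = np.bincount(comp)
        # clusters adjacent to each noise component (via noise-cluster edges)
        mixed = pairs[is_noise[pairs[:, 0]] != is_noise[pairs[:, 1]]]
        touches: dict[int, set[int]] = {}
        for a, b in mixed:
            n, c = (a, b) if is_noise[a] else (b, a)
            touches.setdefault(int(comp[noise_index[n]]), set()).add(int(cluster_of[c]))
        for comp_id, cluster_set in touches.items():
            if comp_sizes[comp_id] >= params.strand_min_path_cells and len(cluster_set) >= 2:
                first, *rest = sorted(cluster_set)
                for other in rest:
                    union(first, other)

    groups: dict[int, list[int]] = {}
    for ci in range(len(clusters)):
        groups.setdefault(find(ci), []).append(ci)

    merged: list[AggregateCluster] = []
    for root in sorted(groups):
        members = groups[root]
        if len(members) == 1:
            merged.append(clusters[members[0]])
            continue
        all_ids = np.concatenate(
            [np.asarray(clusters[ci].member_cell_ids, dtype=object) for ci in members]
        )
        rows = np.array([id_to_row[cid] for cid in all_ids])
        merged.append(
            _make_cluster(all_ids, xy[rows], params.hull_alpha_um, merged_from=len(members))
        )
    merged.sort(key=lambda c: c.member_cell_ids[0])
    return merged


def cluster_table(clusters: list[AggregateCluster]) -> pd.DataFrame:
    """Tabulate clusters: id, size, area, centroid."""
    rows = [
        {
            "cluster_id": f"a{idx + 1:04d}",
            "n_cells": cl.n_cells,
            "area_um2": cl.area_um2,
            "centroid_x": cl.centroid[0],
            "centroid_y": cl.centroid[1],
            "merged_from": cl.merged_from,
        }
        for idx, cl in enumerate(clusters)
    ]
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "n_cells", "area_um2", "centroid_x", "centroid_y", "merged_from"],
    )
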