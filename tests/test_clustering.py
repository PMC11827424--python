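"""Aggregate detection, strand merging and polygonization vs brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from _oracles import density_cluster_oracle, disc_union_area, strand_merge_oracle
from tlsquant.clustering import (
    ClusteringParams,
    alpha_shape,
    detect_aggregates,
    merge_connected,
    polygonize,
)

PARAMS = ClusteringParams()


def frame(xy: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"cell_id": [f"c{i:05d}" for i in range(len(xy))], "x": xy[:, 0], "y": xy[:, 1]}
    )


def disc_points(rng, centre, radius, n):
    r = radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0, 2 * math.pi, n)
    return np.column_stack([centre[0] + r * np.cos(theta), centre[1] + r * np.sin(theta)])


def memberships_by_index(clusters, df):
    pos = {cid: i for i, cid in enumerate(df["cell_id"])}
    return [frozenset(pos[c] for c in cl.member_cell_ids) for cl in clusters]


def test_single_dense_disc_with_far_background_is_one_cluster():
    rng = np.random.default_rng(1)
    core = disc_points(rng, (0, 0), 150, 500)
    # 50 background cells, mutually and jointly isolated (>3x neighbour radius)
    bg = np.column_stack(
        [2000 + 150 * np.arange(50, dtype=float), np.full(50, -3000.0)]
    )
    df = frame(np.vstack([core, bg]))
    clusters = detect_aggregates(df, PARAMS)
    assert len(clusters) == 1
    assert clusters[0].n_cells == 500


def test_two_well_separated_discs_are_two_clusters():
    rng = np.random.default_rng(2)
    a = disc_points(rng, (0, 0), 110, 300)
    b = disc_points(rng, (10 * PARAMS.neighbour_radius_um * 10, 0), 110, 300)
    clusters = detect_aggregates(frame(np.vstack([a, b])), PARAMS)
    assert sorted(c.n_cells for c in clusters) == [300, 300]


def test_two_isolated_cells_are_noise():
    df = frame(np.array([[0.0, 0.0], [1000.0, 1000.0]]))
    assert detect_aggregates(df, PARAMS) == []


def test_memberships_match_epsilon_graph_oracle_on_random_instances():
    rng = np.random.default_rng(1234)
    params = ClusteringParams(
        neighbour_radius_um=30, min_neighbours=6, strand_link_radius_um=40,
        strand_min_path_cells=4, hull_alpha_um=50,
    )
    for trial in range(30):
        n_blobs = int(rng.integers(0, 4))
        pts = [rng.uniform(0, 800, size=(int(rng.integers(10, 80)), 2))]
        for _ in range(n_blobs):
            centre = rng.uniform(100, 700, 2)
            pts.append(centre + rng.normal(0, 18, size=(int(rng.integers(30, 90)), 2)))
        xy = np.vstack(pts)[:500]
        df = frame(xy)
        clusters = detect_aggregates(df, params)
        got = memberships_by_index(clusters, df)

        comp_of, border, noise = density_cluster_oracle(
            xy, params.neighbour_radius_um, params.min_neighbours
        )
        clustered = set().union(*got) if got else set()
        # noise agrees exactly
        assert clustered == set(range(len(xy))) - noise
        # core partition agrees: cores of one oracle component share a cluster
        comp_to_cluster = {}
        for idx, comp in comp_of.items():
            cluster_id = next(k for k, mem in enumerate(got) if idx in mem)
            assert comp_to_cluster.setdefault(comp, cluster_id) == cluster_id
        assert len(set(comp_to_cluster.values())) == len(got) or not got
        # border cells sit in a cluster adjacent to them
        for idx, adjacent in border.items():
            cluster_id = next(k for k, mem in enumerate(got) if idx in mem)
            assert comp_to_cluster_inv(comp_to_cluster, cluster_id) & adjacent


def comp_to_cluster_inv(comp_to_cluster, cluster_id):
    return {comp for comp, cl in comp_to_cluster.items() if cl == cluster_id}


def bridge_instance(rng, gap, spacing=15.0):
    a = disc_points(rng, (0, 0), 120, 450)
    bx = 120 + gap + 120
    b = disc_points(rng, (bx, 0), 120, 450)
    ts = np.arange(120 + spacing / 2, 120 + gap, spacing)
    bridge = np.column_stack([ts, np.zeros(len(ts))])
    return a, b, bridge


def test_strand_bridge_merges_two_discs_and_conserves_membership():
    rng = np.random.default_rng(3)
    a, b, bridge = bridge_instance(rng, gap=200.0)
    df = frame(np.vstack([a, b, bridge]))
    clusters = detect_aggregates(df, PARAMS)
    assert len(clusters) == 2
    merged = merge_connected(clusters, df, PARAMS)
    assert len(merged) == 1
    # strand cells are not absorbed into membership; counts conserved
    assert merged[0].n_cells == sum(c.n_cells for c in clusters)

    # without the bridge the clusters stay apart
    df2 = frame(np.vstack([a, b]))
    clusters2 = detect_aggregates(df2, PARAMS)
    assert len(merge_connected(clusters2, df2, PARAMS)) == 2


def test_merge_is_transitive_across_chained_discs():
    rng = np.random.default_rng(4)
    a, b, bridge_ab = bridge_instance(rng, gap=200.0)
    c = disc_points(rng, (120 + 200 + 120 + 120 + 200 + 120, 0), 120, 450)
    ts = np.arange(120 + 200 + 120 + 120 + 15 / 2, 120 + 200 + 120 + 120 + 200, 15.0)
    bridge_bc = np.column_stack([ts, np.zeros(len(ts))])
    df = frame(np.vstack([a, b, c, bridge_ab, bridge_bc]))
    clusters = detect_aggregates(df, PARAMS)
    assert len(clusters) == 3
    merged = merge_connected(clusters, df, PARAMS)
    assert len(merged) == 1  # A-B and B-C chains fuse all three


def test_merge_decisions_match_bridge_connectivity_oracle():
    rng = np.random.default_rng(99)
    params = ClusteringParams(
        neighbour_radius_um=30, min_neighbours=8, strand_link_radius_um=40,
        strand_min_path_cells=5, hull_alpha_um=50,
    )
    for trial in range(10):
        blobs = []
        centres = [(0, 0), (700, 0), (0, 700), (700, 700)]
        for centre in centres[: int(rng.integers(2, 5))]:
            blobs.append(disc_points(rng, centre, 100, 300))
        strands = []
        if rng.random() < 0.7:  # bridge first two blobs
            ts = np.arange(100 + 7.5, 600 - 100, 15.0)
            strands.append(np.column_stack([ts, rng.normal(0, 2, len(ts))]))
        xy = np.vstack(blobs + strands)
        df = frame(xy)
        clusters = detect_aggregates(df, params)
        merged = merge_connected(clusters, df, params)
        got = sorted(memberships_by_index(merged, df), key=min)

        base = [set(m) for m in memberships_by_index(clusters, df)]
        want = strand_merge_oracle(
            base, xy, params.strand_link_radius_um, params.strand_min_path_cells
        )
        assert [set(m) for m in got] == [set(w) for w in want]


def test_detection_is_invariant_to_input_order():
    rng = np.random.default_rng(8)
    a = disc_points(rng, (0, 0), 120, 400)
    b = disc_points(rng, (500, 0), 120, 400)
    df = frame(np.vstack([a, b]))
    shuffled = df.sample(frac=1.0, random_state=5).reset_index(drop=True)
    m1 = {c.member_cell_ids for c in detect_aggregates(df, PARAMS)}
    m2 = {c.member_cell_ids for c in detect_aggregates(shuffled, PARAMS)}
    assert m1 == m2


def test_square_corners_with_large_alpha_give_convex_hull_area():
    pts = np.array([[0, 0], [100, 0], [100, 100], [0, 100]], dtype=float)
    geom, area = polygonize(pts, hull_alpha_um=1000.0)
    assert area == pytest.approx(10_000.0)
    import shapely

    assert shapely.intersects_xy(geom, pts[:, 0], pts[:, 1]).all()


def test_disc_alpha_area_close_to_true_disc_area():
    rng = np.random.default_rng(21)
    pts = disc_points(rng, (0, 0), 100, 2000)
    _, area = polygonize(pts, hull_alpha_um=50.0)
    true = math.pi * 100**2
    assert abs(area - true) / true < 0.10
    # Monte-Carlo union of 10 µm discs around the cells covers a disc
    # dilated by the disc radius; check it against that closed form
    mc = disc_union_area(pts, 10.0, 200_000, np.random.default_rng(0))
    dilated = math.pi * 110**2
    assert abs(mc - dilated) / dilated < 0.10


def test_c_shape_concave_hull_is_smaller_than_convex_hull():
    rng = np.random.default_rng(5)
    theta = rng.uniform(0.25 * math.pi, 1.75 * math.pi, 1500)
    r = rng.uniform(80, 100, 1500)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    geom, area = polygonize(pts, hull_alpha_um=30.0)
    from shapely.geometry import MultiPoint

    convex = MultiPoint(pts).convex_hull.area
    assert area < convex


def test_degenerate_point_sets_flagged_with_zero_area():
    geom, degenerate = alpha_shape(np.array([[0.0, 0.0], [1.0, 1.0]]), 50.0)
    assert degenerate
    collinear = np.column_stack([np.arange(10.0), np.arange(10.0)])
    geom, degenerate = alpha_shape(collinear, 50.0)
    assert degenerate and geom.area == 0.0


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        ClusteringParams(neighbour_radius_um=-1)
    with pytest.raises(ValueError):
        ClusteringParams(strand_link_radius_um=10.0, neighbour_radius_um=30.0)
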