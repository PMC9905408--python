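"""Scar geometry: neighbor graph, center/radius, layers, interfaces, fractions."""

import numpy as np
import pandas as pd
import pytest
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist, squareform

from scarst import geometry, synthetic
from scarst.errors import EmptyRegionError


def labels_series(lattice, values):
    return pd.Series(values, index=pd.Index(lattice.spot_ids, name="barcode"), name="label")


def brute_force_interface(lattice, labels, a, b, width):
    """Independent oracle: Euclidean adjacency + dense shortest-path matrix."""
    D = squareform(pdist(lattice.coords()))
    adj = np.abs(D - lattice.pitch_um) <= 1e-6
    steps = shortest_path(adj.astype(float), unweighted=True)
    lab = labels.to_numpy()
    ia, ib = np.flatnonzero(lab == a), np.flatnonzero(lab == b)
    spots_a = {lattice.spot_ids[i] for i in ia if steps[i, ib].min() <= width}
    spots_b = {lattice.spot_ids[j] for j in ib if steps[j, ia].min() <= width}
    return spots_a, spots_b


class TestNeighborGraph:
    def test_single_spot_has_no_edges(self):
        g = geometry.neighbor_graph(synthetic.build_lattice(1, 1))
        assert g.number_of_edges() == 0

    def test_interior_degree_is_six(self):
        lat = synthetic.build_lattice(5, 5)
        g = geometry.neighbor_graph(lat)
        assert g.degree["s002x002"] == 6

    def test_edge_set_matches_distance_filter_oracle(self):
        lat = synthetic.build_lattice(10, 10)
        g = geometry.neighbor_graph(lat)
        D = squareform(pdist(lat.coords()))
        expected = {
            frozenset((lat.spot_ids[i], lat.spot_ids[j]))
            for i in range(lat.n_spots)
            for j in range(i + 1, lat.n_spots)
            if abs(D[i, j] - lat.pitch_um) <= 1e-6
        }
        assert {frozenset(e) for e in g.edges} == expected


class TestScarCenterAndRadius:
    def test_single_scar_spot(self, lattice_10x10):
        lab = labels_series(lattice_10x10, ["bg"] * lattice_10x10.n_spots)
        lab.iloc[37] = "scar"
        cx, cy = geometry.scar_center(lab, lattice_10x10, {"scar"})
        assert (cx, cy) == (lattice_10x10.x_um[37], lattice_10x10.y_um[37])
        r_um, r_spots = geometry.scar_radius_spots(lab, lattice_10x10, {"scar"})
        assert (r_um, r_spots) == (0.0, 0)

    def test_center_matches_mean_oracle(self, lattice_10x10, rng):
        values = rng.choice(["scar", "bg"], size=lattice_10x10.n_spots)
        lab = labels_series(lattice_10x10, values)
        cx, cy = geometry.scar_center(lab, lattice_10x10, {"scar"})
        mask = values == "scar"
        assert cx == pytest.approx(lattice_10x10.x_um[mask].mean())
        assert cy == pytest.approx(lattice_10x10.y_um[mask].mean())

    def test_one_point_two_mm_is_twelve_spots(self, lattice_30x30):
        """1.2 mm at the 100-µm pitch corresponds to 12 spots."""
        assert int(np.ceil(1200.0 / lattice_30x30.pitch_um)) == 12
        # place scar spots so the max centroid distance is exactly 1200 µm
        lat = synthetic.build_lattice(1, 25)
        lab = labels_series(lat, ["bg"] * 25)
        lab.iloc[0] = "scar"
        lab.iloc[24] = "scar"  # centroid at 1200, extremes at +/-1200
        r_um, r_spots = geometry.scar_radius_spots(lab, lat, {"scar"})
        assert r_um == pytest.approx(1200.0)
        assert r_spots == 12

    def test_radius_matches_max_distance_oracle(self, lattice_30x30):
        scene = synthetic.make_scene(lattice_30x30, 7, seed=1)
        scar = {"fibroblast", "microglia", "astrocyte"}
        r_um, _ = geometry.scar_radius_spots(scene.truth_labels, lattice_30x30, scar)
        cx, cy = geometry.scar_center(scene.truth_labels, lattice_30x30, scar)
        mask = scene.truth_labels.isin(scar).to_numpy()
        oracle = np.hypot(lattice_30x30.x_um[mask] - cx, lattice_30x30.y_um[mask] - cy).max()
        assert r_um == pytest.approx(oracle)

    def test_empty_scar_raises(self, lattice_10x10):
        lab = labels_series(lattice_10x10, ["bg"] * lattice_10x10.n_spots)
        with pytest.raises(EmptyRegionError):
            geometry.scar_center(lab, lattice_10x10, {"scar"})


class TestAssignLayers:
    def test_single_layer(self, lattice_10x10):
        layers = geometry.assign_layers(lattice_10x10, 1)
        assert set(layers) == {1}

    def test_four_layers_on_forty_rows(self):
        lat = synthetic.build_lattice(40, 4)
        layers = geometry.assign_layers(lat, 4, axis="row")
        by_row = pd.Series(layers.to_numpy(), index=lat.array_row)
        for row, expected in [(0, 1), (9, 1), (10, 2), (19, 2), (20, 3), (29, 3), (30, 4), (39, 4)]:
            assert (by_row.loc[row] == expected).all()

    def test_band_widths_within_one_row(self):
        lat = synthetic.build_lattice(27, 5)
        layers = geometry.assign_layers(lat, 4, axis="row")
        rows_per_layer = pd.DataFrame({"layer": layers.to_numpy(), "row": lat.array_row})
        widths = rows_per_layer.groupby("layer")["row"].nunique()
        assert widths.max() - widths.min() <= 1

    def test_layers_partition_all_spots(self, lattice_30x30):
        layers = geometry.assign_layers(lattice_30x30, 4)
        assert len(layers) == lattice_30x30.n_spots
        assert set(layers) == {1, 2, 3, 4}


class TestExtractInterface:
    def test_half_planes_give_two_boundary_rows_each(self):
        lat = synthetic.build_lattice(10, 10)
        lab = labels_series(lat, np.where(lat.array_row < 5, "A", "B"))
        g = geometry.neighbor_graph(lat)
        region = geometry.extract_interface(lab, g, "A", "B", width=2)
        rows_a = {int(r) for r, s in zip(lat.array_row, lat.spot_ids) if s in region.spots_a}
        rows_b = {int(r) for r, s in zip(lat.array_row, lat.spot_ids) if s in region.spots_b}
        assert rows_a == {3, 4}
        assert rows_b == {5, 6}

    def test_clusters_separated_beyond_width_are_empty(self):
        lat = synthetic.build_lattice(12, 4)
        bands = np.select(
            [lat.array_row < 3, lat.array_row < 9], ["A", "C"], default="B"
        )
        lab = labels_series(lat, bands)
        g = geometry.neighbor_graph(lat)
        region = geometry.extract_interface(lab, g, "A", "B", width=2)
        assert not region
        assert region.spots_a == frozenset() and region.spots_b == frozenset()

    def test_checkerboard_includes_every_spot(self):
        lat = synthetic.build_lattice(8, 8)
        lab = labels_series(lat, np.where((lat.array_row + lat.array_col) % 2 == 0, "A", "B"))
        g = geometry.neighbor_graph(lat)
        region = geometry.extract_interface(lab, g, "A", "B", width=2)
        assert len(region.all_spots) == lat.n_spots

    def test_unknown_cluster_rejected(self, lattice_10x10):
        lab = labels_series(lattice_10x10, ["A"] * lattice_10x10.n_spots)
        g = geometry.neighbor_graph(lattice_10x10)
        with pytest.raises(ValueError, match="unknown"):
            geometry.extract_interface(lab, g, "A", "Z")

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_shortest_path_oracle_random_labelings(self, seed):
        rng = np.random.default_rng(seed)
        lat = synthetic.build_lattice(rng.integers(4, 13), rng.integers(4, 13))
        lab = labels_series(lat, rng.choice(["A", "B", "C"], size=lat.n_spots))
        if not {"A", "B"} <= set(lab):
            pytest.skip("degenerate labeling")
        g = geometry.neighbor_graph(lat)
        region = geometry.extract_interface(lab, g, "A", "B", width=2)
        spots_a, spots_b = brute_force_interface(lat, lab, "A", "B", 2)
        assert set(region.spots_a) == spots_a
        assert set(region.spots_b) == spots_b

    def test_monotone_in_width(self, lattice_10x10, rng):
        lab = labels_series(lattice_10x10, rng.choice(["A", "B"], size=100))
        g = geometry.neighbor_graph(lattice_10x10)
        prev = geometry.extract_interface(lab, g, "A", "B", width=1)
        for w in (2, 3, 4):
            cur = geometry.extract_interface(lab, g, "A", "B", width=w)
            assert prev.spots_a <= cur.spots_a and prev.spots_b <= cur.spots_b
            prev = cur


class TestDomainAdjacency:
    def test_half_plane_split_single_pair(self):
        lat = synthetic.build_lattice(6, 6)
        lab = labels_series(lat, np.where(lat.array_row < 3, "A", "B"))
        g = geometry.neighbor_graph(lat)
        assert geometry.domain_adjacency(lab, g) == {("A", "B")}

    def test_single_label_empty(self, lattice_10x10):
        lab = labels_series(lattice_10x10, ["A"] * 100)
        g = geometry.neighbor_graph(lattice_10x10)
        assert geometry.domain_adjacency(lab, g) == set()

    def test_matches_edge_scan_oracle(self, lattice_10x10, rng):
        lab = labels_series(lattice_10x10, rng.choice(list("WXYZ"), size=100))
        g = geometry.neighbor_graph(lattice_10x10)
        expected = set()
        for u, v in g.edges:
            if lab[u] != lab[v]:
                expected.add(tuple(sorted((lab[u], lab[v]))))
        assert geometry.domain_adjacency(lab, g) == expected


class TestCelltypeFractions:
    def test_counting(self):
        lab = pd.Series(["fibroblast"] * 4 + ["microglia"] * 6,
                        index=[f"b{i}" for i in range(10)])
        table = geometry.celltype_fractions({7: lab})
        fib = table[table.cell_type == "fibroblast"].iloc[0]
        assert fib.n_spots == 4 and fib.fraction == pytest.approx(0.4)

    def test_single_type_fraction_one(self):
        lab = pd.Series(["astrocyte"] * 5, index=[f"b{i}" for i in range(5)])
        table = geometry.celltype_fractions({3: lab})
        assert table.fraction.tolist() == [1.0]

    def test_generated_time_course_sums_and_tallies(self, lattice_30x30):
        labels_by_time = {
            dpi: synthetic.make_scene(lattice_30x30, dpi, seed=3).truth_labels
            for dpi in synthetic.TIME_POINTS_DPI
        }
        table = geometry.celltype_fractions(labels_by_time)
        for dpi, grp in table.groupby("time_dpi"):
            assert grp.fraction.sum() == pytest.approx(1.0, abs=1e-9)
            tallies = labels_by_time[dpi].value_counts()
            for _, row in grp.iterrows():
                assert row.n_spots == tallies[row.cell_type]

    def test_empty_time_point_raises(self):
        with pytest.raises(EmptyRegionError):
            geometry.celltype_fractions({7: pd.Series([], dtype=object)})
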