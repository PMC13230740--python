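"""Expression matrices and cosine-distance typing with gating rules."""

import numpy as np
import pandas as pd
import pytest

from fishflow import celltyping, simkit

LUNG_PANEL = {
    "Chil3": {"AM": 24.0, "AT1": 1.2, "AT2": 1.2, "Endothelial": 0.5, "Fibroblast": 1.2},
    "Rtkn2": {"AM": 1.2, "AT1": 24.0, "AT2": 1.2, "Endothelial": 0.5, "Fibroblast": 1.2},
    "Lamp3": {"AM": 1.2, "AT1": 1.2, "AT2": 24.0, "Endothelial": 0.5, "Fibroblast": 1.2},
    "Pecam1": {"AM": 1.2, "AT1": 1.2, "AT2": 1.2, "Endothelial": 14.0, "Fibroblast": 1.2},
    "Ptprb": {"AM": 1.2, "AT1": 1.2, "AT2": 1.2, "Endothelial": 14.0, "Fibroblast": 1.2},
    "Pdgfra": {"AM": 1.2, "AT1": 1.2, "AT2": 1.2, "Endothelial": 0.5, "Fibroblast": 24.0},
}


def lung_centroids():
    types = ["AM", "AT1", "AT2", "Endothelial", "Fibroblast"]
    return pd.DataFrame({g: {t: LUNG_PANEL[g][t] for t in types} for g in LUNG_PANEL})


class TestCosineDistance:
    def test_parallel_vectors_zero_at_any_scale(self):
        assert celltyping.cosine_distance([2, 4, 6], [1, 2, 3]) == pytest.approx(0, abs=1e-12)

    def test_orthogonal_vectors_one(self):
        assert celltyping.cosine_distance([1, 0], [0, 1]) == 1.0

    def test_closed_form_45_degrees(self):
        d = celltyping.cosine_distance([1, 1], [1, 0])
        assert d == pytest.approx(1 - 1 / np.sqrt(2), abs=1e-12)

    def test_zero_expression_vector_at_distance_one(self):
        assert celltyping.cosine_distance([0, 0], [1, 1]) == 1.0

    def test_zero_centroid_rejected(self):
        with pytest.raises(ValueError):
            celltyping.cosine_distance([1, 1], [0, 0])

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            celltyping.cosine_distance([np.nan, 1], [1, 1])


class TestAssignSpots:
    def _mask(self):
        mask = np.zeros((60, 60), int)
        mask[10:20, 10:20] = 3
        mask[41:51, 41:51] = 7  # (30, 30) is equidistant to both corners
        return mask

    def test_spot_inside_nucleus_counted_for_it(self):
        spots = pd.DataFrame({"gene": ["A"], "y": [15.0], "x": [15.0]})
        matrix, out = celltyping.assign_spots_to_cells(spots, self._mask())
        assert out["cell_id"].iloc[0] == 3
        assert matrix.loc[3, "A"] == 1

    def test_equidistant_spot_goes_to_lower_label(self):
        # (30, 30) is symmetric between nuclei 3 and 7
        spots = pd.DataFrame({"gene": ["A"], "y": [30.0], "x": [30.0]})
        _, out = celltyping.assign_spots_to_cells(
            spots, self._mask(), max_dist_um=5.0, pixel_size_nm=100.0
        )
        assert out["cell_id"].iloc[0] == 3

    def test_far_spot_unassigned(self):
        spots = pd.DataFrame({"gene": ["A"], "y": [0.0], "x": [59.0]})
        _, out = celltyping.assign_spots_to_cells(
            spots, self._mask(), max_dist_um=1.0, pixel_size_nm=100.0
        )
        assert out["cell_id"].iloc[0] == 0

    def test_matrix_conserves_assigned_spots(self, rng):
        spots = pd.DataFrame(
            {
                "gene": rng.choice(["A", "B"], 200),
                "y": rng.uniform(0, 60, 200),
                "x": rng.uniform(0, 60, 200),
            }
        )
        matrix, out = celltyping.assign_spots_to_cells(spots, self._mask())
        assert matrix.to_numpy().sum() == (out["cell_id"] > 0).sum()

    def test_spots_recover_true_cell_when_nuclei_far_apart(self, rng):
        """With nuclei >= 3 x max_dist apart, the reachable nucleus is
        unique, so >= 95% of spots land on their true cell."""
        centers = [(100, 100), (100, 400), (400, 100), (400, 400)]
        cells = pd.DataFrame(
            {
                "cell_id": [1, 2, 3, 4],
                "cell_type": ["t"] * 4,
                "nucleus_y": [c[0] for c in centers],
                "nucleus_x": [c[1] for c in centers],
                "nucleus_radius_px": [12.0] * 4,
                "focus_z": [4] * 4,
            }
        )
        mask = simkit.nucleus_label_mask(cells, (512, 512))
        rows = []
        for cid, (cy, cx) in enumerate(centers, start=1):
            for _ in range(50):
                dy, dx = rng.uniform(-40, 40, 2)
                rows.append({"gene": "A", "cell_id": cid, "y": cy + dy, "x": cx + dx})
        spots = pd.DataFrame(rows)
        _, out = celltyping.assign_spots_to_cells(
            spots, mask, max_dist_um=5.0, pixel_size_nm=100.0
        )
        assigned = out[out["cell_id"] > 0]
        assert len(assigned) > 0
        frac = (assigned["cell_id"] == spots.loc[assigned.index, "cell_id"]).mean()
        assert frac >= 0.95

    def test_no_labels_warns_all_unassigned(self):
        spots = pd.DataFrame({"gene": ["A"], "y": [5.0], "x": [5.0]})
        with pytest.warns(UserWarning):
            matrix, out = celltyping.assign_spots_to_cells(spots, np.zeros((10, 10), int))
        assert (out["cell_id"] == 0).all() and matrix.empty


class TestCallCellTypes:
    def _matrix(self, rows):
        return pd.DataFrame(rows, columns=["A", "B"]).rename_axis("cell_id")

    def test_distance_gate_strictly_below_cutoff(self):
        centroids = pd.DataFrame([[1.0, 0.0]], index=["t1"], columns=["A", "B"])
        # (1, 1.96): cosine distance to (1,0) ~ 0.545; (0, 1) exactly 1
        m = self._matrix([[20, 0], [0, 20]])
        out = celltyping.call_cell_types(m, centroids, d_max=0.8, min_rna=10)
        assert out.iloc[0]["cell_type"] == "t1"
        assert out.iloc[1]["cell_type"] == celltyping.UNCLASSIFIED
        assert out.iloc[1]["reason"] == "distance_gate"

    def test_distance_just_above_gate_unclassified(self):
        centroids = pd.DataFrame([[1.0, 0.0]], index=["t1"], columns=["A", "B"])
        # choose counts with cosine distance ~0.85 > 0.8
        x = np.array([1.0, 6.5])
        d = celltyping.cosine_distance(x, [1.0, 0.0])
        assert d > 0.8
        out = celltyping.call_cell_types(self._matrix([x * 20]), centroids)
        assert out.iloc[0]["cell_type"] == celltyping.UNCLASSIFIED

    def test_count_gate_strictly_more_than_10(self):
        centroids = pd.DataFrame([[1.0, 0.0]], index=["t1"], columns=["A", "B"])
        out = celltyping.call_cell_types(self._matrix([[10, 0], [11, 0]]), centroids)
        assert out.iloc[0]["cell_type"] == celltyping.UNCLASSIFIED
        assert out.iloc[0]["reason"] == "count_gate"
        assert out.iloc[1]["cell_type"] == "t1"

    def test_gates_hold_for_every_assignment(self, rng):
        """Programmatic audit: every assigned cell satisfies both gates."""
        centroids = lung_centroids()
        counts = rng.poisson(5.0, size=(200, 6))
        m = pd.DataFrame(counts, columns=centroids.columns).rename_axis("cell_id")
        out = celltyping.call_cell_types(m, centroids)
        assigned = out[out["cell_type"] != celltyping.UNCLASSIFIED]
        assert (assigned["cosine_distance"] < 0.8).all()
        assert (assigned["total_rna"] > 10).all()

    def test_scale_invariance_of_nearest_centroid(self):
        centroids = lung_centroids()
        base = pd.DataFrame(
            [[24, 1, 1, 1, 1, 1]], columns=centroids.columns
        ).rename_axis("cell_id")
        a = celltyping.call_cell_types(base, centroids)
        b = celltyping.call_cell_types(base * 5, centroids)
        assert a["cell_type"].iloc[0] == b["cell_type"].iloc[0]
        assert a["cosine_distance"].iloc[0] == pytest.approx(
            b["cosine_distance"].iloc[0], abs=1e-12
        )

    def test_five_type_recovery_through_simkit(self):
        """>= 90% of classified cells carry their true type label."""
        cfg = simkit.SimConfig(
            n_rounds=6,
            n_cells=60,
            field_shape=(9, 640, 640),
            seed=21,
            genes=LUNG_PANEL,
            nucleus_radius_px=12,
        )
        _, truth = simkit.generate_experiment(cfg, render=False)
        mask = simkit.nucleus_label_mask(truth.cells, (640, 640))
        matrix, _ = celltyping.assign_spots_to_cells(truth.spots_master, mask)
        calls = celltyping.call_cell_types(matrix, lung_centroids())
        tmap = dict(zip(truth.cells["cell_id"], truth.cells["cell_type"]))
        classified = calls[calls["cell_type"] != celltyping.UNCLASSIFIED]
        assert len(classified) >= 0.5 * len(calls)
        accuracy = (classified["cell_type"] == classified["cell_id"].map(tmap)).mean()
        assert accuracy >= 0.90

    def test_empty_centroids_rejected(self):
        with pytest.raises(ValueError):
            celltyping.call_cell_types(
                self._matrix([[1, 1]]), pd.DataFrame(columns=["A", "B"])
            )


class TestMarkerCentroids:
    def _reference(self, rng, n_per_type=7):
        rows = []
        for t in ("x", "y"):
            mean = [20, 2] if t == "x" else [2, 20]
            for _ in range(n_per_type):
                rows.append({"cell_type": t, "A": rng.poisson(mean[0]), "B": rng.poisson(mean[1])})
        return pd.DataFrame(rows)

    def test_single_cell_per_type_is_its_centroid(self):
        ref = pd.DataFrame([{"cell_type": "t", "A": 3, "B": 5}])
        c = celltyping.marker_centroids_from_reference(ref)
        assert c.loc["t", "A"] == 3 and c.loc["t", "B"] == 5

    def test_duplicating_cells_leaves_centroids_unchanged(self, rng):
        ref = self._reference(rng)
        a = celltyping.marker_centroids_from_reference(ref)
        b = celltyping.marker_centroids_from_reference(
            pd.concat([ref, ref], ignore_index=True)
        )
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("n_per_type", [5, 6])
    def test_median_matches_sort_based_oracle(self, rng, n_per_type):
        ref = self._reference(rng, n_per_type)
        c = celltyping.marker_centroids_from_reference(ref)
        for t, g in ref.groupby("cell_type"):
            for gene in ("A", "B"):
                vals = np.sort(g[gene].to_numpy(float))
                n = len(vals)
                oracle = vals[n // 2] if n % 2 else (vals[n // 2 - 1] + vals[n // 2]) / 2
                assert c.loc[t, gene] == oracle

    def test_precomputed_centroids_accepted_verbatim(self):
        pre = lung_centroids()
        out = celltyping.marker_centroids_from_reference(pre)
        pd.testing.assert_frame_equal(out, pre.astype(float))
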