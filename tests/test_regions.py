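"""Region clustering, quality indices, k selection and summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import (
    adjusted_rand_score,
    calinski_harabasz_score,
    davies_bouldin_score,
)

from rsnmap.io_tables import SegmentedObject
from rsnmap.neighborhoods import Neighborhood, build_raster_grid, count_in_neighborhoods
from rsnmap.regions import (
    assign_cell_regions,
    calinski_harabasz,
    cluster_neighborhoods,
    davies_bouldin,
    distribution_by_region,
    neighborhood_count_matrix,
    normalize_compositions,
    plateau_choice,
    region_composition,
    region_interaction,
    select_num_regions,
)

# hand-computed 4-point, 2-cluster instance: scatters 0.5, centroid gap 10
FOUR_POINTS = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
FOUR_LABELS = np.array([0, 0, 1, 1])


def _blobs(rng, k=2, n_per=50, sep=20.0, dim=3):
    centers = rng.uniform(0, 1, (k, dim)) + sep * np.arange(k)[:, None]
    x = np.vstack([c + rng.normal(0, 0.5, (n_per, dim)) for c in centers])
    labels = np.repeat(np.arange(k), n_per)
    return x, labels


class TestNormalize:
    def test_none_is_identity(self):
        x = np.arange(12.0).reshape(4, 3)
        out, scale = normalize_compositions(x, "none")
        assert np.array_equal(out, x)
        assert np.array_equal(scale, np.ones(3))

    def test_max_maps_to_unit_interval(self):
        x = np.arange(101.0)[:, None]
        out, _ = normalize_compositions(x, "max")
        assert out.min() == 0.0 and out.max() == 1.0

    def test_p95_matches_percentile_and_clips(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(10, size=(200, 4)).astype(float)
        out, scale = normalize_compositions(x, "p95")
        expect_scale = np.percentile(x, 95, axis=0)
        assert scale == pytest.approx(expect_scale)
        assert out.max() <= 1.0
        inner = x / expect_scale
        assert np.array_equal(out, np.clip(inner, None, 1.0))

    def test_zero_column_stays_zero(self):
        x = np.column_stack([np.zeros(10), np.arange(10.0)])
        out, _ = normalize_compositions(x, "p95")
        assert np.array_equal(out[:, 0], np.zeros(10))

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            normalize_compositions(np.ones((2, 2)), "exotic")


class TestIndices:
    def test_davies_bouldin_closed_form(self):
        assert davies_bouldin(FOUR_POINTS, FOUR_LABELS) == pytest.approx(0.1)

    def test_calinski_harabasz_closed_form(self):
        assert calinski_harabasz(FOUR_POINTS, FOUR_LABELS) == pytest.approx(200.0)

    def test_coincident_centroids_error(self):
        x = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ValueError, match="coincident"):
            davies_bouldin(x, np.array([0, 0, 1, 1]))

    def test_zero_within_scatter_is_infinite(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        assert calinski_harabasz(x, np.array([0, 0, 1, 1])) == np.inf

    @pytest.mark.parametrize("trial", range(10))
    def test_match_reference_implementations(self, trial):
        """Both indices agree with scikit-learn within 1e-9 on random data."""
        rng = np.random.default_rng(trial)
        x = rng.normal(0, 1, size=(rng.integers(30, 80), rng.integers(2, 5)))
        labels = rng.integers(0, rng.integers(2, 5), size=len(x))
        if len(np.unique(labels)) < 2:
            labels[0] = labels.max() + 1
        assert davies_bouldin(x, labels) == pytest.approx(
            davies_bouldin_score(x, labels), rel=1e-9
        )
        assert calinski_harabasz(x, labels) == pytest.approx(
            calinski_harabasz_score(x, labels), rel=1e-9
        )


class TestClustering:
    @pytest.mark.parametrize("method", ["som", "kmeans"])
    def test_separable_blobs_recovered(self, method):
        x, truth = _blobs(np.random.default_rng(1))
        labels, protos = cluster_neighborhoods(x, 2, method=method, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0
        assert protos.shape == (2, x.shape[1])

    def test_k_limits(self):
        x = np.zeros((5, 2))
        with pytest.raises(ValueError):
            cluster_neighborhoods(x, 1, seed=0)
        with pytest.raises(ValueError):
            cluster_neighborhoods(x, 2, seed=0)  # only 1 distinct row

    def test_som_matches_kmeans_on_archetypes(self):
        """Six well-separated archetypes: SOM and k-means agree (ARI >= 0.95)."""
        rng = np.random.default_rng(2)
        x, truth = _blobs(rng, k=6, n_per=100, sep=10.0, dim=4)
        som, _ = cluster_neighborhoods(x, 6, method="som", seed=0)
        km, _ = cluster_neighborhoods(x, 6, method="kmeans", seed=0)
        assert adjusted_rand_score(som, km) >= 0.95
        assert adjusted_rand_score(som, truth) >= 0.95

    def test_deterministic_and_permutation_invariant(self):
        rng = np.random.default_rng(3)
        x, _ = _blobs(rng, k=3, n_per=60)
        l1, _ = cluster_neighborhoods(x, 3, seed=7)
        l2, _ = cluster_neighborhoods(x, 3, seed=7)
        assert np.array_equal(l1, l2)
        perm = rng.permutation(len(x))
        lp, _ = cluster_neighborhoods(x[perm], 3, seed=7)
        assert adjusted_rand_score(l1[perm], lp) == 1.0


class TestKSelection:
    def test_two_blobs_selects_two(self):
        x, _ = _blobs(np.random.default_rng(4), k=2, n_per=100, sep=30.0)
        sel = select_num_regions(x, range(2, 9), seeds=[0])
        assert sel.chosen_k == 2 and not sel.warning

    def test_monotone_curves_warn(self):
        """Featureless monotone index curves have no plateau."""
        ks = list(range(2, 7))
        db = np.array([1.0, 0.8, 0.6, 0.4, 0.2])
        ch = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        k, warning = plateau_choice(ks, db, ch)
        assert warning and k == 6  # argmin DB fallback

    def test_plateau_rule_on_crafted_curves(self):
        ks = [2, 3, 4, 5]
        db = np.array([2.0, 0.5, 0.52, 0.51])
        ch = np.array([10.0, 100.0, 99.0, 98.0])
        k, warning = plateau_choice(ks, db, ch)
        assert k == 3 and not warning

    def test_invalid_k_range(self):
        x, _ = _blobs(np.random.default_rng(5))
        with pytest.raises(ValueError):
            select_num_regions(x, [1, 2], seeds=[0])


def _nbhds_from_counts(counts, classes):
    out = []
    for row in counts:
        nb = Neighborhood(center=(0.0, 0.0), radius=50.0)
        nb.counts = {c: int(v) for c, v in zip(classes, row) if v}
        out.append(nb)
    return out


class TestSummaries:
    def test_composition_means_and_conservation(self):
        classes = ["cDC1", "CD8T"]
        counts = np.array([[2, 0], [4, 0], [0, 5], [0, 7]])
        nbhds = _nbhds_from_counts(counts, classes)
        labels = np.array([0, 0, 1, 1])
        comp = region_composition(nbhds, labels, classes)
        assert comp.loc[0, "cDC1"] == pytest.approx(3.0)
        assert comp.loc[1, "CD8T"] == pytest.approx(6.0)
        # conservation: sum over regions of mean * region size = column totals
        sizes = pd.Series(labels).value_counts()
        totals = (comp.mul(sizes, axis=0)).sum()
        assert totals["cDC1"] == 6 and totals["CD8T"] == 12

    def test_interaction_two_by_two(self):
        grid = build_raster_grid((0, 0, 100, 100), 50.0)
        labels = np.array([0, 0, 1, 1])  # bottom row A, top row B
        mat = region_interaction(grid, labels)
        assert mat.loc[0, 1] == pytest.approx(200.0 / 3.0)
        assert mat.loc[0, 0] == pytest.approx(100.0 / 3.0)

    def test_interaction_single_region(self):
        grid = build_raster_grid((0, 0, 100, 100), 50.0)
        mat = region_interaction(grid, np.zeros(4, dtype=int))
        assert mat.loc[0, 0] == pytest.approx(100.0)

    def test_interaction_matches_edge_enumeration(self):
        rng = np.random.default_rng(6)
        grid = build_raster_grid((0, 0, 350, 250), 50.0)
        labels = rng.integers(0, 4, size=len(grid))
        mat = region_interaction(grid, labels)
        ny, nx = grid.shape
        lab = labels.reshape(ny, nx)
        edges = {}
        for j in range(ny):
            for i in range(nx):
                for dj, di in ((0, 1), (1, 0)):
                    jj, ii = j + dj, i + di
                    if jj < ny and ii < nx:
                        a, b = lab[j, i], lab[jj, ii]
                        edges[(a, b)] = edges.get((a, b), 0) + 1
                        if a != b:
                            edges[(b, a)] = edges.get((b, a), 0) + 1
        for a in range(4):
            total = sum(v for (i, _), v in edges.items() if i == a)
            for b in range(4):
                expect = 100.0 * edges.get((a, b), 0) / total
                assert mat.loc[a, b] == pytest.approx(expect)

    def test_assign_cell_regions_matches_brute_force(self):
        rng = np.random.default_rng(7)
        grid = build_raster_grid((0, 0, 200, 200), 40.0)
        labels = rng.integers(0, 3, size=len(grid))
        pts = rng.uniform(0, 200, size=(100, 2))
        got = assign_cell_regions(pts, grid, labels)
        d2 = ((pts[:, None, :] - grid.centers[None, :, :]) ** 2).sum(axis=2)
        assert np.array_equal(got, labels[np.argmin(d2, axis=1)])

    def test_distribution_percentages(self):
        df = pd.DataFrame(
            {
                "section_id": ["s1"] * 4,
                "object_class": ["cDC1"] * 4,
                "region": [0, 0, 1, 1],
            }
        )
        out = distribution_by_region(df)
        assert sorted(out["percent"]) == [50.0, 50.0]
        one_region = df.assign(region=2)
        out2 = distribution_by_region(one_region)
        assert out2["percent"].tolist() == [100.0]

    def test_suggested_region_names_match_extremes(self):
        from rsnmap.regions import suggest_region_names

        comp = pd.DataFrame(
            {
                "cDC1": [0.5, 25.0, 1.0],
                "CD8T": [28.0, 0.5, 1.0],
                "vessel": [1.0, 1.0, 1.5],
                "tumour": [0.5, 0.5, 33.0],
            },
            index=[0, 1, 2],
        )
        names = suggest_region_names(comp)
        assert names[0] == "CD8"
        assert names[1] == "cDC1"
        assert names[2] == "Tumour"

    def test_distribution_recovers_counts(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "section_id": rng.choice(["s1", "s2"], 200),
                "object_class": rng.choice(["cDC1", "CD8T"], 200),
                "region": rng.integers(0, 4, 200),
            }
        )
        out = distribution_by_region(df)
        totals = df.groupby(["section_id", "object_class"]).size()
        merged = out.set_index(["section_id", "object_class"])
        recovered = (
            merged["percent"] * totals.reindex(merged.index) / 100.0
        )
        assert np.allclose(recovered, merged["n"])
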