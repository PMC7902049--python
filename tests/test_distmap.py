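import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spatialsel as ss
from spatialsel.distmap import MccMap, weak_labels, top_location
from spatialsel.io import DataError


def brute_force_mcc(a, b):
    """Independent contingency-table oracle (explicit counting)."""
    tp = sum(1 for x, y in zip(a, b) if x == 1 and y == 1)
    tn = sum(1 for x, y in zip(a, b) if x == 0 and y == 0)
    fp = sum(1 for x, y in zip(a, b) if x == 1 and y == 0)
    fn = sum(1 for x, y in zip(a, b) if x == 0 and y == 1)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom**0.5


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ((1, 0, 1, 0), (1, 0, 1, 0), 1.0),
        ((1, 1, 0, 0), (1, 0, 1, 0), 0.0),
        ((0, 1, 0, 1), (1, 0, 1, 0), -1.0),
        ((1, 1, 1, 1), (1, 0, 1, 0), 0.0),  # empty margin -> 0 convention
    ],
)
def test_mcc_known_values(a, b, expected):
    assert ss.mcc(np.array(a), np.array(b)) == pytest.approx(expected)


def test_mcc_matches_brute_force_oracle():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = rng.integers(1, 21)
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        assert abs(ss.mcc(a, b) - brute_force_mcc(a, b)) < 1e-12


@settings(max_examples=200, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=20))
def test_mcc_symmetry_and_relabel_invariance(pairs):
    a = np.array([p[0] for p in pairs])
    b = np.array([p[1] for p in pairs])
    m = ss.mcc(a, b)
    assert m == pytest.approx(ss.mcc(b, a))            # symmetric
    assert m == pytest.approx(ss.mcc(1 - a, 1 - b))    # joint 0<->1 relabel
    assert -1.0 - 1e-12 <= m <= 1.0 + 1e-12


def test_mcc_length_mismatch():
    with pytest.raises(DataError):
        ss.mcc(np.array([1, 0]), np.array([1, 0, 1]))


class TestBinarization:
    def test_median_threshold_for_half_on_gene(self):
        # gene on in 50% of bins + continuous iid expression -> q nearest 0.5
        rng = np.random.default_rng(0)
        coords = ss.simulate_embryo_bins(40, seed=1)
        insitu = np.zeros((40, 1), dtype=int)
        insitu[:20, 0] = 1
        atlas = ss.SpatialBinAtlas(["g"], insitu, coords)
        expr = ss.ExpressionMatrix(["g"], [f"c{i}" for i in range(500)],
                                   rng.uniform(0, 1, (1, 500)))
        params = ss.fit_binarization(expr, atlas)
        assert abs(params.quantiles[0] - 0.5) <= 0.011
        assert params.thresholds[0] == pytest.approx(
            np.quantile(expr.values[0], params.quantiles[0]))

    def test_constant_gene_degenerate(self, caplog):
        coords = ss.simulate_embryo_bins(10, seed=1)
        insitu = np.ones((10, 1), dtype=int)
        insitu[5:] = 0
        atlas = ss.SpatialBinAtlas(["g"], insitu, coords)
        expr = ss.ExpressionMatrix(["g"], [f"c{i}" for i in range(20)],
                                   np.zeros((1, 20)))
        import logging
        with caplog.at_level(logging.WARNING, logger="spatialsel"):
            params = ss.fit_binarization(expr, atlas)
        assert params.quantiles[0] == pytest.approx(0.05)  # grid minimum
        b = ss.binarize_cells(expr, params)
        assert len(np.unique(b)) == 1
        assert any("degenerate" in r.message for r in caplog.records)

    def test_gene_absent_from_atlas_names_gene(self):
        coords = ss.simulate_embryo_bins(10, seed=1)
        atlas = ss.simulate_atlas_patterns(coords, 2, seed=2)
        expr = ss.ExpressionMatrix(["nope"], ["c0"], np.ones((1, 1)))
        with pytest.raises(DataError, match="nope"):
            ss.fit_binarization(expr, atlas)

    def test_threshold_boundary_is_inclusive(self, small_expr):
        from spatialsel.distmap import BinarizationParams
        v = small_expr.values[0, 0]
        params = BinarizationParams(list(small_expr.gene_names),
                                    np.full(5, 0.5),
                                    np.full(5, v))
        b = ss.binarize_cells(small_expr, params)
        assert b[0, 0] == 1  # expression == threshold -> on
        all_on = BinarizationParams(list(small_expr.gene_names),
                                    np.full(5, 0.5), np.zeros(5))
        assert ss.binarize_cells(small_expr, all_on).all()
        all_off = BinarizationParams(list(small_expr.gene_names),
                                     np.full(5, 0.5), np.full(5, 1e9))
        assert not ss.binarize_cells(small_expr, all_off).any()


class TestMccMap:
    def test_cell_identical_to_bin_column_maxes_there(self, noiseless_data):
        _, atlas, _ = noiseless_data
        b = atlas.insitu[7][None, :]
        m = ss.compute_mcc_map(b, atlas, atlas.gene_names)
        assert np.argmax(m.mcc[0]) == 7
        assert m.mcc[0, 7] == pytest.approx(1.0)

    def test_noiseless_cells_recover_true_bin(self, noiseless_data):
        norm, atlas, truth = noiseless_data
        params = ss.fit_binarization(norm, atlas)
        m = ss.compute_mcc_map(ss.binarize_cells(norm, params), atlas,
                               atlas.gene_names, cell_names=list(norm.cell_names))
        row_max = m.mcc.max(axis=1)
        attains = m.mcc[np.arange(norm.n_cells), truth.true_bins] >= row_max - 1e-12
        assert attains.mean() >= 0.99

    def test_empty_gene_list_rejected(self, noiseless_data):
        _, atlas, _ = noiseless_data
        with pytest.raises(DataError):
            ss.compute_mcc_map(np.zeros((1, 0)), atlas, [])


class TestTopLocationAndWeakLabels:
    def _map(self, rows, coords_n=4):
        coords = ss.simulate_embryo_bins(coords_n, seed=3)
        insitu = np.ones((coords_n, 1), dtype=int)
        insitu[0] = 0
        atlas = ss.SpatialBinAtlas(["g"], insitu, coords)
        m = np.asarray(rows, dtype=float)
        unique = (m == m.max(axis=1, keepdims=True)).sum(axis=1) == 1
        cells = [f"c{i}" for i in range(m.shape[0])]
        return MccMap(cells, m, ["g"], unique), atlas

    def test_unique_max(self):
        mm, atlas = self._map([[0.1, 0.2, 0.9, 0.3]])
        b, x, y, z = top_location(mm, "c0", atlas)
        assert b == 2 and (x, y, z) == tuple(atlas.coords[2])

    def test_tie_goes_to_first_bin_in_file_order(self):
        mm, atlas = self._map([[0.1, 0.9, 0.2, 0.9]])
        assert top_location(mm, "c0", atlas)[0] == 1
        mm2, atlas2 = self._map([[0.5, 0.5, 0.5, 0.5]])
        assert top_location(mm2, "c0", atlas2)[0] == 0

    def test_weak_labels_threshold_arithmetic(self):
        mm, atlas = self._map([[0.80, 0.77, 0.60, 0.40]])
        labels = weak_labels(mm, atlas, tau=0.95)  # threshold 0.76
        assert sorted(labels.bin_indices.tolist()) == [0, 1]

    def test_weak_labels_tau_one_equals_top_location(self, tiny_mcc, tiny_data):
        _, mcc_map = tiny_mcc
        _, _, atlas, _ = tiny_data
        labels = weak_labels(mcc_map, atlas, tau=1.0)
        # cells with unique maxima get exactly their top location
        per_cell = {}
        for c, b in zip(labels.cell_names, labels.bin_indices):
            per_cell.setdefault(c, []).append(int(b))
        for i, c in enumerate(mcc_map.cell_names):
            if mcc_map.unique_max[i]:
                assert per_cell[c] == [top_location(mcc_map, c, atlas)[0]]

    def test_weak_labels_monotone_in_tau(self, tiny_mcc, tiny_data):
        _, mcc_map = tiny_mcc
        _, _, atlas, _ = tiny_data
        sizes = [weak_labels(mcc_map, atlas, tau).n_obs
                 for tau in (1.0, 0.95, 0.8, 0.5, 0.2)]
        assert sizes == sorted(sizes)  # lowering tau never removes observations

    def test_weak_label_coords_match_atlas(self, tiny_mcc, tiny_data):
        _, mcc_map = tiny_mcc
        _, _, atlas, _ = tiny_data
        labels = weak_labels(mcc_map, atlas, 0.95)
        np.testing.assert_array_equal(labels.coords, atlas.coords[labels.bin_indices])


class TestPredictTop10:
    def test_contract_and_ordering(self, tiny_data):
        _, norm, atlas, _ = tiny_data
        train = norm.subset_cells(norm.cell_names[:80])
        test = norm.subset_cells(norm.cell_names[80:])
        preds = ss.predict_top10(train, test, atlas, atlas.gene_names)
        assert preds.bin_indices.shape == (test.n_cells, 10)
        # descending MCC with ties by ascending bin index implies each row
        # has 10 distinct bins
        for row in preds.bin_indices:
            assert len(set(row.tolist())) == 10

    def test_overlap_guard(self, tiny_data):
        _, norm, atlas, _ = tiny_data
        with pytest.raises(DataError, match="leakage"):
            ss.predict_top10(norm, norm, atlas, atlas.gene_names)

    def test_noiseless_true_bin_in_top10(self, noiseless_data):
        norm, atlas, truth = noiseless_data
        train = norm.subset_cells(norm.cell_names[:150])
        test = norm.subset_cells(norm.cell_names[150:])
        preds = ss.predict_top10(train, test, atlas, atlas.gene_names)
        true = truth.true_bins[150:]
        hit = np.mean([t in set(row.tolist())
                       for t, row in zip(true, preds.bin_indices)])
        assert hit >= 0.99

    def test_uses_only_selected_genes(self, tiny_data):
        _, norm, atlas, _ = tiny_data
        genes = atlas.gene_names[:6]
        train = norm.subset_cells(norm.cell_names[:80])
        test = norm.subset_cells(norm.cell_names[80:])
        preds1 = ss.predict_top10(train, test, atlas, genes)
        # perturb expression of genes outside the selection
        vals = test.values.copy()
        outside = [i for i, g in enumerate(test.gene_names) if g not in set(genes)]
        vals[outside] += 100.0
        test2 = ss.ExpressionMatrix(list(test.gene_names), list(test.cell_names), vals)
        preds2 = ss.predict_top10(train, test2, atlas, genes)
        np.testing.assert_array_equal(preds1.bin_indices, preds2.bin_indices)
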