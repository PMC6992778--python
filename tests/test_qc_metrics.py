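"""Cell/gene quality filters and summary statistics."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from nucquant.qc_metrics import (
    QCConfig,
    detection_gain,
    filter_matrix,
    per_cell_summary,
    region_fractions,
    select_top_cells,
    top_gene_fractions,
)
from nucquant.umi_quant import CountMatrix


def mat(dense, genes=None, cells=None, mode="exon_plus_intron"):
    dense = np.array(dense)
    genes = genes or [f"g{i}" for i in range(dense.shape[0])]
    cells = cells or [f"c{i}" for i in range(dense.shape[1])]
    return CountMatrix(genes, cells, sp.csr_matrix(dense), mode)


class TestPerCellSummary:
    def test_detection_and_totals(self):
        m = mat([[0], [1], [5]])
        (s,) = per_cell_summary(m)
        assert (s.genes_detected, s.total_umi) == (2, 6)

    def test_all_zero_column(self):
        m = mat([[0], [0]])
        (s,) = per_cell_summary(m)
        assert (s.genes_detected, s.total_umi) == (0, 0)

    def test_intronic_fraction_from_assignments(self):
        m = mat([[4]], cells=["c0"])
        assignments = pd.DataFrame(
            {
                "cell": ["c0"] * 4,
                "region": ["intronic", "intronic", "exonic", "intergenic"],
            }
        )
        (s,) = per_cell_summary(m, assignments)
        assert s.intronic_fraction == pytest.approx(2 / 3)

    def test_matches_brute_force_on_random_cells(self):
        rng = np.random.default_rng(0)
        dense = rng.integers(0, 4, size=(50, 100))
        m = mat(dense)
        summaries = per_cell_summary(m, n_top=3)
        for j, s in enumerate(summaries):
            assert s.genes_detected == int((dense[:, j] >= 1).sum())
            assert s.total_umi == int(dense[:, j].sum())
            if s.top_gene_fractions:
                top_gene, top_frac = s.top_gene_fractions[0]
                assert top_frac == pytest.approx(dense[:, j].max() / dense[:, j].sum())


class TestFilterMatrix:
    def test_cell_threshold_boundary(self):
        """A cell at exactly the minimum detected genes is kept ('less
        than' is removed)."""
        rng = np.random.default_rng(1)
        dense = np.zeros((500, 3), dtype=int)
        for j, n in enumerate([500, 399, 400]):
            rows = rng.choice(500, size=n, replace=False)
            dense[rows, j] = 1
        m = mat(dense)
        out = filter_matrix(m, QCConfig(min_cells_per_gene=0), mode="cell")
        assert out.cell_barcodes == ["c0", "c2"]

    def test_nucleus_boundary_at_300(self):
        dense = np.zeros((300, 1), dtype=int)
        dense[:, 0] = 1
        out = filter_matrix(mat(dense), QCConfig(min_cells_per_gene=0), mode="nucleus")
        assert out.cell_barcodes == ["c0"]

    def test_gene_filter_applies_after_cell_filter(self):
        """A gene detected in 10 cells overall but fewer than 10 surviving
        cells is removed."""
        n_genes = 401
        dense = np.zeros((n_genes, 12), dtype=int)
        dense[:400, :10] = 1  # 10 good cells with 400 genes
        dense[400, 10:] = 1  # gene 400 detected only in 2 poor cells
        out = filter_matrix(mat(dense), QCConfig(), mode="cell")
        assert len(out.cell_barcodes) == 10
        assert "g400" not in out.gene_ids
        assert len(out.gene_ids) == 400

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(2)
        dense = (rng.random((1000, 500)) < 0.25).astype(int) * rng.integers(
            1, 5, (1000, 500)
        )
        # plant low-quality columns and rows
        dense[:, rng.choice(500, 50, replace=False)] = 0
        cfg = QCConfig(min_genes_cellmode=240, min_cells_per_gene=10)
        out = filter_matrix(mat(dense), cfg, mode="cell")
        keep_cells = [j for j in range(500) if (dense[:, j] >= 1).sum() >= 240]
        sub = dense[:, keep_cells]
        keep_genes = [i for i in range(1000) if (sub[i] >= 1).sum() >= 10]
        assert out.cell_barcodes == [f"c{j}" for j in keep_cells]
        assert out.gene_ids == [f"g{i}" for i in keep_genes]
        np.testing.assert_array_equal(
            out.counts.toarray(), dense[np.ix_(keep_genes, keep_cells)]
        )

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        dense = (rng.random((200, 80)) < 0.3).astype(int)
        m = mat(dense)
        sizes = []
        for min_genes in (10, 30, 50, 70):
            cfg = QCConfig(min_genes_cellmode=min_genes, min_cells_per_gene=5)
            out = filter_matrix(m, cfg, mode="cell")
            sizes.append(out.shape)
        assert all(a[1] >= b[1] for a, b in zip(sizes, sizes[1:]))

    def test_empty_result_is_returned_not_raised(self):
        out = filter_matrix(mat([[1]]), QCConfig(), mode="cell")
        assert out.shape[1] == 0


class TestDetectionGain:
    def test_simple_ratio(self):
        exon = mat(np.vstack([np.ones((10, 1)), np.zeros((5, 1))]).astype(int))
        both = mat(np.ones((15, 1), dtype=int))
        _r, mean, n_inf = detection_gain(exon, both)
        assert mean == pytest.approx(1.5)
        assert n_inf == 0

    def test_identical_matrices_give_unit_ratio(self):
        m = mat([[1, 2], [0, 3]])
        ratios, mean, _ = detection_gain(m, m)
        assert (ratios == 1.0).all()
        assert mean == 1.0

    def test_zero_exon_detection_excluded_from_mean(self):
        exon = mat([[0, 1], [0, 1]])
        both = mat([[2, 1], [2, 2]])
        _r, mean, n_inf = detection_gain(exon, both)
        assert n_inf == 1
        assert mean == 1.0

    def test_barcode_mismatch_rejected(self):
        with pytest.raises(ValueError):
            detection_gain(mat([[1]], cells=["a"]), mat([[1]], cells=["b"]))

    def test_gain_at_least_one_under_entrywise_dominance(self):
        rng = np.random.default_rng(4)
        exon = rng.integers(0, 3, (30, 20))
        both = exon + rng.integers(0, 3, (30, 20))
        ratios, _, _ = detection_gain(mat(exon), mat(both))
        finite = ratios[np.isfinite(ratios)]
        assert (finite >= 1).all()


class TestRegionFractions:
    def test_half_and_half(self):
        df = pd.DataFrame({"region": ["exonic"] * 5 + ["intronic"] * 5})
        f = region_fractions(df)
        assert f["exonic"] == f["intronic"] == 0.5
        assert f["ambiguous"] == f["intergenic"] == 0.0

    def test_all_exonic_and_sum_to_one(self):
        df = pd.DataFrame({"region": ["exonic"] * 7})
        f = region_fractions(df)
        assert f["exonic"] == 1.0
        assert abs(sum(f.values()) - 1.0) < 1e-12

    def test_empty_stream_is_an_error(self):
        with pytest.raises(ValueError):
            region_fractions(pd.DataFrame({"region": []}))


class TestTopGeneFractions:
    def test_descending_shares(self):
        m = mat([[90], [10]], genes=["gA", "gB"])
        assert top_gene_fractions(m, n=2) == [("gA", 0.9), ("gB", 0.1)]

    def test_n_larger_than_gene_count(self):
        m = mat([[1], [1]])
        assert len(top_gene_fractions(m, n=15)) == 2

    def test_ties_break_lexicographically_and_match_brute_force(self):
        rng = np.random.default_rng(5)
        dense = rng.integers(0, 9, (40, 10))
        m = mat(dense)
        got = top_gene_fractions(m, n=15)
        totals = dense.sum(axis=1) / dense.sum()
        expected = sorted(
            zip([f"g{i}" for i in range(40)], totals), key=lambda t: (-t[1], t[0])
        )[:15]
        assert [g for g, _ in got] == [g for g, _ in expected]
        np.testing.assert_allclose([f for _, f in got], [f for _, f in expected])


class TestSelectTopCells:
    def test_keeps_ceiling_fraction(self):
        rng = np.random.default_rng(6)
        dense = np.zeros((100, 10), dtype=int)
        for j in range(10):
            dense[: (j + 1) * 10, j] = 1
        out = select_top_cells(mat(dense), fraction=0.3)
        assert out.cell_barcodes == ["c7", "c8", "c9"]

    def test_fraction_one_is_identity(self):
        m = mat(np.eye(4, dtype=int))
        out = select_top_cells(m, fraction=1.0)
        assert out.cell_barcodes == m.cell_barcodes

    def test_matches_brute_force_sort_and_slice(self):
        rng = np.random.default_rng(7)
        dense = rng.integers(0, 3, (60, 33))
        m = mat(dense)
        out = select_top_cells(m, fraction=0.30)
        detected = (dense >= 1).sum(axis=0)
        totals = dense.sum(axis=0)
        order = sorted(
            range(33), key=lambda j: (-detected[j], -totals[j], f"c{j}")
        )[: int(np.ceil(0.3 * 33))]
        assert set(out.cell_barcodes) == {f"c{j}" for j in order}
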