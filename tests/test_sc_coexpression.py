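"""QC filtering, log-normalization and co-expression cross-tabs."""

import numpy as np
import pandas as pd
import pytest

from p73kit.errors import ModeError, UsageError, ValidationError
from p73kit.sc_coexpression import (
    CellMatrix,
    QCThresholds,
    STATUS_COLUMNS,
    classify_expression,
    coexpression_table,
    log_normalize,
    positive_fraction_by_group,
    qc_filter,
    read_cell_matrix,
    write_cell_matrix,
)
from p73kit.synthetic_data import simulate_cell_matrix


def tiny_matrix(columns: dict, n_spike=2, cluster="c0") -> CellMatrix:
    """Cells from explicit (non-spike list, spike list) count pairs."""
    n_base = max(len(v[0]) for v in columns.values())
    genes = [f"g{i}" for i in range(n_base)] + [f"ERCC-{i}" for i in range(n_spike)]
    data = {}
    for cell, (base, spike) in columns.items():
        col = list(base) + [0] * (n_base - len(base)) + list(spike) + [0] * (
            n_spike - len(spike)
        )
        data[cell] = col
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    spikein = pd.Series([False] * n_base + [True] * n_spike, index=counts.index)
    meta = pd.DataFrame({"cluster": cluster}, index=counts.columns)
    return CellMatrix(counts=counts, spikein=spikein, cell_meta=meta, mode="counts")


class TestQCFilter:
    def test_strict_boundaries(self):
        """<900 genes removed; ==900 genes, ==75000 counts, ==12% spike kept."""
        m = tiny_matrix(
            {
                # 899 genes detected, 94.9k total, ~5% spike -> removed (genes)
                "fail_genes": ([100] * 899, [2500, 2500]),
                # exactly 900 genes -> kept
                "ok_genes": ([100] * 900, [2500, 2500]),
                # 1000 genes but 74,999 total -> removed (counts)
                "fail_counts": ([70] * 1000, [2500, 2499]),
                # exactly 75,000 total -> kept
                "ok_counts": ([70] * 1000, [2500, 2500]),
                # 12,300/102,300 = 12.02% spike -> removed (spikein)
                "fail_spike": ([100] * 900, [6150, 6150]),
                # 12,000/100,000 = exactly 12.0% -> kept
                "ok_spike": ([80] * 1100, [6000, 6000]),
            }
        )
        filtered, report = qc_filter(m, QCThresholds())
        assert set(report.index) == {"fail_genes", "fail_counts", "fail_spike"}
        assert report.loc["fail_genes", "reasons"] == "genes"
        assert report.loc["fail_counts", "reasons"] == "counts"
        assert report.loc["fail_spike", "reasons"] == "spikein"
        assert set(filtered.cells) == {"ok_genes", "ok_counts", "ok_spike"}

    def test_genes_detected_excludes_spikeins(self):
        # 2 non-spike genes detected even though spike-ins are nonzero
        m = tiny_matrix({"c": ([10, 10, 0], [5, 5])})
        _, report = qc_filter(m, QCThresholds(min_genes=3, min_counts=0, max_spikein_pct=100))
        assert report.loc["c", "genes_detected"] == 2
        assert "genes" in report.loc["c", "reasons"]

    def test_multiple_reasons_recorded(self):
        m = tiny_matrix({"c": ([1, 0], [50, 50])})
        _, report = qc_filter(m, QCThresholds(min_genes=2, min_counts=1000, max_spikein_pct=12))
        assert report.loc["c", "reasons"] == "genes,counts,spikein"

    def test_tpm_mode_rejected(self):
        m = tiny_matrix({"c": ([1, 1], [0, 0])})
        m.mode = "tpm"
        with pytest.raises(ModeError):
            qc_filter(m)

    def test_matches_brute_force_on_simulated_cells(self):
        """Exact agreement with an independent per-cell check, 1000 cells."""
        m, truth = simulate_cell_matrix(
            n_clusters=2, cells_per_cluster=500, qc_fail_fraction=0.1, seed=11
        )
        t = QCThresholds()
        # oracle: recompute metrics straight from the raw frame
        spike = m.spikein.to_numpy()
        expected_removed = {}
        for cell in m.cells:
            col = m.counts[cell].to_numpy()
            genes = int((col[~spike] > 0).sum())
            total = int(col.sum())
            spct = 100 * col[spike].sum() / total if total else 0.0
            why = []
            if genes < t.min_genes:
                why.append("genes")
            if total < t.min_counts:
                why.append("counts")
            if spct > t.max_spikein_pct:
                why.append("spikein")
            if why:
                expected_removed[cell] = ",".join(why)
        _, report = qc_filter(m, t)
        assert dict(zip(report.index, report["reasons"])) == expected_removed
        # and the planted truth agrees with both
        assert expected_removed == truth.params["qc_fail"]


class TestLogNormalize:
    def test_closed_form(self):
        # count 10 in a cell totalling 10,000 -> ln(1 + 1e4*10/1e4) = ln(11)
        m2 = tiny_matrix({"c": ([10, 9990], [0, 0])})
        vals = log_normalize(m2, scale_factor=1e4)
        assert vals.loc["g0", "c"] == pytest.approx(np.log(11.0))
        assert vals.loc["ERCC-0", "c"] == 0.0

    def test_zero_count_maps_to_zero(self):
        m = tiny_matrix({"c": ([0, 5], [0, 0])})
        assert log_normalize(m).loc["g0", "c"] == 0.0

    def test_depth_invariance(self):
        m1 = tiny_matrix({"c": ([10, 90], [3, 0])})
        m2 = tiny_matrix({"c": ([20, 180], [6, 0])})
        assert np.allclose(log_normalize(m1)["c"].iloc[:2], log_normalize(m2)["c"].iloc[:2])

    def test_totals_exclude_spikeins(self):
        # same non-spike profile, wildly different spike-ins -> same values
        m1 = tiny_matrix({"c": ([10, 90], [0, 0])})
        m2 = tiny_matrix({"c": ([10, 90], [500, 500])})
        assert np.allclose(
            log_normalize(m1)["c"].iloc[:2], log_normalize(m2)["c"].iloc[:2]
        )

    def test_zero_total_cell_named_in_error(self):
        m = tiny_matrix({"empty": ([0, 0], [5, 5])})
        with pytest.raises(ValidationError, match="empty"):
            log_normalize(m)


class TestClassify:
    @pytest.mark.parametrize(
        "value,mode,threshold,expected",
        [
            (0.5, "lognorm", 0.5, True),   # inclusive threshold
            (0.49, "lognorm", 0.5, False),
            (1.0, "tpm", 1.0, True),
            (0.999, "tpm", 1.0, False),
        ],
    )
    def test_inclusive_threshold(self, value, mode, threshold, expected):
        s = pd.Series([value], index=["cell0"])
        assert classify_expression(s, mode, threshold).iloc[0] is np.bool_(expected)

    def test_bad_mode(self):
        with pytest.raises(UsageError):
            classify_expression(pd.Series([1.0]), "zscore", 0.5)


class TestCoexpressionTable:
    def test_one_cell_of_each_status(self):
        idx = pd.Index([f"c{i}" for i in range(4)])
        a = pd.Series([False, True, False, True], index=idx)
        b = pd.Series([False, False, True, True], index=idx)
        cl = pd.Series(["k"] * 4, index=idx)
        tab = coexpression_table(a, b, cl)
        assert tab.loc["k", "n_cells"] == 4
        assert all(tab.loc["k", c] == 25.0 for c in STATUS_COLUMNS)

    def test_all_double_positive(self):
        idx = pd.Index(["c0", "c1"])
        a = b = pd.Series([True, True], index=idx)
        tab = coexpression_table(a, b, pd.Series(["k", "k"], index=idx))
        assert tab.loc["k", "a+b+"] == 100.0

    def test_rows_sum_to_100(self):
        rng = np.random.default_rng(0)
        idx = pd.Index([f"c{i}" for i in range(300)])
        a = pd.Series(rng.random(300) < 0.3, index=idx)
        b = pd.Series(rng.random(300) < 0.6, index=idx)
        cl = pd.Series(rng.choice(["x", "y", "z"], 300), index=idx)
        tab = coexpression_table(a, b, cl)
        assert np.allclose(tab[list(STATUS_COLUMNS)].sum(axis=1), 100.0, atol=1e-9)

    def test_empty_cluster_omitted_with_warning(self):
        idx = pd.Index(["c0"])
        a = b = pd.Series([True], index=idx)
        cl = pd.Series(pd.Categorical(["k"], categories=["k", "empty"]), index=idx)
        with pytest.warns(UserWarning, match="empty"):
            tab = coexpression_table(a, b, cl)
        assert list(tab.index) == ["k"]

    def test_misaligned_cells_rejected(self):
        a = pd.Series([True], index=["c0"])
        b = pd.Series([True], index=["c1"])
        with pytest.raises(ValidationError):
            coexpression_table(a, b, a.astype(str))


class TestPositiveFraction:
    def test_fraction_and_n(self):
        idx = pd.Index([f"c{i}" for i in range(10)])
        status = pd.Series([True] * 3 + [False] * 7, index=idx)
        groups = pd.Series(["bulge"] * 10, index=idx)
        out = positive_fraction_by_group(status, groups)
        assert out.loc["bulge", "pct_positive"] == 30.0
        assert out.loc["bulge", "n"] == 10

    def test_all_positive(self):
        idx = pd.Index(["c0"])
        out = positive_fraction_by_group(
            pd.Series([True], index=idx), pd.Series(["g"], index=idx)
        )
        assert out.loc["g", "pct_positive"] == 100.0


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        m, _ = simulate_cell_matrix(n_clusters=2, cells_per_cluster=5, n_genes=30, seed=2)
        write_cell_matrix(m, tmp_path / "m.tsv", tmp_path / "g.tsv", tmp_path / "c.tsv")
        back = read_cell_matrix(tmp_path / "m.tsv", tmp_path / "g.tsv", tmp_path / "c.tsv")
        assert back.counts.equals(m.counts)
        assert back.spikein.equals(m.spikein)
        assert (back.cell_meta["cluster"] == m.cell_meta["cluster"]).all()

    def test_mtx_round_trip(self, tmp_path):
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        m, _ = simulate_cell_matrix(n_clusters=1, cells_per_cluster=4, n_genes=20, seed=3)
        mmwrite(tmp_path / "m.mtx", csr_matrix(m.counts.to_numpy()))
        write_cell_matrix(m, tmp_path / "unused.tsv", tmp_path / "g.tsv", tmp_path / "c.tsv")
        back = read_cell_matrix(tmp_path / "m.mtx", tmp_path / "g.tsv", tmp_path / "c.tsv")
        assert np.array_equal(back.counts.to_numpy(), m.counts.to_numpy())
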