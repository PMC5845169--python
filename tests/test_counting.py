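import itertools

import numpy as np
import pandas as pd
import pytest

import plateseq as ps
from plateseq.counting import _hamming1_components


def tag(cell, umi, gene):
    return ps.GeneTaggedRead(cell_barcode=cell, umi=umi, gene=gene)


def brute_force_components(umis):
    """Connected components of the Hamming-1 graph by explicit traversal."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(umis)
    for a, b in itertools.combinations(umis, 2):
        if sum(x != y for x, y in zip(a, b)) <= 1:
            g.add_edge(a, b)
    return nx.number_connected_components(g)


class TestCountUmis:
    def test_pcr_duplicates_collapse(self):
        reads = [tag("CELL1", "AAAAAAAA", "g1")] * 5
        m = ps.count_umis(reads, collapse="exact")
        assert m.counts.tolist() == [[1]]

    def test_hamming1_vs_exact(self):
        reads = [
            tag("CELL1", "AAAAAAAA", "g1"),
            tag("CELL1", "AAAAAAAT", "g1"),
            tag("CELL1", "CCCCCCCC", "g1"),
        ]
        assert ps.count_umis(reads, collapse="hamming1").counts.tolist() == [[2]]
        assert ps.count_umis(reads, collapse="exact").counts.tolist() == [[3]]
        assert brute_force_components(["AAAAAAAA", "AAAAAAAT", "CCCCCCCC"]) == 2

    def test_hamming1_matches_brute_force_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            umis = list({
                "".join("ACGT"[i] for i in rng.integers(0, 4, 4)) for _ in range(n)
            })
            assert _hamming1_components(sorted(umis)) == brute_force_components(umis)

    def test_known_molecule_count_recovered(self):
        rng = np.random.default_rng(5)
        m_true = 50
        codes = rng.choice(4 ** 8, size=m_true, replace=False)
        umis = []
        for code in codes:
            s, c = [], int(code)
            for _ in range(8):
                s.append("ACGT"[c & 3])
                c >>= 2
            umis.append("".join(s))
        reads = [tag("CELL1", u, "g1") for u in umis for _ in range(3)]
        m = ps.count_umis(reads, collapse="exact")
        assert m.counts.tolist() == [[m_true]]

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        reads = [
            tag(f"C{rng.integers(3)}", "".join("ACGT"[i] for i in rng.integers(0, 4, 8)),
                f"g{rng.integers(4)}")
            for _ in range(200)
        ]
        m1 = ps.count_umis(reads)
        perm = [reads[i] for i in rng.permutation(len(reads))]
        m2 = ps.count_umis(perm)
        assert m1.genes == m2.genes and m1.cells == m2.cells
        assert (m1.counts == m2.counts).all()

    def test_hamming1_never_exceeds_exact(self):
        rng = np.random.default_rng(9)
        reads = [
            tag("C1", "".join("ACGT"[i] for i in rng.integers(0, 4, 8)), "g1")
            for _ in range(500)
        ]
        exact = ps.count_umis(reads, collapse="exact").counts
        merged = ps.count_umis(reads, collapse="hamming1").counts
        assert (merged <= exact).all()

    def test_collision_loss_matches_analytic_expectation(self):
        # distinct-UMI expectation when m molecules draw from U = 4^8 codes
        rng = np.random.default_rng(11)
        U = 4 ** 8
        m = 20_000
        reads = []
        for _ in range(m):
            c = int(rng.integers(0, U))
            s = []
            for _ in range(8):
                s.append("ACGT"[c & 3])
                c >>= 2
            reads.append(tag("C1", "".join(s), "g1"))
        observed = ps.count_umis(reads, collapse="exact").counts[0, 0]
        q = 1.0 - 1.0 / U
        expect = U * (1.0 - q ** m)
        var = U * (q ** m - (1 - 2 / U) ** m) + U * U * ((1 - 2 / U) ** m - q ** (2 * m))
        assert abs(observed - expect) <= 3 * np.sqrt(var) + 1e-9

    def test_whitelist_restricts_cells(self):
        reads = [tag("GOOD", "AAAAAAAA", "g1"), tag("BAD", "AAAAAAAA", "g1")]
        m = ps.count_umis(reads, whitelist=["GOOD", "EMPTY"])
        assert m.cells == ["GOOD", "EMPTY"]
        assert m.counts[:, 1].sum() == 0

    def test_empty_gene_rejected(self):
        with pytest.raises(ValueError):
            ps.count_umis([tag("C1", "AAAAAAAA", "")])


class TestCountReads:
    def test_read_counts_dominate_umi_counts(self):
        reads = [tag("C1", "AAAAAAAA", "g1")] * 5 + [
            tag("C1", "AAAAAAAT", "g1"),
            tag("C1", "CCCCCCCC", "g1"),
        ]
        r = ps.count_reads(reads)
        u = ps.count_umis(reads, collapse="exact")
        assert r.counts.tolist() == [[7]]
        assert u.counts.tolist() == [[3]]
        assert (r.counts >= u.counts).all()


class TestFilterCells:
    def _matrix(self):
        counts = np.zeros((7, 3), dtype=np.int64)
        counts[:3, 0] = 1
        counts[:5, 1] = 1
        counts[:7, 2] = 1
        return ps.DigitalExpressionMatrix(
            genes=[f"g{i}" for i in range(7)], cells=["a", "b", "c"], counts=counts
        )

    def test_min_genes_zero_is_identity(self):
        m = self._matrix()
        out = ps.filter_cells(m, 0)
        assert out.cells == m.cells

    def test_boundary_inclusive(self):
        out = ps.filter_cells(self._matrix(), 5)
        assert out.cells == ["b", "c"]

    def test_all_removed_warns(self):
        with pytest.warns(UserWarning, match="all cells removed"):
            out = ps.filter_cells(self._matrix(), 100)
        assert out.cells == []


class TestNormalize:
    def test_single_cell_closed_form(self):
        m = ps.DigitalExpressionMatrix(genes=["g1"], cells=["c1"],
                                       counts=np.array([[10]]))
        norm = ps.normalize(m, scale_target=10_000)
        assert norm.values[0, 0] == pytest.approx(np.log(10_001))

    def test_column_sums_hit_target(self):
        rng = np.random.default_rng(13)
        counts = rng.poisson(5, size=(50, 20))
        counts[0] += 1  # no zero-total cells
        m = ps.DigitalExpressionMatrix(
            genes=[f"g{i}" for i in range(50)], cells=[f"c{i}" for i in range(20)],
            counts=counts,
        )
        norm = ps.normalize(m, scale_target=10_000)
        recovered = (np.exp(norm.values) - 1).sum(axis=0)
        np.testing.assert_allclose(recovered, 10_000, rtol=1e-9)

    def test_mean_total_target(self):
        counts = np.array([[4, 8], [6, 2]])
        m = ps.DigitalExpressionMatrix(genes=["g1", "g2"], cells=["a", "b"], counts=counts)
        norm = ps.normalize(m, scale_target="mean_total")
        assert norm.scale_target == 10.0

    def test_gene_scaling_moments(self):
        rng = np.random.default_rng(17)
        counts = rng.poisson(5, size=(30, 40)) + 1
        m = ps.DigitalExpressionMatrix(
            genes=[f"g{i}" for i in range(30)], cells=[f"c{i}" for i in range(40)],
            counts=counts,
        )
        norm = ps.normalize(m, scale_genes=True)
        np.testing.assert_allclose(norm.values.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(norm.values.var(axis=1), 1, atol=1e-9)

    def test_zero_total_cell_rejected(self):
        m = ps.DigitalExpressionMatrix(
            genes=["g1"], cells=["a", "b"], counts=np.array([[3, 0]])
        )
        with pytest.raises(ValueError, match="filter_cells"):
            ps.normalize(m)


class TestMatrixIO:
    def _matrix(self):
        rng = np.random.default_rng(19)
        return ps.DigitalExpressionMatrix(
            genes=[f"g{i}" for i in range(10)], cells=[f"c{i}" for i in range(4)],
            counts=rng.poisson(2, size=(10, 4)),
        )

    def test_mtx_round_trip(self, tmp_path):
        m = self._matrix()
        m.write_mtx(tmp_path / "mat")
        back = ps.DigitalExpressionMatrix.read_mtx(tmp_path / "mat")
        assert back.genes == m.genes and back.cells == m.cells
        assert (back.counts == m.counts).all()

    def test_tsv_round_trip(self, tmp_path):
        m = self._matrix()
        m.write_tsv(tmp_path / "mat.tsv")
        back = ps.DigitalExpressionMatrix.read_tsv(tmp_path / "mat.tsv")
        assert (back.counts == m.counts).all()

    def test_tagged_tsv_reader(self, tmp_path):
        path = tmp_path / "tagged.tsv"
        path.write_text("cell_barcode\tumi\tgene\nC1\tAAAAAAAA\tg1\n")
        reads = ps.read_tagged_tsv(path)
        assert reads == [ps.GeneTaggedRead("C1", "AAAAAAAA", "g1", None)]

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="non-negative"):
            ps.DigitalExpressionMatrix(genes=["g"], cells=["c"], counts=np.array([[-1]]))
        m = self._matrix()
        assert (m.cell_totals == m.counts.sum(axis=0)).all()
        assert (m.genes_per_cell == (m.counts > 0).sum(axis=0)).all()

    def test_mito_fraction(self):
        m = ps.DigitalExpressionMatrix(
            genes=["mt-Co1", "Actb"], cells=["c1"], counts=np.array([[2], [8]])
        )
        assert ps.mito_fraction(m)["c1"] == pytest.approx(0.2)
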