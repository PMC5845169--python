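import numpy as np
import pandas as pd
import pytest

import plateseq as ps


def matrix_from(counts, genes=None, cells=None):
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    cells = cells or [f"c{i}" for i in range(counts.shape[1])]
    return ps.DigitalExpressionMatrix(genes=genes, cells=cells, counts=counts)


def ercc_reference(molecules: dict[str, float]) -> ps.ERCCReference:
    return ps.ERCCReference(
        table=pd.DataFrame({"input_molecules": pd.Series(molecules, dtype=float)})
    )


class TestConversionEfficiency:
    def test_discussion_arithmetic(self):
        # 11,000 UMIs from 24,000 reads vs the same from 169,000 reads
        m = matrix_from([[11_000]], cells=["c1"])
        high = ps.umi_conversion_efficiency(24_000, m)
        low = ps.umi_conversion_efficiency(169_000, m)
        assert high.mean_percent == pytest.approx(45.8, abs=0.05)
        assert low.mean_percent == pytest.approx(6.5, abs=0.05)
        # same UMI yield costs sevenfold the reads
        assert 169_000 / 24_000 == pytest.approx(7.0, abs=0.1)

    def test_bookkeeping_identity(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(10, size=(20, 8))
        m = matrix_from(counts)
        reads_per_cell = rng.integers(1000, 2000, size=8).astype(float)
        stats = ps.umi_conversion_efficiency(reads_per_cell, m)
        np.testing.assert_allclose(
            stats.per_cell["efficiency"], counts.sum(axis=0) / reads_per_cell
        )

    def test_zero_umis_gives_zero(self):
        m = matrix_from([[0]])
        stats = ps.umi_conversion_efficiency(100, m)
        assert stats.mean_efficiency == 0.0

    def test_zero_reads_rejected(self):
        with pytest.raises(ValueError):
            ps.umi_conversion_efficiency(0, matrix_from([[5]]))

    def test_equal_split_of_total(self):
        m = matrix_from([[10, 10]])
        stats = ps.umi_conversion_efficiency(200, m)
        np.testing.assert_allclose(stats.per_cell["initial_reads"], 100.0)

    def test_monotone_in_byproduct_reads(self):
        m = matrix_from([[500]])
        effs = [
            ps.umi_conversion_efficiency(1000 + extra, m).mean_efficiency
            for extra in (0, 100, 500, 2000)
        ]
        assert effs == sorted(effs, reverse=True)


class TestCaptureEfficiency:
    def test_binomial_simulation_recovers_p(self):
        rng = np.random.default_rng(5)
        p, n_cells = 0.05, 384
        molecules = {f"ERCC-{i:05d}": float(m) for i, m in
                     enumerate([10, 30, 100, 300, 1000, 3000])}
        counts = np.vstack([
            rng.binomial(int(m), p, size=n_cells) for m in molecules.values()
        ])
        m = matrix_from(counts, genes=list(molecules))
        slope = ps.ercc_capture_efficiency(m, ercc_reference(molecules))
        x = np.array(list(molecules.values()))
        se = np.sqrt((x ** 2 * x * p * (1 - p) / n_cells).sum()) / (x ** 2).sum()
        assert abs(slope - p) <= 3 * se

    def test_all_zero_counts_give_zero_slope(self):
        molecules = {f"ERCC-{i}": 10.0 * (i + 1) for i in range(4)}
        m = matrix_from(np.zeros((4, 10), dtype=int), genes=list(molecules))
        assert ps.ercc_capture_efficiency(m, ercc_reference(molecules)) == 0.0

    def test_estimator_unbiased_over_replicates(self):
        rng = np.random.default_rng(7)
        p, n_cells = 0.05, 64
        molecules = {f"ERCC-{i}": float(m) for i, m in enumerate([20, 80, 400, 2000])}
        x = np.array(list(molecules.values()))
        se_one = np.sqrt((x ** 2 * x * p * (1 - p) / n_cells).sum()) / (x ** 2).sum()
        slopes = []
        for _ in range(100):
            counts = np.vstack([
                rng.binomial(int(m), p, size=n_cells) for m in x
            ])
            slopes.append(
                ps.ercc_capture_efficiency(matrix_from(counts, genes=list(molecules)),
                                           ercc_reference(molecules))
            )
        bias = np.mean(slopes) - p
        assert abs(bias) <= 2 * se_one / np.sqrt(100)

    def test_too_few_species_rejected(self):
        molecules = {"ERCC-1": 10.0, "ERCC-2": 20.0}
        m = matrix_from(np.ones((2, 5), dtype=int), genes=list(molecules))
        with pytest.raises(ValueError, match=">= 3"):
            ps.ercc_capture_efficiency(m, ercc_reference(molecules))

    def test_no_ercc_rows_rejected(self):
        m = matrix_from([[1]], genes=["Actb"])
        with pytest.raises(ValueError, match="no ERCC"):
            ps.ercc_capture_efficiency(m, ercc_reference({"ERCC-1": 5.0}))


class TestHalfDetection:
    @staticmethod
    def _simulate(midpoint, rng, n_cells=400, slope=3.0,
                  mols=(0.5, 1, 2, 4, 7, 12, 25, 50, 200)):
        molecules = {f"ERCC-{i:05d}": float(m) for i, m in enumerate(mols)}
        probs = 1 / (1 + np.exp(-slope * (np.log10(list(molecules.values()))
                                          - np.log10(midpoint))))
        counts = np.vstack([
            rng.binomial(1, p, size=n_cells) for p in probs
        ])
        return matrix_from(counts, genes=list(molecules)), ercc_reference(molecules)

    def test_recovers_known_midpoint(self):
        rng = np.random.default_rng(11)
        m, ref = self._simulate(7.0, rng)
        curve = ps.molecules_at_half_detection(m, ref)
        assert curve.m50 == pytest.approx(7.0, rel=0.2)

    def test_symmetric_single_species_design(self):
        # one species at exactly half detection flanked by a symmetric design
        molecules = {"ERCC-A": 2.0, "ERCC-B": 8.0, "ERCC-C": 32.0}
        counts = np.zeros((3, 100), dtype=int)
        counts[0, :10] = 1   # low species: 10%
        counts[1, :50] = 1   # middle species: exactly 50%
        counts[2, :90] = 1   # high species: 90%
        m = matrix_from(counts, genes=list(molecules))
        curve = ps.molecules_at_half_detection(m, ercc_reference(molecules))
        assert curve.m50 == pytest.approx(8.0, rel=0.05)

    def test_downsampling_increases_m50(self):
        rng = np.random.default_rng(13)
        molecules = {f"ERCC-{i:05d}": float(m) for i, m in
                     enumerate([1, 3, 7, 15, 40, 100, 400])}
        full = np.vstack([
            rng.binomial(int(m), 0.1, size=500) for m in molecules.values()
        ])
        thinned = rng.binomial(full, 0.5)
        ref = ercc_reference(molecules)
        m50_full = ps.molecules_at_half_detection(matrix_from(full, genes=list(molecules)), ref).m50
        m50_half = ps.molecules_at_half_detection(matrix_from(thinned, genes=list(molecules)), ref).m50
        assert m50_half > m50_full

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(17)
        m, ref = self._simulate(7.0, rng)
        curve = ps.molecules_at_half_detection(m, ref)
        grid = np.logspace(-1, 3, 50)
        pred = curve.predict(grid)
        assert (np.diff(pred) >= 0).all()
        assert curve.predict(np.array([curve.m50]))[0] == pytest.approx(0.5)

    def test_no_bracketing_rejected(self):
        molecules = {"ERCC-A": 100.0, "ERCC-B": 200.0, "ERCC-C": 400.0}
        counts = np.ones((3, 20), dtype=int)  # everything detected everywhere
        m = matrix_from(counts, genes=list(molecules))
        with pytest.raises(ValueError, match="bracket"):
            ps.molecules_at_half_detection(m, ercc_reference(molecules))


class TestReference:
    def test_molecules_per_well_conversion(self):
        # 1 attomole/uL at 1:10 dilution, 1 uL delivered
        got = ps.molecules_per_well(1.0, dilution=0.1, volume_ul=1.0)
        assert got == pytest.approx(1e-18 * 6.02214076e23 * 0.1)

    def test_reader_accepts_both_schemas(self, tmp_path):
        p1 = tmp_path / "a.tsv"
        p1.write_text("ercc_id\tmolecules_per_well\nERCC-1\t50\n")
        assert ps.read_ercc_reference(p1).table.loc["ERCC-1", "input_molecules"] == 50
        p2 = tmp_path / "b.tsv"
        p2.write_text("ercc_id\tattomoles_per_ul\nERCC-1\t2.0\n")
        ref = ps.read_ercc_reference(p2, dilution=0.1, volume_ul=6.0)
        assert ref.table.loc["ERCC-1", "input_molecules"] == pytest.approx(
            2.0 * 1e-18 * 6.02214076e23 * 0.1 * 6.0
        )

    def test_nonpositive_molecules_rejected(self):
        with pytest.raises(ValueError):
            ps.ERCCReference(table=pd.DataFrame({"input_molecules": [0.0]}))
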