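"""QC filter semantics and allele-dropout estimation."""

import numpy as np
import pytest

from clonotracer import (
    ADORateEstimator,
    CloneSpec,
    GenotypeQC,
    MISSING,
    QCConfig,
    QCError,
    SimulationConfig,
    apply_qc,
    estimate_ado,
    filter_cells,
    filter_variants,
    mask_low_confidence_calls,
    simulate_experiment,
)

from conftest import make_matrix, make_small_panel, random_matrix


def brute_force_mask_count(mat, cfg):
    n = 0
    for i in range(mat.n_cells):
        for j in range(mat.n_variants):
            if mat.genotypes[i, j] == MISSING:
                continue
            if mat.depth[i, j] < cfg.min_depth or mat.quality[i, j] < cfg.min_variant_quality:
                n += 1
    return n


class TestMasking:
    def test_depth_boundary_is_inclusive(self):
        mat = make_matrix([[1, 1]], depth=[[9, 10]], quality=[[60, 60]])
        out, rep = mask_low_confidence_calls(mat, QCConfig(min_depth=10))
        assert out.genotypes[0, 0] == MISSING      # 9 < 10 -> masked
        assert out.genotypes[0, 1] == 1            # 10 passes
        assert rep.calls_masked_low_depth == 1

    def test_quality_boundary_is_inclusive(self):
        mat = make_matrix([[1, 1]], depth=[[50, 50]], quality=[[30, 29]])
        out, _ = mask_low_confidence_calls(mat, QCConfig(min_variant_quality=30))
        assert out.genotypes[0, 0] == 1            # quality 30 retained
        assert out.genotypes[0, 1] == MISSING

    def test_raw_depth_retained_after_masking(self):
        mat = make_matrix([[1]], depth=[[3]], quality=[[60]])
        out, _ = mask_low_confidence_calls(mat)
        assert out.genotypes[0, 0] == MISSING and out.depth[0, 0] == 3

    def test_masked_count_matches_brute_force(self, rng):
        cfg = QCConfig()
        for _ in range(5):
            mat = random_matrix(rng, 200, 20)
            out, rep = mask_low_confidence_calls(mat, cfg)
            expected = brute_force_mask_count(mat, cfg)
            assert rep.calls_masked_low_depth + rep.calls_masked_low_quality >= expected
            # exact equality on entries masked (an entry can fail both filters)
            newly_missing = int(((out.genotypes == MISSING)
                                 & (mat.genotypes != MISSING)).sum())
            assert newly_missing == expected


class TestCellFilter:
    def test_strict_inequality_at_threshold(self):
        # 40 variants; 3 missing = 7.5% retained, 4 missing = 10% excluded
        g = np.zeros((2, 40), dtype=np.int8)
        g[0, :3] = MISSING
        g[1, :4] = MISSING
        mat = make_matrix(g)
        out, _ = filter_cells(mat, QCConfig())
        assert out.cell_ids == ["c000"]

    def test_all_cells_removed_is_error(self):
        g = np.full((3, 4), MISSING, dtype=np.int8)
        with pytest.raises(QCError, match="no cells survive"):
            filter_cells(make_matrix(g), QCConfig())

    def test_retained_set_matches_recount(self, rng):
        cfg = QCConfig(max_cell_missing_fraction=0.2)
        for _ in range(10):
            mat = random_matrix(rng, 50, 12, missing_rate=0.2)
            out, _ = filter_cells(mat, cfg)
            expected = [
                cid for cid, row in zip(mat.cell_ids, mat.genotypes)
                if (row == MISSING).mean() <= 0.2
            ]
            assert out.cell_ids == expected


class TestVariantFilter:
    def test_vacuous_threshold_removes_nothing(self, rng):
        mat = random_matrix(rng, 20, 8, missing_rate=0.5)
        out, _ = filter_variants(mat, QCConfig(max_variant_missing_fraction=1.0))
        assert out.n_variants == 8

    def test_fully_missing_variant_removed(self):
        g = np.zeros((4, 2), dtype=np.int8)
        g[:, 1] = MISSING
        out, _ = filter_variants(make_matrix(g),
                                 QCConfig(max_variant_missing_fraction=0.5))
        assert out.n_variants == 1

    def test_surviving_set_matches_recount(self, rng):
        cfg = QCConfig(max_variant_missing_fraction=0.3)
        for _ in range(10):
            mat = random_matrix(rng, 40, 15, missing_rate=0.3)
            out, _ = filter_variants(mat, cfg)
            expected = [
                v.id for v, col in zip(mat.variants, mat.genotypes.T)
                if (col == MISSING).mean() <= 0.3
            ]
            assert [v.id for v in out.variants] == expected


class TestFilterProperties:
    def test_monotone_in_thresholds(self, rng):
        mat = random_matrix(rng, 100, 15)
        loose, _ = apply_qc(mat, QCConfig(min_depth=5, min_variant_quality=10,
                                          max_cell_missing_fraction=0.5))
        tight, _ = apply_qc(mat, QCConfig(min_depth=20, min_variant_quality=40,
                                          max_cell_missing_fraction=0.5))
        assert tight.n_cells <= loose.n_cells
        assert tight.n_called() <= loose.n_called()

    def test_idempotent(self, rng):
        cfg = QCConfig(max_cell_missing_fraction=0.3)
        mat = random_matrix(rng, 80, 12)
        once, _ = apply_qc(mat, cfg)
        twice, _ = apply_qc(once, cfg)
        assert twice == once

    def test_transformer_wrapper_params(self, rng):
        mat = random_matrix(rng, 30, 10)
        qc = GenotypeQC(min_depth=5, max_cell_missing_fraction=0.5)
        assert qc.get_params()["min_depth"] == 5
        out = qc.fit(mat).transform(mat)
        direct, _ = apply_qc(mat, QCConfig(min_depth=5,
                                           max_cell_missing_fraction=0.5))
        assert out == direct
        assert qc.report_.cells_out == out.n_cells


class TestAdoEstimate:
    def make_control_matrix(self, calls):
        """calls: cells x 3 control-locus genotype codes."""
        panel = make_small_panel(n_common=0, n_pathogenic=0, n_controls=3)
        return make_matrix(calls, panel=panel)

    def test_all_het_gives_zero(self):
        mat = self.make_control_matrix(np.ones((100, 3), dtype=np.int8))
        assert estimate_ado(mat).mean_rate == 0.0

    def test_ten_percent_arithmetic(self):
        calls = np.ones((100, 3), dtype=np.int8)
        calls[:10, 0] = 0
        calls[:10, 1] = 2
        calls[:5, 2] = 0
        calls[5:10, 2] = 2
        est = estimate_ado(self.make_control_matrix(calls))
        assert est.mean_rate == pytest.approx(0.10)
        assert est.n_loci == 3
        assert all(r == pytest.approx(0.10) for r in est.per_locus_rate.values())

    def test_missing_excluded_from_denominator(self):
        calls = np.ones((10, 3), dtype=np.int8)
        calls[0, :] = MISSING
        calls[1, :] = 0
        est = estimate_ado(self.make_control_matrix(calls))
        assert est.mean_rate == pytest.approx(1 / 9)

    def test_too_few_control_loci_is_error(self):
        panel = make_small_panel(n_common=2, n_pathogenic=0, n_controls=2)
        mat = make_matrix(np.ones((5, 4), dtype=np.int8), panel=panel)
        with pytest.raises(QCError, match="at least 3"):
            estimate_ado(mat)

    def test_uncalled_locus_dropped_with_error_below_minimum(self):
        calls = np.ones((10, 3), dtype=np.int8)
        calls[:, 2] = MISSING
        with pytest.raises(QCError, match="at least 3"):
            estimate_ado(self.make_control_matrix(calls))

    def test_recovery_from_simulation(self):
        cfg = SimulationConfig(
            timepoints=("t0",), n_cells_per_timepoint=(2000,),
            donor_fraction_per_timepoint=(0.0,),
            clone_table={"only": CloneSpec((1.0,), {})},
            ado_rate=0.08, seed=13,
        )
        mats, truth = simulate_experiment(cfg)
        filtered, _ = apply_qc(mats[0])
        est = ADORateEstimator().fit(filtered)
        n_calls = filtered.n_cells * est.n_loci_
        se = np.sqrt(0.08 * 0.92 / n_calls)
        assert abs(est.mean_rate_ - 0.08) <= 3 * se
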