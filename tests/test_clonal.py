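"""Genotype distances, clone calling, longitudinal matching and flagging."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import adjusted_rand_score

from clonotracer import (
    CloneCaller,
    CloneSpec,
    MISSING,
    SimulationConfig,
    apply_qc,
    cluster_cells,
    flag_expanding_oncogenic_clones,
    genotype_distance,
    heatmap_frame,
    match_clones,
    pairwise_genotype_distances,
    simulate_experiment,
)

from conftest import make_matrix, make_small_panel


def brute_force_distance(a, b):
    p = len(a)
    shared = [(x, y) for x, y in zip(a, b) if x != MISSING and y != MISSING]
    if not shared:
        return None
    d2 = sum((x - y) ** 2 for x, y in shared)
    return np.sqrt(d2 * p / len(shared))


class TestGenotypeDistance:
    def test_identical_vectors_zero(self):
        a = np.array([0, 1, 2, 0, 1])
        assert genotype_distance(a, a) == 0.0

    def test_single_wt_to_hom_difference(self):
        a = np.zeros(20)
        b = a.copy()
        b[0] = 2
        assert genotype_distance(a, b) == pytest.approx(2.0)

    def test_zero_variants_is_error(self):
        with pytest.raises(ValueError):
            genotype_distance(np.array([]), np.array([]))

    def test_no_shared_loci_is_inf_pairwise_maxplus1(self):
        codes = np.array([
            [0, MISSING, MISSING],
            [MISSING, 1, MISSING],
            [0, 1, 2],
        ])
        assert genotype_distance(codes[0], codes[1]) == np.inf
        d = pairwise_genotype_distances(codes)
        finite = [d[0, 2], d[1, 2]]
        assert d[0, 1] == pytest.approx(max(finite) + 1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_pairwise_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.choice([-1, 0, 1, 2], size=(8, 6),
                           p=[0.2, 0.4, 0.25, 0.15])
        d = pairwise_genotype_distances(codes)
        expected = np.zeros_like(d)
        missing_pairs = []
        for i in range(8):
            for j in range(8):
                if i == j:
                    continue
                bf = brute_force_distance(codes[i], codes[j])
                if bf is None:
                    missing_pairs.append((i, j))
                else:
                    expected[i, j] = bf
        if missing_pairs:
            mx = expected.max() + 1.0
            for i, j in missing_pairs:
                expected[i, j] = mx
        np.testing.assert_allclose(d, expected, atol=1e-9)


class TestCloneCaller:
    def test_two_groups_one_locus_k2_exact(self):
        g = np.zeros((20, 5), dtype=np.int8)
        g[10:, 0] = 2
        cs = cluster_cells(make_matrix(g), k=2)
        truth = np.repeat([0, 1], 10)
        assert adjusted_rand_score(truth, cs.labels) == 1.0

    def test_identical_cells_auto_k_is_one(self):
        g = np.ones((15, 6), dtype=np.int8)
        cs = cluster_cells(make_matrix(g))
        assert cs.n_clones == 1

    def test_simulation_recovery_auto_k(self):
        table = {
            "a": CloneSpec((0.4,), {}),
            "b": CloneSpec((0.35,), {0: 2, 1: 2, 2: 2, 3: 2, 4: 2}),
            "c": CloneSpec((0.25,), {3: 1, 4: 2}),
        }
        cfg = SimulationConfig(
            timepoints=("t0",), n_cells_per_timepoint=(2000,),
            donor_fraction_per_timepoint=(0.0,), n_pathogenic=5,
            clone_table=table, ado_rate=0.1, missing_rate=0.02, seed=3,
        )
        mats, truth = simulate_experiment(cfg)
        filtered, _ = apply_qc(mats[0])
        cs = cluster_cells(filtered)
        labels_true = truth.labels_for(cs.cell_ids, "clone")
        assert cs.n_clones == 3
        assert adjusted_rand_score(labels_true, cs.labels) >= 0.95

    def test_frequencies_sum_to_one(self, default_experiment):
        _, mats, _ = default_experiment
        filtered, _ = apply_qc(mats[1])
        cs = cluster_cells(filtered, k=3)
        assert sum(cs.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
        assert len(np.unique(cs.labels)) == cs.n_clones

    def test_order_invariance(self, rng):
        g = np.zeros((60, 8), dtype=np.int8)
        g[20:40, :3] = 2
        g[40:, 5:] = 1
        mat = make_matrix(g)
        cs = cluster_cells(mat, k=3)
        perm = rng.permutation(60)
        cs_p = cluster_cells(mat.subset_cells(perm), k=3)
        inverse = np.empty(60, dtype=int)
        inverse[perm] = np.arange(60)
        assert adjusted_rand_score(cs.labels, cs_p.labels[inverse]) == 1.0

    def test_estimator_api(self):
        g = np.zeros((12, 4), dtype=np.int8)
        g[6:, 0] = 2
        caller = CloneCaller(k=2)
        assert caller.get_params()["k"] == 2
        labels = caller.fit_predict(g)
        assert caller.n_clusters_ == 2
        assert caller.signatures_.shape == (2, 4)
        assert set(labels) == {0, 1}


class TestMatchClones:
    def run_sets(self, seed=19):
        cfg = SimulationConfig(seed=seed, n_cells_per_timepoint=(600, 600, 600))
        mats, truth = simulate_experiment(cfg)
        sets = []
        for m, k in zip(mats, (2, 3, 3)):
            f, _ = apply_qc(m)
            sets.append(cluster_cells(f, k=k))
        return sets, truth, mats

    def test_identity_matching_and_new_lineage(self):
        sets, truth, mats = self.run_sets()
        table = match_clones(sets)
        # donor population appears only from post-BMT on: a new lineage with
        # a leading zero
        donor_like = [
            lin for lin in table.lineages
            if table.frequencies.loc[lin, "pre_bmt"] == 0.0
            and table.frequencies.loc[lin, "post_bmt"] > 0.3
        ]
        assert len(donor_like) == 1
        # each column sums to <= 1
        assert (table.frequencies.sum(axis=0) <= 1.0 + 1e-9).all()

    def test_matched_lineage_tracks_truth(self):
        sets, truth, mats = self.run_sets()
        table = match_clones(sets)
        onc = [lin for lin in table.lineages if table.pathogenic[lin]]
        assert len(onc) == 1
        for cs in sets:
            true_frac = (truth.labels_for(cs.cell_ids, "clone")
                         == "oncogenic").mean()
            got = table.frequencies.loc[onc[0], cs.timepoint]
            assert abs(got - true_frac) <= 0.03

    def test_reversal_symmetry(self):
        sets, _, _ = self.run_sets()
        fwd = match_clones(sets)
        rev = match_clones(list(reversed(sets)))
        fwd_pairs = {
            frozenset((tp, c) for tp, c in mem.items())
            for mem in fwd.members.values()
        }
        rev_pairs = {
            frozenset((tp, c) for tp, c in mem.items())
            for mem in rev.members.values()
        }
        assert fwd_pairs == rev_pairs

    def test_single_timepoint_is_error(self):
        sets, _, _ = self.run_sets()
        with pytest.raises(ValueError):
            match_clones(sets[:1])


class TestFlagging:
    @staticmethod
    def toy_table(freqs, pathogenic):
        import pandas as pd
        from clonotracer import EvolutionTable

        names = list(freqs)
        df = pd.DataFrame(freqs).T
        df.columns = [f"t{i}" for i in range(df.shape[1])]
        return EvolutionTable(
            frequencies=df,
            pathogenic=pd.Series(pathogenic),
            members={n: {} for n in names},
            variants=make_small_panel(),
        )

    def test_expanding_pathogenic_lineage_flagged(self):
        table = self.toy_table(
            {"L01": [0.09, 0.42, 0.70], "L02": [0.91, 0.58, 0.30]},
            {"L01": True, "L02": False},
        )
        flagged, ann = flag_expanding_oncogenic_clones(table)
        assert flagged == ["L01"]
        assert ann["L01"] == "expanding" and ann["L02"] == "contracting"

    def test_flat_pathogenic_lineage_not_flagged(self):
        table = self.toy_table(
            {"L01": [0.05, 0.052, 0.049], "L02": [0.95, 0.948, 0.951]},
            {"L01": True, "L02": False},
        )
        flagged, ann = flag_expanding_oncogenic_clones(table)
        assert flagged == []
        assert ann["L01"] == "stable"

    def test_wildtype_increasing_lineage_not_flagged(self):
        table = self.toy_table(
            {"L01": [0.1, 0.4, 0.8], "L02": [0.9, 0.6, 0.2]},
            {"L01": False, "L02": False},
        )
        flagged, _ = flag_expanding_oncogenic_clones(table)
        assert flagged == []


class TestHeatmapExport:
    def test_leaf_order_and_annotations(self, default_experiment):
        _, mats, truth = default_experiment
        filtered, _ = apply_qc(mats[0])
        cs = cluster_cells(filtered, k=2)
        origins = truth.labels_for(filtered.cell_ids, "origin")
        df = heatmap_frame(filtered, cs, origins=origins)
        assert len(df) == filtered.n_cells
        assert list(df.columns[:2]) == ["clone", "origin"]
        assert set(df.index) == set(filtered.cell_ids)
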