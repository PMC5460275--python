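import warnings

import numpy as np
import pytest

from palmgs.containers import GenotypeMatrix
from palmgs.evaluate import make_cv_plan, run_cv
from palmgs.reduce import (
    AccuracyCurve,
    ld_filtered_curve,
    ld_prune_ranked,
    ld_r2,
    optimal_density,
    rrblup_b_curve,
)

from conftest import unrelated_genotypes


class TestLDR2:
    def test_identical_and_flipped_vectors(self):
        g = np.array([0, 1, 2, 1, 0, 2])
        assert ld_r2(g, g) == pytest.approx(1.0)
        assert ld_r2(g, 2 - g) == pytest.approx(1.0)

    def test_hand_oracle(self):
        # Pearson r of (0,1,1,2) vs (0,1,2,2) is sqrt(8/11)
        assert ld_r2([0, 1, 1, 2], [0, 1, 2, 2]) == pytest.approx(8 / 11, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2([1, 1, 1, 1], [0, 1, 2, 0])


class TestPrune:
    def _G(self, dosages):
        dosages = np.asarray(dosages)
        m = dosages.shape[1]
        return GenotypeMatrix(
            dosages,
            np.array([f"m{j}" for j in range(m)], dtype=object),
            np.ones(m, dtype=int),
            np.arange(m, dtype=float),
            np.array([f"i{k}" for k in range(len(dosages))], dtype=object),
        )

    def test_nothing_pruned_below_cutoff(self):
        G = unrelated_genotypes(200, 10, seed=1)
        res = ld_prune_ranked(G, np.arange(10), r2_cutoff=0.6)
        assert len(res.kept) == 10 and len(res.dropped) == 0

    def test_duplicate_markers_keep_rank_priority(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, 50)
        other = rng.integers(0, 3, 50)
        G = self._G(np.column_stack([base, base, other]))
        res = ld_prune_ranked(G, np.array([1, 0, 2]), r2_cutoff=0.6)
        assert list(res.kept) == [1, 2]
        assert list(res.dropped) == [0]
        assert res.dropped_against[0] == 1

    def test_greedy_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        base = rng.integers(0, 3, 200).astype(float)
        cols = [
            base,
            np.clip(base + (rng.random(200) < 0.1), 0, 2),  # high LD with 0
            rng.integers(0, 3, 200),
            np.clip(base + (rng.random(200) < 0.4) * rng.integers(-1, 2, 200), 0, 2),
            rng.integers(0, 3, 200),
        ]
        D = np.column_stack(cols).astype(int)
        G = self._G(D)
        ranked = np.array([0, 1, 2, 3, 4])
        res = ld_prune_ranked(G, ranked, r2_cutoff=0.6)
        # independent brute-force greedy oracle
        kept = []
        for j in ranked:
            if all(ld_r2(D[:, j], D[:, k]) < 0.6 for k in kept):
                kept.append(j)
        assert list(res.kept) == kept

    def test_invariant_to_appending_dropped_markers(self):
        rng = np.random.default_rng(4)
        base = rng.integers(0, 3, 100)
        G = self._G(np.column_stack([base, base, rng.integers(0, 3, 100)]))
        first = ld_prune_ranked(G, np.array([0, 1, 2]), r2_cutoff=0.6)
        again = ld_prune_ranked(
            G, np.concatenate([first.kept, first.dropped]), r2_cutoff=0.6
        )
        assert list(again.kept) == list(first.kept)

    def test_cutoff_one_disables_filter(self):
        rng = np.random.default_rng(5)
        base = rng.integers(0, 3, 60)
        G = self._G(np.column_stack([base, base]))
        res = ld_prune_ranked(G, np.array([0, 1]), r2_cutoff=1.0)
        assert list(res.kept) == [0, 1]


class TestOptimalDensity:
    def _curve(self, acc):
        counts = (np.arange(len(acc)) + 1) * 100
        return AccuracyCurve(counts, np.asarray(acc), np.zeros(len(acc)))

    def test_hand_worked_example(self):
        curve = self._curve([0.30, 0.50, 0.54, 0.56])
        assert optimal_density(curve, window=100, threshold=0.05) == 200

    def test_flat_curve_returns_first_window(self):
        curve = self._curve([0.5, 0.5, 0.5])
        assert optimal_density(curve) == 100

    def test_steep_curve_returns_max_with_warning(self):
        curve = self._curve([0.1, 0.3, 0.5, 0.7])
        with pytest.warns(UserWarning, match="max count"):
            assert optimal_density(curve) == 400


def _sim_trait(G, n_qtl, h2, seed):
    rng = np.random.default_rng(seed)
    qtl = rng.choice(G.n_markers, n_qtl, replace=False)
    eff = rng.standard_normal(n_qtl)
    tbv = G.dosages[:, qtl].astype(float) @ eff
    return tbv + rng.normal(0, np.sqrt(tbv.var() * (1 - h2) / h2), G.n_individuals)


class TestCurves:
    def test_endpoint_matches_full_marker_cv(self):
        G = unrelated_genotypes(120, 150, seed=6)
        y = _sim_trait(G, 20, 0.6, seed=6)
        plan = make_cv_plan(120, n_folds=3, seed=0)
        curve = rrblup_b_curve(G, y, plan, counts=[50, 150])
        full = run_cv(G, y, ["RRBLUP"], plan)["RRBLUP"]
        assert curve.at(150) == pytest.approx(full.mean_accuracy, abs=0.02)

    def test_single_fold_curve_has_zero_sd(self):
        G = unrelated_genotypes(60, 80, seed=7)
        y = _sim_trait(G, 10, 0.6, seed=7)

        class OneSplit:  # duck-typed plan yielding a single train/validation split
            def folds(self):
                yield 1, np.arange(20, 60), np.arange(0, 20)

        curve = rrblup_b_curve(G, y, OneSplit(), counts=[20, 40])
        assert np.all(curve.sd_accuracy == 0.0)

    def test_no_leakage_validation_phenotypes_do_not_change_ranking(self):
        G = unrelated_genotypes(100, 120, seed=8)
        y = _sim_trait(G, 15, 0.6, seed=8)
        plan = make_cv_plan(100, n_folds=4, seed=1)
        curve1 = rrblup_b_curve(G, y, plan, counts=[20, 60])
        y2 = y.copy()
        rng = np.random.default_rng(99)
        for k, train, val in plan.folds():
            if k == 1:
                y2[val] = rng.standard_normal(len(val))
                break
        curve2 = rrblup_b_curve(G, y2, plan, counts=[20, 60])
        # the noised individuals sit in fold 1's validation set, so fold 1's
        # training scan (and hence its ranking) must be bit-identical
        assert np.array_equal(curve1.fold_rankings[0], curve2.fold_rankings[0])

    def test_oligogenic_top_markers_reach_full_accuracy(self, oligo_pop):
        G, traits, _ = oligo_pop
        y = traits.values("trait", G.individual_ids)
        plan = make_cv_plan(G.n_individuals, n_folds=3, seed=2)
        curve = rrblup_b_curve(G, y, plan, counts=[60, G.n_markers])
        assert curve.at(60) >= curve.at(G.n_markers) - 0.05

    def test_permuted_phenotype_null_curve_near_zero(self):
        G = unrelated_genotypes(300, 200, seed=9)
        y = _sim_trait(G, 20, 0.6, seed=9)
        y_perm = np.random.default_rng(10).permutation(y)
        plan = make_cv_plan(300, n_folds=5, seed=3)
        curve = rrblup_b_curve(G, y_perm, plan, counts=[20, 100, 200])
        assert np.all(np.abs(curve.mean_accuracy) < 0.1)

    def test_ld_filter_disabled_gives_identical_curves(self):
        G = unrelated_genotypes(90, 100, seed=11)
        y = _sim_trait(G, 10, 0.6, seed=11)
        plan = make_cv_plan(90, n_folds=3, seed=4)
        filt, plain = ld_filtered_curve(
            G, y, plan, top_n=40, r2_cutoff=1.0, plot_n=40, step=10
        )
        np.testing.assert_allclose(filt.mean_accuracy, plain.mean_accuracy)
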