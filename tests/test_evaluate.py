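import numpy as np
import pytest

from palmgs.evaluate import (
    accuracy,
    accuracy_heritability_summary,
    make_cv_plan,
    run_cv,
    selection_response,
)
from palmgs.wgr import WGRConfig

from conftest import unrelated_genotypes


class TestCVPlan:
    def test_reproduces_published_split_arithmetic(self):
        plan = make_cv_plan(1218, n_folds=5, seed=0)
        sizes = np.bincount(plan.assignments)[1:]
        assert sorted(sizes.tolist()) == [243, 243, 244, 244, 244]
        # at least one fold yields the 975/243 training/validation split
        splits = [(1218 - s, s) for s in sizes]
        assert (975, 243) in splits

    def test_exact_division(self):
        plan = make_cv_plan(10, n_folds=5, seed=1)
        assert np.all(np.bincount(plan.assignments)[1:] == 2)

    def test_partition_property(self):
        plan = make_cv_plan(53, n_folds=4, seed=2)
        seen = np.zeros(53, dtype=int)
        for k, train, val in plan.folds():
            assert np.intersect1d(train, val).size == 0
            seen[val] += 1
        assert np.all(seen == 1)

    def test_seed_reproducibility(self):
        a = make_cv_plan(100, 5, seed=7).assignments
        b = make_cv_plan(100, 5, seed=7).assignments
        assert np.array_equal(a, b)

    def test_errors(self):
        with pytest.raises(ValueError):
            make_cv_plan(3, n_folds=5)
        with pytest.raises(ValueError):
            make_cv_plan(10, n_folds=1)


class TestAccuracy:
    def test_identity_and_sign(self):
        y = np.array([1.0, 3.0, 2.0, 5.0])
        assert accuracy(y, y) == pytest.approx(1.0)
        assert accuracy(y, -y) == pytest.approx(-1.0)

    def test_permutation_null(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(10000)
        assert abs(accuracy(y, rng.permutation(y))) < 0.05

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            accuracy([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestRunCV:
    def _trait(self, G, h2, seed, n_qtl=60):
        rng = np.random.default_rng(seed)
        qtl = rng.choice(G.n_markers, n_qtl, replace=False)
        tbv = G.dosages[:, qtl].astype(float) @ rng.standard_normal(n_qtl)
        return tbv + rng.normal(0, np.sqrt(tbv.var() * (1 - h2) / h2), len(tbv))

    def test_shared_plan_and_full_coverage(self):
        G = unrelated_genotypes(80, 100, seed=1)
        y = self._trait(G, 0.6, seed=1)
        plan = make_cv_plan(80, 4, seed=3)
        cfg = WGRConfig(method="BRR", n_iter=800, burn_in=200, seed=1)
        res = run_cv(G, y, ["RRBLUP", "BRR"], plan, config=cfg)
        t1 = res["RRBLUP"].gebv_table.sort_values("id")
        t2 = res["BRR"].gebv_table.sort_values("id")
        assert np.array_equal(t1["fold"].values, t2["fold"].values)
        assert sorted(t1["id"]) == sorted(G.individual_ids)
        assert len(t1) == 80  # every individual predicted exactly once

    def test_high_heritability_accuracy_band(self):
        # family structure puts relatives in training and validation, as in a
        # real breeding population; h2 = 0.8 should predict at r ~ 0.6-0.9
        from palmgs.simulate import SimConfig, simulate_population

        accs = []
        for seed in range(3):
            cfg = SimConfig(n_founders=12, n_families=10, progeny_per_family=40,
                            n_chromosomes=4, markers_per_chromosome=125,
                            n_qtl=100, target_h2=0.8, seed=70 + seed)
            G, traits, _ = simulate_population(cfg)
            y = traits.values("trait", G.individual_ids)
            plan = make_cv_plan(G.n_individuals, 5, seed=seed)
            accs.append(run_cv(G, y, ["RRBLUP"], plan)["RRBLUP"].mean_accuracy)
        assert 0.6 <= np.mean(accs) <= 0.9

    def test_accuracy_increases_with_heritability(self):
        G = unrelated_genotypes(300, 400, seed=50)
        plan = make_cv_plan(300, 5, seed=5)
        acc = {}
        for h2 in (0.2, 0.8):
            y = self._trait(G, h2, seed=51, n_qtl=80)
            acc[h2] = run_cv(G, y, ["RRBLUP"], plan)["RRBLUP"].mean_accuracy
        assert acc[0.8] > acc[0.2]

    def test_accuracy_bounded_by_heritability_ceiling(self):
        G = unrelated_genotypes(300, 400, seed=60)
        y = self._trait(G, 0.5, seed=60, n_qtl=80)
        plan = make_cv_plan(300, 5, seed=6)
        res = run_cv(G, y, ["RRBLUP"], plan)["RRBLUP"]
        assert res.mean_accuracy <= np.sqrt(0.5) + 0.1


class TestSelectionResponse:
    def test_forced_arithmetic(self):
        rep = selection_response(np.arange(1.0, 9.0), top_fraction=0.25)
        assert rep.response == pytest.approx(3.0)
        assert len(rep.selected_ids) == 2

    def test_constant_phenotype_gives_zero(self):
        rep = selection_response(np.full(20, 7.0), top_fraction=0.25)
        assert rep.response == 0.0

    def test_strictly_positive_for_nonconstant(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            y = rng.standard_normal(40)
            assert selection_response(y, 0.25).response > 0

    def test_minimize_orientation(self):
        y = np.arange(1.0, 9.0)
        rep = selection_response(y, 0.25, maximize=False)
        assert rep.response == pytest.approx(1.5 - 4.5)

    def test_zero_selection_errors(self):
        with pytest.raises(ValueError):
            selection_response(np.arange(4.0), top_fraction=0.05)


class TestAccuracyHeritabilitySummary:
    def test_identical_vectors_give_unit_correlation(self):
        acc = {"a": 0.4, "b": 0.6, "c": 0.8}
        r, table = accuracy_heritability_summary(acc, dict(acc))
        assert r == pytest.approx(1.0)
        assert len(table) == 3

    def test_two_traits_insufficient(self):
        with pytest.raises(ValueError, match="3 traits"):
            accuracy_heritability_summary({"a": 0.5, "b": 0.6}, {"a": 0.4, "b": 0.5})

    def test_mismatched_traits_error(self):
        with pytest.raises(ValueError, match="differ"):
            accuracy_heritability_summary(
                {"a": 0.5, "b": 0.6, "c": 0.7}, {"a": 0.4, "b": 0.5, "d": 0.6}
            )
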