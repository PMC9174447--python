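"""Evaluation protocol: Wasserstein identities against a brute-force oracle,
standard-metric definitions, the TRAIN oracle baseline, report pipeline and
KDE bandwidth sharing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from molgenlm import evalsuite as ev
from molgenlm import molio, taskdata

finite_floats = st.floats(min_value=-1e6, max_value=1e6,
                          allow_nan=False, allow_infinity=False)
samples = st.lists(finite_floats, min_size=1, max_size=30)


def sorted_difference_oracle(x, y):
    """Equal-size 1-D Wasserstein: mean |difference| of sorted values."""
    return float(np.mean(np.abs(np.sort(x) - np.sort(y))))


class TestWasserstein:
    def test_worked_example(self):
        assert ev.wasserstein_1d([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0)

    def test_translation_of_point_masses(self):
        assert ev.wasserstein_1d([0, 0], [1, 1]) == pytest.approx(1.0)

    @given(x=samples)
    @settings(derandomize=True, max_examples=50)
    def test_self_distance_zero(self, x):
        assert ev.wasserstein_1d(x, x) == pytest.approx(0.0, abs=1e-9)

    @given(x=samples, c=st.floats(min_value=-100, max_value=100,
                                  allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_shift_equals_offset(self, x, c):
        shifted = [v + c for v in x]
        assert ev.wasserstein_1d(x, shifted) == pytest.approx(abs(c), abs=1e-6)

    @given(x=samples, y=samples, c=st.floats(min_value=-100, max_value=100,
                                             allow_nan=False))
    @settings(derandomize=True, max_examples=50)
    def test_translation_equivariance_and_symmetry(self, x, y, c):
        w = ev.wasserstein_1d(x, y)
        assert w == pytest.approx(ev.wasserstein_1d(y, x), rel=1e-9, abs=1e-9)
        wt = ev.wasserstein_1d([v + c for v in x], [v + c for v in y])
        assert wt == pytest.approx(w, rel=1e-6, abs=1e-6)

    def test_triangle_inequality_random_triples(self, rng):
        for _ in range(50):
            x, y, z = (rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), 40)
                       for _ in range(3))
            assert ev.wasserstein_1d(x, z) <= \
                ev.wasserstein_1d(x, y) + ev.wasserstein_1d(y, z) + 1e-9

    def test_equal_size_matches_sorted_difference_oracle(self, rng):
        for _ in range(20):
            x = rng.normal(0, 3, 100)
            y = rng.normal(1, 2, 100)
            assert ev.wasserstein_1d(x, y) == pytest.approx(
                sorted_difference_oracle(x, y), rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ev.wasserstein_1d([], [1.0])


class TestStandardMetrics:
    def test_validity_fraction(self):
        raws = ["CCO"] * 9 + ["c1ccccc"]
        rep = ev.standard_metrics(raws, "smiles", molio.MoleculeSet())
        assert rep.validity == pytest.approx(0.9)

    def test_uniqueness_over_valid(self):
        rep = ev.standard_metrics(["CCO", "OCC", "CCC"], "smiles",
                                  molio.MoleculeSet())
        assert rep.uniqueness == pytest.approx(2 / 3)

    def test_novelty_over_unique(self):
        train = molio.molecule_set(["CCO"])
        rep = ev.standard_metrics(["CCO", "CCC", "CCN"], "smiles", train)
        assert rep.novelty == pytest.approx(2 / 3)

    def test_degenerate_zero_over_zero(self):
        rep = ev.standard_metrics(["c1ccccc"], "smiles", molio.MoleculeSet())
        assert rep.uniqueness == 0.0 and rep.novelty == 0.0
        assert rep.degenerate

    def test_fractions_bounded_and_consistent(self, druglike_pool):
        raws = druglike_pool.raw_strings()
        train = molio.molecule_set(raws[:100])
        rep = ev.standard_metrics(raws, "smiles", train)
        for v in (rep.validity, rep.uniqueness, rep.novelty):
            assert 0.0 <= v <= 1.0
        assert rep.n_novel <= rep.n_unique <= rep.n_valid <= rep.n_generated


class TestOracle:
    def test_identical_values_give_zero(self):
        assert ev.oracle_distance(np.full(100, 3.3), n_splits=5, seed=0) == 0.0

    def test_shrinks_with_pool_size(self):
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            small = ev.oracle_distance(rng.normal(0, 1, 200), n_splits=10,
                                       seed=seed)
            big = ev.oracle_distance(rng.normal(0, 1, 5000), n_splits=10,
                                     seed=seed)
            assert big < small

    def test_reproducible(self, rng):
        vals = rng.normal(0, 1, 64)
        a = ev.oracle_distance(vals, n_splits=1, seed=7)
        assert a == ev.oracle_distance(vals, n_splits=1, seed=7)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            ev.oracle_distance(np.ones(3), n_splits=1, seed=0)


@pytest.fixture(scope="module")
def split_pool():
    pool = taskdata.make_synthetic_pool("druglike", 2000, seed=77)
    deduped = molio.deduplicate(pool)
    half = len(deduped.records) // 2
    train = molio.MoleculeSet(records=deduped.records[:half], name="train")
    fresh = molio.MoleculeSet(records=deduped.records[half:], name="fresh")
    return train, fresh


class TestDistributionReport:
    def test_fresh_sample_within_twice_oracle(self, split_pool):
        train, fresh = split_pool
        spec = taskdata.TaskSpec("multi")
        rep = ev.distribution_report(fresh, train, spec, seed=0)
        for prop, w in rep.wasserstein.items():
            assert w <= 2.0 * rep.oracle[prop] + 1e-9, prop

    def test_shifted_sample_detected(self, split_pool):
        train, fresh = split_pool
        shifted = molio.molecule_set(
            [r.canonical_smiles + "CCCCCCC" for r in fresh.valid
             if molio.parse_molecule(r.canonical_smiles + "CCCCCCC").is_valid],
            name="shifted")
        spec = taskdata.TaskSpec("multi")
        rep = ev.distribution_report(shifted, train, spec, seed=0)
        assert rep.wasserstein["mw"] > 10.0 * rep.oracle["mw"]

    def test_equalization_to_smallest_survivor_count(self, split_pool):
        train, fresh = split_pool
        a = molio.MoleculeSet(records=fresh.records[:500], name="a")
        b = molio.MoleculeSet(records=fresh.records[:450], name="b")
        reports = ev.compare_models({"a": a, "b": b}, train,
                                    taskdata.TaskSpec("multi"), seed=0)
        assert reports["a"].n_compared == reports["b"].n_compared == 450

    def test_inputs_not_mutated(self, split_pool):
        train, fresh = split_pool
        before = fresh.raw_strings()
        ev.distribution_report(fresh, train, taskdata.TaskSpec("multi"), seed=1)
        assert fresh.raw_strings() == before

    def test_all_overlap_is_error(self, split_pool):
        train, _ = split_pool
        with pytest.raises(ValueError, match="overlap"):
            ev.distribution_report(train, train, taskdata.TaskSpec("multi"))

    def test_plogp_added_for_logp_task(self, split_pool):
        train, fresh = split_pool
        rep = ev.distribution_report(fresh, train, taskdata.TaskSpec("logp"),
                                     seed=0)
        assert "plogp" in rep.wasserstein and "plogp" in rep.oracle


class TestKde:
    def test_curves_normalized_and_share_bandwidth(self, rng):
        train = rng.normal(0, 1, 300)
        models = {"m1": rng.normal(0.5, 1, 200), "m2": rng.normal(0, 2, 200)}
        out = ev.kde_curves(train, models)
        for curve in out["curves"].values():
            assert np.trapezoid(curve, out["grid"]) == pytest.approx(1.0, abs=1e-3)
        assert out["bandwidth"] > 0
        assert set(out["curves"]) == {"train", "m1", "m2"}

    def test_bimodal_train_has_two_peaks(self, rng):
        train = np.concatenate([rng.normal(-5, 1, 300), rng.normal(5, 1, 300)])
        out = ev.kde_curves(train)
        d = out["curves"]["train"]
        peaks = [i for i in range(1, len(d) - 1)
                 if d[i] > d[i - 1] and d[i] > d[i + 1]
                 and d[i] > 0.05 * d.max()]
        assert len(peaks) == 2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ev.kde_curves(np.arange(5))


class TestHistogram2d:
    def test_counts_sum_to_rows(self, druglike_pool):
        from molgenlm import props

        rows = [props.compute_properties(r) for r in druglike_pool.valid[:100]]
        counts, _, _ = ev.histogram2d(rows, "mw", "sa", bins=10)
        assert counts.sum() == len(rows)

    def test_single_point_single_bin(self):
        from molgenlm import props, molio

        rows = [props.compute_properties(molio.parse_molecule("CCO"))]
        counts, _, _ = ev.histogram2d(rows, "mw", "sa", bins=5)
        assert (counts > 0).sum() == 1

    def test_axis_swap_transposes(self, druglike_pool):
        from molgenlm import props

        rows = [props.compute_properties(r) for r in druglike_pool.valid[:50]]
        a, _, _ = ev.histogram2d(rows, "mw", "sa", bins=8)
        b, _, _ = ev.histogram2d(rows, "sa", "mw", bins=8)
        np.testing.assert_array_equal(a, b.T)
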