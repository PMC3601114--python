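"""Module comparison: similarity, matching, fixed-factor reconstruction,
peak timing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synergyflow import analysis, factorization as fz, synthetic

from conftest import FAST_FIT


def make_set(W, P):
    return fz.MotorModuleSet(weightings=W, activations=P, n_modules=W.shape[1])


class TestNormalizedScalarProduct:
    def test_identical_vectors(self):
        v = np.array([0.3, 0.7, 0.1])
        assert analysis.normalized_scalar_product(v, v) == pytest.approx(1.0)

    def test_orthogonal_vectors(self):
        assert analysis.normalized_scalar_product([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_closed_form_example(self):
        s = analysis.normalized_scalar_product([1, 1, 0], [1, 0, 0])
        assert s == pytest.approx(1 / np.sqrt(2), abs=1e-4)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            analysis.normalized_scalar_product([0, 0], [1, 0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.01, 10), min_size=3, max_size=6),
        st.floats(0.1, 5),
        st.floats(0.1, 5),
    )
    def test_symmetric_and_scale_invariant(self, vals, a, b):
        u = np.asarray(vals)
        v = u[::-1].copy()
        s1 = analysis.normalized_scalar_product(u, v)
        s2 = analysis.normalized_scalar_product(a * v, b * u)
        assert s1 == pytest.approx(s2, abs=1e-9)


class TestMatchModules:
    def test_recovers_permutation(self):
        rng = np.random.default_rng(0)
        W = rng.random((8, 4)) + 0.1
        P = rng.random((4, 50))
        perm = [2, 0, 3, 1]
        A = make_set(W, P)
        B = make_set(W[:, perm], P[perm])
        rep = analysis.match_modules(A, B)
        assert np.allclose(rep.pair_similarities, 1.0)
        recovered = [rep.matching[i] for i in range(4)]
        assert [perm[j] for j in recovered] == [0, 1, 2, 3]

    def test_orthogonal_replacement_scores_zero(self):
        W = np.eye(4)[:, :3]
        P = np.ones((3, 10))
        B_w = W.copy()
        B_w[:, 1] = [0, 0, 0, 1]  # orthogonal to every A column
        rep = analysis.match_modules(make_set(W, P), make_set(B_w, P))
        sims = sorted(rep.pair_similarities)
        assert sims[0] == pytest.approx(0.0, abs=1e-12)
        assert sims[1:] == pytest.approx([1.0, 1.0])

    def test_dimension_mismatch_rejected(self):
        A = make_set(np.ones((4, 2)), np.ones((2, 5)))
        B = make_set(np.ones((4, 3)), np.ones((3, 5)))
        with pytest.raises(ValueError):
            analysis.match_modules(A, B)

    def test_weighting_similarity_survives_activation_perturbation(self):
        """When only activation signals are perturbed, weighting similarity
        stays high and the perturbed module's activation similarity drops
        below the others."""
        truth = synthetic.cutting_preset_truth(seed=31)
        upt = synthetic.synthesize_trials(truth, 8, "UPT", seed=32)
        ptb = synthetic.synthesize_trials(truth, 8, "PTB", seed=33)
        mu = fz.nmf(fz.concatenate_trials(list(upt.trials)), 5, seed=34, **FAST_FIT)
        mp = fz.nmf(fz.concatenate_trials(list(ptb.trials)), 5, seed=35, **FAST_FIT)
        rep_w = analysis.match_modules(mu, mp, on="weightings")
        assert rep_w.pair_similarities.mean() >= 0.95
        au = analysis.cycle_average(mu.activations, 200)
        ap = analysis.cycle_average(mp.activations, 200)
        rep_a = analysis.match_modules(
            make_set(mu.weightings, au), make_set(mp.weightings, ap), on="activations"
        )
        # identify the perturbed (hamstring) module via the matching on
        # weightings order of the UPT set
        order = np.argsort(analysis.peak_timing(au, flag_ties=False))
        perturbed_idx = order[synthetic.HAMSTRING_MODULE]
        others = [s for i, s in enumerate(rep_a.pair_similarities) if i != perturbed_idx]
        assert rep_a.pair_similarities[perturbed_idx] < min(others)


class TestGroupSimilarity:
    def test_identical_sets_all_ones(self):
        rng = np.random.default_rng(1)
        s = make_set(rng.random((6, 3)) + 0.1, rng.random((3, 20)))
        rep = analysis.group_similarity([s, s, s])
        assert np.allclose(rep.median, 1.0)

    def test_two_sets_equals_pairwise(self):
        rng = np.random.default_rng(2)
        a = make_set(rng.random((6, 3)) + 0.1, rng.random((3, 20)))
        b = make_set(rng.random((6, 3)) + 0.1, rng.random((3, 20)))
        grp = analysis.group_similarity([a, b])
        pair = analysis.match_modules(a, b)
        np.testing.assert_allclose(np.sort(grp.median), np.sort(pair.pair_similarities))

    def test_shared_truth_with_noise_keeps_high_median(self):
        sets = []
        for s in range(6):
            truth = synthetic.cutting_preset_truth(seed=50, noise_level=0.10)
            ts = synthetic.synthesize_trials(truth, 4, "UPT", seed=60 + s)
            sets.append(
                fz.nmf(fz.concatenate_trials(list(ts.trials)), 5, seed=70 + s, **FAST_FIT)
            )
        rep = analysis.group_similarity(sets)
        assert np.median(rep.pair_similarities) >= 0.9


class TestFixedFactorFit:
    def test_true_weightings_reach_unit_vaf_on_noiseless_data(self, noiseless_truth, noiseless_X):
        res = analysis.fixed_factor_fit(
            noiseless_X, noiseless_truth.weightings, "weightings", iterations=500, seed=1
        )
        assert res.vaf.global_vaf >= 0.999

    def test_true_activations_reach_unit_vaf_on_noiseless_data(self, noiseless_truth, noiseless_X):
        res = analysis.fixed_factor_fit(
            noiseless_X, noiseless_truth.activations, "activations", iterations=500, seed=1
        )
        assert res.vaf.global_vaf >= 0.999

    def test_fixed_matrix_untouched(self, noiseless_truth, noiseless_X):
        fixed = noiseless_truth.weightings.copy()
        before = fixed.copy()
        analysis.fixed_factor_fit(noiseless_X, fixed, "weightings", iterations=50, seed=0)
        np.testing.assert_array_equal(fixed, before)

    def test_zero_iterations_is_random_init_reference(self, noiseless_truth, noiseless_X):
        res0 = analysis.fixed_factor_fit(
            noiseless_X, noiseless_truth.weightings, "weightings", iterations=0, seed=3
        )
        res = analysis.fixed_factor_fit(
            noiseless_X, noiseless_truth.weightings, "weightings", iterations=200, seed=3
        )
        assert res.vaf.global_vaf > res0.vaf.global_vaf

    def test_random_fixed_factor_is_worse_paired_over_seeds(self, noiseless_truth, noiseless_X):
        wins = 0
        for seed in range(10):
            true_fit = analysis.fixed_factor_fit(
                noiseless_X, noiseless_truth.weightings, "weightings",
                iterations=300, seed=seed,
            )
            rand_fit = analysis.fixed_factor_fit(
                noiseless_X,
                analysis.random_factor(noiseless_truth.weightings.shape, seed=seed + 100),
                "weightings", iterations=300, seed=seed,
            )
            wins += true_fit.vaf.global_vaf > rand_fit.vaf.global_vaf
        assert wins == 10

    def test_shape_mismatch_rejected(self, noiseless_X):
        with pytest.raises(ValueError):
            analysis.fixed_factor_fit(noiseless_X, np.ones((3, 5)), "weightings")


class TestPeakTiming:
    @pytest.mark.parametrize(
        "idx,expected", [(0, 0.0), (199, 100.0), (74, 100 * 74 / 199)]
    )
    def test_argmax_to_percent(self, idx, expected):
        row = np.zeros((1, 200))
        row[0, idx] = 1.0
        assert analysis.peak_timing(row)[0] == pytest.approx(expected)

    def test_constant_row_flagged(self):
        with pytest.warns(UserWarning, match="tie"):
            t = analysis.peak_timing(np.ones((1, 50)))
        assert t[0] == 0.0

    def test_cycle_average_folds_concatenation(self):
        P = np.arange(12, dtype=float).reshape(1, 12)
        avg = analysis.cycle_average(P, 4)
        np.testing.assert_allclose(avg, [[4.0, 5.0, 6.0, 7.0]])
        with pytest.raises(ValueError):
            analysis.cycle_average(P, 5)
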