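"""Permutation significance and bootstrap loading stability."""

import itertools

import numpy as np
import pytest

from chronopls import (
    SyntheticTruth,
    bootstrap_loadings,
    fit_pls,
    generate_cohort,
    match_components,
    permutation_test,
)

BLOCKS = {"GMV": 8, "FA": 4, "FC": 6}


def _strong_cohort(seed=21, n=400):
    truth = SyntheticTruth.for_latent_r(
        0.4,
        mode_strengths=(4.0,),
        trait_weights=(1.0,),
        sex_effect=(0.0,),
        age_slope=(0.0,),
        block_sizes=BLOCKS,
        seed=seed,
    )
    return generate_cohort(n, truth=truth)


class TestPermutation:
    def test_seeded_runs_are_identical(self, small_cohort):
        a = permutation_test(
            small_cohort.features, small_cohort.trait, 2, n_perm=30, seed=5
        )
        b = permutation_test(
            small_cohort.features, small_cohort.trait, 2, n_perm=30, seed=5
        )
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.null_rhos, sb.null_rhos)
            assert sa.p_value == sb.p_value

    def test_single_permutation_pvalue_grid(self, small_cohort):
        sig = permutation_test(
            small_cohort.features, small_cohort.trait, 2, n_perm=1, seed=6
        )
        assert all(s.p_value in (0.5, 1.0) for s in sig)

    def test_pvalue_respects_add_one_floor(self):
        cohort = _strong_cohort()
        sig = permutation_test(cohort.features, cohort.trait, 2, n_perm=99, seed=7)
        assert sig[0].p_value >= 1.0 / 100.0
        assert all(0.0 < s.p_value <= 1.0 for s in sig)
        assert all(len(s.null_rhos) == 99 for s in sig)

    def test_strong_planted_mode_detected(self):
        cohort = _strong_cohort()
        sig = permutation_test(
            cohort.features, cohort.trait, 2, n_perm=199, alpha=0.01, seed=8
        )
        assert sig[0].significant and sig[0].p_value == 1.0 / 200.0

    def test_parameter_errors(self, small_cohort):
        with pytest.raises(ValueError):
            permutation_test(small_cohort.features, small_cohort.trait, 2, n_perm=0)
        with pytest.raises(ValueError, match="constant"):
            permutation_test(
                small_cohort.features,
                np.ones(small_cohort.features.n_participants),
                2,
                n_perm=10,
            )


class TestMatchComponents:
    def test_identity_on_self(self, rng):
        l_ref = rng.standard_normal((30, 4))
        perm, signs = match_components(l_ref, l_ref)
        assert np.array_equal(perm, np.arange(4)) and np.all(signs == 1.0)

    def test_recovers_constructed_swap_and_flip(self, rng):
        l_ref = rng.standard_normal((30, 2))
        l_boot = l_ref[:, [1, 0]].copy()
        l_boot[:, 1] *= -1.0  # original column 0, negated
        perm, signs = match_components(l_boot, l_ref)
        assert np.array_equal(l_boot[:, perm] * signs, l_ref)

    def test_any_permutation_and_signs_recovered_exactly(self, rng):
        l_ref = rng.standard_normal((25, 4))
        for p in ([2, 0, 3, 1], [3, 2, 1, 0]):
            for s in ([1, -1, 1, -1], [-1, -1, 1, 1]):
                scrambled = l_ref[:, p] * np.array(s, dtype=float)
                perm, signs = match_components(scrambled, l_ref)
                assert np.allclose(scrambled[:, perm] * signs, l_ref)

    def test_matches_brute_force_enumeration(self, rng):
        """Hungarian == exhaustive search over all K! x 2^K alignments."""

        def abs_corr(a, b):
            ac, bc = a - a.mean(), b - b.mean()
            return abs(ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc))

        for trial in range(5):
            l_boot = rng.standard_normal((30, 4))
            l_ref = rng.standard_normal((30, 4))
            perm, signs = match_components(l_boot, l_ref)
            got = sum(
                abs_corr(l_boot[:, perm[j]], l_ref[:, j]) for j in range(4)
            )
            best = max(
                sum(abs_corr(l_boot[:, p[j]], l_ref[:, j]) for j in range(4))
                for p in itertools.permutations(range(4))
            )
            assert np.isclose(got, best, atol=1e-12)
            # signs match the correlation sign of each matched pair
            for j in range(4):
                a = l_boot[:, perm[j]] - l_boot[:, perm[j]].mean()
                b = l_ref[:, j] - l_ref[:, j].mean()
                assert signs[j] == np.sign(a @ b)

    def test_zero_variance_column_warns_and_matches_last(self, rng):
        l_ref = rng.standard_normal((20, 3))
        l_boot = l_ref.copy()
        l_boot[:, 1] = 5.0  # constant column
        with pytest.warns(UserWarning, match="zero-variance"):
            perm, signs = match_components(l_boot, l_ref)
        assert perm[0] == 0 and perm[2] == 2  # informative columns keep their slot

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            match_components(rng.standard_normal((10, 2)), rng.standard_normal((10, 3)))


class TestBootstrap:
    def test_seeded_runs_are_identical(self, small_cohort):
        a = bootstrap_loadings(
            small_cohort.features, small_cohort.trait, 2, n_boot=20, seed=9
        )
        b = bootstrap_loadings(
            small_cohort.features, small_cohort.trait, 2, n_boot=20, seed=9
        )
        assert np.array_equal(a.boot_loadings, b.boot_loadings)

    def test_planted_high_loading_ci_excludes_zero(self):
        cohort = _strong_cohort(seed=23, n=600)
        st = bootstrap_loadings(cohort.features, cohort.trait, 1, n_boot=100, seed=10)
        top = np.abs(cohort.truth.planted_loadings[:, 0]).argmax()
        assert st.significant_mask[top, 0]

    def test_ci_ordering_and_mask_definition(self, small_cohort):
        st = bootstrap_loadings(
            small_cohort.features, small_cohort.trait, 2, n_boot=30, seed=11
        )
        assert (st.ci_low <= st.ci_high).all()
        expected = (st.ci_low > 0) | (st.ci_high < 0)
        assert np.array_equal(st.significant_mask, expected)

    def test_widening_percentiles_never_adds_significant_loadings(self, small_cohort):
        kw = dict(n_boot=60, seed=12)
        narrow = bootstrap_loadings(
            small_cohort.features, small_cohort.trait, 2, percentiles=(5, 95), **kw
        )
        wide = bootstrap_loadings(
            small_cohort.features, small_cohort.trait, 2, percentiles=(2.5, 97.5), **kw
        )
        assert wide.significant_mask.sum() <= narrow.significant_mask.sum()
        assert not (wide.significant_mask & ~narrow.significant_mask).any()

    def test_two_resamples_degenerate_to_min_max(self, small_cohort):
        st = bootstrap_loadings(
            small_cohort.features, small_cohort.trait, 1, n_boot=2, seed=13
        )
        assert np.allclose(st.ci_low, st.boot_loadings.min(axis=0))
        assert np.allclose(st.ci_high, st.boot_loadings.max(axis=0))

    def test_parameter_errors(self, small_cohort):
        with pytest.raises(ValueError):
            bootstrap_loadings(small_cohort.features, small_cohort.trait, 1, n_boot=1)
        with pytest.raises(ValueError):
            bootstrap_loadings(
                small_cohort.features,
                small_cohort.trait,
                1,
                n_boot=10,
                percentiles=(95, 5),
            )

    def test_matched_reference_is_full_sample_model(self, small_cohort):
        ref = fit_pls(small_cohort.features, small_cohort.trait, n_components=2)
        st = bootstrap_loadings(
            small_cohort.features,
            small_cohort.trait,
            n_boot=20,
            seed=14,
            reference=ref,
        )
        assert st.reference is ref
        # matched bootstrap columns correlate positively with the reference
        for k in range(2):
            mean_load = st.boot_loadings[:, :, k].mean(axis=0)
            r = np.corrcoef(mean_load, ref.x_loadings[:, k])[0, 1]
            assert r > 0.5
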