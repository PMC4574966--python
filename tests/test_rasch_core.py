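"""Partial Credit Model estimation: probabilities, ESF, CML fit, scoring."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from raschgwas.genotypes import MISSING, GenotypeMatrix
from raschgwas.rasch_core import (
    ItemThresholds,
    PCMFit,
    RaschFitError,
    elementary_symmetric,
    fit_pcm_cml,
    pcm_category_probs,
    person_abilities,
    rasch_score,
    simulate_pcm_responses,
)


class TestCategoryProbs:
    def test_dichotomous_item_at_threshold_gives_half(self):
        # when ability equals the difficulty, P(score 1) = 0.5
        p = pcm_category_probs(0.7, np.array([0.7]))
        assert p == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_low_ability_limit_concentrates_on_lowest_category(self):
        p = pcm_category_probs(-200.0, np.array([0.3, -0.2]))
        assert p[0] == pytest.approx(1.0, abs=1e-12)

    def test_three_category_probs_match_direct_normalized_exponentials(self):
        # beta = 0, tau = (-1, 1): cumulative sums are (0, 1, 0)
        expect = np.exp([0.0, 1.0, 0.0])
        expect /= expect.sum()
        p = pcm_category_probs(0.0, np.array([-1.0, 1.0]))
        assert p == pytest.approx(expect, abs=1e-14)

    def test_non_finite_inputs_rejected(self):
        with pytest.raises(ValueError):
            pcm_category_probs(np.nan, np.array([0.0]))
        with pytest.raises(ValueError):
            pcm_category_probs(0.0, np.array([np.inf]))

    @given(
        beta=st.floats(-5, 5),
        taus=st.lists(st.floats(-4, 4), min_size=1, max_size=4),
    )
    @settings(derandomize=True, max_examples=50)
    def test_probabilities_sum_to_one(self, beta, taus):
        p = pcm_category_probs(beta, np.array(taus))
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestElementarySymmetric:
    def test_two_dichotomous_items_expand_the_generating_polynomial(self):
        g = elementary_symmetric([np.array([1.0, 2.5]), np.array([1.0, 0.4])])
        assert g == pytest.approx([1.0, 2.9, 1.0])

    def test_total_mass_equals_product_of_item_sums(self, rng):
        eps = [np.concatenate([[1.0], rng.random(2) + 0.1]) for _ in range(5)]
        g = elementary_symmetric(eps)
        assert g.sum() == pytest.approx(np.prod([e.sum() for e in eps]))

    @pytest.mark.parametrize("n_items", [2, 3, 4])
    def test_matches_exhaustive_pattern_enumeration(self, rng, n_items):
        eps = [np.concatenate([[1.0], rng.random(2) + 0.05]) for _ in range(n_items)]
        g = elementary_symmetric(eps)
        brute = np.zeros(2 * n_items + 1)
        for pattern in itertools.product(range(3), repeat=n_items):
            brute[sum(pattern)] += np.prod([eps[i][x] for i, x in enumerate(pattern)])
        np.testing.assert_allclose(g, brute, rtol=1e-10)

    def test_nonpositive_terms_rejected(self):
        with pytest.raises(ValueError):
            elementary_symmetric([np.array([1.0, 0.0])])


def _conditional_loglik_enumerated(data: GenotypeMatrix, taus) -> float:
    """Independent route to the conditional log-likelihood: explicit
    enumeration of all response patterns per raw score."""
    m_i = [len(t) for t in taus]
    eps = [np.exp(-np.concatenate([[0.0], np.cumsum(t)])) for t in taus]
    gamma = {}
    for pattern in itertools.product(*(range(m + 1) for m in m_i)):
        w = np.prod([eps[i][x] for i, x in enumerate(pattern)])
        gamma[sum(pattern)] = gamma.get(sum(pattern), 0.0) + w
    ll = 0.0
    for row in data.values:
        num = np.prod([eps[i][x] for i, x in enumerate(row)])
        ll += np.log(num / gamma[int(row.sum())])
    return ll


class TestCMLFit:
    def test_two_dichotomous_items_match_grid_search_oracle(self):
        # sum-zero gauge leaves one free parameter d with tau = (d, -d)
        patterns = [(1, 0)] * 30 + [(0, 1)] * 18 + [(0, 0)] * 10 + [(1, 1)] * 12
        data = GenotypeMatrix(np.array(patterns, dtype=np.int16))

        def neg_cl(d):
            return -_conditional_loglik_enumerated(data, [np.array([d]), np.array([-d])])

        oracle = minimize_scalar(neg_cl, bounds=(-4, 4), method="bounded",
                                 options={"xatol": 1e-10})
        fit = fit_pcm_cml(data)
        assert fit.converged
        assert fit.thresholds.tau[0][0] == pytest.approx(oracle.x, abs=1e-4)
        assert fit.thresholds.tau[1][0] == pytest.approx(-oracle.x, abs=1e-4)

    def test_subject_permutation_leaves_thresholds_unchanged(self, pcm_dataset, rng):
        _, data = pcm_dataset
        perm = rng.permutation(data.n_subjects)
        shuffled = GenotypeMatrix(data.values[perm])
        a = fit_pcm_cml(data)
        b = fit_pcm_cml(shuffled)
        np.testing.assert_allclose(
            np.concatenate(a.thresholds.tau), np.concatenate(b.thresholds.tau),
            atol=1e-8,
        )

    def test_sum_zero_normalization_holds(self, pcm_dataset):
        _, data = pcm_dataset
        fit = fit_pcm_cml(data)
        assert np.concatenate(fit.thresholds.tau).sum() == pytest.approx(0.0, abs=1e-10)

    def test_gap_in_observed_categories_is_collapsed_and_recorded(self):
        rng = np.random.default_rng(3)
        values = rng.integers(0, 3, size=(60, 3)).astype(np.int16)
        values[:, 1] = np.where(values[:, 1] == 1, 2, values[:, 1])  # only {0, 2}
        data = GenotypeMatrix(values)
        fit = fit_pcm_cml(data)
        assert fit.converged
        assert any("snp1" == item for item, _ in fit.recodes)
        assert len(fit.thresholds.tau[1]) == 1  # recoded to a dichotomous item

    def test_constant_item_dropped_with_reason(self):
        rng = np.random.default_rng(4)
        values = rng.integers(0, 3, size=(60, 3)).astype(np.int16)
        values[:, 2] = 1
        fit = fit_pcm_cml(GenotypeMatrix(values))
        assert fit.converged
        assert fit.dropped_items and fit.dropped_items[0][0] == "snp2"

    def test_fewer_than_two_usable_items_fails_closed(self):
        values = np.column_stack(
            [np.tile([0, 1, 2], 10), np.ones(30, dtype=int)]
        ).astype(np.int16)
        fit = fit_pcm_cml(GenotypeMatrix(values))
        assert not fit.converged
        assert "fewer than 2" in fit.reason

    def test_missing_genotypes_refused(self):
        values = np.tile([0, 1, 2], (10, 2)).astype(np.int16)[:, :2]
        values[0, 0] = MISSING
        with pytest.raises(ValueError, match="complete data"):
            fit_pcm_cml(GenotypeMatrix(values))

    def test_translation_invariance_of_conditional_likelihood(self, pcm_dataset):
        # shifting all thresholds by a constant changes nothing observable
        thresholds, data = pcm_dataset
        fit = fit_pcm_cml(data)
        shifted = [t + 0.8 for t in fit.thresholds.tau]
        assert _conditional_loglik_enumerated(data, fit.thresholds.tau) == pytest.approx(
            _conditional_loglik_enumerated(data, shifted)
        )


def _bisection_ability(target, taus, lo=-30.0, hi=30.0, tol=1e-10):
    def expected(beta):
        total = 0.0
        for t in taus:
            cum = np.concatenate([[0.0], np.cumsum(beta - t)])
            p = np.exp(cum - cum.max())
            p /= p.sum()
            total += np.arange(len(t) + 1) @ p
        return total

    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _manual_fit(taus, n_items):
    """PCMFit carrying fixed thresholds for identity-coded 0..m items."""
    return PCMFit(
        thresholds=ItemThresholds(taus),
        loglik_conditional=0.0,
        converged=True,
        n_iterations=0,
        item_index=np.arange(n_items),
        category_maps=[np.arange(len(t) + 1) for t in taus],
    )


class TestPersonAbilities:
    def test_abilities_match_bisection_oracle(self, pcm_dataset):
        _, data = pcm_dataset
        fit = fit_pcm_cml(data)
        table, _ = person_abilities(data, fit)
        total = sum(len(t) for t in fit.thresholds.tau)
        for r in range(1, total):
            oracle = _bisection_ability(r, fit.thresholds.tau)
            assert table.beta[r] == pytest.approx(oracle, abs=1e-6)

    def test_equal_raw_scores_share_the_ability(self, pcm_dataset):
        _, data = pcm_dataset
        fit = fit_pcm_cml(data)
        _, scores = person_abilities(data, fit)
        raw = data.values.sum(axis=1)
        for r in np.unique(raw):
            assert np.unique(scores[raw == r]).size == 1

    def test_half_maximum_score_of_identical_items_maps_to_zero_ability(self):
        taus = [np.array([-0.4, 0.4]), np.array([-0.4, 0.4])]
        values = np.array([[0, 0], [1, 1], [2, 2], [2, 0], [0, 2], [1, 0]],
                          dtype=np.int16)
        data = GenotypeMatrix(values)
        table, _ = person_abilities(data, _manual_fit(taus, 2))
        assert table.beta[2] == pytest.approx(0.0, abs=1e-8)

    def test_abilities_strictly_increase_and_extremes_flagged(self, pcm_dataset):
        _, data = pcm_dataset
        fit = fit_pcm_cml(data)
        table, _ = person_abilities(data, fit)
        assert np.all(np.diff(table.beta) > 0)
        assert table.extreme_flags[0] and table.extreme_flags[-1]
        assert not table.extreme_flags[1:-1].any()

    def test_non_converged_fit_is_refused(self, pcm_dataset):
        _, data = pcm_dataset
        bad = PCMFit(thresholds=None, loglik_conditional=np.nan,
                     converged=False, n_iterations=0, reason="test")
        with pytest.raises(RaschFitError):
            person_abilities(data, bad)


class TestRaschScore:
    def test_pointwise_dominating_genotypes_never_score_lower(self, pcm_dataset):
        _, data = pcm_dataset
        scores = rasch_score(data)
        v = data.values
        for i in range(0, 40):
            for j in range(i + 1, 40):
                if np.all(v[i] >= v[j]):
                    assert scores[i] >= scores[j]

    def test_duplicating_every_subject_preserves_scores(self, pcm_dataset):
        # CML depends on the data only through item margins and score counts
        _, data = pcm_dataset
        doubled = GenotypeMatrix(np.vstack([data.values, data.values]))
        np.testing.assert_allclose(
            rasch_score(doubled), np.tile(rasch_score(data), 2), atol=1e-6
        )

    def test_six_subject_fixture_matches_composed_independent_oracle(self):
        values = np.array(
            [[0, 1, 2], [1, 1, 1], [2, 0, 1], [0, 0, 1], [1, 2, 2], [2, 1, 0]],
            dtype=np.int16,
        )
        data = GenotypeMatrix(values)
        fit = fit_pcm_cml(data)
        # oracle: derivative-free maximization of the enumerated conditional
        # likelihood in the sum-zero gauge, then bisection for abilities
        from scipy.optimize import minimize

        def neg_cl(free):
            taus = [free[0:2], free[2:4], np.array([free[4], -free.sum()])]
            return -_conditional_loglik_enumerated(data, taus)

        best = None
        for seed in range(3):
            start = np.random.default_rng(seed).normal(0, 0.5, 5)
            res = minimize(neg_cl, start, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            if best is None or res.fun < best.fun:
                best = res
        free = best.x
        oracle_taus = [free[0:2], free[2:4], np.array([free[4], -free.sum()])]
        np.testing.assert_allclose(
            np.concatenate(fit.thresholds.tau), np.concatenate(oracle_taus), atol=1e-4
        )
        scores = rasch_score(data)
        for i, row in enumerate(values):
            r = int(row.sum())
            target = {0: 0.25, 6: 5.75}.get(r, float(r))
            assert scores[i] == pytest.approx(
                _bisection_ability(target, oracle_taus), abs=1e-4
            )

    def test_deterministic_given_data(self, pcm_dataset):
        _, data = pcm_dataset
        np.testing.assert_array_equal(rasch_score(data), rasch_score(data))


def test_threshold_recovery_improves_with_sample_size():
    """CML estimates of known thresholds tighten as subjects accumulate."""
    rmse = {}
    for n in (200, 2000):
        rng = np.random.default_rng(77)
        taus = [rng.normal(0, 0.7, 2) for _ in range(12)]
        shift = np.mean(np.concatenate(taus))
        taus = [t - shift for t in taus]
        data = simulate_pcm_responses(ItemThresholds(taus), rng.normal(0, 1, n), rng)
        fit = fit_pcm_cml(data)
        assert fit.converged
        err = np.concatenate(fit.thresholds.tau) - np.concatenate(taus)
        rmse[n] = float(np.sqrt(np.mean(err**2)))
    assert rmse[2000] < 0.15
    assert rmse[2000] < rmse[200]
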