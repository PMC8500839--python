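"""Fall-off simulation: weights, step mechanics, coverage, alpha estimation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from axonarray.falloff import (
    AlphaEstimate,
    ArrayPopulation,
    ConditionTable,
    FallOffConfig,
    FallOffModel,
    array_weight,
    coverage,
    end_release_probabilities,
    estimate_alpha,
    length_distribution_discrepancy,
    mean_model_discrepancy,
    oad_count_from_length_nm,
    simulate_lengths_to_coverage,
    simulate_to_coverage,
    step_end_release,
    step_random_break,
)


class ForcedRng:
    """Stub producing fixed uniforms / integers for deterministic step tests."""

    def __init__(self, u=0.0, k=0):
        self.u, self.k = u, k

    def random(self):
        return self.u

    def integers(self, n):
        return self.k


@pytest.mark.parametrize(
    "n,alpha,expected",
    [(7, 0.0, 1.0), (1, 0.73, 1.0), (11, 0.1, 2.0), (2, 1.0, 2.0)],
)
def test_array_weight_values(n, alpha, expected):
    assert array_weight(n, alpha) == pytest.approx(expected, abs=0)


@pytest.mark.parametrize("n,alpha", [(0, 0.5), (-3, 0.0), (5, -0.1), (5, 1.2)])
def test_array_weight_rejects_invalid(n, alpha):
    with pytest.raises(ValueError):
        array_weight(n, alpha)


@pytest.mark.parametrize(
    "lengths,alpha,expected",
    [
        ([5, 5, 5], 0.0, [1 / 3] * 3),
        ([2, 8], 1.0, [0.2, 0.8]),
        ([2, 8], 0.1, [11 / 28, 17 / 28]),
    ],
)
def test_end_release_probabilities(lengths, alpha, expected):
    pop = ArrayPopulation.from_lengths(lengths)
    np.testing.assert_allclose(end_release_probabilities(pop, alpha), expected, atol=1e-15)


@settings(derandomize=True, max_examples=50)
@given(
    lengths=st.lists(st.integers(1, 40), min_size=1, max_size=20),
    alpha=st.floats(0, 1),
)
def test_probabilities_sum_to_one_and_are_order_invariant(lengths, alpha):
    pop = ArrayPopulation.from_lengths(lengths)
    p = end_release_probabilities(pop, alpha)
    assert abs(p.sum() - 1.0) < 1e-12
    perm = list(reversed(lengths))
    q = end_release_probabilities(ArrayPopulation.from_lengths(perm), alpha)
    np.testing.assert_allclose(np.sort(p), np.sort(q), atol=1e-12)


def test_empty_population_cannot_release():
    pop = ArrayPopulation(lengths=[], reference_total=10)
    with pytest.raises(ValueError):
        end_release_probabilities(pop, 0.5)
    with pytest.raises(ValueError):
        step_random_break(pop, np.random.default_rng(0))


def test_step_end_release_mechanics():
    pop = ArrayPopulation.from_lengths([3, 2])
    new, ev = step_end_release(pop, 0.0, ForcedRng(u=0.0))
    assert sorted(new.lengths) == [2, 2] and ev.array_index == 0
    last = ArrayPopulation.from_lengths([1])
    gone, _ = step_end_release(last, 0.0, ForcedRng())
    assert gone.lengths == []


def test_step_random_break_split_and_vanish():
    pop = ArrayPopulation.from_lengths([5])
    # 1-based interior position 3 = 0-based OAD index 2 splits [5] into [2, 2]
    new, ev = step_random_break(pop, ForcedRng(k=2))
    assert new.lengths == [2, 2] and ev.position == 2
    gone, _ = step_random_break(ArrayPopulation.from_lengths([1]), ForcedRng(k=0))
    assert gone.lengths == []


def test_random_break_expected_array_count_from_five():
    # positions 1 and 5 leave one array, 2-4 leave two: (2*1 + 3*2)/5 = 1.6
    counts = []
    for k in range(5):
        new, _ = step_random_break(ArrayPopulation.from_lengths([5]), ForcedRng(k=k))
        counts.append(len(new.lengths))
    assert np.mean(counts) == pytest.approx(1.6)


def test_array_count_monotonicity():
    rng = np.random.default_rng(7)
    pop = ArrayPopulation.from_lengths([4, 3, 2, 6])
    for _ in range(10):
        new, _ = step_end_release(pop, 0.6, rng)
        assert len(new.lengths) <= len(pop.lengths)
        pop = new if new.lengths else ArrayPopulation.from_lengths([4, 3, 2, 6])
    pop = ArrayPopulation.from_lengths([4, 3, 2, 6])
    for _ in range(10):
        new, _ = step_random_break(pop, rng)
        assert len(new.lengths) <= len(pop.lengths) + 1
        pop = new if new.lengths else ArrayPopulation.from_lengths([4, 3, 2, 6])


@pytest.mark.parametrize(
    "lengths,ref,expected", [([3, 7], 20, 0.5), ([], 5, 0.0), ([2, 3], 5, 1.0)]
)
def test_coverage(lengths, ref, expected):
    assert coverage(ArrayPopulation(lengths, ref)) == pytest.approx(expected)


def test_coverage_invariant_violation():
    with pytest.raises(ValueError):
        ArrayPopulation([10, 10], reference_total=5)


def test_simulate_to_coverage_trivial_targets():
    pop = ArrayPopulation.from_lengths([4, 4, 4])
    cfg = FallOffConfig(model=FallOffModel.END_RELEASE, alpha=0.3, seed=5)
    tr = simulate_to_coverage(pop, cfg, 1.0)
    assert tr.events == [] and sorted(tr.final.lengths) == [4, 4, 4]
    tr0 = simulate_to_coverage(pop, cfg, 0.0)
    assert tr0.final.lengths == [] and len(tr0.events) == 12  # conservation
    with pytest.raises(ValueError):
        simulate_to_coverage(ArrayPopulation([2], 10), cfg, 0.9)


def test_trajectory_conservation_and_determinism():
    pop = ArrayPopulation.from_lengths([5, 8, 3, 9])
    cfg = FallOffConfig(model=FallOffModel.RANDOM_BREAK, seed=42)
    tr1 = simulate_to_coverage(pop, cfg, 0.4, record_snapshots=True)
    tr2 = simulate_to_coverage(pop, cfg, 0.4)
    assert pop.reference_total - tr1.final.total() == len(tr1.events)
    assert sorted(tr1.final.lengths) == sorted(tr2.final.lengths)
    for (step, _), snap in zip(tr1.events, tr1.snapshots):
        assert sum(snap) == pop.reference_total - step - 1


def _enumerate_end_release(lengths, alpha):
    """Exact next-step multiset distribution under end release."""
    w = np.array([array_weight(n, alpha) for n in lengths])
    p = w / w.sum()
    dist = {}
    for i, prob in enumerate(p):
        new = list(lengths)
        new[i] -= 1
        if new[i] == 0:
            del new[i]
        key = tuple(sorted(new))
        dist[key] = dist.get(key, 0.0) + prob
    return dist


def _enumerate_random_break(lengths):
    """Exact next-step multiset distribution under random break."""
    total = sum(lengths)
    dist = {}
    for i, n in enumerate(lengths):
        for pos in range(n):
            new = list(lengths)
            if n == 1:
                del new[i]
            elif pos in (0, n - 1):
                new[i] = n - 1
            else:
                new[i : i + 1] = [pos, n - 1 - pos]
            key = tuple(sorted(new))
            dist[key] = dist.get(key, 0.0) + 1.0 / total
    return dist


@pytest.mark.parametrize("lengths", [[2, 3], [4, 1, 2], [3, 3, 3, 2]])
@pytest.mark.parametrize("model,alpha", [("end_release", 0.4), ("random_break", 0.0)])
def test_step_distribution_matches_enumeration(lengths, model, alpha):
    """Empirical next-step outcomes match full enumeration within 3 s.e."""
    exact = (
        _enumerate_end_release(lengths, alpha)
        if model == "end_release"
        else _enumerate_random_break(lengths)
    )
    n_draws = 100_000
    seed = sum((i + 1) * v for i, v in enumerate(lengths)) * 31 + len(model)
    rng = np.random.default_rng(seed)
    pop = ArrayPopulation.from_lengths(lengths)
    counts = {}
    for _ in range(n_draws):
        final = simulate_lengths_to_coverage(
            pop, model, alpha, (pop.total() - 1) / pop.total(), rng
        )
        key = tuple(final.tolist())
        counts[key] = counts.get(key, 0) + 1
    assert set(counts) <= set(exact)
    for key, p in exact.items():
        se = math.sqrt(p * (1 - p) / n_draws)
        assert abs(counts.get(key, 0) / n_draws - p) <= max(3 * se, 1e-4), key


def test_selection_uniform_at_alpha0_proportional_at_alpha1():
    """Chi-square on 1e5 seeded draws against the exact selection law."""
    from scipy.stats import chisquare

    lengths = [1, 2, 3, 4]  # distinct, so the outcome identifies the selection
    pop = ArrayPopulation.from_lengths(lengths)
    outcome_to_index = {}
    for i, n in enumerate(lengths):
        new = [v for v in lengths if v != n] + ([n - 1] if n > 1 else [])
        outcome_to_index[tuple(sorted(new))] = i
    n_draws = 100_000
    for alpha in (0.0, 1.0):
        rng = np.random.default_rng(int(alpha * 7 + 3))
        expected_p = end_release_probabilities(pop, alpha)
        counts = np.zeros(len(lengths))
        for _ in range(n_draws):
            final = simulate_lengths_to_coverage(pop, "end_release", alpha, 9 / 10, rng)
            counts[outcome_to_index[tuple(final.tolist())]] += 1
        res = chisquare(counts, expected_p * n_draws)
        assert res.pvalue > 0.001, (alpha, counts)


def test_random_break_fragments_more_than_end_release():
    """At matched coverage random break leaves more, shorter arrays."""
    pop = ArrayPopulation.from_lengths([10] * 30)
    rng_er = np.random.default_rng(1)
    rng_rb = np.random.default_rng(2)
    n_er, n_rb = [], []
    for _ in range(200):
        n_er.append(simulate_lengths_to_coverage(pop, "end_release", 0.1, 0.5, rng_er).size)
        n_rb.append(simulate_lengths_to_coverage(pop, "random_break", 0.0, 0.5, rng_rb).size)
    assert np.mean(n_rb) >= np.mean(n_er)


def _wasserstein_oracle(a, b):
    """Brute force W1: expand both samples to a common size, sorted mean |diff|."""
    m = len(a) * len(b) // math.gcd(len(a), len(b))
    aa = np.sort(np.repeat(np.sort(a), m // len(a)))
    bb = np.sort(np.repeat(np.sort(b), m // len(b)))
    return np.abs(aa - bb).mean()


def test_discrepancy_values_and_oracle():
    assert length_distribution_discrepancy([1, 2, 3], [3, 1, 2]) == 0.0
    assert length_distribution_discrepancy([2], [5]) == pytest.approx(3.0)
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.integers(1, 20, size=rng.integers(1, 12))
        b = rng.integers(1, 20, size=rng.integers(1, 12))
        assert length_distribution_discrepancy(a, b) == pytest.approx(
            _wasserstein_oracle(a, b)
        )
    with pytest.raises(ValueError):
        length_distribution_discrepancy([], [1])


def test_estimate_alpha_degenerate_tie_goes_to_smallest():
    pop = ArrayPopulation.from_lengths([5] * 40)
    conds = [ConditionTable("ref", np.array([5] * 40), coverage=1.0)]
    est = estimate_alpha(conds, pop, grid=[0.2, 0.6, 1.0], n_replicates=5, seed=0)
    assert np.all(est.mean_discrepancy_per_alpha == 0.0)
    assert est.alpha_hat == 0.2


def test_estimate_alpha_rejects_unreachable_condition():
    pop = ArrayPopulation([3, 3], reference_total=10)  # coverage 0.6
    conds = [ConditionTable("hi", np.array([4, 4]), coverage=0.9)]
    with pytest.raises(ValueError):
        estimate_alpha(conds, pop, n_replicates=2, seed=0)


def test_estimate_alpha_recovers_low_alpha_quickly():
    from axonarray.synthetic import SyntheticArrayConfig, make_array_observations

    obs = make_array_observations(SyntheticArrayConfig(true_alpha=0.0, seed=12))
    est = estimate_alpha(obs.conditions, obs.reference, n_replicates=20, seed=1)
    assert est.alpha_hat <= 0.2
    assert est.alpha_hat in est.alpha_grid


@pytest.mark.parametrize("nm,expected", [(96.0, 4), (24.0, 1), (30.0, 1), (250.0, 10)])
def test_oad_count_from_length(nm, expected):
    assert oad_count_from_length_nm(nm) == expected
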