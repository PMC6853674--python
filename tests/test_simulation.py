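"""Local resampling null, empirical p-values, BH adjustment, per-element test."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from mutclust.genome import ReferenceGenome
from mutclust.io import GenomicElement, Mutation
from mutclust.profiles import MutationalProfile, element_change_probabilities, uniform_profile
from mutclust.simulation import (
    ElementData,
    SimulationConfig,
    analyze_element,
    bh_adjust,
    build_element_data,
    empirical_pvalue,
    placement_weights,
    simulate_iteration,
)
from reference_impls import naive_bh, naive_empirical_pvalue


@pytest.fixture(scope="module")
def flat_probs():
    return np.ones(100)


class TestPlacementWeights:
    def test_uniform_profile_gives_uniform_window(self, ref, flat_probs):
        element = GenomicElement("E1", "E1", "chr1", ((100, 200),))
        probs = element_change_probabilities(element, ref, uniform_profile(3))
        candidates, weights, fallback = placement_weights(50, probs, w_sim=31)
        assert not fallback
        assert candidates.tolist() == list(range(35, 66))
        assert np.allclose(weights, 1 / 31)

    def test_left_edge_clipping(self, flat_probs):
        candidates, weights, _ = placement_weights(2, flat_probs, w_sim=31)
        assert candidates.tolist() == list(range(0, 18))
        assert weights.sum() == pytest.approx(1.0)

    def test_support_restricted_to_profile_contexts(self):
        genome = ReferenceGenome({"c": "ATTCAGGTCATTTTCAGG"})
        element = GenomicElement("E1", "E1", "c", ((0, 18),))
        profile = MutationalProfile(3, {("TCA", "T"): 1.0}, 1)
        probs = element_change_probabilities(element, genome, profile)
        candidates, weights, _ = placement_weights(8, probs, w_sim=31)
        support = {int(c) for c, w in zip(candidates, weights) if w > 0}
        tca_centers = {
            i for i in range(1, 17) if genome.fetch("c", i - 1, i + 2) == "TCA"
        }
        assert support == tca_centers

    def test_all_zero_window_falls_back_to_observed_index(self):
        probs = np.zeros(50)
        candidates, weights, fallback = placement_weights(25, probs, w_sim=11)
        assert fallback
        assert candidates.tolist() == [25]
        assert weights.tolist() == [1.0]


class TestSimulateIteration:
    def test_mutation_count_is_conserved(self, flat_probs, rng):
        out = simulate_iteration([5, 10, 50, 50, 99], flat_probs, 31, rng)
        assert len(out) == 5
        assert np.all((0 <= out) & (out < 100))

    def test_point_mass_profile_keeps_observed_positions(self, rng):
        probs = np.zeros(60)
        probs[[7, 40]] = 1.0
        # windows of 7 and 40 (w_sim=11) contain only themselves as support
        out = simulate_iteration([7, 40], probs, 11, rng)
        assert out.tolist() == [7, 40]

    def test_uniform_window_histogram_is_uniform(self, flat_probs, rng):
        from scipy import stats

        draws = np.concatenate(
            [simulate_iteration([50], flat_probs, 31, rng) for _ in range(20000)]
        )
        observed = np.bincount(draws - 35, minlength=31)
        assert stats.chisquare(observed).pvalue > 0.001


class TestEmpiricalPvalue:
    def test_worked_rank_example(self):
        assert empirical_pvalue(5, [1, 2, 3, 4, 6, 7]) == pytest.approx(3 / 7)

    def test_observed_above_all_gives_minimum(self):
        assert empirical_pvalue(10, list(range(9))) == pytest.approx(1 / 10)

    def test_observed_zero_ties_with_everything(self):
        assert empirical_pvalue(0.0, [0.0, 1.0, 2.0]) == 1.0

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(300):
            observed = float(rng.normal())
            simulated = rng.normal(size=int(rng.integers(1, 40))).tolist()
            assert empirical_pvalue(observed, simulated) == pytest.approx(
                naive_empirical_pvalue(observed, simulated)
            )


class TestBHAdjust:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_empty_input(self):
        assert len(bh_adjust([])) == 0

    def test_matches_naive_step_up(self, rng):
        for _ in range(200):
            p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 50)))
            assert np.allclose(bh_adjust(p), naive_bh(p.tolist()))

    def test_qvalues_dominate_pvalues_and_preserve_order(self, rng):
        p = rng.uniform(0, 1, size=30)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)


def make_element_data(ref, positions, element=None, profile=None):
    element = element or GenomicElement("E1", "E1", "chr1", ((50, 250),))
    profile = profile or uniform_profile(3)
    mutations = []
    seq_start = element.segments[0][0]
    for i, idx in enumerate(positions):
        pos1 = seq_start + idx + 1
        base = ref.base(element.chromosome, pos1)
        alt = next(b for b in "ACGT" if b != base)
        mutations.append((Mutation(element.chromosome, pos1, base, alt, f"s{i}"), idx))
    return build_element_data(element, ref, mutations, profile)


class TestAnalyzeElement:
    def test_single_mutation_yields_null_result(self, ref):
        data = make_element_data(ref, [100])
        result = analyze_element(data, uniform_profile(3), SimulationConfig(n_simulations=10))
        assert result.score == 0.0
        assert result.p_value == 1.0
        assert result.n_clusters == 0

    def test_identical_inputs_and_seed_are_bit_identical(self, ref):
        config = SimulationConfig(n_simulations=50)
        profile = uniform_profile(3)
        r1 = analyze_element(make_element_data(ref, [100, 100, 101, 150]), profile, config)
        r2 = analyze_element(make_element_data(ref, [100, 100, 101, 150]), profile, config)
        assert r1.score == r2.score
        assert r1.p_value == r2.p_value
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_different_seed_changes_null_draws(self, ref):
        profile = uniform_profile(3)
        data = make_element_data(ref, [100, 100, 101, 150])
        r1 = analyze_element(data, profile, SimulationConfig(n_simulations=200, seed=1))
        r2 = analyze_element(data, profile, SimulationConfig(n_simulations=200, seed=2))
        assert r1.score == r2.score  # observed part is seed-free
        # the per-element RNG streams (and per-element ids) must differ
        from mutclust.simulation import element_rng

        assert element_rng(1, "E1").random() != element_rng(2, "E1").random()
        assert element_rng(1, "E1").random() != element_rng(1, "E2").random()

    def test_pvalue_bounds(self, ref):
        config = SimulationConfig(n_simulations=40)
        result = analyze_element(
            make_element_data(ref, [100] * 6), uniform_profile(3), config
        )
        assert 1 / 41 <= result.p_value <= 1.0
        for cl in result.clusters:
            assert 0 < cl.p_value <= 1.0

    def test_hotspot_element_beats_scattered_element(self, ref):
        config = SimulationConfig(n_simulations=300)
        profile = uniform_profile(3)
        hotspot = analyze_element(
            make_element_data(ref, [100] * 10 + [20, 60, 140, 180]), profile, config
        )
        scattered = analyze_element(
            make_element_data(ref, [10, 25, 40, 60, 80, 100, 115, 130, 150, 170, 185, 60, 120, 90]),
            profile,
            config,
        )
        assert hotspot.p_value < scattered.p_value


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_simulations=0)
    with pytest.raises(ValueError):
        SimulationConfig(w_sim=10)
    with pytest.raises(ValueError):
        SimulationConfig(k=4)
    with pytest.raises(ValueError):
        SimulationConfig(fdr_threshold=1.5)
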