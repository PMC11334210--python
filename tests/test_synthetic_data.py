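"""Simulators: trees, chromosome histories, neutral traits, experiments."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_traits
from karyorate import chrom_markov as cm
from karyorate import synthetic_data as sd
from karyorate.phylo_io import TreeSet, scale_to_unit_height
from oracle_utils import phylo


class TestSimulateTree:
    def test_tip_count_and_ultrametricity(self):
        phy = sd.simulate_tree(5, seed=1)
        assert phy.n_tips == 5
        assert phy.is_ultrametric()

    def test_pure_birth_all_branches_positive(self):
        phy = sd.simulate_tree(60, birth=1.0, death=0.0, seed=2)
        lens = [e.length for e in phy.tree.preorder_edge_iter() if e.length is not None]
        assert all(l > 0 for l in lens)

    def test_with_extinction_still_conditioned_on_tips(self):
        phy = sd.simulate_tree(30, birth=1.0, death=0.4, seed=3)
        assert phy.n_tips == 30
        assert phy.is_ultrametric()

    def test_mean_total_length_near_yule_expectation(self):
        """For a Yule tree the expected pendant-plus-internal length is
        n * sum_{k=2..n} 1/k / ... ; use the known E[total] = n/b * H-ish
        identity via Monte Carlo against the closed form
        E[T_total] = (1/b) * sum_{k=2}^{n} k * E[interval_k] = (1/b) * sum 1
        -> E[total length] = (n-1)/b * ... simplest exact form: intervals
        t_k ~ Exp(k*b) while k lineages exist, so E[total] =
        sum_{k=2}^{n} k * 1/(k b) = (n-1)/b."""
        n, b = 12, 1.0
        rng = np.random.default_rng(5)
        totals = []
        for _ in range(400):
            phy = sd.simulate_tree(n, birth=b, death=0.0, seed=rng)
            totals.append(sum(e.length for e in phy.tree.preorder_edge_iter()
                              if e.length))
        want = (n - 1) / b
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - want) < 4 * se + 0.05 * want


class TestSimulateChromosomes:
    def test_zero_rates_nothing_happens(self):
        phy = scale_to_unit_height(sd.simulate_tree(12, seed=7))
        cfg = sd.SimConfig(n_tips=12, params=cm.RateParams(), seed=7)
        data = sd.simulate_chromosomes(phy, cfg, np.random.default_rng(7))
        assert (data.traits["haploid_n"] == 19).all()
        assert data.traits["state"].nunique() == 1
        assert len(data.events) == 0

    def test_fission_only_counts_monotone_up(self):
        phy = scale_to_unit_height(sd.simulate_tree(12, seed=8))
        cfg = sd.SimConfig(n_tips=12, params=cm.RateParams(gamma_S=3, gamma_L=3), seed=8)
        data = sd.simulate_chromosomes(phy, cfg, np.random.default_rng(8))
        assert (data.traits["haploid_n"] >= 19).all()

    def test_event_count_matches_poisson_expectation(self):
        """With counts far from the floor, the total event rate is constant
        (delta + gamma + q) and events over the tree follow a Poisson with
        mean rate x total tree length."""
        phy = scale_to_unit_height(sd.simulate_tree(10, seed=9))
        total_len = sum(e.length for e in phy.tree.preorder_edge_iter() if e.length)
        p = cm.RateParams(0.5, 0.5, 0.5, 0.5, 1.0, 1.0)
        rate = 0.5 + 0.5 + 1.0
        rng = np.random.default_rng(9)
        counts = []
        for _ in range(1000):
            data = sd.simulate_chromosomes(
                phy, sd.SimConfig(n_tips=10, params=p, root_count=100), rng)
            counts.append(len(data.events))
        want = rate * total_len
        se = np.sqrt(want / len(counts))
        assert abs(np.mean(counts) - want) < 3 * se

    def test_replay_event_log_reproduces_tips(self):
        phy = scale_to_unit_height(sd.simulate_tree(25, seed=10))
        cfg = sd.SimConfig(n_tips=25, seed=10)
        data = sd.simulate_chromosomes(phy, cfg, np.random.default_rng(10))
        replayed = replay = sd.replay_events(data)
        merged = data.traits.merge(replay, on="species", suffixes=("", "_r"))
        assert (merged["haploid_n"] == merged["haploid_n_r"]).all()
        assert (merged["state"] == merged["state_r"]).all()

    def test_no_upper_cap_but_floor_at_one(self):
        phy = scale_to_unit_height(sd.simulate_tree(10, seed=11))
        cfg = sd.SimConfig(n_tips=10, root_count=2,
                           params=cm.RateParams(delta_S=30, delta_L=30), seed=11)
        data = sd.simulate_chromosomes(phy, cfg, np.random.default_rng(11))
        assert (data.traits["haploid_n"] >= 1).all()


class TestSimulateBinaryTrait:
    def test_rate_zero_all_tips_share_root_state(self):
        phy = scale_to_unit_height(sd.simulate_tree(15, seed=12))
        t = sd.simulate_binary_trait(phy, rate=0.0, seed=12)
        assert t["state"].nunique() == 1

    def test_stationary_frequency_near_half(self):
        rng = np.random.default_rng(13)
        fracs = []
        for i in range(200):
            phy = scale_to_unit_height(sd.simulate_tree(10, seed=rng))
            t = sd.simulate_binary_trait(phy, rate=2.0, seed=rng)
            fracs.append((t["state"] == "small").mean())
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.05)

    def test_flip_count_matches_poisson_expectation(self):
        phy = scale_to_unit_height(sd.simulate_tree(10, seed=14))
        total_len = sum(e.length for e in phy.tree.preorder_edge_iter() if e.length)
        rng = np.random.default_rng(14)
        events = [sd.simulate_binary_trait(phy, 2.0, rng).attrs["n_events"]
                  for _ in range(800)]
        want = 2.0 * total_len
        se = np.sqrt(want / len(events))
        assert abs(np.mean(events) - want) < 3 * se


class TestSimulatorLikelihoodConsistency:
    def test_star_tree_tip_frequencies_match_transition_matrix(self):
        """The module's central cross-check: simulated endpoint frequencies
        on a two-tip star tree must follow the corresponding row of exp(Qt)
        (chi-squared goodness of fit)."""
        t = 0.35
        star = phylo(f"(A:{t},B:{t});")
        p = cm.RateParams(1.0, 0.6, 1.2, 0.4, 1.0, 1.5)
        cfg = sd.SimConfig(n_tips=2, params=p, root_count=10, root_small_prob=1.0)
        rng = np.random.default_rng(15)
        draws = []
        for _ in range(5000):
            data = sd.simulate_chromosomes(star, cfg, rng)
            draws.extend(zip(data.traits["haploid_n"], data.traits["state"]))
        space = cm.build_state_space(1, 30)
        Q = cm.build_rate_matrix(p, space)
        probs = cm.transition_probabilities(Q, t)[space.index(10, cm.SMALL)]
        obs = np.zeros(space.size)
        extra = 0
        for k, s in draws:
            h = cm.SMALL if s == "small" else cm.LARGE
            if 1 <= k <= 30:
                obs[space.index(int(k), h)] += 1
            else:
                extra += 1
        n = len(draws)
        keep = probs * n >= 5
        o = np.append(obs[keep], obs[~keep].sum() + extra)
        e = np.append(probs[keep], 1 - probs[keep].sum()) * n
        chi = stats.chisquare(o, e)
        assert chi.pvalue > 0.01


class TestExperiments:
    def test_false_positive_report_empty_when_no_traits(self, sim_dataset):
        phy, data = sim_dataset
        table, summary = sd.false_positive_experiment(
            TreeSet([phy]), data.traits[["species", "haploid_n"]], 0)
        assert len(table) == 0
        assert summary["n_neutral"] == 0

    def test_false_positive_fractions_match_independent_tally(self):
        phy = scale_to_unit_height(sd.simulate_tree(25, seed=16))
        cfg = sd.SimConfig(n_tips=25, params=cm.RateParams(0.5, 0.5, 0.5, 0.5, 2, 2),
                           seed=16)
        data = sd.simulate_chromosomes(phy, cfg, np.random.default_rng(16))
        from karyorate.bayes_fit import McmcSettings
        table, summary = sd.false_positive_experiment(
            TreeSet([phy]), data.traits[["species", "haploid_n"]], 3,
            settings=McmcSettings(n_generations=30, burnin=15, n_replicates=1, seed=3),
            seed=16)
        ok = table[table["error"] == ""]
        assert summary["fp_rate_fusion"] == pytest.approx(
            ok["fusion_excludes_zero"].sum() / len(ok))
        assert 0 <= summary["fp_rate_fission"] <= 1

    def test_variance_adequacy_values(self):
        obs = make_traits(["a", "b", "c"], [1, 2, 3], ["small", "small", "large"])
        sims = [make_traits(["a", "b", "c"], [1, 2, 3], ["small"] * 3),
                make_traits(["a", "b", "c"], [5, 5, 5], ["small"] * 3)]
        rep = sd.variance_adequacy(obs, sims)
        assert rep["observed_variance"] == pytest.approx(1.0)  # sample variance
        assert rep["simulated_min"] == 0.0
        assert rep["simulated_max"] == pytest.approx(1.0)
        assert 0 < rep["observed_quantile"] <= 1
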