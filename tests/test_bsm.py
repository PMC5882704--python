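"""Stochastic mapping: samplers, event counts and summaries."""

import numpy as np
import pytest
from scipy.stats import chisquare

from fossilrange.bsm import (CATEGORIES, _Uniformizer, count_events,
                             percentage_from_means, sample_histories,
                             sample_history, summarize_bsm, summarize_counts)
from fossilrange.data import GeographyTable
from fossilrange.likelihood import RangeEvolutionModel
from fossilrange.model import ModelParams, ModelSpec, StateSpace, Stratum, \
    build_q
from fossilrange.simulate import SimConfig, simulate_fossil_tree, \
    simulate_ranges

from conftest import make_timetree, random_geography, random_timetree


def sim_tree(seed, min_tips=20, birth=0.05, death=0.02, origin=110.0):
    for s in range(seed, seed + 60):
        try:
            tree, ages = simulate_fossil_tree(
                SimConfig(birth, death, 0.04, origin, seed=s))
        except RuntimeError:
            continue
        if len(tree.leaf_labels) >= min_tips:
            return tree, ages
    raise RuntimeError("no suitable tree found in seed window")


class TestTrivialHistories:
    def test_static_tips_no_events(self):
        tree = make_timetree((50.0, (30.0, ("T1", 5.0), ("T2", 10.0)),
                              ("T3", 20.0)))
        geo = GeographyTable(["A", "B"], {t: 1 for t in ("T1", "T2", "T3")})
        model = RangeEvolutionModel(tree, geo, ModelSpec("DEC", "M0"),
                                    [Stratum(60.0, 0.0)])
        h = sample_history(model, ModelParams(0.0, 0.0), seed=1)
        assert h.anagenetic == []
        assert all(mask == 1 for mask in h.node_states.values())
        counts = count_events(h)
        assert counts.counts["sympatry"] == 2  # T - 1 nodes, all copies
        assert counts.total == 2

    def test_tip_states_match_observed_ranges(self):
        rng = np.random.default_rng(41)
        for rep in range(5):
            tree = random_timetree(rng, 10)
            geo = random_geography(rng, tree.leaf_labels, 3, m=2)
            model = RangeEvolutionModel(
                tree, geo, ModelSpec("DEC", "M2", max_range_size=2),
                [Stratum(110.0, 50.0), Stratum(50.0, 0.0)])
            params = ModelParams(0.05, 0.01, j=0.5)
            for h in sample_histories(model, params, 5, seed=rep):
                for leaf in tree.leaves():
                    assert h.node_states[leaf.label] == geo.ranges[leaf.label]

    def test_cladogenetic_events_always_tips_minus_one(self):
        tree, _ = sim_tree(900)
        T = len(tree.leaf_labels)
        strata = [Stratum(max(120.0, tree.root_age), 0.0)]
        geo, _ = simulate_ranges(tree, ModelSpec("DEC", "M0"),
                                 ModelParams(0.02, 0.002), strata, 1,
                                 ["A", "B", "C"], seed=2)
        model = RangeEvolutionModel(tree, geo, ModelSpec("DEC", "M0"),
                                    strata)
        for h in sample_histories(model, ModelParams(0.02, 0.002), 10,
                                  seed=3):
            assert len(h.cladogenetic) == T - 1

    def test_seeded_reproducibility(self):
        tree, _ = sim_tree(950)
        strata = [Stratum(max(120.0, tree.root_age), 0.0)]
        geo, _ = simulate_ranges(tree, ModelSpec("DEC", "M0"),
                                 ModelParams(0.02, 0.002), strata, 1,
                                 ["A", "B"], seed=4)
        model = RangeEvolutionModel(tree, geo, ModelSpec("DEC", "M0"),
                                    strata)
        t1 = summarize_bsm(model, ModelParams(0.02, 0.002), n_maps=5, seed=9)
        t2 = summarize_bsm(model, ModelParams(0.02, 0.002), n_maps=5, seed=9)
        assert t1.equals(t2)

    def test_j_zero_never_yields_founder_events(self):
        tree, _ = sim_tree(990)
        strata = [Stratum(max(120.0, tree.root_age), 0.0)]
        geo, _ = simulate_ranges(tree, ModelSpec("DIVALIKE", "M1"),
                                 ModelParams(0.02, 0.002, x=-0.5), strata, 1,
                                 ["A", "B", "C"], seed=5)
        model = RangeEvolutionModel(tree, geo, ModelSpec("DIVALIKE", "M1"),
                                    strata)
        for h in sample_histories(model, ModelParams(0.02, 0.002, x=-0.5),
                                  20, seed=6):
            assert count_events(h).counts["founder"] == 0


class TestSummaries:
    def test_percentages_sum_to_100(self):
        tree, _ = sim_tree(1100)
        strata = [Stratum(max(120.0, tree.root_age), 0.0)]
        geo, _ = simulate_ranges(tree, ModelSpec("DEC", "M2"),
                                 ModelParams(0.03, 0.002, j=0.6), strata, 1,
                                 ["A", "B", "C"], seed=7)
        model = RangeEvolutionModel(tree, geo, ModelSpec("DEC", "M2"),
                                    strata)
        table = summarize_bsm(model, ModelParams(0.03, 0.002, j=0.6),
                              n_maps=10, seed=8)
        assert table["percent"].sum() == pytest.approx(100.0, abs=0.1)
        assert set(table["type"]) == set(CATEGORIES)

    def test_n_maps_guard(self):
        tree = make_timetree((50.0, ("T1", 10.0), ("T2", 20.0)))
        geo = GeographyTable(["A"], {"T1": 1, "T2": 1})
        model = RangeEvolutionModel(tree, geo, ModelSpec("DEC", "M0"),
                                    [Stratum(60.0, 0.0)])
        with pytest.raises(ValueError):
            summarize_bsm(model, ModelParams(0, 0), n_maps=1)

    def test_history_event_log_frame(self):
        tree = make_timetree((50.0, ("T1", 10.0), ("T2", 20.0)))
        geo = GeographyTable(["A", "B"], {"T1": 1, "T2": 2})
        model = RangeEvolutionModel(tree, geo, ModelSpec("DEC", "M0"),
                                    [Stratum(60.0, 0.0)])
        from fossilrange.bsm import history_to_frame
        h = sample_history(model, ModelParams(0.05, 0.01), seed=2)
        df = history_to_frame(h, model.space)
        assert {"branch", "time_ma", "type", "from_range",
                "to_range"} <= set(df.columns)
        assert (df["type"] == "vicariance").sum() + \
            (df["type"] == "sympatry").sum() + \
            (df["type"] == "subset_speciation").sum() == 1  # one node

    def test_percentage_definition_from_mean_counts(self):
        means = {"range_expansion": 28.1, "range_contraction": 0.0,
                 "founder": 0.0, "sympatry": 71.9, "subset_speciation": 0.0,
                 "vicariance": 27.1}
        pct = percentage_from_means(means)
        assert pct["vicariance"] == pytest.approx(21.3, abs=0.05)
        assert sum(pct.values()) == pytest.approx(100.0)


class TestPathSampler:
    """Endpoint-conditioned uniformization vs naive rejection sampling."""

    @pytest.mark.parametrize("a,b,t", [(0, 0, 8.0), (0, 1, 12.0),
                                       (1, 0, 20.0)])
    def test_event_count_distribution_matches_rejection(self, a, b, t):
        # 3-state chain over 2 areas restricted to non-null states
        space = StateSpace(["A", "B"])
        Q = build_q(space, ModelParams(d=0.08, e=0.03), Stratum(30.0, 0.0))
        # map endpoints onto non-null state indices {A}=1, {B}=2, {AB}=3
        a_i, b_i = a + 1, b + 1
        n_draws = 10_000
        rng = np.random.default_rng(55)

        uni = _Uniformizer([Q])
        cond_counts = np.zeros(8, dtype=int)
        for _ in range(n_draws):
            states = uni.sample_path(0, a_i, b_i, t, rng)
            real = sum(1 for s0, s1 in zip(states, states[1:]) if s0 != s1)
            cond_counts[min(real, 7)] += 1

        # naive rejection: forward Gillespie, keep paths hitting b
        rej_counts = np.zeros(8, dtype=int)
        kept = 0
        while kept < n_draws:
            s = a_i
            clock = 0.0
            real = 0
            while True:
                rate = -Q[s, s]
                if rate <= 0:
                    break
                clock += rng.exponential(1 / rate)
                if clock >= t:
                    break
                p = Q[s].clip(min=0)
                p[s] = 0
                s = int(rng.choice(len(p), p=p / p.sum()))
                real += 1
            if s == b_i:
                rej_counts[min(real, 7)] += 1
                kept += 1

        # two-sample homogeneity test on jointly well-populated bins
        from scipy.stats import chi2_contingency
        keep = (cond_counts + rej_counts) >= 10
        _, p, _, _ = chi2_contingency(
            np.vstack([cond_counts[keep], rej_counts[keep]]))
        assert p > 0.01


class TestForwardConsistency:
    def test_bsm_means_match_forward_truth(self):
        """Pooled BSM means equal forward-simulation truth (3 s.e.)."""
        tree, _ = sim_tree(1300, min_tips=25)
        strata = [Stratum(max(120.0, tree.root_age), 0.0)]
        spec = ModelSpec("DEC", "M2", max_range_size=2)
        params = ModelParams(d=0.03, e=0.002, j=0.4)
        areas = ["A", "B", "C"]

        n_data = 10
        n_fwd = 300
        fwd = []
        for s in range(n_fwd):
            _, hist = simulate_ranges(tree, spec, params, strata, 1, areas,
                                      seed=5000 + s)
            fwd.append([count_events(hist).counts[c] for c in CATEGORIES])
        fwd = np.array(fwd, dtype=float)

        bsm_means = []
        for s in range(n_data):
            geo, _ = simulate_ranges(tree, spec, params, strata, 1, areas,
                                     seed=7000 + s)
            # condition on the generating root range so the identity
            # E_data[E(counts | data)] = E_forward[counts] is exact
            model = RangeEvolutionModel(tree, geo, spec, strata,
                                        root_prior=1)
            hs = sample_histories(model, params, 12, seed=100 + s)
            arr = np.array([[count_events(h).counts[c] for c in CATEGORIES]
                            for h in hs], dtype=float)
            bsm_means.append(arr.mean(axis=0))
        bsm_means = np.array(bsm_means)

        diff = bsm_means.mean(axis=0) - fwd.mean(axis=0)
        se = np.sqrt(fwd.var(ddof=1, axis=0) / n_fwd
                     + bsm_means.var(ddof=1, axis=0) / n_data)
        for c, d_, s_ in zip(CATEGORIES, diff, se):
            assert abs(d_) <= 3 * s_ + 1e-9, (c, d_, s_)
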