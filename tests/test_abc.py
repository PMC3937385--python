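import numpy as np
import pandas as pd
import pytest

from msatdem.abc import (
    ReferenceTable,
    build_reference_table,
    concat_tables,
    load_reference_table,
    model_choice_direct,
    model_choice_logistic,
    parameter_posterior,
    save_reference_table,
    summarize_dataset,
    summary_labels,
)
from msatdem.coalsim import MutationModel, SampleConfig, default_loci, simulate_dataset
from msatdem.demography import (
    MERGE,
    DemographicEvent,
    ParameterDraw,
    PriorSpec,
    Scenario,
    sample_parameters,
)
from conftest import build_dataset


def toy_table(stats_a, stats_b, params_a=None, params_b=None):
    """Hand-built two-scenario reference table."""
    stats = np.vstack([stats_a, stats_b])
    n_a, n_b = len(stats_a), len(stats_b)
    params = pd.DataFrame(
        {"t": np.concatenate([params_a if params_a is not None else np.ones(n_a),
                              params_b if params_b is not None else np.ones(n_b)])}
    )
    return ReferenceTable(
        scenario_ids=np.array(["A"] * n_a + ["B"] * n_b),
        params=params,
        stats=stats,
        stat_labels=[f"S{k}" for k in range(stats.shape[1])],
        scenarios=["A", "B"],
    )


def two_pop_scenario(t_low=100.0, t_high=50_000.0, n_low=100.0, n_high=10_000.0):
    return Scenario(
        "split",
        {"a": "N_a", "b": "N_b"},
        [DemographicEvent(MERGE, "t", derived="b", ancestor="a")],
        [
            PriorSpec("N_a", n_low, n_high),
            PriorSpec("N_b", n_low, n_high),
            PriorSpec("t", t_low, t_high),
        ],
    )


class TestSummaryVector:
    def test_layout_length(self):
        labels = summary_labels(["x", "y", "z"])
        assert len(labels) == 3 * 3 + 2 * 3  # 3P + 2*C(P,2)

    def test_identical_populations(self):
        rng = np.random.default_rng(0)
        pool = rng.integers(10, 15, size=(40, 4, 2))
        d = build_dataset({"a": pool[:20], "b": pool[:20].copy()})
        # duplicate blocks renamed: identical data in both populations
        d2 = build_dataset({"a": pool[:20], "b": pool[:20]})
        vec = summarize_dataset(d2)
        labels = summary_labels(["a", "b"])
        fst = vec[labels.index("fst:a|b")]
        dmu2 = vec[labels.index("dmu2:a|b")]
        assert abs(fst) < 0.05
        assert dmu2 == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_dataset(self):
        d = build_dataset({"a": [[[10, 10]]] * 3, "b": [[[10, 10]]] * 3})
        vec = summarize_dataset(d)
        labels = summary_labels(["a", "b"])
        assert vec[labels.index("he:a")] == 0.0
        assert vec[labels.index("var:a")] == 0.0

    def test_hand_built_dataset_oracle(self):
        """Each entry matches an independent spreadsheet-style evaluation."""
        d = build_dataset(
            {
                "a": [[[10, 10], [20, 22]], [[10, 12], [22, 22]]],
                "b": [[[12, 12], [24, 24]], [[12, 12], [24, 26]]],
            }
        )
        vec = summarize_dataset(d)
        labels = summary_labels(["a", "b"])
        # population a, locus 1: copies (10,10,10,12); locus 2: (20,22,22,22)
        assert vec[labels.index("nal:a")] == 2.0
        he_l1 = 4 / 3 * (1 - (0.75**2 + 0.25**2))
        he_l2 = 4 / 3 * (1 - (0.25**2 + 0.75**2))
        assert vec[labels.index("he:a")] == pytest.approx((he_l1 + he_l2) / 2)
        var_l1 = np.var([10, 10, 10, 12], ddof=1)
        var_l2 = np.var([20, 22, 22, 22], ddof=1)
        assert vec[labels.index("var:a")] == pytest.approx((var_l1 + var_l2) / 2)
        dmu2_l1 = (np.mean([10, 10, 10, 12]) - 12.0) ** 2
        dmu2_l2 = (np.mean([20, 22, 22, 22]) - np.mean([24, 24, 24, 26])) ** 2
        assert vec[labels.index("dmu2:a|b")] == pytest.approx((dmu2_l1 + dmu2_l2) / 2)

    def test_empty_population_rejected(self):
        d = build_dataset({"a": [[[0, 0]]], "b": [[[10, 10]]]})
        with pytest.raises(ValueError, match="no typed copies"):
            summarize_dataset(d)


class TestReferenceTable:
    CFG = SampleConfig({"a": (3, 3), "b": (3, 3)})
    MUT = MutationModel(5e-4, range_bound=40)

    def test_counts_per_scenario(self):
        s1 = two_pop_scenario()
        s2 = Scenario("s2", s1.populations, s1.events, s1.priors)
        tab = build_reference_table([s1, s2], 20, self.CFG, default_loci(3), self.MUT, seed=1)
        assert len(tab) == 40
        assert (tab.scenario_ids == "split").sum() == 20

    def test_scaling_positive(self):
        tab = build_reference_table(
            [two_pop_scenario()], 30, self.CFG, default_loci(3), self.MUT, seed=2
        )
        assert (tab.scaling > 0).all()

    def test_chunked_equals_single_shot(self):
        s = two_pop_scenario()
        full = build_reference_table([s], 12, self.CFG, default_loci(2), self.MUT, seed=3)
        c1 = build_reference_table([s], 12, self.CFG, default_loci(2), self.MUT, seed=3, start=0, stop=6)
        c2 = build_reference_table([s], 12, self.CFG, default_loci(2), self.MUT, seed=3, start=6, stop=12)
        merged = concat_tables([c1, c2])
        assert np.allclose(merged.stats, full.stats)
        assert merged.params.equals(full.params)

    def test_save_load_round_trip(self, tmp_path):
        tab = build_reference_table(
            [two_pop_scenario()], 10, self.CFG, default_loci(2), self.MUT, seed=4
        )
        save_reference_table(tab, tmp_path / "tab.tsv")
        back = load_reference_table(tmp_path / "tab.tsv")
        assert np.allclose(back.stats, tab.stats)
        assert back.stat_labels == tab.stat_labels
        assert back.populations == tab.populations
        assert list(back.scenario_ids) == list(tab.scenario_ids)


class TestModelChoiceDirect:
    def test_proportions_definition(self):
        rng = np.random.default_rng(0)
        # 300 A-records near the origin, 200 B-records slightly further,
        # the rest of both far away
        a = np.vstack([rng.normal(0, 0.1, (300, 2)), rng.normal(10, 0.1, (700, 2))])
        b = np.vstack([rng.normal(0.2, 0.1, (200, 2)), rng.normal(10, 0.1, (800, 2))])
        tab = toy_table(a, b)
        res = model_choice_direct(tab, np.zeros(2), n_closest=500)
        assert res.direct_probability["A"] == pytest.approx(0.6, abs=0.05)
        assert sum(res.direct_probability.values()) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_scenarios_certainty(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.5, (400, 3))
        b = rng.normal(50, 0.5, (400, 3))
        tab = toy_table(a, b)
        res = model_choice_direct(tab, a[0], n_closest=100)
        assert res.direct_probability["A"] == 1.0

    def test_identical_scenarios_symmetric(self):
        """Two scenarios with the same generating process: P ≈ 0.5 each."""
        s1 = two_pop_scenario()
        s2 = Scenario("twin", s1.populations, s1.events, s1.priors)
        cfg = SampleConfig({"a": (3, 3), "b": (3, 3)})
        mut = MutationModel(5e-4, range_bound=40)
        tab = build_reference_table([s1, s2], 300, cfg, default_loci(3), mut, seed=5)
        probs = []
        for rep in range(20):
            draw = sample_parameters(s1, 1, seed=1000 + rep)[0]
            obs = tab.summarize(simulate_dataset(s1, draw, cfg, default_loci(3), mut, seed=rep))
            probs.append(model_choice_direct(tab, obs, n_closest=50).direct_probability["split"])
        # mean over replicates within 3 binomial SE of 1/2
        se = 0.5 / np.sqrt(20 * 50)
        assert abs(np.mean(probs) - 0.5) < 3 * se + 0.05

    def test_n_closest_too_large(self):
        tab = toy_table(np.zeros((5, 2)), np.ones((5, 2)))
        with pytest.raises(ValueError):
            model_choice_direct(tab, np.zeros(2), n_closest=11)


class TestModelChoiceLogistic:
    def test_separable_scenarios(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.5, (300, 3))
        b = rng.normal(8, 0.5, (300, 3))
        tab = toy_table(a, b)
        res = model_choice_logistic(tab, np.zeros(3), n_regression=600)
        assert res.logistic_probability["A"] >= 0.99
        assert sum(res.logistic_probability.values()) == pytest.approx(1.0, abs=1e-9)

    def test_identical_scenarios_near_half(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1.0, (500, 3))
        b = rng.normal(0, 1.0, (500, 3))
        tab = toy_table(a, b)
        res = model_choice_logistic(tab, np.zeros(3), n_regression=1000)
        assert res.logistic_probability["A"] == pytest.approx(0.5, abs=0.1)

    def test_absent_scenario_warns_zero(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.3, (200, 2))
        b = rng.normal(40, 0.3, (200, 2))
        c = np.vstack([a, rng.normal(0.1, 0.3, (200, 2))])
        tab = ReferenceTable(
            scenario_ids=np.array(["A"] * 200 + ["B"] * 200 + ["C"] * 400),
            params=pd.DataFrame({"t": np.ones(800)}),
            stats=np.vstack([a, b, c]),
            stat_labels=["S0", "S1"],
            scenarios=["A", "B", "C"],
        )
        with pytest.warns(UserWarning, match="'B'"):
            res = model_choice_logistic(tab, np.zeros(2), n_regression=300)
        assert res.logistic_probability["B"] == 0.0

    def test_concordance_with_direct(self):
        """Direct and logistic rankings agree on a clearly separated study."""
        rng = np.random.default_rng(6)
        agree = 0
        for rep in range(20):
            centers = rng.normal(0, 3, size=(3, 4))
            stats = []
            ids = []
            for s, c in zip("ABC", centers):
                stats.append(c + rng.normal(0, 0.8, size=(200, 4)))
                ids += [s] * 200
            tab = ReferenceTable(
                scenario_ids=np.array(ids),
                params=pd.DataFrame({"t": np.ones(600)}),
                stats=np.vstack(stats),
                stat_labels=[f"S{k}" for k in range(4)],
                scenarios=list("ABC"),
            )
            obs = centers[0] + rng.normal(0, 0.8, size=4)
            direct = model_choice_direct(tab, obs, n_closest=60)
            logistic = model_choice_logistic(tab, obs, n_regression=300)
            agree += int(
                max(direct.direct_probability, key=direct.direct_probability.get)
                == max(logistic.logistic_probability, key=logistic.logistic_probability.get)
            )
        assert agree >= 18


class TestParameterPosterior:
    def test_degenerate_table_point_mass(self):
        rng = np.random.default_rng(7)
        stats = rng.normal(0, 1, size=(50, 2))
        tab = ReferenceTable(
            scenario_ids=np.array(["split"] * 50),
            params=pd.DataFrame({"N_a": np.full(50, 1000.0),
                                 "N_b": np.full(50, 1000.0),
                                 "t": np.full(50, 777.0)}),
            stats=stats,
            stat_labels=["S0", "S1"],
            scenarios=["split"],
        )
        post = parameter_posterior(tab, np.zeros(2), two_pop_scenario(), n_accept=50)
        t = post.parameters["t"]
        assert t.mode == pytest.approx(777.0, rel=1e-9)
        assert t.hpd_low == pytest.approx(777.0, rel=1e-9)
        assert t.hpd_high == pytest.approx(777.0, rel=1e-9)

    def test_no_adjustment_is_weighted_sample(self):
        sc = two_pop_scenario()
        rng = np.random.default_rng(8)
        t_vals = rng.uniform(100, 50_000, 300)
        tab = ReferenceTable(
            scenario_ids=np.array(["split"] * 300),
            params=pd.DataFrame({"N_a": np.full(300, 1000.0),
                                 "N_b": np.full(300, 1000.0),
                                 "t": t_vals}),
            stats=rng.normal(0, 1, size=(300, 2)),
            stat_labels=["S0", "S1"],
            scenarios=["split"],
        )
        post = parameter_posterior(tab, np.zeros(2), sc, n_accept=100, adjust=False)
        t = post.parameters["t"]
        d = tab.distances(np.zeros(2))
        accepted = np.argsort(d, kind="stable")[:100]
        assert np.allclose(np.sort(t.samples), np.sort(t_vals[accepted]))

    def test_hpd_within_prior_and_contains_mode(self):
        sc = two_pop_scenario()
        cfg = SampleConfig({"a": (4, 4), "b": (4, 4)})
        mut = MutationModel(5e-4, range_bound=40)
        tab = build_reference_table([sc], 400, cfg, default_loci(4), mut, seed=9)
        draw = sample_parameters(sc, 1, seed=77)[0]
        obs = tab.summarize(simulate_dataset(sc, draw, cfg, default_loci(4), mut, seed=78))
        post = parameter_posterior(tab, obs, sc, n_accept=100)
        for name, summ in post.parameters.items():
            prior = sc.prior(name)
            assert prior.low <= summ.hpd_low <= summ.hpd_high <= prior.high
            assert summ.hpd_low - 1e-9 <= summ.mode <= summ.hpd_high + 1e-9

    def test_mode_monotone_in_true_split_time(self):
        """Posterior mode of the split time tracks the truth across three
        well separated truth levels."""
        sc = two_pop_scenario()
        cfg = SampleConfig({"a": (5, 5), "b": (5, 5)})
        mut = MutationModel(5e-4, range_bound=40)
        tab = build_reference_table([sc], 1200, cfg, default_loci(6), mut, seed=10)
        modes = []
        for t_true in (300.0, 3000.0, 30_000.0):
            truth = ParameterDraw({"N_a": 2000.0, "N_b": 2000.0, "t": t_true}, "split")
            reps = []
            for rep in range(5):
                obs = tab.summarize(
                    simulate_dataset(sc, truth, cfg, default_loci(6), mut, seed=500 + rep)
                )
                post = parameter_posterior(tab, obs, sc, n_accept=120)
                reps.append(post.parameters["t"].mode)
            modes.append(np.median(reps))
        assert modes[0] < modes[1] < modes[2]

    def test_n_accept_too_large(self):
        tab = toy_table(np.zeros((5, 2)), np.ones((5, 2)))
        sc = two_pop_scenario()
        sc.id = "A"
        with pytest.raises(ValueError, match="exceeds"):
            parameter_posterior(tab, np.zeros(2), sc, n_accept=10)

    def test_probabilities_sum_to_one_everywhere(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, (100, 2))
        b = rng.normal(1, 1, (100, 2))
        tab = toy_table(a, b)
        res_d = model_choice_direct(tab, np.zeros(2), n_closest=50)
        res_l = model_choice_logistic(tab, np.zeros(2), n_regression=150)
        assert sum(res_d.direct_probability.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(res_l.logistic_probability.values()) == pytest.approx(1.0, abs=1e-9)
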