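"""Evaluation metrics, baselines, and inference operations."""

import numpy as np
import pytest

from phosphodyn import evalsuite as ev
from phosphodyn.io import PhosphoTimeCourse
from phosphodyn.model import ModelConfig, PhosphoModel, make_no_pkn_variant
from phosphodyn.pkn import network_from_edges
from phosphodyn.rnn import PerturbationDesign
from phosphodyn.site_map import SiteAssignment


def _tc(values, times=None):
    values = np.asarray(values, dtype=float)
    S, K, I = values.shape
    return PhosphoTimeCourse(values, np.ones_like(values, dtype=bool),
                             [f"s{i}" for i in range(S)],
                             times if times is not None else np.arange(K, dtype=float),
                             [f"p{i}" for i in range(I)])


class TestBaselineSubtract:
    def test_constant_trajectory_becomes_zero(self):
        tc = _tc(np.full((1, 4, 2), 3.0))
        out = ev.baseline_subtract_t0(tc)
        assert np.all(out.values == 0)

    def test_hand_example(self):
        tc = _tc(np.array([[[1.0], [3.0], [4.0]]]))
        out = ev.baseline_subtract_t0(tc)
        assert np.allclose(out.values[0, :, 0], [0, 2, 3])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        tc = _tc(rng.normal(size=(2, 5, 3)))
        once = ev.baseline_subtract_t0(tc)
        twice = ev.baseline_subtract_t0(once)
        assert np.array_equal(once.values, twice.values)

    def test_missing_t0_errors(self):
        tc = _tc(np.zeros((1, 3, 1)), times=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError, match="t = 0"):
            ev.baseline_subtract_t0(tc)


class TestPearsonDifferential:
    def test_identical_differences(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=20)
        c = rng.normal(size=20)
        assert ev.pearson_differential(d + c, d, c, 0.0) == pytest.approx(1.0)

    def test_negated_differences(self):
        d = np.array([1.0, -2.0, 3.0, 0.5])
        assert ev.pearson_differential(-d, d) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        p, o, pc, oc = (rng.normal(size=100) for _ in range(4))
        dp, do = p - pc, o - oc
        expected = (np.mean(dp * do) - dp.mean() * do.mean()) / (
            dp.std() * do.std())
        assert ev.pearson_differential(p, o, pc, oc) == pytest.approx(expected)

    def test_no_controls_equals_plain_pearson(self):
        from scipy import stats
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=30), rng.normal(size=30)
        assert ev.pearson_differential(a, b) == pytest.approx(
            stats.pearsonr(a, b).statistic)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="undefined correlation"):
            ev.pearson_differential(np.ones(5), np.arange(5.0))


class TestNaiveBaseline:
    def test_mean_of_remaining(self):
        responses = {"a": np.array([1.0, 2.0]), "b": np.array([3.0, 4.0]),
                     "held": np.array([9.0, 9.0])}
        assert np.allclose(ev.naive_drug_baseline("held", responses), [2.0, 3.0])

    def test_single_remaining(self):
        responses = {"a": np.array([1.0, 2.0]), "held": np.zeros(2)}
        assert np.allclose(ev.naive_drug_baseline("held", responses), [1, 2])

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        responses = {k: rng.normal(size=4) for k in "abcd"}
        fwd = ev.naive_drug_baseline("a", responses)
        rev = ev.naive_drug_baseline("a", dict(reversed(list(responses.items()))))
        assert np.allclose(fwd, rev)

    def test_no_remaining_errors(self):
        with pytest.raises(ValueError):
            ev.naive_drug_baseline("only", {"only": np.zeros(3)})


class TestBootstrap:
    def test_perfect_vs_anticorrelated(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(size=30)
        p = ev.bootstrap_compare(obs, -obs, obs, n_boot=100_000, seed=1)
        assert p <= 1e-5

    def test_identical_predictors_near_half(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(size=50)
        pred = obs + rng.normal(scale=0.5, size=50)
        p = ev.bootstrap_compare(pred, pred.copy(), obs, n_boot=2000, seed=2)
        assert 0.3 < p < 0.7

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(3)
        obs, a, b = (rng.normal(size=25) for _ in range(3))
        p1 = ev.bootstrap_compare(a, b, obs, n_boot=2000, seed=7)
        p2 = ev.bootstrap_compare(a, b, obs, n_boot=2000, seed=7)
        assert p1 == p2

    def test_too_few_sites(self):
        with pytest.raises(ValueError):
            ev.bootstrap_compare(np.ones(2), np.ones(2), np.ones(2))


class TestUpDownROC:
    def test_perfect_scores(self):
        obs = np.array([2.0, -2.0, 0.1, 1.5, -1.2, 0.0])
        out = ev.updown_roc(obs.copy(), obs, fc_threshold=1.0)
        assert out["up"] == 1.0 and out["down"] == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        obs = rng.normal(scale=1.5, size=10_000)
        pred = rng.normal(size=10_000)  # independent of labels
        out = ev.updown_roc(pred, obs, fc_threshold=1.0)
        assert abs(out["up"] - 0.5) < 0.03
        assert abs(out["down"] - 0.5) < 0.03

    def test_threshold_above_max_reports_missing(self):
        obs = np.array([0.1, -0.2, 0.3])
        out = ev.updown_roc(obs, obs, fc_threshold=1.0)
        assert out["up"] is None and out["down"] is None


class TestSeedStability:
    def test_identical_predictions_zero_cv(self):
        cv, summary = ev.seed_stability(lambda seed: np.ones((2, 3)), n_seeds=4)
        assert np.all(cv == 0)
        assert summary["frac_below_13pct"] == 1.0

    def test_hand_computed_two_seed_cv(self):
        cv, _ = ev.seed_stability(
            lambda seed: np.array([1.0 if seed == 0 else 3.0]), n_seeds=2)
        assert cv[0] == pytest.approx(np.sqrt(2) / 2)

    def test_near_zero_mean_reported_missing(self):
        cv, summary = ev.seed_stability(
            lambda seed: np.array([(-1.0) ** seed]), n_seeds=2)
        assert np.isnan(cv[0])
        assert summary["n_defined"] == 0

    def test_requires_two_seeds(self):
        with pytest.raises(ValueError):
            ev.seed_stability(lambda s: np.zeros(2), n_seeds=1)


class TestKinaseSubstrateInference:
    def _toy_model(self):
        """K1 -> A (activating); B unconnected to K1."""
        net = network_from_edges(
            ["A", "B", "K1", "R"],
            [("R", "K1", 1), ("K1", "A", 1), ("R", "B", 1)])
        net.receptor = "R"
        sites = SiteAssignment(["A:S1", "B:S1", "K1:S1"],
                               {"A:S1": "A", "B:S1": "B", "K1:S1": "K1"})
        design = PerturbationDesign(["control"], ["EGF"], [],
                                    np.ones((1, 1)), np.zeros((1, 0)),
                                    {}, {"EGF": ["R"]})
        model = PhosphoModel(net, sites, design, np.array([0.0, 10.0]),
                             ModelConfig(seed=0, n_steps=40,
                                         site_map_mode="identity",
                                         time_map_mode="fixed"),
                             fixed_anchors=np.array([0.0, 39.0]))
        # hand-set strong generating-style weights so inhibition propagates
        W = np.zeros((4, 4))
        idx = {n: i for i, n in enumerate(net.node_ids)}
        W[idx["K1"], idx["R"]] = 0.9
        W[idx["A"], idx["K1"]] = 0.9
        W[idx["B"], idx["R"]] = 0.9
        model.params["W"] = W
        model.params["b"] = np.zeros(4)
        return model

    def test_constructed_oracle_classification(self):
        model = self._toy_model()
        reference = [("K1", "A:S1"), ("K1", "B:S1")]
        res = ev.infer_kinase_substrates(model, ["K1"], reference,
                                         threshold=0.05)
        # A:S1 responds and is directly downstream -> validated
        assert res.validated["K1"] == ["A:S1"]
        # B:S1 is in the database but not directly downstream of K1
        assert res.database_only["K1"] == ["B:S1"]

    def test_three_lists_partition_candidates(self):
        model = self._toy_model()
        reference = [("K1", "B:S1")]
        res = ev.infer_kinase_substrates(model, ["K1"], reference,
                                         threshold=0.05)
        v, p, d = (set(res.validated["K1"]), set(res.predicted_only["K1"]),
                   set(res.database_only["K1"]))
        assert not (v & p) and not (v & d) and not (p & d)

    def test_unknown_kinase(self):
        model = self._toy_model()
        with pytest.raises(KeyError):
            ev.infer_kinase_substrates(model, ["NOPE"], [])


class TestNaiveDEInference:
    def test_identical_conditions_nothing_flagged(self):
        obs = np.array([1.0, 2.0, 3.0])
        res = ev.naive_de_inference(obs, obs, ["a", "b", "c"], "K1",
                                    [("K1", "a")])
        assert res.validated["K1"] == [] and res.predicted_only["K1"] == []
        assert res.database_only["K1"] == ["a"]

    def test_single_large_difference_flagged(self):
        stim = np.zeros(3)
        inh = np.array([0.0, -2.0, 0.0])
        res = ev.naive_de_inference(inh, stim, ["a", "b", "c"], "K1",
                                    [("K1", "b")], threshold=0.5)
        assert res.validated["K1"] == ["b"]

    def test_no_shared_sites_errors(self):
        with pytest.raises(ValueError):
            ev.naive_de_inference(np.array([]), np.array([]), [], "K1", [])


def test_no_pkn_variant_counts_and_nesting(small_dataset):
    ds = small_dataset
    model = PhosphoModel(ds.ground_truth.network, ds.site_assignment, ds.design,
                         ds.timecourse.times, ModelConfig(seed=0, n_steps=20))
    variant = make_no_pkn_variant(model)
    n = ds.ground_truth.network.n_nodes
    assert int(variant.mask.sum()) == n * n
    assert not variant.has_sign_prior
    # nesting: the variant reproduces the masked model exactly when the
    # weights outside the prior support are zero (they are, by construction)
    x = model.build_inputs(ds.design)
    assert np.allclose(model.forward(x), variant.forward(x))


class TestProtocolsSmoke:
    """End-to-end protocol runs at miniature scale."""

    def test_interpolation_strategies_run_and_report(self, small_dataset,
                                                     quick_training_config):
        ds = small_dataset
        held = [5.0]
        frames = {}
        for strategy in ("linear", "one_to_one", "reference_site"):
            df = ev.run_interpolation_protocol(ds, held, strategy,
                                               cfg=quick_training_config)
            assert set(df.time) == {5.0}
            assert df.r.between(-1, 1).all()
            frames[strategy] = df
        # model strategies report the anchor they used
        assert "anchor" in frames["one_to_one"].columns
        assert frames["one_to_one"].anchor.item() == 4.0  # index of t=5

    def test_interpolation_rejects_t0_holdout(self, small_dataset):
        with pytest.raises(ValueError, match="baseline anchor"):
            ev.run_interpolation_protocol(small_dataset, [0.0], "linear")

    def test_ablation_ladder_runs(self, small_dataset, quick_training_config):
        df = ev.run_ablation_protocol(small_dataset, n_folds=2,
                                      cfg=quick_training_config,
                                      variants=("baseline", "embedding"),
                                      seed=0)
        assert list(df.variant) == ["baseline", "embedding"]
        assert df.r_mean.between(-1, 1).all()

    def test_drug_scaling_rejects_impossible_sizes(self, small_dataset):
        gt = small_dataset.ground_truth
        with pytest.raises(ValueError, match="not enough"):
            ev.run_drug_scaling_protocol(gt, [500], n_folds=1, n_seeds=1)

    def test_zero_shot_unknown_drug(self, small_dataset):
        with pytest.raises(KeyError):
            ev.zero_shot_loo(small_dataset, "D_nope")
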