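import numpy as np
import pandas as pd
import pytest

from stressnet.boosting import (
    BoostModel,
    Condition,
    PromoterSet,
    RegulatorPanel,
    Rule,
    TrainingExample,
    best_condition,
    boost_train,
    build_examples,
    evaluate_condition,
    extract_kmer_features,
    predict_score,
    reverse_complement,
)

from conftest import random_boost_instance


class TestKmerFeatures:
    def test_enumerates_all_windows(self):
        proms = PromoterSet({"g": "ACGTACGT"})
        feats = extract_kmer_features(proms, k_list=(4,))
        for kmer in ("ACGT", "CGTA", "GTAC", "TACG"):
            assert feats.has("g", kmer)
        assert not feats.has("g", "AAAA")

    def test_reverse_complement_matching(self):
        proms = PromoterSet({"g": "TTTTTT"})
        feats = extract_kmer_features(proms, k_list=(4,))
        assert feats.has("g", "AAAA")
        feats_fwd = extract_kmer_features(proms, k_list=(4,), with_revcomp=False)
        assert not feats_fwd.has("g", "AAAA")

    def test_n_blocks_every_window(self):
        proms = PromoterSet({"g": "AANAA"})
        feats = extract_kmer_features(proms, k_list=(4,))
        assert len(feats.motifs) == 0

    def test_k_larger_than_all_promoters_rejected(self):
        with pytest.raises(ValueError):
            extract_kmer_features(PromoterSet({"g": "ACGT"}), k_list=(10,))
        with pytest.raises(ValueError):
            extract_kmer_features(PromoterSet({"g": "ACGT"}), k_list=(2,))


class TestPromoterSet:
    def test_uppercases_and_validates(self):
        p = PromoterSet({"g": "acgt"})
        assert p.sequences["g"] == "ACGT"
        with pytest.raises(ValueError):
            PromoterSet({"g": "ACGU"})
        with pytest.raises(ValueError):
            PromoterSet({"g": ""})


class TestBuildExamples:
    calls = pd.DataFrame(
        {"c1": [1, 1], "c2": [1, 0], "c3": [-1, 1]}, index=["gA", "gB"]
    )

    def test_one_example_per_nonzero_call_uniform_weights(self):
        ex = build_examples(self.calls)
        assert len(ex) == 5
        assert all(e.weight == pytest.approx(1 / 5) for e in ex)
        assert ("gB", "c2") not in {(e.gene, e.condition) for e in ex}

    def test_labels_preserved(self):
        ex = {(e.gene, e.condition): e.label for e in build_examples(self.calls)}
        assert ex[("gA", "c3")] == -1 and ex[("gB", "c3")] == 1

    def test_all_zero_calls_rejected(self):
        zero = pd.DataFrame({"c1": [0]}, index=["g"])
        with pytest.raises(ValueError, match="nothing to learn"):
            build_examples(zero)


class TestEvaluateCondition:
    proms = PromoterSet({"gA": "AAACCCGGG", "gB": "TTTTTTTTT"})
    feats = extract_kmer_features(proms, k_list=(5,))
    panel = RegulatorPanel(pd.DataFrame({"c1": [1], "c2": [-1]}, index=["tfX"]))

    def test_motif_ignores_condition(self):
        cond = Condition("motif", motif="AAACC")
        for c in ("c1", "c2"):
            assert evaluate_condition(cond, TrainingExample("gA", c, 1), self.feats, self.panel)
        assert not evaluate_condition(
            cond, TrainingExample("gB", "c1", 1), self.feats, self.panel
        )

    def test_regulator_state_matches_stated_direction(self):
        cond = Condition("regulator_state", tf="tfX", state=1)
        assert evaluate_condition(cond, TrainingExample("gB", "c1", 1), self.feats, self.panel)
        assert not evaluate_condition(
            cond, TrainingExample("gB", "c2", 1), self.feats, self.panel
        )

    def test_conjunction_is_logical_and(self):
        cond = Condition("conjunction", motif="AAACC", tf="tfX", state=1)
        table = {
            ("gA", "c1"): True,
            ("gA", "c2"): False,
            ("gB", "c1"): False,
            ("gB", "c2"): False,
        }
        for (g, c), expected in table.items():
            assert (
                evaluate_condition(cond, TrainingExample(g, c, 1), self.feats, self.panel)
                is expected
            )

    def test_unknown_tf_rejected(self):
        with pytest.raises(KeyError):
            evaluate_condition(
                Condition("regulator_state", tf="nope", state=1),
                TrainingExample("gA", "c1", 1),
                self.feats,
                self.panel,
            )


class TestBestCondition:
    def test_perfect_separator_achieves_minimal_z(self):
        # gA, gB carry the motif and are +1; gC, gD lack it and are -1
        proms = PromoterSet(
            {
                "gA": "GGAAACCCGG",
                "gB": "TTAAACCCTT",
                "gC": "GGGGGTGGGG",
                "gD": "CCCCCTCCCC",
            }
        )
        feats = extract_kmer_features(proms, k_list=(6,))
        panel = RegulatorPanel(pd.DataFrame({"c1": [1]}, index=["tfX"]))
        examples = [
            TrainingExample("gA", "c1", 1, 0.25),
            TrainingExample("gB", "c1", 1, 0.25),
            TrainingExample("gC", "c1", -1, 0.25),
            TrainingExample("gD", "c1", -1, 0.25),
        ]
        candidates = [Condition("motif", motif=m) for m in feats.motifs] + [
            Condition("regulator_state", tf="tfX", state=1)
        ]
        chosen, z = best_condition(candidates, examples, feats, panel)
        # the winner must satisfy exactly the +1 examples
        sat = [evaluate_condition(chosen, e, feats, panel) for e in examples]
        assert sat == [True, True, False, False]
        for cand in candidates:
            s = [evaluate_condition(cand, e, feats, panel) for e in examples]
            if s != [True, True, False, False] and s != [False, False, True, True]:
                _, z_other = best_condition([cand], examples, feats, panel)
                assert z <= z_other + 1e-12

    def test_uniform_labels_tie_broken_by_kind_then_lex(self):
        proms = PromoterSet({"gA": "AAAAAA", "gB": "AAAAAA"})
        feats = extract_kmer_features(proms, k_list=(4,))
        panel = RegulatorPanel(pd.DataFrame({"c1": [1, 1]}, index=["tfA", "tfB"]))
        examples = [
            TrainingExample("gA", "c1", 1, 0.5),
            TrainingExample("gB", "c1", 1, 0.5),
        ]
        # every candidate is satisfied by both examples -> exact Z ties;
        # regulator_state outranks motif, then lexicographic tf id
        candidates = [
            Condition("motif", motif="AAAA"),
            Condition("regulator_state", tf="tfB", state=1),
            Condition("regulator_state", tf="tfA", state=1),
        ]
        chosen, _ = best_condition(candidates, examples, feats, panel)
        assert chosen == Condition("regulator_state", tf="tfA", state=1)

    def test_duplicated_candidates_deterministic(self):
        proms = PromoterSet({"gA": "AAACCC", "gB": "GGGTTT"})
        feats = extract_kmer_features(proms, k_list=(4,))
        panel = RegulatorPanel(pd.DataFrame({"c1": [1]}, index=["tfX"]))
        examples = [
            TrainingExample("gA", "c1", 1, 0.5),
            TrainingExample("gB", "c1", -1, 0.5),
        ]
        cands = [Condition("motif", motif="AAAC")] * 3
        c1, _ = best_condition(cands, examples, feats, panel, rng=np.random.default_rng(0))
        c2, _ = best_condition(cands, examples, feats, panel, rng=np.random.default_rng(0))
        assert c1 == c2


class TestBoostTrain:
    def _separable(self):
        proms = PromoterSet(
            {
                "gA": "GGCATTACGG",
                "gB": "TTCATTACTT",
                "gC": "GGGGGTGGGG",
                "gD": "CCCCCTCCCC",
            }
        )
        feats = extract_kmer_features(proms, k_list=(6,))
        panel = RegulatorPanel(pd.DataFrame({"c1": [1]}, index=["tfX"]))
        calls = pd.DataFrame({"c1": [1, 1, -1, -1]}, index=["gA", "gB", "gC", "gD"])
        return build_examples(calls), feats, panel

    def test_separable_toy_reaches_zero_error_in_one_round(self):
        examples, feats, panel = self._separable()
        model = boost_train(examples, feats, panel, rounds=1, seed=0, subsample_rate=1.0)
        assert model.error_trace[-1] == 0.0

    def test_zero_rounds_rejected(self):
        examples, feats, panel = self._separable()
        with pytest.raises(ValueError):
            boost_train(examples, feats, panel, rounds=0)

    def test_training_error_bounded_by_product_of_normalizers(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            examples, feats, panel = random_boost_instance(rng)
            model = boost_train(examples, feats, panel, rounds=8, seed=1)
            bound = np.cumprod(model.z_trace)
            for err, zprod in zip(model.error_trace, bound):
                assert err <= zprod + 1e-9

    def test_normalizer_at_most_one(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            examples, feats, panel = random_boost_instance(rng)
            eps = 1.0 / (4 * len(examples))
            model = boost_train(examples, feats, panel, rounds=6, seed=2, epsilon=eps)
            assert all(z <= 1 + 1e-9 for z in model.z_trace)

    def test_bit_reproducible_with_same_seed(self, small_planted):
        sp = small_planted
        m1 = boost_train(sp["examples"], sp["features"], sp["panel"], rounds=12, seed=5)
        m2 = boost_train(sp["examples"], sp["features"], sp["panel"], rounds=12, seed=5)
        assert m1.to_json() == m2.to_json()

    def test_model_json_round_trip(self, small_planted):
        sp = small_planted
        m = boost_train(sp["examples"], sp["features"], sp["panel"], rounds=5, seed=3)
        restored = BoostModel.from_json(m.to_json())
        assert restored.rules == m.rules
        assert restored.z_trace == m.z_trace


class TestPredictScore:
    proms = PromoterSet({"gA": "AAACCCG", "gB": "TTTGGGA"})
    feats = extract_kmer_features(proms, k_list=(5,))
    panel = RegulatorPanel(pd.DataFrame({"c1": [1]}, index=["tfX"]))

    def test_empty_model_scores_zero(self):
        assert predict_score(BoostModel(), "gA", "c1", self.feats, self.panel) == 0.0

    def test_single_rule(self):
        rule = Rule(Condition("motif", motif="AAACC"), 0.7, -0.2, 0)
        model = BoostModel([rule])
        assert predict_score(model, "gA", "c1", self.feats, self.panel) == pytest.approx(0.7)
        assert predict_score(model, "gB", "c1", self.feats, self.panel) == pytest.approx(-0.2)

    def test_score_additive_over_concatenated_models(self, small_planted):
        sp = small_planted
        m1 = boost_train(sp["examples"], sp["features"], sp["panel"], rounds=4, seed=1)
        m2 = boost_train(sp["examples"], sp["features"], sp["panel"], rounds=4, seed=2)
        combined = BoostModel(m1.rules + m2.rules)
        g = sp["truth"].regulons[sp["truth"].tfs[0]][0]
        c = sp["panel"].conditions[0]
        f = lambda mod: predict_score(mod, g, c, sp["features"], sp["panel"])
        assert f(combined) == pytest.approx(f(m1) + f(m2))

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            predict_score(BoostModel(), "missing", "c1", self.feats, self.panel)


def test_structure_recovery_to_noise_floor():
    """At the converged operating point the learner recovers the planted
    regulon structure down to the label-noise floor: mean training accuracy
    on regulon examples >= 0.9 (= 1 - eta attainable by following TF
    states) across seeds."""
    from stressnet.simulate import NetworkSimConfig, generate_planted_network

    cfg = NetworkSimConfig(n_decoy_genes=0)
    accs = []
    for seed in range(3):
        proms, panel, dem, truth = generate_planted_network(cfg, seed=seed)
        feats = extract_kmer_features(proms)
        examples = build_examples(dem.calls)
        model = boost_train(examples, feats, panel, rounds=400, seed=seed)
        accs.append(1 - model.error_trace[-1])
    assert np.mean(accs) >= 0.9
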