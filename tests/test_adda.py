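import numpy as np
import pytest
from dataclasses import replace

from p300adapt.adda import (
    AdaptConfig,
    _to_network_shape,
    adversarial_adapt,
    init_target_extractor,
    run_wd_adstcn,
    split_target,
)
from p300adapt.adda import test_target as evaluate_on_target
from p300adapt.containers import ContractError
from p300adapt.nn import MLP, bce_with_logits
from p300adapt.stcnn import STCNNConfig, TrainConfig, extract_features, pretrain
from p300adapt.synthetic import (
    CohortConfig,
    SubjectProfile,
    make_cohort,
    simulate_subject,
)


@pytest.fixture(scope="module")
def small_setup():
    """Pretrained model + source pool + target, seconds-scale."""
    cohort, _, profiles = make_cohort(CohortConfig(
        n_healthy=3, n_doc=1, n_targets=50, n_nontargets=50, master_seed=21))
    cfg = STCNNConfig()
    sources = [_to_network_shape(es, cfg) for es in cohort
               if es.domain_tag == "source"]
    target = _to_network_shape(
        [es for es in cohort if es.domain_tag == "target"][0], cfg)
    model = pretrain(cfg, TrainConfig(max_epochs=8, seed=4), sources)
    return model, sources, target, profiles


FAST_ADAPT = AdaptConfig(n_adversarial_steps=30, seed=9)


class TestInitTargetExtractor:
    def test_copy_is_exact_and_isolated(self, small_setup):
        model, *_ = small_setup
        mt = init_target_extractor(model)
        for a, b in zip(mt.params, model.extractor.params):
            np.testing.assert_array_equal(a, b)
        mt.Ws += 1.0
        assert not np.array_equal(mt.Ws, model.extractor.Ws)

    def test_fresh_copy_reproduces_source_features(self, small_setup, rng):
        model, *_ = small_setup
        mt = init_target_extractor(model)
        x = rng.normal(size=(3, 150, 10))
        np.testing.assert_array_equal(extract_features(model, x),
                                      extract_features(model, x, mt))


class TestAdversarialAdapt:
    def test_zero_steps_returns_exact_copy(self, small_setup):
        model, sources, target, _ = small_setup
        res = adversarial_adapt(model, sources, target.without_labels(),
                                adapt_config=replace(FAST_ADAPT,
                                                     n_adversarial_steps=0))
        for a, b in zip(res.target_extractor.params, model.extractor.params):
            np.testing.assert_array_equal(a, b)

    def test_source_model_frozen_through_adaptation(self, small_setup):
        model, sources, target, _ = small_setup
        before = model.weight_snapshot()
        adversarial_adapt(model, sources, target.without_labels(),
                          adapt_config=FAST_ADAPT)
        after = model.weight_snapshot()
        for a, b in zip(before, after):
            np.testing.assert_array_equal(a, b)

    def test_target_labels_are_never_used(self, small_setup):
        model, sources, target, _ = small_setup
        with_labels = adversarial_adapt(model, sources, target,
                                        adapt_config=FAST_ADAPT)
        without = adversarial_adapt(model, sources, target.without_labels(),
                                    adapt_config=FAST_ADAPT)
        for a, b in zip(with_labels.target_extractor.params,
                        without.target_extractor.params):
            np.testing.assert_array_equal(a, b)
        assert with_labels.discriminator_accuracy == without.discriminator_accuracy

    def test_loss_curves_have_requested_length(self, small_setup):
        model, sources, target, _ = small_setup
        res = adversarial_adapt(model, sources, target.without_labels(),
                                adapt_config=FAST_ADAPT)
        assert len(res.d_loss_curve) == 30
        assert len(res.mapping_loss_curve) == 30

    def test_discriminator_loss_at_init_near_two_ln2(self, small_setup, rng):
        model, sources, target, _ = small_setup
        disc = MLP(model.extractor.n_features, (32,), 1, rng)
        fs = extract_features(model, sources[0].epochs[:40])
        ft = extract_features(model, target.epochs[:40])
        loss_s, _ = bce_with_logits(disc.forward(fs), np.ones(len(fs)))
        loss_t, _ = bce_with_logits(disc.forward(ft), np.zeros(len(ft)))
        assert loss_s + loss_t == pytest.approx(2 * np.log(2.0), abs=0.1)

    def test_adaptation_near_neutral_when_domains_already_match(self):
        """Adapting onto an identically-distributed target should not move
        accuracy by more than a few points (median over 5 seeds)."""
        cohort, _, profiles = make_cohort(CohortConfig(
            n_healthy=3, n_doc=0, n_targets=60, n_nontargets=60,
            master_seed=5))
        cfg = STCNNConfig()
        sources = [_to_network_shape(es, cfg) for es in cohort]
        model = pretrain(cfg, TrainConfig(max_epochs=10, seed=1), sources)
        twin = replace(profiles[0], subject_id="twin", seed=987654)
        target = _to_network_shape(simulate_subject(twin, 60, 60), cfg)
        pre = evaluate_on_target(None, model, target)["accuracy"]
        deltas = []
        for seed in range(5):
            res = adversarial_adapt(
                model, sources, target.without_labels(),
                adapt_config=AdaptConfig(n_adversarial_steps=200, seed=seed))
            post = evaluate_on_target(res, model, target)["accuracy"]
            deltas.append(post - pre)
        assert abs(np.median(deltas)) <= 0.05


class TestTestTarget:
    def test_accuracy_is_fraction_correct(self, small_setup):
        model, _, target, _ = small_setup
        metrics = evaluate_on_target(None, model, target)
        proba_correct = metrics["accuracy"] * metrics["n_epochs"]
        assert proba_correct == pytest.approx(round(proba_correct))
        conf = np.array(metrics["confusion"])
        assert conf.sum() == metrics["n_epochs"]
        assert np.trace(conf) / conf.sum() == pytest.approx(metrics["accuracy"])

    def test_unlabeled_target_rejected(self, small_setup):
        model, _, target, _ = small_setup
        with pytest.raises(ContractError, match="label"):
            evaluate_on_target(None, model, target.without_labels())

    def test_label_independent_target_scores_at_chance(self):
        cohort, _, _ = make_cohort(CohortConfig(
            n_healthy=3, n_doc=0, n_targets=40, n_nontargets=40,
            master_seed=13))
        cfg = STCNNConfig()
        sources = [_to_network_shape(es, cfg) for es in cohort]
        model = pretrain(cfg, TrainConfig(max_epochs=8, seed=2), sources)
        flat = SubjectProfile("flat", p300_amplitude_uv=0.0, noise_sd_uv=4.0,
                              background_rhythm=(3.0, 10.0), seed=77)
        target = _to_network_shape(simulate_subject(flat, 200, 200), cfg)
        acc = evaluate_on_target(None, model, target)["accuracy"]
        assert abs(acc - 0.5) <= 3 * 0.5 / np.sqrt(400)


class TestRunPipeline:
    def test_identical_seed_identical_result(self, tiny_cohort,
                                             fast_pipeline_config):
        cohort, _, _ = tiny_cohort
        a = run_wd_adstcn(cohort, "P1", fast_pipeline_config)
        b = run_wd_adstcn(cohort, "P1", fast_pipeline_config)
        assert a.to_dict() == b.to_dict()

    def test_no_adapt_equals_direct_baseline(self, tiny_cohort,
                                             fast_pipeline_config):
        cohort, _, _ = tiny_cohort
        no_adapt = run_wd_adstcn(cohort, "P1",
                                 replace(fast_pipeline_config, no_adapt=True))
        zero_steps = run_wd_adstcn(
            cohort, "P1",
            replace(fast_pipeline_config,
                    adapt=replace(fast_pipeline_config.adapt,
                                  n_adversarial_steps=0)))
        assert no_adapt.accuracy == zero_steps.accuracy
        assert no_adapt.adaptation is None

    def test_unknown_target_rejected(self, tiny_cohort, fast_pipeline_config):
        cohort, _, _ = tiny_cohort
        with pytest.raises(ContractError):
            run_wd_adstcn(cohort, "nobody", fast_pipeline_config)

    def test_split_target_is_stratified_and_disjoint(self, tiny_cohort):
        cohort, _, _ = tiny_cohort
        target = cohort[-1]
        adapt_part, test_part = split_target(target, 0.5, seed=3)
        assert adapt_part.n_epochs + test_part.n_epochs == target.n_epochs
        assert adapt_part.labels.sum() == pytest.approx(test_part.labels.sum(),
                                                        abs=1)
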