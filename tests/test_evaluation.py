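import numpy as np
import pytest

from msdsanet.evaluation import (ConfusionCounts, TrainingConfig, confusion,
                                 embed_features, evaluate_holdout, kappa,
                                 kappa_marginal, metrics, noise_sweep, predict,
                                 run_subject_cv, train)
from msdsanet.model import MSDSANet


# ------------------------------------------------------------ confusion/metrics
def test_confusion_basic_and_inverted():
    c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
    assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)
    c = confusion([1, 1, 0, 0], [0, 0, 1, 1])
    assert (c.tp, c.tn) == (0, 0) and (c.fp, c.fn) == (2, 2)
    with pytest.raises(ValueError):
        confusion([1], [1, 0])


def test_confusion_matches_loop_oracle_on_random_pairs(rng):
    for _ in range(200):
        n = rng.integers(1, 50)
        yt = rng.integers(0, 2, n)
        yp = rng.integers(0, 2, n)
        c = confusion(yt, yp)
        tp = fn = fp = tn = 0
        for a, b in zip(yt, yp):
            if a == 1 and b == 1:
                tp += 1
            elif a == 1:
                fn += 1
            elif b == 1:
                fp += 1
            else:
                tn += 1
        assert (c.tp, c.fn, c.fp, c.tn) == (tp, fn, fp, tn)
        assert c.total == n


def test_metrics_hand_computed_table():
    m = metrics(ConfusionCounts(tp=45, fn=5, fp=10, tn=40))
    assert m["acc"] == pytest.approx(0.85)
    assert m["sn"] == pytest.approx(0.90)
    assert m["sp"] == pytest.approx(0.80)
    assert m["precision"] == pytest.approx(45 / 55)
    assert m["f1"] == pytest.approx(2 * (45 / 55) * 0.9 / (45 / 55 + 0.9))
    assert m["f1"] == pytest.approx(0.8571, abs=1e-4)


def test_metrics_perfect_and_degenerate():
    perfect = metrics(ConfusionCounts(tp=5, fn=0, fp=0, tn=5))
    assert all(v == pytest.approx(1.0) for v in perfect.values())
    with pytest.warns(UserWarning):
        m = metrics(ConfusionCounts(tp=0, fn=3, fp=0, tn=3))
    assert np.isnan(m["precision"]) and np.isnan(m["f1"])
    with pytest.raises(ValueError):
        metrics(ConfusionCounts(0, 0, 0, 0))


# ----------------------------------------------------------------------- kappa
def test_kappa_uniform_chance_values():
    assert kappa(0.75, 2) == pytest.approx(0.5)
    assert kappa(0.5, 2) == pytest.approx(0.0)
    assert kappa(1.0, 2) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        kappa(1.2, 2)
    with pytest.raises(ValueError):
        kappa(0.5, 1)


def test_kappa_identity_two_classes(rng):
    for p in rng.uniform(0, 1, 100):
        assert kappa(p, 2) == pytest.approx(2 * p - 1, abs=1e-12)


def test_kappa_forms_agree_on_balanced_table():
    c = ConfusionCounts(tp=40, fn=10, fp=10, tn=40)
    assert kappa_marginal(c) == pytest.approx(0.6)
    assert kappa(metrics(c)["acc"], 2) == pytest.approx(0.6)


def test_kappa_marginal_matches_sklearn(rng):
    from sklearn.metrics import cohen_kappa_score
    for _ in range(50):
        n = int(rng.integers(10, 60))
        yt = rng.integers(0, 2, n)
        yp = rng.integers(0, 2, n)
        if len(np.unique(yt)) < 2 or len(np.unique(yp)) < 2:
            continue
        assert kappa_marginal(confusion(yt, yp)) == pytest.approx(
            cohen_kappa_score(yt, yp), abs=1e-12)


# -------------------------------------------------------------------- training
def test_zero_learning_rate_leaves_weights_and_loss_unchanged(
        tiny_arrays, tiny_model_cfg):
    model = MSDSANet(tiny_model_cfg)
    before = {k: v.copy() for k, v in model.state_dict().items()
              if not k.endswith(("running_mean", "running_var"))}
    trace = train(model, tiny_arrays,
                  TrainingConfig(lr=0.0, batch_size=16, epochs=2, seed=1))
    after = model.state_dict()
    for k, v in before.items():
        np.testing.assert_array_equal(v, after[k])
    assert len(trace) == 2


def test_training_is_deterministic_given_seed(tiny_arrays, tiny_model_cfg):
    traces, states = [], []
    for _ in range(2):
        model = MSDSANet(tiny_model_cfg)
        traces.append(train(model, tiny_arrays,
                            TrainingConfig.reduced(epochs=1, batch_size=16, seed=7)))
        states.append(model.state_dict())
    assert traces[0] == traces[1]
    for k in states[0]:
        np.testing.assert_array_equal(states[0][k], states[1][k])


def test_loss_decreases_on_separable_data(tiny_arrays, tiny_model_cfg):
    model = MSDSANet(tiny_model_cfg)
    trace = train(model, tiny_arrays,
                  TrainingConfig.reduced(epochs=6, batch_size=16, seed=2))
    first, last = np.mean(trace[:2]), np.mean(trace[-2:])
    assert last < first


def test_train_rejects_empty_dataset(tiny_model_cfg):
    with pytest.raises(ValueError):
        train(MSDSANet(tiny_model_cfg),
              {"eeg": np.empty((0, 4, 128)), "grid": np.empty((0, 9, 9, 128)),
               "periph": np.empty((0, 1, 128)), "label": np.empty(0, int)},
              TrainingConfig.reduced())


# ------------------------------------------------------------ cross-validation
def test_cv_report_structure_and_reproducibility(tiny_arrays, tiny_model_cfg):
    hyper = TrainingConfig.reduced(epochs=1, batch_size=16, seed=4)
    r1 = run_subject_cv(tiny_arrays, tiny_model_cfg, hyper, k=3,
                        affect_dimension="valence")
    r2 = run_subject_cv(tiny_arrays, tiny_model_cfg, hyper, k=3,
                        affect_dimension="valence")
    assert len(r1.folds) == 3
    agg = r1.aggregate()
    for name in ("acc", "kappa", "f1", "sn", "sp"):
        vals = [f[name] for f in r1.folds]
        lo, hi = np.nanmin(vals), np.nanmax(vals)
        assert lo - 1e-12 <= agg[name]["mean"] <= hi + 1e-12
    assert r1.to_json() == r2.to_json()
    assert r1.config_fingerprint == r2.config_fingerprint


def test_cv_requires_enough_samples_per_class(tiny_model_cfg, tiny_arrays):
    few = {k: v[:4] for k, v in tiny_arrays.items()}
    with pytest.raises(ValueError, match="each class"):
        run_subject_cv(few, tiny_model_cfg, TrainingConfig.reduced(), k=10)


def test_holdout_report_contains_loss_trace(tiny_arrays, tiny_model_cfg):
    report, model = evaluate_holdout(
        tiny_arrays, tiny_model_cfg,
        TrainingConfig.reduced(epochs=1, batch_size=16, seed=5))
    assert len(report.extra["loss_trace"]) == 1
    assert report.extra["n_train"] + report.extra["n_test"] == 40
    assert 0.0 <= report.folds[0]["acc"] <= 1.0
    preds = predict(model, tiny_arrays)
    assert set(np.unique(preds)) <= {0, 1}


# ----------------------------------------------------------------- noise sweep
def test_noise_sweep_reference_equals_clean_run(tiny_trials, tiny_model_cfg):
    hyper = TrainingConfig.reduced(epochs=1, batch_size=16, seed=6)
    results = noise_sweep(tiny_trials, "valence", 5.0, tiny_model_cfg, hyper,
                          snr_list=(0.0,), seed=6)
    assert len(results) == 2                      # no-noise reference + 1 SNR
    assert np.isinf(results[0][0])
    from msdsanet.preprocessing import preprocess_trials, stack_samples
    arrays = stack_samples(preprocess_trials(tiny_trials, "valence", 5.0))
    clean, _ = evaluate_holdout(arrays, tiny_model_cfg, hyper)
    assert results[0][1].folds == clean.folds     # bit-identical metrics


# ------------------------------------------------------------------ embeddings
def test_embedding_shape_seeding_and_separation(rng):
    a = rng.normal(size=(40, 10)) + 8.0
    b = rng.normal(size=(40, 10)) - 8.0
    feats = np.vstack([a, b])
    labels = np.array([1] * 40 + [0] * 40)
    e1 = embed_features(feats, seed=3)
    e2 = embed_features(feats, seed=3)
    assert e1.shape == (80, 2)
    np.testing.assert_array_equal(e1, e2)
    # 1-NN label agreement in the embedded space
    agree = 0
    for i in range(80):
        d = np.linalg.norm(e1 - e1[i], axis=1)
        d[i] = np.inf
        agree += labels[d.argmin()] == labels[i]
    assert agree / 80 >= 0.95
    with pytest.raises(ValueError):
        embed_features(feats[:4])
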