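"""Generator/discriminator behaviour, balanced batching, adversarial training."""

import numpy as np
import pytest

import eplink
from eplink.model import (DiscriminatorSpec, GeneratorSpec, TrainConfig,
                          balanced_batches, discriminator_forward,
                          generator_forward, init_discriminator,
                          init_generator, _as_tensors)
from conftest import separable_table


@pytest.fixture(scope="module")
def gparams():
    spec = GeneratorSpec()
    return spec, _as_tensors(init_generator(spec, np.random.default_rng(0)))


@pytest.fixture(scope="module")
def dparams():
    spec = DiscriminatorSpec()
    return spec, _as_tensors(init_discriminator(spec, np.random.default_rng(0)))


# ---------------------------------------------------------------------------
# forward passes


def test_generator_eval_is_deterministic(gparams):
    spec, params = gparams
    x = np.random.default_rng(1).normal(size=(5, 11))
    s1 = generator_forward(x, params, spec).data
    s2 = generator_forward(x, params, spec).data
    np.testing.assert_array_equal(s1, s2)


def test_generator_scores_stay_in_unit_interval(gparams):
    spec, params = gparams
    for seed in range(10):
        x = np.random.default_rng(seed).normal(scale=5, size=(8, 11))
        s = generator_forward(x, params, spec).data
        assert ((s > 0) & (s < 1)).all()


def test_zeroed_head_gives_half(gparams):
    spec, params = gparams
    params = dict(params)
    for k in ("head2.w", "head2.b"):
        params[k] = type(params[k])(np.zeros_like(params[k].data))
    x = np.random.default_rng(0).normal(size=(4, 11))
    np.testing.assert_allclose(generator_forward(x, params, spec).data, 0.5)


def test_generator_rejects_bad_input(gparams):
    spec, params = gparams
    with pytest.raises(ValueError, match="non-finite"):
        generator_forward(np.full((1, 11), np.nan), params, spec)
    with pytest.raises(ValueError, match="features"):
        generator_forward(np.zeros((1, 7)), params, spec)


def test_per_feature_token_layout_runs():
    spec = GeneratorSpec(token_layout="per_feature")
    params = _as_tensors(init_generator(spec, np.random.default_rng(0)))
    s = generator_forward(np.random.default_rng(1).normal(size=(6, 11)), params, spec).data
    assert s.shape == (6, 1) and ((s > 0) & (s < 1)).all()


def test_discriminator_zero_weights_give_half(dparams):
    spec, _ = dparams
    zeros = _as_tensors({k: np.zeros_like(v)
                         for k, v in init_discriminator(spec, np.random.default_rng(0)).items()})
    x = np.random.default_rng(0).normal(size=(3, 11))
    out = discriminator_forward(x, np.ones(3), zeros, spec).data
    np.testing.assert_allclose(out, 0.5)


def test_discriminator_range_and_determinism(dparams):
    spec, params = dparams
    x = np.random.default_rng(2).normal(size=(6, 11))
    y = np.random.default_rng(3).random(6)
    o1 = discriminator_forward(x, y, params, spec).data
    o2 = discriminator_forward(x, y, params, spec).data
    np.testing.assert_array_equal(o1, o2)
    assert ((o1 > 0) & (o1 < 1)).all()


# ---------------------------------------------------------------------------
# balanced batching


def test_balanced_batches_even_classes():
    X = np.arange(64, dtype=float).reshape(64, 1)
    y = np.array([1] * 32 + [0] * 32)
    batches = balanced_batches(X, y, 32, np.random.default_rng(0))
    assert len(batches) == 2
    for xb, yb in batches:
        assert len(yb) == 32 and (yb == 1).sum() == 16 and (yb == 0).sum() == 16
    seen = np.concatenate([xb.ravel() for xb, _ in batches])
    assert sorted(seen) == sorted(X.ravel())  # everything used exactly once


def test_balanced_batches_recycles_minority():
    X = np.arange(60, dtype=float).reshape(60, 1)
    y = np.array([1] * 10 + [0] * 50)
    batches = balanced_batches(X, y, 32, np.random.default_rng(0))
    neg_used = np.concatenate([xb[yb == 0].ravel() for xb, yb in batches])
    assert sorted(neg_used) == sorted(X[y == 0].ravel())  # majority exhausted once
    for xb, yb in batches[:-1]:
        assert (yb == 1).sum() == 16 and (yb == 0).sum() == 16
    # positives recycled through reshuffles, never more than needed
    assert sum((yb == 1).sum() for _, yb in batches) >= 48


def test_balanced_batches_seeded_reproducible():
    X = np.arange(40, dtype=float).reshape(40, 1)
    y = np.array([1] * 15 + [0] * 25)
    b1 = balanced_batches(X, y, 8, np.random.default_rng(7))
    b2 = balanced_batches(X, y, 8, np.random.default_rng(7))
    for (x1, y1), (x2, y2) in zip(b1, b2):
        np.testing.assert_array_equal(x1, x2)
        np.testing.assert_array_equal(y1, y2)


def test_balanced_batches_requires_both_classes():
    with pytest.raises(ValueError, match="both classes"):
        balanced_batches(np.zeros((4, 1)), np.array([1, 1, 1, 1]), 2,
                         np.random.default_rng(0))


# ---------------------------------------------------------------------------
# training


def test_training_loss_decreases_on_separable_data():
    table = separable_table(n=200, seed=0)
    model = eplink.train(table, config=TrainConfig(seed=0, epochs=10))
    hist = model.history["g_loss"]
    assert hist[model.best_epoch] < hist[0]
    assert all(np.isfinite(v) and v >= 0 for v in hist)
    assert all(np.isfinite(v) and v >= 0 for v in model.history["d_loss"])


def test_lambda_zero_equals_plain_supervised():
    table = separable_table(n=120, seed=1)
    m0 = eplink.train(table, config=TrainConfig(seed=3, lambda_adv=0.0))
    m1 = eplink.train(table, config=TrainConfig(seed=3, adversarial=False))
    np.testing.assert_allclose(m0.history["val_loss"], m1.history["val_loss"],
                               rtol=0, atol=1e-8)


def test_training_is_deterministic():
    table = separable_table(n=120, seed=2)
    m1 = eplink.train(table, config=TrainConfig(seed=5, epochs=5))
    m2 = eplink.train(table, config=TrainConfig(seed=5, epochs=5))
    assert m1.history == m2.history
    for k in m1.gparams:
        np.testing.assert_array_equal(m1.gparams[k], m2.gparams[k])


# ---------------------------------------------------------------------------
# prediction


def test_predict_row_permutation_equivariance(trained_small, small_split):
    _, test = small_split
    scores = eplink.predict(trained_small, test)
    perm = np.random.default_rng(0).permutation(len(test))
    np.testing.assert_allclose(
        eplink.predict(trained_small, test.subset(perm)), scores[perm], atol=1e-12
    )


def test_predict_invariant_to_batch_size(trained_small, small_split):
    _, test = small_split
    s1 = eplink.predict(trained_small, test, batch_size=3)
    s2 = eplink.predict(trained_small, test, batch_size=512)
    np.testing.assert_array_equal(s1, s2)


def test_predict_rejects_wrong_dimension(trained_small):
    with pytest.raises(ValueError, match="dimension"):
        eplink.predict(trained_small, np.zeros((3, 4)))


def test_true_pairs_score_above_null_pairs():
    """Planted couplings should receive higher scores than null pairs."""
    gaps = []
    for seed in range(5):
        cfg = eplink.SimConfig(n_enhancers=30, n_genes=45, n_true_pairs=24,
                               n_null_pairs=24, n_background_probes=10,
                               chrom_length=3_000_000, seed=seed)
        res = eplink.run_pipeline(sim_config=cfg, seed=seed, importance_repeats=0)
        s, y = res.test_scores, res.test_table.labels
        gaps.append(s[y == 1].mean() - s[y == 0].mean())
    assert np.mean(gaps) > 0
    assert sum(g > 0 for g in gaps) >= 4


# ---------------------------------------------------------------------------
# checkpointing


def test_checkpoint_roundtrip(tmp_path, trained_small, small_split):
    _, test = small_split
    path = tmp_path / "model.ckpt"
    eplink.save_checkpoint(trained_small, path)
    loaded = eplink.load_checkpoint(path)
    assert loaded.best_epoch == trained_small.best_epoch
    assert loaded.history == trained_small.history
    np.testing.assert_array_equal(
        eplink.predict(loaded, test), eplink.predict(trained_small, test)
    )


def test_spec_validation():
    with pytest.raises(ValueError):
        GeneratorSpec(hidden=65, n_heads=2)
    with pytest.raises(ValueError):
        TrainConfig(batch_size=1)
    with pytest.raises(ValueError):
        TrainConfig(val_fraction=1.5)


def test_train_config_from_yaml(tmp_path):
    p = tmp_path / "train.yaml"
    p.write_text("lr: 0.001\nepochs: 7\nseed: 4\n")
    cfg = eplink.model.load_train_config(p)
    assert cfg.lr == 0.001 and cfg.epochs == 7 and cfg.seed == 4
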