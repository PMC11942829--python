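"""Loss functions, the training loop and hyperparameter selection."""

import numpy as np
import pytest

from renodenoise.models import NetworkConfig, build_discriminator, build_model
from renodenoise.training import (TABLE_GRID, LossHistory, TrainingConfig,
                                  hyperparameter_search, mse_loss,
                                  relative_error, train)


# ------------------------------------------------------------- mse_loss ----

def test_mse_loss_closed_forms(rng):
    batch = rng.random((2, 8, 8))
    assert mse_loss(batch, batch) == 0.0
    assert mse_loss(np.ones((3, 4, 4)), np.zeros((3, 4, 4))) == 1.0
    with pytest.raises(ValueError):
        mse_loss(np.ones((2, 4, 4)), np.ones((2, 5, 5)))


def test_mse_loss_matches_brute_force(rng):
    a, b = rng.random((3, 6, 6)), rng.random((3, 6, 6))
    total = sum((float(a[i, j, k]) - float(b[i, j, k])) ** 2
                for i in range(3) for j in range(6) for k in range(6))
    assert abs(mse_loss(a, b) - total / a.size) < 1e-10


# ------------------------------------------------------- relative_error ----

def test_relative_error_closed_forms():
    img = np.full((4, 4), 3.0)
    assert relative_error(img, img) == 0.0
    assert relative_error(np.full((4, 4), 2.0), np.full((4, 4), 1.0)) == 50.0


def test_relative_error_matches_brute_force(rng):
    a, b = rng.random((5, 5)), rng.random((5, 5))
    a[0, 0] = b[0, 0] = 0.0     # exercise the both-zero rule
    expected = 0.0
    for i in range(5):
        for j in range(5):
            hi = max(a[i, j], b[i, j])
            expected += abs(a[i, j] - b[i, j]) / hi if hi > 0 else 0.0
    expected = expected / 25 * 100
    assert abs(relative_error(a, b) - expected) < 1e-10


def test_relative_error_degenerate_pair_warns():
    with pytest.warns(UserWarning):
        assert relative_error(np.zeros((3, 3)), np.zeros((3, 3))) == 0.0


# ------------------------------------------------------- TrainingConfig ----

def test_config_restricted_to_published_grid():
    TrainingConfig(batch_size=4, learning_rate=1e-5)   # on-grid: fine
    with pytest.raises(ValueError):
        TrainingConfig(batch_size=7)
    with pytest.raises(ValueError):
        TrainingConfig(learning_rate=0.5)
    TrainingConfig(batch_size=7, learning_rate=0.5, allow_off_grid=True)
    assert len(TABLE_GRID) == 6
    assert sum(c.optimizer == "sgd" for c in TABLE_GRID) == 1


# ---------------------------------------------------------------- train ----

@pytest.fixture(scope="module")
def tiny_setup(small_pairs=None):
    from tests.conftest import make_records
    from renodenoise import dose

    pairs, _ = dose.build_dataset(make_records(8, image_size=32, n_frames=30))
    return pairs[:6], pairs[6:]


def test_training_reduces_loss_and_records_history(tiny_setup):
    train_pairs, val_pairs = tiny_setup
    config = TrainingConfig(batch_size=4, learning_rate=1e-3, epochs=10, seed=2)
    model = build_model(NetworkConfig(family="udncnn", seed=2))
    model, history = train(model, train_pairs, val_pairs, config, target_size=32)
    assert len(history.train) == len(history.validation) == 11
    assert all(v >= 0 for v in history.train + history.validation)
    assert history.validation[-1] < history.validation[0]


def test_epoch_zero_is_pretraining_loss(tiny_setup):
    train_pairs, val_pairs = tiny_setup
    from renodenoise.training import _epoch_loss, _stack

    model = build_model(NetworkConfig(family="dncnn", seed=4))
    xs, ys = _stack(train_pairs, 32)
    before = _epoch_loss(model, xs, ys, 4)
    config = TrainingConfig(batch_size=4, learning_rate=1e-4, epochs=1, seed=4)
    _, history = train(model, train_pairs, val_pairs, config, target_size=32)
    assert history.train[0] == pytest.approx(before, rel=1e-6)


def test_training_is_seed_deterministic(tiny_setup):
    train_pairs, val_pairs = tiny_setup
    histories = []
    for _ in range(2):
        model = build_model(NetworkConfig(family="udncnn", seed=3))
        config = TrainingConfig(batch_size=4, learning_rate=1e-3, epochs=3, seed=3)
        _, history = train(model, train_pairs, val_pairs, config, target_size=32)
        histories.append(history.train)
    assert histories[0] == histories[1]


def test_identity_task_converges(tiny_setup):
    """On a noiseless identity task (target = input) the default config
    drives the loss below 1e-4 well within 200 epochs."""
    train_pairs, _ = tiny_setup
    identity = []
    for p in train_pairs[:4]:
        q = type(p)(input_image=p.reference_image,
                    reference_image=p.reference_image, rois=p.rois)
        identity.append(q)
    model = build_model(NetworkConfig(family="dncnn", seed=0))
    config = TrainingConfig(batch_size=4, learning_rate=1e-3, epochs=120, seed=0)
    _, history = train(model, identity, identity, config, target_size=16)
    assert min(history.validation) < 1e-4
    assert history.validation[-1] < history.validation[0]


def test_adversarial_training_runs(tiny_setup):
    train_pairs, val_pairs = tiny_setup
    config = TrainingConfig(batch_size=4, learning_rate=1e-4, epochs=1, seed=1)
    model = build_model(NetworkConfig(family="attngan", seed=1))
    disc = build_discriminator(NetworkConfig(family="attngan", seed=1))
    model, history = train(model, train_pairs[:2], val_pairs[:2], config,
                           target_size=32, discriminator=disc)
    assert len(history.train) == 2
    assert np.isfinite(history.train).all()


def test_empty_split_rejected(tiny_setup):
    train_pairs, _ = tiny_setup
    config = TrainingConfig(epochs=1)
    with pytest.raises(ValueError):
        train(build_model(NetworkConfig()), train_pairs, [], config)


# ------------------------------------------------- hyperparameter search ----

def test_search_singleton_grid(tiny_setup):
    train_pairs, val_pairs = tiny_setup
    grid = [TrainingConfig(batch_size=4, learning_rate=1e-3, epochs=2, seed=0)]
    ranked = hyperparameter_search("dncnn", train_pairs, val_pairs[:1],
                                   val_pairs[1:], grid=grid, target_size=32)
    assert len(ranked) == 1 and ranked[0][0] is grid[0]


def test_search_ranking_is_a_permutation_and_penalises_crippled_lr(tiny_setup):
    train_pairs, val_pairs = tiny_setup
    good = TrainingConfig(batch_size=4, learning_rate=1e-3, epochs=6, seed=0)
    crippled = TrainingConfig(batch_size=4, learning_rate=1e3, epochs=6, seed=0,
                              allow_off_grid=True)
    ranked = hyperparameter_search("dncnn", train_pairs, val_pairs[:1],
                                   val_pairs[1:], grid=[crippled, good],
                                   target_size=32)
    assert {id(c) for c, _ in ranked} == {id(good), id(crippled)}
    assert ranked[-1][0] is crippled, "a diverging learning rate must rank last"
    assert ranked[0][1] <= ranked[-1][1]
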