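"""Training recipe: schedule, initialization, loop and serialization."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from monetseg.architectures import MoNetConfig, build_monet, count_parameters
from monetseg.nn import Conv2d
from monetseg.phantoms import PhantomConfig, phantom_slices
from monetseg.training import (
    IntegrityError,
    PlateauScheduler,
    TrainingConfig,
    deserialize_weights,
    initialize_weights,
    plateau_scheduler_step,
    replay_lr_trace,
    serialize_weights,
    serialized_size_bytes,
    train,
)


# -- plateau schedule -------------------------------------------------------

def test_plateau_decay_after_two_stagnant_epochs():
    """Hand simulation: [1.0, 0.9, 0.95, 0.94] with patience 2 decays at 4."""
    lr = plateau_scheduler_step([1.0, 0.9, 0.95, 0.94], 5e-4)
    assert lr == pytest.approx(5e-5)
    assert plateau_scheduler_step([1.0, 0.9, 0.95], 5e-4) == 5e-4


def test_strictly_decreasing_losses_never_decay():
    sched = PlateauScheduler(5e-4)
    for v in np.linspace(1.0, 0.1, 20):
        sched.step(v)
    assert sched.lr == 5e-4 and sched.n_decays == 0


def test_consecutive_decays_need_fresh_stagnation_windows():
    sched = PlateauScheduler(1e-3, patience=2, factor=10)
    for v in [1.0, 0.9, 0.95, 0.94]:
        sched.step(v)
    assert sched.n_decays == 1 and sched.lr == pytest.approx(1e-4)
    sched.step(0.96)                      # one stagnant epoch: no decay yet
    assert sched.n_decays == 1
    sched.step(0.97)                      # second consecutive: decay
    assert sched.n_decays == 2 and sched.lr == pytest.approx(1e-5)


def test_scheduler_rejects_bad_lr():
    with pytest.raises(ValueError):
        PlateauScheduler(0.0)
    with pytest.raises(ValueError):
        plateau_scheduler_step([], 1e-3)


@given(st.lists(st.floats(0.0, 2.0), min_size=1, max_size=30))
@settings(max_examples=50, deadline=None)
def test_lr_trace_is_nonincreasing_by_exact_factors(losses):
    trace = replay_lr_trace(losses, 5e-4, patience=2, factor=10)
    assert trace[0] == 5e-4
    for a, b in zip(trace, trace[1:]):
        assert b == a or b == pytest.approx(a / 10)


# -- initialization ---------------------------------------------------------

def test_he_uniform_bound_holds_for_every_layer():
    net = build_monet(MoNetConfig(widths=(4, 8, 16)))
    initialize_weights(net, seed=1)
    for _, layer in net.modules():
        if isinstance(layer, Conv2d):
            bound = np.sqrt(6.0 / np.prod(layer.weight.shape[1:]))
            assert float(np.abs(layer.weight).max()) <= bound
            assert (layer.bias == 0).all()


def test_he_uniform_variance_matches_2_over_fanin():
    conv = Conv2d(36, 36, 3)       # 11,664 weights, fan_in = 324
    initialize_weights(conv, seed=0)
    var = float(conv.weight.var())
    assert var == pytest.approx(2.0 / 324, rel=0.05)


def test_initialization_is_deterministic():
    a = initialize_weights(build_monet(MoNetConfig(widths=(2, 4, 8))), seed=5)
    b = initialize_weights(build_monet(MoNetConfig(widths=(2, 4, 8))), seed=5)
    for (n1, t1, _), (n2, t2, _) in zip(a.named_tensors(), b.named_tensors()):
        assert n1 == n2
        np.testing.assert_array_equal(t1, t2)


# -- the loop ---------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_phantoms():
    cfg = PhantomConfig(image_size=(32, 32),
                        target_fraction_range=(0.02, 0.08), seed=4)
    return phantom_slices(cfg, 10)


def test_one_epoch_updates_weights(tiny_phantoms):
    net = build_monet(MoNetConfig(widths=(2, 4, 8)))
    cfg = TrainingConfig(max_epochs=1, batch_size=4, seed=0, augment=False)
    before = initialize_weights(
        build_monet(MoNetConfig(widths=(2, 4, 8))), seed=0).state_dict()
    net, history = train(net, tiny_phantoms[:8], tiny_phantoms[8:], cfg)
    after = net.state_dict()
    moved = sum(float(np.abs(after[k] - before[k]).sum())
                for k in before if "running" not in k)
    assert moved > 0
    assert len(history.epochs) == 1


def test_history_lr_column_replays_from_plateau_rule(tiny_phantoms):
    net = build_monet(MoNetConfig(widths=(2, 4, 8)))
    cfg = TrainingConfig(max_epochs=8, batch_size=4, seed=1, augment=True)
    net, history = train(net, tiny_phantoms[:8], tiny_phantoms[8:], cfg)
    expected = replay_lr_trace(history.val_losses, cfg.initial_lr,
                               cfg.plateau_patience, cfg.decay_factor)
    assert history.learning_rates == expected
    # non-increasing by construction
    lrs = history.learning_rates
    assert all(b <= a for a, b in zip(lrs, lrs[1:]))


def test_training_is_deterministic(tiny_phantoms):
    results = []
    for _ in range(2):
        net = build_monet(MoNetConfig(widths=(2, 4, 8)))
        cfg = TrainingConfig(max_epochs=2, batch_size=4, seed=3)
        net, history = train(net, tiny_phantoms[:8], tiny_phantoms[8:], cfg)
        results.append((history.to_frame().drop(columns="seconds"),
                        net.state_dict()))
    (f1, s1), (f2, s2) = results
    assert f1.equals(f2)
    for k in s1:
        np.testing.assert_array_equal(s1[k], s2[k])


def test_train_rejects_empty_sets(tiny_phantoms):
    net = build_monet(MoNetConfig(widths=(2, 4, 8)))
    with pytest.raises(ValueError):
        train(net, [], tiny_phantoms, TrainingConfig())


# -- overfit harness (shared session run) -----------------------------------

def test_overfit_harness_reaches_high_dice(overfit_run):
    _, scores = overfit_run
    assert max(scores.values()) >= 0.95
    assert max(scores) <= 300          # within the step budget


# -- serialization ----------------------------------------------------------

def test_serialization_round_trip_is_bit_exact(rng):
    net = initialize_weights(build_monet(MoNetConfig(widths=(3, 6, 12))),
                             seed=2)
    x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
    y0 = net.forward(x)
    buf = io.BytesIO()
    n_bytes = serialize_weights(net, buf)
    assert n_bytes == len(buf.getvalue())
    buf.seek(0)
    back = deserialize_weights(buf)
    np.testing.assert_array_equal(back.forward(x), y0)
    # write -> read -> write produces byte-identical containers
    buf2 = io.BytesIO()
    serialize_weights(back, buf2)
    assert buf.getvalue() == buf2.getvalue()


def test_payload_is_four_bytes_per_parameter():
    net = build_monet(MoNetConfig(widths=(2, 4, 8)))
    total = serialized_size_bytes(net)
    n = count_parameters(net)
    overhead = total - 4 * n
    assert overhead > 0
    assert overhead < 0.02 * 4 * n or overhead < 32_768


def test_corrupt_container_raises_integrity_error():
    net = build_monet(MoNetConfig(widths=(2, 4, 8)))
    buf = io.BytesIO()
    serialize_weights(net, buf)
    truncated = io.BytesIO(buf.getvalue()[:-100])
    with pytest.raises(IntegrityError):
        deserialize_weights(truncated)
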