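import numpy as np
import pytest

from rnaloci.encoding import EncodedWindow, one_hot_sequence
from rnaloci.intervals import GenomicInterval
from rnaloci.model import (
    ConfigError,
    Model,
    ModelConfig,
    ModelIOError,
    NotTrainedError,
    ShapeError,
    build_model,
    class_weights,
    load_model,
    predict,
    read_model_config,
    save_model,
    stack_blocks,
    train,
    _weighted_bce,
)

TINY = ModelConfig(
    branches=("S",),
    conv_filters=(4, 4, 8),
    kernel=3,
    dense_units=(8,),
    epochs=15,
    batch_size=16,
    input_length=40,
    seed=0,
)


def _window(seq, label, cons=None, struct=None, name="w"):
    L = len(seq)
    return EncodedWindow(
        GenomicInterval("chrT", 0, L, "+", name),
        seq_block=one_hot_sequence(seq),
        struct_block=struct,
        cons_block=cons,
        label=label,
    )


def _motif_dataset(n=200, L=40, seed=0):
    """Linearly separable toy set: planted central motif vs random."""
    rng = np.random.default_rng(seed)
    motif = "ACGTACGTACGT"
    bases = np.array(list("ACGT"))
    windows = []
    for i in range(n):
        seq = "".join(rng.choice(bases, size=L))
        label = i % 2
        if label:
            mid = (L - len(motif)) // 2
            seq = seq[:mid] + motif + seq[mid + len(motif):]
        windows.append(_window(seq, label, name=f"w{i}"))
    return windows


class TestModelConfig:
    def test_empty_branches_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(branches=())

    def test_unknown_branch_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(branches=("S", "X"))

    def test_wrong_layer_count_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(conv_filters=(8, 8))

    def test_even_kernel_rejected(self):
        with pytest.raises(ConfigError):
            ModelConfig(kernel=4)

    def test_json_round_trip(self):
        cfg = ModelConfig(branches=("F", "C"), epochs=3, seed=9)
        assert ModelConfig.from_json(cfg.to_json()) == cfg


class TestBuildModel:
    def test_three_branch_variant_accepts_three_blocks(self):
        m = build_model(ModelConfig(branches=("S", "F", "C"), input_length=20,
                                    conv_filters=(4, 4, 4), dense_units=(4,)))
        xs = [np.zeros((2, 20, 4)), np.zeros((2, 20, 3)), np.zeros((2, 20, 1))]
        p = m.forward(xs)
        assert p.shape == (2,) and np.all((p >= 0) & (p <= 1))

    def test_structure_only_variant(self):
        m = build_model(ModelConfig(branches=("F",), input_length=20,
                                    conv_filters=(4, 4, 4), dense_units=(4,)))
        p = m.forward([np.zeros((3, 20, 3))])
        assert p.shape == (3,)

    def test_wrong_block_count_raises(self):
        m = build_model(ModelConfig(branches=("F",), input_length=20,
                                    conv_filters=(4, 4, 4), dense_units=(4,)))
        with pytest.raises(ShapeError):
            m.forward([np.zeros((2, 20, 3)), np.zeros((2, 20, 1))])

    def test_wrong_channel_count_raises(self):
        m = build_model(ModelConfig(branches=("F",), input_length=20,
                                    conv_filters=(4, 4, 4), dense_units=(4,)))
        with pytest.raises(ShapeError):
            m.forward([np.zeros((2, 20, 4))])  # S-shaped block into F branch

    def test_seeded_init_reproducible(self):
        cfg = ModelConfig(branches=("S",), input_length=20,
                          conv_filters=(4, 4, 4), dense_units=(4,), seed=5)
        m1, m2 = build_model(cfg), build_model(cfg)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])


class TestClassWeights:
    def test_one_to_four(self):
        assert class_weights([1] * 100 + [0] * 400) == {0: 0.625, 1: 2.5}

    def test_balanced(self):
        assert class_weights([1] * 100 + [0] * 100) == {0: 1.0, 1: 1.0}

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            class_weights([1, 1, 1])

    def test_disabled_weighting_uses_unit_weights(self):
        windows = _motif_dataset(n=40)
        cfg = ModelConfig(**{**TINY.__dict__, "class_weighting": False, "epochs": 1})
        m = build_model(cfg)
        train(m, windows, config=cfg)  # must not fail, weights all 1.0
        assert m.trained

    def test_weighted_loss_equals_duplicated_positive_loss(self):
        # {1: 2.5, 0: 0.625} on a 1:4 set == unweighted loss on the same set
        # with positives duplicated 4x (exact identity, not just approximate)
        rng = np.random.default_rng(0)
        p_pos, p_neg = rng.random(100), rng.random(400)
        y = np.r_[np.ones(100), np.zeros(400)]
        p = np.r_[p_pos, p_neg]
        w = np.where(y == 1, 2.5, 0.625)
        weighted = _weighted_bce(p, y, w)
        p_dup = np.r_[np.tile(p_pos, 4), p_neg]
        y_dup = np.r_[np.ones(400), np.zeros(400)]
        unweighted = _weighted_bce(p_dup, y_dup, np.ones(800))
        assert weighted == pytest.approx(unweighted, rel=1e-12)


class TestTrain:
    def test_learns_separable_motif(self):
        windows = _motif_dataset(n=200)
        m = build_model(TINY)
        train(m, windows, config=TINY)
        acc = np.mean((predict(m, windows) >= 0.5) == [w.label for w in windows])
        assert acc > 0.95

    def test_single_epoch_single_history_record(self):
        windows = _motif_dataset(n=40)
        cfg = ModelConfig(**{**TINY.__dict__, "epochs": 1})
        m = build_model(cfg)
        train(m, windows, config=cfg)
        assert len(m.history) == 1
        assert "train_loss" in m.history[0]

    def test_validation_history_and_early_stop(self):
        windows = _motif_dataset(n=80)
        cfg = ModelConfig(**{**TINY.__dict__, "epochs": 30, "patience": 2})
        m = build_model(cfg)
        train(m, windows[:60], val_examples=windows[60:], config=cfg)
        assert all("val_loss" in rec for rec in m.history)
        assert len(m.history) <= 30

    def test_block_branch_mismatch(self):
        windows = _motif_dataset(n=20)  # only seq blocks present
        cfg = ModelConfig(branches=("F",), conv_filters=(4, 4, 4),
                          dense_units=(4,), epochs=1, input_length=40)
        m = build_model(cfg)
        with pytest.raises(ShapeError):
            train(m, windows, config=cfg)

    def test_single_class_rejected(self):
        windows = [w for w in _motif_dataset(n=20) if w.label == 1]
        m = build_model(TINY)
        with pytest.raises(ValueError):
            train(m, windows, config=TINY)

    def test_reproducible_given_seed(self):
        windows = _motif_dataset(n=60)
        m1 = train(build_model(TINY), windows, config=TINY)
        m2 = train(build_model(TINY), windows, config=TINY)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])


@pytest.fixture(scope="module")
def trained_with_windows():
    windows = _motif_dataset(n=80)
    return train(build_model(TINY), windows, config=TINY), windows


@pytest.fixture(scope="module")
def trained_small():
    return train(build_model(TINY), _motif_dataset(n=60), config=TINY)


class TestPredict:
    @pytest.fixture
    def trained(self, trained_with_windows):
        return trained_with_windows

    def test_codomain(self, trained):
        m, windows = trained
        p = predict(m, windows)
        assert np.all((p >= 0) & (p <= 1))

    def test_determinism(self, trained):
        m, windows = trained
        assert np.array_equal(predict(m, windows), predict(m, windows))

    def test_empty_input(self, trained):
        m, _ = trained
        assert predict(m, []).shape == (0,)

    def test_untrained_error(self):
        m = build_model(TINY)
        with pytest.raises(NotTrainedError):
            predict(m, _motif_dataset(n=4))

    def test_order_preserved(self, trained):
        m, windows = trained
        p = predict(m, windows)
        rev = predict(m, windows[::-1])
        assert np.allclose(p, rev[::-1])

    def test_sequence_only_model_ignores_conservation(self, trained):
        m, windows = trained
        base = predict(m, windows)
        perturbed = [
            EncodedWindow(w.interval, w.seq_block,
                          w.struct_block,
                          np.full((40, 1), 99.0, dtype=np.float32), w.label)
            for w in windows
        ]
        assert np.array_equal(base, predict(m, perturbed))


class TestStackBlocks:
    def test_missing_block_raises(self):
        windows = _motif_dataset(n=4)
        with pytest.raises(ShapeError):
            stack_blocks(windows, ("F",))


class TestSerialization:
    @pytest.fixture
    def trained(self, trained_small):
        return trained_small

    def test_round_trip_bit_for_bit(self, trained, tmp_path):
        probe = _motif_dataset(n=10, seed=3)
        before = predict(trained, probe)
        path = tmp_path / "model.npz"
        save_model(trained, path)
        loaded = load_model(path)
        assert np.array_equal(before, predict(loaded, probe))
        assert loaded.config == trained.config

    def test_truncated_file_errors(self, trained, tmp_path):
        path = tmp_path / "model.npz"
        save_model(trained, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 2])
        with pytest.raises(ModelIOError):
            load_model(path)

    def test_garbage_file_errors(self, tmp_path):
        path = tmp_path / "junk.npz"
        path.write_bytes(b"not a model at all")
        with pytest.raises(ModelIOError):
            load_model(path)

    def test_config_readable_without_weights(self, trained, tmp_path):
        path = tmp_path / "model.npz"
        save_model(trained, path)
        assert read_model_config(path) == trained.config

    def test_history_preserved(self, trained, tmp_path):
        path = tmp_path / "model.npz"
        save_model(trained, path)
        assert load_model(path).history == trained.history


class TestGradients:
    def test_numeric_gradient_check(self):
        """Backprop agrees with central finite differences on a tiny net."""
        cfg = ModelConfig(branches=("S", "C"), conv_filters=(2, 2, 2), kernel=3,
                          dense_units=(3,), input_length=12, seed=1)
        m = build_model(cfg)
        rng = np.random.default_rng(0)
        xs = [rng.random((3, 12, 4)), rng.random((3, 12, 1))]
        y = np.array([1.0, 0.0, 1.0])
        w = np.ones(3)

        def loss_value():
            p = m.forward(xs)
            return _weighted_bce(p, y, w)

        p, cache = m.forward(xs, want_cache=True)
        dzo = (w * (p - y) / 3)[:, None]
        grads = m.backward(cache, dzo)
        eps = 1e-6
        for name in ["S_conv0_W", "C_conv1_b", "dense0_W", "out_W", "out_b"]:
            param = m.params[name]
            flat_idx = rng.integers(0, param.size, size=min(5, param.size))
            for fi in flat_idx:
                orig = param.flat[fi]
                param.flat[fi] = orig + eps
                up = loss_value()
                param.flat[fi] = orig - eps
                down = loss_value()
                param.flat[fi] = orig
                numeric = (up - down) / (2 * eps)
                assert grads[name].flat[fi] == pytest.approx(numeric, rel=1e-4, abs=1e-7)
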