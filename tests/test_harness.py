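"""Harness: parameter counting, evaluation, history accounting, training."""

import numpy as np
import pytest
from scipy.stats import binomtest

from oddity.harness import (CHANCE_ACCURACY, History, TrainConfig,
                            count_parameters, epochs_to_threshold,
                            evaluate_accuracy, load_checkpoint,
                            preprocess_samples, save_checkpoint, train_model)
from oddity.nn import Dense
from oddity.oren import OReNModel
from oddity.riddlegen import DatasetConfig, build_dataset
from oddity.saccadic import SaccadicModel
from oddity.vision import VisionConfig

TINY_VISION = VisionConfig(input_side=16, channels=2, kernel=3, n_conv=2,
                           pool_after=(2,), dropout_after=(1,))

# hand-summed per-layer oracle, frozen before implementation:
#   vision: 5x5 convs without bias (BN follows) + BN scale/shift
#     conv1 25*1*32 = 800, conv2..5 25*32*32 = 25600 each, BN 2*32 = 64 each
#     total 103,520
#   OReN N=128: g = 6400*128+128 + 3*(128*128+128) = 868,864
#               f = 2*(128*128+128) + 129 = 33,153          -> 1,005,537
#   saccadic, input 3206: SNN/sSNU layer = fan*N + N; sSNU-R adds N^2;
#   LSTM layer = 4*(fan*N + N^2 + N); readout N+1
HAND_COUNTS = {
    ("oren", 128, None): 1_005_537,
    ("saccadic", 128, "snn"): 547_169,
    ("saccadic", 64, "ssnu"): 317_153,
    ("saccadic", 32, "ssnu-r"): 211_361,
    ("saccadic", 256, "lstm"): 4_700_513,
}


class TestCountParameters:
    @pytest.mark.parametrize("key,expected", list(HAND_COUNTS.items()))
    def test_matches_hand_summed_oracle(self, key, expected):
        arch, n, unit = key
        assert count_parameters(arch, n, unit=unit or "ssnu") == expected

    def test_single_dense_layer(self):
        layer = Dense(np.random.default_rng(0), 10, 5)
        assert layer.w.size + layer.b.size == 55

    @pytest.mark.parametrize("arch,n,unit", [("oren", 8, "ssnu"),
                                             ("saccadic", 8, "snn"),
                                             ("saccadic", 8, "ssnu-r"),
                                             ("saccadic", 8, "lstm")])
    def test_matches_built_model(self, arch, n, unit):
        """Analytic count equals the actual number of trainable scalars."""
        rng = np.random.default_rng(0)
        if arch == "oren":
            model = OReNModel(rng, n=n, vision_config=TINY_VISION)
        else:
            model = SaccadicModel(rng, n=n, unit=unit, vision_config=TINY_VISION)
        assert count_parameters(arch, n, unit=unit, vision_config=TINY_VISION) \
            == model.num_params()

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError, match="unknown arch"):
            count_parameters("transformer", 8)


class TestEpochsToThreshold:
    def _history(self, accs):
        h = History()
        for i, a in enumerate(accs, start=1):
            h.record(i, 0.0, None, a, 100)
        return h

    def test_first_crossing_epoch(self):
        h = self._history([0.20, 0.50, 0.70, 0.90])
        assert epochs_to_threshold(h, 0.668) == 3

    def test_not_reached_returns_none_with_warning(self):
        h = self._history([0.2, 0.3])
        with pytest.warns(UserWarning, match="never reached"):
            assert epochs_to_threshold(h, 0.9) is None

    def test_zero_threshold_is_first_epoch(self):
        assert epochs_to_threshold(self._history([0.1, 0.2]), 0.0) == 1

    def test_examples_seen_accounting(self):
        h = self._history([0.1, 0.2, 0.3])
        assert h.examples_seen == [100, 200, 300]
        h2 = History()
        for e in range(1, 4):
            h2.record(e, 0.0, None, 0.0, 2560)
        assert h2.examples_seen[-1] == 7680


class _OracleStub:
    """Predicts from the label array it was given (for accuracy accounting)."""

    def __init__(self, labels):
        self.labels = list(labels)
        self._cursor = 0

    def predict(self, grids):
        n = len(grids)
        out = self.labels[self._cursor:self._cursor + n]
        self._cursor += n
        return np.asarray(out)


@pytest.fixture(scope="module")
def tiny_data():
    from test_riddlegen import _tiny_registry
    reg = _tiny_registry()
    cfg = DatasetConfig(mode="separate", concepts=("c0",), size=120, seed=3)
    return build_dataset(cfg, registry=reg)


class TestEvaluateAccuracy:
    def test_perfect_oracle_scores_one(self, tiny_data):
        labels = [s.oddity_index for s in tiny_data.test]
        assert evaluate_accuracy(_OracleStub(labels), tiny_data.test) == 1.0

    def test_constant_predictor_near_chance(self, tiny_data):
        labels = [s.oddity_index for s in tiny_data.train + tiny_data.val + tiny_data.test]
        samples = tiny_data.train + tiny_data.val + tiny_data.test
        acc = evaluate_accuracy(_OracleStub([0] * len(samples)), samples)
        k = int(round(acc * len(samples)))
        assert binomtest(k, len(samples), CHANCE_ACCURACY).pvalue > 0.01

    def test_untrained_model_near_chance(self, tiny_data):
        """Freshly initialised network answers at chance (binomial 99% CI)."""
        model = SaccadicModel(np.random.default_rng(0), n=4, unit="ssnu",
                              vision_config=TINY_VISION)
        samples = (tiny_data.train + tiny_data.val + tiny_data.test)
        grids = np.stack([[_shrink(f) for f in s.frames] for s in samples])
        labels = np.array([s.oddity_index for s in samples])
        acc = evaluate_accuracy(model, (grids, labels), rng=np.random.default_rng(1))
        k = int(round(acc * len(labels)))
        assert binomtest(k, len(labels), CHANCE_ACCURACY).pvalue > 0.01

    def test_empty_split_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_accuracy(_OracleStub([]), [])


def _shrink(frame):
    """Downsample a 100x100 frame to the tiny vision input for cheap tests."""
    from skimage.transform import resize
    return resize(frame.pixels.astype(np.float32) / 255.0, (16, 16),
                  order=1, preserve_range=True).astype(np.float32)


class TestTraining:
    @pytest.mark.parametrize("arch", ["oren", "saccadic"])
    def test_short_training_runs_and_records(self, arch):
        """Two epochs on a micro dataset produce a consistent History."""
        from test_riddlegen import _tiny_registry
        reg = _tiny_registry()
        cfg = DatasetConfig(mode="separate", concepts=("c0",), size=24, seed=5)
        data = build_dataset(cfg, registry=reg)
        # shrink frames so the tiny vision config applies
        for split in data:
            for s in split:
                for f in s.frames:
                    f.pixels = (255 * _shrink(f)).astype(np.uint8)[:, :]
        tc = TrainConfig(arch=arch, unit="ssnu", n=4, epochs=2, batch_size=8,
                         seed=0, vision_config=TINY_VISION, eval_val=True)
        model, hist = train_model(tc, data)
        assert hist.epochs == [1, 2]
        assert hist.examples_seen == [16, 32]
        assert all(np.isfinite(hist.train_loss))
        assert all(0 <= a <= 1 for a in hist.test_accuracy)

    def test_checkpoint_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        tc = TrainConfig(arch="saccadic", unit="ssnu-r", n=4,
                         vision_config=TINY_VISION)
        model = SaccadicModel(rng, n=4, unit="ssnu-r", vision_config=TINY_VISION)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, tc)
        model2, cfg2 = load_checkpoint(path)
        assert cfg2.unit == "ssnu-r"
        for a, b in zip(sorted(model.state_arrays().items()),
                        sorted(model2.state_arrays().items())):
            assert a[0] == b[0]
            np.testing.assert_array_equal(a[1], b[1])


def test_train_separate_reports_mean_over_concepts():
    """One model per concept; the report averages their test accuracies."""
    from test_riddlegen import _tiny_registry
    from oddity.harness import train_separate
    reg = _tiny_registry()
    cfg = TrainConfig(arch="saccadic", unit="ssnu", n=4, epochs=1,
                      batch_size=8, seed=0, vision_config=TINY_VISION,
                      eval_val=False)
    res = train_separate(["c0", "c1"], cfg, size=12, data_seed=1, registry=reg,
                         human_thresholds={"c0": 0.0})
    assert set(res["per_concept"]) == {"c0", "c1"}
    accs = [r["test_accuracy"] for r in res["per_concept"].values()]
    assert res["mean_test_accuracy"] == pytest.approx(np.mean(accs))
    # threshold 0 is reached at the first epoch for c0
    assert res["per_concept"]["c0"]["epochs_to_human_level"] == 1


def test_preprocess_samples_shapes():
    from test_riddlegen import _tiny_registry
    reg = _tiny_registry()
    cfg = DatasetConfig(mode="separate", concepts=("c0",), size=6, seed=0)
    data = build_dataset(cfg, registry=reg)
    grids, labels = preprocess_samples(data.train)
    assert grids.shape == (4, 6, 80, 80)
    assert labels.shape == (4,)
    assert grids.dtype == np.float32
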