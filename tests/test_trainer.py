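"""Fitting loop, early stopping, best-checkpoint restoration, checkpoints."""

import numpy as np
import pytest

from msifuse.errors import CheckpointError
from msifuse.losses import EdgeKernel, LossWeights
from msifuse.network import build_network
from msifuse.trainer import (
    Adam,
    EarlyStopState,
    TrainConfig,
    early_stop_update,
    load_checkpoint,
    rebuild_model_from_checkpoint,
    save_checkpoint,
    train,
)


def simulate_stopping(sequence, patience):
    """Independent scalar simulation of the cumulative-increase rule."""
    best = float("inf")
    counter = 0
    for idx, value in enumerate(sequence, start=1):
        if value < best:
            best = value
        else:
            counter += 1
        if counter >= patience:
            return idx
    return None


class TestEarlyStopRule:
    def test_monotone_decrease_never_halts(self):
        state = EarlyStopState(patience=5)
        for v in [3.0, 2.0, 1.0]:
            state, halt = early_stop_update(state, v)
            assert not halt
        assert state.counter == 0

    def test_plateau_halts_at_patience(self):
        # ties count as increases: [1,2,2,2,2,2] with patience 5 halts at the 6th
        state = EarlyStopState(patience=5)
        halts = []
        for v in [1.0, 2.0, 2.0, 2.0, 2.0, 2.0]:
            state, halt = early_stop_update(state, v)
            halts.append(halt)
        assert halts == [False, False, False, False, False, True]

    def test_patience_one_boundary(self):
        # a repeat of the minimum is not an improvement -> immediate halt
        state = EarlyStopState(patience=1)
        state, halt = early_stop_update(state, 1.0)
        assert not halt
        state, halt = early_stop_update(state, 1.0)
        assert halt

    def test_counter_is_cumulative_not_consecutive(self):
        # alternating improve/worsen: a consecutive rule would never halt
        seq = [5, 4, 6, 3, 7, 2, 8, 1, 9, 0.5, 10, 0.4, 11]
        state = EarlyStopState(patience=5)
        halted_at = None
        for i, v in enumerate(seq, start=1):
            state, halt = early_stop_update(state, float(v))
            if halt:
                halted_at = i
                break
        # increases occur at indices 3, 5, 7, 9, 11 -> halt on the fifth
        assert halted_at == simulate_stopping(seq, 5) == 11

    @pytest.mark.parametrize("patience", [1, 3, 5])
    def test_matches_scalar_simulation_on_random_sequences(self, rng, patience):
        for _ in range(30):
            seq = rng.uniform(0, 1, size=rng.integers(1, 40)).tolist()
            state = EarlyStopState(patience=patience)
            halted_at = None
            for i, v in enumerate(seq, start=1):
                state, halt = early_stop_update(state, v)
                if halt:
                    halted_at = i
                    break
            assert halted_at == simulate_stopping(seq, patience)


class TestTrainLoop:
    def test_single_epoch_run(self, small_pair):
        model = build_network(seed=0)
        fused, trace = train(model, small_pair, cfg=TrainConfig(max_epochs=1))
        assert trace.epochs == [1]
        assert trace.stopped_at == 1
        assert trace.best_epoch == 1
        assert fused.values.shape == small_pair.microscopy.spatial_shape

    def test_zero_weight_config_rejected(self, small_pair):
        model = build_network(seed=0)
        with pytest.raises(ValueError, match="no training signal"):
            train(model, small_pair,
                  cfg=TrainConfig(weights=LossWeights(0.0, 0.0), max_epochs=2))

    def test_loss_decreases_with_training(self, small_pair):
        model = build_network(seed=0)
        _, trace = train(model, small_pair, cfg=TrainConfig(max_epochs=50))
        assert trace.l_total[49] < trace.l_total[0]

    def test_trace_invariants(self, small_pair):
        model = build_network(seed=1)
        _, trace = train(model, small_pair, cfg=TrainConfig(max_epochs=60))
        assert trace.epochs == sorted(trace.epochs)
        assert trace.stopped_at <= 60
        best_idx = trace.epochs.index(trace.best_epoch)
        assert trace.l_edge[best_idx] == min(trace.l_edge)

    def test_returned_image_is_best_epoch_not_halting_epoch(self, small_pair):
        # patience 1 forces an early halt; the restored model must reproduce
        # the recorded best output, not the halting-epoch output
        model = build_network(seed=3)
        cfg = TrainConfig(max_epochs=200, stop_patience=1)
        fused, trace = train(model, small_pair, cfg=cfg)
        assert trace.stopped_at < 200 or trace.best_epoch <= trace.stopped_at
        assert fused.epoch_of_best == trace.best_epoch
        x = np.ascontiguousarray(small_pair.microscopy.values.transpose(2, 0, 1))
        np.testing.assert_array_equal(model.forward(x), fused.values)

    def test_seeded_determinism(self, small_pair):
        cfg = TrainConfig(max_epochs=15)
        f1, t1 = train(build_network(seed=4), small_pair, cfg=cfg)
        f2, t2 = train(build_network(seed=4), small_pair, cfg=cfg)
        np.testing.assert_array_equal(f1.values, f2.values)
        assert t1.l_total == t2.l_total

    def test_nonfinite_loss_aborts_with_epoch(self, small_pair):
        from msifuse.errors import DataError

        model = build_network(seed=0)
        # overflowing parameters turn the first forward pass non-finite
        model.set_state([np.full_like(p, 1e200) for p in model.parameters()])
        with pytest.raises(DataError, match="epoch 1"):
            train(model, small_pair, cfg=TrainConfig(max_epochs=5))


class TestCheckpoints:
    def _fit(self, small_pair, tmp_path, epochs=8, every=2, seed=0):
        model = build_network(seed=seed)
        cfg = TrainConfig(max_epochs=epochs, checkpoint_every=every)
        fused, trace = train(model, small_pair, cfg=cfg,
                             checkpoint_dir=tmp_path, config_hash="h123")
        return model, fused, trace

    def test_save_load_forward_identical(self, small_pair, tmp_path):
        self._fit(small_pair, tmp_path / "a")
        self._fit(small_pair, tmp_path / "b")
        ckpts_a = sorted((tmp_path / "a").glob("*.ckpt.npz"))
        ckpts_b = sorted((tmp_path / "b").glob("*.ckpt.npz"))
        assert len(ckpts_a) == 4
        x = np.ascontiguousarray(small_pair.microscopy.values.transpose(2, 0, 1))
        for pa, pb in zip(ckpts_a, ckpts_b, strict=True):
            ma, ca = rebuild_model_from_checkpoint(pa)
            mb, _ = rebuild_model_from_checkpoint(pb)
            assert ca["header"]["config_hash"] == "h123"
            np.testing.assert_array_equal(ma.forward(x), mb.forward(x))

    def test_tampered_file_refused(self, small_pair, tmp_path):
        self._fit(small_pair, tmp_path)
        path = sorted(tmp_path.glob("*.ckpt.npz"))[0]
        blob = bytearray(path.read_bytes())
        blob[len(blob) // 2] ^= 0xFF
        path.write_bytes(bytes(blob))
        with pytest.raises(CheckpointError):
            load_checkpoint(path)

    def test_config_hash_mismatch_refused(self, small_pair, tmp_path):
        self._fit(small_pair, tmp_path)
        path = sorted(tmp_path.glob("*.ckpt.npz"))[0]
        with pytest.raises(CheckpointError, match="config hash"):
            load_checkpoint(path, expect_hash="other")

    def test_resume_reproduces_uninterrupted_trace(self, small_pair, tmp_path):
        cfg = TrainConfig(max_epochs=12, checkpoint_every=1)
        full_model = build_network(seed=9)
        _, full_trace = train(full_model, small_pair, cfg=cfg,
                              checkpoint_dir=tmp_path / "full", config_hash="h")
        resumed_model = build_network(seed=9)
        fused_r, resumed_trace = train(
            resumed_model, small_pair, cfg=cfg, config_hash="h",
            resume_from=tmp_path / "full" / "epoch_00006.ckpt.npz",
        )
        assert resumed_trace.epochs[-1] == 12
        merged = full_trace.l_total[6:]
        np.testing.assert_allclose(resumed_trace.l_total[-6:], merged, rtol=0, atol=0)
        for pa, pb in zip(full_model.parameters(), resumed_model.parameters(),
                          strict=True):
            np.testing.assert_array_equal(pa, pb)


class TestAdam:
    def test_single_step_closed_form(self):
        # one Adam step from zero moments moves by ~lr * sign(g)
        p = np.array([1.0])
        opt = Adam([p], lr=0.1)
        g = np.array([0.5])
        opt.step([g])
        mhat, vhat = 0.5, 0.25
        expected = 1.0 - 0.1 * mhat / (np.sqrt(vhat) + 1e-8)
        assert p[0] == pytest.approx(expected, rel=1e-12)

    def test_state_roundtrip(self, rng):
        p1 = rng.normal(size=(3, 3))
        p2 = p1.copy()
        a, b = Adam([p1], lr=0.01), Adam([p2], lr=0.01)
        g = rng.normal(size=(3, 3))
        a.step([g])
        b.set_state(a.get_state())
        b.params[0][...] = p1
        a.step([g * 2])
        b.step([g * 2])
        np.testing.assert_array_equal(p1, p2)


def test_trace_csv_roundtrip(small_pair, tmp_path):
    import pandas as pd

    model = build_network(seed=0)
    _, trace = train(model, small_pair, cfg=TrainConfig(max_epochs=5))
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["epoch", "l_mse", "l_edge", "l_total",
                                "stop_counter", "is_best"]
    np.testing.assert_allclose(df["l_total"], trace.l_total, rtol=1e-15)
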