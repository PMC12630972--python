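"""Training protocol: split counts, scheduler/early-stop counter logic
against a direct rule simulation, loop reproducibility and checkpointing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lesionseg import ModelConfig, build_model
from lesionseg.metrics import hybrid_loss
from lesionseg.training import (ABLATION_LABELS, EarlyStopper,
                                PlateauScheduler, SplitSpec, TrainConfig,
                                run_ablation, split_manifest, train)


def rule_oracle(improvements, lr0=1e-4, factor=0.1, lr_patience=10,
                stop_patience=15, min_lr=1e-7):
    """Direct simulation of the stated rules on a binary improvement trace.

    Returns (lr trace, first stop epoch or None).  Written independently of
    the package classes: plain counters, nothing shared.
    """
    lr = lr0
    lr_stall = 0
    stop_stall = 0
    stop_at = None
    lrs = []
    for step, improved in enumerate(improvements, start=1):
        if improved:
            lr_stall = 0
            stop_stall = 0
        else:
            lr_stall += 1
            stop_stall += 1
            if lr_stall >= lr_patience:
                lr = max(lr * factor, min_lr)
                lr_stall = 0
            if stop_stall >= stop_patience and stop_at is None:
                stop_at = step
        lrs.append(lr)
    return lrs, stop_at


def run_package(improvements, lr0=1e-4, lr_patience=10, stop_patience=15):
    """Drive the package classes with synthetic losses encoding the trace.

    Both monitors start from an established best of 100 so that the first
    trace element already means improvement-or-stall (matching the oracle's
    reading of the trace).
    """
    sched = PlateauScheduler(lr0, patience=lr_patience)
    stopper = EarlyStopper(patience=stop_patience)
    sched.best = stopper.best = 100.0
    loss = 100.0
    best = 100.0
    lrs = []
    stop_at = None
    for step, improved in enumerate(improvements, start=1):
        loss = (min(best, loss) - 1.0) if improved else loss
        best = min(best, loss)
        lrs.append(sched.step(loss))
        if not stopper.step(loss) and stop_at is None:
            stop_at = step
    return lrs, stop_at


class TestSplitManifest:
    def test_isic2018_counts(self):
        records = pd.DataFrame({"image": [f"i{i}.png" for i in range(2594)],
                                "mask": [f"m{i}.png" for i in range(2594)]})
        out = split_manifest(records, SplitSpec(counts=(1815, 259, 520)))
        counts = out["split"].value_counts()
        assert counts["train"] == 1815
        assert counts["val"] == 259
        assert counts["test"] == 520

    def test_ph2_counts_no_test(self):
        records = pd.DataFrame({"image": [f"i{i}" for i in range(200)],
                                "mask": [f"m{i}" for i in range(200)]})
        out = split_manifest(records, SplitSpec(counts=(160, 40, 0)))
        counts = out["split"].value_counts()
        assert counts["train"] == 160 and counts["val"] == 40
        assert "test" not in counts

    def test_same_seed_identical(self):
        records = pd.DataFrame({"image": list("abcdefghij"),
                                "mask": list("abcdefghij")})
        a = split_manifest(records, SplitSpec(counts=(6, 2, 2), seed=5))
        b = split_manifest(records, SplitSpec(counts=(6, 2, 2), seed=5))
        assert (a["split"] == b["split"]).all()

    def test_infeasible_counts_raise(self):
        records = pd.DataFrame({"image": ["a"], "mask": ["a"]})
        with pytest.raises(ValueError, match="requested"):
            split_manifest(records, SplitSpec(counts=(2, 1, 0)))


class TestSchedulerRules:
    def test_ten_stalls_decay_lr(self):
        sched = PlateauScheduler(1e-4)
        sched.step(1.0)                      # establishes the best
        for _ in range(10):
            lr = sched.step(1.0)             # no improvement
        assert lr == pytest.approx(1e-5)

    def test_improving_sequence_keeps_lr(self):
        sched = PlateauScheduler(1e-4)
        for loss in np.linspace(1.0, 0.1, 20):
            assert sched.step(loss) == 1e-4

    def test_nine_stalls_then_improvement_resets(self):
        sched = PlateauScheduler(1e-4)
        sched.step(1.0)
        for _ in range(9):
            sched.step(1.0)
        assert sched.step(0.5) == 1e-4
        assert sched.counter == 0

    def test_early_stop_exact_patience(self):
        stopper = EarlyStopper(patience=15)
        assert stopper.step(1.0)
        for i in range(14):
            assert stopper.step(1.0)
        assert not stopper.step(1.0)         # 15th consecutive stall

    def test_fourteen_stalls_then_improvement_continues(self):
        stopper = EarlyStopper(patience=15)
        stopper.step(1.0)
        for _ in range(14):
            stopper.step(1.0)
        assert stopper.step(0.5)
        assert stopper.counter == 0

    @pytest.mark.parametrize("length", range(1, 13))
    def test_exhaustive_short_sequences_match_rule_oracle(self, length):
        for bits in itertools.product([True, False], repeat=length):
            want = rule_oracle(bits, lr_patience=3, stop_patience=4)
            got = run_package(bits, lr_patience=3, stop_patience=4)
            assert got == want, f"trace {bits}"

    def test_state_closure_to_depth_twenty(self):
        """Exhaustively covers every improvement/stall sequence of length
        <= 20 at the stated patiences: behaviour depends only on the
        (scheduler counter, LR level, stop counter) state, so checking every
        reachable state transition at both inputs covers all 2^20 traces."""
        start = (0, 0, 0)     # (lr_stall, n_decays, stop_stall)
        seen = {start}
        frontier = [start]
        depth = 0
        while frontier and depth < 20:
            depth += 1
            nxt = []
            for state in frontier:
                for improved in (True, False):
                    lr_stall, n_decays, stop_stall = state
                    # oracle transition, straight from the stated rules
                    if improved:
                        want = (0, n_decays, 0)
                    else:
                        lr_stall += 1
                        stop_stall += 1
                        if lr_stall >= 10:
                            lr_stall = 0
                            n_decays += 1
                        want = (lr_stall, n_decays, min(stop_stall, 15))
                    # package transition from the same state
                    sched = PlateauScheduler(1e-4 * 0.1 ** state[1])
                    sched.best = 10.0
                    sched.counter = state[0]
                    stopper = EarlyStopper()
                    stopper.best = 10.0
                    stopper.counter = state[2]
                    loss = 5.0 if improved else 10.0
                    lr = sched.step(loss)
                    cont = stopper.step(loss)
                    decays = round(np.log10(1e-4 / lr))
                    got = (sched.counter, decays,
                           min(stopper.counter, 15))
                    assert got == want, f"state {state}, improved={improved}"
                    assert cont == (want[2] < 15)
                    if want not in seen:
                        seen.add(want)
                        nxt.append(want)
            frontier = nxt
        assert len(seen) > 1


class TestTrainLoop:
    @pytest.fixture
    def easy_task(self, rng):
        """Tiny separable segmentation problem: dark square on light field."""
        n = 12
        images = np.full((n, 32, 32, 3), 0.8, dtype=np.float32)
        masks = np.zeros((n, 32, 32), dtype=np.uint8)
        for i in range(n):
            r, c = rng.integers(4, 16, 2)
            images[i, r:r + 12, c:c + 12] -= 0.4
            masks[i, r:r + 12, c:c + 12] = 1
        images += rng.normal(0, 0.02, images.shape).astype(np.float32)
        return images[:8], masks[:8], images[8:], masks[8:]

    def test_loss_decreases_on_easy_task(self, tiny_config, easy_task):
        xtr, ytr, xva, yva = easy_task
        model = build_model(tiny_config, seed=2)
        config = TrainConfig(lr=3e-3, batch_size=4, max_epochs=4, seed=2)
        history = train(model, xtr, ytr, xva, yva, config)
        assert len(history) <= 4
        assert history[-1].train_loss < history[0].train_loss
        assert history[0].epoch == 1
        assert [r.epoch for r in history] == list(range(1, len(history) + 1))

    def test_same_seed_identical_histories(self, tiny_config, easy_task):
        xtr, ytr, xva, yva = easy_task
        config = TrainConfig(lr=1e-3, batch_size=4, max_epochs=2, seed=7)
        h1 = train(build_model(tiny_config, seed=5), xtr, ytr, xva, yva, config)
        h2 = train(build_model(tiny_config, seed=5), xtr, ytr, xva, yva, config)
        assert [vars(r) for r in h1] == [vars(r) for r in h2]

    def test_best_weights_restored(self, tiny_config, easy_task):
        xtr, ytr, xva, yva = easy_task
        model = build_model(tiny_config, seed=3)
        config = TrainConfig(lr=3e-3, batch_size=4, max_epochs=3, seed=3)
        history = train(model, xtr, ytr, xva, yva, config)
        best = min(r.val_loss for r in history)
        re_eval = hybrid_loss(model.predict(xva), yva)
        assert re_eval == pytest.approx(best, abs=1e-6)

    def test_empty_sets_raise(self, tiny_config):
        model = build_model(tiny_config, seed=0)
        with pytest.raises(ValueError, match="nonempty"):
            train(model, np.zeros((0, 32, 32, 3)), np.zeros((0, 32, 32)),
                  np.zeros((1, 32, 32, 3)), np.zeros((1, 32, 32)))


class TestAblationHarness:
    def test_five_rows_reproducible_and_bounded(self, tiny_config, rng):
        images = np.full((8, 32, 32, 3), 0.8, dtype=np.float32)
        masks = np.zeros((8, 32, 32), dtype=np.uint8)
        for i in range(8):
            images[i, 8:24, 8:24] -= 0.35
            masks[i, 8:24, 8:24] = 1
        images += rng.normal(0, 0.02, images.shape).astype(np.float32)
        tc = TrainConfig(lr=1e-3, batch_size=4, max_epochs=1, seed=1)
        table = run_ablation(images[:6], masks[:6], images[6:], masks[6:],
                             tiny_config, tc, seed=1)
        assert list(table["configuration"]) == list(ABLATION_LABELS)
        assert len(table) == 5
        assert (table["iou"] <= table["dice"] + 1e-12).all()
        table2 = run_ablation(images[:6], masks[:6], images[6:], masks[6:],
                              tiny_config, tc, seed=1)
        pd.testing.assert_frame_equal(table, table2)
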