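"""Cloze corruption, whole-word masking, masked loss, pretraining loop."""

import numpy as np
import pytest

from dxsum import nn
from dxsum.model import CharTransformer, ModelConfig
from dxsum.pretrain import (
    BRANCH_KEEP,
    BRANCH_MASK,
    BRANCH_NONE,
    BRANCH_RANDOM,
    TrainHyper,
    corrupt_sequence,
    mlm_loss,
    pretrain_loop,
    whole_word_corrupt,
)
from dxsum.synthetic import DiagnosisRecord, GeneratorParams, generate_diagnosis
from dxsum.tokenizer import build_symbol_table, encode, segment_units

TABLE = build_symbol_table()


def _random_ids(rng, n):
    return rng.integers(0, 100, size=n)


class TestCorruptSequence:
    def test_selection_and_branch_rates(self, rng):
        total = sel = masked = randomized = kept = 0
        for _ in range(40):
            ids = _random_ids(rng, 5000)
            ex = corrupt_sequence(ids, TABLE, rng)
            total += ids.size
            sel += ex.mask_positions.size
            masked += int((ex.branches == BRANCH_MASK).sum())
            randomized += int((ex.branches == BRANCH_RANDOM).sum())
            kept += int((ex.branches == BRANCH_KEEP).sum())
        assert abs(sel / total - 0.15) < 0.005
        assert abs(masked / sel - 0.80) < 0.01
        assert abs(randomized / sel - 0.10) < 0.01
        assert abs(kept / sel - 0.10) < 0.01

    def test_untouched_outside_mask_positions(self, rng):
        for _ in range(20):
            ids = _random_ids(rng, 300)
            ex = corrupt_sequence(ids, TABLE, rng)
            outside = np.setdiff1d(np.arange(ids.size), ex.mask_positions)
            np.testing.assert_array_equal(ex.corrupted_ids[outside], ids[outside])
            np.testing.assert_array_equal(ex.target_ids, ids)

    def test_mask_branch_writes_caret(self, rng):
        ids = _random_ids(rng, 5000)
        ex = corrupt_sequence(ids, TABLE, rng)
        assert (ex.corrupted_ids[ex.branches == BRANCH_MASK] == TABLE.mask_id).all()

    def test_random_branch_preserves_class(self, rng):
        for _ in range(30):
            ids = _random_ids(rng, 2000)
            ex = corrupt_sequence(ids, TABLE, rng)
            for pos in np.flatnonzero(ex.branches == BRANCH_RANDOM):
                a = TABLE.char_of(int(ids[pos]))
                b = TABLE.char_of(int(ex.corrupted_ids[pos]))
                ga, gb = TABLE.replacement_group(a), TABLE.replacement_group(b)
                if ga is None:  # spaces / mask symbol stay as they are
                    assert a == b
                else:
                    assert ga == gb
                    assert a != b

    def test_short_sequence_can_escape_selection(self):
        rng = np.random.default_rng(0)
        outcomes = {corrupt_sequence([5], TABLE, rng).mask_positions.size
                    for _ in range(200)}
        assert outcomes == {0, 1}

    def test_empty_rejected(self, rng):
        with pytest.raises(ValueError):
            corrupt_sequence([], TABLE, rng)

    def test_deterministic_given_seed(self):
        ids = _random_ids(np.random.default_rng(1), 500)
        a = corrupt_sequence(ids, TABLE, np.random.default_rng(42))
        b = corrupt_sequence(ids, TABLE, np.random.default_rng(42))
        np.testing.assert_array_equal(a.corrupted_ids, b.corrupted_ids)
        np.testing.assert_array_equal(a.mask_positions, b.mask_positions)


class TestWholeWordCorrupt:
    TEXT = "1.Bladder cancer with chemotherapy cycle 3"

    def _example(self, seed, word_rate=0.5):
        ids = np.array(encode(self.TEXT), dtype=np.int64)
        units = segment_units(self.TEXT)
        rng = np.random.default_rng(seed)
        return ids, units, whole_word_corrupt(ids, units, TABLE, rng,
                                              word_rate=word_rate)

    def test_rate_zero_is_identity(self):
        ids, _, ex = self._example(0, word_rate=0.0)
        np.testing.assert_array_equal(ex.corrupted_ids, ids)
        assert ex.mask_positions.size == 0

    def test_selection_aligns_with_unit_boundaries(self):
        for seed in range(20):
            ids, units, ex = self._example(seed)
            selected = set(ex.mask_positions.tolist())
            for u in units:
                span = set(range(u.start, u.end))
                assert span <= selected or not (span & selected)

    def test_mask_branch_is_all_or_nothing(self):
        saw_full_word = False
        for seed in range(40):
            ids, units, ex = self._example(seed)
            for u in units:
                if u.kind not in ("letter_run", "digit_run"):
                    continue
                branch = set(ex.branches[u.start:u.end].tolist())
                assert len(branch) == 1  # one branch per unit
                if branch == {BRANCH_MASK}:
                    assert (ex.corrupted_ids[u.start:u.end] == TABLE.mask_id).all()
                    if u.end - u.start >= 5:
                        saw_full_word = True
        assert saw_full_word

    def test_spaces_and_punctuation_never_selected(self):
        for seed in range(20):
            ids, units, ex = self._example(seed, word_rate=1.0)
            for u in units:
                if u.kind in ("space_run", "punct"):
                    assert (ex.branches[u.start:u.end] == BRANCH_NONE).all()


class TestMlmLoss:
    def test_uniform_logits_closed_form(self):
        logits = np.zeros((7, 100))
        loss = mlm_loss(logits, np.arange(7), np.arange(7))
        assert abs(loss.item() - np.log(100)) < 1e-9

    def test_perfect_prediction_near_zero(self):
        targets = np.array([3, 1, 4])
        logits = np.full((3, 100), -1e4)
        logits[np.arange(3), targets] = 1e4
        assert mlm_loss(logits, targets, np.arange(3)).item() < 1e-8

    def test_three_position_brute_force(self, rng):
        logits = rng.standard_normal((6, 100))
        targets = rng.integers(0, 100, 6)
        positions = np.array([0, 2, 5])
        # independent oracle: direct per-position -log softmax
        expected = 0.0
        for p in positions:
            z = logits[p] - logits[p].max()
            expected += -(z[targets[p]] - np.log(np.exp(z).sum()))
        expected /= 3
        assert abs(mlm_loss(logits, targets, positions).item() - expected) < 1e-9

    def test_unmasked_positions_do_not_contribute(self, rng):
        logits = rng.standard_normal((5, 100))
        targets = rng.integers(0, 100, 5)
        base = mlm_loss(logits, targets, [1, 3]).item()
        logits[0] += 100.0  # perturb an unmasked row
        assert mlm_loss(logits, targets, [1, 3]).item() == pytest.approx(base)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mlm_loss(np.zeros((3, 100)), np.zeros(3, dtype=int), [])


TINY_CFG = ModelConfig(n_layers=1, n_heads=2, hidden=16, dropout=0.1, seed=0)
FAST_HYPER = dict(batch_size=2, warmup_steps=20, max_stitch=2)


class TestPretrainLoop:
    def test_loss_decreases(self, short_corpus):
        _, state = pretrain_loop(TINY_CFG, short_corpus,
                                 TrainHyper(steps=150, **FAST_HYPER), seed=3)
        losses = [h["loss"] for h in state.history]
        assert np.mean(losses[-30:]) < np.mean(losses[:30])

    def test_same_seed_same_trajectory(self, short_corpus):
        h = TrainHyper(steps=25, **FAST_HYPER)
        _, s1 = pretrain_loop(TINY_CFG, short_corpus, h, seed=4)
        _, s2 = pretrain_loop(TINY_CFG, short_corpus, h, seed=4)
        assert [x["loss"] for x in s1.history] == [x["loss"] for x in s2.history]

    def test_warmup_schedule(self, short_corpus):
        _, state = pretrain_loop(TINY_CFG, short_corpus,
                                 TrainHyper(steps=25, **FAST_HYPER), seed=5)
        assert state.history[0]["lr"] == 1e-5
        assert state.history[-1]["lr"] == 1e-4

    def test_phase2_manual_trigger(self, short_corpus):
        hyper = TrainHyper(steps=30, phase2_step=10, **FAST_HYPER)
        _, state = pretrain_loop(TINY_CFG, short_corpus, hyper, seed=6)
        phases = [h["phase"] for h in state.history]
        assert phases[5] == 1 and phases[-1] == 2

    def test_single_example_memorization(self):
        record = generate_diagnosis(GeneratorParams(seed=21, min_items=1,
                                                    max_items=1))
        # deterministic net and a larger step size: a pure capacity check
        cfg = ModelConfig(n_layers=1, n_heads=2, hidden=16, dropout=0.0, seed=0)
        hyper = TrainHyper(steps=2000, batch_size=2, warmup_steps=20,
                           max_stitch=1, lr_main=1e-3)
        _, state = pretrain_loop(cfg, [record], hyper, seed=7)
        assert np.mean([h["loss"] for h in state.history[-50:]]) < 0.1

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            pretrain_loop(TINY_CFG, [], TrainHyper(steps=1), seed=0)
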