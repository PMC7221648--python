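"""Stage-1 unsupervised pretraining: character-level cloze with ``^`` masks.

Each position of a character sequence is independently selected with
probability 0.15.  Of the selected positions, 80% are replaced by the mask
symbol ``^``, 10% by a uniformly random *different* symbol of the same
character class (letters with letters, digits with digits, punctuation with
punctuation — dates, cycle counts and staging indices cannot be guessed from
context, so corrupting a digit into a letter would teach nothing), and 10%
are left unchanged.  The loss is the mean cross-entropy of decoder A's
symbol probabilities at the selected positions only.

After the phase-1 loss converges, a second phase masks entire words
(all-or-nothing per letter/digit run) under the same 80/10/10 branch policy.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import nn
from .model import CharTransformer, ModelConfig
from .synthetic import DiagnosisRecord, stitch_augment
from .tokenizer import SymbolTable, WordUnit, build_symbol_table, encode

SELECT_RATE = 0.15
MASK_FRAC = 0.80
RANDOM_FRAC = 0.10

# branch codes recorded per position
BRANCH_NONE, BRANCH_MASK, BRANCH_RANDOM, BRANCH_KEEP = 0, 1, 2, 3


@dataclass(frozen=True)
class MaskedExample:
    """A corrupted sequence, its reconstruction targets, and bookkeeping."""

    corrupted_ids: np.ndarray
    target_ids: np.ndarray
    mask_positions: np.ndarray  # sorted offsets of all selected positions
    branches: np.ndarray  # per-position branch code (diagnostic)

    def __post_init__(self) -> None:
        if self.corrupted_ids.shape != self.target_ids.shape:
            raise ValueError("corrupted and target sequences must have equal length")


def _table_arrays(table: SymbolTable) -> dict:
    """Per-id replacement pools, cached on the table instance."""
    try:
        return object.__getattribute__(table, "_pools_cache")
    except AttributeError:
        pass
    pools: dict[str, np.ndarray] = {
        g: np.array([table.id_of(c) for c in table.group_members(g)])
        for g in ("letter", "digit", "punctuation")
    }
    group_of = np.full(100, -1, dtype=np.int64)
    for gi, g in enumerate(("letter", "digit", "punctuation")):
        group_of[pools[g]] = gi
    cache = {"pools": [pools["letter"], pools["digit"], pools["punctuation"]],
             "group_of": group_of, "mask_id": table.mask_id}
    object.__setattr__(table, "_pools_cache", cache)
    return cache


def _apply_branches(ids: np.ndarray, branches: np.ndarray, table: SymbolTable,
                    rng: np.random.Generator) -> np.ndarray:
    """Corrupt ``ids`` according to per-position branch codes."""
    cache = _table_arrays(table)
    out = ids.copy()
    out[branches == BRANCH_MASK] = cache["mask_id"]
    for pos in np.flatnonzero(branches == BRANCH_RANDOM):
        gi = cache["group_of"][ids[pos]]
        if gi < 0:  # space or mask symbol: no same-class pool, leave unchanged
            continue
        pool = cache["pools"][gi]
        j = int(rng.integers(len(pool) - 1))
        repl = int(pool[j])
        if repl == ids[pos]:
            repl = int(pool[-1])
        out[pos] = repl
    return out


def corrupt_sequence(ids, table: SymbolTable | None = None,
                     rng: np.random.Generator | None = None,
                     select_rate: float = SELECT_RATE) -> MaskedExample:
    """Independent Bernoulli cloze corruption with the 80/10/10 policy."""
    table = table or build_symbol_table()
    rng = rng if rng is not None else np.random.default_rng()
    ids = np.asarray(ids, dtype=np.int64)
    if ids.size == 0:
        raise ValueError("cannot corrupt an empty sequence")
    selected = rng.random(ids.size) < select_rate
    branches = np.full(ids.size, BRANCH_NONE, dtype=np.int64)
    u = rng.random(ids.size)
    branches[selected & (u < MASK_FRAC)] = BRANCH_MASK
    branches[selected & (u >= MASK_FRAC) & (u < MASK_FRAC + RANDOM_FRAC)] = BRANCH_RANDOM
    branches[selected & (u >= MASK_FRAC + RANDOM_FRAC)] = BRANCH_KEEP
    corrupted = _apply_branches(ids, branches, table, rng)
    return MaskedExample(corrupted, ids, np.flatnonzero(selected), branches)


def whole_word_corrupt(ids, units: list[WordUnit],
                       table: SymbolTable | None = None,
                       rng: np.random.Generator | None = None,
                       word_rate: float = SELECT_RATE) -> MaskedExample:
    """Phase-2 corruption: whole letter/digit runs, all-or-nothing.

    Each letter_run/digit_run unit is selected independently with
    probability ``word_rate``; a selected unit is assigned one branch for
    all of its characters (80% every character becomes ``^``, 10% every
    character is replaced by a random same-class symbol, 10% unchanged).
    Space and punctuation units are never selected.
    """
    table = table or build_symbol_table()
    rng = rng if rng is not None else np.random.default_rng()
    ids = np.asarray(ids, dtype=np.int64)
    branches = np.full(ids.size, BRANCH_NONE, dtype=np.int64)
    for unit in units:
        if unit.kind not in ("letter_run", "digit_run"):
            continue
        if rng.random() >= word_rate:
            continue
        u = rng.random()
        if u < MASK_FRAC:
            code = BRANCH_MASK
        elif u < MASK_FRAC + RANDOM_FRAC:
            code = BRANCH_RANDOM
        else:
            code = BRANCH_KEEP
        branches[unit.start:unit.end] = code
    corrupted = _apply_branches(ids, branches, table, rng)
    return MaskedExample(corrupted, ids, np.flatnonzero(branches != BRANCH_NONE),
                         branches)


def mlm_loss(logits, target_ids, mask_positions) -> nn.Tensor:
    """Mean cross-entropy of the target symbol over masked positions only."""
    mask_positions = np.asarray(mask_positions, dtype=np.intp)
    if mask_positions.size == 0:
        raise ValueError("mlm_loss is undefined with no masked positions")
    if not isinstance(logits, nn.Tensor):
        logits = nn.Tensor(np.asarray(logits, dtype=np.float64))
    target_ids = np.asarray(target_ids, dtype=np.intp)
    logp = nn.log_softmax(logits, axis=-1)
    rows = nn.take_rows(logp, mask_positions)
    picked = nn.gather_last(rows, target_ids[mask_positions])
    return -picked.mean()


@dataclass
class TrainHyper:
    """Optimization schedule shared by both training stages."""

    steps: int = 2000
    batch_size: int = 2
    lr_warmup: float = 1e-5
    lr_main: float = 1e-4
    warmup_steps: int = 100
    max_stitch: int = 29
    # phase-2 (whole-word) trigger: manual step override, or smoothed-loss
    # convergence (relative improvement below phase2_tol over a window)
    phase2_step: int | None = None
    phase2_window: int = 200
    phase2_tol: float = 0.01
    word_rate: float = SELECT_RATE
    log_every: int = 50
    checkpoint_every: int | None = None


@dataclass
class TrainState:
    """Serializable trace of one training run."""

    step: int = 0
    phase: int = 1
    history: list[dict] = field(default_factory=list)

    def log_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=["step", "phase", "lr", "loss"])
            w.writeheader()
            w.writerows(self.history)


def _lr_at(step: int, hyper: TrainHyper) -> float:
    return hyper.lr_warmup if step < hyper.warmup_steps else hyper.lr_main


def _phase2_due(state: TrainState, hyper: TrainHyper) -> bool:
    if hyper.phase2_step is not None:
        return state.step >= hyper.phase2_step
    w = hyper.phase2_window
    losses = [h["loss"] for h in state.history]
    if len(losses) < 2 * w:
        return False
    recent = float(np.mean(losses[-w:]))
    previous = float(np.mean(losses[-2 * w:-w]))
    return previous - recent < hyper.phase2_tol * previous


def _run_steps(model: CharTransformer, corpus: list[DiagnosisRecord],
               hyper: TrainHyper, seed: int,
               step_fn: Callable, out_path=None) -> TrainState:
    """Shared minibatch loop: stitch, build example, backprop, Adam."""
    if not corpus:
        raise ValueError("corpus must be non-empty")
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.params)
    state = TrainState()
    table = build_symbol_table()
    for step in range(hyper.steps):
        opt.zero_grad()
        losses = []
        total = None
        for _ in range(hyper.batch_size):
            loss = step_fn(model, corpus, table, rng, state)
            total = loss if total is None else total + loss
            losses.append(loss.item())
        batch_loss = total * (1.0 / hyper.batch_size)
        if not np.isfinite(batch_loss.item()):
            raise RuntimeError(
                f"non-finite loss {batch_loss.item()} at step {step}; aborting"
            )
        batch_loss.backward()
        lr = _lr_at(step, hyper)
        opt.step(lr)
        state.step = step + 1
        state.history.append(
            {"step": step, "phase": state.phase, "lr": lr,
             "loss": float(np.mean(losses))}
        )
        if state.phase == 1 and _phase2_due(state, hyper):
            state.phase = 2
        if (out_path is not None and hyper.checkpoint_every
                and (step + 1) % hyper.checkpoint_every == 0):
            model.save(out_path)
    return state


def _mlm_step(model: CharTransformer, corpus, table, rng, state: TrainState,
              hyper: TrainHyper):
    from .tokenizer import segment_units
    while True:
        rec = stitch_augment(corpus, rng, max_k=hyper.max_stitch)
        if rec.text.strip():
            break
    ids = np.array(encode(rec.text, table), dtype=np.int64)
    while True:  # resample the (rare) draws that select nothing
        if state.phase == 2:
            ex = whole_word_corrupt(ids, segment_units(rec.text), table, rng,
                                    word_rate=hyper.word_rate)
        else:
            ex = corrupt_sequence(ids, table, rng)
        if ex.mask_positions.size:
            break
    hidden = model.encode_sequence(ex.corrupted_ids, train=True, rng=rng)
    logits = model.decoder_A(hidden)
    return mlm_loss(logits, ex.target_ids, ex.mask_positions)


def pretrain_loop(config: ModelConfig | CharTransformer,
                  corpus: list[DiagnosisRecord],
                  hyper: TrainHyper | None = None,
                  seed: int = 0, out_path=None) -> tuple[CharTransformer, TrainState]:
    """Run stage-1 pretraining; returns the model and its training trace.

    Each batch item is built by stitching random corpus records into one
    long diagnosis, then applying cloze corruption (phase 1) or whole-word
    corruption (phase 2, entered when the smoothed loss converges or at the
    manual ``phase2_step`` override).  Fully deterministic given the seed.
    """
    hyper = hyper or TrainHyper()
    model = config if isinstance(config, CharTransformer) else CharTransformer(config)
    state = _run_steps(
        model, corpus, hyper, seed,
        lambda m, c, t, r, s: _mlm_step(m, c, t, r, s, hyper),
        out_path,
    )
    if out_path is not None:
        model.save(out_path)
    return model, state
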