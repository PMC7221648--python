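"""Stage-2 supervised fine-tuning of the selection head on highlight labels.

Highlight labels mark, character by character, which parts of a diagnosis a
summarizer should keep ("1.Bladder cancer with" labeled
"001111111111111110000").  Fine-tuning continues from the pretrained
checkpoint and optimizes the mean two-class cross-entropy of decoder S over
*all* character positions (selected and unselected alike, with no class
weighting).  Training batches reuse the stitching augmentation over the
labeled pool and inject random class-preserving typos at a 0.1% character
rate so the model tolerates misspellings; labels are never altered by the
typo step.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .model import CharTransformer
from .pretrain import TrainHyper, TrainState, _run_steps
from .synthetic import DiagnosisRecord, inject_typos, stitch_augment
from .tokenizer import encode

TYPO_RATE = 0.001


def align_label(text: str, highlight_spans: list[tuple[int, int]]) -> str:
    """Turn 0-based half-open highlight intervals into a 0/1 mask string."""
    n = len(text)
    mask = np.zeros(n, dtype=np.int64)
    last_end = -1
    for start, end in sorted(highlight_spans):
        if not (0 <= start <= end <= n):
            raise ValueError(f"span ({start}, {end}) out of range [0, {n})")
        if start < last_end:
            raise ValueError(f"span ({start}, {end}) overlaps a previous span")
        mask[start:end] = 1
        last_end = end
    return "".join("1" if b else "0" for b in mask)


def selection_loss(logits, labels) -> nn.Tensor:
    """Mean two-class cross-entropy over every character position."""
    labels = np.asarray(labels, dtype=np.intp)
    if not isinstance(logits, nn.Tensor):
        logits = nn.Tensor(np.asarray(logits, dtype=np.float64))
    if logits.shape[0] != labels.size:
        raise ValueError(
            f"logits length {logits.shape[0]} != labels length {labels.size}"
        )
    logp = nn.log_softmax(logits, axis=-1)
    return -nn.gather_last(logp, labels).mean()


def _labels_array(record: DiagnosisRecord) -> np.ndarray:
    return np.frombuffer(record.label.encode(), dtype=np.uint8) - ord("0")


def _selection_step(model: CharTransformer, corpus, table, rng,
                    state: TrainState, hyper: TrainHyper, typo_rate: float):
    while True:
        rec = stitch_augment(corpus, rng, max_k=hyper.max_stitch)
        if rec.text.strip():
            break
    rec = inject_typos(rec, typo_rate, rng)
    ids = np.array(encode(rec.text, table), dtype=np.int64)
    labels = _labels_array(rec)
    hidden = model.encode_sequence(ids, train=True, rng=rng)
    logits = model.decoder_S(hidden)
    return selection_loss(logits, labels)


def finetune_loop(model: CharTransformer | str, labeled_corpus: list[DiagnosisRecord],
                  hyper: TrainHyper | None = None, seed: int = 0,
                  typo_rate: float = TYPO_RATE,
                  out_path=None) -> tuple[CharTransformer, TrainState]:
    """Fine-tune a pretrained model (object or checkpoint path) on labels.

    The whole network is trained jointly — encoder and selection head — with
    the same optimizer schedule as pretraining.  Raises before training if
    any corpus record lacks a label or has a label/text length mismatch.
    """
    hyper = hyper or TrainHyper(phase2_step=0)  # no cloze phases here
    if isinstance(model, (str, bytes)) or hasattr(model, "__fspath__"):
        model = CharTransformer.load(model)
    for i, rec in enumerate(labeled_corpus):
        if rec.label is None:
            raise ValueError(f"record {i} has no label; fine-tuning needs labels")
        if len(rec.label) != len(rec.text):
            raise ValueError(f"record {i}: label/text length mismatch")
    state = _run_steps(
        model, labeled_corpus, hyper, seed,
        lambda m, c, t, r, s: _selection_step(m, c, t, r, s, hyper, typo_rate),
        out_path,
    )
    if out_path is not None:
        model.save(out_path)
    return model, state
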