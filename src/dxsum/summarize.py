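"""Inference: per-character selection probabilities to extracted summaries.

A fine-tuned model scores every character of a diagnosis with a selection
probability.  Because characters of one word are scored independently, raw
thresholding can select word fragments; the cleanup step therefore replaces
every character's probability inside a word unit (letter run, digit run, or
punctuation mark) by the unit's mean, so after thresholding each word is
kept whole or dropped whole.  Space runs keep their raw per-character
values.  The summary string is the selected characters with unselected gaps
collapsed to single spaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .model import CharTransformer
from .tokenizer import WordUnit, encode, segment_units


@dataclass(frozen=True)
class SummaryProposal:
    """Everything inference produces for one diagnosis."""

    text: str
    raw_probs: np.ndarray
    clean_probs: np.ndarray
    threshold: float
    selected_mask: np.ndarray
    summary: str


def predict_probabilities(model: CharTransformer | str, text: str) -> np.ndarray:
    """Selected-class probability for each character (evaluation mode)."""
    if isinstance(model, (str, bytes)) or hasattr(model, "__fspath__"):
        model = CharTransformer.load(model)
    if len(text) > model.config.max_positions:
        raise ValueError(
            f"text length {len(text)} exceeds max_positions "
            f"{model.config.max_positions}; preprocess() truncates to the limit"
        )
    if not text:
        return np.zeros(0)
    ids = encode(text)
    hidden = model.encode_sequence(ids, train=False)
    probs = nn.softmax(model.decoder_S(hidden), axis=-1)
    return probs.data[:, 1].astype(np.float64)


def cleanup(raw_probs: np.ndarray, units: list[WordUnit]) -> np.ndarray:
    """Word-average smoothing: constant per non-space unit, raw on spaces."""
    raw_probs = np.asarray(raw_probs, dtype=np.float64)
    if not units and raw_probs.size == 0:
        return raw_probs.copy()
    if not units or units[0].start != 0 or units[-1].end != raw_probs.size or any(
        u.end != nxt.start for u, nxt in zip(units, units[1:])
    ):
        raise ValueError("units must tile the probability vector exactly")
    clean = raw_probs.copy()
    for u in units:
        if u.kind == "space_run":
            continue
        clean[u.start:u.end] = raw_probs[u.start:u.end].mean()
    return clean


def threshold_select(clean_probs: np.ndarray, threshold: float) -> np.ndarray:
    """0/1 mask; a position is selected iff its probability >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    return (np.asarray(clean_probs) >= threshold).astype(np.int64)


def extract_summary(text: str, mask) -> str:
    """Render the selected characters, collapsing dropped runs to one space."""
    mask = np.asarray(
        [int(c) for c in mask] if isinstance(mask, str) else mask, dtype=np.int64
    )
    if mask.size != len(text):
        raise ValueError("mask length must equal text length")
    pieces: list[str] = []
    in_gap = False
    for ch, keep in zip(text, mask):
        if keep:
            if in_gap and pieces:
                pieces.append(" ")
            pieces.append(ch)
            in_gap = False
        else:
            in_gap = True
    return "".join(pieces).strip()


def summarize_text(model: CharTransformer | str, text: str,
                   threshold: float = 0.5) -> SummaryProposal:
    """Full inference pipeline for one preprocessed diagnosis."""
    raw = predict_probabilities(model, text)
    units = segment_units(text)
    clean = cleanup(raw, units)
    mask = threshold_select(clean, threshold)
    return SummaryProposal(
        text=text, raw_probs=raw, clean_probs=clean, threshold=threshold,
        selected_mask=mask, summary=extract_summary(text, mask),
    )
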