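"""Scikit-learn style estimator facade over the two-stage training engine.

``DiagnosisSummarizer`` wraps synthetic/real corpus handling, stage-1 cloze
pretraining, stage-2 selection fine-tuning and threshold calibration behind
the familiar fit/predict surface, so the summarizer composes with sklearn
model-selection utilities.  ``X`` is a sequence of preprocessed diagnosis
texts; ``y`` the aligned 0/1 highlight mask strings.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .evaluate import choose_threshold, f1_binary
from .finetune import finetune_loop
from .model import ModelConfig
from .pretrain import TrainHyper, pretrain_loop
from .summarize import SummaryProposal, summarize_text
from .synthetic import DiagnosisRecord


class DiagnosisSummarizer(BaseEstimator):
    """Character-level extractive summarizer with a fit/predict interface.

    Parameters mirror the model configuration and the optimization
    schedule; see :class:`~dxsum.model.ModelConfig` and
    :class:`~dxsum.pretrain.TrainHyper`.  After ``fit`` the fitted network
    is in ``model_`` and the calibrated selection threshold in
    ``threshold_``.
    """

    def __init__(self, n_layers: int = 2, n_heads: int = 2, hidden: int = 32,
                 ff_width: int | None = None, dropout: float = 0.1,
                 pretrain_steps: int = 500, finetune_steps: int = 500,
                 batch_size: int = 2, lr_warmup: float = 1e-5,
                 lr_main: float = 1e-4, warmup_steps: int = 100,
                 max_stitch: int = 29, typo_rate: float = 0.001,
                 threshold: float | None = None, validation_fraction: float = 0.1,
                 random_state: int = 0):
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.hidden = hidden
        self.ff_width = ff_width
        self.dropout = dropout
        self.pretrain_steps = pretrain_steps
        self.finetune_steps = finetune_steps
        self.batch_size = batch_size
        self.lr_warmup = lr_warmup
        self.lr_main = lr_main
        self.warmup_steps = warmup_steps
        self.max_stitch = max_stitch
        self.typo_rate = typo_rate
        self.threshold = threshold
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _config(self) -> ModelConfig:
        return ModelConfig(
            n_layers=self.n_layers, n_heads=self.n_heads, hidden=self.hidden,
            ff_width=self.ff_width, dropout=self.dropout,
            seed=self.random_state,
        )

    def _hyper(self, steps: int, phase2_step: int | None = None) -> TrainHyper:
        return TrainHyper(
            steps=steps, batch_size=self.batch_size, lr_warmup=self.lr_warmup,
            lr_main=self.lr_main, warmup_steps=self.warmup_steps,
            max_stitch=self.max_stitch, phase2_step=phase2_step,
        )

    @staticmethod
    def _records(X, y=None) -> list[DiagnosisRecord]:
        if y is None:
            return [DiagnosisRecord(text=t) for t in X]
        return [DiagnosisRecord(text=t, label=lab) for t, lab in zip(X, y)]

    # -- sklearn surface ---------------------------------------------------
    def fit(self, X, y, pretrain_X=None) -> "DiagnosisSummarizer":
        """Pretrain on texts, fine-tune on highlight masks, calibrate.

        ``pretrain_X`` optionally provides extra unlabeled texts (e.g. an
        ICD-style pool) for the cloze stage; labeled texts are always
        included there too.
        """
        X = list(X)
        y = list(y)
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        if not X:
            raise ValueError("cannot fit on an empty corpus")
        labeled = self._records(X, y)
        pool = labeled + (self._records(pretrain_X) if pretrain_X is not None else [])
        model, self.pretrain_state_ = pretrain_loop(
            self._config(), pool, self._hyper(self.pretrain_steps),
            seed=self.random_state,
        )
        if self.threshold is None and len(labeled) >= 10:
            n_val = max(1, int(round(self.validation_fraction * len(labeled))))
            train, val = labeled[:-n_val], labeled[-n_val:]
        else:
            train, val = labeled, labeled
        model, self.finetune_state_ = finetune_loop(
            model, train, self._hyper(self.finetune_steps, phase2_step=0),
            seed=self.random_state + 1, typo_rate=self.typo_rate,
        )
        self.model_ = model
        self.threshold_ = (self.threshold if self.threshold is not None
                           else choose_threshold(model, val))
        return self

    def predict_proba(self, X) -> list[np.ndarray]:
        """Cleaned per-character selection probabilities for each text."""
        self._check_fitted()
        return [summarize_text(self.model_, t, self.threshold_).clean_probs
                for t in X]

    def predict(self, X) -> list[str]:
        """0/1 highlight mask strings at the calibrated threshold."""
        self._check_fitted()
        out = []
        for t in X:
            mask = summarize_text(self.model_, t, self.threshold_).selected_mask
            out.append("".join(str(int(b)) for b in mask))
        return out

    def summarize(self, text: str) -> SummaryProposal:
        """Full proposal (probabilities, mask, summary string) for one text."""
        self._check_fitted()
        return summarize_text(self.model_, text, self.threshold_)

    def score(self, X, y) -> float:
        """Mean character-level F1 of predicted vs true highlight masks."""
        preds = self.predict(X)
        return float(np.mean([f1_binary(p, t).f1 for p, t in zip(preds, y)]))

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("this DiagnosisSummarizer instance is not fitted yet")
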