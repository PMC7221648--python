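"""End-to-end seeded run management: synth -> split -> pretrain -> finetune
-> threshold calibration -> evaluation, with a reproducibility manifest.

One global seed expands deterministically (via ``numpy.random.SeedSequence``)
into independent per-stage seeds, so a manifest plus the package version is
enough to reproduce every artifact bit-for-bit on one device.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .corpus_io import write_corpus
from .evaluate import choose_threshold, evaluate_model
from .finetune import finetune_loop
from .model import ModelConfig
from .pretrain import TrainHyper, pretrain_loop
from .synthetic import GeneratorParams, generate_corpus, split_corpus


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything one reproducible end-to-end run needs."""

    out_dir: str
    seed: int = 0
    n_discharge: int = 400
    n_icd: int = 100
    n_labeled: int = 100
    train_fraction: float = 0.95
    model: ModelConfig = field(default_factory=ModelConfig.tiny)
    pretrain: TrainHyper = field(default_factory=lambda: TrainHyper(steps=300))
    finetune: TrainHyper = field(default_factory=lambda: TrainHyper(steps=300, phase2_step=0))


def _stage_seeds(seed: int, n: int = 6) -> list[int]:
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def _config_hash(cfg: RunConfig) -> str:
    blob = yaml.safe_dump(json.loads(json.dumps(asdict(cfg), default=str)),
                          sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages, writing artifacts and a manifest under out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    manifest: dict = {"seed": cfg.seed, "stage_seeds": seeds,
                      "config_hash": _config_hash(cfg)}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # annotate with the failing stage
                raise PipelineError(name, exc) from exc
        return deco

    @stage("synth")
    def corpus():
        params = GeneratorParams(seed=seeds[0])
        records = generate_corpus(cfg.n_discharge, cfg.n_icd, params)
        write_corpus(records, out / "corpus.jsonl")
        labeled = [r for r in records if r.label is not None][:cfg.n_labeled]
        write_corpus(labeled, out / "labels.jsonl")
        return records, labeled

    records, labeled = corpus

    @stage("split")
    def splits():
        train, val = split_corpus(records, cfg.train_fraction, seeds[1])
        ltrain, lval = split_corpus(labeled, 0.8, seeds[1])
        return train, val, ltrain, lval

    train, _val, ltrain, lval = splits

    @stage("pretrain")
    def pretrained():
        model, state = pretrain_loop(cfg.model, train, cfg.pretrain,
                                     seed=seeds[2], out_path=out / "pretrained.npz")
        state.log_csv(out / "pretrain_log.csv")
        return model

    @stage("finetune")
    def finetuned():
        if not (out / "pretrained.npz").exists():
            raise FileNotFoundError("pretrained checkpoint missing")
        model, state = finetune_loop(pretrained, ltrain, cfg.finetune,
                                     seed=seeds[3], out_path=out / "finetuned.npz")
        state.log_csv(out / "finetune_log.csv")
        return model

    @stage("threshold")
    def threshold():
        return choose_threshold(finetuned, lval)

    @stage("evaluate")
    def report():
        rep = evaluate_model(finetuned, lval, threshold)
        rep.pop("per_record")
        return rep

    manifest["threshold"] = threshold
    manifest["metrics"] = report
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
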