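"""Synthetic discharge-diagnosis corpus with rule-defined highlight labels.

Real discharge diagnoses and their doctor-highlighted summaries come from a
private hospital database, so this module generates structurally similar
stand-ins: numbered multi-item lists where each item is a disease phrase
followed by an optional treatment clause with dates, cycle counts and
abbreviations, plus short ICD-style single-phrase diagnoses.  The highlight
label is deterministic — exactly the characters of the disease head phrases
(including the single spaces joining multi-word phrases) are labeled ``1`` —
so supervised learning has a recoverable signal, unlike the subjective
doctor labels it emulates.

Also implements the two training-time augmentations: stitching 1-29 records
into one long renumbered diagnosis (truncated to 1350 characters) and
class-preserving random typo injection at a 0.1% character rate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np

from .tokenizer import MAX_CHARS, build_symbol_table, preprocess

# Disease head phrases: pairwise non-substring so labels can be re-derived
# from the text by phrase matching.
DISEASES: tuple[str, ...] = (
    "Bladder cancer",
    "Urothelial carcinoma",
    "Hepatocellular carcinoma",
    "Colon adenocarcinoma",
    "Rectal tumor",
    "Breast invasive ductal carcinoma",
    "Lung adenocarcinoma",
    "Nasopharyngeal carcinoma",
    "Gastric ulcer with bleeding",
    "Liver cirrhosis",
    "Chronic hepatitis B",
    "Chronic kidney disease",
    "End stage renal disease",
    "Type 2 diabetes mellitus",
    "Hypertensive cardiovascular disease",
    "Congestive heart failure",
    "Atrial fibrillation",
    "Coronary artery disease",
    "Old myocardial infarction",
    "Ischemic stroke",
    "Chronic obstructive pulmonary disease",
    "Community acquired pneumonia",
    "Urinary tract infection",
    "Acute pyelonephritis",
    "Cellulitis of left lower leg",
    "Septic shock",
    "Acute pancreatitis",
    "Cholangitis",
    "Femoral neck fracture",
    "Major depressive disorder",
    "COPD AE",
    "ESRD under H/D",
)

TREATMENTS: tuple[str, ...] = (
    "chemotherapy",
    "radiotherapy",
    "targeted therapy",
    "immunotherapy",
    "antibiotic treatment",
    "laparoscopic resection",
    "radical cystectomy",
    "transurethral resection",
    "hemodialysis",
    "insulin therapy",
    "anticoagulation",
    "percutaneous coronary intervention",
    "open reduction and internal fixation",
    "supportive care",
    "C/T",
    "R/T",
    "OP",
)

MODIFIERS: tuple[str, ...] = (
    "suspected",
    "recurrent",
    "stable",
    "post",
    "newly diagnosed",
    "advanced",
    "bilateral",
    "left",
    "right",
)

ABBREVIATIONS: tuple[str, ...] = ("s/p", "r/o", "with", "under", "status post")


@dataclass(frozen=True)
class DiagnosisRecord:
    """One diagnosis text with an optional aligned 0/1 highlight mask."""

    text: str
    label: str | None = None
    source: str = "synthetic_discharge"  # synthetic_discharge | synthetic_icd | stitched
    n_sources: int | None = None  # stitching provenance; None for base records

    def __post_init__(self) -> None:
        if self.label is not None:
            if len(self.label) != len(self.text):
                raise ValueError(
                    f"label length {len(self.label)} != text length {len(self.text)}"
                )
            if set(self.label) - {"0", "1"}:
                raise ValueError("label must contain only '0' and '1'")


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the synthetic corpus generator; the seed fixes everything."""

    diseases: tuple[str, ...] = DISEASES
    treatments: tuple[str, ...] = TREATMENTS
    modifiers: tuple[str, ...] = MODIFIERS
    abbreviations: tuple[str, ...] = ABBREVIATIONS
    min_items: int = 1
    max_items: int = 3
    typo_rate: float = 0.001
    seed: int = 0

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _date(rng: np.random.Generator) -> str:
    y = int(rng.integers(2010, 2021))
    m = int(rng.integers(1, 13))
    d = int(rng.integers(1, 29))
    if rng.random() < 0.5:
        return f"{y}-{m:02d}-{d:02d}"
    return f"{y}/{m}/{d}"


def _treatment_clause(params: GeneratorParams, rng: np.random.Generator) -> str:
    """A clause describing treatment; never contains a digit-dot pattern."""
    treat = str(rng.choice(params.treatments))
    joiner = str(rng.choice(params.abbreviations))
    parts = [f" {joiner} {treat}"]
    u = rng.random()
    if u < 0.35:
        parts.append(f" on {_date(rng)}")
    elif u < 0.6:
        parts.append(f", cycle {int(rng.integers(1, 13))}")
    elif u < 0.7:
        parts.append(f" x{int(rng.integers(2, 9))} courses")
    return "".join(parts)


def _one_item(number: int, params: GeneratorParams, rng: np.random.Generator
              ) -> tuple[str, str]:
    """Build 'n.<disease><clause>' and its aligned 0/1 label string."""
    disease = str(rng.choice(params.diseases))
    prefix = f"{number}."
    clause = _treatment_clause(params, rng) if rng.random() < 0.8 else ""
    text = prefix + disease + clause
    label = "0" * len(prefix) + "1" * len(disease) + "0" * len(clause)
    return text, label


def generate_diagnosis(params: GeneratorParams,
                       rng: np.random.Generator | None = None) -> DiagnosisRecord:
    """Generate one numbered multi-item discharge diagnosis with its label.

    Exactly the characters of the disease head phrases are labeled 1; item
    numbers, joiners, treatments, dates and cycle counts are labeled 0.
    """
    rng = params.rng() if rng is None else rng
    n_items = int(rng.integers(params.min_items, params.max_items + 1))
    texts, labels = [], []
    for i in range(n_items):
        t, l = _one_item(i + 1, params, rng)
        texts.append(t)
        labels.append(l)
    text = " ".join(texts)
    label = "0".join(labels)
    return DiagnosisRecord(text=text, label=label, source="synthetic_discharge")


def generate_icd_entry(params: GeneratorParams,
                       rng: np.random.Generator | None = None) -> DiagnosisRecord:
    """Generate a short unlabeled ICD-style diagnosis phrase (2-8 words)."""
    rng = params.rng() if rng is None else rng
    words: list[str] = []
    if rng.random() < 0.5:
        words.append(str(rng.choice(params.modifiers)))
    words.extend(str(rng.choice(params.diseases)).split())
    if rng.random() < 0.3:
        words.append("without complication")
    text = " ".join(words)[:MAX_CHARS]
    return DiagnosisRecord(text=text, label=None, source="synthetic_icd")


def generate_corpus(n_discharge: int, n_icd: int,
                    params: GeneratorParams) -> list[DiagnosisRecord]:
    """Generate a mixed corpus; a single seed fixes the full stream."""
    rng = params.rng()
    records = [generate_diagnosis(params, rng) for _ in range(n_discharge)]
    records += [generate_icd_entry(params, rng) for _ in range(n_icd)]
    return records


# -- stitching augmentation ------------------------------------------------

_ITEM_START_RE = re.compile(r"(?:^| )(\d+)\.")


def _items_of(record: DiagnosisRecord) -> list[tuple[str, str | None]]:
    """Split a record into numbered items, stripping the old number prefixes.

    A record without a leading 'n.' pattern is a single unnumbered item.
    Returns (item_text, item_label_or_None) pairs.
    """
    text, label = record.text, record.label
    starts = [m for m in _ITEM_START_RE.finditer(text)]
    if not starts or starts[0].start() != 0:
        return [(text, label)]
    items = []
    for i, m in enumerate(starts):
        # content begins after 'n.'; item ends just before the next ' n.'
        beg = m.end()
        end = starts[i + 1].start() if i + 1 < len(starts) else len(text)
        items.append((text[beg:end], label[beg:end] if label is not None else None))
    return items


def stitch_augment(pool: list[DiagnosisRecord], rng: np.random.Generator,
                   max_k: int = 29, max_chars: int = MAX_CHARS) -> DiagnosisRecord:
    """Stitch k ~ Uniform{1..max_k} records (with replacement) into one.

    Items are renumbered sequentially across the stitched text and joined by
    single spaces; labels are concatenated in parallel (number prefixes and
    joiners labeled 0, unlabeled constituents contributing all-0 labels when
    any constituent is labeled).  The result is truncated to ``max_chars``
    with the label truncated identically.
    """
    if not pool:
        raise ValueError("pool must be non-empty")
    k = int(rng.integers(1, max_k + 1))
    picks = [pool[int(i)] for i in rng.integers(0, len(pool), size=k)]
    any_label = any(r.label is not None for r in picks)

    text_parts: list[str] = []
    label_parts: list[str] = []
    counter = 1
    for rec in picks:
        for item_text, item_label in _items_of(rec):
            prefix = f"{counter}."
            if text_parts:
                text_parts.append(" ")
                label_parts.append("0")
            text_parts.append(prefix + item_text)
            if any_label:
                body = item_label if item_label is not None else "0" * len(item_text)
                label_parts.append("0" * len(prefix) + body)
            counter += 1

    text = "".join(text_parts)[:max_chars]
    label = "".join(label_parts)[:max_chars] if any_label else None
    return DiagnosisRecord(text=text, label=label, source="stitched", n_sources=k)


# -- typo injection --------------------------------------------------------

_table = build_symbol_table()
_GROUP_OF: dict[str, str | None] = {ch: _table.replacement_group(ch) for ch in _table.symbols}
_GROUP_MEMBERS: dict[str, str] = {
    g: _table.group_members(g) for g in ("letter", "digit", "punctuation")
}


def inject_typos(record: DiagnosisRecord, rate: float,
                 rng: np.random.Generator) -> DiagnosisRecord:
    """Independently replace each character with probability ``rate``.

    Replacements stay within the character's class pool (letter→letter,
    digit→digit, punctuation→punctuation) and never equal the original;
    spaces and mask characters are untouched.  The label is unchanged: typo
    robustness is trained, not labeled.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0 or not record.text:
        return record
    chars = list(record.text)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        group = _GROUP_OF.get(chars[i])
        if group is None:
            continue
        members = _GROUP_MEMBERS[group]
        j = int(rng.integers(len(members) - 1))
        repl = members[j]
        if repl == chars[i]:  # skip-self trick keeps the draw uniform
            repl = members[-1]
        chars[i] = repl
    return replace(record, text="".join(chars))


def split_corpus(records: list[DiagnosisRecord], train_fraction: float,
                 seed: int) -> tuple[list[DiagnosisRecord], list[DiagnosisRecord]]:
    """Deterministic shuffled split into (train, validation).

    ``|train| = round(train_fraction * N)``; the two parts partition the
    input exactly.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(train_fraction * n))
    train = [records[int(i)] for i in order[:n_train]]
    val = [records[int(i)] for i in order[n_train:]]
    return train, val


def check_fixed_point(record: DiagnosisRecord) -> bool:
    """True when the record's text is unchanged by preprocess()."""
    return preprocess(record.text) == record.text
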