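"""Corpus file codec: UTF-8 JSON-lines, one diagnosis record per line.

Each line is an object with fields ``text``, ``label`` (nullable 0/1 string
of the same length) and ``source``.  Reading validates every record — label
alignment and the preprocess fixed-point property — and reports the
offending line number on failure.
"""

from __future__ import annotations

import json
from pathlib import Path

from .synthetic import DiagnosisRecord
from .tokenizer import preprocess


class CorpusFormatError(ValueError):
    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def read_corpus(path: str | Path) -> list[DiagnosisRecord]:
    """Read and validate a JSON-lines corpus file."""
    records: list[DiagnosisRecord] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(line_no, f"malformed JSON ({exc.msg})") from None
            text = obj.get("text")
            label = obj.get("label")
            if not isinstance(text, str):
                raise CorpusFormatError(line_no, "missing or non-string 'text'")
            if label is not None:
                if not isinstance(label, str) or len(label) != len(text):
                    raise CorpusFormatError(
                        line_no, f"label length {len(label) if isinstance(label, str) else '?'} "
                                 f"does not match text length {len(text)}")
                if set(label) - {"0", "1"}:
                    raise CorpusFormatError(line_no, "label contains characters other than 0/1")
            if preprocess(text) != text:
                raise CorpusFormatError(
                    line_no, "text contains out-of-table characters or exceeds 1350 chars")
            records.append(DiagnosisRecord(
                text=text, label=label,
                source=obj.get("source", "synthetic_discharge"),
            ))
    return records


def write_corpus(records: list[DiagnosisRecord], path: str | Path) -> None:
    """Write records as JSON-lines with a deterministic field order."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(
                {"text": rec.text, "label": rec.label, "source": rec.source},
                ensure_ascii=False,
            ) + "\n")
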