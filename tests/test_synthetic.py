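"""Synthetic corpus generation, stitching augmentation, typos, splitting."""

import re

import numpy as np
import pytest

from dxsum.synthetic import (
    DISEASES,
    DiagnosisRecord,
    GeneratorParams,
    generate_corpus,
    generate_diagnosis,
    generate_icd_entry,
    inject_typos,
    split_corpus,
    stitch_augment,
)
from dxsum.tokenizer import build_symbol_table, preprocess

TABLE = build_symbol_table()


def rederive_label(text: str) -> str:
    """Independent label oracle: union of disease-phrase occurrences."""
    lab = ["0"] * len(text)
    for phrase in DISEASES:
        for m in re.finditer(re.escape(phrase), text):
            for i in range(m.start(), m.end()):
                lab[i] = "1"
    return "".join(lab)


class TestGenerator:
    def test_deterministic(self):
        p = GeneratorParams(seed=1)
        assert generate_diagnosis(p) == generate_diagnosis(p)
        assert generate_icd_entry(p) == generate_icd_entry(p)

    def test_disease_vocab_pairwise_non_substring(self):
        for a in DISEASES:
            for b in DISEASES:
                assert a == b or a not in b

    def test_single_item_shape(self):
        rec = generate_diagnosis(GeneratorParams(seed=1, min_items=1, max_items=1))
        assert rec.text.startswith("1.")
        assert rec.label.startswith("00")
        assert "1" in rec.label

    def test_labels_match_generation_rule(self):
        corpus = generate_corpus(150, 0, GeneratorParams(seed=2))
        for rec in corpus:
            assert rec.label == rederive_label(rec.text)

    def test_records_are_preprocess_fixed_points(self):
        for rec in generate_corpus(100, 50, GeneratorParams(seed=3)):
            assert preprocess(rec.text) == rec.text

    def test_label_text_length_invariant(self):
        for rec in generate_corpus(300, 0, GeneratorParams(seed=4)):
            assert len(rec.label) == len(rec.text)

    def test_icd_entry_short_unlabeled(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            rec = generate_icd_entry(GeneratorParams(seed=7), rng)
            assert rec.label is None
            assert 2 <= len(rec.text.split()) <= 8

    def test_record_validation(self):
        with pytest.raises(ValueError):
            DiagnosisRecord(text="abc", label="01")
        with pytest.raises(ValueError):
            DiagnosisRecord(text="ab", label="2x")


@pytest.fixture(scope="module")
def pool():
    return generate_corpus(60, 20, GeneratorParams(seed=5))


@pytest.fixture(scope="module")
def record():
    rng = np.random.default_rng(8)
    params = GeneratorParams(seed=8)
    text = " ".join(generate_diagnosis(params, rng).text for _ in range(500))
    return DiagnosisRecord(text=text[:50000], label="0" * len(text[:50000]))


class TestStitchAugment:
    def test_k_range_covered(self, pool):
        rng = np.random.default_rng(0)
        ks = {stitch_augment(pool, rng).n_sources for _ in range(3000)}
        assert ks == set(range(1, 30))

    def test_truncated_to_limit(self, pool):
        rng = np.random.default_rng(1)
        for _ in range(200):
            assert len(stitch_augment(pool, rng).text) <= 1350

    def test_k1_is_renumbering_only(self, pool):
        labeled = [r for r in pool if r.label is not None][:1]
        rec = stitch_augment(labeled, np.random.default_rng(2), max_k=1)
        assert rec.n_sources == 1
        # same disease content: strip item numbers before comparing
        strip = lambda t: re.sub(r"(?:^| )\d+\.", " ", t).strip()
        assert strip(rec.text) == strip(labeled[0].text)

    def test_items_renumbered_sequentially(self, pool):
        rng = np.random.default_rng(3)
        rec = stitch_augment(pool, rng, max_k=10, max_chars=100000)
        numbers = [int(m.group(1)) for m in re.finditer(r"(?:^| )(\d+)\.", rec.text)]
        assert numbers == list(range(1, len(numbers) + 1))

    def test_label_mass_preserved_without_truncation(self, pool):
        # single-record pool: stitched highlighted mass must be exactly
        # k times the constituent's mass when nothing is truncated
        one = next(r for r in pool if r.label is not None)
        for seed in range(5):
            rec = stitch_augment([one], np.random.default_rng(seed),
                                 max_chars=10 ** 6)
            assert rec.label.count("1") == rec.n_sources * one.label.count("1")

    def test_stitched_labels_align(self):
        # labeled-only pool, no truncation: a cut mid-phrase or an unlabeled
        # constituent (whose phrases are deliberately labeled 0) would
        # defeat the phrase-matching oracle
        labeled_pool = generate_corpus(60, 0, GeneratorParams(seed=5))
        rng = np.random.default_rng(6)
        for _ in range(50):
            rec = stitch_augment(labeled_pool, rng, max_chars=10 ** 6)
            assert len(rec.label) == len(rec.text)
            assert rec.label == rederive_label(rec.text)

    def test_truncation_cuts_text_and_label_identically(self, pool):
        rng = np.random.default_rng(8)
        for _ in range(20):
            full = stitch_augment(pool, np.random.default_rng(42), max_chars=10 ** 6)
            cut = stitch_augment(pool, np.random.default_rng(42), max_chars=200)
            assert cut.text == full.text[:200]
            if full.label is not None:
                assert cut.label == full.label[:200]

    def test_unlabeled_only_pool_gives_unlabeled_stitch(self, pool):
        icd = [r for r in pool if r.label is None]
        rec = stitch_augment(icd, np.random.default_rng(7))
        assert rec.label is None

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            stitch_augment([], np.random.default_rng(0))


class TestInjectTypos:
    def test_rate_zero_identity(self, record):
        assert inject_typos(record, 0.0, np.random.default_rng(0)) == record

    def test_label_never_changes(self, record):
        out = inject_typos(record, 0.05, np.random.default_rng(1))
        assert out.label == record.label

    def test_replacements_preserve_class(self, record):
        rng = np.random.default_rng(2)
        out = inject_typos(record, 0.2, rng)
        changed = 0
        for a, b in zip(record.text, out.text):
            if a != b:
                changed += 1
                assert TABLE.replacement_group(a) == TABLE.replacement_group(b)
        assert changed > 0

    def test_spaces_untouched(self, record):
        out = inject_typos(record, 1.0, np.random.default_rng(3))
        for a, b in zip(record.text, out.text):
            if a == " ":
                assert b == " "
            else:
                assert b != a  # rate 1: every poolable character replaced

    def test_empirical_rate(self, record):
        rng = np.random.default_rng(4)
        changed = total = 0
        for _ in range(30):
            out = inject_typos(record, 0.001, rng)
            changed += sum(a != b for a, b in zip(record.text, out.text))
            total += len(record.text)
        # non-space characters are ~90% of the text, so the realized
        # all-character rate sits slightly below the nominal 0.1%
        assert 0.0006 < changed / total < 0.0012

    def test_bad_rate_rejected(self, record):
        with pytest.raises(ValueError):
            inject_typos(record, 1.5, np.random.default_rng(0))


class TestSplitCorpus:
    def test_95_5_split(self):
        records = generate_corpus(1000, 0, GeneratorParams(seed=9))
        train, val = split_corpus(records, 0.95, seed=0)
        assert (len(train), len(val)) == (950, 50)

    def test_exact_partition(self):
        records = generate_corpus(101, 0, GeneratorParams(seed=10))
        train, val = split_corpus(records, 0.8, seed=1)
        assert len(train) + len(val) == 101
        key = lambda r: r.text
        assert sorted(train + val, key=key) == sorted(records, key=key)

    def test_deterministic(self):
        records = generate_corpus(50, 0, GeneratorParams(seed=11))
        assert split_corpus(records, 0.5, seed=2) == split_corpus(records, 0.5, seed=2)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_corpus([generate_diagnosis(GeneratorParams(seed=0))], 0.5, 0)

    def test_bad_fraction_rejected(self):
        records = generate_corpus(10, 0, GeneratorParams(seed=12))
        with pytest.raises(ValueError):
            split_corpus(records, 1.0, 0)
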