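"""Vocabulary loading, token normalization, and tumor-relevance matching."""
import random

import pytest

from carcwoe.dataset import Finding
from carcwoe.vocab import (
    TumorRelevanceRule,
    VocabularyError,
    is_human_relevant,
    load_vocabulary,
    normalize_token,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestLoadVocabulary:
    def test_packaged_lookup(self, kb):
        assert kb.vocab.organ("li").name == "liver"
        assert kb.vocab.organ("UGT").code == "UGT"
        assert kb.vocab.morphology("bpha").behavior == "benign"
        assert kb.vocab.morphology("ac").behavior == "malignant"

    def test_empty_morphology_file_gives_empty_lookup(self, tmp_path):
        organs = _write(tmp_path, "o.csv", "code,name,system\nli,liver,hepatobiliary\n")
        morphs = _write(tmp_path, "m.csv", "code,name,behavior\n")
        vocab = load_vocabulary(organs, morphs)
        assert vocab.morphologies == {}
        assert vocab.has_organ("li")

    def test_duplicate_code_names_the_offender(self, tmp_path):
        organs = _write(
            tmp_path, "o.csv", "code,name,system\nli,liver,x\nli,liver again,x\n"
        )
        morphs = _write(tmp_path, "m.csv", "code,name,behavior\n")
        with pytest.raises(VocabularyError, match="'li'"):
            load_vocabulary(organs, morphs)

    def test_missing_header_is_hard_error(self, tmp_path):
        organs = _write(tmp_path, "o.csv", "code,label\nli,liver\n")
        morphs = _write(tmp_path, "m.csv", "code,name,behavior\n")
        with pytest.raises(VocabularyError, match="name"):
            load_vocabulary(organs, morphs)

    def test_invalid_behavior_rejected(self, tmp_path):
        organs = _write(tmp_path, "o.csv", "code,name,system\n")
        morphs = _write(tmp_path, "m.csv", "code,name,behavior\nad,adenoma,benignish\n")
        with pytest.raises(VocabularyError, match="behavior"):
            load_vocabulary(organs, morphs)


class TestNormalization:
    @pytest.mark.parametrize(
        "raw,expected",
        [("LI", "li"), ("  thyr ", "thyr"), ("scc", "SCC"), ("Ugt", "UGT"),
         ("soft  t", "soft t")],
    )
    def test_case_and_whitespace(self, raw, expected):
        assert normalize_token(raw) == expected


class TestHumanRelevance:
    @pytest.mark.parametrize(
        "organ,morph,expected",
        [
            ("adr", "bpha", False),   # pheochromocytoma of the adrenal medulla
            ("mam", "fad", False),    # mammary fibroadenoma
            ("kid", "ac", True),      # kidney carcinoma matches no rule
            ("li", "ac", True),       # hepatocellular carcinoma (non-fibrate)
            ("skin", "sar", True),
            ("tes", "ad", False),     # Leydig cell adenoma
        ],
    )
    def test_published_examples(self, kb, organ, morph, expected):
        finding = Finding(organ, morph)
        assert is_human_relevant(finding, kb.relevance_rules) is expected

    def test_specificity_beats_file_order(self):
        # exact pair wins over organ wildcard wins over morphology wildcard,
        # regardless of list order
        rules = [
            TumorRelevanceRule("*", "ad", human_relevant=False),
            TumorRelevanceRule("kid", "*", human_relevant=False),
            TumorRelevanceRule("kid", "ad", human_relevant=True),
        ]
        for perm in range(6):
            shuffled = rules[:]
            random.Random(perm).shuffle(shuffled)
            assert is_human_relevant(Finding("kid", "ad"), shuffled) is True
            assert is_human_relevant(Finding("kid", "ca"), shuffled) is False
            assert is_human_relevant(Finding("li", "ad"), shuffled) is False

    def test_total_and_deterministic_over_fixture(self, fixture_ds, kb):
        # every tumor type occurring in the reference dataset gets a stable
        # boolean answer
        seen = {f for rec in fixture_ds for f in rec.tumor_findings}
        assert seen
        for finding in seen:
            first = is_human_relevant(finding, kb.relevance_rules, kb.vocab)
            assert first in (True, False)
            assert is_human_relevant(finding, kb.relevance_rules, kb.vocab) is first

    def test_fully_wildcarded_rule_rejected(self):
        with pytest.raises(VocabularyError):
            TumorRelevanceRule("*", "*", human_relevant=False)


def test_every_fixture_token_resolves(fixture_ds, kb):
    """Full-coverage check over all 289 rows: each organ/morphology token in
    any finding list resolves to exactly one vocabulary entry."""
    assert len(fixture_ds) == 289
    for rec in fixture_ds:
        for f in (
            rec.weight_findings
            + rec.hypertrophy_findings
            + rec.hyperplasia_findings
            + rec.tumor_findings
        ):
            assert kb.vocab.has_organ(f.organ), f.organ
            if f.morphology is not None:
                assert kb.vocab.has_morphology(f.morphology), f.morphology
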