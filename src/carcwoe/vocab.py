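"""Controlled vocabularies and knowledge bases.

The whole pipeline speaks a compact abbreviation grammar: every
histopathological observation is an ``(organ, morphology)`` token pair such
as ``li ad`` (liver adenoma) or a bare organ token for non-neoplastic
findings.  This module owns the code tables that give those tokens meaning —
organ codes, morphology codes with their benign/malignant behavior, the
human-relevance rules for rat tumor types, the pharmacological
class-decision table, and the per-compound final-category overrides.

All knowledge bases are plain UTF-8 CSV files so that a toxicologist can
review and extend them without touching code; the packaged defaults live in
``carcwoe/data`` and are loaded with :func:`load_default_vocabulary` and
friends.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CATEGORIES",
    "PHARM_CATEGORIES",
    "HISTO_CATEGORIES",
    "WILDCARD",
    "OrganCode",
    "MorphologyCode",
    "TumorRelevanceRule",
    "ClassDecision",
    "OverrideRule",
    "Vocabulary",
    "VocabularyError",
    "UnknownTokenError",
    "normalize_token",
    "load_vocabulary",
    "load_relevance_rules",
    "load_class_decisions",
    "load_overrides",
    "load_default_vocabulary",
    "load_default_relevance_rules",
    "load_default_class_decisions",
    "load_default_overrides",
    "is_human_relevant",
]

#: Histopathological / final categories (screen outcome x bioassay outcome).
HISTO_CATEGORIES = ("TP", "FP", "TN", "FN")
#: Pharmacological categories; NT = no mammalian target, NC = non-categorizable.
PHARM_CATEGORIES = ("TP", "TN", "NT", "NC")
#: Every category value that may appear anywhere in a dataset.
CATEGORIES = ("TP", "FP", "TN", "FN", "NT", "NC")

WILDCARD = "*"

# Tokens stored canonically in upper case; everything else is lower-cased.
_CANONICAL_UPPER = {"SCC", "SCP", "UGT"}


class VocabularyError(ValueError):
    """Malformed or inconsistent vocabulary/knowledge-base input."""


class UnknownTokenError(KeyError):
    """A finding token does not resolve against the vocabulary."""

    def __init__(self, token: str, context: str = ""):
        self.token = token
        self.context = context
        msg = f"unknown token {token!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return self.args[0]


def normalize_token(token: str) -> str:
    """Normalize a vocabulary token.

    Comparison is case-insensitive except for the all-caps codes
    (``SCC``, ``SCP``, ``UGT``) which are stored canonically; surrounding
    whitespace is stripped and internal runs collapsed.
    """
    tok = " ".join(token.split())
    if tok.upper() in _CANONICAL_UPPER:
        return tok.upper()
    return tok.lower()


@dataclass(frozen=True)
class OrganCode:
    code: str
    name: str
    system: str = ""


@dataclass(frozen=True)
class MorphologyCode:
    code: str
    name: str
    behavior: str = "unspecified"

    def __post_init__(self) -> None:
        if self.behavior not in ("benign", "malignant", "unspecified"):
            raise VocabularyError(
                f"morphology {self.code!r}: behavior {self.behavior!r} not in "
                "{'benign', 'malignant', 'unspecified'}"
            )


@dataclass(frozen=True)
class TumorRelevanceRule:
    """Match a tumor type and declare whether it is predictive for humans.

    ``organ`` and ``morphology`` may be the wildcard ``"*"`` (not both);
    matching specificity is organ+morphology > organ-only > morphology-only.
    """

    organ: str
    morphology: str
    human_relevant: bool
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.organ == WILDCARD and self.morphology == WILDCARD:
            raise VocabularyError("relevance rule may not be fully wildcarded")

    @property
    def specificity(self) -> int:
        """2 = exact pair, 1 = organ wildcardless, 0 = morphology-only."""
        if self.organ != WILDCARD and self.morphology != WILDCARD:
            return 2
        return 1 if self.organ != WILDCARD else 0

    def matches(self, organ: str, morphology: str | None) -> bool:
        if self.organ != WILDCARD and self.organ != organ:
            return False
        if self.morphology != WILDCARD and self.morphology != morphology:
            return False
        return True


@dataclass(frozen=True)
class ClassDecision:
    """Expert category for one pharmacological class.

    ``table_of_origin`` records the printed placement of the class among the
    positive / negative / mixed class tables (or ``none`` for classes outside
    them); it is transcribed, never recomputed, because the published
    placement reflects literature judgment beyond the tumor fraction.
    """

    class_id: str
    table_of_origin: str
    decision: str
    n_compounds: int
    n_with_tumors: int

    def __post_init__(self) -> None:
        if self.decision not in PHARM_CATEGORIES:
            raise VocabularyError(
                f"class {self.class_id!r}: decision {self.decision!r} not in "
                f"{PHARM_CATEGORIES}"
            )
        if self.table_of_origin not in ("positive", "negative", "mixed", "none"):
            raise VocabularyError(
                f"class {self.class_id!r}: table_of_origin "
                f"{self.table_of_origin!r} invalid"
            )
        if not 0 <= self.n_with_tumors <= self.n_compounds:
            raise VocabularyError(
                f"class {self.class_id!r}: n_with_tumors out of range"
            )


@dataclass(frozen=True)
class OverrideRule:
    """Force a compound's final category, citing the supporting narrative."""

    compound_id: int
    forced_final: str
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.forced_final not in HISTO_CATEGORIES:
            raise VocabularyError(
                f"override for {self.compound_id}: {self.forced_final!r} "
                f"not in {HISTO_CATEGORIES}"
            )


@dataclass
class Vocabulary:
    """Organ and morphology lookup bundle."""

    organs: dict[str, OrganCode] = field(default_factory=dict)
    morphologies: dict[str, MorphologyCode] = field(default_factory=dict)

    def organ(self, token: str) -> OrganCode:
        code = normalize_token(token)
        try:
            return self.organs[code]
        except KeyError:
            raise UnknownTokenError(token, "organ") from None

    def morphology(self, token: str) -> MorphologyCode:
        code = normalize_token(token)
        try:
            return self.morphologies[code]
        except KeyError:
            raise UnknownTokenError(token, "morphology") from None

    def has_organ(self, token: str) -> bool:
        return normalize_token(token) in self.organs

    def has_morphology(self, token: str) -> bool:
        return normalize_token(token) in self.morphologies


# --------------------------------------------------------------------------
# loaders


def _read_csv(path: Path | str, required: Sequence[str]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise VocabularyError(f"{path}: missing header column(s) {missing}")
        return [dict(row) for row in reader]


def load_vocabulary(organ_path: Path | str, morphology_path: Path | str) -> Vocabulary:
    """Load organ and morphology code tables from CSV.

    Duplicate codes are a hard error naming the offending code; an empty file
    (header only) yields an empty lookup.
    """
    vocab = Vocabulary()
    for row in _read_csv(organ_path, ("code", "name", "system")):
        code = normalize_token(row["code"])
        if not code:
            raise VocabularyError(f"{organ_path}: empty organ code")
        if code in vocab.organs:
            raise VocabularyError(f"{organ_path}: duplicate organ code {code!r}")
        vocab.organs[code] = OrganCode(code, row["name"], row.get("system", ""))
    for row in _read_csv(morphology_path, ("code", "name", "behavior")):
        code = normalize_token(row["code"])
        if not code:
            raise VocabularyError(f"{morphology_path}: empty morphology code")
        if code in vocab.morphologies:
            raise VocabularyError(
                f"{morphology_path}: duplicate morphology code {code!r}"
            )
        vocab.morphologies[code] = MorphologyCode(code, row["name"], row["behavior"])
    return vocab


def load_relevance_rules(path: Path | str) -> list[TumorRelevanceRule]:
    rules = []
    for row in _read_csv(path, ("organ", "morphology", "human_relevant")):
        rules.append(
            TumorRelevanceRule(
                organ=normalize_token(row["organ"]) if row["organ"] != WILDCARD else WILDCARD,
                morphology=(
                    normalize_token(row["morphology"])
                    if row["morphology"] != WILDCARD
                    else WILDCARD
                ),
                human_relevant=row["human_relevant"].strip().lower()
                in ("true", "1", "yes"),
                rationale=row.get("rationale", ""),
            )
        )
    return rules


def load_class_decisions(path: Path | str) -> dict[str, ClassDecision]:
    table: dict[str, ClassDecision] = {}
    for row in _read_csv(
        path, ("class_id", "table_of_origin", "decision", "n_compounds", "n_with_tumors")
    ):
        cid = row["class_id"].strip()
        if cid in table:
            raise VocabularyError(f"{path}: duplicate class id {cid!r}")
        table[cid] = ClassDecision(
            class_id=cid,
            table_of_origin=row["table_of_origin"].strip(),
            decision=row["decision"].strip(),
            n_compounds=int(row["n_compounds"]),
            n_with_tumors=int(row["n_with_tumors"]),
        )
    return table


def load_overrides(path: Path | str) -> dict[int, OverrideRule]:
    table: dict[int, OverrideRule] = {}
    for row in _read_csv(path, ("compound_id", "forced_final")):
        cid = int(row["compound_id"])
        if cid in table:
            raise VocabularyError(f"{path}: duplicate override for compound {cid}")
        table[cid] = OverrideRule(cid, row["forced_final"].strip(), row.get("rationale", ""))
    return table


def _data_path(name: str) -> Path:
    return Path(str(resources.files("carcwoe").joinpath("data", name)))


def load_default_vocabulary() -> Vocabulary:
    return load_vocabulary(_data_path("organs.csv"), _data_path("morphologies.csv"))


def load_default_relevance_rules() -> list[TumorRelevanceRule]:
    return load_relevance_rules(_data_path("relevance.csv"))


def load_default_class_decisions() -> dict[str, ClassDecision]:
    return load_class_decisions(_data_path("class_decisions.csv"))


def load_default_overrides() -> dict[int, OverrideRule]:
    return load_overrides(_data_path("overrides.csv"))


# --------------------------------------------------------------------------
# relevance matching


def is_human_relevant(
    finding,
    rules: Iterable[TumorRelevanceRule],
    vocab: Vocabulary | None = None,
) -> bool:
    """Decide whether a tumor finding is considered predictive for humans.

    The most specific matching rule wins (organ+morphology before organ-only
    before morphology-only); rule file order is irrelevant.  A tumor type
    matched by no rule defaults to human-relevant — the conservative choice
    for a screening procedure.  If ``vocab`` is given, unresolvable codes
    raise :class:`UnknownTokenError` identifying the token.
    """
    organ = normalize_token(finding.organ)
    morph = normalize_token(finding.morphology) if finding.morphology else None
    if vocab is not None:
        if not vocab.has_organ(organ):
            raise UnknownTokenError(finding.organ, "organ")
        if morph is not None and not vocab.has_morphology(morph):
            raise UnknownTokenError(finding.morphology, "morphology")
    best: TumorRelevanceRule | None = None
    for rule in rules:
        if rule.matches(organ, morph) and (
            best is None or rule.specificity > best.specificity
        ):
            best = rule
    return True if best is None else best.human_relevant


def matching_relevance_rule(
    finding, rules: Iterable[TumorRelevanceRule]
) -> TumorRelevanceRule | None:
    """Return the winning rule for a finding, or None if unmatched."""
    organ = normalize_token(finding.organ)
    morph = normalize_token(finding.morphology) if finding.morphology else None
    best: TumorRelevanceRule | None = None
    for rule in rules:
        if rule.matches(organ, morph) and (
            best is None or rule.specificity > best.specificity
        ):
            best = rule
    return best
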