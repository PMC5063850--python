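"""Compound data model, findings grammar, and dataset I/O.

A compound record holds four finding lists from the subchronic study
(organ-weight changes, hypertrophy, hyperplasia) and the 2-year bioassay
(tumors), all expressed in the abbreviation grammar: findings are separated
by ``;``, a tumor token splits into organ and morphology on its *last*
space (organ codes may contain an internal space, e.g. ``soft t sar``), and
``–``/``-``/empty cells mean "no findings".

The packaged fixture (``carcwoe/data/compounds.csv``) is the hand-checked
289-compound reference dataset; its three published category columns are
ground truth for regression tests and are never read by the pipeline stages
themselves.
"""
from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

from .vocab import (
    CATEGORIES,
    UnknownTokenError,
    Vocabulary,
    load_default_vocabulary,
    normalize_token,
)

__all__ = [
    "Finding",
    "CompoundRecord",
    "Dataset",
    "DatasetError",
    "SchemaError",
    "DuplicateIdError",
    "parse_finding_list",
    "format_finding_list",
    "read_dataset",
    "write_dataset",
    "load_fixture",
]

_EMPTY_MARKERS = {"", "-", "–", "—"}

_COLUMNS = [
    "compound_id",
    "mode_of_action",
    "therapeutic_area",
    "pharm_class_id",
    "single_in_class",
    "peroxisome_proliferator",
    "weight_findings",
    "hypertrophy_findings",
    "hyperplasia_findings",
    "tumor_findings",
    "cat_his_published",
    "cat_ph_published",
    "cat_final_published",
]


class DatasetError(ValueError):
    """Malformed dataset input."""


class SchemaError(DatasetError):
    """Input file does not match the declared column schema."""


class DuplicateIdError(DatasetError):
    """Two rows share a compound id."""


@dataclass(frozen=True)
class Finding:
    """One ``(organ, morphology)`` token; morphology is None for
    weight/hypertrophy/hyperplasia findings."""

    organ: str
    morphology: str | None = None

    def __str__(self) -> str:
        return self.organ if self.morphology is None else f"{self.organ} {self.morphology}"


@dataclass
class CompoundRecord:
    compound_id: int
    mode_of_action: str
    therapeutic_area: str
    pharm_class_id: str
    single_in_class: bool = False
    peroxisome_proliferator: bool = False
    weight_findings: tuple[Finding, ...] = ()
    hypertrophy_findings: tuple[Finding, ...] = ()
    hyperplasia_findings: tuple[Finding, ...] = ()
    tumor_findings: tuple[Finding, ...] = ()
    cat_his_published: str | None = None
    cat_ph_published: str | None = None
    cat_final_published: str | None = None

    def __post_init__(self) -> None:
        for attr in ("cat_his_published", "cat_ph_published", "cat_final_published"):
            val = getattr(self, attr)
            if val is not None and val not in CATEGORIES:
                raise DatasetError(
                    f"compound {self.compound_id}: {attr}={val!r} not in {CATEGORIES}"
                )

    @property
    def subchronic_positive(self) -> bool:
        """Putative preneoplastic lesions present (hyperplasia column only;
        hypertrophy and organ-weight changes are adaptive and do not count)."""
        return bool(self.hyperplasia_findings)

    @property
    def carcinogenicity_positive(self) -> bool:
        return bool(self.tumor_findings)


@dataclass
class Dataset:
    records: list[CompoundRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def by_id(self, compound_id: int) -> CompoundRecord:
        for rec in self.records:
            if rec.compound_id == compound_id:
                return rec
        raise KeyError(compound_id)

    def class_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.pharm_class_id)
        return list(seen)


# --------------------------------------------------------------------------
# findings grammar


def parse_finding_list(
    cell: str,
    with_morphology: bool,
    vocab: Vocabulary | None = None,
    row_id: int | None = None,
) -> tuple[Finding, ...]:
    """Parse one finding-list cell.

    ``"tes tu; li ad"`` -> ``(Finding("tes","tu"), Finding("li","ad"))``;
    dash markers and empty cells parse to the empty tuple.  Token order and
    duplicates are preserved (the transcription is lossless; consumers
    deduplicate by organ where their operation calls for it).
    """
    cell = cell.strip()
    if cell in _EMPTY_MARKERS:
        return ()
    findings: list[Finding] = []
    for token in cell.split(";"):
        token = " ".join(token.split())
        if not token:
            continue  # tolerate trailing separators ("tes ad;")
        if with_morphology:
            organ, sep, morph = token.rpartition(" ")
            if not sep:
                raise DatasetError(
                    f"row {row_id}: tumor token {token!r} has no morphology"
                )
            finding = Finding(normalize_token(organ), normalize_token(morph))
        else:
            finding = Finding(normalize_token(token))
        if vocab is not None:
            if not vocab.has_organ(finding.organ):
                raise UnknownTokenError(finding.organ, f"row {row_id}")
            if finding.morphology is not None and not vocab.has_morphology(
                finding.morphology
            ):
                raise UnknownTokenError(finding.morphology, f"row {row_id}")
        findings.append(finding)
    return tuple(findings)


def format_finding_list(findings: Sequence[Finding]) -> str:
    """Inverse of :func:`parse_finding_list` (empty list -> empty cell)."""
    return "; ".join(str(f) for f in findings)


# --------------------------------------------------------------------------
# readers / writers


def _parse_bool(text: str) -> bool:
    return text.strip().lower() in ("true", "1", "yes")


def read_dataset(path: Path | str, vocab: Vocabulary | None = None) -> Dataset:
    """Read a compounds CSV, validating every finding against ``vocab``.

    Raises :class:`SchemaError` on a column mismatch,
    :class:`~carcwoe.vocab.UnknownTokenError` on an unresolvable finding
    token, and :class:`DuplicateIdError` on a repeated compound id.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in _COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        rows = list(reader)
    records: list[CompoundRecord] = []
    seen: set[int] = set()
    for row in rows:
        cid = int(row["compound_id"])
        if cid in seen:
            raise DuplicateIdError(f"{path}: duplicate compound id {cid}")
        seen.add(cid)
        records.append(
            CompoundRecord(
                compound_id=cid,
                mode_of_action=row["mode_of_action"],
                therapeutic_area=row["therapeutic_area"],
                pharm_class_id=row["pharm_class_id"],
                single_in_class=_parse_bool(row["single_in_class"]),
                peroxisome_proliferator=_parse_bool(row["peroxisome_proliferator"]),
                weight_findings=parse_finding_list(
                    row["weight_findings"], False, vocab, cid
                ),
                hypertrophy_findings=parse_finding_list(
                    row["hypertrophy_findings"], False, vocab, cid
                ),
                hyperplasia_findings=parse_finding_list(
                    row["hyperplasia_findings"], False, vocab, cid
                ),
                tumor_findings=parse_finding_list(
                    row["tumor_findings"], True, vocab, cid
                ),
                cat_his_published=row["cat_his_published"] or None,
                cat_ph_published=row["cat_ph_published"] or None,
                cat_final_published=row["cat_final_published"] or None,
            )
        )
    if not records:
        warnings.warn(f"{path}: dataset is empty", stacklevel=2)
    return Dataset(records=records, provenance=str(path))


def write_dataset(ds: Dataset, path: Path | str) -> None:
    """Write a dataset; ``read_dataset`` on the result round-trips exactly."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for rec in ds.records:
            writer.writerow(
                [
                    rec.compound_id,
                    rec.mode_of_action,
                    rec.therapeutic_area,
                    rec.pharm_class_id,
                    str(rec.single_in_class).lower(),
                    str(rec.peroxisome_proliferator).lower(),
                    format_finding_list(rec.weight_findings),
                    format_finding_list(rec.hypertrophy_findings),
                    format_finding_list(rec.hyperplasia_findings),
                    format_finding_list(rec.tumor_findings),
                    rec.cat_his_published or "",
                    rec.cat_ph_published or "",
                    rec.cat_final_published or "",
                ]
            )


def load_fixture(vocab: Vocabulary | None = None) -> Dataset:
    """Load the packaged 289-compound reference dataset."""
    if vocab is None:
        vocab = load_default_vocabulary()
    path = Path(str(resources.files("carcwoe").joinpath("data", "compounds.csv")))
    ds = read_dataset(path, vocab)
    ds.provenance = "packaged 289-compound reference dataset"
    return ds
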