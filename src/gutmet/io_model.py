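"""Domain records and tab-separated readers/writers for interaction datasets.

The pipeline operates on four tables: curated bacterium-metabolite interactions,
per-metabolite chemistry (SMILES, category, optional precomputed properties),
per-taxon enzyme annotations (EC numbers with a prediction confidence), and
metabolite-protein association scores on the STITCH-style 0-1000 integer scale.
All files are UTF-8, tab-separated, header required; lines starting with ``#``
are ignored.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

from . import chem

logger = logging.getLogger(__name__)

# Two-value label vocabulary after normalization.
CONSUMPTION = "consumption"
PRODUCTION = "production"
LABELS = (CONSUMPTION, PRODUCTION)

# Four-value raw vocabulary as curated from literature sources.
MOLECULAR_DEGRADATION = "molecular_degradation"
CONSUMPTION_AND_PRODUCTION = "consumption_and_production"
RAW_LABELS = (CONSUMPTION, PRODUCTION, MOLECULAR_DEGRADATION, CONSUMPTION_AND_PRODUCTION)

# Synonyms seen in curated sources: consumption is import, production is export,
# and degradation phrasings fold into the molecular-degradation raw label.
LABEL_SYNONYMS = {
    "import": CONSUMPTION,
    "export": PRODUCTION,
    "degradation": MOLECULAR_DEGRADATION,
    "molecular degradation": MOLECULAR_DEGRADATION,
    "consumption and production": CONSUMPTION_AND_PRODUCTION,
    "consumption & production": CONSUMPTION_AND_PRODUCTION,
}

PROVENANCES = ("experimental", "negative", "background", "unseen")


class SchemaError(ValueError):
    """A table is missing a required column."""


class ParseError(ValueError):
    """A data row could not be interpreted; the message names the line."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant."""


@dataclass(frozen=True)
class RawInteractionRecord:
    bacterium: str
    metabolite: str
    raw_label: str

    def __post_init__(self) -> None:
        if self.raw_label not in RAW_LABELS:
            raise ValidationError(f"unknown raw label {self.raw_label!r}")


@dataclass(frozen=True)
class InteractionRecord:
    bacterium: str
    metabolite: str
    label: str
    provenance: str = "experimental"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.bacterium, self.metabolite)


@dataclass(frozen=True)
class MetaboliteRecord:
    metabolite: str
    smiles: str
    category: str
    mw: float | None = None
    logp: float | None = None
    hbd: int | None = None
    hba: int | None = None

    def __post_init__(self) -> None:
        if not self.category:
            raise ValidationError(f"metabolite {self.metabolite}: empty category")
        if self.mw is not None and self.mw <= 0:
            raise ValidationError(f"metabolite {self.metabolite}: mw must be > 0")
        for name in ("hbd", "hba"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"metabolite {self.metabolite}: {name} must be >= 0")


@dataclass(frozen=True)
class EnzymeAnnotation:
    taxon: str
    protein: str
    ec: "ECNumber"  # forward ref; encoders.ECNumber
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(
                f"protein {self.protein}: confidence {self.confidence} outside [0, 1]"
            )


@dataclass(frozen=True)
class AssociationScore:
    metabolite: str
    taxon: str
    protein: str
    score: int

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 1000:
            raise ValidationError(
                f"score {self.score} for ({self.metabolite}, {self.taxon}, "
                f"{self.protein}) outside [0, 1000]"
            )


# ---------------------------------------------------------------------------
# TSV plumbing


def _read_rows(path: str | Path, required: Sequence[str]) -> Iterable[tuple[int, dict]]:
    """Yield (line_number, row_dict) from a commented TSV with a header."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        header: list[str] | None = None
        for lineno, raw in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not raw or (raw[0].startswith("#")):
                continue
            if header is None:
                header = [col.strip() for col in raw]
                missing = [col for col in required if col not in header]
                if missing:
                    raise SchemaError(f"{path}: missing column(s) {missing}")
                continue
            yield lineno, dict(zip(header, (cell.strip() for cell in raw)))
    if header is None:
        raise SchemaError(f"{path}: empty file, header required")


def parse_interaction_table(path: str | Path) -> list[RawInteractionRecord]:
    """Read (bacterium, metabolite, label) rows into raw interaction records.

    Labels are mapped through the synonym table onto the four-value raw
    vocabulary; an unknown token raises :class:`ParseError` naming the line.
    """
    records = []
    for lineno, row in _read_rows(path, ("bacterium", "metabolite", "label")):
        token = row["label"].lower().replace("-", " ").strip()
        label = LABEL_SYNONYMS.get(token, token.replace(" ", "_"))
        if label not in RAW_LABELS:
            raise ParseError(f"{path}, line {lineno}: unknown label {row['label']!r}")
        records.append(RawInteractionRecord(row["bacterium"], row["metabolite"], label))
    return records


def parse_normalized_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read a normalized interaction table (optionally with a provenance column)."""
    records = []
    for lineno, row in _read_rows(path, ("bacterium", "metabolite", "label")):
        if row["label"] not in LABELS:
            raise ParseError(f"{path}, line {lineno}: unknown label {row['label']!r}")
        records.append(
            InteractionRecord(
                row["bacterium"],
                row["metabolite"],
                row["label"],
                row.get("provenance") or "experimental",
            )
        )
    return records


def parse_metabolite_table(path: str | Path) -> list[MetaboliteRecord]:
    records = []
    for lineno, row in _read_rows(path, ("metabolite", "smiles", "category")):
        def _opt(key: str, cast):
            value = row.get(key)
            if value in (None, ""):
                return None
            try:
                return cast(value)
            except ValueError as exc:
                raise ParseError(f"{path}, line {lineno}: bad {key} {value!r}") from exc

        records.append(
            MetaboliteRecord(
                row["metabolite"],
                row["smiles"],
                row["category"],
                mw=_opt("mw", float),
                logp=_opt("logp", float),
                hbd=_opt("hbd", int),
                hba=_opt("hba", int),
            )
        )
    return records


def parse_enzyme_annotations(path: str | Path) -> dict[str, list[EnzymeAnnotation]]:
    """Group enzyme annotations by taxon, preserving input order."""
    from .encoders import parse_ec

    grouped: dict[str, list[EnzymeAnnotation]] = {}
    for lineno, row in _read_rows(path, ("taxon", "protein", "ec", "confidence")):
        try:
            annotation = EnzymeAnnotation(
                row["taxon"], row["protein"], parse_ec(row["ec"]), float(row["confidence"])
            )
        except ValueError as exc:
            raise ParseError(f"{path}, line {lineno}: {exc}") from exc
        grouped.setdefault(row["taxon"], []).append(annotation)
    return grouped


def parse_association_scores(
    path: str | Path,
    annotations: dict[str, list[EnzymeAnnotation]] | None = None,
) -> dict[tuple[str, str], list[tuple[str, int]]]:
    """Group (protein, score) lists by (metabolite, taxon), preserving input order.

    Scores are validated to the 0-1000 integer scale. If ``annotations`` are
    supplied, score rows whose protein has no annotation are kept but flagged
    with a warning (they still count as metabolite-binding proteins).
    """
    known: set[tuple[str, str]] = set()
    if annotations is not None:
        known = {(t, a.protein) for t, anns in annotations.items() for a in anns}
    grouped: dict[tuple[str, str], list[tuple[str, int]]] = {}
    n_dangling = 0
    for lineno, row in _read_rows(path, ("metabolite", "taxon", "protein", "score")):
        try:
            record = AssociationScore(
                row["metabolite"], row["taxon"], row["protein"], int(row["score"])
            )
        except ValueError as exc:
            raise ValidationError(f"{path}, line {lineno}: {exc}") from exc
        if annotations is not None and (record.taxon, record.protein) not in known:
            n_dangling += 1
        grouped.setdefault((record.metabolite, record.taxon), []).append(
            (record.protein, record.score)
        )
    if n_dangling:
        logger.warning("%s: %d score rows reference unannotated proteins", path, n_dangling)
    return grouped


def write_interactions(path: str | Path, records: Iterable[InteractionRecord]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["bacterium", "metabolite", "label", "provenance"])
        for r in records:
            writer.writerow([r.bacterium, r.metabolite, r.label, r.provenance])


def write_raw_interactions(path: str | Path, records: Iterable[RawInteractionRecord]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["bacterium", "metabolite", "label"])
        for r in records:
            writer.writerow([r.bacterium, r.metabolite, r.raw_label])


def write_metabolites(path: str | Path, records: Iterable[MetaboliteRecord]) -> None:
    def _fmt(value):
        return "" if value is None else value

    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["metabolite", "smiles", "category", "mw", "logp", "hbd", "hba"])
        for r in records:
            writer.writerow(
                [r.metabolite, r.smiles, r.category, _fmt(r.mw), _fmt(r.logp), _fmt(r.hbd), _fmt(r.hba)]
            )


def write_enzyme_annotations(path: str | Path, grouped: dict[str, list[EnzymeAnnotation]]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["taxon", "protein", "ec", "confidence"])
        for taxon in grouped:
            for a in grouped[taxon]:
                writer.writerow([taxon, a.protein, str(a.ec), f"{a.confidence:.3f}"])


def write_association_scores(
    path: str | Path, grouped: dict[tuple[str, str], list[tuple[str, int]]]
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["metabolite", "taxon", "protein", "score"])
        for (metabolite, taxon), pairs in grouped.items():
            for protein, score in pairs:
                writer.writerow([metabolite, taxon, protein, score])


# ---------------------------------------------------------------------------
# Record-level preprocessing


def normalize_labels(records: Sequence[RawInteractionRecord]) -> list[InteractionRecord]:
    """Map the four-value raw vocabulary onto consumption/production.

    Molecular degradation is treated as consumption (the metabolite is taken up
    and broken down); a combined consumption-and-production entry is split into
    one record per process. Duplicate (bacterium, metabolite, label) triples
    are collapsed, keeping first occurrence order.
    """
    out: list[InteractionRecord] = []
    seen: set[tuple[str, str, str]] = set()

    def _emit(bacterium: str, metabolite: str, label: str) -> None:
        key = (bacterium, metabolite, label)
        if key not in seen:
            seen.add(key)
            out.append(InteractionRecord(bacterium, metabolite, label))

    for r in records:
        if r.raw_label == CONSUMPTION_AND_PRODUCTION:
            _emit(r.bacterium, r.metabolite, CONSUMPTION)
            _emit(r.bacterium, r.metabolite, PRODUCTION)
        elif r.raw_label == MOLECULAR_DEGRADATION:
            _emit(r.bacterium, r.metabolite, CONSUMPTION)
        else:
            _emit(r.bacterium, r.metabolite, r.raw_label)
    return out


def filter_metabolites(
    metabolites: Sequence[MetaboliteRecord],
    min_mw: float = 50.0,
    max_mw: float = 500.0,
    engine: "chem.ChemistryEngine | None" = None,
    stats: dict | None = None,
) -> list[MetaboliteRecord]:
    """Keep metabolites with min_mw <= MW <= max_mw (inclusive) and >= 1 carbon.

    The weight window targets compounds small enough to diffuse across
    membranes yet large enough to be metabolically meaningful. Molecular
    weights missing from the table are computed with the chemistry engine
    (RDKit by default). Records whose SMILES cannot be interpreted are dropped
    with a warning and counted in ``stats``.
    """
    kept: list[MetaboliteRecord] = []
    counters = {"unparsable": 0, "out_of_range": 0, "no_carbon": 0}
    for record in metabolites:
        try:
            if not chem.smiles_has_carbon(record.smiles):
                counters["no_carbon"] += 1
                continue
            mw = record.mw
            if mw is None:
                active = engine if engine is not None else chem.default_engine()
                mw = active.compute_properties(record.smiles).mw
                record = replace(record, mw=mw)
        except chem.SmilesError:
            counters["unparsable"] += 1
            logger.warning("metabolite %s: unparsable SMILES %r", record.metabolite, record.smiles)
            continue
        if min_mw <= mw <= max_mw:
            kept.append(record)
        else:
            counters["out_of_range"] += 1
    if stats is not None:
        stats.update(counters)
    return kept
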