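"""Alias corpus: ingestion, validation, activation, and indexed lookup.

One :class:`ChemicalRecord` holds everything known about one indexed
chemical: the standard name (the primary key), its unique SMILES, density
at 25 °C, and the alias lists (abbreviations, synonyms, trade names) that
make it findable.  A record is *active* — and therefore searchable — only
once at least one alias field is populated; rows that arrive without any
alias are retained in a side list so the corpus can grow without
re-reading its source.

The :class:`Corpus` precomputes, for every non-empty name field of every
active record, its bag-of-characters signature, and maintains exact-name
and BOC indexes over them.  Exact lookups are case-insensitive and
whitespace-trimmed but otherwise literal; punctuation tolerance is
deliberately left to the BOC/BOW matching algorithms.

Ingest format: CSV/TSV with header
``standard_name,usmiles,density,abbreviations,synonyms,trade_names``;
multi-valued cells are ``;``-delimited (commas occur inside chemical
names).  Corpora serialize to JSON lines, one record per line, with the
cached BOC strings included.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from .encode import boc_alph, boc_encode, canonical_usmiles, validate_boc, CanonicalizationError

__all__ = [
    "ChemicalRecord",
    "Corpus",
    "CorpusValidationError",
    "NAME_FIELDS",
    "ingest_table",
    "lookup_exact",
    "lookup_boc",
    "read_corpus_csv",
    "load_corpus_csv",
    "write_corpus_jsonl",
    "load_corpus_jsonl",
]

#: Searchable name fields, in serialization order.
NAME_FIELDS = ("standard", "abbreviation", "synonym", "trade")

#: Delimiter for multi-valued CSV cells.
MULTI_VALUE_DELIMITER = ";"

KINDS = ("pol", "fil")


class CorpusValidationError(ValueError):
    """Ingest-time validation failure (duplicate key, bad density, bad SMILES)."""


@dataclass(frozen=True)
class ChemicalRecord:
    """One indexed chemical and its aliases.

    ``kind`` distinguishes polymers ("pol") from composite fillers ("fil");
    fillers are indexed with synonyms and density only.
    """

    standard_name: str
    usmiles: str | None = None
    density: float | None = None
    abbreviations: tuple[str, ...] = ()
    synonyms: tuple[str, ...] = ()
    trade_names: tuple[str, ...] = ()
    kind: str = "pol"

    @property
    def record_id(self) -> str:
        """Case-folded standard name; the corpus-wide primary key."""
        return self.standard_name.casefold()

    @property
    def active(self) -> bool:
        """Searchable iff at least one alias field is populated."""
        return bool(self.abbreviations or self.synonyms or self.trade_names)

    def named_fields(self) -> Iterator[tuple[str, str]]:
        """Yield (field, value) for every non-empty name in this record."""
        yield "standard", self.standard_name
        for a in self.abbreviations:
            yield "abbreviation", a
        for s in self.synonyms:
            yield "synonym", s
        for t in self.trade_names:
            yield "trade", t


@dataclass
class Corpus:
    """Indexed collection of active records plus retained inactive rows."""

    records: dict[str, ChemicalRecord] = field(default_factory=dict)
    inactive: list[ChemicalRecord] = field(default_factory=list)
    # boc string -> {(record_id, field)}
    boc_index: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    # 26-digit prefix -> {(record_id, field)}
    boc_alph_index: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    # field -> folded name -> {record_id}
    name_index: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    # canonical uSMILES -> {record_id}
    usmiles_index: dict[str, set[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.records

    def add(self, record: ChemicalRecord) -> None:
        """Index one record (active) or shelve it (inactive)."""
        if not record.active:
            self.inactive.append(record)
            return
        rid = record.record_id
        if rid in self.records:
            raise CorpusValidationError(f"duplicate standard name: {record.standard_name!r}")
        self.records[rid] = record
        for fld, value in record.named_fields():
            folded = value.casefold().strip()
            self.name_index.setdefault(fld, {}).setdefault(folded, set()).add(rid)
            boc = boc_encode(value)
            self.boc_index.setdefault(boc, set()).add((rid, fld))
            self.boc_alph_index.setdefault(boc[:26], set()).add((rid, fld))
        if record.usmiles:
            self.usmiles_index.setdefault(record.usmiles, set()).add(rid)

    def ids_of_kind(self, kind: str) -> set[str]:
        return {rid for rid, rec in self.records.items() if rec.kind == kind}


def _split_multi(cell: str | None) -> tuple[str, ...]:
    if not cell:
        return ()
    return tuple(v.strip() for v in cell.split(MULTI_VALUE_DELIMITER) if v.strip())


def ingest_table(rows: Iterable[Mapping[str, object]], kind: str = "pol") -> Corpus:
    """Build a :class:`Corpus` from delimited-table rows.

    Each row maps the header columns (``standard_name``, ``usmiles``,
    ``density``, ``abbreviations``, ``synonyms``, ``trade_names``) to cell
    text; multi-valued cells use ``;``.  SMILES are canonicalized on
    ingest.  Only active rows are indexed; inactive rows are retained in
    ``corpus.inactive``.

    Raises :class:`CorpusValidationError` naming the offending row for
    duplicate standard names, malformed densities, or uncanonicalizable
    SMILES.  An empty table yields an empty corpus.
    """
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    corpus = Corpus()
    seen: dict[str, str] = {}
    for row_no, row in enumerate(rows, start=1):
        name = str(row.get("standard_name") or "").strip()
        if not name:
            raise CorpusValidationError(f"row {row_no}: empty standard_name")
        key = name.casefold()
        if key in seen:
            raise CorpusValidationError(
                f"row {row_no}: duplicate standard name {name!r} (also {seen[key]!r})"
            )
        seen[key] = name

        raw_density = row.get("density")
        density: float | None = None
        if raw_density not in (None, ""):
            try:
                density = float(raw_density)  # type: ignore[arg-type]
            except (TypeError, ValueError):
                raise CorpusValidationError(
                    f"row {row_no}: malformed density {raw_density!r}"
                ) from None
            if density <= 0:
                raise CorpusValidationError(
                    f"row {row_no}: density must be positive, got {density}"
                )

        raw_smiles = str(row.get("usmiles") or "").strip()
        usmiles: str | None = None
        if raw_smiles:
            try:
                usmiles = canonical_usmiles(raw_smiles)
            except CanonicalizationError as exc:
                raise CorpusValidationError(f"row {row_no}: {exc}") from exc

        corpus.add(
            ChemicalRecord(
                standard_name=name,
                usmiles=usmiles,
                density=density,
                abbreviations=_split_multi(str(row.get("abbreviations") or "")),
                synonyms=_split_multi(str(row.get("synonyms") or "")),
                trade_names=_split_multi(str(row.get("trade_names") or "")),
                kind=kind,
            )
        )
    return corpus


def lookup_exact(corpus: Corpus, fld: str, query: str) -> set[str]:
    """Ids of records whose *fld* contains *query* after case folding/trimming.

    No punctuation stripping: ``"polyvinyl alcohol"`` does not hit the
    standard name ``"Poly(vinyl alcohol)"`` — that tolerance belongs to the
    BOC algorithms.
    """
    if fld not in NAME_FIELDS:
        raise ValueError(f"unknown field {fld!r}; expected one of {NAME_FIELDS}")
    return set(corpus.name_index.get(fld, {}).get(query.casefold().strip(), ()))


def lookup_boc(
    corpus: Corpus,
    boc: str,
    scope: str = "all_fields",
    alph_only: bool = False,
) -> set[str]:
    """Ids of records with an in-scope field whose stored BOC equals *boc*.

    ``scope`` is ``"all_fields"`` or ``"abbreviations_only"``.  With
    ``alph_only`` equality is tested on the 26 letter counts only, so
    numeral differences are forgiven.
    """
    validate_boc(boc)
    if scope not in ("all_fields", "abbreviations_only"):
        raise ValueError(f"unknown scope {scope!r}")
    if alph_only:
        entries = corpus.boc_alph_index.get(boc_alph(boc), set())
    else:
        entries = corpus.boc_index.get(boc, set())
    if scope == "abbreviations_only":
        return {rid for rid, fld in entries if fld == "abbreviation"}
    return {rid for rid, _ in entries}


# ---------------------------------------------------------------------------
# I/O

CSV_HEADER = ["standard_name", "usmiles", "density", "abbreviations", "synonyms", "trade_names"]


def read_corpus_csv(path: str | Path, delimiter: str = ",") -> list[dict[str, str]]:
    """Read the ingest table from a CSV/TSV file into row dicts."""
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter=delimiter))


def load_corpus_csv(path: str | Path, kind: str = "pol", delimiter: str = ",") -> Corpus:
    """Read and ingest a corpus CSV in one step."""
    return ingest_table(read_corpus_csv(path, delimiter=delimiter), kind=kind)


def _record_to_json(rec: ChemicalRecord, active: bool) -> dict:
    return {
        "standard_name": rec.standard_name,
        "usmiles": rec.usmiles,
        "density": rec.density,
        "abbreviations": list(rec.abbreviations),
        "synonyms": list(rec.synonyms),
        "trade_names": list(rec.trade_names),
        "kind": rec.kind,
        "active": active,
        "boc": {f"{fld}:{value}": boc_encode(value) for fld, value in rec.named_fields()},
    }


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    """Serialize the corpus as JSON lines, one record per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in corpus.records.values():
            fh.write(json.dumps(_record_to_json(rec, True), ensure_ascii=False) + "\n")
        for rec in corpus.inactive:
            fh.write(json.dumps(_record_to_json(rec, False), ensure_ascii=False) + "\n")


def load_corpus_jsonl(path: str | Path) -> Corpus:
    """Rebuild a corpus from its JSON-lines serialization."""
    corpus = Corpus()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            corpus.add(
                ChemicalRecord(
                    standard_name=obj["standard_name"],
                    usmiles=obj.get("usmiles"),
                    density=obj.get("density"),
                    abbreviations=tuple(obj.get("abbreviations") or ()),
                    synonyms=tuple(obj.get("synonyms") or ()),
                    trade_names=tuple(obj.get("trade_names") or ()),
                    kind=obj.get("kind", "pol"),
                )
            )
    return corpus
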