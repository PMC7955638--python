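"""Synthetic alias corpora and labeled query sets for testing and training.

Real polymer nomenclature varies along a handful of recurring axes:
capitalization, parenthesization ("Poly(vinyl alcohol)" vs "polyvinyl
alcohol"), separator choice ("PA 6-6" / "PA 66" / "PA 6/6"), descriptive
suffixes ("... epoxy resin"), word order, and abbreviations shared by
distinct chemicals (PVA for both poly(vinyl alcohol) and poly(vinyl
acetate)).  This module generates corpora of *pseudo*-polymers — so tests
never depend on chemical-knowledge fixtures — whose aliases and query
perturbations exhibit exactly those axes.

Every generated record has a unique standard name of the form
``Poly(<w1> <w2>)`` built from pseudoword syllables, with the letter
multiset of each name unique across the corpus (so bag-of-characters
signatures never collide between records), synonyms covering the
deparenthesized and suffix-extended spellings, one abbreviation, an
optional trade name, a valid toy SMILES (alkane chain with ``[*]`` ends),
and a density in (0.8, 2.5) g/cm³.  A requested number of record pairs
share an abbreviation, reproducing the shared-PVA ambiguity pattern.

Generation is a pure function of its seed: the same arguments always
yield byte-identical tables and identical query sets.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, ingest_table
from .match import SearchPackage, build_match_vectors

__all__ = [
    "PERTURBATION_KINDS",
    "PerturbationSpec",
    "DEFAULT_SPECS",
    "generate_corpus",
    "generate_queries",
]

PERTURBATION_KINDS = (
    "case_flip",
    "parenthesize",
    "deparenthesize",
    "hyphen_space_slash",
    "suffix_extend",
    "word_reorder",
    "shared_abbreviation",
)

_SYLLABLES = (
    "vin", "sty", "eth", "prop", "but", "acry", "lact", "oxa", "sil",
    "carb", "fluo", "ure", "amid", "est", "ket", "sulf", "benz", "tol",
    "glyc", "mal", "fum", "ald", "cro", "ter", "pyr", "fur", "thi", "azo",
)
_TRADE_SUFFIXES = ("lon", "ex", "ite", "foam", "flex", "dur")


@dataclass(frozen=True)
class PerturbationSpec:
    """One perturbation class applied to queries with a given probability."""

    kind: str
    rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {self.rate}")


#: Perturbation mix exercising every nomenclature axis at realistic rates.
DEFAULT_SPECS = (
    PerturbationSpec("case_flip", 0.3),
    PerturbationSpec("parenthesize", 0.1),
    PerturbationSpec("deparenthesize", 0.3),
    PerturbationSpec("hyphen_space_slash", 0.4),
    PerturbationSpec("suffix_extend", 0.15),
    PerturbationSpec("word_reorder", 0.15),
    PerturbationSpec("shared_abbreviation", 0.3),
)


def _pseudoword(rng: np.random.Generator) -> str:
    return "".join(rng.choice(_SYLLABLES) for _ in range(2))


def generate_corpus(
    n_records: int, ambiguous_pairs: int, seed: int
) -> list[dict[str, str]]:
    """Emit *n_records* synthetic polymer rows as ingest-table row dicts.

    Exactly ``ambiguous_pairs`` disjoint pairs of records share an
    abbreviation; all standard names have pairwise-distinct letter
    multisets so name-level BOC signatures identify records uniquely.
    """
    if n_records < 2 * ambiguous_pairs:
        raise ValueError(
            f"n_records={n_records} cannot host {ambiguous_pairs} disjoint pairs"
        )
    if n_records < 1 or ambiguous_pairs < 0:
        raise ValueError("n_records must be >= 1 and ambiguous_pairs >= 0")
    rng = np.random.default_rng(seed)
    rows: list[dict[str, str]] = []
    seen_letter_sets: set[str] = set()
    seen_abbrs: set[str] = set()
    seen_trades: set[str] = set()

    words: list[tuple[str, str]] = []
    while len(words) < n_records:
        w1, w2 = _pseudoword(rng), _pseudoword(rng)
        key = "".join(sorted(w1 + w2))
        if w1 == w2 or key in seen_letter_sets:
            continue
        seen_letter_sets.add(key)
        words.append((w1, w2))

    for i, (w1, w2) in enumerate(words):
        standard = f"Poly({w1} {w2})"
        synonyms = [f"poly{w1} {w2}", f"poly {w1} {w2} resin"]
        if rng.random() < 0.5:
            synonyms.append(f"{w1} {w2} polymer")
        abbr = f"P{w1[0].upper()}{w2[0].upper()}"
        pair_index = i // 2 if i < 2 * ambiguous_pairs else None
        if pair_index is not None and i % 2 == 1:
            abbr = rows[-1]["abbreviations"]  # share with pair partner
        else:
            while abbr in seen_abbrs:
                abbr += str(rng.integers(2, 10))
            seen_abbrs.add(abbr)
        trade = ""
        if rng.random() < 0.6:
            trade = (str(rng.choice(_SYLLABLES)) + str(rng.choice(_TRADE_SUFFIXES))).capitalize()
            while trade in seen_trades:
                trade += str(rng.integers(2, 10))
            seen_trades.add(trade)
        rows.append(
            {
                "standard_name": standard,
                "usmiles": "[*]" + "C" * (i + 1) + "[*]",
                "density": f"{rng.uniform(0.81, 2.49):.2f}",
                "abbreviations": abbr,
                "synonyms": ";".join(synonyms),
                "trade_names": trade,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# Query perturbations

_BOUNDARY_RE = re.compile(r"(?<=[a-zA-Z])(?=[0-9])|(?<=[0-9])(?=[a-zA-Z])")
_SEPARATORS = (" ", "-", "/", "")


def _case_flip(name: str, rng: np.random.Generator) -> str:
    return "".join(c.upper() if rng.random() < 0.5 else c.lower() for c in name)


def _parenthesize(name: str, rng: np.random.Generator) -> str:
    if "(" in name:
        return name
    low = name.lower()
    if low.startswith("poly") and len(name) > 4:
        return f"{name[:4]}({name[4:].lstrip()})"
    parts = name.rsplit(" ", 1)
    return f"{parts[0]} ({parts[1]})" if len(parts) == 2 else name


def _deparenthesize(name: str, rng: np.random.Generator) -> str:
    return name.replace("(", "").replace(")", "")


def _hyphen_space_slash(name: str, rng: np.random.Generator) -> str:
    # maybe open a separator at each letter<->digit boundary, then rewrite
    # every existing separator with a random choice (including deletion)
    def boundary(m: re.Match) -> str:
        return str(rng.choice(("", " ", "-", "/"))) if rng.random() < 0.7 else ""

    name = _BOUNDARY_RE.sub(boundary, name)
    return "".join(
        str(rng.choice(_SEPARATORS)) if c in " -/" else c for c in name
    )


def _suffix_extend(name: str, rng: np.random.Generator) -> str:
    return name + " resin"


def _word_reorder(name: str, rng: np.random.Generator) -> str:
    tokens = re.findall(r"[A-Za-z0-9]+", name)
    if len(tokens) < 2:
        return name
    rng.shuffle(tokens)
    return " ".join(tokens)


_PERTURB_FUNCS = {
    "case_flip": _case_flip,
    "parenthesize": _parenthesize,
    "deparenthesize": _deparenthesize,
    "hyphen_space_slash": _hyphen_space_slash,
    "suffix_extend": _suffix_extend,
    "word_reorder": _word_reorder,
}


def _shared_abbreviations(corpus: Corpus) -> dict[str, list[str]]:
    """Abbreviation (folded) -> record ids, for abbreviations held by >= 2."""
    index = corpus.name_index.get("abbreviation", {})
    return {a: sorted(ids) for a, ids in index.items() if len(ids) >= 2}


def generate_queries(
    corpus: Corpus,
    specs: tuple[PerturbationSpec, ...] | list[PerturbationSpec],
    n_queries: int,
    seed: int,
) -> list[SearchPackage]:
    """Sample labeled queries from *corpus* through the perturbation pipeline.

    Each query starts from a record's standard name, passes through the
    perturbation kinds in *specs* (each firing with its rate), and carries
    the true standard name as its label.  Every kind in *specs* is forced
    to appear at least once when ``n_queries >= len(specs)``.  Queries are
    certified resolvable in principle: if the perturbed package no longer
    touches its ground truth through any algorithm, it is resampled.
    """
    if not len(corpus):
        raise ValueError("corpus is empty")
    rng = np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF] + [s.seed for s in specs])
    )
    record_ids = sorted(corpus.records)
    shared = _shared_abbreviations(corpus)
    shared_ids = sorted({rid for ids in shared.values() for rid in ids})

    queries: list[SearchPackage] = []
    for q in range(n_queries):
        forced = specs[q].kind if q < len(specs) else None
        for _attempt in range(20):
            sp = _one_query(corpus, specs, forced, rng, record_ids, shared, shared_ids)
            truth = sp.label.casefold()  # type: ignore[union-attr]
            if truth in build_match_vectors(sp, corpus):
                break
        else:
            # fall back to the unperturbed standard name, always resolvable
            rid = record_ids[int(rng.integers(len(record_ids)))]
            rec = corpus.records[rid]
            sp = SearchPackage(
                polfil=rec.kind, chemical_name=rec.standard_name, label=rec.standard_name
            )
        queries.append(sp)
    return queries


def _one_query(
    corpus: Corpus,
    specs,
    forced: str | None,
    rng: np.random.Generator,
    record_ids: list[str],
    shared: dict[str, list[str]],
    shared_ids: list[str],
) -> SearchPackage:
    want_shared = forced == "shared_abbreviation" or any(
        s.kind == "shared_abbreviation" and rng.random() < s.rate for s in specs
    )
    if want_shared and shared_ids:
        rid = shared_ids[int(rng.integers(len(shared_ids)))]
    else:
        want_shared = False
        rid = record_ids[int(rng.integers(len(record_ids)))]
    rec = corpus.records[rid]
    name = rec.standard_name
    for s in specs:
        if s.kind == "shared_abbreviation":
            continue
        fire = s.kind == forced or rng.random() < s.rate
        if fire:
            name = _PERTURB_FUNCS[s.kind](name, rng)
    abbreviation = None
    if want_shared:
        abbreviation = rec.abbreviations[0]
    elif rec.abbreviations and rng.random() < 0.25:
        abbreviation = rec.abbreviations[0]
    if abbreviation is not None:
        for s in specs:
            if s.kind == "hyphen_space_slash" and rng.random() < s.rate:
                abbreviation = _hyphen_space_slash(abbreviation, rng)
    trade_name = None
    if rec.trade_names and rng.random() < 0.15:
        trade_name = rec.trade_names[0]
    return SearchPackage(
        polfil=rec.kind,
        chemical_name=name,
        abbreviation=abbreviation,
        trade_name=trade_name,
        label=rec.standard_name,
    )


def generate_corpus_object(
    n_records: int, ambiguous_pairs: int, seed: int, kind: str = "pol"
) -> Corpus:
    """Convenience: generate rows and ingest them in one step."""
    return ingest_table(generate_corpus(n_records, ambiguous_pairs, seed), kind=kind)
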