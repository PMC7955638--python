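"""Candidate generation (12 algorithms) and weighted-voting resolution.

A query arrives as a *searching package* (SP): the ``polfil`` search type
plus a required ``ChemicalName`` and optional ``Abbreviation``,
``TradeName`` and ``SMILES``.  Twelve independent algorithms each nominate
the set of corpus records they consider a match:

==  ========================================================================
 1  stored uSMILES equals the canonicalized query SMILES
 2  exact (case-folded) ChemicalName within standard names
 3  exact ChemicalName within abbreviations
 4  exact ChemicalName within synonyms
 5  exact Abbreviation within abbreviations
 6  BOC of Abbreviation within abbreviation BOCs
 7  relaxed bag-of-words TradeName against stored trade names
 8  BOC-alph of TradeName within all name-field BOCs (letters only)
 9  BOC of ChemicalName within all name-field BOCs
10  BOC-alph of ChemicalName within all name-field BOCs (letters only)
11  relaxed bag-of-words ChemicalName against standard names
12  relaxed bag-of-words ChemicalName against synonyms
==  ========================================================================

An algorithm whose input field is absent abstains (empty set).  For filler
queries (``polfil="fil"``) the SMILES-, abbreviation- and trade-name-based
algorithms (#1, #3, #5–#8) abstain as well, since fillers are indexed with
synonyms and density only.

Per record, the algorithm outcomes form a 12-flag *match vector* R;
records touched by no algorithm are never materialized.  Resolution scores
every candidate by the dot product w·R with a non-negative weight vector
and returns the strict argmax; ties and empty scoreboards are reported as
statuses (and appended to an unresolved-query log), never broken silently.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .corpus import Corpus, lookup_boc, lookup_exact
from .encode import (
    CanonicalizationError,
    boc_encode,
    canonical_usmiles,
    relaxed_bow_match,
)

__all__ = [
    "N_ALGORITHMS",
    "DEFAULT_WEIGHTS",
    "FILLER_DISABLED_ALGORITHMS",
    "SearchPackage",
    "Resolution",
    "QueryLog",
    "run_algorithm",
    "build_match_vectors",
    "score",
    "resolve",
]

#: Number of candidate-generation algorithms; match vectors have this length.
N_ALGORITHMS = 12

#: Consolidated consensus weights shipped as the packaged default
#: configuration (w_1..w_12).
DEFAULT_WEIGHTS: tuple[float, ...] = (1, 1, 1, 1, 0.8, 0.8, 0, 0, 1.2, 1.2, 1, 2)

#: Algorithms that abstain for filler queries (fillers carry synonyms and
#: density only — no SMILES, abbreviations, or trade names).
FILLER_DISABLED_ALGORITHMS = frozenset({1, 3, 5, 6, 7, 8})

#: Score ties closer than this are treated as exact ties.
SCORE_TIE_TOL = 1e-9


@dataclass(frozen=True)
class SearchPackage:
    """One query payload, optionally carrying a training label."""

    polfil: str
    chemical_name: str
    abbreviation: str | None = None
    trade_name: str | None = None
    smiles: str | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        if self.polfil not in ("pol", "fil"):
            raise ValueError(f"polfil must be 'pol' or 'fil', got {self.polfil!r}")
        if not self.chemical_name or not self.chemical_name.strip():
            raise ValueError("chemical_name must be non-empty")

    def to_params(self) -> dict[str, str]:
        """Render as the GET-parameter mapping the service accepts."""
        params = {"polfil": self.polfil, "ChemicalName": self.chemical_name}
        if self.abbreviation:
            params["Abbreviation"] = self.abbreviation
        if self.trade_name:
            params["TradeName"] = self.trade_name
        if self.smiles:
            params["SMILES"] = self.smiles
        return params


@dataclass
class Resolution:
    """Outcome of weighted voting for one searching package."""

    status: str  # "resolved" | "tie" | "no_result"
    winner: str | None
    scoreboard: dict[str, tuple[tuple[int, ...], float]]
    tied: tuple[str, ...] = ()

    @property
    def margin(self) -> float | None:
        """Winner's score lead over the runner-up (None unless resolved)."""
        if self.status != "resolved" or len(self.scoreboard) < 2:
            return None
        ordered = sorted((s for _, s in self.scoreboard.values()), reverse=True)
        return ordered[0] - ordered[1]


class QueryLog:
    """JSON-lines log of unresolved (tie / no-result) queries.

    Stands in for the deployed system's notify-the-admin channel.  With no
    path the entries are kept in memory only.
    """

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path else None
        self.entries: list[dict] = []

    def append(self, sp: SearchPackage, resolution: Resolution) -> None:
        entry = {
            "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "sp": sp.to_params(),
            "status": resolution.status,
            "scoreboard": {
                rid: {"R": list(vec), "score": sc}
                for rid, (vec, sc) in sorted(resolution.scoreboard.items())
            },
        }
        self.entries.append(entry)
        if self.path:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(entry, ensure_ascii=False) + "\n")


def _query_usmiles(sp: SearchPackage) -> str | None:
    """Canonicalize the query SMILES; a bad query SMILES means abstention,
    not failure, so name evidence still gets to vote."""
    if not sp.smiles:
        return None
    try:
        return canonical_usmiles(sp.smiles)
    except CanonicalizationError:
        return None


def run_algorithm(algo_id: int, sp: SearchPackage, corpus: Corpus) -> set[str]:
    """Run one of the 12 candidate-generation algorithms.

    Returns the set of matching record ids (restricted to records of the
    queried ``polfil`` kind).  Algorithms whose input field is absent, and
    filler-disabled algorithms under ``polfil="fil"``, return the empty set.
    """
    if not isinstance(algo_id, int) or not 1 <= algo_id <= N_ALGORITHMS:
        raise ValueError(f"algo_id must be in 1..{N_ALGORITHMS}, got {algo_id!r}")
    if sp.polfil == "fil" and algo_id in FILLER_DISABLED_ALGORITHMS:
        return set()

    name = sp.chemical_name
    hits: set[str]
    if algo_id == 1:
        usm = _query_usmiles(sp)
        hits = set(corpus.usmiles_index.get(usm, ())) if usm else set()
    elif algo_id == 2:
        hits = lookup_exact(corpus, "standard", name)
    elif algo_id == 3:
        hits = lookup_exact(corpus, "abbreviation", name)
    elif algo_id == 4:
        hits = lookup_exact(corpus, "synonym", name)
    elif algo_id == 5:
        hits = lookup_exact(corpus, "abbreviation", sp.abbreviation) if sp.abbreviation else set()
    elif algo_id == 6:
        if sp.abbreviation:
            hits = lookup_boc(corpus, boc_encode(sp.abbreviation), scope="abbreviations_only")
        else:
            hits = set()
    elif algo_id == 7:
        hits = _bow_scan(corpus, sp.trade_name, "trade_names") if sp.trade_name else set()
    elif algo_id == 8:
        if sp.trade_name:
            hits = lookup_boc(corpus, boc_encode(sp.trade_name), scope="all_fields", alph_only=True)
        else:
            hits = set()
    elif algo_id == 9:
        hits = lookup_boc(corpus, boc_encode(name), scope="all_fields")
    elif algo_id == 10:
        hits = lookup_boc(corpus, boc_encode(name), scope="all_fields", alph_only=True)
    elif algo_id == 11:
        hits = _bow_scan(corpus, name, "standard_name")
    else:  # algo_id == 12
        hits = _bow_scan(corpus, name, "synonyms")

    return hits & corpus.ids_of_kind(sp.polfil)


def _bow_scan(corpus: Corpus, query: str, attr: str) -> set[str]:
    """Relaxed-BOW scan of one record attribute over the whole corpus."""
    out: set[str] = set()
    for rid, rec in corpus.records.items():
        values = getattr(rec, attr)
        if isinstance(values, str):
            values = (values,)
        if any(relaxed_bow_match(query, v) for v in values):
            out.add(rid)
    return out


def build_match_vectors(sp: SearchPackage, corpus: Corpus) -> dict[str, tuple[int, ...]]:
    """Evaluate all 12 algorithms and assemble per-record match vectors.

    Only records touched by at least one algorithm appear; all-zero
    vectors are never materialized.
    """
    per_algo = [run_algorithm(i, sp, corpus) for i in range(1, N_ALGORITHMS + 1)]
    touched = set().union(*per_algo)
    return {
        rid: tuple(1 if rid in hits else 0 for hits in per_algo)
        for rid in sorted(touched)
    }


def score(w, r) -> float:
    """Dot product of a weight vector with a match (or margin) vector."""
    w = tuple(w)
    r = tuple(r)
    if len(w) != N_ALGORITHMS or len(r) != N_ALGORITHMS:
        raise ValueError(
            f"expected length-{N_ALGORITHMS} vectors, got {len(w)} and {len(r)}"
        )
    return float(sum(wi * ri for wi, ri in zip(w, r)))


def resolve(
    sp: SearchPackage,
    corpus: Corpus,
    w=DEFAULT_WEIGHTS,
    log: QueryLog | None = None,
) -> Resolution:
    """Weighted-voting resolution of one searching package.

    Builds match vectors, scores candidates with *w*, and returns the
    record with the strictly highest score.  A tie at the top or an empty
    scoreboard yields status ``"tie"`` / ``"no_result"`` and is appended to
    the unresolved-query log when one is given.  Record iteration order
    never influences the outcome.
    """
    vectors = build_match_vectors(sp, corpus)
    scoreboard = {rid: (vec, score(w, vec)) for rid, vec in vectors.items()}
    if not scoreboard:
        res = Resolution(status="no_result", winner=None, scoreboard={})
    else:
        top = max(s for _, s in scoreboard.values())
        leaders = sorted(rid for rid, (_, s) in scoreboard.items() if top - s <= SCORE_TIE_TOL)
        if len(leaders) == 1:
            res = Resolution(status="resolved", winner=leaders[0], scoreboard=scoreboard)
        else:
            res = Resolution(status="tie", winner=None, scoreboard=scoreboard, tied=tuple(leaders))
    if log is not None and res.status != "resolved":
        log.append(sp, res)
    return res
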