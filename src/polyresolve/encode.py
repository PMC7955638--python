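"""String encodings and SMILES canonicalization for polymer-name matching.

Polymer names are riddled with incidental punctuation, spacing and
capitalization differences ("PA 6-6" vs "PA 66" vs "PA 6/6",
"Poly(vinyl alcohol)" vs "polyvinyl alcohol").  Two cheap, order-free
signatures make names comparable across those variations:

* **BOC** (bag of characters): a 36-digit count string — 26 digits for the
  letters a–z followed by 10 digits for the numerals 0–9, each count capped
  at 9.  Invariant to character order, case, and any character outside
  ``[a-z0-9]``.
* **BOC-alph**: the 26-letter prefix of a BOC string, discarding numeral
  counts, so "nylon 66" and "nylon" coincide.

For names whose variants add or drop whole words ("diglycidyl ether of
bisphenol-A" vs "Diglycidyl ether of bisphenol-A epoxy resin") the
*relaxed bag-of-words* comparison applies instead: the query matches an
entry when every alphabetic token of the query occurs among the entry's
tokens.

Chemical identity is anchored by canonical Kekulé SMILES (uSMILES) with
polymer repeat-unit attachment points written ``[*]``; both stored and
query SMILES pass through the same local canonicalizer so equality is
self-consistent.
"""

from __future__ import annotations

import re
import string
import unicodedata

from rdkit import Chem, RDLogger

__all__ = [
    "BOC_LENGTH",
    "BOC_ALPH_LENGTH",
    "CanonicalizationError",
    "boc_encode",
    "boc_alph",
    "tokenize_bow",
    "relaxed_bow_match",
    "canonical_usmiles",
    "validate_boc",
]

#: Total length of a BOC string: 26 letter counts + 10 numeral counts.
BOC_LENGTH = 36
#: Length of the alphabet-only prefix.
BOC_ALPH_LENGTH = 26
#: Per-character occurrence cap; counts saturate at this digit.
BOC_CAP = 9

_LETTERS = string.ascii_lowercase
_DIGITS = string.digits
_CHAR_SLOT = {c: i for i, c in enumerate(_LETTERS)}
_CHAR_SLOT.update({c: BOC_ALPH_LENGTH + i for i, c in enumerate(_DIGITS)})

_BOC_RE = re.compile(r"^[0-9]{36}$")
_NON_ALPHA_RE = re.compile(r"[^a-z]+")

# rdkit reports parse failures on its own logger; errors are surfaced as
# exceptions here, so the duplicate log line is suppressed.
RDLogger.DisableLog("rdApp.error")


class CanonicalizationError(ValueError):
    """Raised when a SMILES string cannot be parsed and canonicalized."""

    def __init__(self, smiles: str, reason: str = "unparsable SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


def _normalize_text(name: str) -> str:
    """Compatibility-fold to ASCII: strip accents, lowercase.

    Typographic characters (en dash, ligatures, accented letters) must not
    silently change letter counts: accents are stripped to their base letter
    and anything that does not decompose to ASCII ``[a-z0-9]`` is left for
    the counting step to ignore.
    """
    decomposed = unicodedata.normalize("NFKD", name)
    return decomposed.encode("ascii", "ignore").decode("ascii").lower()


def boc_encode(name: str) -> str:
    """Encode *name* as a 36-digit bag-of-characters string.

    Lowercases the input, counts occurrences of ``a-z`` and ``0-9`` (all
    other characters are ignored), and caps each count at 9.  Total
    function: any text, including the empty string, encodes.

    >>> boc_encode("PA 66") == boc_encode("PA 6/6") == boc_encode("PA 6-6")
    True
    """
    counts = [0] * BOC_LENGTH
    for ch in _normalize_text(name):
        slot = _CHAR_SLOT.get(ch)
        if slot is not None and counts[slot] < BOC_CAP:
            counts[slot] += 1
    return "".join(str(c) for c in counts)


def validate_boc(boc: str) -> str:
    """Return *boc* if it is a well-formed 36-digit BOC string, else raise."""
    if not isinstance(boc, str) or not _BOC_RE.match(boc):
        raise ValueError(f"malformed BOC string: {boc!r}")
    return boc


def boc_alph(boc: str) -> str:
    """Return the 26-digit alphabet-only prefix of a BOC string."""
    return validate_boc(boc)[:BOC_ALPH_LENGTH]


def tokenize_bow(name: str) -> frozenset[str]:
    """Split *name* on non-alphabetic characters into a set of lowercase words.

    Digits act as separators, so ``"66"`` yields an empty bag.
    """
    return frozenset(t for t in _NON_ALPHA_RE.split(_normalize_text(name)) if t)


def relaxed_bow_match(query: str, entry: str, *, symmetric: bool = False) -> bool:
    """Relaxed bag-of-words comparison between a query and a stored entry.

    True iff the query's word bag is non-empty and every query word occurs
    in the entry's bag.  An all-punctuation query (empty bag) never matches.
    With ``symmetric=True`` containment in either direction counts.
    """
    q = tokenize_bow(query)
    if not q:
        return False
    e = tokenize_bow(entry)
    if q <= e:
        return True
    return symmetric and bool(e) and e <= q


_WILDCARD_RE = re.compile(r"(?<!\[)\*(?!\])")


def canonical_usmiles(smiles: str) -> str:
    """Canonicalize a SMILES string to its unique Kekulé form (uSMILES).

    Internal whitespace is stripped before parsing; polymer attachment
    points may be written ``*`` or ``[*]`` and are normalized to ``[*]`` in
    the output.  Deterministic and idempotent.

    Raises :class:`CanonicalizationError` on unparsable input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise CanonicalizationError(smiles, "empty SMILES")
    cleaned = re.sub(r"\s+", "", smiles)
    mol = Chem.MolFromSmiles(cleaned)
    if mol is None:
        raise CanonicalizationError(smiles)
    try:
        Chem.Kekulize(mol, clearAromaticFlags=True)
        out = Chem.MolToSmiles(mol, kekuleSmiles=True, canonical=True)
    except Exception as exc:  # pragma: no cover - rdkit internal failures
        raise CanonicalizationError(smiles, str(exc)) from exc
    return _WILDCARD_RE.sub("[*]", out)
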