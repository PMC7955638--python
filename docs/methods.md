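# Methods

## The resolution model

polyresolve treats polymer-name standardization as weighted-voting entity
resolution against an alias corpus. Each corpus record carries a standard
name (the primary key, unique case-insensitively), a unique Kekulé SMILES
(uSMILES) with polymer attachment points written `[*]`, a density in g/cm³
at 25 °C, and alias lists: abbreviations, synonyms, trade names. A record is
*active* — searchable — only once at least one alias field is populated;
alias-less rows are retained unindexed so the corpus can grow in place.
Records are typed `pol` (polymer) or `fil` (filler); fillers are indexed
with synonyms and density only, so the SMILES-, abbreviation- and
trade-name-based algorithms abstain for filler queries.

Twelve candidate-generation algorithms run per query (see the README table
and `polyresolve.match`). They fall into three families:

* **Exact lookups** (#2–#5): case-folded, whitespace-trimmed, otherwise
  literal. Deliberately brittle to punctuation — `polyvinyl alcohol` does
  not exact-match `Poly(vinyl alcohol)` — because punctuation tolerance is
  the job of the next family, and keeping the families orthogonal gives the
  weight optimizer independent evidence channels.
* **Bag-of-characters (BOC) lookups** (#6, #8–#10): a name's BOC is 26
  letter counts then 10 numeral counts, each saturating at 9 (names rarely
  repeat a character more often, and capping keeps the signature a
  fixed-width digit string). Inputs are compatibility-normalized first:
  accents stripped to their base letter, typographic dashes (e.g. the
  en dash in `PA 6–6`) treated like any other non-alphanumeric character.
  The alphabet-only variant compares the 26-letter prefix, so `nylon` hits
  `Nylon 66`. Algorithm #6 searches abbreviation BOCs only (its input is
  the query abbreviation; the motivating case is `PA 6/6` vs `PA 66`),
  while #8–#10 search the BOC index over all name fields — that scope split
  is what lets a deparenthesized chemical name hit the standard name.
* **Relaxed bag-of-words** (#7, #11, #12): the query's set of alphabetic
  tokens (split on every non-letter, lowercased) must be contained in the
  entry's token set. This direction — query ⊆ entry — handles stored
  synonyms that extend a query with descriptive suffixes ("… epoxy
  resin"). An empty query bag never matches, so an all-punctuation query
  cannot match everything. A symmetric (either-direction) mode exists
  behind a keyword flag, default off, for deployments whose stored entries
  are the shorter spelling.

Per record the twelve outcomes form a match vector **R**; all-zero vectors
are never materialized. Resolution scores candidates by w·R, returns the
strict argmax, and reports a top-score tie or an empty scoreboard as a
status. Unresolved queries go to a JSON-lines log (timestamp, query,
status, scoreboard) — the library's stand-in for alerting a database
administrator. Ties within 1e-9 in score are treated as exact, so float
noise cannot silently pick a winner.

SMILES handling is local: both stored and query SMILES pass through the
same rdkit canonical Kekulé serialization (wildcards normalized to `[*]`,
internal whitespace stripped, idempotent), so algorithm #1's equality test
is self-consistent even where the canonical strings differ from those some
other toolchain would print. A query SMILES that fails to parse makes #1
abstain with a warning instead of failing the request — one malformed
optional field must not mask name evidence.

## Weight learning

Labeled queries are evaluated once under unit weights. Sole-candidate
queries whose candidate is the truth contribute their vector as **Rc**;
multi-candidate queries contribute one margin vector
x = R_truth − R_wrong ∈ {−1,0,1}¹² per wrong candidate in the top two
unit-weight score ranks (ties at a rank all included; the top-two selection
is one-shot and not revisited during optimization). Entries are +1 where an
algorithm found only the truth, −1 where only the wrong candidate, 0 where
both or neither, so x·w is exactly the resolver's decision margin for that
pair. Queries whose truth matched nothing are excluded with a warning;
truth/wrong pairs with identical vectors are flagged irrecoverable and kept
out of the program, since no weights can separate identical evidence.

The max-min-margin program — maximize min_i x_i·w subject to w ≥ 0,
Rc_k·w ≥ ε and w ≤ w_max — is solved exactly as a linear program
(auxiliary margin variable t, HiGHS solver). Two numerical choices matter:

* ε (default 0.1) replaces the strict constraint Rc·w > 0, which an LP
  cannot express; any positive value works, and 0.1 keeps sole-candidate
  scores visibly positive at the default weight scale.
* w_max (default 4) bounds the objective: margins scale linearly with w
  (the test suite documents this scale property), so without a box bound
  the optimum is unbounded. The packaged default weights lie well inside
  the box.

Because the optimum vertex of an LP need not be unique, a lexicographic
second stage minimizes Σw at the achieved margin (relaxed by 1e-9 for
feasibility). This pins one well-defined solution per training set, which
is what makes k-fold consolidation by *modal vector* meaningful: folds with
the same binding geometry return identical vectors. A non-separable
training set (achieved margin ≤ 0) is reported as a status with the binding
margin vectors listed, never as an exception.

K-fold validation partitions the x's into k near-equal random groups with a
caller-supplied seed (the partition is otherwise irreproducible); each fold
optimizes on the retained x's with all Rc constraints and must achieve a
positive minimum x·w on the omitted group. Consolidation re-scores every
fold under the modal w\* and adopts it only if both the recomputed training
minimum and holdout minimum are positive for every fold — zero is not
positive. Failing folds are identified in the audit.

The packaged default weights `{1,1,1,1,0.8,0.8,0,0,1.2,1.2,1,2}` are a
consensus configuration for deployments that do not train their own; they
put the largest masses on the BOC name algorithms (#9, #10) and the synonym
BOW algorithm (#12) and zero on the trade-name algorithms.

## The synthetic-data generator

`polyresolve.synth` emulates the nomenclature variability the method is
built for, with pseudo-polymer names so tests carry no chemical-knowledge
fixtures. `generate_corpus(n_records, ambiguous_pairs, seed)` emits records
named `Poly(<w1> <w2>)` from syllable pseudowords, with deparenthesized and
suffix-extended synonyms, one abbreviation (a requested number of record
pairs share one, reproducing the PVA ambiguity), an optional trade name, a
toy alkane SMILES `[*]C…C[*]` (always canonicalizable, unique per record),
and a density drawn uniformly from (0.8, 2.5) g/cm³ — the range spanned by
common polymers. Standard names are resampled until their letter multisets
are pairwise distinct, so name-level BOC signatures identify records
uniquely and every shared-abbreviation pair is separable by the BOC
algorithms.

`generate_queries` renders perturbed labeled queries through seven
perturbation classes (case flips, parenthesization and deparenthesization,
separator swaps/insertions/deletions at letter–digit boundaries, descriptive
suffixes, word reordering, shared abbreviations), each firing with a
configurable rate; the default mix exercises every class at rates a curator
would recognize from literature data (separator and parenthesis noise most
common, suffixes and reorderings rarer). Every requested class is forced to appear at
least once when the query count allows, generation is a pure function of
its seeds, and every emitted query is certified resolvable in principle
(its truth's match vector is non-trivial) with resampling otherwise.

What the generator does *not* emulate: misspellings and edit-distance
noise (out of scope for the matcher, which has no fuzzy algorithm),
real-world alias distributions, homonyms across chemical classes, and
non-ASCII nomenclature beyond accent folding. Passing end-to-end tests
therefore show that the pipeline recovers separating weights and resolves
perfectly *when the perturbation classes are the ones the algorithms were
designed for* — they do not bound accuracy on arbitrary literature data.

## Problem sizes and verification

The end-to-end check trains on a 50-record corpus with 3 shared-abbreviation
pairs and 160 labeled queries under 10-fold validation — comfortably the
regime where every pipeline stage (multi-candidate queries, sole-candidate
Rc constraints, fold disagreement machinery) is exercised — and verifies a
positive consolidated margin with 100% resolution on training and fresh
held-out queries. The LP is cross-checked against an exhaustive 0.1-step
grid search on 3-dimensional random instances. Encoding invariants
(permutation/punctuation/case invariance of BOC, canonicalizer idempotence,
score monotonicity, order-independent tie detection) run as seeded
property suites.

## Known limitations

* Exact lookups are literal by design; a query that is both punctuated
  differently *and* letter-different from every stored alias (a true
  misspelling) matches nothing.
* Weighted voting returns a single winner or a tie; there is no ranked
  output or confidence beyond the margin.
* The LP may have multiple optimal vertices even after the lexicographic
  stage when whole weight groups are interchangeable; consolidation then
  reports no consensus rather than inventing one.
* The shipped default weights reflect one deployment's training data;
  retraining on local query logs via `polyresolve train` is the intended
  path as a corpus grows.
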