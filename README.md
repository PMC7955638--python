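# polyresolve

Polymer and composite-filler names are written dozens of ways — `PMMA`,
`poly(methyl methacrylate)`, `polymethyl methacrylate`; `PA 66`, `PA 6-6`,
`PA 6/6` — and that variability breaks indexing, search, and data exchange in
polymer databases. **polyresolve** standardizes free-form names: given a query
(a *searching package*: `polfil` + `ChemicalName`, optionally `Abbreviation`,
`TradeName`, `SMILES`), it returns the standard chemical name, the unique
Kekulé SMILES (uSMILES, with repeat-unit attachment points written `[*]`),
and the density at 25 °C.

## Method

Twelve candidate-generation algorithms each nominate matching records from an
alias corpus: exact (case-folded) lookups against standard names,
abbreviations and synonyms; SMILES identity after local canonicalization;
**bag-of-characters (BOC)** signatures — a 36-digit count string (26 letters
then 10 numerals, each capped at 9) invariant to character order, case and
punctuation — with an alphabet-only variant that also forgives numeral
differences; and **relaxed bag-of-words** containment, which matches when
every alphabetic token of the query occurs in a stored entry.

For a query *SP* and record *r*, the algorithm outcomes form a binary match
vector **R** ∈ {0,1}¹². Candidates are scored by **w·R** with a non-negative
weight vector **w** and the strict argmax wins; ties and empty scoreboards
are logged as unresolved instead of guessed.

The weights are learned from labeled queries. Each truth/wrong candidate pair
(wrong candidates taken from the top two unit-weight score ranks) yields a
margin vector **x** = **R**\_truth − **R**\_wrong ∈ {−1,0,1}¹², so x·w is the
decision margin. The weights solve

```
max_w  min_i x_i·w     s.t.  w_j ≥ 0,  w_j ≤ w_max,  Rc_k·w ≥ ε
```

where the **Rc** are the match vectors of queries whose sole candidate is the
truth (kept strictly positive so those queries keep resolving). The program
is solved exactly as a linear program, validated by k-fold holdout on the
x's, and the modal fold solution is adopted as the consensus **w\*** only if
it keeps every fold's training and holdout margins positive. A consensus
weight configuration `{1, 1, 1, 1, 0.8, 0.8, 0, 0, 1.2, 1.2, 1, 2}` ships as
the packaged default.

## Worked example

The packaged example corpus holds a handful of well-known records, including
the two polymers abbreviated PVA. The deparenthesized spelling misses the
exact-name lookup, both PVA records match the abbreviation algorithms (#5,
#6), and only the true record matches the name's BOC signature (#9, #10), so
the vote resolves by a margin of w₉ + w₁₀ = 2.4:

```console
$ polyresolve resolve --corpus src/polyresolve/data/example_corpus.csv \
    --polfil pol --name "polyvinyl alcohol" --abbr PVA
{"StandardName": "Poly(vinyl alcohol)", "density": "", "uSMILES": ""}

$ polyresolve resolve --corpus src/polyresolve/data/example_corpus.csv \
    --polfil pol --name "polystyrene"
{"StandardName": "Polystyrene", "density": "1.04", "uSMILES": "[*]CC([*])C1=CC=CC=C1"}

$ polyresolve resolve --corpus src/polyresolve/data/example_corpus.csv \
    --polfil pol --name "notachemical"
No results found. Admin alerted to update the database. Please try again in a week.
```

The second query returns polystyrene's density (1.04 g/cm³) and its
canonical Kekulé SMILES; the third exits 1 with the service's standard
not-found message. The same contract is exposed over HTTP
(`polyresolve serve --config config.json`): GET parameters per the table
above, 200 with `{StandardName, density, uSMILES}`, 404 with the message
shown, 400 for missing required parameters.

Training runs on labeled queries (JSON lines with a `label` field):

```bash
polyresolve ingest corpus.csv corpus.jsonl
polyresolve train --corpus corpus.jsonl --queries queries.jsonl \
    --out weights.json --k 10 --seed 7
polyresolve validate --corpus corpus.jsonl --queries queries.jsonl \
    --weights weights.json
```

`weights.json` records the consensus weights, the achieved minimum margin,
and a per-fold audit. The `polyresolve.synth` module generates synthetic
corpora and perturbed query sets (case flips, parenthesization, separator
swaps, suffixes, word reorderings, shared abbreviations) for testing and
training without external data.

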