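"""polyresolve: polymer-name standardization by multi-algorithm weighted voting.

The package resolves free-form polymer (and composite-filler) names to a
standard name, unique Kekulé SMILES, and density, using twelve candidate
generation algorithms over an alias corpus — exact lookups, bag-of-characters
signatures, relaxed bag-of-words containment, and SMILES identity — combined
by a weighted vote whose weights are learned from labeled queries via a
max-min-margin linear program with k-fold validation.
"""

from importlib import resources as _resources

from .encode import (
    BOC_LENGTH,
    BOC_ALPH_LENGTH,
    CanonicalizationError,
    boc_alph,
    boc_encode,
    canonical_usmiles,
    relaxed_bow_match,
    tokenize_bow,
)
from .corpus import (
    ChemicalRecord,
    Corpus,
    CorpusValidationError,
    ingest_table,
    load_corpus_csv,
    load_corpus_jsonl,
    lookup_boc,
    lookup_exact,
    read_corpus_csv,
    write_corpus_jsonl,
)
from .match import (
    DEFAULT_WEIGHTS,
    N_ALGORITHMS,
    QueryLog,
    Resolution,
    SearchPackage,
    build_match_vectors,
    resolve,
    run_algorithm,
    score,
)
from .optimize import (
    FoldResult,
    MarginVector,
    TrainingSet,
    build_training_set,
    consolidate,
    evaluate_accuracy,
    first_pass,
    kfold_validate,
    optimize_weights,
    train_weights,
)
from .service import NOT_FOUND_MESSAGE, ServiceConfig, handle_get, make_wsgi_app
from .synth import (
    DEFAULT_SPECS,
    PerturbationSpec,
    generate_corpus,
    generate_corpus_object,
    generate_queries,
)

__version__ = "1.0.0"


def example_corpus_path():
    """Path to the small packaged corpus of well-known worked examples."""
    return _resources.files("polyresolve").joinpath("data", "example_corpus.csv")


def load_example_corpus() -> Corpus:
    """Load the packaged worked-example corpus (polystyrene, the PVA pair, ...)."""
    return load_corpus_csv(str(example_corpus_path()))


__all__ = [name for name in dir() if not name.startswith("_")]
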