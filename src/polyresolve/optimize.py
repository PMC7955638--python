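"""Learning the algorithm weights by max-min-margin optimization.

Given labeled searching packages, a first pass under unit weights records,
per query, the candidate records and their match vectors R.  Queries whose
sole candidate is the ground truth contribute that vector as an *Rc*
("correct") vector; queries with several candidates contribute, for every
wrong candidate ranked in the top two by unit-weight score, a *margin
vector* x = R_truth − R_wrong with entries in {−1, 0, +1}: +1 where an
algorithm found only the truth, −1 where it found only the wrong
candidate, 0 where it found both or neither.  The decision margin of the
resolver for that truth/wrong pair is exactly x·w.

The weights solve the max-min-margin program

    maximize   min_i  x_i · w
    subject to w_j ≥ 0,          j = 1..12
               Rc_k · w ≥ ε,     k = 1..K   (truths stay strictly positive)
               w_j ≤ w_max                  (margins scale with w, so an
                                             upper box bound is required
                                             for a finite optimum)

solved exactly as a linear program with an auxiliary margin variable,
followed by a lexicographic second stage that minimizes Σw at the optimal
margin so the reported vertex is stable across nearby training sets.

K-fold validation partitions the x's at random, re-optimizes per fold, and
requires the minimum x·w over each omitted group to be positive.
Consolidation takes the modal fold solution as the consensus w*,
re-scores every fold under w*, and adopts w* only if both the training and
holdout minima stay positive everywhere.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .corpus import Corpus
from .match import N_ALGORITHMS, SearchPackage, build_match_vectors

__all__ = [
    "MarginVector",
    "FirstPassEntry",
    "TrainingSet",
    "OptimizeResult",
    "FoldResult",
    "ConsolidationResult",
    "first_pass",
    "build_training_set",
    "optimize_weights",
    "kfold_validate",
    "consolidate",
    "train_weights",
]

logger = logging.getLogger(__name__)

#: Slack standing in for the strict constraint Rc·w > 0 (an LP cannot
#: express strict inequalities).
DEFAULT_EPSILON = 0.1
#: Box bound on each weight; without it the max-min margin is unbounded.
DEFAULT_W_MAX = 4.0


@dataclass(frozen=True)
class MarginVector:
    """Truth-minus-wrong difference of two match vectors, with provenance."""

    x: tuple[int, ...]
    sp_id: int
    wrong_id: str

    def __post_init__(self) -> None:
        if len(self.x) != N_ALGORITHMS:
            raise ValueError(f"margin vector must have length {N_ALGORITHMS}")
        if any(v not in (-1, 0, 1) for v in self.x):
            raise ValueError("margin vector entries must be in {-1, 0, 1}")


@dataclass
class FirstPassEntry:
    """Candidates and vectors recorded for one labeled query."""

    sp: SearchPackage
    candidates: dict[str, tuple[int, ...]]
    truth_id: str | None  # None when the label matched no candidate


@dataclass
class TrainingSet:
    """Margin vectors, sole-candidate Rc vectors, and bookkeeping."""

    xs: list[MarginVector] = field(default_factory=list)
    rcs: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    excluded: list[int] = field(default_factory=list)
    irrecoverable: list[tuple[int, str]] = field(default_factory=list)
    truth_below_top_two: list[int] = field(default_factory=list)

    @property
    def x_matrix(self) -> np.ndarray:
        return np.array([m.x for m in self.xs], dtype=float).reshape(-1, N_ALGORITHMS)

    @property
    def rc_matrix(self) -> np.ndarray:
        return np.array([rc for _, rc in self.rcs], dtype=float).reshape(-1, N_ALGORITHMS)


@dataclass
class OptimizeResult:
    """Weights and achieved minimum margin from one LP solve."""

    w: tuple[float, ...]
    margin: float
    status: str  # "ok" | "non_separable" | "infeasible"
    binding: tuple[int, ...] = ()  # indices of x's at (or below) zero margin


@dataclass
class FoldResult:
    """Per-fold weights and the two validation scores."""

    fold: int
    w: tuple[float, ...]
    min_train_score: float
    holdout_score: float
    omitted: tuple[int, ...]

    @property
    def passed(self) -> bool:
        return self.holdout_score > 0


@dataclass
class ConsolidationResult:
    """Consensus weights, adoption status, and the per-fold audit."""

    w_star: tuple[float, ...] | None
    status: str  # "adopted" | "rejected" | "no_consensus"
    audit: list[dict] = field(default_factory=list)
    failing_folds: tuple[int, ...] = ()

    @property
    def adopted(self) -> bool:
        return self.status == "adopted"


def first_pass(sps: Sequence[SearchPackage], corpus: Corpus) -> list[FirstPassEntry]:
    """Evaluate every labeled query under unit weights and record candidates.

    Queries whose ground-truth label is absent from the candidate set are
    kept in the output with ``truth_id=None`` (and a logged warning); the
    training-set builder excludes them.
    """
    entries: list[FirstPassEntry] = []
    for idx, sp in enumerate(sps):
        if sp.label is None:
            raise ValueError(f"searching package {idx} has no ground-truth label")
        candidates = build_match_vectors(sp, corpus)
        truth_id = sp.label.casefold()
        if truth_id not in candidates:
            logger.warning(
                "query %d (%r): ground truth %r not among %d candidates; excluded",
                idx, sp.chemical_name, sp.label, len(candidates),
            )
            truth_id = None
        entries.append(FirstPassEntry(sp=sp, candidates=candidates, truth_id=truth_id))
    return entries


def build_training_set(entries: Sequence[FirstPassEntry]) -> TrainingSet:
    """Assemble Rc and x vectors from the first-pass output.

    Sole-candidate queries contribute their vector as an Rc.  For
    multi-candidate queries, the candidates are ranked by unit-weight score
    and every *wrong* candidate in the top two ranks (ties at a rank all
    included) yields one x = R_truth − R_wrong.  Identical truth/wrong
    vectors produce an all-zero x that no weight vector can separate; these
    are flagged irrecoverable and kept out of the optimization.
    """
    ts = TrainingSet()
    for idx, entry in enumerate(entries):
        if entry.truth_id is None:
            ts.excluded.append(idx)
            continue
        truth_vec = entry.candidates[entry.truth_id]
        if len(entry.candidates) == 1:
            ts.rcs.append((idx, truth_vec))
            continue
        unit_scores = {rid: sum(vec) for rid, vec in entry.candidates.items()}
        top_values = sorted(set(unit_scores.values()), reverse=True)[:2]
        top_ids = {rid for rid, s in unit_scores.items() if s in top_values}
        if entry.truth_id not in top_ids:
            ts.truth_below_top_two.append(idx)
        for rid in sorted(top_ids - {entry.truth_id}):
            x = tuple(t - w for t, w in zip(truth_vec, entry.candidates[rid]))
            if all(v == 0 for v in x):
                ts.irrecoverable.append((idx, rid))
            else:
                ts.xs.append(MarginVector(x=x, sp_id=idx, wrong_id=rid))
    return ts


def _solve_lp(
    X: np.ndarray,
    RC: np.ndarray,
    epsilon: float,
    w_max: float,
) -> tuple[np.ndarray, float, str]:
    """Two-stage LP: maximize min margin, then minimize Σw at that margin."""
    n = N_ALGORITHMS
    # Stage 1: variables (w_1..w_12, t); maximize t.
    a_rows, b_vals = [], []
    for x in X:
        a_rows.append(np.append(-x, 1.0))  # t - x·w <= 0
        b_vals.append(0.0)
    for rc in RC:
        a_rows.append(np.append(-rc, 0.0))  # -rc·w <= -epsilon
        b_vals.append(-epsilon)
    bounds = [(0.0, w_max)] * n + [(None, None)]
    c = np.zeros(n + 1)
    c[-1] = -1.0
    res = linprog(c, A_ub=np.array(a_rows), b_ub=np.array(b_vals), bounds=bounds, method="highs")
    if not res.success:
        return np.zeros(n), float("-inf"), "infeasible"
    t_star = float(res.x[-1])

    # Stage 2: fix the margin, pick the smallest-Σw vertex for stability.
    a2 = np.vstack([-X, -RC]) if len(RC) else -X
    b2 = np.concatenate([np.full(len(X), -(t_star - 1e-9)), np.full(len(RC), -epsilon)])
    res2 = linprog(
        np.ones(n), A_ub=a2, b_ub=b2, bounds=[(0.0, w_max)] * n, method="highs"
    )
    w = res2.x if res2.success else res.x[:n]
    margin = float(np.min(X @ w))
    return w, margin, "ok" if margin > 0 else "non_separable"


def optimize_weights(
    ts: TrainingSet,
    epsilon: float = DEFAULT_EPSILON,
    w_max: float = DEFAULT_W_MAX,
    x_subset: Sequence[int] | None = None,
) -> OptimizeResult:
    """Solve the max-min-margin program for the training set.

    ``x_subset`` optionally restricts the objective to those x indices
    (used by k-fold validation); the Rc constraints always apply in full.
    Raises ``ValueError`` on an empty x set.  A result with
    ``status="non_separable"`` lists the binding x indices whose margin is
    pinned at or below zero.
    """
    if not ts.xs:
        raise ValueError("training set has no margin vectors to optimize over")
    X = ts.x_matrix
    idx = np.arange(len(ts.xs)) if x_subset is None else np.asarray(list(x_subset), dtype=int)
    if idx.size == 0:
        raise ValueError("x_subset selects no margin vectors")
    if ts.irrecoverable:
        warnings.warn(
            f"{len(ts.irrecoverable)} irrecoverable truth/wrong pairs (identical "
            "match vectors) excluded from optimization",
            stacklevel=2,
        )
    w, margin, status = _solve_lp(X[idx], ts.rc_matrix, epsilon, w_max)
    margins = X[idx] @ w
    binding = tuple(int(idx[i]) for i in np.flatnonzero(margins <= 1e-9)) if margin <= 0 else ()
    return OptimizeResult(w=tuple(float(v) for v in w), margin=margin, status=status, binding=binding)


def kfold_validate(
    ts: TrainingSet,
    k: int,
    seed: int,
    epsilon: float = DEFAULT_EPSILON,
    w_max: float = DEFAULT_W_MAX,
) -> list[FoldResult]:
    """K-fold validation of the weight optimization.

    The x's are partitioned into *k* near-equal groups at random (seeded);
    each fold optimizes on the retained groups (Rc constraints always
    included) and scores the omitted group by its minimum x·w.  A fold
    passes when that holdout minimum is positive.
    """
    n = len(ts.xs)
    if k < 2 or k > n:
        raise ValueError(f"k must be in 2..{n}, got {k}")
    rng = np.random.default_rng(seed)
    groups = np.array_split(rng.permutation(n), k)
    X = ts.x_matrix
    folds: list[FoldResult] = []
    for i, omitted in enumerate(groups, start=1):
        retained = np.setdiff1d(np.arange(n), omitted)
        opt = optimize_weights(ts, epsilon=epsilon, w_max=w_max, x_subset=retained)
        w = np.array(opt.w)
        folds.append(
            FoldResult(
                fold=i,
                w=opt.w,
                min_train_score=float(np.min(X[retained] @ w)),
                holdout_score=float(np.min(X[omitted] @ w)),
                omitted=tuple(int(j) for j in omitted),
            )
        )
    return folds


def _round_key(w: Sequence[float], ndigits: int = 6) -> tuple[float, ...]:
    return tuple(round(float(v), ndigits) for v in w)


def consolidate(folds: Sequence[FoldResult], ts: TrainingSet) -> ConsolidationResult:
    """Consolidate fold solutions into a consensus w*.

    The modal (most frequent) fold weight vector is the candidate w*.
    Every fold is then re-scored under w*: its training minimum and holdout
    minimum are recomputed, and w* is adopted only if both are positive for
    every fold.  With no modal vector (all folds distinct) consolidation
    fails; with any non-positive recomputed score w* is rejected and the
    offending folds are identified.
    """
    if not folds:
        raise ValueError("no fold results to consolidate")
    counts = Counter(_round_key(f.w) for f in folds)
    modal_key, modal_count = counts.most_common(1)[0]
    if modal_count == 1 and len(folds) > 1:
        return ConsolidationResult(w_star=None, status="no_consensus")
    w_star = next(f.w for f in folds if _round_key(f.w) == modal_key)
    wv = np.array(w_star)
    X = ts.x_matrix
    n = len(ts.xs)
    audit: list[dict] = []
    failing: list[int] = []
    for f in folds:
        omitted = np.asarray(f.omitted, dtype=int)
        retained = np.setdiff1d(np.arange(n), omitted)
        new_train = float(np.min(X[retained] @ wv))
        new_holdout = float(np.min(X[omitted] @ wv))
        conforming = _round_key(f.w) == modal_key
        audit.append(
            {
                "fold": f.fold,
                "conforming": conforming,
                "min_train_score": f.min_train_score,
                "holdout_score": f.holdout_score,
                "min_train_score_under_w_star": new_train,
                "holdout_score_under_w_star": new_holdout,
            }
        )
        if new_train <= 0 or new_holdout <= 0:
            failing.append(f.fold)
    status = "adopted" if not failing else "rejected"
    return ConsolidationResult(
        w_star=w_star, status=status, audit=audit, failing_folds=tuple(failing)
    )


def train_weights(
    sps: Sequence[SearchPackage],
    corpus: Corpus,
    k: int = 10,
    seed: int = 0,
    epsilon: float = DEFAULT_EPSILON,
    w_max: float = DEFAULT_W_MAX,
) -> dict:
    """Full pipeline: first pass → training set → k-fold → consolidation.

    Returns a JSON-serializable report with the consensus weights, the
    achieved minimum margin over all x's, and the per-fold audit.
    """
    entries = first_pass(sps, corpus)
    ts = build_training_set(entries)
    folds = kfold_validate(ts, k=k, seed=seed, epsilon=epsilon, w_max=w_max)
    cons = consolidate(folds, ts)
    w = cons.w_star if cons.w_star is not None else optimize_weights(ts, epsilon, w_max).w
    overall_margin = float(np.min(ts.x_matrix @ np.array(w)))
    return {
        "weights": list(w),
        "margin": overall_margin,
        "epsilon": epsilon,
        "w_max": w_max,
        "seed": seed,
        "k": k,
        "consolidation_status": cons.status,
        "n_x": len(ts.xs),
        "n_rc": len(ts.rcs),
        "n_excluded": len(ts.excluded),
        "n_irrecoverable": len(ts.irrecoverable),
        "fold_audit": cons.audit,
    }


def evaluate_accuracy(
    sps: Sequence[SearchPackage], corpus: Corpus, w
) -> float:
    """Fraction of labeled queries resolved to their ground truth under *w*."""
    from .match import resolve

    if not sps:
        raise ValueError("no queries to evaluate")
    correct = 0
    for sp in sps:
        if sp.label is None:
            raise ValueError("evaluate_accuracy requires labeled queries")
        res = resolve(sp, corpus, w)
        if res.status == "resolved" and res.winner == sp.label.casefold():
            correct += 1
    return correct / len(sps)
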