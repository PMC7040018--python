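"""Two-stage greedy search for the training participants that best separate
two blood conditions.

Exhaustively trying every, say, 20-of-30 training subset would cost
C(30, 20) = 30,045,015 discriminator fits per side.  The greedy search
instead anchors on the first two participants of a condition and grows the
training slice one participant at a time, keeping an addition only if it
strictly lowers the all-sample distance-ratio error:

* stage A: with the full second-condition matrix as its training half,
  scan anchor pairs {a, i} over all i, then greedily extend the best pair;
  repeat for both anchors and keep the better run;
* stage B: fix stage A's winning subset and run the same greedy scan over
  the second condition's participants.

Every candidate is scored by fitting the PCA+LDA discriminator on the
candidate training columns and classifying ALL participants of both
conditions (training included — the published protocol, whose optimistic
bias is documented rather than corrected).  Cost is O(n^2) discriminator
fits per anchor instead of a binomial blow-up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .discriminant import PCALDAClassifier

__all__ = [
    "OptimiserConfig",
    "OptimiserTrace",
    "OptimisationResult",
    "evaluate_training",
    "greedy_stage_A",
    "greedy_stage_B",
    "optimise_training",
    "exhaustive_oracle",
]


@dataclass(frozen=True)
class OptimiserConfig:
    """Greedy-search settings.

    ``starting_anchors`` are (0-based) participant indices seeding the
    scans; ``max_subset_size`` caps growth (None = unbounded).  Additions
    are accepted only on strict error decrease; equal-error candidates are
    broken by lowest participant index, and equal-error final subsets by
    smaller size then lexicographic order.
    """

    max_subset_size: int | None = None
    starting_anchors: tuple[int, int] = (0, 1)
    n_keep: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.starting_anchors)) != len(self.starting_anchors):
            raise ValueError("starting anchors must be distinct")


@dataclass
class OptimiserTrace:
    """Per-evaluation record of the greedy search."""

    records: list[dict] = field(default_factory=list)
    n_evaluations: int = 0

    def log(self, subset_a, subset_b, error, stage) -> None:
        self.n_evaluations += 1
        self.records.append(
            {
                "stage": stage,
                "subset_A": tuple(subset_a),
                "subset_B": tuple(subset_b),
                "error": float(error),
            }
        )

    @property
    def best_error(self) -> float:
        return min(r["error"] for r in self.records)


@dataclass
class OptimisationResult:
    subset_A: tuple[int, ...]
    subset_B: tuple[int, ...]
    error: float
    trace: OptimiserTrace


def evaluate_training(
    train_A: "np.ndarray | list[int]",
    train_B: "np.ndarray | list[int]",
    all_A: np.ndarray,
    all_B: np.ndarray,
    n_keep: int | None = None,
) -> float:
    """Percentage error of a discriminator trained on the given participant
    subsets and validated on every participant of both conditions."""
    train_A = np.asarray(train_A, dtype=int)
    train_B = np.asarray(train_B, dtype=int)
    if train_A.size == 0 or train_B.size == 0:
        raise ValueError("training subsets must be non-empty")
    if train_A.size < 2 or train_B.size < 2:
        raise ValueError("need at least 2 training participants per class for LDA")
    X_train = np.vstack([all_A[train_A], all_B[train_B]])
    y_train = np.concatenate([np.zeros(train_A.size, int), np.ones(train_B.size, int)])
    clf = PCALDAClassifier(n_keep=n_keep).fit(X_train, y_train)
    X_all = np.vstack([all_A, all_B])
    y_all = np.concatenate([np.zeros(len(all_A), int), np.ones(len(all_B), int)])
    return clf.error_rate(X_all, y_all)


def _better(cand: tuple[float, tuple[int, ...]], best: tuple[float, tuple[int, ...]]) -> bool:
    """Tie rule: lower error, then smaller subset, then lexicographically."""
    e1, s1 = cand
    e0, s0 = best
    if e1 != e0:
        return e1 < e0
    if len(s1) != len(s0):
        return len(s1) < len(s0)
    return s1 < s0


def _greedy_one_side(
    evaluate,
    log,
    n_side: int,
    cfg: OptimiserConfig,
    stage: str,
) -> tuple[tuple[int, ...], float]:
    """Anchor-pair scan plus strict-improvement growth over one condition."""
    best: tuple[float, tuple[int, ...]] | None = None
    for anchor in cfg.starting_anchors:
        if anchor >= n_side:
            continue
        # pair scan: {anchor, i} over every other participant
        pair_best: tuple[float, tuple[int, ...]] | None = None
        for i in range(n_side):
            if i == anchor:
                continue
            subset = tuple(sorted((anchor, i)))
            err = evaluate(subset)
            log(subset, err, stage)
            cand = (err, subset)
            if pair_best is None or _better(cand, pair_best):
                pair_best = cand
        if pair_best is None:
            continue
        err, subset = pair_best
        # strict-improvement growth
        while cfg.max_subset_size is None or len(subset) < cfg.max_subset_size:
            step_best: tuple[float, tuple[int, ...]] | None = None
            for i in range(n_side):
                if i in subset:
                    continue
                cand_subset = tuple(sorted(subset + (i,)))
                cand_err = evaluate(cand_subset)
                log(cand_subset, cand_err, stage)
                cand = (cand_err, cand_subset)
                if step_best is None or _better(cand, step_best):
                    step_best = cand
            if step_best is None or step_best[0] >= err:
                break
            err, subset = step_best
        run = (err, subset)
        if best is None or _better(run, best):
            best = run
    if best is None:
        raise ValueError("degenerate cohort: no admissible anchor pair")
    return best[1], best[0]


def greedy_stage_A(
    all_A: np.ndarray,
    all_B: np.ndarray,
    cfg: OptimiserConfig | None = None,
    trace: OptimiserTrace | None = None,
) -> tuple[tuple[int, ...], float, OptimiserTrace]:
    """Find the training subset of condition A, training against all of B."""
    cfg = cfg or OptimiserConfig()
    trace = trace if trace is not None else OptimiserTrace()
    if len(all_A) < 3 or len(all_B) < 3:
        raise ValueError("need at least 3 participants per condition")
    full_B = tuple(range(len(all_B)))

    def evaluate(subset_a):
        return evaluate_training(subset_a, full_B, all_A, all_B, n_keep=cfg.n_keep)

    subset, err = _greedy_one_side(
        evaluate, lambda s, e, stage: trace.log(s, full_B, e, stage), len(all_A), cfg, "A"
    )
    return subset, err, trace


def greedy_stage_B(
    all_A: np.ndarray,
    all_B: np.ndarray,
    best_A: tuple[int, ...],
    cfg: OptimiserConfig | None = None,
    trace: OptimiserTrace | None = None,
) -> tuple[tuple[int, ...], float, OptimiserTrace]:
    """Find the training subset of B with A's training fixed to ``best_A``.

    The stage-A incumbent (best_A vs all of B) stays a candidate, so the
    returned configuration never scores worse than stage A's.
    """
    cfg = cfg or OptimiserConfig()
    trace = trace if trace is not None else OptimiserTrace()
    best_A = tuple(best_A)

    def evaluate(subset_b):
        return evaluate_training(best_A, subset_b, all_A, all_B, n_keep=cfg.n_keep)

    subset, err = _greedy_one_side(
        evaluate, lambda s, e, stage: trace.log(best_A, s, e, stage), len(all_B), cfg, "B"
    )
    full_B = tuple(range(len(all_B)))
    incumbent_err = evaluate(full_B)
    trace.log(best_A, full_B, incumbent_err, "B-incumbent")
    if _better((incumbent_err, full_B), (err, subset)):
        subset, err = full_B, incumbent_err
    return subset, err, trace


def optimise_training(
    all_A: np.ndarray,
    all_B: np.ndarray,
    cfg: OptimiserConfig | None = None,
) -> OptimisationResult:
    """Full two-stage optimisation; deterministic given inputs and config."""
    cfg = cfg or OptimiserConfig()
    trace = OptimiserTrace()
    best_A, _, trace = greedy_stage_A(all_A, all_B, cfg, trace)
    best_B, err, trace = greedy_stage_B(all_A, all_B, best_A, cfg, trace)
    return OptimisationResult(subset_A=best_A, subset_B=best_B, error=err, trace=trace)


def exhaustive_oracle(
    all_A: np.ndarray,
    all_B: np.ndarray,
    subset_size: int,
    budget: int = 100_000,
    n_keep: int | None = None,
) -> tuple[tuple[int, ...], tuple[int, ...], float]:
    """Globally optimal k-subset training pair by brute-force enumeration.

    Intended purely as a small-instance oracle: the request is rejected,
    reporting the combination count, whenever C(n, k) on either side (or
    the pair product) exceeds the budget.
    """
    from itertools import combinations

    nA, nB = len(all_A), len(all_B)
    k = subset_size
    if not 2 <= k <= min(nA, nB):
        raise ValueError(f"subset size {k} out of range")
    cA, cB = math.comb(nA, k), math.comb(nB, k)
    for n, c in ((nA, cA), (nB, cB)):
        if c > budget:
            raise ValueError(
                f"C({n},{k}) = {c} combinations exceeds the oracle budget {budget}"
            )
    if cA * cB > budget:
        raise ValueError(
            f"C({nA},{k})*C({nB},{k}) = {cA * cB} subset pairs exceeds the budget {budget}"
        )
    best: tuple[float, tuple[int, ...], tuple[int, ...]] | None = None
    for sa in combinations(range(nA), k):
        for sb in combinations(range(nB), k):
            err = evaluate_training(sa, sb, all_A, all_B, n_keep=n_keep)
            cand = (err, sa, sb)
            if best is None or cand < best:
                best = cand
    assert best is not None
    return best[1], best[2], best[0]
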