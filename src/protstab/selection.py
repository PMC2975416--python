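"""Wrapper feature-subset selection under the pooled-CV AUC objective.

Three search strategies over the scale registry:

* rank every single scale (one-feature classifiers);
* evaluate the nested prefixes of that ranking (best-1, best-2, ...);
* exhaustively evaluate all subsets of each size up to ``kmax``, with a
  budget cap that falls back to greedy forward selection (flagged as
  approximate) when a size's combination count exceeds what remains.

Every candidate subset within one search is evaluated with the identical
fold partition (same seed), so subset comparisons are paired: ranking
differences reflect the features, not fold re-randomization.  Subsets are
ordered by AUC (descending), with prediction strength and then the
lexicographic subset as tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .dataset import Dataset
from .encoding import FeatureBlocks, precompute_blocks
from .metrics import EvalReport, MetricsError, stratified_folds
from .model import TrainConfig, train_svc
from .scales import ScaleRegistry


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class SearchResult:
    subset: tuple[str, ...]
    report: EvalReport
    rank: int = 0
    exact: bool = True  # False when found by the greedy fallback

    @property
    def objective(self) -> tuple:
        st = self.report.st if self.report.st is not None else -1.0
        return (-self.report.auc, -st, self.subset)


def _sort_results(results: list[SearchResult]) -> list[SearchResult]:
    ordered = sorted(results, key=lambda r: r.objective)
    return [
        SearchResult(r.subset, r.report, rank=i + 1, exact=r.exact)
        for i, r in enumerate(ordered)
    ]


class SubsetEvaluator:
    """Evaluates feature subsets by pooled CV over one fixed fold partition.

    Encoding blocks are precomputed per scale and assembled per subset;
    evaluations are memoized so shared subsets (e.g. singles reused by the
    exhaustive search) cost nothing the second time.
    """

    def __init__(
        self,
        dataset: Dataset,
        registry: ScaleRegistry,
        window_size: int,
        cfg: TrainConfig,
        seed: int | None = None,
        k: int = 5,
        features: tuple[str, ...] | None = None,
    ) -> None:
        self.registry = registry
        self.cfg = cfg
        self.k = k
        self.seed = seed if seed is not None else cfg.seed
        self.blocks: FeatureBlocks = precompute_blocks(
            dataset, window_size, registry, codes=features
        )
        self.codes: tuple[str, ...] = self.blocks.codes
        try:
            self.folds = stratified_folds(self.blocks.y, k, self.seed)
        except MetricsError as exc:
            raise SelectionError(str(exc)) from exc
        self._cache: dict[tuple[str, ...], EvalReport] = {}
        self.n_evaluations = 0

    def evaluate(self, subset) -> EvalReport:
        subset = tuple(subset)
        if len(set(subset)) != len(subset):
            raise SelectionError(f"duplicate features in subset {subset}")
        key = tuple(sorted(subset))
        if key in self._cache:
            return self._cache[key]
        X = self.blocks.assemble(subset)
        y = self.blocks.y
        scores = np.empty(len(y))
        for train_idx, test_idx in self.folds:
            svc = train_svc(X[train_idx], y[train_idx], self.cfg)
            scores[test_idx] = svc.decision_function(X[test_idx])
        report = EvalReport.from_scores(scores, y)
        report.roc_points = []  # drop per-subset ROC detail; keeps logs small
        self._cache[key] = report
        self.n_evaluations += 1
        return report

    def evaluations_frame(self) -> pd.DataFrame:
        rows = []
        for subset, report in self._cache.items():
            row = {"subset": ",".join(subset)}
            row.update(report.to_row())
            rows.append(row)
        return pd.DataFrame(rows)


def rank_single_features(
    dataset: Dataset,
    registry: ScaleRegistry,
    window_size: int = 11,
    cfg: TrainConfig | None = None,
    seed: int | None = None,
    k: int = 5,
    evaluator: SubsetEvaluator | None = None,
) -> list[SearchResult]:
    """One-feature classifier per registered scale, sorted by the objective."""
    cfg = cfg or TrainConfig()
    ev = evaluator or SubsetEvaluator(
        dataset, registry, window_size, cfg, seed=seed, k=k
    )
    results = [SearchResult((code,), ev.evaluate((code,))) for code in ev.codes]
    return _sort_results(results)


def combine_best_singles(
    dataset: Dataset,
    registry: ScaleRegistry,
    ranked: list[SearchResult],
    max_size: int,
    window_size: int = 11,
    cfg: TrainConfig | None = None,
    seed: int | None = None,
    k: int = 5,
    evaluator: SubsetEvaluator | None = None,
) -> list[SearchResult]:
    """Evaluate the nested prefixes of the single-feature ranking.

    Returns ``max_size`` results: best single, best two singles, ... — each
    a superset of the previous one (reported in prefix order, rank by size).
    """
    cfg = cfg or TrainConfig()
    ev = evaluator or SubsetEvaluator(
        dataset, registry, window_size, cfg, seed=seed, k=k
    )
    order = [r.subset[0] for r in ranked]
    if max_size < 1 or max_size > len(order):
        raise SelectionError(f"max_size {max_size} outside 1..{len(order)}")
    out = []
    for size in range(1, max_size + 1):
        subset = tuple(order[:size])
        out.append(SearchResult(subset, ev.evaluate(subset), rank=size))
    return out


@dataclass
class ExhaustiveSearchOutcome:
    """Best subset per size, the all-features control, and the audit log."""

    best_per_size: list[SearchResult]
    all_features: SearchResult
    evaluations: pd.DataFrame = field(repr=False, default=None)  # type: ignore


def exhaustive_search(
    dataset: Dataset,
    registry: ScaleRegistry,
    kmax: int,
    window_size: int = 11,
    cfg: TrainConfig | None = None,
    seed: int | None = None,
    k: int = 5,
    budget: int | None = None,
    features: tuple[str, ...] | None = None,
    evaluator: SubsetEvaluator | None = None,
) -> ExhaustiveSearchOutcome:
    """Brute-force subset search up to size ``kmax`` under an evaluation
    budget.

    For each size ``1..kmax`` every combination is evaluated, unless the
    budget cannot cover that size's combination count — then that size is
    searched greedily (forward selection from the previous best subset) and
    the result is flagged ``exact=False``.  The all-features classifier is
    always evaluated as a control.  All candidates share one fold partition.
    """
    cfg = cfg or TrainConfig()
    ev = evaluator or SubsetEvaluator(
        dataset, registry, window_size, cfg, seed=seed, k=k, features=features
    )
    codes = ev.codes
    if not (1 <= kmax <= len(codes)):
        raise SelectionError(f"kmax {kmax} outside 1..{len(codes)}")
    from math import comb

    if budget is not None and budget < len(codes):
        raise SelectionError(
            f"budget {budget} cannot cover the {len(codes)} size-1 evaluations"
        )
    spent = 0
    best_per_size: list[SearchResult] = []
    prev_best: tuple[str, ...] = ()
    for size in range(1, kmax + 1):
        n_combos = comb(len(codes), size)
        exhaustive_ok = budget is None or spent + n_combos <= budget
        if exhaustive_ok:
            candidates = [tuple(c) for c in combinations(codes, size)]
            exact = True
        else:
            # greedy forward step from the previous best subset
            candidates = [
                prev_best + (code,) for code in codes if code not in prev_best
            ]
            exact = False
        results = [
            SearchResult(s, ev.evaluate(s), exact=exact) for s in candidates
        ]
        spent = ev.n_evaluations
        best = _sort_results(results)[0]
        best = SearchResult(best.subset, best.report, rank=size, exact=exact)
        best_per_size.append(best)
        prev_best = best.subset
    all_report = ev.evaluate(codes)
    outcome = ExhaustiveSearchOutcome(
        best_per_size=best_per_size,
        all_features=SearchResult(codes, all_report, rank=0),
        evaluations=ev.evaluations_frame(),
    )
    return outcome


def results_frame(results: list[SearchResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"subset": ",".join(r.subset), "rank": r.rank, "exact": r.exact}
        row.update(r.report.to_row())
        rows.append(row)
    return pd.DataFrame(rows)
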