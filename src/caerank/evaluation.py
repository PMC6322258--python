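"""Ranking evaluation: AP/MAP, P@X, %P@X>0, cross-validation, t-tests.

For article *i* with k_i gold CAEs among its ranked candidates, average
precision is AP(i) = (1/k_i) Σ_j j / Seen_i(j), where Seen_i(j) is the
rank of the j-th best-ranked CAE; MAP averages AP over articles.  P@X is
the fraction of the top X ranked entities that are CAEs (denominator X
even when fewer candidates exist), and %P@X>0 the percentage of articles
with at least one CAE in the top X.  Score ties are broken
deterministically (entity id ascending) before any metric is computed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import numpy as np
from scipy import stats as sps

from .corpus_io import GoldStandard
from .entity_recognition import AnnotatedArticle
from .fusion import RankedList, RankerModel, ScorerConfig, ScorerSpec, rank_article, train_ranker
from .indicators import build_features, compute_corpus_stats

logger = logging.getLogger(__name__)

P_AT_X_VALUES = (1, 2, 3, 5)
PCT_X_VALUES = (1, 2, 3)


def average_precision(ranked: RankedList, gold_caes: Set[str]) -> float:
    """AP for one article; gold CAEs absent from the candidate list are
    dropped (logged); raises if no gold CAE is among the candidates."""
    present = [e for e in ranked.entity_ids if e in gold_caes]
    dropped = len(gold_caes) - len(present)
    if dropped:
        logger.debug(
            "article %s: %d gold CAEs not among candidates", ranked.article_id, dropped
        )
    if not present:
        raise ValueError(
            f"article {ranked.article_id!r}: no gold CAE among ranked candidates"
        )
    ranks = sorted(
        rank for eid, _, rank in ranked.entries if eid in gold_caes
    )
    return sum((j + 1) / r for j, r in enumerate(ranks)) / len(ranks)


def precision_at_x(ranked: RankedList, gold_caes: Set[str], x: int) -> float:
    if x < 1:
        raise ValueError("X must be >= 1")
    return len([e for e in ranked.top(x) if e in gold_caes]) / x


@dataclass
class EvalReport:
    """Pooled ranking metrics over a set of test articles."""

    map: float
    avg_p_at: Dict[int, float]
    pct_p_at_positive: Dict[int, float]
    per_article_ap: Dict[str, float]
    n_articles: int
    n_excluded_no_cae: int = 0
    n_excluded_no_candidates: int = 0
    n_dropped_gold: int = 0

    def to_dict(self) -> dict:
        return {
            "map": self.map,
            "avg_p_at": {str(k): v for k, v in self.avg_p_at.items()},
            "pct_p_at_positive": {
                str(k): v for k, v in self.pct_p_at_positive.items()
            },
            "n_articles": self.n_articles,
            "n_excluded_no_cae": self.n_excluded_no_cae,
            "n_excluded_no_candidates": self.n_excluded_no_candidates,
            "n_dropped_gold": self.n_dropped_gold,
            "per_article_ap": dict(sorted(self.per_article_ap.items())),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def summary(self) -> str:
        lines = [f"articles evaluated: {self.n_articles}", f"MAP: {self.map:.4f}"]
        for x in sorted(self.avg_p_at):
            lines.append(f"Average P@{x}: {self.avg_p_at[x]:.4f}")
        for x in sorted(self.pct_p_at_positive):
            lines.append(f"%P@{x}>0: {self.pct_p_at_positive[x]:.2f}")
        if self.n_excluded_no_cae or self.n_excluded_no_candidates:
            lines.append(
                f"excluded: {self.n_excluded_no_candidates} without candidates, "
                f"{self.n_excluded_no_cae} without a CAE among candidates"
            )
        return "\n".join(lines)


def evaluate(
    rankings: Mapping[str, RankedList], gold: GoldStandard
) -> EvalReport:
    """Pool per-article metrics.  Articles with no candidates, or whose
    gold CAEs are all absent from the candidates, are excluded and
    counted; an article missing from the gold standard is an error."""
    per_ap: Dict[str, float] = {}
    p_at: Dict[int, List[float]] = {x: [] for x in P_AT_X_VALUES}
    pct_hits: Dict[int, int] = {x: 0 for x in PCT_X_VALUES}
    n_no_cae = n_no_cand = n_dropped = 0

    for aid in sorted(rankings):
        ranked = rankings[aid]
        if aid not in gold:
            raise ValueError(f"article {aid!r} has no gold annotation")
        caes = gold[aid]
        if not ranked.entries:
            n_no_cand += 1
            continue
        present = set(ranked.entity_ids) & caes
        n_dropped += len(caes) - len(present)
        if not present:
            n_no_cae += 1
            continue
        per_ap[aid] = average_precision(ranked, caes)
        for x in P_AT_X_VALUES:
            p_at[x].append(precision_at_x(ranked, caes, x))
        for x in PCT_X_VALUES:
            if precision_at_x(ranked, caes, x) > 0:
                pct_hits[x] += 1

    n = len(per_ap)
    if n == 0:
        raise ValueError("no article could be evaluated")
    return EvalReport(
        map=float(np.mean(list(per_ap.values()))),
        avg_p_at={x: float(np.mean(v)) for x, v in p_at.items()},
        pct_p_at_positive={x: 100.0 * pct_hits[x] / n for x in PCT_X_VALUES},
        per_article_ap=per_ap,
        n_articles=n,
        n_excluded_no_cae=n_no_cae,
        n_excluded_no_candidates=n_no_cand,
        n_dropped_gold=n_dropped,
    )


@dataclass
class FoldPlan:
    """Seeded even partition of articles into cross-validation folds."""

    assignments: Dict[str, int]
    n_folds: int
    seed: int

    def fold_ids(self, fold: int) -> List[str]:
        return sorted(a for a, f in self.assignments.items() if f == fold)


def make_folds(
    article_ids: Sequence[str], n_folds: int = 5, seed: int = 0
) -> FoldPlan:
    ids = list(article_ids)
    if len(ids) < n_folds:
        raise ValueError(
            f"corpus of {len(ids)} articles is too small for {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(sorted(ids)))
    assignments = {aid: i % n_folds for i, aid in enumerate(order)}
    return FoldPlan(assignments, n_folds, seed)


@dataclass
class LearnedScorer:
    """Scorer spec for cross_validate: a pairwise ranker re-trained on the
    training folds with the given feature subset."""

    features: Tuple[str, ...]
    regularization: float = 1.0
    seed: int = 0


def rank_corpus(
    annotated: Sequence[AnnotatedArticle],
    scorer: ScorerSpec,
    stats,
    config: Optional[ScorerConfig] = None,
    seed: int = 0,
) -> Dict[str, RankedList]:
    return {
        ann.article_id: rank_article(ann, scorer, stats, config=config, seed=seed)
        for ann in annotated
    }


def cross_validate(
    annotated: Sequence[AnnotatedArticle],
    gold: GoldStandard,
    scorer: Union[ScorerSpec, LearnedScorer],
    plan: FoldPlan,
    config: Optional[ScorerConfig] = None,
    seed: int = 0,
) -> EvalReport:
    """K-fold protocol: per fold, corpus statistics (and the model, for a
    :class:`LearnedScorer`) come from the training folds only; held-out
    rankings are pooled and evaluated once."""
    by_id = {a.article_id: a for a in annotated}
    pooled: Dict[str, RankedList] = {}
    for fold in range(plan.n_folds):
        test_ids = [i for i in plan.fold_ids(fold) if i in by_id]
        train_anns = [
            a for a in annotated if plan.assignments.get(a.article_id) != fold
        ]
        if not train_anns or not test_ids:
            raise ValueError(f"fold {fold}: empty training or test part")
        stats = compute_corpus_stats(train_anns)
        if isinstance(scorer, LearnedScorer):
            feats = build_features(train_anns, stats)
            try:
                model: ScorerSpec = train_ranker(
                    feats,
                    gold,
                    feature_subset=scorer.features,
                    regularization=scorer.regularization,
                    seed=scorer.seed,
                )
            except ValueError as exc:
                raise ValueError(f"fold {fold}: training failed: {exc}") from exc
        else:
            model = scorer
        for aid in test_ids:
            pooled[aid] = rank_article(
                by_id[aid], model, stats, config=config, seed=seed
            )
    return evaluate(pooled, gold)


def paired_ttest(
    ap_a: Mapping[str, float],
    ap_b: Mapping[str, float],
    alpha: float = 0.01,
) -> Tuple[float, float, bool]:
    """Two-sided paired t-test on per-article metric values.

    Returns (t statistic, p value, significant at ``alpha``).  Article
    sets must match; all-zero differences give t = 0, p = 1.
    """
    if set(ap_a) != set(ap_b):
        raise ValueError("paired t-test requires identical article sets")
    keys = sorted(ap_a)
    if len(keys) < 2:
        raise ValueError("paired t-test requires at least 2 articles")
    a = np.array([ap_a[k] for k in keys])
    b = np.array([ap_b[k] for k in keys])
    if np.allclose(a, b):
        return 0.0, 1.0, False
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p), bool(p < alpha)


def significance_matrix(
    per_article: Mapping[str, Mapping[str, float]], alpha: float = 0.01
) -> Dict[str, Dict[str, dict]]:
    """Pairwise scorer-vs-scorer paired t-tests on shared articles."""
    out: Dict[str, Dict[str, dict]] = {}
    names = sorted(per_article)
    for a in names:
        out[a] = {}
        for b in names:
            if a == b:
                continue
            shared = set(per_article[a]) & set(per_article[b])
            t, p, sig = paired_ttest(
                {k: per_article[a][k] for k in shared},
                {k: per_article[b][k] for k in shared},
                alpha=alpha,
            )
            out[a][b] = {"t": t, "p": p, "significant": sig}
    return out
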