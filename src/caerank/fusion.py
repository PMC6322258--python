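"""Indicator fusion: fixed-formula scorers and learned pairwise ranking.

Typical fusion strategies
-------------------------
* ``TFIDF`` — TF × IDF.
* ``BM25e`` — TF(k1+1) / (TF + k1(1 − b + b·|a|/avgal)) · IDF, the BM25
  saturation applied to an entity; defaults k1=1.2, b=0.75.
* ``ESe``  — [TF / (TF + 0.45·sqrt(|a|/avgdl))] · sqrt((c(e,C)/DF(e))³ ·
  N/DF(e)): frequency saturation times a concentration/rareness factor.
* ``CCSEe`` — positional linear weights for the goal (title), background
  (leading sentences) and conclusion (trailing sentences) zones, summed
  over occurrences.
* ``eGRABe-X`` — one point each for TF ≥ 3, a title occurrence, and an
  occurrence in the first/last X abstract sentences.

Learning-based fusion
---------------------
``train_ranker`` fits a linear large-margin model on pairwise feature
differences: within each training article every (CAE, non-CAE) candidate
pair contributes the difference of their z-scored feature vectors with
label +1 and its negation with label −1 — the RankingSVM objective family
realised as a linear SVM on difference vectors.  The ``ALL`` feature set
is {TF, IDF, CoOcc, AvgTF, TITLE, Abstract2}; ablations ``ALL-X`` drop
one member (``ALL_MINUS_ABSTRACT2`` being the strongest configuration in
the original study).
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
from sklearn.svm import LinearSVC

from .corpus_io import GoldStandard
from .entity_recognition import AnnotatedArticle
from .indicators import (
    FEATURE_NAMES,
    CorpusStats,
    FeatureVector,
    feature_vector,
)

logger = logging.getLogger(__name__)

ALL_FEATURES = ("tf", "idf", "cooc", "avg_tf", "title", "abstract_2")
ALL_MINUS_ABSTRACT2 = ("tf", "idf", "cooc", "avg_tf", "title")


def ablation(feature: str, base: Sequence[str] = ALL_FEATURES) -> Tuple[str, ...]:
    """The ALL-X configuration: ``base`` without ``feature``."""
    if feature not in base:
        raise ValueError(f"{feature!r} not in feature set {base}")
    return tuple(f for f in base if f != feature)


@dataclass
class ScorerConfig:
    """Parameters of the fixed-formula scorers."""

    k1: float = 1.2
    b: float = 0.75
    goal_w: float = 1.0
    # positional weights: background_profile[i] weights the (i+1)-th
    # abstract sentence from the start, conclusion_profile[i] the
    # (i+1)-th sentence from the end
    background_profile: Tuple[float, ...] = (1.0, 2 / 3, 1 / 3)
    conclusion_profile: Tuple[float, ...] = (1.0, 2 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if self.k1 < 0 or not (0 <= self.b <= 1):
            raise ValueError("require k1 >= 0 and 0 <= b <= 1")
        if any(w < 0 for w in self.background_profile + self.conclusion_profile):
            raise ValueError("positional weight profiles must be non-negative")


def tfidf_score(fv: FeatureVector) -> float:
    return fv.tf * fv.idf


def bm25e_score(
    fv: FeatureVector,
    article_len: float,
    stats: CorpusStats,
    k1: float = 1.2,
    b: float = 0.75,
) -> float:
    denom = fv.tf + k1 * (1 - b + b * article_len / stats.avg_article_len)
    return fv.tf * (k1 + 1) / denom * fv.idf


def ese_score(
    fv: FeatureVector, article_len: float, stats: CorpusStats
) -> float:
    df_e = stats.df.get(fv.entity_id, 0)
    if df_e == 0:
        raise ValueError(
            f"ESe undefined for entity {fv.entity_id!r}: DF = 0 in this collection"
        )
    c_e = stats.total_count[fv.entity_id]
    sat = fv.tf / (fv.tf + 0.45 * np.sqrt(article_len / stats.avg_article_len))
    conc = np.sqrt((c_e / df_e) ** 3 * stats.num_articles / df_e)
    return float(sat * conc)


def ccsee_score(
    ann: AnnotatedArticle, entity_id: str, cfg: Optional[ScorerConfig] = None
) -> float:
    """Goal/background/conclusion positional score, summed over every
    occurrence so repeated mentions in different zones amplify."""
    cfg = cfg or ScorerConfig()
    n = ann.n_sentences
    score = 0.0
    for m in ann.mentions_of(entity_id):
        if m.in_title:
            score += cfg.goal_w
            continue
        if m.location < len(cfg.background_profile):
            score += cfg.background_profile[m.location]
        from_end = n - 1 - m.location
        if from_end < len(cfg.conclusion_profile):
            score += cfg.conclusion_profile[from_end]
    return score


def egrabe_score(fv: FeatureVector, x: int) -> int:
    if x not in (1, 2, 3):
        raise ValueError("eGRABe X must be 1, 2 or 3")
    return int(fv.tf >= 3) + fv.title + fv.value(f"abstract_{x}")


@dataclass
class RankerModel:
    """Linear pairwise ranking model on z-scored indicator features."""

    feature_names: Tuple[str, ...]
    weights: Tuple[float, ...]
    means: Tuple[float, ...]
    sds: Tuple[float, ...]
    regularization: float = 1.0
    training_meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.feature_names)
        if not (len(self.weights) == len(self.means) == len(self.sds) == n):
            raise ValueError("feature_names/weights/means/sds length mismatch")

    def score(self, fv: FeatureVector) -> float:
        total = 0.0
        for name, w, mu, sd in zip(
            self.feature_names, self.weights, self.means, self.sds
        ):
            if sd > 0:
                total += w * (fv.value(name) - mu) / sd
        return total

    def to_json(self, path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "weights": list(self.weights),
            "means": list(self.means),
            "sds": list(self.sds),
            "regularization": self.regularization,
            "training_meta": self.training_meta,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RankerModel":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            feature_names=tuple(d["feature_names"]),
            weights=tuple(d["weights"]),
            means=tuple(d["means"]),
            sds=tuple(d["sds"]),
            regularization=d.get("regularization", 1.0),
            training_meta=d.get("training_meta", {}),
        )


def train_ranker(
    features: Sequence[FeatureVector],
    gold: GoldStandard,
    feature_subset: Sequence[str] = ALL_FEATURES,
    regularization: float = 1.0,
    seed: int = 0,
) -> RankerModel:
    """Fit the pairwise linear ranker.

    Articles without at least one CAE candidate and one non-CAE candidate
    carry no ranking information and are skipped (count logged).
    """
    feature_subset = tuple(feature_subset)
    unknown = set(feature_subset) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}")

    by_article: Dict[str, List[FeatureVector]] = {}
    for fv in features:
        by_article.setdefault(fv.article_id, []).append(fv)

    X_rows: List[List[float]] = []
    usable_pairs: List[Tuple[List[float], List[float]]] = []
    skipped = 0
    for aid in sorted(by_article):
        fvs = by_article[aid]
        caes = gold.get(aid, set())
        pos = [fv for fv in fvs if fv.entity_id in caes]
        neg = [fv for fv in fvs if fv.entity_id not in caes]
        if not pos or not neg:
            skipped += 1
            continue
        for fv in fvs:
            X_rows.append(fv.as_array(feature_subset))
        for p in pos:
            for q in neg:
                usable_pairs.append(
                    (p.as_array(feature_subset), q.as_array(feature_subset))
                )
    if skipped:
        logger.info("train_ranker: skipped %d articles without usable pairs", skipped)
    if not usable_pairs:
        raise ValueError("no usable (CAE, non-CAE) training pairs")

    X = np.asarray(X_rows, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    scale = np.where(sds > 0, sds, 1.0)

    diffs = []
    labels = []
    for p, q in usable_pairs:
        d = (np.asarray(p) - np.asarray(q)) / scale
        diffs.append(d)
        labels.append(1)
        diffs.append(-d)
        labels.append(-1)
    D = np.asarray(diffs)
    y = np.asarray(labels)

    clf = LinearSVC(
        C=regularization,
        fit_intercept=False,
        loss="squared_hinge",
        dual=False,
        max_iter=20000,
        tol=1e-10,
        random_state=seed,
    )
    clf.fit(D, y)
    weights = clf.coef_[0]
    # constant features contribute nothing
    weights = np.where(sds > 0, weights, 0.0)

    return RankerModel(
        feature_names=feature_subset,
        weights=tuple(float(w) for w in weights),
        means=tuple(float(m) for m in means),
        sds=tuple(float(s) for s in sds),
        regularization=regularization,
        training_meta={
            "seed": seed,
            "n_pairs": len(usable_pairs),
            "n_articles": len(by_article) - skipped,
            "skipped_articles": skipped,
        },
    )


@dataclass
class RankedList:
    """Per-article ranking: entries are (entity_id, score, rank) with
    scores non-increasing and ties broken by entity_id ascending."""

    article_id: str
    entries: List[Tuple[str, float, int]]

    @property
    def entity_ids(self) -> List[str]:
        return [e for e, _, _ in self.entries]

    def top(self, k: int) -> List[str]:
        return self.entity_ids[:k]


INDICATOR_SCORERS = (
    "tf", "idf", "cooc", "avgtf", "title",
    "abstract1", "abstract2", "abstract3",
)
TYPICAL_SCORERS = (
    "tfidf", "bm25e", "ese", "ccsee", "egrabe1", "egrabe2", "egrabe3",
)

ScorerSpec = Union[str, RankerModel]

_FEATURE_OF_SCORER = {
    "tf": "tf", "idf": "idf", "cooc": "cooc", "avgtf": "avg_tf",
    "title": "title", "abstract1": "abstract_1", "abstract2": "abstract_2",
    "abstract3": "abstract_3",
}


def _stable_hash(s: str) -> int:
    return zlib.crc32(s.encode("utf-8"))


def rank_article(
    ann: AnnotatedArticle,
    scorer: ScorerSpec,
    stats: CorpusStats,
    config: Optional[ScorerConfig] = None,
    seed: int = 0,
) -> RankedList:
    """Score and rank an article's candidate entities.

    ``scorer`` is an indicator name, a typical-fusion name, ``"random"``
    (seeded, reproducible per article) or a trained :class:`RankerModel`.
    """
    config = config or ScorerConfig()
    candidates = sorted(ann.candidates)
    if not candidates:
        logger.warning("article %s: ranking an empty candidate set", ann.article_id)
        return RankedList(ann.article_id, [])

    scores: Dict[str, float] = {}
    if isinstance(scorer, RankerModel):
        for eid in candidates:
            scores[eid] = scorer.score(feature_vector(eid, ann, stats))
    elif scorer == "random":
        rng = np.random.default_rng([seed, _stable_hash(ann.article_id)])
        vals = rng.random(len(candidates))
        scores = dict(zip(candidates, vals))
    elif scorer in _FEATURE_OF_SCORER:
        feat = _FEATURE_OF_SCORER[scorer]
        for eid in candidates:
            scores[eid] = float(feature_vector(eid, ann, stats).value(feat))
    elif scorer in TYPICAL_SCORERS:
        for eid in candidates:
            fv = feature_vector(eid, ann, stats)
            if scorer == "tfidf":
                scores[eid] = tfidf_score(fv)
            elif scorer == "bm25e":
                scores[eid] = bm25e_score(
                    fv, ann.token_count, stats, config.k1, config.b
                )
            elif scorer == "ese":
                try:
                    scores[eid] = ese_score(fv, ann.token_count, stats)
                except ValueError:
                    # entity unseen in (training) stats: saturation term only
                    scores[eid] = fv.tf / (fv.tf + 0.45)
            elif scorer == "ccsee":
                scores[eid] = ccsee_score(ann, eid, config)
            else:  # egrabeX
                scores[eid] = float(egrabe_score(fv, int(scorer[-1])))
    else:
        raise ValueError(f"unknown scorer {scorer!r}")

    ordered = sorted(candidates, key=lambda e: (-scores[e], e))
    entries = [(e, float(scores[e]), r) for r, e in enumerate(ordered, start=1)]
    return RankedList(ann.article_id, entries)
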