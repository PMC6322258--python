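"""Corpus statistics and the six per-entity statistical indicators.

For an entity *e* in article *a* within a collection *C*:

* ``TF(e,a)`` — number of times *e* appears in *a* (title + abstract);
* ``IDF(e)`` — log2((|A|+1)/(DF(e)+1)), rareness over the collection,
  with +1 smoothing so unseen entities stay finite;
* ``CoOcc(e,a)`` — sum over the article's other candidates *x* of
  |S_e∩x(a)| / |S_e(a)|, where S_e(a) is the set of abstract sentences
  mentioning *e*; 0 for title-only entities;
* ``AvgTF(e)`` — c(e,C)/DF(e), the micro-average per-article frequency
  (concentration) of *e* across the collection;
* ``TITLE(e,a)`` — 1 iff *e* appears in the title;
* ``AbstractX(e,a)`` — 1 iff *e* appears in the first X or last X
  abstract sentences (X in {1,2,3}).

Statistics can be computed on a training subset (cross-validation mode,
no test leakage) or on the whole collection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import pandas as pd

from .entity_recognition import AnnotatedArticle

FEATURE_NAMES = (
    "tf", "idf", "cooc", "avg_tf", "title",
    "abstract_1", "abstract_2", "abstract_3",
)


@dataclass
class CorpusStats:
    """Collection-level counts: |A|, DF(e), c(e,C) and average article
    length in tokens (avgal / avgdl)."""

    num_articles: int
    df: Dict[str, int]
    total_count: Dict[str, int]
    avg_article_len: float


def compute_corpus_stats(annotated: Sequence[AnnotatedArticle]) -> CorpusStats:
    if not annotated:
        raise ValueError("cannot compute corpus statistics on an empty collection")
    df: Dict[str, int] = {}
    total: Dict[str, int] = {}
    for ann in annotated:
        counts: Dict[str, int] = {}
        for m in ann.mentions:
            counts[m.entity_id] = counts.get(m.entity_id, 0) + 1
        for eid, c in counts.items():
            df[eid] = df.get(eid, 0) + 1
            total[eid] = total.get(eid, 0) + c
    avg_len = sum(a.token_count for a in annotated) / len(annotated)
    return CorpusStats(len(annotated), df, total, avg_len)


def _require_candidate(entity_id: str, ann: AnnotatedArticle) -> None:
    if entity_id not in ann.candidates:
        raise ValueError(
            f"entity {entity_id!r} is not a candidate in article {ann.article_id!r}"
        )


def tf(entity_id: str, ann: AnnotatedArticle) -> int:
    """TF(e,a): mention count in title + abstract."""
    _require_candidate(entity_id, ann)
    return len(ann.mentions_of(entity_id))


def idf(entity_id: str, stats: CorpusStats) -> float:
    """IDF(e) = log2((|A|+1)/(DF(e)+1)); DF=0 for entities unseen in C."""
    df_e = stats.df.get(entity_id, 0)
    return math.log2((stats.num_articles + 1) / (df_e + 1))


def cooc(entity_id: str, ann: AnnotatedArticle) -> float:
    """CoOcc(e,a) = Σ_{x≠e} |S_e∩x(a)| / |S_e(a)| over co-candidates x.

    Zero when the entity appears in no abstract sentence (title-only) or
    when it is the article's sole candidate.
    """
    _require_candidate(entity_id, ann)
    s_e = ann.sentence_set(entity_id)
    if not s_e:
        return 0.0
    total = 0.0
    for other in ann.candidates:
        if other == entity_id:
            continue
        s_x = ann.sentence_set(other)
        total += len(s_e & s_x) / len(s_e)
    return total


def avg_tf(entity_id: str, stats: CorpusStats) -> float:
    """AvgTF(e) = c(e,C)/DF(e); undefined (error) for unseen entities."""
    df_e = stats.df.get(entity_id, 0)
    if df_e == 0:
        raise ValueError(
            f"AvgTF undefined for entity {entity_id!r}: DF = 0 in this collection"
        )
    return stats.total_count[entity_id] / df_e


def title_flag(entity_id: str, ann: AnnotatedArticle) -> int:
    _require_candidate(entity_id, ann)
    return int(any(m.in_title for m in ann.mentions_of(entity_id)))


def abstract_x(entity_id: str, ann: AnnotatedArticle, x: int) -> int:
    """1 iff the entity appears in the first X or last X abstract
    sentences.  Short abstracts (<= 2X sentences) make every
    abstract-located entity eligible."""
    if x < 1:
        raise ValueError("X must be >= 1")
    _require_candidate(entity_id, ann)
    n = ann.n_sentences
    for m in ann.mentions_of(entity_id):
        if m.in_title:
            continue
        if m.location < x or m.location >= n - x:
            return 1
    return 0


@dataclass
class FeatureVector:
    """Indicator values for one (entity, article) pair."""

    entity_id: str
    article_id: str
    tf: int
    idf: float
    cooc: float
    avg_tf: float
    title: int
    abstract_1: int
    abstract_2: int
    abstract_3: int

    def value(self, name: str) -> float:
        return getattr(self, name)

    def as_array(self, names: Sequence[str] = FEATURE_NAMES) -> List[float]:
        return [float(getattr(self, n)) for n in names]


def feature_vector(
    entity_id: str, ann: AnnotatedArticle, stats: CorpusStats
) -> FeatureVector:
    """All six Table-of-indicators values for one candidate.

    For entities unseen in the statistics collection (possible when stats
    come from training folds only) AvgTF falls back to the entity's TF in
    this article — its concentration estimated from the only article
    available — keeping every feature finite.
    """
    t = tf(entity_id, ann)
    try:
        a_tf = avg_tf(entity_id, stats)
    except ValueError:
        a_tf = float(t)
    return FeatureVector(
        entity_id=entity_id,
        article_id=ann.article_id,
        tf=t,
        idf=idf(entity_id, stats),
        cooc=cooc(entity_id, ann),
        avg_tf=a_tf,
        title=title_flag(entity_id, ann),
        abstract_1=abstract_x(entity_id, ann, 1),
        abstract_2=abstract_x(entity_id, ann, 2),
        abstract_3=abstract_x(entity_id, ann, 3),
    )


def build_features(
    annotated: Iterable[AnnotatedArticle], stats: CorpusStats
) -> List[FeatureVector]:
    """One FeatureVector per (candidate entity, article), ordered by
    (article_id, entity_id) for determinism."""
    out: List[FeatureVector] = []
    for ann in sorted(annotated, key=lambda a: a.article_id):
        for eid in sorted(ann.candidates):
            out.append(feature_vector(eid, ann, stats))
    return out


def features_to_frame(features: Sequence[FeatureVector]) -> pd.DataFrame:
    """Tabular view (fixed column order) for TSV export and inspection."""
    cols = ["article_id", "entity_id", *FEATURE_NAMES]
    rows = [
        [fv.article_id, fv.entity_id, *fv.as_array()] for fv in features
    ]
    return pd.DataFrame(rows, columns=cols)
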