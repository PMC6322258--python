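"""Distribution / probability-gain analysis and frequency–recency maps.

For an indicator, candidate (entity, article) pairs are binned by the
indicator value (20 equal-width bins over [0, max]; integer bins for TF).
Per bin *i*:

* P_i(CAE)    = CAEs in bin i / total CAEs,
* P_i(NonCAE) = non-CAEs in bin i / total non-CAEs,
* ProbGain_i  = CAE fraction within bin i − overall CAE rate,

so a positive ProbGain marks indicator ranges where curated entities are
over-represented.  The positional variant bins mention positions within
abstracts (words or sentences, 20 relative parts) with title mentions as
a separate leading category.

The frequency–recency map scatters predicted CAEs by the number of
articles predicting them (frequency) against the mean publication year
of those articles (recency), split into four threshold-defined zones for
exploratory curation; a focused view rebuilds the map over the articles
sharing one entity of interest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .corpus_io import GoldStandard
from .entity_recognition import AnnotatedArticle
from .fusion import ScorerConfig, ScorerSpec, rank_article
from .indicators import CorpusStats

logger = logging.getLogger(__name__)

TITLE_PART = -1  # positional category for title mentions


@dataclass
class DistributionProfile:
    """Binned CAE / non-CAE prevalence and probability gain."""

    indicator: str
    bin_edges: np.ndarray  # len n_bins + 1 (integer bins: edges at k-0.5)
    bin_labels: List[str]
    cae_counts: np.ndarray
    noncae_counts: np.ndarray
    overall_cae_rate: float

    @property
    def p_cae(self) -> np.ndarray:
        total = self.cae_counts.sum()
        return self.cae_counts / total if total else self.cae_counts * 0.0

    @property
    def p_noncae(self) -> np.ndarray:
        total = self.noncae_counts.sum()
        return self.noncae_counts / total if total else self.noncae_counts * 0.0

    @property
    def prob_gain(self) -> np.ndarray:
        """Per-bin CAE fraction minus the overall CAE rate; NaN on empty
        bins (the gain is undefined there)."""
        totals = self.cae_counts + self.noncae_counts
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, self.cae_counts / np.maximum(totals, 1), np.nan)
        frac = np.where(totals > 0, frac, np.nan)
        return frac - self.overall_cae_rate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bin_labels,
                "cae_count": self.cae_counts.astype(int),
                "noncae_count": self.noncae_counts.astype(int),
                "p_cae": self.p_cae,
                "p_noncae": self.p_noncae,
                "prob_gain": self.prob_gain,
            }
        )


def bin_indicator_distribution(
    values: Sequence[float],
    is_cae: Sequence[bool],
    indicator: str,
    n_bins: int = 20,
) -> DistributionProfile:
    """Bin indicator values of candidate entities and compute the
    prevalence probabilities and probability gain per bin.

    TF (integer-valued) gets one bin per integer value; other indicators
    get ``n_bins`` equal-width bins over [0, observed max].
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(is_cae, dtype=bool)
    if values.shape != labels.shape or values.size == 0:
        raise ValueError("values and labels must be equal-length and non-empty")
    if labels.all() or not labels.any():
        raise ValueError("need at least one CAE and one non-CAE")

    if indicator.lower() == "tf":
        vmax = int(values.max())
        edges = np.arange(0.5, vmax + 1.5)  # bins centred on 1..max
        bin_labels = [str(k) for k in range(1, vmax + 1)]
        idx = np.clip(values.astype(int) - 1, 0, vmax - 1)
        n = vmax
    else:
        vmax = float(values.max())
        if vmax <= 0:
            vmax = 1.0
        edges = np.linspace(0.0, vmax, n_bins + 1)
        idx = np.minimum((values / vmax * n_bins).astype(int), n_bins - 1)
        idx = np.where(values < 0, 0, idx)
        bin_labels = [
            f"({100 * edges[i] / vmax:.0f}%, {100 * edges[i + 1] / vmax:.0f}%]"
            for i in range(n_bins)
        ]
        n = n_bins

    cae_counts = np.bincount(idx[labels], minlength=n).astype(float)
    non_counts = np.bincount(idx[~labels], minlength=n).astype(float)
    return DistributionProfile(
        indicator=indicator,
        bin_edges=edges,
        bin_labels=bin_labels,
        cae_counts=cae_counts,
        noncae_counts=non_counts,
        overall_cae_rate=float(labels.mean()),
    )


def positional_distribution(
    annotated: Sequence[AnnotatedArticle],
    gold: GoldStandard,
    unit: str = "sentences",
    n_parts: int = 20,
) -> DistributionProfile:
    """Bin mention positions into ``n_parts`` relative parts of the
    abstract (words or sentences); title mentions form a separate leading
    category.  Each mention is one observation, labelled CAE when its
    entity is a gold CAE of the article."""
    if unit not in ("words", "sentences"):
        raise ValueError("unit must be 'words' or 'sentences'")
    cae_counts = np.zeros(n_parts + 1)  # part 0 = TITLE
    non_counts = np.zeros(n_parts + 1)
    for ann in annotated:
        caes = gold.get(ann.article_id, set())
        for m in ann.mentions:
            is_cae = m.entity_id in caes
            if m.in_title:
                part = 0
            elif unit == "sentences":
                if ann.n_sentences == 0:
                    continue
                part = 1 + min(
                    int(m.location / ann.n_sentences * n_parts), n_parts - 1
                )
            else:
                if ann.abstract_token_count == 0 or m.abstract_pos is None:
                    continue
                part = 1 + min(
                    int(m.abstract_pos / ann.abstract_token_count * n_parts),
                    n_parts - 1,
                )
            if is_cae:
                cae_counts[part] += 1
            else:
                non_counts[part] += 1
    total = cae_counts.sum() + non_counts.sum()
    if total == 0 or cae_counts.sum() == 0 or non_counts.sum() == 0:
        raise ValueError("need mentions of both CAEs and non-CAEs")
    labels = ["TITLE"] + [
        f"part {i + 1}/{n_parts}" for i in range(n_parts)
    ]
    return DistributionProfile(
        indicator=f"position ({unit})",
        bin_edges=np.arange(-1.5, n_parts + 0.5),
        bin_labels=labels,
        cae_counts=cae_counts,
        noncae_counts=non_counts,
        overall_cae_rate=float(cae_counts.sum() / total),
    )


@dataclass
class MapPoint:
    entity_id: str
    frequency: int  # number of articles with the entity as predicted CAE
    recency: float  # mean publication year of those articles
    zone: str  # I..IV


@dataclass
class FrequencyRecencyMap:
    """Scatter of predicted CAEs by article frequency vs mean year."""

    points: List[MapPoint]
    freq_threshold: int
    year_threshold: float
    articles_per_entity: Dict[str, Set[str]]
    n_skipped_no_year: int = 0

    def point(self, entity_id: str) -> Optional[MapPoint]:
        for p in self.points:
            if p.entity_id == entity_id:
                return p
        return None

    def zone_members(self, zone: str) -> List[MapPoint]:
        return [p for p in self.points if p.zone == zone]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "entity_id": p.entity_id,
                    "frequency": p.frequency,
                    "recency": p.recency,
                    "zone": p.zone,
                }
                for p in sorted(self.points, key=lambda p: p.entity_id)
            ]
        )


def _zone(freq: int, recency: float, fthr: int, ythr: float) -> str:
    """I = frequent/older, II = frequent/recent, III = infrequent/older,
    IV = infrequent/recent (the zone of emerging entities)."""
    frequent = freq >= fthr
    recent = recency >= ythr
    if frequent:
        return "II" if recent else "I"
    return "IV" if recent else "III"


def predict_caes(
    annotated: Sequence[AnnotatedArticle],
    scorer: ScorerSpec,
    stats: CorpusStats,
    top_k: int = 2,
    config: Optional[ScorerConfig] = None,
    seed: int = 0,
) -> Dict[str, List[str]]:
    """Treat each article's top-k ranked entities as its predicted CAEs."""
    out: Dict[str, List[str]] = {}
    for ann in annotated:
        ranked = rank_article(ann, scorer, stats, config=config, seed=seed)
        if ranked.entries:
            out[ann.article_id] = ranked.top(top_k)
    return out


def build_frequency_recency_map(
    annotated: Sequence[AnnotatedArticle],
    scorer: ScorerSpec,
    stats: CorpusStats,
    top_k: int = 2,
    freq_threshold: int = 100,
    year_threshold: float = 2012,
    config: Optional[ScorerConfig] = None,
    seed: int = 0,
    predictions: Optional[Mapping[str, Sequence[str]]] = None,
) -> FrequencyRecencyMap:
    """Frequency–recency map over predicted CAEs.  Articles without a
    publication year cannot contribute to recency and are skipped (count
    recorded)."""
    years = {a.article_id: a.pub_year for a in annotated}
    if predictions is None:
        predictions = predict_caes(
            annotated, scorer, stats, top_k=top_k, config=config, seed=seed
        )
    per_entity: Dict[str, Set[str]] = {}
    skipped = 0
    for aid, eids in predictions.items():
        if years.get(aid) is None:
            skipped += 1
            continue
        for eid in eids:
            per_entity.setdefault(eid, set()).add(aid)
    points = []
    for eid in sorted(per_entity):
        arts = per_entity[eid]
        recency = float(np.mean([years[a] for a in arts]))
        freq = len(arts)
        points.append(
            MapPoint(eid, freq, recency, _zone(freq, recency, freq_threshold, year_threshold))
        )
    if skipped:
        logger.info("frequency-recency map: skipped %d articles without a year", skipped)
    return FrequencyRecencyMap(
        points=points,
        freq_threshold=freq_threshold,
        year_threshold=year_threshold,
        articles_per_entity=per_entity,
        n_skipped_no_year=skipped,
    )


def focused_view(
    annotated: Sequence[AnnotatedArticle],
    scorer: ScorerSpec,
    stats: CorpusStats,
    focus: str,
    top_k: int = 2,
    freq_threshold: int = 100,
    year_threshold: float = 2012,
    config: Optional[ScorerConfig] = None,
    seed: int = 0,
) -> FrequencyRecencyMap:
    """Map rebuilt over the articles where ``focus`` is a predicted CAE,
    showing its co-predicted entities (the focus itself is excluded)."""
    predictions = predict_caes(
        annotated, scorer, stats, top_k=top_k, config=config, seed=seed
    )
    focus_articles = {aid for aid, eids in predictions.items() if focus in eids}
    if not focus_articles:
        raise ValueError(f"entity {focus!r} is never a predicted CAE")
    sub_pred = {
        aid: [e for e in eids if e != focus]
        for aid, eids in predictions.items()
        if aid in focus_articles
    }
    sub_anns = [a for a in annotated if a.article_id in focus_articles]
    return build_frequency_recency_map(
        sub_anns,
        scorer,
        stats,
        top_k=top_k,
        freq_threshold=freq_threshold,
        year_threshold=year_threshold,
        predictions=sub_pred,
    )


def jaccard_article_sets(a1: Set[str], a2: Set[str]) -> float:
    """|A1 ∩ A2| / |A1 ∪ A2| between two article sets (e.g., the articles
    recommending an entity vs those curators used)."""
    union = set(a1) | set(a2)
    if not union:
        raise ValueError("Jaccard undefined for two empty sets")
    return len(set(a1) & set(a2)) / len(union)


def plot_profile(profile: DistributionProfile, path) -> None:
    """Dashed CAE / non-CAE prevalence lines, solid probability-gain line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(profile.bin_labels))
    fig, ax = plt.subplots(figsize=(8, 4.5))
    ax.plot(x, profile.p_cae, "--", label="P(CAE)", color="tab:blue")
    ax.plot(x, profile.p_noncae, "--", label="P(NonCAE)", color="tab:orange")
    ax.plot(x, profile.prob_gain, "-", label="ProbGain", color="tab:red")
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xticks(x)
    ax.set_xticklabels(profile.bin_labels, rotation=60, fontsize=6, ha="right")
    ax.set_xlabel(profile.indicator)
    ax.set_ylabel("probability")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_frequency_recency(fr_map: FrequencyRecencyMap, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    if fr_map.points:
        xs = [p.recency for p in fr_map.points]
        ys = [p.frequency for p in fr_map.points]
        ax.scatter(xs, ys, s=12, alpha=0.7)
    ax.axvline(fr_map.year_threshold, color="grey", ls=":")
    ax.axhline(fr_map.freq_threshold, color="grey", ls=":")
    ax.set_xlabel("recency (mean publication year)")
    ax.set_ylabel("frequency (articles as predicted CAE)")
    ax.set_yscale("symlog")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def profile_to_json(profile: DistributionProfile, path) -> None:
    payload = {
        "indicator": profile.indicator,
        "bins": profile.bin_labels,
        "cae_counts": profile.cae_counts.astype(int).tolist(),
        "noncae_counts": profile.noncae_counts.astype(int).tolist(),
        "p_cae": profile.p_cae.tolist(),
        "p_noncae": profile.p_noncae.tolist(),
        "prob_gain": [None if np.isnan(v) else v for v in profile.prob_gain],
        "overall_cae_rate": profile.overall_cae_rate,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")
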