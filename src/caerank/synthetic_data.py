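"""Synthetic corpora with the statistical structure the indicators exploit.

The generator emits articles (title + abstract + year), a CTD-style
lexicon, and a gold CAE file, fully reproducible from a seed.  It
emulates the contrasts the real curation data exhibits between CAEs and
non-CAEs without attempting linguistic realism:

* a designated "focal" subset of entities is mentioned with boosted
  per-article frequency (``concentration_boost``), giving them high
  concentration (AvgTF) across the collection; CAEs are drawn from an
  article's candidates with affinity for focal entities;
* CAEs receive mild extra term frequency (``tf_rate_cae`` vs
  ``tf_rate_noncae``; mention counts are 1 + Poisson(λ) so every
  candidate appears at least once) and are placed in the title / the
  first-or-last abstract sentences with higher probability;
* entity popularity follows a Zipf law (``df_zipf_exponent``), spreading
  document frequency and hence IDF;
* some entities are rendered through a synonym, or through an
  author-defined abbreviation introduced in parentheses on first use,
  exercising the synonym and abbreviation matching paths.

Filler vocabulary is generated from the same collision-free token stream
as entity names, so no filler word ever matches a lexicon surface form.
Setting both rates, both title probabilities, both boundary
probabilities and the affinity/boost to equal values yields an
exchangeability null in which no indicator carries signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .corpus_io import (
    Article,
    Corpus,
    EntityLexicon,
    GoldStandard,
    LexiconEntry,
    write_articles,
    write_gold,
    write_lexicon,
)

_LETTERS = np.array(list("abcdefghijklmnopqrstuvwxyz"))
_UPPER = np.array(list("BCDFGHJKLMNPQRSTVWXZ"))


@dataclass
class SimConfig:
    """Study conditions of a synthetic corpus.  The defaults describe a
    corpus in which concentration is the dominant signal and frequency /
    title placement carry milder signal, qualitatively matching the
    contrasts reported for real curated abstracts."""

    n_articles: int = 500
    vocab_size: int = 300
    candidates_per_article: Tuple[int, int] = (5, 10)
    caes_per_article: Tuple[int, int] = (1, 3)
    tf_rate_cae: float = 1.0
    tf_rate_noncae: float = 0.6
    p_title_cae: float = 0.35
    p_title_noncae: float = 0.10
    p_boundary_cae: float = 0.50
    p_boundary_noncae: float = 0.30
    concentration_boost: float = 3.0
    focal_fraction: float = 0.25
    cae_focal_affinity: float = 25.0
    df_zipf_exponent: float = 1.1
    sentences_per_abstract: Tuple[int, int] = (5, 9)
    year_range: Tuple[int, int] = (2000, 2016)
    p_missing_year: float = 0.0
    p_synonym_entity: float = 0.5
    p_abbreviation_entity: float = 0.15
    p_synonym_use: float = 0.25
    p_shared_synonym: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_title_cae", "p_title_noncae", "p_boundary_cae",
                     "p_boundary_noncae", "p_missing_year", "p_synonym_entity",
                     "p_abbreviation_entity", "p_synonym_use", "p_shared_synonym"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.tf_rate_cae <= 0 or self.tf_rate_noncae <= 0:
            raise ValueError("term-frequency rates must be > 0")
        if self.concentration_boost <= 0 or self.cae_focal_affinity <= 0:
            raise ValueError("boost and affinity must be > 0")
        for name in ("candidates_per_article", "caes_per_article",
                     "sentences_per_abstract", "year_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range {lo}..{hi} is empty")
        if self.caes_per_article[0] > self.candidates_per_article[1] - 1:
            raise ValueError(
                "caes_per_article exceeds candidates_per_article: every "
                "article needs at least one non-CAE candidate"
            )
        if self.candidates_per_article[1] > self.vocab_size:
            raise ValueError("candidates_per_article exceeds vocab_size")

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        for key in ("candidates_per_article", "caes_per_article",
                    "sentences_per_abstract", "year_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)
            fh.write("\n")


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """Exchangeability-null conditions: CAE and non-CAE candidates are
    generated identically, so no indicator can separate the classes."""
    base = dict(
        tf_rate_cae=0.8,
        tf_rate_noncae=0.8,
        p_title_cae=0.2,
        p_title_noncae=0.2,
        p_boundary_cae=0.4,
        p_boundary_noncae=0.4,
        concentration_boost=1.0,
        cae_focal_affinity=1.0,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SimTruth:
    """The generative ground truth actually drawn for a corpus."""

    cae_sets: Dict[str, Set[str]]
    mention_counts: Dict[str, Dict[str, int]]
    focal_entities: Set[str]
    abbreviations: Dict[str, str]  # short form -> entity_id
    config: SimConfig

    def to_json(self, path) -> None:
        payload = {
            "cae_sets": {a: sorted(s) for a, s in sorted(self.cae_sets.items())},
            "mention_counts": {
                a: dict(sorted(c.items())) for a, c in sorted(self.mention_counts.items())
            },
            "focal_entities": sorted(self.focal_entities),
            "abbreviations": dict(sorted(self.abbreviations.items())),
            "config": asdict(self.config),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


class _TokenFactory:
    """Collision-free random token stream (lowercase words and uppercase
    short symbols share one uniqueness pool)."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.seen: Set[str] = set()

    def word(self, lo: int = 5, hi: int = 9) -> str:
        while True:
            n = int(self.rng.integers(lo, hi + 1))
            w = "".join(self.rng.choice(_LETTERS, size=n))
            if w not in self.seen:
                self.seen.add(w)
                return w

    def symbol(self) -> str:
        while True:
            n = int(self.rng.integers(3, 5))
            s = "".join(self.rng.choice(_UPPER, size=n))
            if s not in self.seen and s.lower() not in self.seen:
                self.seen.add(s)
                self.seen.add(s.lower())
                return s


def _weighted_subset(
    rng: np.random.Generator, items: Sequence[str], weights: np.ndarray, k: int
) -> List[str]:
    """Weighted sampling without replacement via the Gumbel-max trick."""
    keys = np.log(weights) + rng.gumbel(size=len(items))
    idx = np.argsort(-keys)[:k]
    return [items[i] for i in sorted(idx)]


def generate_corpus(
    cfg: SimConfig,
) -> Tuple[Corpus, EntityLexicon, GoldStandard, SimTruth]:
    """Draw a full synthetic study: corpus, lexicon, gold CAEs, truth."""
    rng = np.random.default_rng(cfg.seed)
    tokens = _TokenFactory(rng)

    # --- entities -------------------------------------------------------
    entity_ids = [f"E{i:05d}" for i in range(cfg.vocab_size)]
    types = ["gene", "disease", "chemical"]
    names = {eid: tokens.word() for eid in entity_ids}
    synonyms: Dict[str, List[str]] = {eid: [] for eid in entity_ids}
    for eid in entity_ids:
        if rng.random() < cfg.p_synonym_entity:
            synonyms[eid].append(tokens.word())
    if cfg.p_shared_synonym > 0:
        for i in range(0, cfg.vocab_size - 1, 2):
            if rng.random() < cfg.p_shared_synonym:
                shared = tokens.word()
                synonyms[entity_ids[i]].append(shared)
                synonyms[entity_ids[i + 1]].append(shared)
    abbreviations: Dict[str, str] = {}
    abbrev_of: Dict[str, str] = {}
    for eid in entity_ids:
        if rng.random() < cfg.p_abbreviation_entity:
            short = tokens.symbol()
            abbreviations[short] = eid
            abbrev_of[eid] = short

    lexicon = EntityLexicon(
        [
            LexiconEntry(
                eid,
                types[i % 3],
                (names[eid],),
                tuple(synonyms[eid]),
            )
            for i, eid in enumerate(entity_ids)
        ]
    )

    n_focal = max(1, round(cfg.focal_fraction * cfg.vocab_size))
    focal_idx = rng.choice(cfg.vocab_size, size=n_focal, replace=False)
    focal = {entity_ids[i] for i in focal_idx}

    ranks = rng.permutation(cfg.vocab_size) + 1
    zipf_w = 1.0 / ranks.astype(float) ** cfg.df_zipf_exponent
    zipf_p = zipf_w / zipf_w.sum()

    filler = [tokens.word(4, 8) for _ in range(400)]

    # --- articles -------------------------------------------------------
    articles: List[Article] = []
    gold: GoldStandard = {}
    mention_counts: Dict[str, Dict[str, int]] = {}

    for ai in range(cfg.n_articles):
        aid = f"{7000000 + ai}"
        n_cand = int(rng.integers(cfg.candidates_per_article[0],
                                  cfg.candidates_per_article[1] + 1))
        cand_idx = rng.choice(cfg.vocab_size, size=n_cand, replace=False, p=zipf_p)
        candidates = [entity_ids[i] for i in sorted(cand_idx)]
        k = int(rng.integers(cfg.caes_per_article[0], cfg.caes_per_article[1] + 1))
        k = max(1, min(k, n_cand - 1))
        aff = np.array(
            [cfg.cae_focal_affinity if e in focal else 1.0 for e in candidates]
        )
        caes = set(_weighted_subset(rng, candidates, aff, k))

        n_sent = int(rng.integers(cfg.sentences_per_abstract[0],
                                  cfg.sentences_per_abstract[1] + 1))
        # per-entity placement draws
        title_entities: List[str] = []
        sent_mentions: Dict[int, List[str]] = {i: [] for i in range(n_sent)}
        counts: Dict[str, int] = {}
        for eid in candidates:
            is_cae = eid in caes
            lam = cfg.tf_rate_cae if is_cae else cfg.tf_rate_noncae
            if eid in focal:
                lam *= cfg.concentration_boost
            count = 1 + int(rng.poisson(lam))
            counts[eid] = count
            remaining = count
            p_title = cfg.p_title_cae if is_cae else cfg.p_title_noncae
            p_bound = cfg.p_boundary_cae if is_cae else cfg.p_boundary_noncae
            if rng.random() < p_title:
                title_entities.append(eid)
                remaining -= 1
            if remaining > 0 and rng.random() < p_bound:
                s = 0 if rng.random() < 0.5 else n_sent - 1
                sent_mentions[s].append(eid)
                remaining -= 1
            for _ in range(remaining):
                s = int(rng.integers(0, n_sent))
                sent_mentions[s].append(eid)

        # per-(article, entity) rendering style, constant within the article
        style: Dict[str, str] = {}
        for eid in candidates:
            if eid in abbrev_of and rng.random() < 0.6:
                style[eid] = "abbrev"
            elif synonyms[eid] and rng.random() < cfg.p_synonym_use:
                style[eid] = "synonym"
            else:
                style[eid] = "official"

        defined: Set[str] = set()

        def render(eid: str) -> str:
            if style[eid] == "synonym":
                return synonyms[eid][0]
            if style[eid] == "abbrev":
                if eid in defined:
                    return abbrev_of[eid]
                defined.add(eid)
                return f"{names[eid]} ({abbrev_of[eid]})"
            return names[eid]

        def compose(mention_ids: List[str], n_filler: int, capitalize: bool) -> str:
            words = [filler[int(i)] for i in rng.integers(0, len(filler), n_filler)]
            out = list(words)
            for eid in mention_ids:
                pos = int(rng.integers(0, len(out) + 1))
                out.insert(pos, render(eid))
            if capitalize and out:
                # uppercase only the first character: str.capitalize would
                # lowercase the rest and corrupt abbreviation symbols
                out[0] = out[0][0].upper() + out[0][1:]
            return " ".join(out)

        title = compose(title_entities, int(rng.integers(3, 6)), capitalize=True)
        sentences = []
        for si in range(n_sent):
            sentences.append(
                compose(sent_mentions[si], int(rng.integers(4, 9)), capitalize=True)
                + "."
            )
        abstract = " ".join(sentences)
        # the "name (ABBR)" definition renders the entity twice (long form
        # + symbol); truth counts textual occurrences
        for eid in defined:
            counts[eid] += 1
        year: Optional[int] = int(
            rng.integers(cfg.year_range[0], cfg.year_range[1] + 1)
        )
        if rng.random() < cfg.p_missing_year:
            year = None
        articles.append(Article(aid, title, abstract, year))
        gold[aid] = caes
        mention_counts[aid] = counts

    corpus = Corpus(articles, provenance=f"synthetic seed={cfg.seed}")
    truth = SimTruth(
        cae_sets=gold,
        mention_counts=mention_counts,
        focal_entities=focal,
        abbreviations=abbreviations,
        config=cfg,
    )
    return corpus, lexicon, dict(gold), truth


def save_run(
    corpus: Corpus,
    lexicon: EntityLexicon,
    gold: GoldStandard,
    truth: SimTruth,
    outdir,
) -> Dict[str, str]:
    """Write the run directory (articles.jsonl, lexicon.tsv, gold.txt,
    truth.json, manifest.json) and return the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "articles": str(outdir / "articles.jsonl"),
        "lexicon": str(outdir / "lexicon.tsv"),
        "gold": str(outdir / "gold.txt"),
        "truth": str(outdir / "truth.json"),
    }
    write_articles(corpus, paths["articles"])
    write_lexicon(lexicon, paths["lexicon"])
    write_gold(gold, paths["gold"])
    truth.to_json(paths["truth"])
    manifest = {
        "seed": truth.config.seed,
        "n_articles": len(corpus),
        "vocab_size": len(lexicon),
        "files": paths,
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def expected_random_pct_p_at_x(
    article_sizes: Sequence[Tuple[int, int]], x: int
) -> float:
    """Analytic %P@X>0 of a uniformly random ranking.

    For an article with n candidates of which k are CAEs, the chance that
    at least one CAE lands in the top X is 1 − C(n−k, X)/C(n, X) (and 1
    whenever X > n − k).  Returns the mean over articles, as a
    percentage.
    """
    if x < 1:
        raise ValueError("X must be >= 1")
    probs = []
    for n, k in article_sizes:
        if k <= 0 or n <= 0 or k > n:
            raise ValueError(f"invalid (n={n}, k={k})")
        if x > n - k:
            probs.append(1.0)
        else:
            probs.append(1.0 - math.comb(n - k, x) / math.comb(n, x))
    return 100.0 * float(np.mean(probs))
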