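"""Data model and file I/O for article corpora, entity lexicons, and gold annotations.

The on-disk formats are deliberately plain text:

* articles — JSON-lines, one object per article with keys ``id``, ``title``,
  ``abstract`` and optional ``year``; a best-effort MEDLINE reader
  (PMID/TI/AB/DP fields) is provided for convenience.
* lexicon — 4-column TSV: ``entity_id``, ``entity_type``,
  ``official_names`` ('|'-separated), ``synonyms`` ('|'-separated, may be
  empty).  This emulates a CTD-style controlled vocabulary of genes,
  diseases and chemicals.
* gold annotations — one article per line: the article identifier, then
  whitespace, then the '|'-separated identifiers of its conclusive
  association entities (CAEs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Set

ENTITY_TYPES = ("gene", "disease", "chemical")

__all__ = [
    "Article",
    "Corpus",
    "LexiconEntry",
    "EntityLexicon",
    "GoldStandard",
    "read_articles",
    "write_articles",
    "read_lexicon",
    "write_lexicon",
    "read_gold",
    "write_gold",
]


@dataclass(frozen=True)
class Article:
    """One title + abstract record (the article *a* the indicators score)."""

    article_id: str
    title: str
    abstract: str
    pub_year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.article_id:
            raise ValueError("article_id must be non-empty")
        if not self.title and not self.abstract:
            raise ValueError(
                f"article {self.article_id!r}: title and abstract both empty"
            )


@dataclass
class Corpus:
    """Ordered, duplicate-free collection of articles."""

    articles: List[Article]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: Set[str] = set()
        for art in self.articles:
            if art.article_id in seen:
                raise ValueError(f"duplicate article id {art.article_id!r}")
            seen.add(art.article_id)

    def __len__(self) -> int:
        return len(self.articles)

    def __iter__(self) -> Iterator[Article]:
        return iter(self.articles)

    def __getitem__(self, i: int) -> Article:
        return self.articles[i]

    @property
    def article_ids(self) -> List[str]:
        return [a.article_id for a in self.articles]


def _norm_surface(s: str) -> str:
    """Collapse internal whitespace and strip; surface forms are compared
    token-wise downstream, so only whitespace is normalised here."""
    return " ".join(s.split())


@dataclass(frozen=True)
class LexiconEntry:
    entity_id: str
    entity_type: str
    official_names: tuple
    synonyms: tuple

    def __post_init__(self) -> None:
        if not self.entity_id:
            raise ValueError("blank entity_id in lexicon entry")
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(
                f"entity {self.entity_id!r}: unknown entity_type "
                f"{self.entity_type!r} (expected one of {ENTITY_TYPES})"
            )
        if not self.official_names:
            raise ValueError(f"entity {self.entity_id!r}: no official names")
        for form in (*self.official_names, *self.synonyms):
            if not form:
                raise ValueError(f"entity {self.entity_id!r}: empty surface form")

    @property
    def all_surfaces(self) -> tuple:
        return self.official_names + self.synonyms


class EntityLexicon:
    """ID -> names/synonyms mapping used for dictionary-based candidate
    detection.  The same surface string may belong to several entities;
    that ambiguity is retained, not dropped."""

    def __init__(self, entries: List[LexiconEntry]):
        self.entries: Dict[str, LexiconEntry] = {}
        for e in entries:
            if e.entity_id in self.entries:
                raise ValueError(f"duplicate entity id {e.entity_id!r} in lexicon")
            self.entries[e.entity_id] = e

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries.values())

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.entries

    def __getitem__(self, entity_id: str) -> LexiconEntry:
        return self.entries[entity_id]

    def surfaces_of(self, entity_id: str) -> tuple:
        return self.entries[entity_id].all_surfaces


# dict article_id -> frozenset of entity ids; plain mapping is the contract
GoldStandard = Dict[str, Set[str]]


def read_articles(path, format: str = "jsonl") -> Corpus:
    """Read a corpus, preserving input order.

    ``format`` is ``jsonl`` (canonical) or ``medline`` (best-effort
    PMID/TI/AB/DP reader).  Records missing both title and abstract, and
    duplicate ids, are rejected with the offending line/id named.
    """
    path = Path(path)
    if format == "jsonl":
        articles = list(_iter_jsonl(path))
    elif format == "medline":
        articles = list(_iter_medline(path))
    else:
        raise ValueError(f"unknown article format {format!r}")
    return Corpus(articles, provenance=str(path))


def _iter_jsonl(path: Path) -> Iterator[Article]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                art = Article(
                    article_id=str(rec["id"]),
                    title=rec.get("title", "") or "",
                    abstract=rec.get("abstract", "") or "",
                    pub_year=int(rec["year"]) if rec.get("year") is not None else None,
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed article record: {exc}") from exc
            yield art


def _iter_medline(path: Path) -> Iterator[Article]:
    """Minimal MEDLINE flat-file reader: PMID, TI, AB, DP fields only."""
    fields: Dict[str, List[str]] = {}
    key = None

    def flush() -> Optional[Article]:
        if not fields:
            return None
        pmid = " ".join(fields.get("PMID", [])).strip()
        title = " ".join(fields.get("TI", [])).strip()
        abstract = " ".join(fields.get("AB", [])).strip()
        dp = " ".join(fields.get("DP", [])).strip()
        year = None
        if dp[:4].isdigit():
            year = int(dp[:4])
        return Article(pmid, title, abstract, year)

    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                art = flush()
                if art is not None:
                    yield art
                fields, key = {}, None
                continue
            if line.startswith("      ") and key:  # continuation
                fields[key].append(line.strip())
            elif len(line) >= 6 and line[4:6] == "- ":
                key = line[:4].strip()
                fields.setdefault(key, []).append(line[6:].strip())
    art = flush()
    if art is not None:
        yield art


def write_articles(corpus: Corpus, path) -> None:
    """Write a corpus as canonical JSONL (inverse of :func:`read_articles`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for a in corpus:
            rec = {"id": a.article_id, "title": a.title, "abstract": a.abstract}
            if a.pub_year is not None:
                rec["year"] = a.pub_year
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_lexicon(path) -> EntityLexicon:
    """Read a CTD-style 4-column lexicon TSV (see module docstring)."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
            entity_id = parts[0].strip()
            entity_type = parts[1].strip()
            names = tuple(
                _norm_surface(t) for t in parts[2].split("|") if _norm_surface(t)
            )
            syn_field = parts[3] if len(parts) > 3 else ""
            synonyms = tuple(
                _norm_surface(t) for t in syn_field.split("|") if _norm_surface(t)
            )
            try:
                entries.append(
                    LexiconEntry(entity_id, entity_type, names, synonyms)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return EntityLexicon(entries)


def write_lexicon(lexicon: EntityLexicon, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in sorted(lexicon, key=lambda e: e.entity_id):
            fh.write(
                "\t".join(
                    [
                        e.entity_id,
                        e.entity_type,
                        "|".join(e.official_names),
                        "|".join(e.synonyms),
                    ]
                )
                + "\n"
            )


def read_gold(path) -> GoldStandard:
    """Read gold CAE annotations: ``article_id <ws> id1|id2|...`` per line.

    Empty tokens from trailing '|' are dropped; a line with an id but no
    CAEs is a parse error.
    """
    gold: GoldStandard = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            article_id = parts[0]
            ids = set()
            if len(parts) > 1:
                ids = {tok for tok in parts[1].split("|") if tok.strip()}
            if not ids:
                raise ValueError(f"{path}:{lineno}: article {article_id!r} has no CAE ids")
            gold[article_id] = ids
    return gold


def write_gold(gold: GoldStandard, path) -> None:
    """Write gold annotations; ids sorted so output is byte-stable."""
    if not gold:
        raise ValueError("refusing to write an empty gold standard")
    with open(path, "w", encoding="utf-8") as fh:
        for article_id in sorted(gold):
            caes = gold[article_id]
            if not caes:
                raise ValueError(f"article {article_id!r} has an empty CAE set")
            fh.write(f"{article_id}\t{'|'.join(sorted(caes))}\n")
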