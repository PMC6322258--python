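"""Sentence segmentation and dictionary-based candidate-entity detection.

Candidate entities are the lexicon entities found in an article's title or
abstract.  Matching is a three-pass dictionary scan:

1. surface forms (official names + synonyms) of *priority* entities — the
   gold CAEs of the article, whose presence has already been confirmed by
   curators, so they are matched first and never lost;
2. official names/symbols of every lexicon entity;
3. synonyms, but only for entities not already matched in the article.

Author-defined abbreviations introduced in parentheses ("dopamine (DA)")
are resolved per article and matched like ordinary surface forms of the
entity they abbreviate.

Matching conventions (these are package design choices; they are applied
identically by the brute-force oracle used in the tests):

* token = alphanumeric run with internal hyphens ("2-bromolisuride" is one
  token); punctuation delimits;
* multi-character names match case-insensitively; all-uppercase short
  symbols (length <= 4) match case-sensitively, protecting gene symbols;
* overlaps resolve longest-match-first, left-to-right, and a token span is
  consumed by at most one match per pass, so term frequencies are never
  double-counted;
* the title is segmented separately and is NOT part of the abstract
  sentence list: sentence-level statistics (co-occurrence, first/last-X
  locality) see only abstract sentences, while term frequency counts title
  mentions too.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

from .corpus_io import Article, Corpus, EntityLexicon, GoldStandard

logger = logging.getLogger(__name__)

TITLE = "TITLE"

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")

# abbreviations that do not end a sentence even when followed by a capital
_NON_TERMINAL = {
    "e.g", "i.e", "cf", "vs", "etc", "al", "fig", "figs", "ref", "refs",
    "dr", "mr", "mrs", "ms", "st", "no", "ca", "approx", "spp", "sp",
}


def tokenize(text: str) -> List[str]:
    """Alphanumeric tokens with internal hyphens kept."""
    return _TOKEN_RE.findall(text)


def split_sentences(text: str) -> List[str]:
    """Rule-based sentence splitting for abstracts.

    A boundary is a terminal ``.``, ``?`` or ``!`` followed by whitespace
    and an uppercase letter or digit.  Decimal points never qualify (no
    whitespace follows them) and a guard list of common abbreviations
    ("e.g.", "vs.", "Fig." ...) plus single-initial patterns ("J. Smith")
    suppresses spurious breaks.
    """
    if not text.strip():
        return []
    boundaries = []
    for m in re.finditer(r"[.?!]+", text):
        end = m.end()
        rest = text[end:]
        stripped = rest.lstrip()
        if not stripped or stripped == rest:  # need trailing whitespace
            continue
        if not (stripped[0].isupper() or stripped[0].isdigit()):
            continue
        before = text[: m.start()]
        last_word = re.findall(r"[\w.]+$", before)
        if last_word:
            w = last_word[0].rstrip(".").lower()
            if w in _NON_TERMINAL:
                continue
            if len(w) == 1 and last_word[0][-1:] != "." and w.isalpha() \
                    and before[-2:-1].isupper():
                pass
            if len(last_word[0].rstrip(".")) == 1 and last_word[0].rstrip(".").isupper():
                continue  # personal initial, "J. Smith"
        boundaries.append(end)
    sentences = []
    start = 0
    for b in boundaries:
        chunk = text[start:b].strip()
        if chunk:
            sentences.append(chunk)
        start = b
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


@dataclass
class SegmentedArticle:
    """Tokenised view of one article: title tokens plus ordered abstract
    sentences.  ``token_count`` is |a|, the article length in tokens."""

    article_id: str
    title_text: str
    sentence_texts: List[str]
    title_tokens: List[str]
    sentences: List[List[str]]
    pub_year: Optional[int] = None

    @property
    def token_count(self) -> int:
        return len(self.title_tokens) + sum(len(s) for s in self.sentences)

    @property
    def abstract_token_count(self) -> int:
        return sum(len(s) for s in self.sentences)


def segment_article(article: Article) -> SegmentedArticle:
    sent_texts = split_sentences(article.abstract)
    return SegmentedArticle(
        article_id=article.article_id,
        title_text=article.title,
        sentence_texts=sent_texts,
        title_tokens=tokenize(article.title),
        sentences=[tokenize(s) for s in sent_texts],
        pub_year=article.pub_year,
    )


@dataclass(frozen=True)
class Mention:
    """One matched occurrence of an entity surface form."""

    entity_id: str
    surface: str
    location: Union[str, int]  # TITLE or 0-based abstract sentence index
    token_offset: int  # within its segment
    abstract_pos: Optional[int] = None  # absolute token index in abstract

    @property
    def in_title(self) -> bool:
        return self.location == TITLE


@dataclass
class AnnotatedArticle:
    """Article plus its detected candidate-entity mentions."""

    article_id: str
    token_count: int
    n_sentences: int
    abstract_token_count: int
    mentions: List[Mention]
    pub_year: Optional[int] = None

    @property
    def candidates(self) -> Set[str]:
        return {m.entity_id for m in self.mentions}

    @property
    def flagged(self) -> bool:
        """True when no candidate entity was found."""
        return not self.mentions

    def mentions_of(self, entity_id: str) -> List[Mention]:
        return [m for m in self.mentions if m.entity_id == entity_id]

    def sentence_set(self, entity_id: str) -> Set[int]:
        """S_e(a): abstract sentence indices mentioning the entity (the
        title is not a sentence)."""
        return {m.location for m in self.mentions
                if m.entity_id == entity_id and not m.in_title}

    def to_record(self) -> dict:
        rec = {
            "article_id": self.article_id,
            "token_count": self.token_count,
            "n_sentences": self.n_sentences,
            "abstract_token_count": self.abstract_token_count,
            "mentions": [
                [m.entity_id, m.surface, m.location, m.token_offset, m.abstract_pos]
                for m in self.mentions
            ],
        }
        if self.pub_year is not None:
            rec["year"] = self.pub_year
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "AnnotatedArticle":
        return cls(
            article_id=rec["article_id"],
            token_count=rec["token_count"],
            n_sentences=rec["n_sentences"],
            abstract_token_count=rec["abstract_token_count"],
            mentions=[
                Mention(e, s, loc if loc == TITLE else int(loc), off,
                        None if ap is None else int(ap))
                for e, s, loc, off, ap in rec["mentions"]
            ],
            pub_year=rec.get("year"),
        )


# mapping short form -> entity id, per article
AbbreviationTable = Dict[str, str]

_PAREN_RE = re.compile(r"\(([^()]{1,12})\)")


def _form_key(form: str) -> Tuple[str, Tuple[str, ...]]:
    """Comparison key for a surface form under the case convention:
    all-uppercase symbols of length <= 4 are case-sensitive, everything
    else case-insensitive."""
    toks = tokenize(form)
    compact = form.replace(" ", "")
    if len(compact) <= 4 and compact.isupper() and compact.isalpha():
        return ("cs", tuple(toks))
    return ("ci", tuple(t.lower() for t in toks))


class _FormIndex:
    """Surface-form lookup: comparison key -> sorted owner entity ids."""

    def __init__(self) -> None:
        self._index: Dict[Tuple[str, Tuple[str, ...]], Set[str]] = {}
        self.max_len = 0

    def add(self, form: str, entity_id: str) -> None:
        key = self._form_key_cached(form)
        if not key[1]:
            return
        self._index.setdefault(key, set()).add(entity_id)
        self.max_len = max(self.max_len, len(key[1]))

    @staticmethod
    def _form_key_cached(form: str):
        return _form_key(form)

    def lookup(self, tokens: Sequence[str]) -> Optional[List[str]]:
        toks = tuple(tokens)
        owners = self._index.get(("cs", toks))
        result: Set[str] = set(owners) if owners else set()
        ci = self._index.get(("ci", tuple(t.lower() for t in toks)))
        if ci:
            result |= ci
        return sorted(result) if result else None


def _lexicon_index(
    lexicon: EntityLexicon,
    ids: Optional[Set[str]] = None,
    *,
    officials: bool = True,
    synonyms: bool = True,
    extra_forms: Optional[Dict[str, str]] = None,
) -> _FormIndex:
    idx = _FormIndex()
    for entry in lexicon:
        if ids is not None and entry.entity_id not in ids:
            continue
        if officials:
            for form in entry.official_names:
                idx.add(form, entry.entity_id)
        if synonyms:
            for form in entry.synonyms:
                idx.add(form, entry.entity_id)
    if extra_forms:
        for short, eid in extra_forms.items():
            if ids is None or eid in ids:
                idx.add(short, eid)
    return idx


def detect_abbreviations(
    segmented: SegmentedArticle, lexicon: EntityLexicon
) -> AbbreviationTable:
    """Resolve author-defined parenthesised abbreviations.

    For each ``long form (SHORT)`` pattern whose immediately preceding
    tokens match a lexicon surface form, the short form is mapped to that
    entity.  Short forms that are already lexicon surface forms are left
    to ordinary matching; the first definition of a short form wins.
    """
    full_index = _lexicon_index(lexicon)
    # every known surface-form comparison key, to avoid overriding lexicon terms
    known_keys = set(full_index._index)

    table: AbbreviationTable = {}
    texts = [segmented.title_text] + list(segmented.sentence_texts)
    for text in texts:
        for m in _PAREN_RE.finditer(text):
            inner = m.group(1).strip()
            toks = tokenize(inner)
            if len(toks) != 1 or not re.fullmatch(r"[A-Za-z][A-Za-z0-9-]*", inner):
                continue
            if _form_key(inner) in known_keys:
                continue  # already a lexicon surface form
            if inner in table:
                continue  # first definition wins
            before_tokens = tokenize(text[: m.start()])
            matched_id = None
            for k in range(min(full_index.max_len, len(before_tokens)), 0, -1):
                owners = full_index.lookup(before_tokens[-k:])
                if owners:
                    matched_id = owners[0]  # deterministic under ambiguity
                    if len(owners) > 1:
                        logger.warning(
                            "article %s: abbreviation %r long form is ambiguous "
                            "(%s); mapped to %s",
                            segmented.article_id, inner, owners, matched_id,
                        )
                    break
            if matched_id is not None:
                table[inner] = matched_id
    return table


def _scan_segment(
    tokens: Sequence[str],
    claimed: List[bool],
    index: _FormIndex,
    allowed: Optional[Set[str]],
) -> List[Tuple[int, int, List[str]]]:
    """Longest-match-first, left-to-right scan over unclaimed token spans.

    Returns (start, length, owner_ids) triples and marks spans claimed.
    """
    hits = []
    n = len(tokens)
    i = 0
    while i < n:
        if claimed[i]:
            i += 1
            continue
        match = None
        max_n = min(index.max_len, n - i)
        for span in range(max_n, 0, -1):
            if any(claimed[i: i + span]):
                continue
            owners = index.lookup(tokens[i: i + span])
            if owners:
                if allowed is not None:
                    owners = [o for o in owners if o in allowed]
                    if not owners:
                        continue
                match = (i, span, owners)
                break
        if match:
            _, span, _ = match
            for j in range(i, i + span):
                claimed[j] = True
            hits.append(match)
            i += span
        else:
            i += 1
    return hits


def match_entities(
    segmented: SegmentedArticle,
    lexicon: EntityLexicon,
    priority_ids: Optional[Set[str]] = None,
    abbreviations: Optional[AbbreviationTable] = None,
) -> AnnotatedArticle:
    """Three-pass dictionary matching (see module docstring).

    ``priority_ids`` are entity ids whose presence is externally confirmed
    (gold CAEs); any of their surface forms present in the text is
    guaranteed to yield a candidate.  ``abbreviations`` defaults to
    :func:`detect_abbreviations` on the segmented article.
    """
    priority_ids = priority_ids or set()
    if abbreviations is None:
        abbreviations = detect_abbreviations(segmented, lexicon)

    idx_priority = _lexicon_index(
        lexicon, priority_ids, extra_forms=abbreviations
    ) if priority_ids else None
    idx_official = _lexicon_index(
        lexicon, officials=True, synonyms=False, extra_forms=abbreviations
    )

    segments: List[Tuple[Union[str, int], Sequence[str]]] = [
        (TITLE, segmented.title_tokens)
    ]
    for si, toks in enumerate(segmented.sentences):
        segments.append((si, toks))

    claimed = {loc: [False] * len(toks) for loc, toks in segments}
    raw_hits: List[Tuple[Union[str, int], int, int, List[str]]] = []

    def run_pass(index: _FormIndex, allowed: Optional[Set[str]] = None) -> None:
        for loc, toks in segments:
            for start, span, owners in _scan_segment(toks, claimed[loc], index, allowed):
                raw_hits.append((loc, start, span, owners))

    if idx_priority is not None:
        run_pass(idx_priority, allowed=priority_ids)
    run_pass(idx_official)
    matched_so_far = {o for *_, owners in raw_hits for o in owners}
    unmatched = {e.entity_id for e in lexicon} - matched_so_far
    if unmatched:
        idx_syn = _lexicon_index(
            lexicon, unmatched, officials=False, synonyms=True
        )
        if idx_syn.max_len:
            run_pass(idx_syn)

    # absolute abstract token offsets per sentence
    sent_start = []
    acc = 0
    for toks in segmented.sentences:
        sent_start.append(acc)
        acc += len(toks)

    mentions: List[Mention] = []
    token_map = dict(segments)
    for loc, start, span, owners in raw_hits:
        surface = " ".join(token_map[loc][start: start + span])
        abstract_pos = None if loc == TITLE else sent_start[loc] + start
        if len(owners) > 1:
            logger.warning(
                "article %s: surface %r is ambiguous between %s; "
                "all owners recorded",
                segmented.article_id, surface, owners,
            )
        for eid in owners:
            mentions.append(Mention(eid, surface, loc, start, abstract_pos))

    mentions.sort(
        key=lambda m: (0 if m.in_title else 1,
                       -1 if m.in_title else m.location,
                       m.token_offset, m.entity_id)
    )
    ann = AnnotatedArticle(
        article_id=segmented.article_id,
        token_count=segmented.token_count,
        n_sentences=len(segmented.sentences),
        abstract_token_count=segmented.abstract_token_count,
        mentions=mentions,
        pub_year=segmented.pub_year,
    )
    if ann.flagged:
        logger.info("article %s: no candidate entities found", segmented.article_id)
    return ann


def annotate_corpus(
    corpus: Corpus,
    lexicon: EntityLexicon,
    gold: Optional[GoldStandard] = None,
) -> List[AnnotatedArticle]:
    """Segment and match every article.  When a gold standard is supplied,
    each article's curated CAEs act as priority entities (gold-first
    mapping); without one the matcher runs in pure prediction mode."""
    out = []
    for art in corpus:
        seg = segment_article(art)
        priority = set(gold.get(art.article_id, set())) if gold else set()
        out.append(match_entities(seg, lexicon, priority))
    return out
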