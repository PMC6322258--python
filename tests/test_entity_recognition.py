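"""Segmentation, abbreviation resolution, and dictionary matching.

The matching oracle used here is an independent brute-force scan: every
lexicon surface form is tried at every token offset, with the same
longest-match-first resolution and case convention as the package.
"""

from typing import List, Tuple

import pytest

import caerank as cr
from caerank.entity_recognition import (
    TITLE,
    _form_key,
    detect_abbreviations,
    segment_article,
    split_sentences,
    tokenize,
)


class TestSentenceSplitting:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("A b. C d.", ["A b.", "C d."]),
            ("", []),
            (
                "Rats received 2.5 mg/kg daily. Effects ceased.",
                ["Rats received 2.5 mg/kg daily.", "Effects ceased."],
            ),
            ("One sentence only", ["One sentence only"]),
            ("Is it? Yes! Done.", ["Is it?", "Yes!", "Done."]),
            (
                "Known drugs (e.g. cocaine) act fast. Others do not.",
                ["Known drugs (e.g. cocaine) act fast.", "Others do not."],
            ),
            ("Written by J. Smith at the lab.", ["Written by J. Smith at the lab."]),
        ],
    )
    def test_rule_based_boundaries(self, text, expected):
        assert split_sentences(text) == expected

    def test_concatenation_reconstructs_text(self):
        text = "First part here. Second part there. Third ends."
        assert " ".join(split_sentences(text)) == text


class TestTokenize:
    def test_hyphenated_chemical_is_one_token(self):
        assert tokenize("2-bromolisuride uptake") == ["2-bromolisuride", "uptake"]

    def test_punctuation_delimits(self):
        assert tokenize("dopamine (DA), stable.") == ["dopamine", "DA", "stable"]


class TestCaseConvention:
    def test_short_uppercase_symbol_case_sensitive(self):
        assert _form_key("PRL")[0] == "cs"

    def test_long_name_case_insensitive(self):
        kind, toks = _form_key("Lisuride")
        assert kind == "ci" and toks == ("lisuride",)

    def test_five_letter_uppercase_not_protected(self):
        assert _form_key("ABCDE")[0] == "ci"


class TestAbbreviations:
    def test_known_long_forms_resolved(self, tiny_lexicon, demo_article):
        table = detect_abbreviations(segment_article(demo_article), tiny_lexicon)
        assert table["LIS"] == "C_LIS"
        assert table["DA"] == "C_DOPA"

    def test_non_entity_parenthesis_ignored(self, tiny_lexicon):
        art = cr.Article("1", "t", "Mice cohorts (n = 12) were used. Fine.")
        table = detect_abbreviations(segment_article(art), tiny_lexicon)
        assert table == {}

    def test_lexicon_surface_not_overridden(self, tiny_lexicon):
        # PRL is already an official symbol of G_PRL; a parenthesised PRL
        # after another entity must not remap it
        art = cr.Article("1", "t", "Serum lisuride (PRL) was measured.")
        table = detect_abbreviations(segment_article(art), tiny_lexicon)
        assert "PRL" not in table

    def test_first_definition_wins(self, tiny_lexicon):
        art = cr.Article(
            "1", "t", "We gave lisuride (XDR) and dopamine (XDR) together."
        )
        table = detect_abbreviations(segment_article(art), tiny_lexicon)
        assert table["XDR"] == "C_LIS"


# ---------------------------------------------------------------------------
# brute-force mention oracle


def _oracle_mentions(segmented, lexicon, priority_ids=None, abbrevs=None):
    """Try every surface form at every offset; longest match first,
    left-to-right; passes and span claiming as in the package contract."""
    priority_ids = priority_ids or set()
    abbrevs = abbrevs if abbrevs is not None else detect_abbreviations(segmented, lexicon)

    def forms_of(level: str, ids=None) -> List[Tuple[Tuple[str, Tuple[str, ...]], str]]:
        out = []
        for entry in lexicon:
            if ids is not None and entry.entity_id not in ids:
                continue
            surfaces = ()
            if level in ("official", "all"):
                surfaces += entry.official_names
            if level in ("synonym", "all"):
                surfaces += entry.synonyms
            for s in surfaces:
                out.append((_form_key(s), entry.entity_id))
        if level in ("official", "all"):
            for short, eid in abbrevs.items():
                if ids is None or eid in ids:
                    out.append((_form_key(short), eid))
        return out

    def token_matches(tokens, i, key):
        kind, ftoks = key
        n = len(ftoks)
        if i + n > len(tokens):
            return 0
        window = tuple(tokens[i:i + n])
        if kind == "ci":
            window = tuple(t.lower() for t in window)
        return n if window == ftoks else 0

    segments = [(TITLE, segmented.title_tokens)] + list(enumerate(segmented.sentences))
    claimed = {loc: [False] * len(t) for loc, t in segments}
    mentions = []

    def scan(forms, loc, tokens):
        i = 0
        while i < len(tokens):
            if claimed[loc][i]:
                i += 1
                continue
            best, owners = 0, set()
            for key, eid in forms:
                n = token_matches(tokens, i, key)
                if n and not any(claimed[loc][i:i + n]):
                    if n > best:
                        best, owners = n, {eid}
                    elif n == best:
                        owners.add(eid)
            if best:
                for j in range(i, i + best):
                    claimed[loc][j] = True
                for eid in sorted(owners):
                    mentions.append((eid, loc, i))
                i += best
            else:
                i += 1

    if priority_ids:
        forms = forms_of("all", priority_ids)
        for loc, tokens in segments:
            scan(forms, loc, tokens)
    forms = forms_of("official")
    for loc, tokens in segments:
        scan(forms, loc, tokens)
    matched = {m[0] for m in mentions}
    remaining = {e.entity_id for e in lexicon} - matched
    forms = forms_of("synonym", remaining)
    for loc, tokens in segments:
        scan(forms, loc, tokens)
    return sorted(mentions, key=_loc_key)


def _loc_key(m):
    eid, loc, off = m
    return (eid, "T" if loc == TITLE else f"S{loc:04d}", off)


def _package_mentions(ann):
    return sorted(
        ((m.entity_id, m.location, m.token_offset) for m in ann.mentions),
        key=_loc_key,
    )


class TestMatching:
    def test_demo_article_mention_locations(self, tiny_lexicon, demo_article):
        ann = cr.match_entities(segment_article(demo_article), tiny_lexicon)
        lis = ann.mentions_of("C_LIS")
        # title, "lisuride (LIS)" in s0 (2 textual occurrences), s1 via LIS,
        # s3 via LIS
        assert TITLE in [m.location for m in lis]
        assert len(lis) == 5
        assert ann.sentence_set("C_LIS") == {0, 1, 3}
        assert "C_2BR" in ann.candidates
        assert "D_HPRL" in ann.candidates

    def test_no_lexicon_term_flags_article(self, tiny_lexicon):
        art = cr.Article("9", "Nothing here", "Plain words only. More words.")
        ann = cr.match_entities(segment_article(art), tiny_lexicon)
        assert ann.candidates == set()
        assert ann.flagged

    def test_priority_entity_guaranteed(self, tiny_lexicon):
        # synonym-only occurrence of a priority entity: pass-3 rules alone
        # would skip it if the entity had been matched officially elsewhere,
        # the priority pass must keep it
        art = cr.Article("9", "t", "Severe hyperprolactinemia was observed. It persisted.")
        ann = cr.match_entities(
            segment_article(art), tiny_lexicon, priority_ids={"D_HPRL"}
        )
        assert "D_HPRL" in ann.candidates

    def test_longest_match_preferred(self, tiny_lexicon):
        # "2-bromolisuride" must not also fire a nested "lisuride" match
        art = cr.Article("9", "t", "Only 2-bromolisuride was given. Nothing else.")
        ann = cr.match_entities(segment_article(art), tiny_lexicon)
        assert ann.candidates == {"C_2BR"}

    def test_case_sensitive_symbol_not_matched_lowercase(self, tiny_lexicon):
        art = cr.Article("9", "t", "The prl value rose. It fell later.")
        ann = cr.match_entities(segment_article(art), tiny_lexicon)
        # 'prl' (lowercase) must not match the case-sensitive symbol PRL
        assert "G_PRL" not in ann.candidates

    def test_matches_equal_bruteforce_oracle(self, tiny_lexicon, demo_article):
        seg = segment_article(demo_article)
        ann = cr.match_entities(seg, tiny_lexicon)
        assert _package_mentions(ann) == _oracle_mentions(seg, tiny_lexicon)

    def test_matches_equal_oracle_on_synthetic_articles(self, small_sim):
        lexicon = small_sim["lexicon"]
        gold = small_sim["gold"]
        for art in small_sim["corpus"].articles[:40]:
            seg = segment_article(art)
            priority = gold[art.article_id]
            ann = cr.match_entities(seg, lexicon, priority)
            assert _package_mentions(ann) == _oracle_mentions(seg, lexicon, priority)

    def test_ambiguous_surface_mentions_all_owners(self):
        lex = cr.EntityLexicon(
            [
                cr.LexiconEntry("C1", "chemical", ("sharedterm",), ()),
                cr.LexiconEntry("C2", "gene", ("sharedterm",), ()),
            ]
        )
        art = cr.Article("1", "t", "We measured sharedterm today. It varied.")
        ann = cr.match_entities(segment_article(art), lex)
        assert ann.candidates == {"C1", "C2"}

    def test_candidates_equal_mention_ids(self, small_sim):
        for ann in small_sim["annotated"][:20]:
            assert ann.candidates == {m.entity_id for m in ann.mentions}


def test_annotate_corpus_gold_priority_completeness(small_sim):
    """Gold CAEs with an in-text surface form are never lost."""
    gold = small_sim["gold"]
    for ann in small_sim["annotated"]:
        assert gold[ann.article_id] <= ann.candidates


def test_token_count_consistency(demo_article):
    seg = segment_article(demo_article)
    assert seg.token_count == len(seg.title_tokens) + sum(len(s) for s in seg.sentences)
    assert seg.abstract_token_count == seg.token_count - len(seg.title_tokens)
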