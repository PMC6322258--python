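"""Fixed-formula fusion scorers and the learned pairwise ranker."""

import numpy as np
import pytest

import caerank as cr
from caerank.entity_recognition import TITLE, AnnotatedArticle, Mention
from caerank.fusion import (
    ScorerConfig,
    ablation,
    bm25e_score,
    ccsee_score,
    egrabe_score,
    ese_score,
    rank_article,
    tfidf_score,
    train_ranker,
)
from caerank.indicators import FeatureVector


def _fv(**kw):
    base = dict(
        entity_id="E", article_id="a", tf=1, idf=1.0, cooc=0.0,
        avg_tf=1.0, title=0, abstract_1=0, abstract_2=0, abstract_3=0,
    )
    base.update(kw)
    return FeatureVector(**base)


def _stats(n=10, df=5, c=5, avgal=50.0, eid="E"):
    return cr.CorpusStats(n, {eid: df}, {eid: c}, avgal)


class TestTfidf:
    @pytest.mark.parametrize(
        "tf,idf,expected", [(2, 1.0, 2.0), (7, 0.0, 0.0), (3, 2.0, 6.0)]
    )
    def test_product(self, tf, idf, expected):
        assert tfidf_score(_fv(tf=tf, idf=idf)) == pytest.approx(expected)


class TestBM25e:
    def test_tf1_average_length_reduces_to_idf(self):
        stats = _stats(avgal=60.0)
        for k1, b in [(0.0, 0.0), (1.2, 0.75), (2.0, 1.0), (5.5, 0.3)]:
            got = bm25e_score(_fv(tf=1, idf=1.7), 60.0, stats, k1, b)
            assert got == pytest.approx(1.7, abs=1e-12)

    def test_large_tf_asymptote(self):
        stats = _stats(avgal=60.0)
        got = bm25e_score(_fv(tf=10_000, idf=1.0), 60.0, stats, 1.2, 0.75)
        assert got == pytest.approx(2.2, rel=1e-3)

    def test_direct_substitution(self):
        stats = _stats(avgal=60.0)
        got = bm25e_score(_fv(tf=2, idf=1.0), 60.0, stats, 1.2, 0.75)
        assert got == pytest.approx(2 * 2.2 / 3.2)  # 1.375 * idf

    def test_b_zero_length_independent(self):
        stats = _stats(avgal=60.0)
        s1 = bm25e_score(_fv(tf=3, idf=1.0), 10.0, stats, 1.2, 0.0)
        s2 = bm25e_score(_fv(tf=3, idf=1.0), 500.0, stats, 1.2, 0.0)
        assert s1 == pytest.approx(s2)

    def test_monotone_in_tf(self):
        stats = _stats(avgal=60.0)
        vals = [
            bm25e_score(_fv(tf=t, idf=1.0), 60.0, stats, 1.2, 0.75)
            for t in range(1, 20)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))


class TestESe:
    def test_equal_length_concentration_one(self):
        stats = _stats(n=5, df=5, c=5, avgal=60.0)
        got = ese_score(_fv(tf=1), 60.0, stats)
        assert got == pytest.approx(1 / 1.45)

    def test_second_factor_sqrt_n_over_df(self):
        # c == DF makes the concentration factor sqrt(N/DF)
        stats = _stats(n=20, df=5, c=5, avgal=60.0)
        sat = 1 / 1.45
        assert ese_score(_fv(tf=1), 60.0, stats) == pytest.approx(sat * 2.0)

    def test_unseen_entity_errors(self):
        stats = cr.CorpusStats(10, {}, {}, 50.0)
        with pytest.raises(ValueError):
            ese_score(_fv(tf=1), 50.0, stats)

    def test_monotone_in_tf_and_concentration(self):
        stats = _stats(n=20, df=5, c=5, avgal=60.0)
        v = [ese_score(_fv(tf=t), 60.0, stats) for t in range(1, 10)]
        assert all(a < b for a, b in zip(v, v[1:]))
        low = ese_score(_fv(tf=2), 60.0, _stats(n=20, df=5, c=5))
        high = ese_score(_fv(tf=2), 60.0, _stats(n=20, df=5, c=15))
        assert high > low


def _ann(mention_spec, n_sentences=5):
    mentions = [
        Mention(eid, eid.lower(), loc, i, None if loc == TITLE else i)
        for i, (eid, loc) in enumerate(mention_spec)
    ]
    return AnnotatedArticle("a", 50, n_sentences, 45, mentions)


class TestCCSEe:
    def test_out_of_zone_entity_scores_zero(self):
        ann = _ann([("A", 3), ("B", 0)], n_sentences=8)
        cfg = ScorerConfig(background_profile=(1.0,), conclusion_profile=(1.0,))
        assert ccsee_score(ann, "A", cfg) == 0.0

    def test_title_only(self):
        ann = _ann([("A", TITLE)])
        assert ccsee_score(ann, "A", ScorerConfig(goal_w=1.0)) == 1.0

    def test_title_plus_last_sentence(self):
        ann = _ann([("A", TITLE), ("A", 4)], n_sentences=5)
        cfg = ScorerConfig(
            goal_w=1.0,
            background_profile=(),
            conclusion_profile=(1.0, 0.5, 0.25),
        )
        assert ccsee_score(ann, "A", cfg) == pytest.approx(2.0)

    def test_multiple_occurrences_amplify(self):
        one = ccsee_score(_ann([("A", 0)]), "A")
        two = ccsee_score(_ann([("A", 0), ("A", 1)]), "A")
        assert two > one


class TestEGRABe:
    @pytest.mark.parametrize(
        "fv_kw,x,expected",
        [
            (dict(tf=3, title=1, abstract_1=1), 1, 3),
            (dict(tf=1), 1, 0),
            (dict(tf=4), 2, 1),
            (dict(tf=2, title=1, abstract_3=1), 3, 2),
        ],
    )
    def test_rule_sum(self, fv_kw, x, expected):
        assert egrabe_score(_fv(**fv_kw), x) == expected

    def test_monotone_in_x(self):
        fv = _fv(tf=1, abstract_1=0, abstract_2=1, abstract_3=1)
        assert (
            egrabe_score(fv, 1) <= egrabe_score(fv, 2) <= egrabe_score(fv, 3)
        )


class TestRankArticle:
    def test_sort_and_lexicographic_tiebreak(self):
        ann = _ann([("A", 0), ("B", 0), ("B", 1), ("B", 2), ("C", 1)])
        stats = cr.compute_corpus_stats([ann])
        ranked = rank_article(ann, "tf", stats)
        assert ranked.entity_ids == ["B", "A", "C"]
        assert [r for _, _, r in ranked.entries] == [1, 2, 3]

    def test_single_candidate(self):
        ann = _ann([("A", 0)])
        ranked = rank_article(ann, "tf", cr.compute_corpus_stats([ann]))
        assert ranked.entries[0][2] == 1

    def test_random_reproducible_by_seed(self):
        ann = _ann([("A", 0), ("B", 1), ("C", 2), ("D", 3)])
        stats = cr.compute_corpus_stats([ann])
        r1 = rank_article(ann, "random", stats, seed=5)
        r2 = rank_article(ann, "random", stats, seed=5)
        r3 = rank_article(ann, "random", stats, seed=6)
        assert r1.entity_ids == r2.entity_ids
        assert r1.entity_ids != r3.entity_ids or r1.entries != r3.entries

    def test_unknown_scorer_rejected(self):
        ann = _ann([("A", 0)])
        with pytest.raises(ValueError):
            rank_article(ann, "pagerank", cr.compute_corpus_stats([ann]))


class TestAblation:
    def test_all_minus_abstract2(self):
        assert ablation("abstract_2") == cr.ALL_MINUS_ABSTRACT2

    def test_unknown_member_rejected(self):
        with pytest.raises(ValueError):
            ablation("abstract_9")


class TestTrainRanker:
    def _separable(self, small_sim):
        """Features where avg_tf strictly separates CAEs within articles."""
        return cr.build_features(small_sim["annotated"], small_sim["stats"])

    def test_separable_corpus_recovery(self):
        # synthetic feature vectors: CAEs have strictly larger avg_tf
        rng = np.random.default_rng(0)
        feats, gold = [], {}
        for a in range(30):
            aid = f"a{a:02d}"
            gold[aid] = {f"{aid}_cae"}
            feats.append(_fv(entity_id=f"{aid}_cae", article_id=aid,
                             avg_tf=3.0 + rng.random(), tf=1))
            for j in range(4):
                feats.append(_fv(entity_id=f"{aid}_n{j}", article_id=aid,
                                 avg_tf=1.0 + rng.random(), tf=1))
        model = train_ranker(feats, gold, feature_subset=("tf", "avg_tf"), seed=0)
        w = dict(zip(model.feature_names, model.weights))
        assert w["avg_tf"] > 0
        # perfect ranking on training articles
        for a in range(30):
            aid = f"a{a:02d}"
            scored = sorted(
                (fv for fv in feats if fv.article_id == aid),
                key=lambda fv: -model.score(fv),
            )
            assert scored[0].entity_id == f"{aid}_cae"

    def test_identical_seed_identical_weights(self, small_sim):
        feats = self._separable(small_sim)
        gold = small_sim["gold"]
        m1 = train_ranker(feats, gold, seed=3)
        m2 = train_ranker(feats, gold, seed=3)
        assert m1.weights == m2.weights

    def test_antisymmetry_of_pairwise_objective(self, small_sim):
        """Swapping CAE and non-CAE roles negates the learned weights."""
        feats = self._separable(small_sim)
        gold = small_sim["gold"]
        inverted = {
            ann.article_id: ann.candidates - gold[ann.article_id]
            for ann in small_sim["annotated"]
            if ann.candidates - gold[ann.article_id]
        }
        m = train_ranker(feats, gold, seed=0)
        m_inv = train_ranker(
            [fv for fv in feats if fv.article_id in inverted], inverted, seed=0
        )
        w = np.array(m.weights)
        w_inv = np.array(m_inv.weights)
        assert np.allclose(w, -w_inv, atol=5e-3 * max(1, np.abs(w).max()))

    def test_no_usable_pairs_errors(self):
        feats = [_fv(entity_id="x", article_id="a")]
        with pytest.raises(ValueError):
            train_ranker(feats, {"a": {"x"}})

    def test_constant_feature_gets_zero_weight(self):
        rng = np.random.default_rng(1)
        feats, gold = [], {}
        for a in range(20):
            aid = f"a{a}"
            gold[aid] = {f"{aid}_c"}
            feats.append(_fv(entity_id=f"{aid}_c", article_id=aid,
                             avg_tf=2 + rng.random(), title=1))
            feats.append(_fv(entity_id=f"{aid}_n", article_id=aid,
                             avg_tf=1 + rng.random(), title=1))
        model = train_ranker(feats, gold, feature_subset=("title", "avg_tf"))
        assert dict(zip(model.feature_names, model.weights))["title"] == 0.0

    def test_model_json_roundtrip(self, tmp_path, small_sim):
        model = train_ranker(self._separable(small_sim), small_sim["gold"], seed=1)
        p = tmp_path / "m.json"
        model.to_json(p)
        back = cr.RankerModel.from_json(p)
        assert back.feature_names == model.feature_names
        assert np.allclose(back.weights, model.weights)
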