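import pytest

import caerank as cr


@pytest.fixture(scope="session")
def tiny_lexicon() -> cr.EntityLexicon:
    """Hand-built CTD-style lexicon used by the recognition fixtures."""
    rows = [
        ("D003042", "chemical", ("cocaine",), ()),
        ("C_LIS", "chemical", ("lisuride",), ()),
        ("C_DOPA", "chemical", ("dopamine",), ()),
        ("C_TDHL", "chemical", ("transdihydrolisuride",), ()),
        ("G_PRL", "gene", ("prolactin", "PRL"), ()),
        ("D_HPRL", "disease", ("hyperprolactinaemia",), ("hyperprolactinemia",)),
        ("C_2BR", "chemical", ("2-bromolisuride",), ()),
    ]
    return cr.EntityLexicon(
        [cr.LexiconEntry(*row) for row in rows]
    )


@pytest.fixture
def demo_article() -> cr.Article:
    return cr.Article(
        article_id="6492995",
        title="Lisuride effects on prolactin secretion",
        abstract=(
            "Rats received 2.5 mg/kg lisuride (LIS) daily. "
            "LIS reduced prolactin and 2-bromolisuride uptake. "
            "Dopamine (DA) levels were stable. "
            "DA and LIS interact in hyperprolactinaemia."
        ),
        pub_year=1984,
    )


@pytest.fixture(scope="session")
def small_sim():
    """Moderate synthetic study shared by indicator/fusion/evaluation tests."""
    cfg = cr.SimConfig(n_articles=120, vocab_size=120, seed=11)
    corpus, lexicon, gold, truth = cr.generate_corpus(cfg)
    anns = cr.annotate_corpus(corpus, lexicon, gold)
    return {
        "cfg": cfg,
        "corpus": corpus,
        "lexicon": lexicon,
        "gold": gold,
        "truth": truth,
        "annotated": anns,
        "stats": cr.compute_corpus_stats(anns),
    }
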