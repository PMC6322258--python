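# caerank

Ranking **conclusive association entities** (CAEs) in biomedical titles and
abstracts.

A CAE of an article is a gene, disease or chemical that is *specifically*
involved in the associations the article concludes — the entities a curator
of a database such as CTD (Comparative Toxicogenomics Database) would record
for it. Among the candidate entities a controlled vocabulary detects in a
title and abstract, CAEs are a small subset: an entity may appear
prominently (even in the title) and still not be one of the article's
conclusive targets. `caerank` ranks each article's candidates so that its
CAEs surface at the top, for curation support and exploratory literature
analysis.

## Method

Candidates are detected by dictionary matching against a lexicon of entity
names, symbols and synonyms (with per-article resolution of author-defined
parenthesised abbreviations such as "dopamine (DA)"). Each candidate *e* in
article *a* within collection *C* is scored by five families of statistical
indicators:

| family        | indicator    | definition |
|---------------|--------------|------------|
| frequency     | `TF(e,a)`    | number of times *e* appears in *a* |
| rareness      | `IDF(e)`     | log₂((\|A\|+1)/(DF(e)+1)) |
| co-occurrence | `CoOcc(e,a)` | Σ_{x≠e} \|S_{e∩x}(a)\| / \|S_e(a)\| over abstract sentences |
| concentration | `AvgTF(e)`   | c(e,C) / DF(e) |
| locality      | `TITLE(e,a)`, `AbstractX(e,a)` | presence in the title / first-or-last X abstract sentences |

where DF(e) is the number of articles mentioning *e*, c(e,C) its total
mention count, and S_e(a) the set of abstract sentences mentioning *e*.
Indicators are fused either by fixed formulas (TF·IDF, a BM25-style
saturation `BM25e`, the concentration-weighted `ESe`, positional `CCSEe`,
rule-count `eGRABe-X`) or by a learned linear pairwise ranker trained on
(CAE, non-CAE) feature differences within articles. Rankings are evaluated
with MAP, average P@X and %P@X>0 under 5-fold cross-validation with paired
t-tests; distribution analysis (per-bin probability gain of finding CAEs)
and frequency–recency maps of predicted CAEs support exploratory curation.

A seeded synthetic-corpus generator emits articles, lexicon and gold CAE
files with tunable class contrasts (frequency, concentration, title and
boundary placement), so the whole pipeline is testable without any
downloads.

## Worked example

```python
import caerank as cr

cfg = cr.SimConfig(n_articles=200, vocab_size=150, seed=42)
corpus, lexicon, gold, truth = cr.generate_corpus(cfg)
anns = cr.annotate_corpus(corpus, lexicon, gold)

plan = cr.make_folds([a.article_id for a in anns], n_folds=5, seed=42)
for scorer in ("avgtf", "tfidf", "random"):
    report = cr.cross_validate(anns, gold, scorer, plan, seed=42)
    print(f"{scorer:8s}  MAP={report.map:.4f}  %P@2>0={report.pct_p_at_positive[2]:.2f}")

fused = cr.cross_validate(
    anns, gold, cr.LearnedScorer(cr.ALL_MINUS_ABSTRACT2, seed=42), plan
)
print(f"{'fused':8s}  MAP={fused.map:.4f}  %P@2>0={fused.pct_p_at_positive[2]:.2f}")
```

prints

```
avgtf     MAP=0.7383  %P@2>0=86.00
tfidf     MAP=0.6277  %P@2>0=71.50
random    MAP=0.4690  %P@2>0=50.00
fused     MAP=0.8127  %P@2>0=90.00
```

On this corpus the concentration indicator AvgTF alone ranks a CAE into
the top two positions for 86% of articles (random ordering: 50%), and the
learned fusion of TF, IDF, CoOcc, AvgTF and TITLE lifts MAP from 0.74 to
0.81 and top-2 coverage to 90%. The same pipeline is available from the
shell via the `caerank` command (`simulate`, `annotate`, `features`,
`score`, `train`, `evaluate`, `compare`, `analyze`, `map`).

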