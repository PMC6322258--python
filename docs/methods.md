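# Methods

## Problem and pipeline

Given an article's title and abstract, the task is to rank its candidate
entities — the lexicon entities detected in the text — so that the
conclusive association entities (CAEs, the entities curators would record
as targets of the article's concluded associations) appear at the top.
The pipeline has five stages: dictionary-based candidate detection,
per-(entity, article) indicator computation, score fusion, ranking
evaluation, and exploratory analysis/visualisation. Every stage is
deterministic given its inputs and a seed.

## Candidate detection

Text is tokenised into alphanumeric runs with internal hyphens
("2-bromolisuride" is one token); sentences are split by a rule-based
segmenter (terminal `.?!` followed by whitespace and an uppercase letter
or digit, with guards for decimals, common abbreviations and personal
initials). The title is segmented separately and is *not* an abstract
sentence: term frequency counts title mentions, but sentence-level
statistics (co-occurrence, first/last-X locality) see abstract sentences
only.

Matching is a three-pass scan: (1) surface forms of *priority* entities —
the article's curated CAEs, whose presence is externally confirmed, so
they can never be lost to matching heuristics; (2) official names and
symbols of all entities; (3) synonyms, only for entities not already
matched in the article. Within each pass, overlaps resolve
longest-match-first and left-to-right, and a token span is consumed by at
most one match per pass so frequencies are never double-counted. Matching
is case-insensitive except for all-uppercase symbols of length ≤ 4
(e.g. gene symbols), which match exactly — the standard dictionary-matching
trade-off between recall on names and precision on short symbols.
Author-defined abbreviations ("dopamine (DA)") are resolved per article by
the parenthesis pattern: a single-token short form whose immediately
preceding tokens match a lexicon surface form is mapped to that entity
(first definition wins; forms already in the lexicon are not overridden).
Ambiguous surface forms owned by several entities yield a mention for
every owner, with a logged warning; no statistical disambiguation is
attempted.

## Indicators

For entity *e* in article *a* of collection *C* (|A| articles):

* `TF(e,a)` — mention count in title + abstract.
* `IDF(e) = log2((|A|+1)/(DF(e)+1))`, with +1 smoothing so entities
  unseen in the statistics collection stay finite.
* `CoOcc(e,a) = Σ_{x≠e} |S_e∩x(a)|/|S_e(a)|`, zero for title-only
  entities (guarded division) and sole candidates.
* `AvgTF(e) = c(e,C)/DF(e)` — concentration; ≥ 1 by construction and
  undefined (an error) when DF = 0. When feature vectors must be built
  for an entity unseen in the statistics collection (cross-validation
  prediction), its concentration is estimated from the only article
  available, i.e. its TF there.
* `TITLE(e,a)` and `AbstractX(e,a)` for X ∈ {1,2,3}; abstracts with
  ≤ 2X sentences make every abstract-located entity eligible.

Article length |a| counts *all* tokens, not only lexicon terms, and the
same mean token count serves as both `avgal` (BM25e) and `avgdl` (ESe).
In cross-validation, collection statistics come from the training folds
only; a whole-collection mode is available for exploratory use.

## Fusion

Typical strategies: `TFIDF = TF·IDF`;
`BM25e = TF(k1+1)/(TF + k1(1−b+b|a|/avgal))·IDF` with the standard BM25
defaults k1 = 1.2, b = 0.75 (configurable);
`ESe = [TF/(TF+0.45√(|a|/avgdl))]·√((c/DF)³·N/DF)`;
`CCSEe` sums positional weights for the goal (title, weight 1), the
background (first three sentences, weights 1, 2/3, 1/3) and the
conclusion (last three sentences, weights 1, 2/3, 1/3 from the end) over
all occurrences, so repeated mentions amplify — the zone profiles are
configuration, since only their qualitative shape is prescribed;
`eGRABe-X` adds one point each for TF ≥ 3, a title occurrence, and a
first/last-X occurrence.

Learned fusion is a linear pairwise ranker: within each training article
every (CAE, non-CAE) candidate pair contributes the difference of their
z-scored feature vectors with label +1 and its negation with label −1,
and a linear SVM (squared hinge, primal, C = 1.0 by default, no
intercept) is fit on the differences — the RankingSVM objective family.
Features are z-scored on training data; constant features receive zero
weight. Articles lacking either a CAE candidate or a non-CAE candidate
carry no pairwise information and are skipped with a logged count. The
`ALL` feature set is {TF, IDF, CoOcc, AvgTF, TITLE, Abstract2};
`ALL-X` ablations drop one member, `ALL_MINUS_ABSTRACT2` being the
default fused configuration.

Every ranking breaks score ties by entity id ascending, so all
downstream metrics are deterministic.

## Evaluation

AP(i) = (1/k_i) Σ_j j/Seen_i(j) with Seen_i(j) the rank of the j-th
best-ranked CAE; MAP is the mean over articles. Average P@X is reported
for X ∈ {1,2,3,5} and %P@X>0 for X ∈ {1,2,3}. P@X keeps denominator X
even when fewer candidates exist. Gold CAEs absent from the candidate
list are dropped from k_i (counted in the report); articles with no
candidates, or none of whose CAEs are candidates, are excluded and
counted. Cross-validation uses a seeded even 5-fold split; one fold plan
is reused across scorers so paired comparisons are valid. Scorer
comparisons use two-sided paired t-tests on per-article AP (or P@X for
P@X comparisons) at α = 0.01; identical vectors short-circuit to
t = 0, p = 1.

The analytic random baseline uses the hypergeometric identity
P(≥1 of k CAEs in top X of n) = 1 − C(n−k,X)/C(n,X) (probability 1 when
X > n−k), averaged over articles.

## Distribution analysis and maps

Indicator profiles use 20 equal-width bins over [0, observed max]
(one bin per integer value for TF). Per bin, P_i(CAE) and P_i(NonCAE)
normalise over classes, and ProbGain_i is the CAE fraction within the
bin minus the overall CAE rate — its bin-count-weighted mean is
identically zero, which the tests verify. Positional profiles assign
each mention to one of 20 relative parts of the abstract (word- or
sentence-based) with title mentions as a separate leading category.

The frequency–recency map plots, for each entity predicted as a CAE
(top-2 of the fused ranking by default), the number of predicting
articles against their mean publication year, split into four zones by a
frequency and a year threshold (I frequent/older, II frequent/recent,
III infrequent/older, IV infrequent/recent — the "emerging entities"
zone). Articles without a publication year are skipped with a count.
A focused view rebuilds the map over the articles sharing one entity of
interest, excluding that entity. Jaccard similarity compares article
sets (e.g. recommended vs curated).

## Synthetic corpora

The generator draws a vocabulary of collision-free single-token names
(optional synonyms, optional uppercase abbreviations introduced in text
via the parenthesis pattern), assigns Zipf popularity (exponent 1.1),
designates 25% of entities "focal", and per article samples 5–10
candidates, 1–3 of which become CAEs with strong affinity for focal
candidates. Mention counts are 1 + Poisson(λ) so every candidate
appears; λ is 1.0 for CAEs vs 0.6 for non-CAEs, multiplied by the
concentration boost (3.0) for focal entities — making concentration the
dominant signal, with milder frequency, title (0.35 vs 0.10) and
boundary-sentence (0.50 vs 0.30) effects. Abstracts have 5–9 sentences
of filler words drawn from the same uniqueness pool as entity names;
years are uniform on 2000–2016. These defaults were fixed once as a
realistic concentration-dominant regime; `null_config()` equalises all
class contrasts to give an exchangeability null.

What the generator does *not* emulate: real linguistic structure,
correlated entity co-occurrence patterns, multi-word and ambiguous
nomenclature at realistic rates, curation noise, and corpus scale.
Passing tests therefore demonstrate correctness of the computations and
the qualitative behaviour of the indicators under controlled contrasts,
not performance levels on real curated literature.

## Numerical and design choices

* Tie-breaks: entity id ascending everywhere; fold assignment by seeded
  permutation, round-robin.
* IDF smoothing: +1 in numerator and denominator, as printed.
* Degenerate inputs: empty candidate sets rank to empty lists with a
  warning; title-only entities have CoOcc 0; DF = 0 entities are an
  error for AvgTF/ESe (with the fallbacks above where a finite feature
  value is required).
* The per-article random scorer seeds a generator from (seed,
  CRC32(article id)), so corpora and article order can change without
  breaking reproducibility.
* Problem sizes in the test suite (corpora of 120–500 articles, 5 seeds
  for ordering checks, 1000 replicates for t-test calibration, 20 seeds
  for the random-baseline check) were chosen so each property is
  decided well inside its sampling error at desk scale.

## Known limitations

* Dictionary matching has no statistical NER component; recall is
  bounded by the lexicon, and short-symbol case sensitivity can miss
  unconventional casings.
* The abbreviation detector handles only the immediate
  long-form-(short-form) pattern.
* The learned ranker is linear; no kernels or listwise objectives.
* Reported performance on synthetic corpora does not transfer to real
  curated collections, whose scale and vocabulary (millions of terms)
  are out of scope here.
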