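# Methods

This note records the package's modelling choices, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## The study design being emulated

The pipeline reproduces a weblog-mining study design: a crawl of blog
posts is filtered by a personal-story classifier; the resulting story
index is searched with a fictional *prototype story* describing a
stroke; retrieved stories are judged relevant (a stroke experience),
irrelevant, or skipped; relevance feedback refines the query; relevant
stories are hand-coded for narrator, patient sex and age, symptoms,
stroke type and delays; and the coded records are analysed with
chi-square tests and logistic regression. The original corpus (a
two-year crawl, millions of posts) is not redistributable, so the
package generates synthetic corpora whose *coded-margin structure*
matches the published summary tables, and ships those tables as a
fixture so the printed statistics can be recomputed from counts alone.

## Synthetic corpus generator

`CorpusConfig` defaults encode the published margins on a 2000-post desk
corpus (200 stroke stories, 800 other personal stories, 1000 non-story
posts):

- narrator: first-person fraction 97/191 ≈ 0.508;
- patient sex: female fraction 91/174 ≈ 0.523 (among symptom-reporting
  stories);
- stroke type: ischemic/hemorrhagic/unknown = 67:29:78 over 174;
- per-symptom prevalence by sex from the symptom table (e.g. impaired
  speech 59/91 women, 47/83 men), with mental status change additionally
  split by narrator (27/48, 16/44 first person; 12/43, 11/39 third) —
  the narrator interaction is the analysis target, so it is planted;
- hemiparesis subtype (body/face/both) mix by sex conditional on
  hemiparesis;
- age reported with probability 85/174, banded by the seven-band age
  table; witness, relation, assistance, delay (by sex: 35/80 vs 24/76)
  and treatment fields at their reported rates.

**Independence simplification.** Symptom flags are drawn independently
per symptom at the marginal rates. The source reports only marginals;
any joint structure (symptom co-occurrence, age×sex×narrator) would be
invented, so none is. Consequences: analyses of *pooled* flags (e.g.
"≥1 nontraditional symptom") have margins implied by independence, not
by the published pooled table; tests exercising pooled flags on
synthetic data are therefore qualitative, not count-exact.

**Two modes.** `exact_margins` plants narrator, sex and stroke-type
counts exactly via largest-remainder apportionment (floor each target,
hand leftover units to the largest fractional parts, ties by category
order — so 5 stories at fraction 0.5 deterministically split 3/2).
`sampled` draws everything binomially. Margin-exactness tests need the
former; prevalence-recovery tests need the latter.

**Rendering.** Each story is assembled from templated sentences with
pronoun slots. Every flagged symptom contributes one phrase from its
lexicon; each phrase carries a pronoun-free *signature* substring, and
signatures are mutually non-overlapping across symptoms (enforced by a
test). The auto-coder inverts this: a symptom is coded present iff one
of its signatures occurs. Narrator, patient sex, relation, witness,
stroke type, age and delay fields are likewise recoverable from marker
phrases, which is what makes the generate → render → code round trip
exact (≥99% flag accuracy is asserted; in practice it is 100%). Symptoms
are only narrated for the window before medical help arrives — the
renderer never plants post-arrival symptoms, matching the coding rule.

**Distractors.** Non-story posts are review/news/recipe boilerplate.
Non-stroke personal stories mix everyday topics (travel, sports, work),
ER-adjacent minor emergencies, vague health scares, and — the largest
share — *stroke mimics*: migraine with aura, inner-ear vertigo, panic
attack, Bell's palsy, hypoglycemia, narrated through the same sentence
machinery and symptom lexicons as true stroke stories but ending in a
non-stroke diagnosis. Mimics exist because a prototype-story query's
real failure mode is stories that sound like stroke; without them the
desk-scale retrieval task is trivially separable and feedback has
nothing to improve. Polysemous uses of "stroke" (heat stroke, golf
strokes) are planted in the everyday topics for the same reason.

**What the generator does not emulate**: real lexical diversity (the
phrase pools are small), misspellings, topic drift, post length
variation at crawl scale, blogger demographics beyond the configured
margins, and any joint symptom structure. Passing tests therefore show
the *pipeline machinery* is correct under the published margins, not
that the method would achieve the same precision on real blog text.

## Story filter

The original classifier's features live in prior work and are not
reproducible; its *operating point* (precision 0.66, recall 0.50) is the
contract. The default `noise_filter` therefore selects
`TP = round(0.5 × #stories)` true stories and
`FP = round(TP × (1−0.66)/0.66)` non-stories uniformly at random —
calibration is exact up to integer rounding at any corpus size, which a
per-post flip probability would not give. A trainable bag-of-words
logistic classifier is provided behind the same interface as a
convenience baseline; it claims fidelity only to the operating-point
floor, not to the original architecture.

## Retrieval

The index is deliberately self-contained rather than an external search
engine: the contract is ranked retrieval, and a bespoke index keeps the
pipeline dependency-light and fully testable. Conventions:

- tokenizer: lowercase, split on non-alphanumerics, keep alphabetic
  tokens of length ≥2 and digit tokens of length ≥3 (so "911"
  survives); no stemming or stopword removal;
- document weight `(1 + ln tf)·ln(N/df)`, L2-normalized; terms present
  in every document get idf 0 and are dropped;
- cosine scoring, ties broken by ascending document id, so rankings are
  invariant to insertion order;
- Rocchio defaults (α, β, γ) = (1.0, 0.75, 0.15) — the classical SMART
  values, configurable; the source system left them unspecified.
  Negative weights are clipped to zero and the query re-normalized;
- judged documents (including skips) are excluded from later result
  pages; only relevant/irrelevant judgments enter the update. Whether
  the original system re-ranked the full corpus or only unjudged
  documents is not stated; the queue semantics described for skipping
  support the unjudged-only reading adopted here;
- feedback batch size defaults to 10 (unspecified in the source;
  configurable), and the benchmark sessions use batch 20 so
  precision@20 is measured on a full page.

The original prototype-story text is not published in the available
material; the package ships its own exemplar written in the same
colloquial register around the documented keyword families (slurred
speech, one-sided weakness, confusion, "911", "emergency room",
"paramedics", "diagnosed with stroke").

## Coding and agreement

The taxonomy is closed: six traditional symptom heads (hemiparesis with
a body/face/both subtype, impaired speech or comprehension, visual
disturbance, ataxia/discoordination, vertigo, balance difficulty) and
six nontraditional (pain excluding headache, mental status change,
headache, lightheadedness, other neurologic, nonneurologic). Headache
is nontraditional because it is not a focal sign. Derived flags pool
"any traditional", "any nontraditional", and "any nontraditional
excluding mental status change" (the last because mental status change
is analysed on its own).

Coder agreement is *raw percent agreement over (story, field) cells*,
missing-equals-missing counting as agreement. The published figure
(83%) does not state per-field versus per-story granularity; per-field
is this package's stated reading. Cohen's κ is offered alongside,
clearly labelled as not the published metric. Records lacking patient
sex are retained but flagged excluded (the study skipped rather than
deleted them).

## Statistics

- Pearson chi-square, `Σ(O−E)²/E`, **no continuity correction** — the
  printed p-values (.056, .002, .008, .01, .12) only reproduce without
  it. No multiple-testing adjustment, matching the source.
- Expected cell counts below 5 raise a warning rather than switching to
  an exact test, because the source used chi-square throughout.
- Logistic fits use IRLS (deviance tolerance 1e-10, ≤50 iterations) and
  report Wald, likelihood-ratio, and score tests; on a 2×2 the score
  test is algebraically the Pearson chi-square, which is property-
  tested to 1e-10. Any |coefficient| > 15 marks the fit non-converged
  (separation) instead of returning silently. The published logistic
  models' covariate sets are unstated; the single-factor model is
  fitted and all three tests reported.
- P values render at both two and three decimals with the leading zero
  dropped, because the source mixes precisions; percentages render at
  one decimal with half-up rounding (56.25 → 56.3, matching the printed
  style, where Python's default banker's rounding would give 56.2).

## Printed values that do not recompute

Recomputing every printed statistic from the printed counts finds:

- **P=.006** (≥1 nontraditional symptom excluding mental status change,
  first- vs third-person, 41/92 vs 21/82) recomputes to **.009**
  (Pearson; LRT .008, Wald .010). Not reproducible as printed.
- **P=.001** (≥1 nontraditional symptom, hemorrhagic vs ischemic,
  23/29 vs 36/67) recomputes to **.018** (Pearson; LRT/Wald similar).
  Not reproducible as printed.

Both are asserted *at their recomputed values* in the test suite and
excluded from reproduction targets — they are flagged, not silently
"matched". Smaller display-level discrepancies, also left as printed in
the fixture but not asserted: a third-person narrator cell prints 51.5%
where the counts give 50.5% (apparent typo); one table header says men
n=82 where the text uses n=83 (counts taken as printed per table); the
third-person mental-status-change P prints .97 but recomputes to .976
(.98 at two decimals); one symptom row prints P=.62 where its counts
(identical to the ataxia row's, possibly a copy error) give .43; another
prints .67 vs a recomputed .49; the hemiparesis-subtype-by-stroke-type
P prints .30 vs a recomputed .32. The vertigo-by-stroke-type P prints
.01; the recomputation is .0082, i.e. ".008" at three decimals and
".01" at two — consistent.

## Problem sizes and determinism

The standard benchmark corpus is 2000 posts with 200 planted stroke
stories; feedback benchmarks average over 20 seeds; calibration checks
use 1000-story corpora; round-trip accuracy uses 500 planted stories;
recovery checks use n=2000 draws against 3-binomial-SE bands. These
sizes make every check fast while leaving the statistical assertions
well-powered. All randomness flows from a single seed per run
(`numpy.random.default_rng`); pipeline stages derive sub-seeds at fixed
offsets, and re-running a pipeline with the same configuration
reproduces identical artifact checksums (timestamps aside, which live
only in the manifest).

## Known limitations

- The auto-coder is lexicon inversion for closing the synthetic loop;
  it is not a clinical NLP system and will not generalize to free text.
- Cross-table joint consistency cannot be recovered from published
  marginals; record expansion is exact per table only, and the
  generator's pooled-flag margins follow from independence rather than
  from the published pooled tables.
- The trainable story classifier is a baseline, not a reconstruction of
  the original crawl classifier.
- Retrieval quality numbers are properties of the synthetic benchmark,
  not estimates of performance on real weblog data.
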