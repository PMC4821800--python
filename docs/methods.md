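# Methods

## Scope and unit of analysis

`micemeta` operates at the document level throughout. A full-text article is
one observation; mentions found anywhere in its text (sections, tables,
captions included) are candidates for a single unified sex annotation and a
single unified age annotation. No attempt is made to link mentions to
specific experiments or cohorts within an article, and group/subgroup
membership is consumed as input metadata, never computed from text.

## Extraction model

### Sex: dictionary matching

Sex detection is word/phrase matching over a small dictionary, by design.
Categories are *female*, *male* and *both*; both-sex phrases ("either sex",
"both sexes", "males and females", "separated by sex", …) are listed
alongside the single-word entries and win by span length. The two
consequences of this minimalism are intentional and preserved:

* **No inference.** Sex implied only by proxy words (a pregnancy, a dam, a
  gestation time) is not detected; such documents count as sex-not-reported.
* **No discourse filtering.** Literal sex words inside breeding or husbandry
  descriptions ("crossing male carriers with FVB/NJ females") do match even
  when the experimental animals themselves have no stated sex. This is the
  dominant false-positive class of the dictionary approach.

### Age: clue-gated numeral–unit patterns

An age mention requires all three of: a numeral (digits, or the number words
one–twelve), a day/week/month unit (full or abbreviated: `d`, `wk`, `mo`,
plurals), and an age clue (`aged …`, `… old`, `… of age`, `age of …`,
`age: …`, `between X and Y <unit> of age`, …). Ranges accept `to`, `and`,
hyphen, en and em dashes as connectors. It follows that:

* open-ended spans with no closed numeric range ("postnatal day 7 to several
  months") produce no mention — the documented false-negative class;
* a bare numeral–unit with no clue ("15-d timed-pregnant") produces no
  mention, even though `15-d` itself parses as an age phrase;
* decimal ages, the hours/years units, and embryonic/postnatal staging
  (E14.5, P7) are excluded by default. Decimals sit behind
  `allow_decimals=True`; postnatal staging behind the `extended` rule
  profile. Both default off so that the default behavior remains the
  conservative one.

### Matching semantics

Matching is case-insensitive regex over raw text, no tokenization or
lemmatization. Within one kind (sex or age), overlapping candidates are
resolved leftmost-longest: candidates are ordered by start offset, longer
matches shadow shorter ones at the same start, and declaration order breaks
exact ties. Sex and age mentions of different kinds may overlap freely.
Every mention's `surface` equals the text slice at its offsets (0-based,
half-open), and matching is deterministic.

The shipped rule inventory (14 sex, 18 age rules) is declarative — id, kind,
pattern with `<NUM>/<RANGE>/<SEP>/<UNIT>` macros, emitted category — and can
be exported to YAML, edited and reloaded, so an alternative inventory can be
substituted without code changes.

## Unification

Among a document's candidate mentions of one kind, the longest span is
selected; ties are broken by the smallest start offset, then rule id, which
makes the choice independent of input order and idempotent. A document with
separate *male* and *female* mentions and no both-phrase resolves to the
single winning mention's category — faithful to the unification algorithm
even though it can under-count both-sex designs; these documents are flagged
in the debug log. The *mixed*/*separated* qualifier on a both-sex annotation
is set only when the winning surface itself encodes it; analytics aggregate
all of them as *both*.

## Evaluation protocol

Scoring is per document and per characteristic. The system is positive on a
document when it emits an annotation; a positive is true only if the value
agrees with gold — sex by category, age by exact range equality after
normalizing both ranges to days (day = 1, week = 7, month = 30; a declared
convention, not a biological claim). An `age_tolerance_days` flag relaxes the
range comparison; it defaults to 0 because "correct" is taken strictly.
A reported value that disagrees with gold counts as a false positive (the
system returned a wrong term), not additionally as a false negative; as a
result the swap symmetry FP↔FN between system and gold holds only for
presence/absence disagreements.

Precision, recall and F are computed on the percent scale. Zero-denominator
cases raise `UndefinedMetricError` rather than returning 0. **Display
convention:** reported metrics are truncated (not rounded) to one decimal,
and the displayed F is the harmonic mean of the truncated P/R pair, itself
truncated — the convention under which a printed evaluation table is exactly
reproducible from its integer confusion counts (e.g. TP=31, FP=1 → P=96.8;
TP=31, FN=4 → R=88.5; F=92.4). Raw unrounded values are always exposed
alongside.

## Corpus analytics

* **Reporting categories** are a partition: both / sex-only / age-only /
  none, so counts sum to the stratum size in every stratum. A document in
  several disease groups contributes to each (groups are not exclusive).
* **Trends** divide each year's category counts by that year's article
  count; the trend slope is the OLS slope of fraction on year (via
  `numpy.polyfit`). Single-year corpora skip the slope with a note.
* **Sex-bias ratio** uses female-only vs male-only documents; both-sex
  documents are excluded from both sides. It is reported majority:minority
  (≥ 1) with the majority sex as direction; ties give ratio 1, direction
  *none*; a zero minority count is signalled as undefined.
* **Binomial test**: two-sided exact test (`scipy.stats.binomtest`) of
  p = 0.5 on female-only successes among single-sex documents. The 95% CI
  uses the normal approximation p̂ ± 1.96·√(p̂(1−p̂)/n) on the percent scale
  (Clopper–Pearson behind `ci_method="exact"`). The normal CI is the default
  because it is the conventional companion to proportion summaries at these
  corpus sizes (n in the thousands, p̂ far from 0/1).
* **Two-way ANOVA without replication** is the classical partition
  SS_total = SS_rows + SS_cols + SS_residual with df (r−1), (c−1),
  (r−1)(c−1); with one observation per cell the interaction is the error
  term, F = MS_factor/MS_residual, p from the F distribution. It is run on
  the stratum × category *percentage* table, since percentages are the
  figure-level quantity of interest; a constant table yields SS = 0 and an
  undefined F (signalled as `None`, not 0/0). Implemented directly (the
  partition is a dozen lines); tests cross-check it against an
  OLS/`anova_lm` fit and a cell-by-cell oracle to 1e-9 relative tolerance.
* **Journal reporting index** = articles reporting sex and/or age ÷ articles
  reporting neither; journals with a zero denominator are excluded from the
  correlation with a note. Correlations are Spearman (mid-ranks, two-sided p
  via `scipy.stats.spearmanr`).

## Synthetic corpus generator

The generator emulates the *structure* of a reporting-quality study corpus,
not scientific prose. Each document is filler text (from a fixed word list
screened to contain no sex words, units or age clues) plus informative
sentences drawn by category, plus optionally one distractor.

Defaults (chosen once, as the study conditions):

| parameter | default | rationale |
|---|---|---|
| category mix | both 0.50, sex-only 0.12, age-only 0.18, none 0.20 | roughly one article in five reports neither; about half report both |
| sex mix (f, m, both) | 0.51, 0.37, 0.12 | female-only studies outnumber male-only ≈1.4:1; both-sex designs are the rarest |
| group overrides | cardiovascular (0.28, 0.63, 0.09); infectious (0.708, 0.20, 0.092); diabetes (0.35, 0.55, 0.10) | strong male bias (2.25:1) in cardiovascular models, strong female bias (3.54:1) in infectious models, mild male bias (1.57:1) in diabetes |
| age unit mix (d, w, m) | 0.15, 0.75, 0.10 | weeks dominate rodent age reporting |
| year range | 1994–2014 | two-decade corpus window |
| journals | 20 synthetic names | enough journal-level points for a rank correlation |
| distractor rate | 0.0 | distractors are opt-in so the clean corpus is the baseline |

Template tiers are strict: *in-grammar* sentences are guaranteed matchable
by the default rules and their informative spans are always longer than any
span a distractor can produce (so the informative mention wins unification);
*hard-case* distractor sentences reproduce the three documented error
classes (pregnancy-implied sex, breeding-cross sex words, open-ended age
span) and never contribute to gold. Consequences, verified by tests: a
distractor-free corpus scores P = R = 100%; with distractors, age extraction
remains perfect and sex errors occur only in documents carrying the
breeding-cross sentence with no informative sex sentence.

What the generator does **not** emulate — and hence what passing tests do
not show about real articles: genuine prose variability (rule coverage on
real text is far below 100%), within-corpus time trends in reporting rates
(years are sampled uniformly, so fitted trend slopes on synthetic corpora
are near zero), correlated metadata (journal and disease group are drawn
independently), multi-group articles, and any systematic relationship
between journal identity and reporting quality.

## Numerical and size choices

Problem sizes in the test suite and acceptance script (2,000-document
corpora; 3-binomial-σ recovery bounds; 1e-9 relative tolerance on ANOVA and
Spearman oracle agreement) were chosen so that stochastic checks are stable
across seeds while the whole pipeline remains fast (seconds per run). The
day-normalization constants (1/7/30) and the z = 1.96 CI multiplier are
declared conventions. ANOVA p-values can underflow to 0 for extreme F; they
are reported as computed.

## Known limitations

* The rule inventory is intentionally conservative; recall on real full-text
  articles will be bounded by phrase-pattern coverage, and the dictionary
  false-positive class (breeding descriptions) is reproduced, not fixed.
* Reference lists and figure captions are not stripped before matching, so
  sex words occurring there count toward mentions.
* "Both (mixed)" vs "both (separated)" designs cannot generally be
  distinguished from a single unified mention; the qualifier is best-effort.
* Number words stop at twelve; hours/years units are not recognized.
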