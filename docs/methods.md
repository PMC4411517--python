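# Methods

This note documents the retrieval model, the evaluation framework, the
synthetic data bench, and the numerical and design choices made where the
design was genuinely open. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Retrieval model

### Query normalization

Collection keywords are MeSH-style headings. Two rules are applied in fixed
order before querying:

1. **Comma inversion.** Inverted headings read poorly as text words, so
   "Anemia, Sickle Cell" becomes "Sickle Cell Anemia". Headings with several
   commas reverse all segments ("X, Y, Z" → "Z Y X") — a uniform
   generalization of the single-comma case; commas inside parenthetical
   qualifiers are not treated specially. The operation is idempotent.
2. **Vocabulary substitution.** The whole word "neoplasms" (exactly that
   plural, case-insensitive) becomes "cancer", matching lay and full-text
   usage. "neoplasm" and embedded occurrences are untouched.

Normalized terms joined with `AND` form the Boolean query; no field tags are
attached, so terms match both as subject headings and as text words. The web
query joins terms with spaces and appends the literal suffix
`PMID ~random ~trial` (ASCII tilde — the historical synonym operator of web
search).

### Term matching and tokenization

Text is lowercased and split on non-alphanumeric runs; a phrase matches when
its tokens occur contiguously. A term matches a record when it token-equals a
MeSH descriptor or entry term, or occurs as a phrase in title or abstract.
Title and abstract are tokenized with a separator sentinel so phrases cannot
straddle the boundary. Descriptor/entry-term matching is flat — no MeSH tree
explosion — and the only stemming anywhere is the `random*` prefix rule of
the sensitive filter below. Under the MeSH-major restriction (iteration 5)
only major-topic descriptors/entry terms are consulted and the text-word path
is disabled, mirroring a major-field search restriction; all base terms are
restricted, not a subset.

### Methodological filters (hedges)

The published therapy filters are PubMed query strings; to run offline they
are encoded as record-level predicates with equivalent intent, shipped as a
replaceable table (`HEDGE_PREDICATES`) so verbatim filter strings can be
substituted for live use:

* **sensitive** — publication type `Randomized Controlled Trial` or
  `Clinical Trial`; or any title/abstract token starting with `random`; or
  MeSH `Random Allocation` / `Clinical Trials as Topic`; or any
  `therapeutic use` subheading.
* **specific** — publication type `Randomized Controlled Trial`, or all three
  tokens `randomized`, `controlled`, `trial` in title/abstract.
* **systematic-review subset** — publication type `Meta-Analysis`, the phrase
  "systematic review" in title/abstract, or the Cochrane review journal. This
  is a documented approximation: the historical `systematic[sb]` definition
  is not public in usable form, and the predicate is configurable.

Specific implies sensitive by construction, which guarantees the iteration
ladder's hit counts are non-increasing (property-tested on random corpora).

### The iterative strategy

Iterations 1–5 add, cumulatively: nothing; sensitive-or-review filter +
exclusion of review/letter/editorial publication types + abstract
requirement; the specific filter; a core-journal whitelist; the MeSH-major
restriction. The engine returns the results of the last iteration that
retrieved at least `target_count` citations (default 50, the futility point).
Two boundary decisions:

* When even iteration 1 falls short, iteration 1's results are returned
  rather than nothing — the broadest available set is the conservative
  reading of "last iteration with ≥ 50".
* The engine stops at the first sub-target level instead of evaluating all
  five. Under the nesting invariant this is observationally equivalent
  (verified exhaustively against a brute-force restatement of the rule) and
  cheaper; `per_iteration_counts` records only levels actually executed.

Ranking is date-descending with PMID-descending tie-break. Date sorting is
the model's deliberate property (recency matters clinically); the tie-break
merely makes the order total so repeated runs are byte-identical. Records
lacking a day of publication are completed as the first of the month.

The journal whitelist is a user-supplied plain-text file (one title per
line), matched case-insensitively after whitespace normalization; the shipped
synthetic core list stands in for the 106-journal core clinical list, whose
exact historical contents are no longer published. It travels in
`StrategyConfig` because the escalation needs it from level 4 on.

### Web-result parsing

Saved result pages (live scraping is out of scope; the interfaces changed
long ago) are scanned entry-by-entry — each anchor in HTML, each non-empty
line in plain text — for at most `max_results` entries (entries, not
identifiers: 50 result entries may yield any number of citations). PMIDs are
recognized as 7–8-digit runs inside PubMed URLs or adjacent to a `PMID`
marker; bare digit runs are ignored to avoid years and phone numbers. DOIs
use the `10.<registrant>/<suffix>` pattern with trailing punctuation trimmed.
Hits deduplicate on first appearance; unresolvable identifiers are dropped
with a logged count and resolved records deduplicate by PMID.

## Reference standard

A citation qualifies when **relevant** — every original (pre-normalization)
keyword present as MeSH descriptor, entry term, or title/abstract phrase;
comma keywords are also tried inverted, since both surface forms denote the
same heading — and **high quality** — abstracted by one of six evidence-based
synoptic journals (configurable) or published with an accompanying editorial
(the corpus's `has_editorial` flag, as supplied by metadata; no same-issue
requirement is imposed). Keyword matching reuses the retrieval matcher so
adjudication and search agree on string semantics.

**Incorporation-bias guard.** The search modules have no read path to the
quality fields; an architectural test scans their source for the field names.
A strategy therefore cannot gain credit by searching for the signals that
define the reference standard.

## Outcomes and statistics

* **Precision at k = 50.** Boolean strategies: qualifying / examined, where
  examined = min(k, retrieved). Web strategies: qualifying / resolved PubMed
  citations among the first k result entries — the denominator a reader
  actually faces. Precision is 0 when the denominator is 0. Summaries average
  per-search fractions; the pooled ratio of means is a different (and wrong)
  quantity, demonstrated in a test with the 0/10-and-2/2 example.
* **NNR** = 1/median precision, rounded half away from zero; undefined
  (raised) at median precision 0.
* **Quartiles** use linear interpolation between order statistics (R type 7 /
  numpy default) — the convention of the reference statistical environment.
* **Wald CI** without continuity correction, z = Φ⁻¹(0.975) ≈ 1.959964,
  clipped to [0, 1], reported as whole percent.
* **Friedman test** with within-question mid-ranks and the standard tie
  correction; if every block is fully tied the statistic is defined as 0. The
  post hoc is a Nemenyi-style critical difference on mean ranks at α = 0.05
  (q from the studentized range at infinite df, divided by √2) — a standard
  choice, documented as this package's selection since no specific post-hoc
  procedure is canonical for this design. Cross-checked against
  `scipy.stats.friedmanchisquare` exhaustively on small matrices.
* **Chi-square** on the strategies × {≥1 hit, 0 hits} table, no continuity
  correction; a degenerate margin (identical all-zero or all-one rates) is
  defined as statistic 0, p 1.
* **Lilliefors normality test**: KS distance to the normal with estimated
  mean/sd (ddof = 1); because parameter estimation invalidates standard KS
  tables, the p-value is Monte-Carlo calibrated with `n_mc` standard-normal
  replicates under a fixed seed, `p = (1 + #{D* ≥ D}) / (n_mc + 1)`. Null
  rejection rate ≈ α is verified by simulation; agreement with statsmodels'
  table-based implementation is verified within MC/table error.

## Synthetic data bench

The generator emulates the statistical shape the method assumes, not natural
language: titles/abstracts are bags of vocabulary surface forms plus filler
tokens. Defaults are the modeled study's conditions where it states them and
field-plausible values otherwise, chosen once: 312 questions; keyword count
{1, 2, 3} with probabilities {0.25, 0.5, 0.25} (median 2); 20% of questions
forced to carry a comma keyword and 20% a "neoplasms" keyword, to exercise
normalization; P(RCT publication type) = 0.15 and P(meta-analysis) = 0.05
(plausible for therapy-focused MEDLINE slices); P(abstract present) = 0.8;
background quality-flag rate 5%; a 14-journal pool whose first 8 form the
core list; dates uniform on 2000–2009. The corpus default of 2,000 citations
is a desk-scale stand-in for MEDLINE chosen so full pipelines run in seconds;
all statistical-convergence checks use n = 10,000 draws. Each generator draws
from a named substream split from the master seed, so adding one generator
never perturbs another and identical seeds give byte-identical output.

**Planting.** `plant_answers` makes end-to-end precision analytically forced:
planted records receive the newest dates (the head of the date-descending
ranking) and attributes passing every iteration filter up to a chosen
`stop_level` (non-qualifying plants fail level `stop_level + 1`, pinning the
escalation's returned iteration); fillers pad the ranking head to exactly k
records; and background records that would qualify for the question have
their quality flags stripped. The strategy's first-k results then contain
exactly `n_qualifying_in_topk` qualifying citations, so precision@k = q/k
holds as an identity, not a tendency. High-quality-but-irrelevant plants
(retrieved on the wrong topic, earning no credit) are only constructible when
a keyword changes surface form under normalization — with identical forms,
matching the query implies the relevance rule — so they require a
"neoplasms" keyword and the function raises otherwise.

**What passing tests do and do not show.** The bench exercises every code
path with known ground truth, but token-bag text has none of real MEDLINE's
term co-occurrence, citation structure, or indexing noise; real entry-term
coverage is far sparser than the synthetic vocabulary's. Planted-precision
results validate the machinery, not the strategies' field performance:
empirical medians from the original corpus-and-questions setting are not
reproducible at this scale and are not asserted anywhere.

## Known limitations

* Hedge predicates approximate the published filter strings; live-PubMed
  equivalence is not claimed (a live Entrez adapter can implement the same
  backend contract but is deliberately untested here).
* The `.nbib` and PubMed-XML dialects carry entry terms, synoptic reviews and
  the editorial flag in documented extension tags/elements (`ZET`/`ZSY`/`ZED`;
  `EntryTermList`/`SynopticReviewList`/`HasEditorial`) so round-trips are
  lossless; third-party files simply leave those fields empty. JSONL is the
  canonical full-fidelity format.
* Multi-question planting into one corpus (the `simulate` subcommand) scrubs
  background qualifiers question by question, so a later plant can strip an
  earlier plant's quality flags; the manifest is therefore computed from the
  final corpus, keeping evaluation internally consistent.
* Sensitivity/recall is out of scope by design: the target use is
  precision-oriented clinical search, not comprehensive retrieval for
  meta-analysis.
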