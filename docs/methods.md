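# Methods

## The measurement problem

Free-report paradigms ask participants to type whatever words describe a
briefly presented, masked image.  Without an answer key, a report can only
be scored against other people's reports.  The intersubjective-agreement
(IA) index formalises that: a word is *specific* to an image to the extent
that the image's other viewers report it and viewers of every other image
do not.  The index assumes nothing about word meaning — "boat" and
"speedboat" are distinct words throughout — and therefore measures report
*consistency*, not accuracy.

## Study design assumed

The design the package models (and the generator emits): images divided
into disjoint blocks; each participant sees every image of one block exactly
once; three stimulus onset asynchronies (SOA, the target-to-mask interval:
67, 133, 267 ms) with a third of each image's cohort at each SOA; each
(image, SOA) cell holding exactly `n_per_cell` participants (10 at full
design); five words per trial, each with a confidence rating 1–5 (1 =
"don't know", the value participants were told to use for arbitrary
filler words).  `build_cohorts` validates these constraints and flags
irregular cells rather than repairing them.

Participant **order** within a cell — the quantity the baseline exclusion
keys on — is not part of the raw data.  The package defines it as the rank
of first appearance in the input table, overridable by an explicit order
column.  This makes the rule reproducible: any table round-tripped through
`write_responses`/`read_responses` yields identical cohorts.

## Word IA

For reporter *p* of word *w* on image *i*:

* per-SOA scope: within-fraction over the other 9 cell participants;
  baseline fraction for each other image over its 9 cell participants after
  removing the one at *p*'s order position, so numerator and denominator
  match;
* pooled scope: the same with 27 = 3 × 9 participants, removing *p* from
  their own cell and the same-order participant from each of the other two
  SOA cells — and identically for the baseline cells.

The ROC is built over the criterion grid formed by the union of all
observed fractions with {1, 0} (no binning), with the origin (0, 0)
prepended as the criterion nothing passes.  The trapezoidal area over this
grid equals the closed form `P(b < t) + ½·P(b = t)`; the equivalence is
property-tested over random instances, and the production path exploits it
by comparing integer report *counts* (both sides share a denominator), so
every AUC is an exact rational.  Ties are handled by the ½ term — no
jitter, no smoothing.

Word IA is the mean of the reporters' AUCs.  Groups with a single reporter
("rarely reported words") have *no* IA: the result carries an explicit
absent value (`None`/`NaN`), never 0, so downstream means cannot silently
absorb them.  A word never reported on an image at all raises
`WordNotReportedError`, distinct from the defined-but-singleton case.

Registered similar image pairs are excluded from each other's baselines.
Direction of the effect: removing a baseline image whose fraction strictly
exceeds the within-fraction can only raise the AUC.  (For an image exactly
tied with the target the monotonicity holds only when the AUC is at or
above ½ — removing a tie from a below-chance comparison lowers it — which
is why the guarantee is stated for strict exceedance.)

Image IA is the mean of an image's defined pooled Word IAs, undefined when
the image has none; `prop_rare` is the share of the image's unique
(word, image) groups with exactly one reporter.

## Cleaning pipeline

Order: lowercase (whitespace → hyphen, other non-alphanumerics dropped) →
spell-correction → lemmatization → within-trial deduplication on the
normalized form.  Two deliberate choices where practice is often
ambiguous:

* **Deterministic spelling.**  Manual inspection of suggestion lists is not
  reproducible, so a correction is applied only when (a) the shipped manual
  map has an entry, or (b) the word is purely alphabetic, unknown to the
  dictionary, and exactly one dictionary word lies at edit distance one.
  Anything ambiguous passes through unchanged.  The dictionary, lemma table
  (inflected → base form) and manual map are versioned plain-text assets;
  users can supply their own.
* **Dedup after normalization**, so "cat" and "Cats" in one trial collapse
  to a single row (earliest slot, its confidence kept).  Dedup before
  normalization would double-count such variants.

Filler words like "na", "none", "arbitrary" are retained with their
confidence; they are data.  The pipeline is idempotent and touches only the
`word` column.

## SSE and its null

An image's frequency vector counts distinct participants (across SOAs)
reporting each word.  For a pair, SSE sums squared deviations from y = x
over the union vocabulary.  Default convention: perpendicular distance to
the line, `Σ(f_A − f_B)²/2`; the vertical convention `Σ(f_A − f_B)²`
(factor 2) is a switch (`convention="vertical"`, CLI
`--sse-convention`).  The conventions never reorder pairs, but reported
magnitudes differ, so outputs always record which was used.

The null re-pairs images: each iteration picks one member of every
registered pair and partners it with a uniformly drawn *different* image
from the pooled pair members, then records the mean SSE (default 100
iterations).  Self-pairing is disallowed — a self-pair has SSE 0 and would
bias the null toward consistency.  The interval on the null is a central
percentile interval (99% by default).  When a registry contains trios, one
image per trio should be dropped before pairing; which one is a user
choice, as it cannot affect synthetic tests and is dataset-specific.

## Correlation analyses

Pearson correlations with df = n − 2 and Fisher-z 95% CIs: (a) word level,
mean reporter confidence vs pooled Word IA, one point per defined group;
(b) response level per SOA, each response's confidence vs its word's
per-SOA IA; (c) per image, rare-word proportion vs Image IA.  Confidence-1
responses are included by default with an exclusion flag, since
participants were instructed to pad with arbitrary low-confidence words and
the analysis should show, not hide, that regime.  |r| numerically at 1
collapses the CI onto r (Fisher z diverges); constant inputs raise instead
of returning NaN.  Multilevel (mixed-effects) modelling is deliberately out
of scope: `model_ready_table` exports the per-response point table for
lme4-style tooling.

Image rankings order by Image IA (ties by image id) and display each
image's words by IA, then report frequency descending, then
lexicographically — a fixed tie-break so listings are deterministic.

## Synthetic generator

The generator is the package's test bed and defines its study conditions.
Defaults: 20 blocks × 21 images × 30 participants (63,000 responses);
per-image specific lexicons of 12 disjoint tokens; a 40-word shared generic
lexicon of real scene words; noise tokens at rate 0.05 with confidence
pinned to 1.  The probability that a word slot draws from the image's
specific lexicon rises with SOA (0.45 / 0.55 / 0.65) — longer exposures
yield more specific reports — and specific words draw higher confidence
than generic ones, with a mild SOA shift.  These values were chosen once as
a plausible regime in which specific and generic vocabulary coexist at
every SOA; they are ordinary config fields, not calibrated constants.
Misspellings (rate 0.02) and inflections (rate 0.03) are planted only from
the shipped manual map and lemma table, so cleaning recovery is exactly
checkable.  24 natural similar pairs (specific-lexicon overlap 0.8) and 4
artificial pairs (overlap 0.3) are placed across different blocks, as the
design forbids one participant seeing both members.

The SOA assignment uses a cyclic Latin-style grid, row- and
column-permuted: every participant gets 7 trials per SOA and every image
exactly 10 participants per SOA, for any seed.

What the generator does **not** emulate: natural-language statistics
(words are tokens — no synonymy, no frequency skew, no semantic distance
between "specific" and "generic" vocabulary), participant heterogeneity,
typo processes beyond the planted map, and images as anything but opaque
identifiers.  Passing tests therefore certify the *pipeline mechanics and
the statistic's behaviour* under a known generative process, not conclusions
about human vision; with real data the cleaning step inherits whatever
ambiguity the original semi-automatic curation had, and counts can shift by
a small margin accordingly.

Three hand-checkable fixtures pin the arithmetic: `eiffel` (a word reported
by 6 of 10 in one cell and nowhere else — every reporter's within-fraction
is 5/9, every baseline 0, AUC = 1), `uniform` (a word reported by the same
half of every cohort — AUC exactly 0.5), and `sperling` (letter-array
images with fully specific letter tokens — every pooled Word IA and both
Image IAs are 1).

## Problem sizes and runtime

The test suite and the acceptance script run the *full* default design
(63,000 responses, 1,260 cells, ≈21k pooled word groups); the bulk Word-IA
kernel vectorises over order positions using bitmask report sets, so a full
pooled pass takes under a second and the whole acceptance run a few
seconds.  Property tests use 100–300 random instances each (seeded /
derandomized); the desk-scale AUC identity check uses 1,000.

## Known limitations

* The same-order baseline exclusion assumes exactly-`n_per_cell` cells;
  over-recruited cells must be truncated upstream (the first-`n` rule), and
  irregular cells are flagged, not fixed.
* Spell-correction fidelity to any particular human-curated dataset is
  bounded: only unambiguous or manually mapped corrections are applied.
* Word IA is undefined for singletons by construction; studies with few
  participants per cell will discard many words (the package reports those
  counts rather than imputing).
* SSE's absolute scale depends on the distance convention and cohort size;
  compare only within one convention.
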