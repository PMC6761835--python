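# Methods

## Problem and pipeline

Live bivalve molluscs (mussels, clams, oysters, cockles) are sold under
labels that must state the species, packaging date, production method and
country of production, and often also carry a classified production-area
code and a purification (depuration) mention. The zone code and packaging
date together let a consumer or inspector look up the official contaminant
monitoring results for the batch; the package automates reading those
fields from a label photograph and auditing what information labels carry.

The reading pipeline has four stages:

1. **Imaging.** The photo is decoded to three single-channel variants:
   plain greyscale (BT.601 luma), a 3×3 sharpened version (identity + 4-
   neighbour Laplacian, kernel `[[0,-1,0],[-1,5,-1],[0,-1,0]]`), and a 3×3
   box-blurred version binarized by mean-adaptive thresholding. Kernel
   "filters" are implemented as correlation (the kernel slides unflipped),
   the universal image-processing convention; borders replicate the edge
   pixel to avoid dark halos at label edges. Adaptive thresholding marks a
   pixel foreground iff it exceeds its local block mean minus an offset
   (defaults: block 11 px, offset 2), which makes binarization insensitive
   to smooth shadows because pixel and reference shift together. Images
   smaller than the block fall back to a global mean (logged).
2. **OCR.** Each variant is recognized independently. The engine is
   pluggable: a Tesseract adapter (Portuguese language pack, sparse-text
   page segmentation, alphabet whitelist) for real photographs, and a
   simulated backend that replays the label's known layout text through a
   seeded character-error model. Either way the output is restricted to
   the Portuguese alphabet, digits, and the separators `/ - . : ,`.
3. **Extraction.** The text is normalized (lowercase, diacritics stripped
   by Unicode decomposition, punctuation collapsed to spaces — OCR is
   unreliable on case and accents) and matched against controlled
   vocabularies with the normalized Levenshtein similarity
   `sim(a,b) = 1 − lev(a,b)/max(|a|,|b|)` evaluated over sliding windows of
   consecutive tokens, window length equal to the synonym's token count.
   A field is accepted at similarity ≥ 0.6 (configurable); purification
   keywords use a stricter 0.85 because a false "purified" claim is worse
   than a missed one. Dates are matched as `d{1,2} sep d{1,2}` with an
   optional same-separator 2- or 4-digit year, day 1–31 and month 1–12;
   mixed-separator strings and patterns glued to further separator+digit
   material are rejected as lot codes. Two-digit years map to 2000+yy.
4. **Aggregation.** Categorical fields take the candidate with the highest
   similarity across the three variants (matched always beats unmatched;
   ties broken by the fixed precedence greyscale > sharpened > blurred).
   Day and month are each decided by plurality vote over the variants that
   produced a date — voted independently, so the final pair may mix
   variants. The year comes from print when present; otherwise the
   caller-supplied reference date's year is assumed, unless that would put
   the packaging date in the future, in which case the previous year is
   used (a December label read in January). A printed year is trusted even
   if in the future, since the inference rule exists only for labels that
   omit the year. Day/month pairs impossible in both candidate years
   (31/02) flag the reading invalid. A reading is *complete* when species,
   method, country and a valid date were all decoded, and has *extra*
   consumer-usable information when a zone code was decoded or purification
   mentioned.

The reference date is an explicit input everywhere in the library; only the
CLI defaults it to the system clock, and it is echoed into every output
manifest for reproducibility.

## Synthetic labels and the error model

No photo collection ships with the package, so the generator emulates one.
`sample_record` draws ground truth with the frequencies observed in the
audited retail collection: zone code printed with probability 54/86,
purification mentioned 13/86, origins 60/86 Portugal, 22/86 Spain, 4/86
Netherlands. Separator dialects are uniform over `/ - .`; half the labels
omit the year and the rest split evenly between two- and four-digit print
(no distribution is reported for either; these follow common retail
practice). Production method is uniform aquaculture/wild. The default
packaging year is 2017 (the collection window) and 29 February is never
generated. `render_label` draws the fields in a seeded non-uniform layout —
field order, prefix wording, decoy lot/weight lines and font size all vary —
using Pillow's embedded default vector font at seed-varied sizes, and
returns the exact drawn character sequence (`layout_text`) as the
noiseless-OCR ground truth. `degrade` applies Gaussian blur, a
multiplicative horizontal shadow ramp, additive Gaussian noise and
down/up-scaling, in that order; all-zero parameters are a bitwise identity.

The OCR error model corrupts characters with independent substitution,
deletion and insertion probabilities; substitutions draw from a confusion
table of plausible misreads (l↔1, O↔0, S↔5, separator swaps, …), falling
back to a uniform alphabet draw. Whitespace is never substituted, so line
structure survives even when characters do not. A convenience constructor
splits a total character error rate as 60% substitutions, 20% deletions,
20% insertions. Each variant corrupts the text with an independently
derived seed, emulating the three preprocessed images erring differently.

What the simulator does *not* emulate: spatially correlated failures
(glare, folds destroying whole words), layout-dependent OCR behaviour
(merged columns, reordered lines), and realistic coupling between image
degradation and error rate. Passing the simulated-noise tests therefore
shows the post-OCR logic is correct and noise-tolerant, not that any given
accuracy will be reached on real photographs — that depends on the engine
and the collection.

## The completeness audit and its fixture

`completeness_audit` cross-tabulates decoded records by country ×
zone-presence × purification and derives the headline shares: fraction of
labels with a zone code, fraction with consumer-usable extra information
(zone or purification), and origin shares. The bundled 86-record fixture
reproduces the audited collection's marginals: 60/22/4 by origin, 54 labels
with a zone code (42 of the 60 Portuguese — 70% — and 12 Spanish, all
Galician), and 64 with extra information. The published sub-cells of that
cross-tabulation are internally inconsistent in two places (a with-zone
purification split summing to 11 against a stated total of 12, and an
extra-information total of 64 against 63 derivable from the other cells);
the fixture keeps every row total, the zone totals and the extra-information
count fixed and absorbs the two-label slack into the Spanish purification
sub-cells, which no headline quantity uses.

## Evaluation conventions

Accuracies are exact-match per field. A field absent from a truth record
(a label that never printed a zone) is excluded from that field's
denominator — missing data is not a wrong read. The date is scored both as
*components* (day and month pooled separately; 2n instances for n labels)
and as a *whole* (both correct), and whole-date accuracy is additionally
stratified by separator dialect, omitting empty strata. The overall
accuracy is the micro-average over all evaluable field instances with the
date contributing its two components; this definition is documented rather
than asserted against any published figure, which used a photo set not
available for reproduction. Empty denominators report as not-applicable,
never 0%.

## Problem sizes and numerical choices

The test and acceptance runs use 100 noiseless labels (covering all nine
separator × year-style combinations), a character-error-rate sweep over
{0, 0.02, 0.05, 0.10} with 20 seeds × 25 labels per rate (compared via
means within one standard error, since accuracy at adjacent rates differs
by less than sampling noise at small n), and 500 labels at rate 0.05 for
the purification false-positive check — sizes at which every quantity is
stable to well under a percentage point across seeds. Oracle equivalence
uses 1,000 random string pairs (length ≤ 10) against a textbook DP edit
distance and random 8×8 images against a nested-loop convolution.
Similarity of two empty strings is 1; `max(|a|,|b|)` normalization keeps
the measure in [0,1] and symmetric. Ties anywhere in aggregation resolve
by the documented variant precedence, making every run bit-reproducible
from its seeds.

## Known limitations

- The zone vocabulary is a plausible placeholder, not the official registry
  of classified production areas; deployments must supply their own file.
- Matching is text-only: no bounding boxes or key–value spatial pairing, so
  a stray token resembling a vocabulary entry can match even when printed
  as part of another field. The acceptance thresholds and the ensemble
  merge mitigate but cannot eliminate this.
- Very short zone codes (two characters) are effectively matched exactly:
  at threshold 0.6 a single edit already disqualifies them.
- The real-engine path (Tesseract) is wired but not quantitatively
  validated here; its accuracy depends on engine version, language data and
  photo quality.
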