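# Methods

`triread` simulates how oral vocabulary knowledge shapes individual
differences in reading within the triangle-model framework, and runs the
accompanying statistical analysis end-to-end at desk scale.  This note
records the model, the synthetic language, the measures, the estimators,
and the numerical and design choices behind them.

## The model

The reading system is a deep recurrent network over three key layers —
orthography (14 letter slots x alphabet size), phonology (8 phoneme slots
x 25 phonological features), semantics (one unit per semantic feature) —
plus 4 context units that disambiguate homophone meanings.  Five hidden
layers and two attractor layers connect them:

| route | layers | role |
|---|---|---|
| O→P | `orthography → h_op → phonology` | direct print-to-sound |
| O→S | `orthography → h_os1 → h_os2 → semantics` | print-to-meaning (deepest mapping, two hidden layers) |
| P→S | `phonology → h_ps → semantics`, `context → h_ps` | spoken-word comprehension |
| S→P | `semantics → h_sp → phonology` | meaning naming |
| attractors | `phonology ↔ attr_p`, `semantics ↔ attr_s` | pattern clean-up |

Units are logistic, updated synchronously in discrete time; every listed
connection is full.  The wiring is a data-driven table in
`NetworkConfig`, so alternative routes are testable.  Hidden/attractor
unit counts are free parameters; the defaults (60/40/40/40/40 hidden,
30/30 attractor) are proportioned to the toy layer sizes.

Trial structure (1-indexed time steps):

* comprehension (PS) and naming (SP): input clamped steps 1–8, targets
  scored on steps 7–8; context units are clamped as input on PS trials
  only.
* attractor tasks (PP, SS): pattern clamped steps 1–2, free-running to
  step 8 with the initial pattern as target over steps 3–8 (the scored
  window is switchable to the last two steps).
* reading (READ): orthography clamped steps 1–12; phonological and
  semantic targets both scored on steps 7–12.

Training is stochastic gradient descent with backpropagation through time
over the unrolled trial, learning rate 0.05 in both phases, no momentum
or weight decay.  The training objective is cross-entropy per output unit
(switchable to squared error); summed squared error (SSE) is always the
*evaluation* metric.  Targets are never forced onto a layer — they enter
only through the error signal.  Initial weights and biases are i.i.d.
uniform in ±0.25; with a tighter ±0.1 range one grid cell's reading phase
conditioned badly (slow convergence, a dead O→S hidden layer), while
±0.25 trains every cell cleanly.

Phase one (oral language) interleaves PS/SP/PP/SS at 40/40/10/10,
drawing words frequency-weighted with replacement from the `ovs` most
frequent items, for `ove` total presentations.  Phase two freezes every
oral-phase parameter — the P↔S routes, both attractors, and the biases of
the layers they train (including phonology and semantics) — and trains
only the orthographic routes, with the identical procedure, trial count
and word sequence in every grid cell, so that cells differ only in their
oral history.

Updates may be mini-batched (`batch_size`; each presented word still
counts as one trial, and one task is drawn per update).  `batch_size=1`
is the classical per-trial online regime; the grid uses 16, which makes
the desk-scale grid tractable and, at learning rate 0.05 with summed
cross-entropy, is also *more* stable than strictly online updates.

## The synthetic language

Real-corpus inputs (a 6000-word class of monosyllabic words with
WordNet-derived semantics, corpus frequencies and imageability norms) are
out of scope; the generator produces an artificial language with the same
covariate structure:

* **Words** are monosyllabic `onset + rime` strings over a 12-letter
  alphabet (3 vowels).  Default: 300 words from 25 onsets x 30 rimes.
* **Rime consistency.**  Each consonant letter is always pronounced
  canonically; a controlled fraction of words (default 20%) pronounce
  their rime's vowel with an alternate phoneme.  Exceptions cluster
  family-by-family (as English exceptions do), stay a strict minority of
  their family, and leave other families fully consistent for the
  nonword sets.  `rc` is type-based friends/(friends+enemies) including
  the word itself.
* **Frequencies** are Zipfian (exponent 1.0) over a random rank order,
  normalized; log frequency is ln(relative frequency x 1e6 + 1).
  Vocabulary-size conditions are frequency truncations (top-k).
* **Semantics** are sparse binary vectors; the number of active features
  (uniform 2–8 of 60) doubles as the imageability proxy, the only
  semantic-richness dial a synthetic lexicon offers.  It is monotone in
  what imageability norms index but shares none of their noise structure.
* **Homophones** (3 pairs) duplicate a regular word's form with a second,
  feature-disjoint meaning; the two meanings get distinct context
  indices in 1–4.
* **Nonwords** are unused onset x rime combinations, preferring onsets
  never attested in the lexicon (novel letter strings, like behavioural
  nonword sets); consistent nonwords take rimes from fully consistent
  families, inconsistent nonwords from families with exceptions, and any
  attested family pronunciation counts as correct.
* **Phoneme inventory**: 9-of-25 random binary feature vectors with
  pairwise Hamming distance >= 6, plus an all-zero null phoneme for
  empty slots.

What the generator does **not** emulate: English phonotactics and
orthographic redundancy, morphology, multisyllabicity, the heavy-tailed
semantic feature correlations of WordNet, and norm-based imageability.
Passing tests therefore show that the *mechanism and pipeline* behave as
described on a language with this covariate structure, not that the model
reproduces English-corpus coefficient magnitudes.

## Evaluation

SSE between output and target patterns, read at the final time step of
the trial (switchable to the mean over the scored window).  Accuracy by
nearest-neighbour decoding under Euclidean distance: per phoneme slot
against the inventory (null phoneme included; ties to the lowest index),
and for semantics against all training-set vectors, scoring only the
context-designated meaning of a homophone as correct.  A nonword is read
correctly if its decoded phoneme string matches any acceptable
pronunciation.

## Semantic-reliance measures

**EoCSR** (effect-of-consistency): within the low tertile of the
imageability proxy (ties to the lower tertile), after dropping misread
words and ±2 SD SSE outliers, OLS of phonological SSE on rime consistency
with log frequency and neighbourhood size as controls; the consistency
coefficient, sign-reversed.  Default output is the standardized partial
coefficient (all variables z-scored); the raw-scale coefficient is
available (`standardize=False`).  Note that trimming on the dependent
variable truncates it and attenuates the slope by roughly 15% — an
artifact inherent to DV-based outlier rules, visible in parameter-recovery
simulations and worth remembering when comparing EoCSR magnitudes.

**DoLSR** (division of labour): run a reading trial, take the absolute
net input each unit of the target layer receives via the final connection
of each orthographic route — `h_os2 → semantics` (OS) and `h_op →
phonology` (OP) — at the last time step, average over units and over a
probe set (default: the whole lexicon), and return OS/(OS+OP).

At this scale the two measures correlate strongly but behave differently:
the oral-exposure effect (more exposure → lower SR) is robust on both,
while the vocabulary-size effect at low exposure is reliably visible only
on EoCSR — with two versions per condition, DoLSR's between-version
spread (~0.03) exceeds its between-condition differences.  The grid-level
directional test therefore uses EoCSR, plus DoLSR's exposure direction.

## Statistical battery

* **Preprocessing**: drop misread items, rows with missing covariates,
  and DV outliers beyond ±2 SD of the retained mean, then z-score
  analysis columns.  This is a single pass (trimming again after
  re-standardizing would remove more; iterating a 2 SD rule to a fixed
  point would discard ~16% of a Gaussian sample instead of 4.6%).
* **LMMs** via statsmodels `MixedLM` with crossed random intercepts for
  item and model version, fit as variance components (REML by default,
  ML for likelihood-ratio comparisons).  Significance bookkeeping uses
  the |t| > 1.96 normal approximation throughout.
* **Model comparison**: likelihood-ratio chi-square with df = number of
  added fixed effects, requiring ML fits on the same data.
* **Interaction OLS**: SR score on z-scored OVE, OVS and their product;
  the product of z-scores is deliberately not re-scaled (re-scaling a
  product distorts the interaction).
* **Structural model**: a recursive path model — OVE, OVS, OVExOVS → SR →
  mean phonological SSE, with direct oral-knowledge → performance paths;
  exogenous covariances free.  The single-indicator latent SR is
  identified by fixing its loading to 1 and residual to 0, i.e. treated
  as observed.  Estimation is per-equation OLS, which is exact maximum
  likelihood for this recursive structure; fit statistics come from the
  ML discrepancy between implied and sample covariance (chi-square, CFI,
  TLI, RMSEA against the independence baseline; a just-identified model
  reports chi-square 0, CFI 1, RMSEA 0).  Close-fit flags use the 0.95 /
  0.06 / 0.95 conventions.
* **Factorial analysis**: imageability (low/high tertile, ±0.5) x
  consistency (rc = 1 vs rc < 0.5, ±0.5, inconsistent-minus-consistent)
  x SR three-way LMM, with model-free cell means reported alongside.

All estimators are verified by generate-and-recover simulations with
planted parameters, and the likelihood-ratio statistic is checked to be
chi-square distributed under the null.

## The simulation grid

Default study conditions, sized for a single CPU (roughly ten minutes):
a 300-word language; oral vocabulary sizes {100, 200, 300}; oral
exposures {20 000, 80 000} trials; two versions (initial-weight seeds);
80 000 reading trials in every cell; batch 16; 80 consistent and 80
inconsistent nonwords.  The exposure-per-word ratios (67–200) bracket
the full-scale design's ratios.  The full-scale grid (6 vocabulary sizes
x 5 exposures x 4 versions, 6000-word language, 1M reading trials) is
expressible in the same `GridSpec` but is cluster-scale.

Randomness is organised as named substreams of one master seed
(`numpy.random.SeedSequence`): per-version initial weights, per-cell oral
streams, per-version reading streams shared across cells (identical
reading word sequences), and a fixed nonword stream.  Cells are therefore
order-independent and individually reproducible, and runs resume from
per-cell checkpoints.

## Known limitations

* Magnitudes (accuracy ranges, SR score ranges, regression R²,
  coefficient sizes) are not comparable to full-scale English-corpus
  results; only directions and mechanisms are.
* Orthography→semantics accuracy stays low in the toy regime (an
  arbitrary 300-way mapping given 80K reading trials); reading-aloud
  accuracy, the analysis target, does not depend on it.
* With two versions per cell, version-level variance dominates some
  between-condition contrasts (see the DoLSR note above).
* Homographic homophones cannot be disambiguated from print; their
  second meanings count against written-word comprehension by design.
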