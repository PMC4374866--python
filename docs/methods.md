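# Methods

## Data model

All intervals are 0-based half-open (BED convention). A
`CopyNumberProfile` holds one sample's ordered probe-level log2 ratios of
tumor vs matched-control DNA; a `SegmentedProfile` is its partition into
constant-copy-number segments. Discrete copy number is carried as an
integer **level**: −1 (loss), 0 (neutral), 1 (single-copy gain), and
2, 3, … for amplification tiers binned by mean log2 ratio in steps of
0.5 (configurable `tier_step`). The 4-way class label
LOSS/NEUTRAL/GAIN/AMP is the collapse of the level. Merging of adjacent
same-state segments operates on levels, not on the 4-way collapse: two
amplified segments at different tiers are genuinely different copy-number
states, and collapsing them would erase exactly the stair structure that
breakage-fusion-bridge detection must see.

Chromosomes without a recorded centromere are treated as single-armed
(whole chromosome = arm). This matches the largely acrocentric rat
karyotype; a centromere column in the genome-build table switches any
chromosome to p/q arms. Sex chromosomes are expected to be placed on the
build's excluded list; excluded chromosomes are dropped at load time and
never reach any detector.

## Threshold calibration

Under a self–self hybridization every probe's expected log2 ratio is zero,
so the null scatter can be read off directly. The extreme 1 % of probes on
each tail is trimmed, then

* gain cut = trimmed mean + k · trimmed sd (default k = 3),
* loss cut = trimmed mean − k · trimmed sd,
* amplification cut = 5 × gain cut (default multiplier).

Three-sigma on a self–self array is the standard conservative choice; both
k and the amplification multiplier are exposed. Calibration refuses fewer
than 100 probes or zero variance. Note that trimming 1 % per tail shrinks
a Gaussian sd to ≈ 0.935 σ, so the three-sigma cut on an sd-0.10 null
lands near 0.28, not 0.30.

## Segmentation

Per chromosome, breakpoints minimize

    Σ within-segment SSE + penalty × (number of breakpoints)

subject to a minimum of `min_probes` probes per segment, by an exact
O(n²) dynamic program (prefix-sum segment costs, ties broken toward the
earlier split). Exactness makes the optimum provably equal to exhaustive
enumeration over breakpoint subsets — a property the test suite checks on
random small chromosomes — and deterministic in the penalty; raising the
penalty can never increase the segment count.

When no penalty is given, a BIC-style default 2·σ̂²·log n is used with σ̂
estimated from the median absolute first difference (robust to the
segment structure itself). State assignment classifies each segment mean
by the thresholds — boundary values go to the altered state (≥ cut ⇒
altered) — and then merges adjacent same-level segments, recomputing the
mean bp-weighted and summing probe counts.

`min_probes` defaults to 5 to suppress single-probe artifacts, mirroring
common aCGH practice. The simulator's minimum planted segment width is 3
probe spacings, so experiments that must recover every planted breakpoint
exactly run with `min_probes = 3`; the default 5 is intended for noisy
real data where 3-probe segments are unreliable anyway.

## Signature definitions

* **Arm-level aneuploidy**: per arm and per state class (LOSS vs
  GAIN∪AMP), same-class segment bp are aggregated; a call is emitted when
  one class strictly exceeds 75 % of the arm. At most one call per arm
  (larger fraction wins; an exact tie is logged and dropped). The altered
  bp count — the focal CNV burden — sums non-neutral segment bp after
  subtracting the bp lying on arms with a same-class aneuploidy call, so
  aneuploid and focal bp are conserved by construction.
* **Chromothripsis**: a chromosome is called when the number of
  adjacent-segment level switches (after same-level merging) is ≥ 10 and
  the number of distinct levels present on the chromosome is 2 or 3.
  "Changes in segmental copy-number" is operationalized as
  adjacent-segment switches — the only unambiguous reading on segmented
  data — and the distinct-state count is taken over the whole chromosome
  including NEUTRAL, since the oscillation pattern includes the baseline.
  The count tolerates no interruption accounting: it is a plain
  whole-chromosome switch count (the literal reading).
* **Breakage-fusion-bridge**: from each terminus the maximal run of
  above-neutral segments with strictly decreasing level moving inward is
  collected; a call requires ≥ 3 run segments and an interior neighbor at
  or below NEUTRAL or ≥ 2 levels (configurable `drop_levels`) below the
  run minimum — the single sharp drop. Anchors mirror under coordinate
  reflection. Genes are annotated against stair segments at level ≥ 2
  (AMP) with an any-overlap rule.
* **LOH mechanism** (given LOH established independently, e.g. by
  sequencing): chromothripsis on the locus chromosome takes precedence
  over deletion, which takes precedence over the copy-neutral label —
  chromothriptic chromosomes contain losses, but the mechanism category
  of record is chromothripsis.

## Telomere length estimation

A read is telomeric when the fraction of its positions matching the
periodic telomere hexamer, maximized over 6 phases × 2 orientations
(TTAGGG / CCCTAA), reaches `min_repeat_fraction` (default 0.9 — tolerant
of ~10 % sequencing error while excluding interstitial telomere-like
sequence). This phase-and-orientation maximum emulates alignment to a
tandem-repeat reference and keeps the package free of external aligners.

With coverage computed from non-telomeric reads against the reference
genome size, the estimator

    mean length = telomeric bases / (coverage × n_ends)

is scale-free and unbiased in the shallow regime: writing T for total
telomeric bp and G for genome size, the expected telomeric base yield is
coverage·T and dividing by coverage and the number of ends returns T per
end regardless of coverage. `n_ends` defaults to 84 (rat 2n = 42, two
telomeres per chromosome) and is configurable for other karyotypes.

TRAP (telomerase) and C-circle (ALT) signals are normalized to their
positive controls (the kit's telomerase-positive line and U-2 OS
respectively); the "activated" flag is a strict comparison against a
configurable threshold, default 0.1 × control, since the underlying
criterion is qualitative. Group contrasts use the pooled-variance
Student's t-test (Welch behind a flag).

## Synthetic data

The generator is the inverse of the detectors. The state→log2 map places
single-copy changes on a diploid background — loss log2(1/2) = −1.0, gain
log2(3/2) ≈ 0.58 — with amplification tiers at 1.5 + 0.5 per extra tier;
probe values are segment means plus Gaussian noise (default sd 0.15 log2
units, typical aCGH scatter). Chromothripsis plans draw uniformly random
grid-snapped breakpoints with a minimum segment width of 3 probe spacings
and assign adjacent segments different states from a 2–3 letter alphabet,
so the planted switch count is exact by construction. BFB plans place a
strictly increasing stair against a terminus with a NEUTRAL interior.
Breakpoints snap to the probe grid so that noise-free profiles are
*exactly* recoverable — the closure tests assert breakpoint-for-breakpoint
identity, not approximate overlap. Read simulation mixes pure-repeat
telomeric reads (phase- and strand-randomized, per-base substitution
errors) with uniform random background in the binomial proportion implied
by the true telomere length.

What the simulator does **not** model: probe density variation, GC waves
and dye bias, subtelomeric transition sequence, interstitial telomeric
repeats, paired-end structure, and indel errors. Passing tests therefore
demonstrate correctness of the decision rules and estimators under the
stated noise model, not robustness to every artifact of real arrays or
SOLiD sequencing.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical outputs.

## Problem sizes in the test and acceptance experiments

Experiments run on desk-scale genomes chosen so every stage remains
exactly checkable: 5–10 chromosomes of 50 Mb at 100 kb probe spacing
(500 probes per chromosome) for the detector closure (100 genomes per
signature, noise 0) and null-specificity (200 genomes, noise sd 0.15,
calibrated 3σ thresholds, `min_probes` 5) experiments; a 2 Mb background
genome with the rat's 84 telomere ends, 50 bp reads and 1 % error for the
telomere recovery experiment (true lengths 20/50/100 kb — the rat range —
at 0.1/0.5/1.3× coverage, 20 replicates each). The telomere estimator is
scale-free, so the background genome size only sets the Monte-Carlo
effort.

## Known limitations

* Real aCGH segment boundaries depend on the original vendor software's
  averaging windows and penalties, which are not public; exact segment
  coordinates from the deposited arrays are therefore not a reproduction
  target, only the derived signature calls.
* Absolute telomere lengths from the deposited sequencing runs depend on
  an unstated normalization; the estimator here is the standard
  shallow-WGS form and is validated by parameter recovery, with relative
  group differences as the meaningful output.
* The pipeline emits the three-way LOH label only; distinguishing gene
  conversion from copy-neutral structural variation requires orthogonal
  (sequence-level) evidence the copy-number data cannot provide.
* Detection is purely copy-number-signature based: no breakpoint-junction
  (split-read/paired-end) evidence and no statistical randomness tests
  for chromothripsis are implemented.
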