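# Methods

`nucpos` analyzes nucleosome positioning from mapped nuclease-protected
reads: it extracts positional dinucleotide patterns, quantifies their helical
periodicity and phase, clusters promoters by TSS-anchored occupancy, predicts
dyad positions by sliding pattern correlation, and computes intrinsic DNA
curvature under the wedge model. Because the real datasets this kind of
analysis consumes (tens of millions of MNase or apoptotic-nuclease reads) are
not practical at desk scale, the package ships a first-class synthetic-data
generator that plants every statistical structure the analysis assumes, so
each stage can be validated by parameter recovery.

## Coordinate conventions

All coordinates are 0-based, half-open. A minus-strand read's 5' end sits at
`end - 1`. Nucleosome footprints are 147 bp with the dyad at base 73
(0-based); a footprint profile therefore has 146 dinucleotide steps and step
`s` covers bases `(s, s+1)`, at distance `s - 73` from the dyad.

## The synthetic-data generator

**Genome layout.** One chromosome per promoter class. Each promoter occupies
a `2*flank + spacer` slot (defaults 2000 + 400 bp) with its TSS at
`slot_start + flank` and a random strand; 200 bp margins keep every window
inside the chromosome. Background sequence is i.i.d. at the class G+C
fraction (defaults: AT-rich class 0.40, GC-rich class 0.60).

**Nucleosome placement.** Each promoter receives exactly
`round(2*flank * density)` nucleosomes (capped at the packing limit),
uniformly placed with footprints separated by at least a 20 bp minimum gap.
The count is deterministic so a class's density is realized exactly;
promoter-to-promoter variability comes from placement and read sampling.
Linker lengths are not modeled explicitly — the min-gap spacing stands in
for them. Default densities encode the apoptotic contrast of the two
promoter classes: one nucleosome per 250 bp (AT-rich, retaining) versus one
per 1000 bp (GC-rich, depleted). The pipeline's simulate stage instead
plants both classes at the normal density and derives the apoptotic state by
depletion (below), which is the more mechanistic route to the same contrast.

**Planted dinucleotide signal.** Within each footprint, sequence is emitted
first-order, base by base. A step is *WW-phased* when its distance from the
dyad lies within ±1 bp of an integer multiple of the period (default
10.2 bp), and *SS-phased* when offset from those positions by half the
rounded period (5 bp) — so AA/TT and GG/CC enrichments are counter-phased by
5 bp, and multiples of both signs make the masks symmetric about the dyad.
At a phased step whose previous base can extend the favored class (A/T for
AA/TT, G/C for GG/CC), the probability of repeating that base is raised by
`enrichment_strength × envelope` and renormalized; equivalently the favored
repeat is emitted with probability `b/(1+b)` and the background draw
otherwise. Two counter-running linear amplitude envelopes (depth
`gradient`, default 0.5) make GG/CC enrichment strongest at the dyad and
AA/TT strongest toward the edges — the convex/concave gradient whole-set
nucleosome patterns show, and the feature that gives a footprint an absolute
(not merely phase-modular) positional signature. The defaults
`enrichment_strength = 0.6, gradient = 0.5` were fixed once so that the
downstream prediction experiment operates in the regime real nucleosome
collections exhibit (per-pattern hits near 30% at ±15 bp against the 21%
analytic baseline); the periodicity and phase-lag recoveries are insensitive
to this choice.

**Apoptotic depletion.** `apply_apoptotic_depletion` retains a nucleosome
with probability `retention_gc_rich` (default 0.2) when its footprint G+C
fraction exceeds 0.5, and with probability 1 otherwise. The truth label is a
parameterized threshold because real group membership comes from clustering,
not a cutoff.

**Read protocols.** Fragments per retained dyad are Poisson with the
protocol's `reads_per_nucleosome_mean`; fragment length is a rounded normal
(MNase-like: 150 ± 4 bp; apoptotic-like: 170 ± 6 bp) and the fragment center
jitters around the dyad with SD 2 bp — tight positioning, as appropriate for
well-phased nucleosome collections. The unpaired protocol emits one stranded
24–25 bp 5'-anchored read per fragment on a random strand and records the
protocol's nominal fragment length (what gel fractionation tells the
experimenter); the paired protocol emits both ends as 120 bp mates (`/1`
forward, `/2` reverse) with the realized length. Fragments crossing a
chromosome end are dropped and counted; drawn = emitted + dropped is
asserted in tests. No sequencing-error, quality or PCR-duplicate model is
included.

**What the generator does not emulate.** Real genomes have repeats,
isochores, CpG islands and correlated linker structure; real digestion has
sequence-specific cut preferences; real nucleosome arrays are statistically
positioned against barriers. Passing recovery tests on this generator
demonstrates that the estimators are correct and well-calibrated under the
model's assumptions — not that the biological conclusions transfer to any
particular real dataset.

## Pattern extraction

Windows of length 147 are cut from each read's 5' end strand-wise
(minus-strand windows reverse complemented), and per-step relative
frequencies of all 16 dinucleotides are tabulated. Steps touching an N are
excluded from numerator and denominator alike, keeping every covered column
an exact probability vector. Profiles are invariant to read order and
duplication, and the profile of a reverse-complemented window set equals the
row-permuted (AA↔TT, AC↔GT, …), column-reversed profile exactly.

**Dyad offset from two strands.** With fragments centered on the dyad, the
dyad lies a fixed distance `d` from every 5' end (≈ fragment_length/2: 75 bp
for the MNase-like protocol, 85 bp for the apoptotic-like one). The
estimator builds the plus-strand profile `A` and the minus-strand profile
`B` in the *forward genome frame* (no reverse complement): the footprint
pattern then sits at step `d` of `A` and step `145 - d` of `B`, so the
cross-correlation of the two 16-row profiles over steps peaks at lag
`s = 145 - 2d`. Each candidate offset `c` is scored by the Pearson
correlation at lag `145 - 2c`, with each row centered over the overlap so
positional structure rather than overall composition drives the statistic;
the argmax recovers `d` (ties toward the smaller offset). Because integer
offsets sample only every other lag, recovery is exact to ±1 bp.

**Length-stratified profiles.** For paired protocols, profiles per
fragment-length bin reproduce the flank-anchored geometry: strata 10 bp
apart in fragment length shift 5'-anchored pattern peaks by 5 bp.

## Periodicity and phase

`dominant_period` detrends a track (none/linear/quadratic polynomial; linear
by default, since whole-set profiles carry the envelope gradient), zero-pads
to a 4096-point FFT, and returns the period in [5, 50] bp with maximum
power. Significance compares that power with the 95th percentile of maximum
in-band power over 200 null tracks — by default random permutations of the
detrended values; callers holding sequences may pass explicit null tracks
(e.g. profiles of dinucleotide-shuffled windows). Off-center window frames
(apoptotic 5'-anchored windows put the dyad at 85 of 147) leave envelope
power that a linear detrend cannot remove, so the pipeline recomputes
profiles re-anchored at the inferred dyad before spectral analysis.

`profile_lag` scans Pearson correlation over lags up to ±20 bp on the
overlapping segments, ties broken toward the smallest |lag|; it is
antisymmetric under argument exchange. The AA+TT vs GG+CC lag of the default
synthetic extraction is ±5 bp, the planted counter-phase.

## Occupancy and promoter groups

Dyads are inferred as read 5' position plus the estimated dyad offset
(strand-aware). `dyad_counts_around_tss` accumulates strand-oriented counts
over ±1000 bp of each TSS (antisense promoters flipped), drops promoters
whose window crosses a chromosome end, and conserves totals before the
30 bp boxcar smoothing (a display/clustering choice; the counts matrix keeps
raw totals). Promoters in overlapping windows double-count by design.

K-means (k = 2, 10 restarts, fixed seed) partitions promoters; the default
feature is the per-promoter total occupancy, because the class signal is
density and per-position z-scoring of sparse count tracks drowns it (full
smoothed-track features remain available as options). Group 1 is relabeled
to the higher-occupancy group; on the planted two-density simulation label
agreement with truth exceeds 95% across seeds. Group base composition
(per-position G+C and AA/TT/GG/CC occurrence tracks) confirms the retaining
group is AT-rich.

Per-promoter count summaries report means to one decimal and percent changes
to the nearest integer, both rounded half-up, matching the reporting style
of printed occupancy tables. Group contrasts use a promoter-level bootstrap:
resample each group with replacement, `z = observed difference / bootstrap
SD`, percentile 95% CI; degenerate (zero-SD) inputs raise. Calibration on
same-distribution groups keeps |z| < 2 in ≈95% of replicates.

## Dyad prediction by pattern correlation

A *pattern set* (e.g. {AA, TT, AT} or {GG, CC, GC}; IUPAC classes like WW
expand to their dinucleotide sets) is trained by summing its member rows of
a training profile into a 146-step template. A placement of the footprint on
a sequence is scored by the Pearson correlation between the template and the
binary indicator "step's dinucleotide belongs to the set"; zero-variance
indicators and footprints containing N score as missing, and a flat template
is an error. Whether the 16 rows should be correlated separately instead of
through the summed template is not decidable from the protocol's published
description; the summed form is the default and the abstraction point for
alternatives.

Evaluation windows are 313 bp (147 + 2×83 flanks) with the true dyad at the
center. Placements are confined to the central one-footprint range (147
placements), so a uniform random predictor hits `(2·tol + 1)/147` — 31/147 ≈
21% at ±15 bp — exactly, saturates at tol = 73, and the null-signal hit rate
is testable against a closed form. Per set, the predicted dyad is the argmax
placement + 73 (ties to the smaller offset); when sets compete, the higher
peak correlation wins (ties to the first listed set). Precision reports
per-set, combined-winner, union and intersection hit fractions per
tolerance. On default synthetic data the union of the two standard sets
exceeds twice the analytic baseline at ±15 bp.

**Dinucleotide-preserving shuffle.** Null sequences use the swap algorithm:
choose positions `i < j ≤ k < l` with `s[i] = s[k]` and `s[j] = s[l]` and
exchange segments `s(i..j]` and `s(k..l]`. Every boundary edge remains a
dinucleotide of the original sequence, so all 16 counts (and the first and
last base) are conserved exactly — asserted on every call. Default moves:
10× sequence length. Sequences admitting no composition-changing move
(homopolymers) return unchanged with a flag.

## DNA curvature (wedge model)

Each dinucleotide step deflects the helix axis by a fixed wedge (magnitude
`hypot(roll, tilt)`, direction `atan2(tilt, roll)` in the base-pair plane)
and rotates by its twist. The step rotation is
`Rz(t/2 + φ) · Rx(w) · Rz(t/2 − φ)` — half the twist on either side of the
wedge — and each base advances one unit along the z-axis of the *mid-wedge*
frame. That mid-step convention is what makes the model exactly
strand-symmetric: the curvature profile of a reverse complement is the
original profile reversed (machine precision), and the profile is
translation invariant. Curvature at base `p` is the angle in degrees between
the chords entering and leaving an 11 bp window centered at `p` — net axis
deflection per window, approximately per helical turn. Positions within 5 bp
of an end or of an N are undefined.

The bundled wedge-angle table (`data/wedge_angles.tsv`, version 1) is
transcribed from the classic trinucleotide-calibrated wedge parameter set of
the curvature literature, with complementary steps carrying equal roll/twist
and opposite tilt; it is injectable so alternative parameter sets can be
tested. Only relative comparisons are meaningful: phased A-tracts out-curve
their dinucleotide-shuffled controls, and nucleosome window sets are
compared as dyad-centered mean tracks.

## Pipeline

`run_pipeline` executes simulate → patterns → periodicity → occupancy →
predict → curvature with per-stage seeds derived by hashing the stage name
with the global seed (toggling one stage never reshuffles another), stamps
outputs with a config hash, and emits a machine-readable `summary.json` that
is byte-identical for identical config + seed. The CLI (`nucpos simulate |
patterns | periodicity | occupancy | predict | curvature | all`) is a thin
veneer over the same functions.

## Problem sizes

Default validation scales, chosen to exercise every estimator comfortably on
a single CPU: 600 promoters per class (~2.9 Mb of genome), ~50,000 reads for
pattern extraction and parameter recovery, 2,000 evaluation windows for
prediction precision, 10 independent simulations for clustering recovery,
400 replicates for bootstrap calibration, and 200 shuffles for empirical
null comparisons.

## Known limitations

The generator's first-order emission cannot represent longer-range motif
structure (e.g. true TTAA/AATT tetramer preferences); the prediction
statistic treats pattern-set membership as binary rather than weighting the
16 rows; curvature is a rigid-wedge geometry, not an elastic model; and all
acceptance-style checks run on synthetic data, so they validate estimator
correctness and calibration, not biological generality.
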