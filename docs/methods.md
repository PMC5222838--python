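# Methods

## Spelled pitch and the line of fifths

All harmonic arithmetic operates on *spelled* pitch classes indexed on the
line of fifths (…, B♭ = −2, F = −1, C = 0, G = +1, D = +2, …; each sharp
adds 7, each flat subtracts 7). Enharmonic spellings are distinct objects:
C♯ (k = 7) and D♭ (k = −5) are twelve fifths apart, which is what makes the
root-interval viewpoint well defined and places the two chords far apart on
the spiral-array helix. Chords are reduced to major/minor triads; an
inversion bass is parsed and preserved through IO but ignored by every
model. The MIDI renderer is the one deliberately 12-TET layer (enharmonic
equality), with the chord → pitch-class projection as the boundary.

Tonal consistency of a loop is decided by brute force: a loop is consistent
iff its chord set is contained in the major/minor triads of a single
diatonic major key (I, IV, V, ii, iii, vi — the diminished vii° cannot occur
in a major/minor-reduced corpus) or a single harmonic-minor key (i, iv, V,
VI; the augmented and diminished degrees likewise cannot occur). Tonics are
scanned over a window four fifths either side of the loop's own roots,
which covers every spellable candidate key.

## Viewpoint model and cyclic information content

The first-order model is a distribution over linked viewpoint values
⟨Δfifths, mode pair⟩ estimated by relative frequency from all loop
transitions, each loop augmented by its wrap transition (last → first
chord). Because the viewpoint is relative, training is exactly invariant to
diatonic transposition of the corpus. No smoothing is applied — the
generator only walks observed values; an add-one (Laplace) mode over a
declared viewpoint alphabet is available for scoring arbitrary sequences.

Information content is computed on the *merged* chord sequence (consecutive
duplicates collapsed; ℓ = merged length), since a corpus without
self-transitions assigns no probability to them. The per-chord complexity
of a loop in the infinite-repetition limit is I(e + e₁)/ℓ — the IC of the
merged sequence extended by its first chord, divided by ℓ. IC is
accumulated in log space (base 2, bits), so long unrolled sequences whose
raw probability underflows a double still score correctly. An out-of-support
transition yields a distinguished *unreachable* flag, never a large finite
number. A loop that merges to a single chord has no transitions; its cyclic
IC is defined as 0 bits/chord (maximally predictable).

A subtlety about the repetition-limit oracle used in tests: unrolling a
loop n times *open-ended* approaches the cyclic value only at rate
I(wrap)/(ℓ·n) (about 0.02 bits at n = 50), exactly and monotonically;
unrolling it and re-extending by the first chord (the cyclically closed
form, which is what the limit derivation manipulates) equals I(e + e₁)/ℓ
identically for every n. The tests assert both behaviours.

## Semiotic patterns and repetition features

Patterns are 8 labels in two 4-slot halves. Construction rules: the first
half is AABB-shaped or ABCD-shaped; an AABB start requires at least one
adjacent repeated pair in the second half; an ABCD start forbids adjacent
repeats *within* the second half. A repeat across the half boundary
(slot 4 = slot 5) is allowed — the experiment set itself contains
ABCD-DABD. The three categorical features (first-half structure,
second-half unique count, structural overlap with its
AllSame/PartiallySame/AllDifferent discretization) are label-level
properties of the structure, not of any instantiation. An overlap of 3 is
impossible under the rules, so the discretizer treats it as a hard error
rather than silently binning it.

## Generation

The random walk moves left to right over the 8 slots. A bound label reuses
its chord (failing if the forced transition is unobserved); an unbound
label samples from candidates that continue from the previous merged chord
through an observed viewpoint value, are not bound elsewhere, and — with
the diatonic filter on — lie in the start chord's key collection, with
probability proportional to the transition probability, biasing walks
toward low IC. For a major start the collection is the six major/minor
triads of its key; for a minor start it is the natural-minor (relative
major) collection plus the harmonic-minor triads, adding the major
dominant — harmonic minor alone has only four major/minor triads, too few
for the pattern set, while trance practice freely mixes the dominant into
the natural-minor palette. When no diatonic candidate exists (patterns
such as ABCD-EFGH need eight distinct chords), the walk falls back to the
full vocabulary for that slot and logs it. The candidate vocabulary is all
major and minor triads over spelled roots with fifths index −6…+9, which
covers every diatonic triad of the four start keys with headroom.

Per pattern and key class (major starts {D, G}, minor starts {Bm, Em};
start drawn uniformly within the class per iteration), 1000 walk iterations
are attempted by default; distinct successes are ranked by cyclic IC (ties
broken lexicographically on chord tokens for determinism) and the two
lowest are selected, except that a runner-up differing from the best in at
most one of the 8 slots (configurable) is deemed "almost identical" and
passed over for the next distinct candidate. Dead ends and unreachable
wraps count as failures within the iteration budget; fewer than two
qualifying sequences raises an error naming the pattern and key class. One
seeded NumPy generator is threaded through all walks, so runs replay
bit-identically from the seed.

## Spiral array and Cloud Momentum

Pitch class k sits at (r·sin kπ/2, r·cos kπ/2, k·h) with the standard
calibration r = 1, h = √(2/15) (the calibration is exposed in
`SpiralConfig`). Fifths neighbours are a quarter turn apart; a major third
(Δk = 4) lies directly above its root. A triad's cloud is {root, root+1,
third} with the third at +4 (major) or −3 (minor); its center of effect is
the unweighted mean of the three points — all stimulus chords last equally
long, so duration weighting has nothing to weight; the source model's
root/fifth/third weights remain available behind `weighted_ce` for
sensitivity analysis. Cloud Momentum is the Euclidean distance between
successive centers of effect; a stimulus's average is taken over its 7
adjacent slot pairs, with identical-chord pairs contributing 0 (they encode
repetitiveness; a switch can drop them, and a cyclic flag adds the wrap
pair). Cloud Diameter and Tensile Strain are not computed: the former is
constant across major/minor triads and the latter barely varies when
generation is key-constrained.

## MIDI rendering

The packaged template is an original synthetic arrangement — quarter-note
bass, sustained pad triads and a 16th-note arpeggio over eight two-bar
regions at 138 BPM, 4/4, 480 ticks/quarter (typical UT values; metadata
only). Rendering first snaps any non-chord note to the closest chord tone
of its region, then re-pitches every note to the same harmonic function
under the stimulus chord in the octave minimizing the pitch change (ties
resolve downward; the change is always ≤ 6 semitones). Only pitches change:
rendering a template onto its own chords reproduces the file byte for byte.
The SMF codec (format 1; tempo, time-signature and track-name metadata,
note on/off) is implemented in-package.

## Regression and the Wundt verdict

Both models are OLS with y, x and x² each z-scored (sample sd) before
fitting, so reported coefficients are standardized βs; a raw-scale switch
exists. The verdict is "wundt" iff the quadratic R² exceeds the linear R²
and the squared term is significantly negative at α = 0.05 (df n − 3);
otherwise "linear" iff the linear slope is significant (df n − 2);
otherwise "neither". The analysis unit is the stimulus (n = 56 mean
ratings). Note that when the covariate is positive with a narrow range —
as cyclic IC is — z(x) and z(x²) correlate above 0.999, so the paired β
magnitudes inflate; the squared term's t-test and sign, on which the
verdict rests, are unaffected. A condition-number guard (10⁸) rejects
genuinely degenerate designs. The per-participant repeated-measures ANOVA
over the categorical features is out of scope; grouped descriptive
summaries can be derived from the feature table instead.

## Synthetic data

The corpus simulator draws, per loop, a key (major with probability 0.61,
else minor), a tonic in fifths −2…+5, and a 4–8-chord no-immediate-repeat
walk over that key's triads with minor triads weighted 0.39 against 0.61
for major, so the corpus-level minor-chord share lands near 39% (the
key-collection mode mix keeps realized values within a few points). Loops
sample from exactly one consistent collection (major or harmonic minor), and
a fixed 4% of loops then have one chord replaced by a tonally foreign triad,
verified to actually break single-key consistency — yielding a 96%
consistency fraction by construction. Durations are 1–2 bars.

The ratings simulator draws per-participant ratings
a + b·z − c·z² + ε, ε ~ N(0, sd²), clips to [1, 7] and rounds to the
Likert grid (rounding can be disabled for exact-shape checks), then
averages over participants. Defaults a = 4.2, b = 0.25, c = 0.30,
sd = 1.8, 20 participants were sized by power analysis so that, at 56
stimuli, the quadratic term is detected in essentially all Wundt-mode
replicates while the quadratic R² on mean ratings stays moderate (≈ 0.45),
the linear mode (c = 0) is identified as linear, and the null mode keeps
the squared-term false-positive rate at the nominal 5%. The simulators
emulate the summary structure of real corpora and ratings — not voice
leading, participant heterogeneity, order or fatigue effects — so passing
tests demonstrate that the pipeline recovers known structure at realistic
sizes, not that any specific empirical effect exists in real listeners.

## Problem sizes and determinism

Module tests run the full 14-pattern generation at 300 walk iterations per
key class and the recovery study at 100 ratings replicates (plus 2000 null
replicates), sizes at which the whole suite completes in well under a
minute while every statistical check retains comfortable Monte-Carlo
margins; the generator's own default remains 1000 iterations. All
randomness flows from explicit integer seeds through NumPy generators;
hypothesis-based property tests are derandomized by its fixed default
profile.

## Known limitations

* The viewpoint distribution is unconditional over viewpoint values (a
  first-order model in the transition sense, not a per-context conditional
  table); this matches the transposition-invariance rationale but cannot
  express context-specific preferences.
* Generation scores patterns on their merged distinct-chord skeleton, so
  patterns with internal repeats are compared on fewer transitions than
  slots (the slot-count normalization is exposed as the merged length ℓ in
  `SequenceIC`).
* The synthetic template is deliberately simple; renders are structural
  stand-ins, not production-grade trance audio.
* Chord vocabulary and key collections assume the major/minor triad
  reduction throughout; sevenths, suspensions and modal mixture beyond the
  harmonic-minor dominant are out of scope.
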