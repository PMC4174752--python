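# Methods

## Model overview

The model asks how much of a coarse-coded neural population a perceptual
readout must sample to identify a cluttered target. It has three stages:

1. **Stimuli.** Square black displays with white binary glyphs
   (20 × 20 px): a target centered on the image and flankers elsewhere.
   Glyphs combine by element-wise max. The horizontal pixel coordinate
   stands for eccentricity; the left edge is the most foveal position.
2. **Encoding.** `n` receptive fields (RFs) are tiled at random locations.
   Each RF prefers one symbol; its filter is that symbol's bitmap divided
   by its squared Euclidean norm, so the zero-lag correlation of a glyph
   with its own template is exactly 1. The RF response is the maximum of
   the rectified cross-correlation map over the pixels inside the RF's
   elliptical footprint. Because displays are binary and the template
   non-negative, responses lie in [0, 1] by construction: 1.0 whenever the
   preferred symbol sits wholly inside the footprint (translation
   tolerance), 0 for an empty footprint.
3. **Decoding.** The response vector feeds a fully connected network with
   10 tanh hidden units and one softmax output unit per symbol class;
   classification is winner-take-all (argmax; exact ties, a measure-zero
   event, resolve to the lowest class index). Sparse selection is modelled
   by removing input units or connections (below).

Each iteration redraws stimuli, RF positions, RF tuning assignment and
decoder initialisation; reported numbers are means over iterations with
Monte-Carlo standard errors.

## Parameters

| parameter | default | meaning |
|---|---|---|
| display size | 101 px (61 foveal, 151 zone map) | square stimulus canvas |
| glyph size | 20 px, stroke 2 px | symbol raster |
| n_rfs | 24 (45 foveal, 48 zone & feature tasks) | population size |
| mean diameter | 50 px (20 for feature-tuned RFs) | RF horizontal extent at the reference eccentricity |
| scaling slope | 0.7 | px of diameter per px of eccentricity |
| diameter floor | 10 px | keeps far-foveal RFs usable |
| ellipticity | 1.0 (0.5 in the zone map) | vertical/horizontal footprint ratio |
| n_train / n_test | 120 / 60 (240 train for the zone map) | class-balanced set sizes |
| hidden units | 10 | decoder capacity |
| iterations | experiment-dependent (see below) | Monte-Carlo averaging |

The foveal variant keeps the peripheral diameter anchor
(`d(x) = 50 + 0.7·(x − 50)`, so `d(x) = 15 + 0.7x` from the left edge):
the smaller 61-px display plus placement biased toward low eccentricity
(x sampled with density ∝ 1/(x + 22.5 px), the standard inverse-eccentricity
cortical-magnification profile with the half-saturation constant at
~0.75° × 30 px/°) yields both smaller RFs and 5× the RF density of the
peripheral model — the two factors that abolish crowding at fixation.

## Glyph geometry

Symbol shapes are not prescribed beyond their identity, so the renderer
uses: circle = centered ring whose outer radius touches the box; triangle =
unfilled isoceles outline inscribed in the box; X = both diagonals; line
segments = centered 2-px bands; tumbling T = full-width crossbar plus
full-height centered stem, rotated to the four cardinal orientations.
Exact geometry shifts absolute accuracy by a few points but not the
phenomena, which are all relative comparisons.

## Flanker placement

Random flankers take uniform identities from the task's symbol set and
uniform in-bounds positions, rejected until their 20 × 20 bounding boxes
overlap neither the target box nor each other (up to 1000 retries). The
non-overlap rule is only documented for the foveal variant of the original
simulations; it is applied everywhere here for consistency, after checking
that allowing overlap changes full-model accuracy by ~1 point and no
conclusion.
Fixed probe batteries: single flankers ±25 px horizontally (12 images,
flanker ≠ target) for the asymmetry/substitution probes; flanker pairs at
±25 px horizontally or vertically (12 images per axis, all ordered pairs
of non-target symbols) for the radial-bias probe; a strided grid of single
flanker positions (6 target/flanker pairings per cell, overlap with the
target allowed) for the zone map.

## Decoder training

Training minimises cross-entropy by full-batch L-BFGS (scikit-learn
`MLPClassifier`, tanh hidden layer, α = 1e-4, ≤ 500 iterations,
tol = 1e-6), run to convergence on all training items with no validation
split. On problems of this size a convergent quasi-Newton fit reaches the
same solution quality as scaled-conjugate-gradient backpropagation; the
claims under test concern representational capacity, not optimizer
identity. One consequence documented below: a *convergent* retrained
decoder is substantially more robust to unit removal than the originally
reported retrained results imply.

Chance calibration uses an empirical null: shuffle the training labels,
train, test against the true labels; the null mean sits at 1/k for k = 2,
3, 4 output classes, and p-values are the fraction of the null at or above
the observed accuracy.

## Sparse selection regimes

- `drop_units_no_retrain`: zero the input→hidden weights of a uniformly
  random subset of RF units in the trained net (a readout that can only
  reach part of the population).
- `drop_units_retrain`: remove the units, then train a fresh decoder on
  the reduced input layer (a separate readout circuit); the kept set is
  balanced across tuning classes where possible.
- `drop_connections`: zero a uniformly random subset of individual
  input→hidden weights; hidden→output weights are never ablated.

Sampling curves evaluate a descending fraction grid {1.0, 0.9, …, 0.1}
with stimuli and population shared across fractions within an iteration
(paired design) and the removed set redrawn per fraction. The summary
statistic is the linearly interpolated fraction at which the mean curve
first falls to 90% of full-model performance.

### Regime-dependence of the peripheral crossing

With convergent retraining, the peripheral model tolerates removal of
~53% of its units before falling to 90% of full performance, while merely
silencing units in the trained readout crosses that level at ~87% sampled
(~13% removed). The published account gives 85% sampled for its
retraining procedure yet also states that the foveal model's 75% removal
tolerance is "20%" more than the peripheral model's — an arithmetic that
implies a peripheral removal tolerance near 55%, matching our retrained
curve, while the 85%-sampled figure matches our silenced readout. The
package therefore treats the silenced-readout curve as the published
sampling-curve landmark and the retrained curve as the basis of the
foveal/peripheral comparison, and reports both curves everywhere. The
qualitative ordering is unambiguous in both regimes: retraining never
hurts, removal never helps, and connection drops degrade performance more
slowly than unit drops.

## Experiment battery and problem sizes

Desk-scale iteration counts (one CPU, minutes): 100 iterations for
full-model accuracies (peripheral, foveal, feature, tumbling-T, and their
75%-removed variants), 50–100 per grid point for sampling curves, 100 per
ellipticity for the radial bias, 1000 for the single-flanker probe (it is
by far the cheapest per iteration, so it runs at the original count),
200 label shuffles for the chance null, and 12–25 iterations at grid
stride 5 for the zone map. Monte-Carlo SEs accompany all means, and
result-level checks use ± max(3 SE, 5 percentage points) bands.

The asymmetry and radial-bias significance tests are sign-flip permutation
tests on per-iteration paired differences (5000 flips, +1 correction);
the substitution comparison is a binomial test on errors pooled across
iterations against the 50% no-preference null.

## What the generator does and does not emulate

Stimuli are noiseless binary glyphs with known ground truth; RF responses
are deterministic; there is no response noise, contrast variation,
anti-aliasing, or natural-image structure. Passing tests therefore show
that the coding/readout architecture produces the crowding signatures
under idealised conditions — not that it quantitatively fits human
psychophysics, which is out of scope.

## Known limitations and discrepancies

- **Substitution-error magnitude.** The 50%-silenced readout reports the
  flanker on ~60% of its errors — clearly above the 50% no-bias null
  (p ≪ 0.001) but below the published 70.4%. Our ablated probe accuracy
  (~0.54 on the 12-image battery) leaves errors closer to an even split;
  the direction and significance of the effect are robust.
- **Retrained-curve steepness.** See the regime discussion above; the
  published retrained-curve steepness is not reproducible with a
  convergent trainer.
- **Ellipticity convention.** RF ellipticity is the vertical/horizontal
  ratio with 1.0 = circular and 0.5 = half-height; reported ellipticity
  grids sometimes use an inverted scale (0 = circular), which this package
  does not.
- **Foveal RF size.** Only the density increase and display shrink are
  stated for the foveal model; RF diameters here follow the unchanged
  eccentricity rule on the smaller display, which also shrinks them.
- Absolute accuracies depend mildly on glyph geometry (± a few points);
  all comparisons under test are within-model contrasts.
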