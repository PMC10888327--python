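# Methods

`chromathresh` models a calibrated-tablet color-perception test end to end:
stimulus colorimetry, plate rendering, adaptive threshold estimation,
simulated observers, and the agreement statistics used to validate such a
test. This note records the models, the defaults that matter, and the
choices made where the design was genuinely open.

## Display model and colorimetry

The display is modeled as calibrated: sRGB primaries, D65 white
(x, y = 0.3127, 0.3290), a pure power-law transfer function with exponent
2.2, peak white luminance 120 cd/m², 2736 × 1824 pixels on a 12.3-inch
diagonal (pixel pitch 0.0950 mm). The pure power law follows the
calibration target ("gamma 2.2"); the piecewise sRGB curve is available via
`DisplayModel(transfer="srgb")` but is not the default. The RGB→XYZ matrix
is derived from the primary and white chromaticities (white Y normalized to
1), and CIELAB is computed against the display white, so (1,1,1) maps to
L\* = 100 exactly.

Color differences are CIE76 (Euclidean in L\*a\*b\*). This is the package's
ΔE everywhere: the staircase level, the thresholds, the severity anchors.
CIEDE2000 is implemented (`delta_e_2000`) for comparison but drives nothing.

**Confusion pairs.** Each stimulus is a pair of isoluminant colors on one
dichromatic confusion line, i.e. collinear in CIE 1931 xy with the axis's
copunctal point. Copunctal defaults are the standard literature values:
protan (0.7465, 0.2535), deutan (1.4000, −0.4000), tritan (0.1748, 0.0000).
The two members are placed symmetrically (in xy) about a base point and the
displacement is bisected until the pair's CIE76 separation matches the
request (tolerance 0.01 ΔE, well inside the 0.1 ΔE contract; ≤ 60
iterations). Symmetric placement keeps the mean stimulus chromaticity
constant along the whole staircase, removing adaptation-drift cues.

**Base point and luminance.** Deficient observers reach thresholds near
78 ΔE, so every axis needs at least ~80 ΔE of symmetric headroom. Stimuli
are presented at 40% of peak luminance (48 cd/m²), and the default base for
each axis is the ΔE-midpoint of the gamut chord cut by the confusion line
through D65 at that luminance, computed once and cached. Centering on the
chord midpoint rather than exactly on D65 shifts the base only slightly
(e.g. protan base x, y ≈ 0.3214, 0.3275) but raises the symmetric headroom
to ≈ 86 / 99 / 120 ΔE on the protan / deutan / tritan axes; centering
exactly on white caps the protan axis at ≈ 79 ΔE at any luminance. Both
the base and the luminance fraction are configurable.

## Plate geometry and rendering

Coordinates are visual-angle degrees from the screen center for a viewer at
50 cm on the screen normal; extents convert through the exact tangent
mapping `size = 2·d·tan(θ/2)` and the pixel pitch.

The mosaic packs circles of diameter 0.0466°–0.1244° (uniformly sampled) by
rejection (dart-throwing), inserting candidates largest-first so small
circles fill interstices; this reaches the 55% coverage target on the full
screen, above the ~54.7% jamming limit of equal-disk rejection packing.
Candidates are drawn up front from the seed, so a packing is a pure
function of its seed. Circles may touch but never overlap (`min_gap` in
pixels is available and defaults to 0; a 1-pixel gap would make the 55%
target unreachable at these radii). The attempt budget is 600 000.

The arrow is a filled polygon — shaft plus triangular head, long axis
4.26°, shaft width 0.8°, head occupying the distal 35% at width 1.8° — in
one of 8 compass directions, positioned by polar sampling about the screen
center and resampled until the perpendicular distance from the screen
center to the centerline segment is below 2° (keeping the stimulus over the
cone-dense fovea) and the polygon is fully on-screen.

Rendering assigns the arrow chromaticity to circles whose center lies
inside the polygon and the background chromaticity to the rest, then
multiplies each circle's luminance by a jitter factor drawn Uniform(0.4,
1.6) — a ±60% spread, symmetric about nominal. At fixed chromaticity linear
RGB scales linearly with luminance, so the jitter is applied in linear
light and chromaticity is preserved exactly; factors that would leave the
gamut are clipped to the headroom. Both roles draw jitter from the same
distribution, so luminance carries no information about the arrow. The
inter-circle field is neutral gray at the nominal stimulus luminance.
Quantization to 8 bits rounds half-up, making renders bit-identical across
runs and platforms.

A response is a hit iff the touch lies within 0.774 cm of the arrowhead tip
(inclusive); no touch within the (modeled, not timed) 3-s window scores as
a timeout and is treated as incorrect. Catch plates pair a near-white arrow
with a dark neutral background (≈ 73 ΔE, dominated by the L\* difference),
so detecting them requires no color discrimination.

## Adaptive engine

The per-axis staircase runs on log-ΔE: color-difference discrimination is
ratio-like across the 1–80 ΔE working range, so steps are multiplicative
and the threshold estimate is a geometric mean. A correct response lowers
the level and an incorrect one raises it, with the down/up step ratio fixed
at (1 − p\*)/p\* for p\* = 1 − 1/e ≈ 0.632 (a weighted up/down rule). The
track therefore equilibrates where the probability of a correct response is
p\*, which for a Weibull observer with scale t is the level dE = t — the
estimator converges on the observer's threshold parameter itself. An
equal-step rule would converge on the 50% point, ≈ 0.90 t for slope 3.5,
an avoidable −10% bias.

Steps halve at every reversal, never dropping below an effective 1 ΔE at
the current level (`log(1 + 1/level)`). The threshold is the geometric mean
of the last reversal levels. Guard rails: two consecutive hits at the floor
(1 ΔE) or misses at the ceiling pin the estimate there and flag it. The
ceiling is the smaller of 80 ΔE and the axis's gamut headroom.

Two protocols:

| parameter            | full extended | optimized |
|----------------------|--------------:|----------:|
| start level          | 40 ΔE         | 40 ΔE     |
| first up-step        | 16 ΔE         | 30 ΔE     |
| reversals (averaged) | 14 (last 10)  | 3 (last 2)|
| max trials per axis  | 80            | 25        |

These parameters are declared defaults chosen to satisfy the engine's
recovery contract — |bias| < 10% and RMSE < 15% of the true threshold for
Weibull observers at 5–60 ΔE under the full protocol — and to keep the
optimized track under 40% of the full track's trial count (measured mean
ratio ≈ 0.29). A session runs the three axes in seeded random order with a
catch plate after every 5 stimulus trials; catch accuracy below 80%
invalidates the session. The engine is deterministic given the responder
and the seed, and wall-clock free.

**Scoring.** The Global Chromatic Score is the mean of the three axis
thresholds. Classification: trichromat iff no axis exceeds its cutoff,
otherwise the axis with the largest threshold-to-cutoff ratio (both
red-green axes are typically co-elevated in deficiency; the relative
elevation disambiguates). Cutoffs default to protan 11.0, deutan 9.5,
tritan 13.5 ΔE — just above the trichromatic maxima observed in the
validation cohort — and are configurable. Severity is nearest-anchor
against 22 (low), 40 (mild), 60 (high) ΔE, with band edges at the midpoints
31 and 50.

## Simulated observers

Detection follows a Weibull psychometric function
p = γ + (1 − γ − λ)(1 − exp(−(dE/t)^β)) with slope β = 3.5 and lapse
λ = 0.02 by default — standard detection-task values; the study gives no
response model, so recovery tolerances are defined relative to this
declared slope. The guess rate γ is computed, not assumed: under the
default random-touch policy it is the hit-disc to screen area ratio
(≈ 0.004); under no-touch it is 0. Seen arrows are touched at the arrowhead
plus isotropic Gaussian motor noise (σ = 0.15 cm default); catch plates are
answered correctly with probability 1 − λ.

Cohorts draw per-axis thresholds independently from truncated normals with
each group's mean, SD and (min–max) truncation bounds; the default spec
reproduces the validation study's structure — 65 trichromats, 12
protan-deficient, 23 deutan-deficient. With strongly asymmetric bounds the
truncated mean shifts away from the nominal location parameter (most
visible on the deutan group's tritan axis); the generator is validated
against the analytic truncated-normal moments.

What the simulator does *not* model: cone-level physiology (no
Brettel-style dichromat rendering), learning or fatigue, reaction times,
eye movements, anisotropic or distance-dependent touch error. Passing
recovery tests therefore demonstrates the engine's statistical behavior
under a clean psychometric observer, not human performance.

## Study driver

`run_study` generates the default cohort, runs the full-extended protocol
on everyone, re-derives the optimized result for the same observers
(separate seeded replay), gives a seeded 40-subject subsample (27
trichromats, 13 deficient: 4 protan + 9 deutan, preserving the 12:23
split) a second session, and computes the report: classification-vs-truth
Cohen's kappa, per-axis Bland–Altman and ICC(A,1), per-group summary and
protocol-comparison tables, and a Bland–Altman figure. Every stage derives
its seed as a SHA-256 hash of (master seed, stage label, subject id), so
stages are insulated from reordering and the whole report is reproducible
byte-for-byte from the master seed.

Statistics are implemented from their defining formulas (kappa from the
contingency marginals; ICC(A,1) from the two-way ANOVA mean squares;
Spearman as the Pearson correlation of average ranks; the paired t as a
one-sample t on differences; the sensitivity sample size via Buderer's
formula) and cross-checked in the test suite against sklearn, pingouin and
scipy. Patient-level comparisons against the analog tests (the GCS–TES
Spearman of 0.80, the type-agreement kappas) require the raw human data,
which is not available; the comparator statistics are implemented and
tested, but those particular values are out of reach at desk scale.

## Problem sizes and numerical notes

The shipped study scenario is 100 subjects (240 sessions including the
optimized replays and the retest arm), about 25 000 simulated trials;
staircase recovery checks use 100 runs per condition. Color pairs are
cached per (axis, level) so repeated staircase levels cost one bisection
each. Degenerate inputs: a requested ΔE beyond the gamut raises an error
carrying the maximum achievable value; kappa on a single-category table,
ICC on zero variance, Spearman on constant input and the paired t on zero
difference variance raise explicit errors rather than returning NaN.

## Known limitations

- The device's actual adaptive rule, stopping criteria, base chromaticity
  and ΔE formula are proprietary/unstated; ours are declared defaults, and
  absolute threshold values depend on them even though the validation-loop
  statistics are robust to that choice.
- CIE76 treats CIELAB as uniform; near-gamut-edge pairs at high ΔE are
  less perceptually uniform than near-neutral ones.
- The cohort model samples axes independently within a group, ignoring the
  within-subject correlation between red-green axes seen in real
  dichromats; this slightly understates classification difficulty.
- Rendering targets fidelity of the modeled display, not of any physical
  screen the package happens to run on.
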