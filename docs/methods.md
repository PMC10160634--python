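# Methods

## Scope and model of the measurement

`chlorokin` models a pulsed-fluorescence imaging assay of chlorophyll
biosynthesis in dark-grown (etiolated) seedlings on vertically oriented
plates. One *measuring round* is a short blue actinic pulse (default 50 ms,
470 nm, 240 µmol photons m⁻² s⁻¹) followed by darkness until the next round
(default 2 min); the pulse simultaneously initiates greening and excites the
chlorophyll fluorescence integrated by the camera in the 680–750 nm band.
A 4-h protocol therefore yields 120 frames. Frame timestamps mark the start
of each round's pulse; the first frame (t = 0) is the first-ever illumination
of the sample, so there is no pre-illumination baseline frame. Because no
photosynthetic electron transport is active during the first hours of
de-etiolation, the emitted fluorescence is taken as proportional to the
chlorophyll amount in the pixel, not modulated by variable fluorescence.

The cumulative light dose is tracked in µmol photons m⁻² (intensity × pulse
length × rounds); no per-pulse photon count is derived, since that would
require an illuminated-area convention the package does not impose.

## Synthetic data generator

The generator is first-class, tested code: it defines the conditions under
which every downstream stage is validated.

**Plate layout.** A square plate carries a sowing grid of 3 rows × 5 areas
(15 cells); each genotype/treatment variant is assigned to 3 replicate cells
by a seeded shuffle. With ~30 visible seedlings per cell this gives 90
seedlings per genotype in the default design. The reduced-scale
configuration used by the simulation studies (`small_test_config`) keeps the
full 120-round timing but shrinks the frame to 64×64 px with a 3×6 grid of
two variants × 9 replicate cells (matching the n = 9 replicate ROIs of the
standard design) and 3 seedlings per cell; problem sizes for all
Monte-Carlo studies are stated with their results.

**Chlorophyll kinetic.** The fluorescence of a tissue zone follows the
simplest smooth curve with the three phases of de-etiolation greening:

F(t) = F₀ + A·(1 − e^(−t/τ)) + P·[σ(r·(t − t₀)) − σ(−r·t₀)]

with σ the logistic function. Defaults: baseline F₀ = 150 a.u., burst
amplitude A = 120 a.u. with τ = 4 min (the fast initial burst — consumption
of dark-accumulated protochlorophyllide — is ~95 % complete at 12 min),
logistic plateau P = 600 a.u., midpoint t₀ = 120 min (the exponential
phase), rate r = 0.15 min⁻¹. The offset term makes F(0) = F₀ exact and the
curve is monotone non-decreasing. The rate was chosen so that the
exponential phase is sharply delineated: the derivative reaches 25 % of its
maximum ~18 min before the midpoint, giving a flat lag phase until ~100 min
and a terminal plateau within the 4-h record. A consequence, and a known
limitation, is that the terminal slow-down begins around 150–160 min rather
than close to 4 h as in real seedlings; a slower logistic would blur the lag
phase instead, and the symmetric logistic cannot produce both.

Tissue zones scale this curve multiplicatively: cotyledon 1.0, hypocotyl
0.45, root 0.08 — cotyledons by far the brightest, roots faint (≈ 70 counts
above background at the reference frame) yet still separable by the
iterative background threshold described under segmentation.

**Protochlorophyllide.** P(t) = p₀·e^(−kt) plus a logistic resynthesis term
pinned to 0 at t = 0. Defaults k = 0.05 min⁻¹, resynthesis amplitude 0.8·p₀,
rate 0.05 min⁻¹, onset 120 min put the trajectory minimum at ≈ 63 min, inside
the 50–70 min window expected for the dark-pool photoconversion minimum, with
clear re-accumulation by 4 h.

**Rendering.** Each seedling is a vertical raster structure: 3-px-wide
cotyledon lobes in the top 25 % of its length, a 1-px hypocotyl (45 %), and
a 1-px root band (30 %), drawn shoot-up (row 0 = image top, plates vertical).
Pixel value = background (100 counts) + zone scale × F(t), plus Gaussian
read noise (SD 6 counts) and a Gaussian shot-noise proxy with
SD = 0.5·√signal, rounded and clipped to the 16-bit ceiling (65535). The
shot-noise proxy keeps all moments analytic; true Poisson statistics are not
simulated. Replicate biology is emulated by a per-cell log-normal multiplier
(CV 5 %) on the burst and plateau amplitudes only — deliberately not on the
baseline, so that replicate differences survive F/F0 normalization the way
biological amplitude variation does. Every generator output is a pure
function of (config, seed).

What the generator does **not** emulate: optical blur/PSF, seedling growth
or movement during the 4 h, overlap between neighbouring seedlings, spatial
illumination inhomogeneity, and hormone pharmacokinetics (treatments are
represented only as altered kinetic parameters). Passing tests therefore
demonstrate correctness of the measurement and statistics pipeline under
idealized plant geometry, not robustness to those real-data effects.

**Virtual destructive sampling.** Pigment "collections" are taken at nine
timepoints T0–T8 = {0, 10, 30, 60, 90, 120, 150, 180, 240} min — dense early
(burst, pchlide minimum at T3 = 60 min, resynthesis onset at T5 = 120 min)
and anchored at the endpoint. Chlorophyll *a* is proportional to the
fluorescence kinetic, chlorophyll *b* a fixed fraction (0.3) of *a*,
protochlorophyllide follows its own trajectory; measurement noise is
multiplicative log-normal (default CV 5 %). Tables are reported normalized
to the T8 value per variant and pigment.

**77 K spectra.** Emission spectra are sums of Gaussian bands over a
580–800 nm grid: free protochlorophyllide (630 nm, amplitude following the
pchlide trajectory), photoactive protochlorophyllide (654 nm, fast decay,
τ = 10 min), unbound chlorophyll (centre drifting 675 → 683 nm, amplitude
proportional to the bulk chlorophyll kinetic), PSII core (695 nm, logistic
onset ≈ 165 min), and a broad LHC antenna band (740 nm, width 16 nm, rising
from ~60 min). All time-dependent amplitudes are exactly zero at t = 0
except the two protochlorophyllide bands, so the initial spectrum shows only
the 630/654 nm maxima.

## Segmentation

One plant mask is built from a single reference frame and applied unchanged
to all rounds (seedling movement neglected). The reference frame is the
frame nearest a configured target time (default 180 min, near-maximal
cotyledon signal) provided its saturated-pixel fraction is ≤ 10⁻³; in auto
mode (no target) the unsaturated frame with the highest intensity SD wins,
earliest index on ties.

Background subtraction is by intensity threshold. The default method is
parameter-free and derived from Otsu's criterion: a plain two-class Otsu cut
falls *between* the tissue tiers (root ≪ hypocotyl < cotyledon) rather than
at the background, so the cut is refined iteratively — sub-threshold pixels
are re-split by Otsu and the lower cut adopted while the split remains
clearly bimodal. Bimodality is judged robustly (median separation > 2 × the
summed MAD-based scales) so that a handful of stray pixels from a brighter
tier cannot mask the valley, and pure background noise is never split. A
`fixed` method replays an explicit threshold for exact reproduction of a
previous analysis.

Zones are assigned geometrically: within each grid cell, the occupied row
extent of the mask is divided top-down into cotyledon/hypocotyl/root bands
(default fractions 0.25/0.45/0.30, matching the rendered seedling
proportions and configurable for other morphologies). Trace extraction then
computes, per ROI (grid cell × zone) and per round, the mean and SD of the
fixed mask pixels; empty ROIs yield missing values, never zeros.

## Kinetics and statistics

Traces are normalized per ROI to the round-0 mean (F/F0), cancelling
camera gain exactly; normalization precedes aggregation (the two orders
differ; the normalize-then-aggregate order matches how replicate curves are
conventionally displayed). Aggregation reports pointwise mean ± sample SD
(n − 1) across the replicate ROIs of a variant.

Phase annotation smooths the mean trace with a centred 5-round moving
average, differentiates on the time grid, and thresholds the derivative:
burst end = first time the rate falls below 50 % of its early maximum
(maximum over the first window); lag end (exponential onset) = last
pre-maximum time with rate ≤ 25 % of the global maximum. The 50 %/25 %
thresholds are package defaults exposed in the API; a trace whose early rate
never dominates (no burst) is flagged rather than mis-annotated. Missing
rounds are interpolated for annotation only, never for statistics.

Group comparison is per round, two-sided: a linear mixed model
(`value ~ group` with a random intercept per replicate unit) when ≥ 3 units
exist, otherwise — including every single-plate synthetic run — a Welch
unequal-variance test, with the fallback logged. Raw p-values across the
rounds of one comparison (120 tests) form the Benjamini–Hochberg family;
the adjustment is the standard step-up (implemented via
`statsmodels.stats.multitest`, cross-checked in the tests against an
independent textbook implementation). Maximal runs of adjusted p < α
(default 0.05) are reported as significant time intervals. Whether the BH
family should span timepoints, genotype pairs, or both is ambiguous in
general; this package corrects across timepoints within one comparison,
matching per-curve interval displays.

Imaging-vs-destructive correlation renormalizes the fluorescence trace to
its final-frame value (nominally 240 min; the last frame is stamped 238 min,
and Pearson's r is affine-invariant, so the 2-min discrepancy cannot affect
it), matches pigment timepoints to the nearest frame within ±1 min, and
reports Pearson's r over ≥ 3 matched pairs.

## Spectral decomposition

Measured spectra are first corrected by subtracting a blank reference taken
on the same wavelength grid (negatives floored at zero, floored fraction
reported). Decomposition is a bounded nonlinear least-squares fit of a
Gaussian sum: amplitudes ≥ 0, centres within ±6 nm of the template (±20 nm
for the broad LHC band, which both drifts and is wide), widths in
[2, 25] nm. Initialization is fixed at the template centres/widths with unit
amplitudes, so fits are deterministic; non-convergence sets a flag with the
residual RMS instead of raising. The drifting 675→683 nm chlorophyll band is
one component with wide centre bounds rather than two fixed components,
avoiding degenerate two-component fits of a single shifting band. Pool
tracking reports amplitude trajectories over the series and flags a
component increasing/decreasing when the Spearman correlation of amplitude
vs time exceeds 0.8 in magnitude; constant series carry no flag.

## Numerical and edge-case conventions

- Coordinates are 0-based; row 0 is the image top; grid cells are half-open
  pixel rectangles.
- Rendered stacks are uint16, so noiseless round-trip checks agree with
  ground truth to the 0.5-count rounding quantum; trace extraction itself is
  exact (verified against a brute-force per-pixel loop at 1e-13 relative).
- Replicate-mean coverage: with SD estimated from n = 9 replicates, the
  event |mean − truth| ≤ 2·SD/√n is a |T₈| ≤ 2 event with probability
  0.919 (not the normal 0.954); the test suite asserts the t-based value.
- Degenerate inputs fail loudly and specifically: non-positive durations,
  pulses longer than a round, over-capacity layouts, constant frames under
  Otsu, F0 ≤ 0 baselines (ROI dropped with a warning), fewer than 2
  replicates, fewer than 3 matched correlation points.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  config + seed reproduces stacks and tables byte-for-byte.

## Validation summary

The test suite validates each stage against independent oracles (brute-force
extraction loops, textbook BH step-up, grid-search argmin, quadrature of
Gaussian sums) and the pipeline end to end on simulation studies at the
reduced 64×64 scale: with identical kinetics in both groups the mean flagged
round fraction stays well under the nominal 0.05; with a +30 min exponential
onset shift, at least one significant interval (starting after the burst,
typically ~90 min) is found in essentially all seeded runs. All simulation
study sizes (100 null runs, 20 shifted runs, 50 correlation draws) are fixed
in `scripts/acceptance.py`, which recomputes every headline number from
scratch.
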