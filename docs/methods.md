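# Methods

This note documents the models, parameter choices and numerical decisions
behind each module, and what the synthetic benchmarks do and do not
establish about real data.

## Imaging regime and coordinates

All defaults emulate a widefield single-molecule acquisition with a 130
nm/pixel camera at 10 frames/s (Δt = 0.1 s), a diffraction-limited Gaussian
PSF of σ = 169 nm (1.3 px), ~500 detected photons per spot per frame over a
background of ~10 photons/px, and Gaussian read noise of SD 1 photon. The
noise model is Poisson shot noise plus Gaussian read noise with no EM excess
factor, appropriate for an sCMOS detector.

Continuous positions are in μm with the origin at the corner of image pixel
(0, 0); pixel index i spans [i, i+1), so a pixel's centre is at i + 0.5.
Sequence coordinates are 0-based, half-open, on the sense strand.

## Synthetic data generator

Particles move inside an elliptical cell mask containing an elliptical
nucleus. Motion states are fixed per particle (no interconversion), so
mixture fractions are exact by construction and recovery tests have a sharp
ground truth; a fraction `F_slow` is slow — fully stationary when
`anchored`, else diffusing at `D_slow` — and the remainder diffuses at
`D_fast` or, when `run_speed > 0`, undergoes directed transport.

Brownian updates use 10 Gaussian substeps per frame (per-axis SD
√(2·D·dt_sub)); a substep leaving the cell mask is mirrored about its start,
and a mirror that also leaves the mask leaves the particle in place for that
substep. Substepping keeps single-frame displacement statistics near the
boundary close to the free-space law; with the boundary disabled the
generator reproduces E[r²] = 4DΔt to sampling error, which the tests verify.

Directed particles follow the straight line from their birth position to the
nearest cell-edge point at constant `run_speed`, emulating microtubule
transport toward the periphery. Per frame they may pause (probability
`pause_prob_per_step`; pause length geometric with mean 5 frames), reverse
direction (`reversal_prob_per_step`), or terminate the run (exponential run
duration, mean `run_duration_mean_s`), anchoring on arrival at the edge.

Shipped presets encode the emulated study conditions:

| preset | kinetics | rationale |
|---|---|---|
| `notch2_untreated` | F_slow = 0.7, anchored; D_fast = 2 μm²/s | large translation-anchored fraction of an ER-docked mRNA (the true fractions are not published; 0.7 is a plausible ground truth, not a reported value) |
| `notch2_puromycin` | F_slow = 0.2, anchored | release of the anchored population by translation inhibition |
| `map1b_untreated` | run_speed = 1.3 μm/s; pause 0.05/frame; reversal 0.02/frame | reported mean transit speed without treatment |
| `map1b_puromycin` | run_speed = 1.5 μm/s | reported mean transit speed under puromycin |
| `coloc_fixed` | 85% of channel-A spots with a jittered channel-B partner | reported colocalization of labelled spots with reference FISH |

The transport presets set `F_slow = 0` because they describe the directed
subpopulation whose per-event speeds are measured; D_fast = 2 μm²/s is a
typical fast cytoplasmic mRNP diffusivity and makes the default pairing
radius (below) capture >95% of fast steps.

Rendering integrates the Gaussian PSF exactly over pixel areas (error-
function differences) within a ±(4σ+1) px window, conserving expected
photons to ~0.01%. The generator does not model photobleaching, blinking,
z-drift, focal blur, granule fusion or motion blur within a frame, so
passing recovery tests demonstrates correctness of the estimators under the
stated model, not robustness to those real-data effects.

## Localization

Per frame: difference-of-Gaussians band-pass (σ = 1 and 3 px, output
recentred to zero mean), 8-connected local maxima above k·SD of the filtered
frame (k = 4), candidates closer than 3 px merged keeping the brighter, then
least-squares fitting of a symmetric 2D Gaussian (amplitude, centre, σ,
offset) on a 7×7 window. Fits are flagged invalid — never raised — when the
window leaves the frame, the optimizer fails, σ falls outside [0.5, 4] px,
or the centre leaves the window. At the default photon budget the fit
achieves ≈0.14 px RMSE (2D) with no measurable bias, and ≥95% recall and
precision on well-separated spots, which the acceptance tests measure.
Least-squares (not Poisson MLE) fitting was chosen for robustness and speed;
at ~500 photons over low background its efficiency loss is immaterial to the
downstream statistics.

## Linking

Two linkers serve the two downstream analyses:

* displacement pairing for SMdM takes **mutual** nearest neighbours between
  consecutive frames within r_max, each localization used once. Mutuality
  minimizes false pairs; what remains is absorbed by the likelihood's b·r
  term.
* track linking greedily assigns track-ends to next-frame localizations in
  ascending distance order (ties broken by the earlier endpoint's
  (frame, y, x) order), starts new tracks for unmatched spots, closes no
  gaps by default (blinking is not simulated), and discards tracks shorter
  than 3 frames.

r_max defaults to 8 px = 1.04 μm: a D = 2 μm²/s particle moves an RMS of
0.89 μm per 100 ms, so the radius keeps >95% of fast-population steps while
bounding mismatches at realistic spot densities.

## SMdM maximum likelihood

The single-component density (2r/a)e^(−r²/a) + b·r is improper on (0, ∞)
for b > 0, so both likelihoods are renormalized over the observable support
(0, r_max]: the closed-form normalizer is (1 − e^(−r_max²/a)) + b·r_max²/2,
and the mixture normalizer is the F-weighted sum of component normalizers
plus the background term. An infinite r_max is allowed only with b = 0, in
which case the single-component MLE has the closed form â = mean(r²) — used
as an exactness oracle for the optimizer, not as the implementation.

Optimization is bounded quasi-Newton (L-BFGS-B, ftol 1e−13) on log-scale
parameters with deterministic multistart: scale starts derived from sample
quantiles of r² (for a Rayleigh, the q-quantile of r² is −a·ln(1−q)),
mixture-weight starts at {0.3, 0.5, 0.7}, background starts at 0 and
1/r_max². With b fixed at 0 the problem is one-dimensional and solved by
bounded scalar minimization to ~1e−10 relative precision. D is bounded to
[1e−4, 20] μm²/s, b to [0, 100] μm⁻².

Two-component fits require n ≥ 200 (weights are unstable below that,
observed in recovery simulations); components are relabelled so D₁ ≤ D₂ and
flagged **degenerate** when D₂/D₁ < 1.5 *or* the mixture improves on the
single-component log-likelihood by less than 3 (2ΔlogL < 6) — on
single-population data the mixture optimum lies on the a₁ = a₂ ridge where
F₁ is meaningless, and the likelihood-ratio screen catches exactly that.

A caveat inherent to the truncated model: when 4DΔt approaches r_max², a
truncated Rayleigh is nearly linear in r and trades off against b, so joint
(D, b) estimates of fast components from heavily truncated samples carry a
known negative bias on D. The acceptance recovery tests therefore draw from
the exact generating model; per-bin map values are interpreted through
wide-band checks rather than tight tolerances.

Maps assign each displacement to the 2.5-px bin (325 nm at 130 nm/px)
containing the midpoint of its endpoints — symmetric in the two endpoints —
and fit bins with at least n_min = 30 displacements, leaving the rest NaN
rather than extrapolated.

## Transport

Kymographs resample the movie at unit arc-length positions along a polyline
with bilinear interpolation, taking the maximum over an odd perpendicular
width (wide-reslice idiom; a mean aggregate is available). A particle moving
at v along the path appears as a ridge of slope v, recovered within 10% for
v ∈ [0.5, 2] μm/s at the default imaging regime.

Run detection segments a track into maximal stretches of consecutive
"moving" steps (instantaneous speed ≥ 0.5 μm/s — pauses break segments) and
accepts a stretch as a directed run when it spans ≥ 5 frames, its
straightness (net over path length) is ≥ 0.8, its mean turning-angle cosine
is ≥ 0.7, and its regression speed is ≥ 0.5 μm/s. The cosine criterion
discriminates motor-driven motion (cos ≈ 1) from random walks (cos ≈ 0) and
holds the false-positive rate on Brownian tracks at D ≤ 0.2 μm²/s below 5%
(measured ≈4% at D = 0.05, ≈1% at D = 0.2 over 1,000 simulated 50-frame
tracks) with no effect on true runs. Event speed is the slope of the
least-squares fit of position projected on the run's net-displacement
direction against time; per-event speeds from kymograph ridges are available
but the track regression is the reported statistic, being independent of
path digitization.

Distance statistics interpolate Euclidean distance transforms of the
nucleus- and cell-mask **boundaries** (not centroids) at subpixel spot
positions; spots outside the cell mask are flagged and excluded from
summaries.

## Colocalization

Matching is one-to-one and greedy in ascending distance within a 3 px
(≈390 nm ≈ 2 PSF σ) radius. The percentage reported divides matched
channel-A spots by all channel-A spots — asymmetric by design, as channel A
is the label under validation. No chance-colocalization correction is
applied to the headline number (raw percentages are the convention for this
validation); a randomization control can be built by shuffling one channel.
Focus counting (e.g. P-bodies per field) reuses the spot detector with
granule-scale band-pass sigmas (2, 6 px).

## Array design

Spacer windows tile the 3′ UTR from its 5′ end, gapless by default, at the
default length of 36 nt and a default budget of 48 spacers; each spacer is
the exact reverse complement of its sense window (the crRNA base-pairs with
the mRNA) and windows containing N are skipped with a warning. Splitting
across plasmids is contiguous and near-even. Assembly produces
signal + repeat + (spacer + repeat)…; the direct-repeat and 5′ signal
sequences are experiment-specific mandatory inputs, not defaults. No
spacer-efficiency filtering (secondary structure, accessibility) is
performed.

The build planner partitions an array into blocks of ≤ 12 spacers. Within a
block, fragments split recursively sharing exactly one spacer at each split
(5–7 spacers → two leaves of 3–4; 8–12 → near-even halves), bottoming out at
3–4-spacer leaves — the sizes orderable as one oligo pool. Disjoint blocks
are joined pairwise left-to-right, each join preceded by adding the right
block's first spacer as a PCR overhang to the left product, so every
overlap-extension join in the plan overlaps in exactly one spacer. The
planner is validated exhaustively for 3–48 spacers.

## Pipeline and reproducibility

Stages communicate through files (16-bit multi-page TIFF movies with
plain-text sidecars, 8-bit mask TIFFs, fixed-schema CSVs, JSON plans and
summaries). A run manifest records the package version, configuration,
per-stage seeds and SHA-256 hashes of all outputs. Per-stage seeds derive
from the global seed by hashing the stage name, so adding or reordering
stages never changes another stage's random stream.

## Benchmark problem sizes

The shipped benchmarks use: n = 10⁴ displacements for parameter-recovery
checks; 18 + 10 simulated cells (~40 particles, ~250 frames each) for the
slow-fraction contrast; 39 and 35 directed events simulated one particle
per 128×128 movie for transit-speed recovery; ten 512×512 scenes of 200
spots per channel for colocalization; and 100 Monte-Carlo refits for
localization error. These sizes match the emulated study's reported event
and cell counts where those are known, and otherwise were chosen to make
sampling error small against the tolerance being checked.
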