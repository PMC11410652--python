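# Methods

`heatseek` quantifies two-choice host-seeking assays: mosquitoes in a cage
face two rectangular scoring zones (e.g. one backed by a 34 °C thermal-IR
source, one at ambient temperature) and their behaviour is video-recorded
from behind the mesh. This note documents the models and numerical choices
the package makes, and what its synthetic tests do and do not establish.

## Coordinate and frame conventions

Image coordinates: origin top-left, x rightward, y downward; "upward"
movement on the mesh is decreasing y. The default recording is 720 × 1280 px
at 10 fps for 300 s (3,000 frames). The two scoring zones default to
466 × 456 px rectangles placed symmetrically about the vertical midline,
each centred within its half of the frame; zone membership is half-open
(`[x, x+w) × [y, y+h)`), so no pixel can belong to both zones. Zone
placement within the frame is configurable; the symmetric default preserves
left/right neutrality.

## Tracking pipeline

1. **Foreground.** Either a fixed dark-object threshold (pixel < level,
   default 128) or a per-video background model: the per-pixel mode over
   100 uniformly sampled frames, with foreground where
   |frame − background| > 30 grey levels (strict inequality). Mode ties
   break to the lower intensity. The modal background assumes objects move
   enough that no blob occupies a pixel in the majority of sampled frames —
   true for 5-minute recordings with landed bouts of a few seconds, and the
   reason very short synthetic recordings are avoided (a bout spanning most
   of a short clip is absorbed into the background and leaves only a
   flickering fringe).
2. **Blobs.** Connected components under 8-connectivity; centroid = mean
   pixel coordinate, area = pixel count; components ordered by the raster
   position of their first pixel. Two overlapping mosquitoes merge into one
   detection; no splitting is attempted.
3. **Linking.** Greedy nearest-neighbour assignment between consecutive
   frames with a maximum jump (default 20 px/frame; the true cutoff used on
   the original videos is unpublished). Ties break by smallest distance,
   then earliest track, then earliest blob. Greedy rather than globally
   optimal assignment is deliberate — it matches the described
   nearest-neighbour stitching — and an exhaustive minimum-cost oracle
   exists in the tests; the two agree whenever objects stay farther apart
   than twice the per-frame step. Length-1 fragments are kept; filtering is
   downstream.

## Behavioural classification

Flying mosquitoes are less opaque on video, so their thresholded blobs are
smaller than landed ones. An inclusive area window (default [50, 400] px²,
calibrated on the synthetic fixtures; the original numeric window is
unpublished) keeps landed detections and re-segments tracks where interior
detections are removed.

Walking is the proxy for host seeking (probing cannot be seen from the
tracking camera). Per-step speeds (displacement × fps) are smoothed with a
centred 5-frame moving average; a detection is *seeking* iff its smoothed
speed strictly exceeds a threshold. Stationary mosquitoes show nonzero
apparent speed from centroid jitter, so the default threshold is the 97.5th
percentile of smoothed stationary speeds for the default jitter scale
(0.5 px SD at 10 fps → ≈14 px/s), computed by a seeded Monte-Carlo
calibration; it was cross-checked against rendered stationary tracks
(measured 97.5th percentile ≈14.5 px/s). A `landing_only` mode scores every
landed detection instead, for species that land on the preferred zone
without walking about.

## Metrics

With per-zone seeking-observation counts `o1, o2` over `F` frames:

- `HSI = (o1 + o2 + o_outside)/F` — mean number of simultaneously seeking
  mosquitoes (all seeking observations count, in-zone or not);
- `PI = (o2 − o1)/(o1 + o2)` — PI < 0 prefers zone 1, PI > 0 zone 2; the
  counts- and per-zone-HSI formulations are identical because `F` cancels.
  A PI of an experiment with zero in-zone observations is an error, not 0,
  so empty experiments cannot silently score as neutral;
- `IHSI(t)` — per-frame seeker count in one zone averaged over experiments,
  optionally smoothed (centred moving average, off by default);
- `ATT/ATD/DTT` — per-zone bout statistics (mean seeking time per bout,
  mean path length per bout, bout count), each summarised as the
  normalised differential `(m2 − m1)/(m1 + m2) ∈ [−1, 1]`. A bout counts in
  a zone when it has at least one seeking detection there; a bout crossing
  both zones counts once per zone; a step's distance belongs to the zone of
  its starting detection. A 0/0 differential is defined as 0. (The ATT/ATD
  normalisation in the original description is ambiguous — "a score of <1"
  for a ±1-bounded quantity is read as "<0"; this package uses the
  normalised-differential reading throughout.)
- Dwell times: contiguous in-zone residence runs per track, in seconds.
- Replicate inclusion: a technical replicate passes with HSI ≥ 5
  (inclusive); a cage needs ≥ 2 passing replicates, and its summary is the
  mean over passing replicates only.
- EAG amplitude: extremal deflection within 5 s after stimulus onset minus
  the mean potential over the 5 s before it; default polarity is the
  largest absolute deflection, reported as a magnitude.

## Synthetic assay generator

Each mosquito is an independent renewal process: flight segments alternate
with landed bouts. Landings arrive as a Poisson process (rate = sum of the
two per-zone rates, default 0.01 /s each per mosquito); each landing picks
zone 2 with probability `r2/(r1+r2)`, so preference is encoded purely as a
rate ratio and the expected PI is `(r2 − r1)/(r1 + r2)`. Bouts are
exponential (mean 6 s) and stationary with probability 0.25 (fixed point +
0.5 px Gaussian centroid jitter) or seeking otherwise (upward-biased walk).
Walk speeds are log-normal (median 25 px/s ≈ 1 cm/s at the default optics,
log-SD 0.5); headings are wrapped-normal centred on "up" with 0.8 rad
spread — symmetric in left/right, as observed for seeking mosquitoes; walks
reflect at the frame borders. Flight is a fast undirected walk (median
250 px/s). An optional piecewise activity schedule multiplies the landing
rate over given intervals to emulate CO₂ pulses; no fixed pulse series is
baked in because the original timing is configurable per experiment. Bout
durations, speeds and heading spreads were fitted to unpublished curated
data in the original work, so the defaults here are this package's own
choices of realistic values, not reproduced numbers.

Rendering draws landed mosquitoes as opaque dark ellipses (intensity 30 on
a 230 background, 2:1 aspect, area = the ground-truth pixel area) and
flying ones smaller and fainter (intensity blended 40% toward the blob
value, so they clear the Δ>30 background rule but not the fixed dark
threshold), plus i.i.d. Gaussian pixel noise (SD 3 grey levels, clipped to
[0, 255]) — comfortably inside the Δ>30 margin. What rendering does *not*
emulate: illumination gradients and drift, shadows, mesh texture, motion
blur, lens distortion, partial occlusion by the cage frame, and
photorealistic mosquito shape. A green round-trip test therefore
establishes that the pipeline's logic is self-consistent at realistic
densities and noise, not that it would meet the same error bounds on real
video.

Randomness: one master seed; per-mosquito sub-streams are spawned
deterministically (`SeedSequence.spawn`), so cohorts are reproducible and
insensitive to iteration order.

## Random-walk power study

Fictive walkers on the full-size arena alternate walking bouts and pauses
(both exponential, means 5 s / 5 s) and move with the same log-normal speed
and upward-biased heading model; starts are uniform over the frame and
borders reflect. Scoring mirrors the real pipeline: walking observations in
a zone are seeking observations. Each (walker count, iteration) cell yields
a PI and an HSI; iterations with zero in-zone observations have an
undefined PI and are excluded from the moments but reported. With the
default parameters the SD of the PI is ≈ 0.8/√HSI.

The minimum-HSI rule makes the informal "little additional decrease of
variance" criterion explicit: after an isotonic (non-increasing) projection
of the SD curve — the true SD provably shrinks with walker count, so the
projection only removes Monte-Carlo noise — the threshold is the smallest
mean HSI from which every subsequent marginal SD reduction per unit HSI
stays below a tolerance (default 0.01). At the study's design scale of
10,000 iterations the marginal-gain noise (~0.006) sits below that default;
at desk-scale 1,000-iteration runs it does not, which inflates the
estimated threshold — use more iterations or a larger tolerance there. With
this package's movement parameters the default tolerance plateaus near
HSI ≈ 12; a tolerance of ~0.035 reproduces the original choice of 5.

Implementation note: the walker kernel is vectorised over
(iterations × walkers) with preallocated float32 buffers; border reflection
is computed by folding the unconstrained cumulative path (valid because
steps do not depend on position), and the walk/pause alternation uses the
memoryless two-state chain equivalent to exponential bouts.

## Radiometry

Temperatures are kelvin internally (Celsius helpers at the interfaces).
Constants: Wien `b = 2897.77 μm·K` (fixed), CODATA
`σ = 5.670374419 × 10⁻⁸ W m⁻² K⁻⁴`, second radiation constant from
`scipy.constants`. Band fractions integrate `x³/(eˣ−1)` by adaptive
quadrature (relative tolerance 10⁻¹⁰; the integrand is cut off above
x = 700 where it underflows double precision); the full-band integral
reproduces σT⁴ to better than 10⁻⁶ relative. The detector interception
fraction is sensor area over the hemisphere `2πd²` (uniform angular
emission), which is exactly inverse-square in distance. The lock-in
calibration interpolates the reference signal linearly in σT⁴ — the
physical quantity the signal tracks — not in temperature, and refuses to
extrapolate outside the reference range. The pyroelectric detector's
spectral responsivity is treated as flat over its 1–25 μm window.

## Known limitations

- Merged blobs are single detections; at the highest simulated densities
  this costs a few percent of observations (well inside the 10% round-trip
  bound but a real bias).
- The modal background model assumes no object dominates a pixel's sampled
  values; it is unsuited to very short recordings or to animals that never
  move.
- Movement-parameter defaults are plausible stand-ins, not fitted values;
  quantities that depend on them (e.g. the absolute HSI-variance curve)
  transfer only qualitatively to real data.
- In-memory rendering of a full 3,000-frame recording needs ~2.7 GB; render
  shorter clips or write frame ranges to disk for full-length videos.
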