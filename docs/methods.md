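# Methods

This note records the models implemented in `tidetrack`, the defaults and
their rationale, the numerical choices, and what the synthetic-world
validation does and does not establish.

## Data model and conditioning

A `DepthTempSeries` holds one tag's record: strictly increasing UTC
timestamps, depth in metres positive-down (surface = 0), temperature in °C
(possibly at a coarser cadence, hence NaNs), and a censored flag set where
depth reached the pressure-sensor ceiling. A censored sample is a lower
bound on true depth, never an estimate of it: downstream, a censored daily
maximum contributes only the "seabed must be at least this deep" direction
of the bathymetric emission term and suppresses the seabed-contact term.

Conditioning follows two documented rules:

* **Down-sampling** to a common resolution (default 600 s) keeps the first
  sample at or after each midnight-aligned bin boundary. No averaging or
  interpolation: a bin mean would attenuate the tidal sinusoid's amplitude,
  which is the geolocation signal. The operation is idempotent.
* **Surface-drift trimming** removes the maximal trailing run of civil days
  on which the detached tag floated: ≥ 95 % of samples at ≤ 1 m, daily
  depth sd ≤ 0.25 m, and no sample deeper than 1 m + 3 × 0.25 m. The
  max-depth guard guarantees no day containing a genuine dive is ever
  trimmed. Interior days are never removed. All three thresholds are
  config-exposed; they are conventions of this package, chosen to be
  conservative for float-jacketed tags.

A "24-hour cycle" is everywhere the UTC civil day (00:00–24:00): tag clocks
run UTC, and a fixed boundary keeps every per-day statistic reproducible.

## Synthetic world

The generator produces the study conditions the analysis assumes, as pure
functions of (parameters, seed).

**Environment.** A 25 × 25 grid (default 4° lon × 3° lat, cells ≈ 13 km)
with: low-order random-cosine bathymetry scaled to ≈ 8–130 m and a land
strip along the western edge; a single M2 tidal constituent whose amplitude
rises monotonically west→east from 0.3 to 3 m and whose phase rotates
smoothly across the domain (amplitude and phase gradients deliberately
non-parallel, so the pair identifies position); and temperature = latitude
gradient (−1 °C/° north) + seasonal sinusoid (amplitude 7 °C, peak
mid-August), spanning ≈ 7–22 °C over the year — the range a temperate shelf
sea and its demersal fish experience.

**Movement.** A two-state Markov-switching Brownian walk: per-axis daily
displacement sd = √(2·D_s) km, switch matrix defaulting to 0.9 persistence.
Default diffusivities 30 (resident) and 750 km²/day (transiting) give
sub-cell daily moves at residence and ~20–40 km/day transits — desk-scale
analogues of coastal-shark redistribution versus residency. Proposals
landing on land or off-grid are resampled (≤ 100 attempts, then stay);
resampling is simpler than reflecting boundaries and adequate at this
scale.

**Tag records.** Each day is partitioned into alternating rest and active
bouts. Active bout lengths are exponential with mean 2 h; rest bout means
are scaled by rf/(1−rf) so the requested rest fraction rf is attained in
expectation. At rest, depth = seabed + A·cos(ωt − φ) with the cell's tidal
amplitude and phase (t in absolute seconds, so phase is coherent across
days). Active depth = seabed − excursion (exponential, mean 10 m) plus a
within-bout random walk (sd 1.5 m per 10-min step). The wander term is what
makes active bouts *look* active: without it an off-bottom hover is
piecewise-constant and indistinguishable from seabed rest by any
residual-based detector, which would contaminate the tidal evidence with
spurious zero-amplitude fits. All night samples (18:00–06:00 UTC in the
generator's simplified diel clock) are shifted shallower by `dvm_offset`
(default 15 m): the offset is *planted* as the expected day-minus-night
mean depth difference, which is exact when the day and night rest fractions
are equal — hence both default to 0.55. The night shift turns night rest
into off-bottom hovering that still carries the tidal sinusoid; the
per-window intercepts of the tidal fit (below) absorb the level shift.
Depths are clipped to [0, seabed + amplitude + 4·noise sd].

**Mark–recapture.** Releases uniform over the central 60 % of the domain
(resampled to sea); displacement magnitude Rayleigh with sex-specific scale
(defaults 162 km female / 118.1 km male, i.e. mean displacements
≈ 203 km and ≈ 148 km, the field-scale sex bias the dispersal summaries
are meant to detect); direction uniform; recapture Bernoulli; days at
liberty geometric with mean 191.

What the synthetic world does *not* emulate: realistic coastlines, multiple
tidal constituents, depth-dependent temperature profiles, tag clock drift,
measurement spikes, or behaviour that correlates movement with the
environment. Passing tests therefore demonstrate that the estimators
recover what they are built to recover under the stated generative
assumptions — not that real records satisfy those assumptions.

## Diel labelling

Sunrise/sunset use the NOAA (Meeus-based) solar-position equations at
zenith 90.833°, evaluated at solar noon of the civil day; agreement with an
independent low-precision sunrise-equation oracle is within a few minutes
at temperate latitudes, and polar day/night return a no-event marker. The
one-hour buffer is applied *inward* of both events (day =
[sunrise+1 h, sunset−1 h), night = [sunset+1 h, next sunrise−1 h)): the
point of the buffer is to exclude crepuscular behaviour from both periods.
Night belongs to the evening's civil day, so each classification cycle is
self-contained; the next-day sunrise is computed at the same position
(sub-daily position change shifts solar times by under ~3 minutes at these
movement scales). The solar position is the geolocated daily position when
available, else the release position — the choice matters little below
~100 km of position error.

## Vertical metrics and classification

Vertical speed attaches |Δdepth|/Δt (m/min) to the later sample; intervals
longer than 3× the nominal cadence yield no speed. The seabed proxy is the
cycle's maximum depth over *all* samples (crepuscular included — a maximum
is a maximum); day/night proximity fractions and means use only the
buffered day- and night-labelled samples. "Near the seabed" is
proxy − depth ≤ 10 m, boundary inclusive.

The day-vs-night test is a two-sided Mann–Whitney rank-sum test (day and
night samples are unpaired). When both samples have ≤ 12 observations the
p-value is the exact permutation probability P(|R₁ − E R₁| ≥ observed),
computed by a subset-sum dynamic programme over doubled midranks — exact
under ties, unlike the textbook no-ties exact distribution. Larger samples
use the tie-corrected normal approximation with continuity correction.
Significance uses p ≤ α (α = 0.05): a p of exactly 0.05 counts as
significant, since only a strictly non-significant result means no
migration. Direction is decided by the median difference, the location
statistic that matches the rank test's robustness. Cycles with fewer than
5 samples in either period are reported *unclassified*, not nVM — tiny
samples cannot reach significance, and counting them as "no migration"
would silently inflate the nVM proportion. Unclassified cycles are excluded
from monthly behaviour proportions.

Monthly summaries are per fish per calendar month (mean ± sd of each
metric, behaviour proportions over classified days); cross-fish monthly
figures are unweighted means over the fish present that month. The headline
day-vs-night contrasts are Welch unequal-variance t tests on fish-month
means, with Welch–Satterthwaite fractional degrees of freedom — fish-month
means are heteroscedastic across fish, and pooled-variance t would not be.

## Geolocation HMM

**State space.** Joint (cell, behaviour) over sea cells; daily time step;
day-0 prior is a delta at the release cell with equal behaviour weights;
optionally the final day's emission is restricted to the recapture cell
(both anchored and unanchored modes are provided).

**Transition.** Behaviour switches by the 2×2 matrix, then position
diffuses with the *new* state's D: Gaussian convolution with per-axis sd
√(2·D·Δt) converted to cell units (longitude km-per-degree taken at the
domain's central latitude), truncated at 4 sd. This is the exact solution
of the constant-coefficient diffusion (Fokker–Planck) step and is far
easier to verify than explicit PDE time-stepping. Mass landing on land is
redistributed by renormalising over sea cells — an approximate reflecting
boundary. In the filter the diffusion is mass-preserving per state surface
so relative state probabilities survive; the backward pass uses the
kernel's adjoint (mask, then convolve; the Gaussian is symmetric). The
global land-renormalisation factors are per-step scalars that cancel in the
smoothed surfaces up to the boundary approximation; the identities that
matter — every surface sums to 1 and vanishes on land, final-day smoothed
equals filtered, day-0 smoothed is the release delta — hold exactly and are
asserted in tests. A diffusivity whose 4-sd kernel exceeds the grid is
rejected rather than silently truncated.

**Rest detection and tidal fit.** Sliding 3-h windows (step 30 min) over
each day qualify as seabed rest when the M2 harmonic fit has rmse
≤ 0.75 m *and* the fitted-curve-removed vertical speed never exceeds
0.1 m/min; overlapping windows are merged. The day's tidal fit then pools
the samples of *all* rest windows with a shared (amplitude, phase) and one
intercept per window: phase is coherent across windows at a fixed daily
position, the per-window intercepts absorb level shifts between rest bouts
(notably the diel offset between daytime seabed rest and night-time
hovering), and pooling is what makes tidal evidence available on most days
— single rest bouts rarely span the half M2 period (6.21 h) required to
separate amplitude from the mean. The fit is reported only when the pooled
samples number ≥ 8 and span ≥ half a period. On noiseless sinusoids the
least-squares fit is exact to machine precision.

**Emission.** Per sea cell, the sum of independent log-terms described in
the README, with error scales σ_bathy = 4 m, σ_contact = 5 m,
σ_amp = 0.3 m, κ_phase = 20, σ_temp = 1 °C. These are this package's
defaults, set to plausible magnitudes for shelf-sea fields and a 10-minute
record: σ_contact covers tidal range plus near-bottom swimming above the
true seabed; σ_amp and κ_phase (circular sd ≈ 0.22 rad) reflect harmonic
fits on a few dozen noisy samples; σ_temp covers within-cell and
within-day thermal variability. All are config-exposed and should be tuned
to the fields in use. Days with under 25 % of expected samples fall back to
temperature-only evidence. If even the best sea cell's likelihood
underflows to zero (log-likelihood < −745 everywhere), the day's surface is
replaced by a uniform one with a warning — an impossible observation should
degrade gracefully rather than zero the filter.

**Point estimates.** The per-day most-probable position is the argmax cell
of the smoothed position marginal; the daily positional spread is the
root-mean-square great-circle distance from the posterior-mean position —
a documented substitute for a formal credible radius, monotone in posterior
dispersion. The joint Viterbi decoder over (cell, state) is provided as the
alternative whole-path estimator; it uses a dense untruncated Gaussian
kernel over sea cells, so its path can differ slightly from the smoothed
argmax sequence near kernel tails. Diffusivity pairs are compared by
forward log-evidence over an explicit candidate grid; no EM estimation is
attempted.

## Dispersal

Haversine on a sphere of radius 6371.0088 km; ellipsoidal corrections are
below 0.5 % at shelf-sea scales and are not worth the dependency. Days at
liberty are whole calendar-day differences. Return rates are percentages
rounded half-up to one decimal. Group summaries use n−1 standard
deviations; single-member groups report sd 0 with an explicit
`sd_defined = False` flag; records with missing recapture positions are
excluded with the count reported.

## Validation sizes and determinism

The test suite and the acceptance script size their simulations to run on a
single CPU in well under their budgets while keeping Monte-Carlo error
small relative to the margins tested: 90-day tracks on the 25 × 25 grid for
track recovery (20 tracks for the information-ordering property), 45-day
tracks × 50 replicates for evidence preference, 200 synthetic cycles for
behaviour recovery, 500 replicates for harmonic-fit recovery, and 5000
deployments for dispersal means. Every random quantity derives from an
explicit seed; hypothesis profiles are derandomised. The 10×-mis-specified
diffusivity comparison uses 10× *smaller* values: 10× larger ones produce a
transition kernel wider than the 25-cell grid and are rejected by the
kernel-width guard.

## Known limitations

* The land boundary is mask-and-renormalise, not a true reflecting stencil;
  posterior mass near complex coastlines is approximate.
* One tidal constituent: real amplitude/phase fields mix constituents, and
  a single-harmonic fit to a mixed record biases amplitude; the emission
  scales would need widening on real data.
* The temperature emission compares the daily mean experienced temperature
  with a 2-D field; no depth-resolved profile is modelled.
* Behaviour states are defined purely by diffusivity; emissions are not
  behaviour-dependent.
* The rank-sum classification treats samples within a day as exchangeable;
  serial autocorrelation in depth inflates the effective significance of
  both DVM and rDVM labels on real records. The planted-offset recovery
  rates quantify sensitivity, not field false-positive rates.
* No automatic artefact screening beyond the documented trimming and
  censoring rules: visual inspection of raw records remains the analyst's
  responsibility.
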