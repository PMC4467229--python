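# Methods

This note documents the models, defaults, and numerical choices behind
omskit, and what the synthetic data do and do not establish about real
recordings.

## Stimuli

All stimuli are unitless intensity movies in [0, 1] around a mean of 0.5;
Michelson contrast `c` maps a region to `mean·(1 ± c)`. Photometric
calibration (photoisomerization rates), display gamma, and optical blur
are metadata outside the model. The default rendering is a 1200-µm square
field at 2 µm/pixel and 60 Hz; analyses in the tests and the acceptance
script use a scaled rendering (800 µm, 8 µm/pixel, 30 Hz) that keeps every
stimulus, including the widest surrounds, inside the field while the whole
battery simulates in seconds. Results reported by the package state the
rendering they used.

Two timing conventions exist for the spot series: a 0.125-Hz square wave
versus 2 s ON / 2 s OFF per cycle. The package defaults to 2 s ON / 2 s
OFF (the annotation that accompanies every example trace) and exposes
`period_s` so either convention can be selected.

Every clip carries an event table (label, start, end) sufficient to
reconstruct all analysis windows; stimulus makers include a static lead-in
whose final 0.5 s is the labeled baseline epoch.

Luminance neutrality: stimuli built from anti-phase pairs (split fields,
counterphase annuli) are balanced per frame by construction, using an odd
square-wave phase so positive and negative bars cover equal area on the
centered pixel grid. Texture-motion stimuli mask a square-wave grating
with a disc/annulus; chord lengths are not whole spatial periods, so exact
balance holds for the average over whole motion cycles (one spatial-period
displacement) rather than per frame. Per-frame residuals are a few percent
of the mean at the default geometry.

## The rectified-subunit circuit

The generator is a linear–nonlinear cascade, not a biophysical model; its
purpose is to provide ground-truth data exhibiting the qualitative
response signatures of the OMS pathway.

**Subunits.** ON and OFF lattices share square 25-µm spacing (σ = 12.5 µm
Gaussian pooling). Each subunit pools stimulus contrast, convolves with a
biphasic, zero-DC temporal kernel (difference of third-order gamma bumps,
peak ≈ 60 ms, trough ≈ 135 ms, 500 ms support, positive lobe normalized to
unit time-integral), and half-wave rectifies at zero. The OFF lattice sees
inverted contrast with a 1.5× gain (the OFF dominance of the measured
responses; only its direction, not magnitude, is constrained by data). The
25-µm spacing places the step-like rise of frequency-doubled surround
inhibition between 25-µm bars (averaged away within single subunits) and
50-µm bars, as observed. A diagnostic `rectified=False` switch replaces
the rectifiers with halved linear terms; it exists to demonstrate that
frequency doubling collapses (>10×) without rectification.

**Wide-field inhibition.** A single collapsed stage: Gaussian-weighted
(σ = 150 µm, both lattices) sum of subunit outputs, passed through a
rectify-above-threshold nonlinearity `(x − θ)₊` with θ = 0.06 drive units,
and zeroed entirely by `ttx=True` (the population signals through sodium
spikes). Two deliberate departures from a literal reading of the measured
profiles:

* The measured inhibitory receptive field (258-µm ON 1-SD diameter) is the
  composite of a spatially distributed spiking population. A single
  pooling stage mimicking that composite with σ = 129 µm would let center
  stimulation recruit as much inhibition as surround stimulation, making
  the differential-motion sign pattern unattainable; the collapsed kernel
  must be wider, and 150 µm for both lattices reproduces the observed
  center/surround asymmetry. The excitatory center pools keep the
  measured tie (σ = 68.5 µm ON, 41.55 µm OFF, from 137/83.1-µm diameters).
* The threshold is continuous (`(x−θ)₊`) rather than a discontinuous gate;
  it is still exactly zero below threshold.

The threshold and the pre-/postsynaptic weights (both 3.0) were fixed once
on the default battery so that: 200-µm bars ride below threshold while
600-µm bars recruit suppression, differential-center texture motion stays
largely below threshold while global and differential-surround motion
drive it strongly, and high-contrast large spots produce the measured
switch from depolarizing to hyperpolarizing responses.

**VG3 cell.** Excitatory conductance = center-pooled subunit drive minus
presynaptic inhibition, floored at zero, × 6 nS per drive unit; inhibitory
conductance = postsynaptic weight × wide-field drive × 6 nS. Voltage is
the quasi-static mix `V∞ = (g_L·E_rest + g_e·E_exc + g_i·E_inh)/Σg`
(E_exc = 0 mV, E_inh = −60 mV, E_rest = −38 mV, g_L = 1 nS) relaxed with a
first-order 20-ms membrane filter, which also guarantees the voltage stays
inside the conductance-mix hull. EPSC/IPSC are the conductances at the
−60/0 mV holding potentials. Gaussian noise (default SD 0.01 nS) is added
to the conductances, seeded. Simulation runs at 1 kHz and is resampled to
10-kHz output traces. The VG3 cell does not spike (graded potentials).

**W3 cell.** Excitation mixes threshold-rectified VG3 release (threshold
−37 mV, 1 mV above rest; 10-ms synaptic delay) and a direct bipolar center
pool (σ = 58 µm). The release gain (0.032) was calibrated once so the two
pathways contribute equal differential-center EPSC amplitude at the
default 0.5/0.5 weights; the knockout switch therefore removes the
configured ~50% share of diff-center excitation while leaving
global-motion excitation (to which VG3 contributes nothing, being
hyperpolarized below release threshold) unchanged. Spikes are an
inhomogeneous Poisson process on the rectified net drive with a 2-ms
absolute refractory period, seeded.

**What the generator does not emulate.** Real trial-to-trial variability
structure, adaptation, series-resistance and junction-potential artifacts,
direction-selective mechanisms (the model is isotropic by construction),
the ~5× diff-center/global ratio of W3 excitation (the direct bipolar
pathway here lacks its own presynaptic surround), and any biophysical
(channel-level) detail. Passing tests therefore establish that the
analysis code recovers known ground truth under realistic geometry and
noise — not that the circuit model is a quantitative fit to any recorded
cell.

## Response metrics

Amplitudes are baseline-subtracted means in a 150-ms window (the
measurement convention allows 100–200 ms), with the baseline the 0.5 s of
static display before stimulus onset. Within a labeled segment the window
is placed where the absolute baseline-subtracted running mean is largest
and the signed value there is reported, so suppression and
hyperpolarization come out negative. Edge responses are measured the same
way within 0.35 s after the geometric center-crossing time from the event
table (a fixed-latency mode is available). F1/F2 are single-frequency
projection amplitudes over the largest whole number of fundamental
periods; squared amplitudes ("power") are exposed as derived fields. The
DSI is `|Σ F1(θ)e^{iθ}| / Σ F1(θ)`.

## Receptive-field fits

Spot-response curves are fit with the disc-integrated (cumulative) DoG —
the natural form when the x-axis is spot radius. Multi-start least squares
(σ_c ∈ {15, 30, 60} µm × σ_s ∈ {75, 150, 300} µm, bounded, tolerances
1e-8) guards against local minima; fits with σ_s ≤ σ_c are rejected and
the best valid start wins. Curves whose dominant response is negative are
sign-flipped before fitting (flag recorded) so amplitude parameters stay
non-negative. The single-Gaussian (inhibition) model is the k_s = 0
special case, so DoG RSS ≤ Gaussian RSS by nesting.

## Temporal-filter recovery

Overlapping lagged stimulus windows (default 15 frames = 500 ms at 30 Hz;
lag 0 is the simultaneous frame) are weighted by the frame-binned,
baseline-subtracted response; for stationary noise runs the baseline is
the run mean. PCA is computed on mean-centered weighted segments: on LN
simulations with known kernels, centering recovers both pathways reliably
(OFF correlation ~0.91–0.96) where raw second-moment PCA can fail
(~0.34–0.74), because the uncentered first component is dominated by the
ensemble mean; the uncentered variant remains available via
`center=False`. The SVD sign is fixed by orienting the component's
dominant extremum positive, realizing the "positive projection = ON"
convention; group labels are confirmed by the sign of each average's
dominant extremum. Both filters are rescaled by one factor so the sum of
their samples equals the sum of the global weighted average ("sum" is the
time-sample sum). A purely linear cell projects one-sidedly onto the
principal axis, so one group carries the kernel and the other only
residual noise — the expected linearity limit of this estimator.

## Anatomy statistics

Hard-core mosaics use sequential inhibition (dart throwing) with a
packing-limit guard at the random-sequential-adsorption jamming coverage.
DRP edge correction intersects every annulus with the rectangular region
exactly; the areas are evaluated by 96-node Gauss–Legendre quadrature
after the substitution x = c + r·sin φ, which removes the square-root
endpoint singularity (relative error ≲1e-6, verified against polygon
intersections). The effective exclusion radius converts the contiguous
central-dip deficit into the radius of an equivalent empty disc:
`r_eff = sqrt(Σ_dip (λ − λ_k)·ā_k / (π λ))` with λ the (n−1)/area mean
density and ā_k the mean corrected annulus area. With 2-µm bins this
recovers an 18-µm hard core to within ~1% (median over seeds).

Apposition distances honor the anisotropic voxel size (0.103, 0.103,
0.3 µm defaults) via a sampled Euclidean distance transform; puncta are
assigned the distance of their containing voxel. The Monte Carlo null
repositions puncta uniformly over the full x–y extent and the z-slab of
the synaptic layer, and `p = fraction of null iterations ≥ observed`,
ties counted as extreme. Because observed and null fractions live on a
1/n_puncta grid, tie mass makes the test conservative for sparse scenes;
calibration scenes therefore use dense plexus masks (dilated volume
fraction ~0.13) and 400 puncta, for which the type-I error at 0.05 lands
in the nominal range. The synthetic neurite generator (random-walk tubes
rasterized at voxel resolution, puncta placed on-mask for a configurable
connected fraction) is a labeled synthetic stand-in for segmented confocal
stacks, not an imitation of real neurite morphology.

## Pipeline and reproducibility

One global seed fans out to per-stage child seeds through
`SeedSequence(entropy=seed, spawn_key=(stage,))`, so stages rerun in
isolation bit-identically; bundle manifests record SHA-256 checksums.
`validate_run` checks the signatures derivable from a bundle's tables
(motion signs, TTX reversal, F2 dominance and its linear-control collapse,
size suppression with TTX release, knockout share, coverage arithmetic,
filter contracts, DRP radius, apposition enrichment); the
simulation-calibration properties (fit round trips, null calibrations) are
recomputed from scratch by the test suite and `scripts/acceptance.py`
instead of being re-read from a bundle.

## Known limitations

* The collapsed wide-field stage trades the measured inhibition profile
  for the correct center/surround selectivity; a faithful treatment needs
  a population of thresholded units.
* Per-frame luminance neutrality of disc-masked square gratings is only
  approximate (see Stimuli).
* The Poisson spike model has no refractory structure beyond an absolute
  dead time and no bursting.
* The conductance-to-current mapping ignores space clamp and series
  resistance, which real voltage-clamp data would not.
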