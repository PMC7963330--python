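# Methods

This note documents the models, estimators and numerical choices behind
`astroglia-age`: what the synthetic generators emulate, how each analysis
stage works, which parameters matter, and what passing the benchmark does
and does not demonstrate about real data.

## The scientific problem

Ageing astrocytes in hippocampal CA1 *stratum radiatum* atrophy: their
branches shorten, their territorial domains shrink, the volume fraction (VF)
of optically unresolved perisynaptic leaflets drops, gap-junction coupling
declines, K⁺ and glutamate clearance weaken, Ca²⁺ activity reorganizes into
fixed microdomains, and LTP at CA3→CA1 synapses is impaired. Quantifying
these effects requires a chain of analyses — photon calibration, filtering,
binarization, branch tracing, Sholl counting, cross-section profiling,
x-y-t event segmentation, current decomposition, fEPSP timecourse
normalization — none of which were published as reusable code, and the raw
data were not deposited. This package re-implements the full chain and
pairs it with synthetic-data generators that plant every published group
value as machine-readable ground truth, so each stage is verified by
parameter recovery rather than by eye.

## Image model

Every synthetic image follows one detector model:

    expected photon rate λ(x)  →  Gaussian PSF blur  →  Poisson(λ)
        →  gain·counts + offset + read noise

Defaults: gain 2 units/photon, offset 100, read noise 0.6 units
(0.3 photons), PSF σ 0.25 µm lateral / 1.0 µm axial, voxels 0.2 µm
laterally with 1-µm z-steps. A uniform tissue background of 4 photons/voxel
models autofluorescence and stray dye. That background does double duty:

* its shot noise is what the 1×/3×σ hysteresis thresholds ride on, and
* being Poisson, it sits exactly on the variance-vs-mean line, so it does
  not bias the photon-transfer calibration.

Read noise is deliberately small because the x-intercept of the
variance-mean fit is offset by −σ²ᵣ/gain; at 0.3 photons this bias
(≈0.1 photon) is negligible against the dimmest signal of interest, the
old-group leaflet haze (≈2.4 photons above background).

## Synthetic astrocytes

The cell is a sphere (soma, radius 4 µm, 300 photons/voxel) plus a branch
tree grown by persistent random walks: quasi-evenly spaced primaries leave
the soma, wander with directional jitter, draw segment lengths from a
normal distribution, and bifurcate with a preset probability at wide angles
(0.55–1.1 rad — daughters that diverge more slowly produce blurred tubes
that stay fused for several micrometres and hide the junction from any
tracer, human or automated). Walks stop at a flattened domain ellipsoid.
Because boundary truncation shortens realized segments, the raw draw mean
is calibrated per preset (`length_draw_mean`) so the *realized* mean equals
the published group value (8.4 µm for the adult group).

Unresolved leaflets appear as dim haze. The adult cell carries a merged
haze cloud (a 6-µm soft sleeve around all structure, which coalesces into a
near-ball — consistent with the adult domain area being close to the disc
area at the measured radius). The dystrophic old cell instead carries
discrete leaflet blobs (26 soft spheres, r≈2.4 µm) scattered in the
annulus 13–23.5 µm from the soma centre in a thin slab around the soma
plane, plus bare branch tubes: this is the only geometry consistent with
*both* published old-group numbers at once — a small projected footprint
(757 µm²) and a measurable VF (2.1 %) out to 20 µm beyond the soma border.
The haze brightness `h` is solved per stack so that the blurred noiseless
soma-plane annulus (10–20 µm outside the soma border, branch-leakage pixels
excluded, background included) averages exactly `leaflet_vf` of the soma
plateau — the planted VF is exact by construction, whatever the coverage.

Ground-truth domain area is defined by pushing the noiseless photon rates
through the same deterministic front end the pipeline applies (diffusion
enhancement, threshold at background + 1 nominal σ, z-projection,
morphological closing at 1 µm, hole fill). Enhancement widens contours
slightly; thresholding raw rates would define a footprint no measurement
can return.

## Photon-transfer calibration

`estimate_pmt_gain_offset` fits per-patch variance against per-patch mean;
the slope is the gain and the x-axis intercept the offset. Getting this to
work on *structured* stacks (the only stacks anyone calibrates) required:

* thin 1×7×7 patches — on this anisotropic grid a geometric cube of voxels
  is a 5-µm-tall slab that straddles every thin process;
* variance estimated from lateral pixel-pair differences, which cancel
  smooth structure to first order (an order of magnitude less gradient
  leakage than the raw patch variance);
* a homogeneity pre-filter (box-averaging a noise-only patch divides its
  variance by the box size; a gradient-dominated patch keeps most of it);
* stratified sampling (half background, half spread over the elevated
  intensity range) so a sparse cell still yields slope leverage;
* Theil–Sen initialization plus relative-residual trimming, and a final
  1/variance² weighted fit whose heavy background weight pins the
  intercept.

Typical recovery on synthetic cells: gain within ~5 % (median), offset
within ~1 detector unit — sufficient for every downstream stage (VF is the
most offset-sensitive: 1 unit ≈ 0.17 percentage points).

## Enhancement and binarization

`enhance_tubular` is a Weickert-type coherence-enhancing diffusion run
plane-wise along each axis with the three results averaged (this makes the
filter commute with axis transposition). The diffusion tensor follows the
2D structure tensor (gradient scale 1 px, integration scale 4 px);
diffusivity is `alpha`=0.25 across structures and up to 1 along them, 18
iterations at dt=0.2. The explicit scheme uses staggered forward/backward
differences for the diagonal flux terms — a central-difference divergence
leaves the Nyquist noise mode undamped and the filter then barely denoises.

`binarize_hysteresis` seeds at background + 3σ and grows through 26-
connected voxels above background + 1σ; σ and the residual background are
estimated on the raw stack (corner box, MAD) and scaled by the calibration,
because a MAD taken on zero-clipped photon counts collapses.
`prune_small` removes 26-connected components under 100 voxels (exactly
100 is kept). The haze cloud is intentionally part of this mask: the domain
area is the planar territory the cell's processes occupy, leaflets
included.

## Branch tracing

Automated tracing replaces the original manual neurite tracing; recovery of
planted topology is its benchmark. Voxel thinning proved unusable — the
installed 3D skeletonizer deletes thin plates of certain even widths
outright — so branches are extracted by geodesic shortest-path tracing
(TEASAR-style): a virtual source attaches to all mask voxels at the soma
surface; Dijkstra distances are computed over the 26-connected voxel graph
with steps weighted inversely by distance-to-boundary (paths hug tube
centrelines) and a 12× surcharge off the tube mask (dim haze may bridge
short segmentation gaps but must not offer shortcuts); branches are pulled
out longest-tip-first. A trace that runs into territory captured by an
earlier branch attaches to it — splitting it at a junction — only if the
two points share one local tube cross-section; parallel lanes inside one
thick trunk are the same process, a branch merely passing by is not. New
tips must stand 1.7 µm clear (with z counted at half weight, reflecting the
~4× worse axial resolution) of already-traced paths; remaining duplicate
lanes are suppressed and the resulting degree-2 nodes dissolved so real
branches are not left fragmented.

Tracing operates on the branch-level mask: voxels above 10 % of the
smoothed soma peak. The constant mirrors the cross-section excision
criterion and relies on the same physics — few-percent haze cannot reach
it, even an axially diluted branch does.

A "primary branch" is an edge whose proximal node lies on the soma surface
(within 3.5 µm of the soma mask; the soma is excluded with a 2.2-µm halo,
z-compressed, because its blurred skirt otherwise seeds spurious stubs).

`sholl_3d` counts transversal crossings of edge polylines with spheres of
radius 5–50 µm (1-µm steps) about the soma centre; a brute-force
shell-component oracle cross-checks it in the tests. Note the synthetic
arbors are sparser than real adult astrocytes (peak Sholl counts ~10
versus ~28 in tissue); branch statistics, not arbor density, are the
planted quantities here.

## Volume fraction

On a calibrated stack: pick the z-plane with maximal soma-integrated
intensity; cast five full lines through the soma centre at 72° spacing
(ten half-profiles, bilinear sampling at 0.1 µm); normalize to the smoothed
soma peak (=100 %); excise runs exceeding the local baseline by >10
percentage points and wider than >0.5 µm (branch peaks), leaving gaps; the
VF of a half-profile is the mean surviving fluorescence 10–20 µm outside
the soma border (the radius where the radially averaged profile first falls
below 50 % of peak); the cell's VF is the mean over the ten half-profiles.

The excision baseline is a running 15th percentile over 12 µm rather than
a median: branches running obliquely along a sampled line can occupy half
the window, and a median climbs onto them while a low percentile stays on
the unresolved-fluorescence floor. Excised runs are widened by 0.6 µm
(~2.5 lateral PSF σ) to drop blurred peak skirts. Because there is no
background subtraction in this procedure, the uniform tissue background is
part of the measured VF — as it is in the real measurement — and the
generator's haze calibration accounts for it.

## Ca²⁺ events

Movies are 60×60 µm at 1 µm/px, 600 frames at 1 frame/s, with 30 dark
frames. Planted events are connected pixel footprints of exactly the drawn
area (log-normal, median 20.2 µm² for the adult preset) active for a drawn
whole-frame duration (log-normal, median 6 s, clipped above the 4-s
filter) with a trapezoidal temporal profile (edge frames at 75 % of an
8σ plateau, zero outside): the planted duration and area are crisp targets
for the detector, which the tests require to be recovered within one frame
/ 10 %. Real events have graded rise/decay kinetics and so a softer
effective support; that realism is traded away deliberately, since with
kinetic tails the "true" duration becomes a matter of definition.
Re-initiations (probability `reuse_prob`) reuse the spot's footprint, so
initiation pixels repeat exactly.

Detection: per-pixel σ from dark frames; F₀ as a rolling 20th percentile
(121-frame window, evaluated every 10 frames and interpolated) shifted up
by the Gaussian-quantile bias z₀.₂σ so the ΔF > 3σ threshold has its
nominal false-positive rate; per-pixel active runs of ≤4 s erased; the
surviving voxels combined into 26-connected x-y-t components; components
under 4 voxels dropped. Metrics follow the definitions: duration =
(last−first frame+1)×Δt, area = distinct (y,x) pixels × px², volume =
voxel count × px² × Δt, initiation pixel = ΔF-weighted centroid of the
first active frame (2×2 binning in the initiation map).

The published adult event frequency density (0.9 s⁻¹µm⁻²) is dimensionally
implausible for a 10-minute recording of ~33 events per field;
`frequency_density` implements the stated definition
(n/(area×duration) ≈ 1.5·10⁻⁵ s⁻¹µm⁻² under these conditions) and the
discrepancy is left unreconciled.

## Electrophysiology

Voltage-clamp sweeps are sampled at 5 kHz. I-V protocols step −140…+80 mV
(Δ20 mV, 500 ms); ΔI is the plateau mean (last 100 ms) minus the pre-step
baseline; input resistance divides the −5 mV test step by its ΔI.
Synaptic sweeps are built component-wise — the 4-stimulus sweep is the
exact sum of components 1–4 and the 5-stimulus sweep adds the planted 5th
component, so burst subtraction recovers it by construction. I_K is
parametrized by its value 200 ms after the stimulus (the measurement
point), with a 30-ms rise and mono-exponential decay; I_GluT is a fast
peak-normalized transient (τ ≈ 10 ms). A transporter-blocked residual
template (`residual_ik_scale` × I_K) is emitted per burst count and
least-squares scaled to the tail (last stimulus + 100 ms onward) before
subtraction, leaving pure I_GluT. Mono-exponential fits include a free
offset (holding-current drift) and reject segments that do not decay
toward their asymptote within the window.

fEPSP timecourses run 15 min of baseline and 60 min post-HFS at 20-s
intervals, with a brief post-tetanic overshoot decaying (τ = 4 min) onto
the plateau at `potentiation_factor` × baseline and 2 % multiplicative
noise. LTP magnitude is the 50–60-min post-HFS mean as a percentage of
the baseline mean; a baseline of at least 15 min with CV < 0.15 is
required.

## Statistics and the report pipeline

Group comparisons use the two-tailed equal-variance two-sample t-test
(Welch by flag) and the two-sided Mann–Whitney U (exact for small tie-free
samples, tie-corrected normal approximation otherwise); α = 0.05, p < α
significant. `run_pipeline` executes configurable stages per age group,
writes tidy CSV tables (mean ± SEM, n, test, p), a run log and a
provenance JSON, and is deterministic given its seed.

## Problem sizes and replicate counts

The benchmark sizes are chosen so that recovery accuracy, not sampling
noise, decides the outcome: 20 stacks per group for VF (per-cell SD ≈
0.2–0.4 pp), 10 stacks for domain area and branch length, 11 movies
totalling 358 events for the Ca²⁺ medians, 40 SR101 fields (the planted
per-field count is itself Poisson; 40 fields keep its sampling error under
one placement quantum), 10 sweep families for the τ ratio. The unit-test
suite runs reduced replicate counts of the same experiments.

## Known limitations

* The synthetic arbors are sparser than real adult astrocytes; Sholl peak
  counts are not planted quantities.
* The geodesic tracer's tip-clearance and spur thresholds (1.7 µm / 2 µm)
  trade missed short branchlets against duplicate lanes; mean branch
  length recovery is accurate to ~10 %, individual-cell topology less so.
* VF carries a small positive bias (≈ +3–6 % relative) from un-excised
  branch skirts between the excision threshold and the baseline.
* The photon-transfer gain can read a few percent high on sparse cells
  (residual gradient leakage); VF is insensitive to gain, and the offset —
  which VF does feel — is recovered to ~1 unit.
* Passing these benchmarks shows the estimators invert this generator's
  forward model at realistic noise; real tissue adds depth-dependent
  scattering, motion, bleaching and anatomy (endfeet, neuropil texture)
  that the generator does not emulate.
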