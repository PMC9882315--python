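# Methods

## Scope and coordinate conventions

All measurements are along-hypha quantities. A hypha is represented by a
polyline traced **tip-first** in micrometres; arclength *s* measures distance
from the tip, so anterograde (tipward) motion decreases *s* and signed run
displacements are positive for anterograde runs. Pixel size defaults to
0.11 μm/px (100× objective on an 11-μm-pixel sensor); the frame interval
defaults to 0.3 s and the z-step to 0.2 μm. Neither is ever hard-coded in
analysis code — both travel with the `Movie` as OME-TIFF metadata and are
required on read (a missing calibration tag is an error, not a default).

## The synthetic movie generator

The generator (`synthio`) emulates the two-channel spinning-disk acquisitions
the pipeline targets, with complete ground truth.

**Motility model.** Each 561-channel punctum alternates between a stationary
state and directed runs. Stationary positions get iid Gaussian jitter
(σ = 0.03 μm per frame, non-accumulating). Runs start after a waiting time
`min_pause_s + Exp(1/ν)` with ν = `run_init_rate_per_s` (default 0.05 s⁻¹);
speed is drawn from 𝒩(μ_v, σ_v) truncated > 0 and run length from
𝒩(μ_L, σ_L) truncated above `runlen_trunc_um`. Direction is anterograde with
probability *p* (default 0.5). Runs end early at a hypha end or the end of
the movie and are then flagged `clipped`. The 1.5-s refractory minimum pause
is a deliberate realism choice: with bare exponential waits, a punctum can
chain two same-direction runs across a sub-frame pause, and no pause rule
operating on 0.3-s samples can separate them — the chained pair reads as one
slower run and biases chord speeds down by ~10%. Distinct runs in real
kymographs are separated by visible pauses; the refractory interval encodes
that.

**Pairing.** A fraction `frac_paired` of 561 puncta carry an attached
488-channel punctum sharing the trajectory. While stationary the 488 centroid
is offset by `pair_offset_um` (default 0.15 μm, sub-resolution) along the
axis with a random fixed sign, modeling the polarized Woronin body on the
peroxisome surface; during runs the offset is zero, matching the observation
that the two signals overlap during movement.

**Rendering.** Each punctum becomes an integral-normalized 2-D Gaussian of
width `psf_sigma_um` (default 0.15 μm) whose total above-background signal is
`photon_scale × brightness` (defaults 6000 × U(0.8, 1.3) counts). A planar
background (level 100 counts, tilt 1 count/μm along x) is added, then Poisson
shot noise and Gaussian read noise (σ = 2 counts); noisy output is quantized
to uint16, noiseless output stays float32 so analytic identities (signal
conservation to < 0.5%, leakage recovery to < 1%) hold exactly. 3-D PSFs,
photobleaching, and camera misalignment are not modeled.

**Scene builders.** Single-frame germling fields with a known pairing
fraction (for co-occurrence recovery), septal crops with Woronin bodies on
both/one/neither side of a membrane-dye ridge, burst-tip scenes with a
disk-shaped cytoplasmic puddle of exactly known integrated signal, and flux
cells whose ground-truth line-crossing counts are set by construction. Scene
builders enforce ≥ 1.1–1.2 μm separation between distinct organelles
(including run landing points) so that ground truth is optically resolvable;
real fields contain unresolvable conjunctions, which is one reason passing
recovery tests on these scenes bounds algorithmic error but not biological
ambiguity.

## Segmentation and colocalization

`preprocess` applies the published recipe: Gaussian blur (σ = 1 px) followed
by rolling-ball background subtraction (radius 50 px). One implementation
detail matters on noisy data: a ball rolled directly under shot noise hugs
the lower noise envelope and leaves spiky positive residuals that cross the
15/20-count floors on blank regions. As in the ImageJ implementation, the
background is therefore estimated on a smoothed copy (σ = 2 px) and
subtracted from the blurred image. For per-frame use in tracking, where the
exact ball (≈ 1 s/frame) is too slow, a flat grayscale opening of the same
window ("tophat" mode) removes the same smooth background in milliseconds;
still images use the exact ball.

`yen_threshold` maximizes Yen's maximum-correlation criterion on a 256-bin
histogram of the preprocessed image; "dark" polarity means foreground =
pixels ≥ threshold. The effective segmentation threshold is
`max(Yen, channel floor)` with floors 15 (488) and 20 (561) counts — this
reproduces the published combination of automatic thresholding with fixed
ranges; a `fixed` mode using the floors alone is also exposed, since the
Methods can be read either way. Components are 8-connected; `min_area_px`
defaults to 4 px to suppress single-pixel noise. Intensities are measured on
the preprocessed image within the mask only.

Pearson and Manders coefficients are direct implementations of the standard
formulas over masked pixels. The co-occurrence rule takes the overlap
denominator to be the **smaller** punctum (the printed "> 50%" does not say
which), uses a strict inequality, and tests the opposite channel's mean over
the scored punctum against 1.1 × background, where background is the median
outside a 2-px dilation of that channel's mask — a robust local choice the
protocol leaves unspecified. Intensity ratios are measured on sum-Z
projections, co-occurrence on max-Z projections.

## Tracking and run detection

Per-frame detections are linked by gated optimal assignment
(`linear_sum_assignment`) on 2-D centroid distance with a
constant-velocity prediction per track and a gate of 1.5 μm/frame (≈ 5 μm/s,
above all observed speeds). A track may coast through up to 3 unmatched
frames, which carries identities through the transient merges that occur when
a moving punctum passes a stationary one. Tracks shorter than 3 frames are
discarded. Centroids are projected onto the traced axis for arclength
coordinates.

`detect_runs` finds maximal monotone segments: steps with instantaneous speed
≥ 0.2 μm/s carry the run's sign; sub-threshold steps are tolerated up to 2
consecutive frames ("no pauses" rule — the printed criterion names no
numbers, these are the package defaults and are configurable). Two
refinements remove known discretization biases:

1. **Boundary trimming.** Positional jitter occasionally exceeds the pause
   speed with the run's sign and extends a segment through stationary frames;
   boundaries are trimmed to steps at least half the segment's median
   moving-step speed.
2. **Ridge-fit endpoints.** The first and last samples of a segment sit on
   the stationary shoulders, not the moving ridge, adding up to one frame of
   dead time per end (a 10% speed underestimate for 3-s runs). A line is fit
   to the interior samples (with one round of outlier rejection) and the run
   endpoints are taken where it meets the shoulders — exactly how a manual
   kymograph trace is laid along the ridge. Speed remains the inverse chord
   slope |Δs|/Δt with these endpoints.

A run is emitted when |Δs| > 3 μm (strict). Comigration scoring admits runs
> 2 μm, as the two thresholds serve different published measurements. Known
residual bias: runs near the pause speed (≲ 0.3 μm/s) fragment and are
under-detected, so detected mean speeds sit 1–4% above the generator mean for
wide speed distributions; the same selection operates in manual scoring,
where near-stationary excursions do not read as directed runs.

`count_flux` counts sustained crossings of a line 10 μm from the tip: a sign
change of (s − line) with at least 2 consecutive frames strictly on each
side. The sustain rule is an invention that makes manual counting
automatable; it rejects jitter oscillations across the line by construction.

`aligned_profile` extracts 1-px line scans around a run in both kymographs,
sets the spatial origin at the 561 maximum per time point, and averages —
flat reference windows raise an alignment error.

## Spatial measurements

Tip line scans average a 20-px-wide perpendicular band along the trace
(bilinear interpolation at 1-px arclength steps), subtract the cell's own
background (median outside the dilated band mask), and bin at 0.5 μm —
sub-μm binning resolves the tip-proximal structure the line scans exist to
show. Averages across cells weight cells equally.

Septum crops are classified by segmenting 488 puncta within 1 μm of the
(centered, vertical) septal plane; side assignment uses the sign of the
centroid's offset, with an exactly-on-plane centroid counting toward the
tipward side. Septal intensity is the mean of a bilinearly sampled
0.5 × 1 μm rectangle at the septum minus a same-size rectangle displaced
1 μm away from the tip, divided by the wild-type mean.

Leakage is measured on sum-Z projections as
`corrected = Σ(puddle) − mean(background) × area`, which is exactly invariant
to any constant image offset; normalization divides by the wild-type group
mean, so the wild-type group normalizes to exactly 1. Puddle ROIs are inputs
(they were drawn by hand in the original protocol); background ROIs should be
adjacent to the puddle so the background tilt cancels.

Group summaries are descriptive only (n, mean, SD with ddof = 1, SEM);
significance testing is out of scope.

## Validation protocols and problem sizes

Because no raw imaging data are available, validation closes the loop on the
generator (`validation` module): set the generator to the published
parameters, re-measure blind, compare. Problem sizes were chosen for a few
hundred events per estimate at ~1 minute per protocol: run-statistics
recovery uses 30 noiseless 60-s movies with 3 puncta per 60-μm hypha
(≈ 200–250 detected runs; the low density of simultaneously motile puncta
matches the observation that only ~1 in 10 puncta makes long-distance runs);
co-occurrence recovery uses 9 noisy fields of 16–18 scored puncta;
flux recovery uses 30 noisy cells tuned to exactly one anterograde and one
retrograde crossing each; the motility-null control uses 12 noisy movies
(≈ 100 tracked puncta).

When run lengths are drawn truncated above the 3-μm detection criterion, the
generator's mean exceeds the untruncated Gaussian location parameter (4.67 vs
4.39 μm for the Woronin-body channel); recovered means are compared against
the truncated-distribution mean, which is what the generator actually
produces.

## Configuration and reproducibility

Every printed protocol constant lives in `QuantConfig` (YAML, frozen schema
version); `validate_config` reports any deviation from the `reference`
preset. All stochastic operations take explicit integer seeds and are
bit-reproducible; `run_pipeline` writes a provenance log (config hash, seed,
package version, per-item status) and produces byte-identical outputs on
re-runs.

## Limitations

Motion is 1-D along the axis; lateral dynamics, 3-D PSFs, photobleaching and
chromatic shift are not modeled. The tracker is a gated nearest-neighbor
linker: it survives brief merges but will break identity in dense fields or
during prolonged organelle contact, and the scene builders deliberately avoid
such configurations when ground-truth counts must be exact. Run detection
under-samples the slowest runs (near the pause speed). Passing recovery tests
therefore demonstrates estimator correctness under the modeled imaging
physics, not robustness to every pathology of real data.
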