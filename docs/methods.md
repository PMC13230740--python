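# Methods

This note documents the models, parameter choices, and numerical
decisions behind `fishflow`, and what the synthetic benchmarks do and do
not establish about real data.

## The synthetic generator defines the study conditions

All quantitative guarantees are measured on data from `simkit`, which
emulates the statistical structure of a sequential smFISH experiment
rather than its optics:

- **Geometry.** Nuclei are non-overlapping disks placed by dart throwing
  (radius ~1.2 µm at the default 100 nm/px desk scale, jittered ±15%);
  cell territories are the Voronoi regions of nucleus centers. Spots are
  uniform within their cell's territory, excluding a 2σ border margin so
  no PSF is edge-truncated, with z in the central stack range.
- **Counts.** Master spot counts per cell and gene are Poisson with the
  configured per-cell-type mean (default 20/cell for the HeLa-like
  two-gene design; a 6-gene, 5-type marker panel with ~30 RNAs/cell for
  the typing benchmark).
- **Per-round effects.** Each round re-detects every master spot of its
  scheduled gene independently with probability `redetect_prob` (default
  0.9, matching the ~90% cross-round colocalization a stable platform
  shows); coordinates get the round's global drift (uniform up to ±5 px
  per axis) plus Gaussian localization jitter (0.1 px); amplitudes are
  lognormal (median 150, σ=0.2) scaled by `intensity_decay_per_round`
  (default 0.98 — the paper-scale decay is not published, so this is a
  free parameter chosen to give a visible but mild trend) and by the
  amplification factor on amplified rounds. Optional stripping residuals
  re-render a previous round's spots at 20% amplitude to let tests probe
  false-positive behavior.
- **Rendering.** Spots are 3D Gaussians (σ_lat 1.4 px, σ_ax 1.5 px, peak
  = amplitude) on a constant background (100) with additive Gaussian
  read noise (SD 10) — no Poisson shot noise. The configured spot SNR is
  therefore amplitude/noise_sd (median 15, 5th percentile ≈ 10). DAPI
  nuclei are textured disks blurred per plane with
  σ = defocus_rate·|z − focus_plane|, focus planes drawn per nucleus.

What passing tests show: the pipeline's algorithms are correct and
calibrated under Gaussian noise, translation-only drift, isolated PSFs
and flat background. What they do not show: robustness to
autofluorescent tissue background, optical aberrations, chromatic
shifts, dense spot clusters, or segmentation errors from real nuclei —
all outside the generator's model.

## Detection

Detection runs in 3D on the negated Laplacian-of-Gaussian response at
the PSF scale (`truncate=8` in the Gaussian derivative removes the DC
offset a truncated kernel otherwise leaves, ~1e-4 of the background).
Candidate maxima are non-maximum-suppressed over a *spherical*
neighborhood of radius `min_separation_px` (default 3 px ≈ 2σ): a cubic
window suppresses along diagonals out to √3 times farther and measurably
costs recall at realistic densities. Subpixel refinement is a 3-point
parabolic fit per axis (clamped to ±0.5 px); Gaussian fitting would be
more accurate but is unnecessary at the ≤0.3 px RMSE target.

**Automatic threshold.** The count of candidate maxima is evaluated on a
60-point log-spaced threshold grid spanning 3 decades below the maximum
response. Genuine spots produce a *plateau* — a stretch of thresholds
where the count is constant because all noise maxima lie below and all
spots above. The rule returns the geometric midpoint of the widest
plateau spanning ≥1.5× in threshold, holding ≥2 and ≤10% of all
candidates (the fraction cap rejects the degenerate full-count plateau a
pure-noise response produces at the grid bottom). We evaluated the
common elbow-of-the-chord reading of the same curve and found it lands
in the noise tail (halving precision) or above the weakest spots,
depending on the grid; the plateau reading is the robust form of the
same idea. When no plateau qualifies, the fallback is the (1 − 2·10⁻⁶)
quantile of the response — high enough that pure noise yields at most a
few detections per megavoxel — and the result is flagged.

**Metrics.** Background statistics use the annulus 3σ–5σ (inner ≥ the
2σ signal radius) on the spot's central z-plane — measuring on one plane
matches the diffraction-limited assumption and avoids axial truncation.
The SD is the population SD (ddof=0); `snr = intensity/background_sd`
exactly where defined, with a flagged NaN sentinel on perfectly flat
backgrounds. The annulus geometry is a package definition (no community
standard exists) and is recorded in output metadata.

## Registration

Drift is modeled as pure 2D translation; rotation and scale are out of
model and show up as a degraded correlation peak ratio, which is
reported per round as a confidence score. Estimation uses phase
cross-correlation with subpixel refinement by local upsampling (default
upsample 20, i.e. 0.05 px resolution — the choice is reported in
outputs). The sign convention is fixed throughout: the estimate is
**added** to moving-round coordinates to land in the reference frame.
Spots mode rasterizes tables into binary disk maps (radius 2 px);
image mode correlates maximum-intensity projections. Rounds with <3
spots fall back to image mode or report (0,0) flagged low-confidence.
Axial drift is assumed handled by microscope autofocus.

## Colocalization

Matching is a rectangular assignment problem on 2D Euclidean distances
(z is ignored — drift correction is lateral), solved exactly; pairs
beyond `cost_cap_factor`×threshold are forbidden before solving and a
pair counts as colocalized when its distance is strictly below the
threshold. The percentage denominator is the query round's spot count
(a reference-round denominator is available as an option). Default
thresholds: 0.5 µm for long alternating-gene series, 0.2 µm for
amplified short series; both are configuration, not constants.

The cap radius is a substantive modeling choice, not an efficiency
detail, and two numerical findings drove the default. First, the
uncapped assignment (minimizing the plain distance sum over all pairs)
systematically displaces ~2–3% of true sub-threshold pairs at any
density: far leftover pairs trade against near pairs in the global sum.
Second, intermediate caps (e.g. 4× the threshold) reintroduce a milder
form of the same bias whenever chance pairs within the cap are not rare
(≳0.3 per spot): the solver maximizes the number of sub-cap pairs, and
super-threshold chance candidates displace true sub-threshold pairs,
which showed up as an all-rounds ~1.5% deficit at realistic clustered
densities. The default is therefore `cost_cap_factor = 1`: the
assignment becomes the maximum-cardinality, minimum-cost matching at
the colocalization radius — exactly the estimator the re-detection
percentage is defined by — and the calibration benchmark lands the
per-round percentages on the generator's re-detection probability
(|z| ≤ 1.5 across seeds, against a 99% bound of 2.576). Wider caps
remain available for the threshold-strictly-after-assignment variant;
monotonicity of the percentage in the threshold is guaranteed only with
the cap held fixed.

## Focus scoring

The Helmli–Scherer mean-ratio contrast R = max(I/μ, μ/I) uses a local
mean over a 7 px window (no published value exists; 7 px spans the
nuclear texture grain at desk scale and is configurable and reported).
R = 1 where I = μ = 0; where exactly one is 0 the ratio is capped at
10⁶ and flagged. The measure is ≥1, equals 1 on constant images, is
exactly scale-invariant, and strictly decreases under blurring on
noise-free texture — these are tested properties. Scoring averages the
contrast over the nucleus *bounding box* (a mask-restricted variant is
available); ties in the argmax resolve to the lowest plane. The
composite image fills background from the plane at the median of the
per-nucleus best planes, median rounded to the nearest integer with
half-values toward the lower plane. The bundled Otsu-based segmenter is
a test/demo fallback; externally produced label masks are accepted
everywhere and preferred.

## Cell typing

Spot-to-cell assignment is a deliberate baseline for point-cloud cell
segmentation: each spot goes to the nucleus (interior distance 0)
nearest in 2D, if within `max_dist` (default 5 µm); exact ties resolve
to the lower label via strict-inequality updates over per-label distance
transforms. Typing computes cosine distances to per-type median
centroids and accepts a call only under both gates — distance strictly
below 0.8 (the boundary case at exactly 0.8 is rejected; the inclusive
reading is equally defensible but strictness is auditable) and total RNA
strictly greater than 10. Unclassified cells are retained with reason
codes (`distance_gate`, `count_gate`) for auditability. The benchmark
panel mirrors a mouse-lung marker set (Chil3/Rtkn2/Lamp3/Pecam1/Ptprb/
Pdgfra over five cell types, pairwise centroid cosine distance ≥ 0.89).

## Fluidics

The run specification is YAML with a fixed schema: `n_rounds`, `buffers`
(kind `syringe` with a port, or `plate` with a well address — `{round}`
substitutes the round number, `{round_well}` walks the 96-well plate
row-major for runs longer than one row), and ordered `steps` (`flush`
needs a buffer, a positive rate, and exactly one of volume or duration;
`incubate`/`pause` advance the clock; `image` arms the acquisition
trigger). Steps carry `rounds: all` or an explicit list; validation
resolves every templated well for every applicable round and names the
offending step in errors.

Execution is in simulated time — the clock advances by computed
durations, nothing sleeps — so a 20-round run executes in milliseconds
and logs are byte-reproducible given a seed. Wells enforce the 2.0 mL
capacity: over-aspiration emits an error event and halts the run with
the log intact. Dispensed volumes are tracked as rate×duration, exactly
consistent with the pump events in the log. The flow sensor samples
every 1 s of pumping (artifact-defined; no published rate exists) with
2% multiplicative noise; the anomaly detector reports maximal runs of
samples deviating more than a tolerance fraction (default 20%) that span
at least a minimum duration (default 5 s), merging sub-sample gaps.
Hardware is an interface with only simulated backends; serial drivers,
GUIs, and real-time waiting (a rate multiplier exists, default instant)
are out of scope. Triggers implement the two microscope handshakes that
don't require controlling the microscope: a shared sync file (content
flip 1→0, or existence/deletion) and a TTL pulse pair, each with a mock
acquirer for closed-loop tests.

## Benchmark problem sizes

Chosen as the smallest sizes at which the measured statistics are
stable: detection pools three ~45 µm fields (~350 spots, median SNR 15);
colocalization calibration uses 20 rounds of ~1000 spots on a 1024² px
field with ±5 px drift; focus recovery uses 200 nuclei across four
fields; typing uses 60 cells of five types. Residual detection misses at
these conditions are sub-resolution pairs (<2σ apart) — a physical limit
of single-scale LoG detection, not a parameter artifact.

## Known limitations

- Translation-only registration; no non-rigid or chromatic correction.
- Cross-gene alignment reuses the phase-correlation machinery on spot
  maps of *different* genes, which share no true structure; the estimate
  is usable only as a rough control alignment and its peak ratio should
  be treated as the warning it is.
- The nearest-nucleus assignment ignores cell morphology; expect
  boundary misassignment in confluent tissue.
- The generator's noise model (additive Gaussian, flat background) is a
  simplification; a shot-noise switch is a noted extension point.
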