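# Methods

This note documents the measurement models implemented in `mitoquant`,
the synthetic scenes used to validate them, the numerical choices made
where the procedure was genuinely open, and what the validation does and
does not establish.

## Image model and conventions

All measurements operate on `CalibratedStack` objects: non-negative
intensity arrays with named channels, canonical `TCZYX` axis order, and
a physical calibration (μm per pixel in-plane, μm per z-step, s per
frame). Coordinates are 0-based `(y, x)` with pixel centres at integer
positions; every physical distance is an index difference times the
calibration. Morphological offsets, ring ROIs and point-to-surface
distances are computed on the exact Euclidean distance transform, so
they are isotropic in physical units (for 3D, axes are scaled by the
z-aspect first). Measurement ROIs that an experimenter would draw by
hand — extracellular background boxes, buffer rectangles, boundary-
crossing lines, the cell outline — are *inputs* to the pipelines; for
synthetic scenes they come from the scene's truth record.

## Segmentation and profiling primitives

- **Gaussian denoising** (σ in pixels, default 2 for chromatin, 1 for
  centromere spots, 5 for FRET channels) precedes every threshold.
- **Otsu with dark background**: threshold maximizing between-class
  variance of the 256-bin histogram; foreground is strictly above. This
  is the chromatin/droplet/nucleus segmenter throughout.
- **Phansalkar local threshold** for low-contrast filaments: pixel
  foreground iff `v > m·(1 + p·e^{−q·m} + k·(s/r − 1))` with (k, r, p, q)
  = (0.25, 0.5, 2, 10), mean m and population sd s over a disk
  neighbourhood clipped to the image, after min–max rescaling to [0, 1].
  The neighbourhood statistics use direct disk convolution up to radius
  16 (bit-exact against per-pixel evaluation) and FFT convolution above.
- **Prominence maxima** (spot detection): a union-find watershed-by-
  descending-intensity. A peak's prominence is its height above the
  highest saddle connecting it to any higher region; the surviving
  global maximum is measured against the image minimum, so an isolated
  peak lower than the prominence cut yields no spot. Equal-valued
  plateaus are pooled and reported once at their centroid; when two
  equal-height peaks merge, the peak earlier in raster order survives
  (a deterministic convention — the flood-fill definition does not
  decide this case). Maxima whose peak plateau touches the border are
  dropped when edge exclusion is on.
- **Rolling-ball background**: grayscale opening with a flat disk
  footprint, subtracted and clipped at 0. For radii above 16 px the
  opening runs on a block-minimum coarse grid and is bilinearly
  upsampled (clipped under the image); backgrounds at these radii are
  smooth by assumption, and the result only preconditions a threshold.
- **Skeleton length**: topology-preserving thinning; length is the sum
  over 8-adjacent skeleton pixel pairs of the step length (1 or √2 px)
  times the pixel size.
- **Profiles**: line profiles sample every 1 px with bilinear
  interpolation, averaging `width_px` parallel samples symmetric about
  the segment; distances are in μm from the start. Radial profiles
  integrate per rounded-radius bin within a cone Θ about an orientation
  (Θ = 360° full circle, 180° half-plane).

## Metric pipelines

**Congression.** Poles are the two highest separated prominence maxima
of the σ = 2 denoised tubulin channel. A band profile (default
22.5 × 7.06 μm; 12.04 μm preset available) is extracted along the
pole-to-pole axis centred between the poles; after per-sample
subtraction of the extracellular background (negatives clipped to 0) the
central 5 μm window sum is divided by the whole-profile sum. The
fraction is invariant to intensity scaling and to the subtracted offset.

**Chromatin density.** Mean DNA intensity within the σ = 2 + Otsu mask,
optionally minus an extracellular background, divided by a reference
(control) mean. The background option is not part of the classical
recipe but is required for density *ratios* between conditions to
reflect chromatin signal rather than camera offset; with it, generator
scene pairs sharing a layout recover their amplitude ratio to < 0.03.

**Radial displacement (monopolar).** The cumulative radial signal around
the pole (tubulin centre of mass) is built from exact per-pixel radii
rather than the binned radial profile: integer binning carries a
half-bin bias that already exceeds 5 % at an edge radius of 30 px. The
edge radius R is where the cumulative signal reaches 99 %; the statistic
is inner (≤ 0.3R) over outer signal. The background is subtracted
without clipping so that zero-mean noise cancels in the sums.

**Kinetochore displacement.** Spots from prominence maxima of the σ = 1
denoised centromere channel (prominence 100 for immunofluorescence
presets, 2000 for live imaging); chromatin mask as above; a spot is
displaced iff its signed surface distance exceeds +0.5 μm (boundary
values count as inside). Per-spot distances are returned so individual
calls can be audited.

**Partitioning.** All four variants report
`(inside − bg)/(outside − bg)`. The line variant locates the boundary at
the 50 %-of-max crossing of the DNA reference profile and takes the side
with the higher DNA mean as "inside"; offsets extending past the
sampled line are clamped to the profile end and flagged rather than
refused (the 1.3 μm tubulin preset with 1 μm offsets requires this).
The circle variant searches the distance transform for the cytoplasmic
disc centre farthest from chromatin, subject to clearance, image bounds
and the cell outline — without a cell mask the optimum would be
extracellular. "~25 % of droplet area" and "~5 μm diameter" are
implemented as exact values, configurable.

**Ki-67 confinement.** Profiles are resampled to a common 0.05 μm grid
after alignment either at the first local maximum from the cytoplasmic
end (requiring it to stand above the baseline) or at the DNA half-max
edge for diffuse chromatin. The confinement score evaluates the
condition curve at the control-defined surface (argmax) and interior
(chromatid-centre offset) positions; it is invariant to scaling of the
condition curve.

**FRAP.** Double normalization (ROI over whole-region, rescaled by the
pre-bleach ratio) is exactly invariant to a common per-frame
multiplicative factor and to an additive background shared by all
traces — the two corrections it exists to perform. Recovery is
summarized by a bounded trust-region fit of
`N(t) = F₀ + m (1−F₀)(1 − 2^{−t/τ})`; the base-2 parameterization makes
τ directly the half-recovery time. Initialization: F₀ from the first
post-bleach samples, the plateau from the last fifth, τ from the first
half-level crossing.

**FRET.** Nuclear mask from the σ = 5 denoised YFP channel (Otsu-dark);
per-channel backgrounds from a 1 μm² extracellular square; ratio of the
σ = 5 denoised, background-corrected FRET and CFP channels inside the
mask. Pixels with non-positive corrected CFP are excluded and counted;
the display map is clipped to [0, 1.4].

**Filaments.** Fluorescence route: σ = 2 denoise → rolling-ball →
Phansalkar (radius 100) → skeletonize; skeleton pixels are assigned to
chromatin or buffer by region membership (chromatin ROIs: σ = 2 + Otsu +
particles ≥ 5 px², the particle unit being the classical unitless
default). Both the raw length ratio and the per-unit-area density ratio
are reported, since a raw ratio conflates abundance with region size.
Tomography route: polyline segments are clipped against the voxel mask
by uniform subsampling at 0.25× the voxel pitch with midpoint
membership (sub-0.5 % against a 1 nm dense-sampling oracle), restricted
to the sharp central z-window; lengths are normalized by each domain's
voxel volume in that window.

**Statistics.** Two-tailed Mann–Whitney U: exact null distribution for
tie-free samples up to n = 25 per group, tie-corrected normal
approximation otherwise; p-values below 1e-15 are clamped and flagged
as upper bounds. Group normalization divides by the reference-group
mean. No multiple-testing correction is applied.

## The synthetic scenes

The generator emulates the *image statistics* these pipelines consume,
not the underlying biology or optics. Scenes are built from explicit
continuous models — Gaussian chromatin blobs or hard-edged discs,
Gaussian point sources (default σ = 2 px, standing in for a
diffraction-limited PSF), uniform droplets, line segments, Gaussian
surface shells — rendered on the pixel grid, optionally blurred by a
small Gaussian PSF, then subjected to Poisson shot noise on the
expectation plus additive Gaussian read noise (default σ = 20 intensity
units ≈ 2 % of a typical 1000-count dynamic range; the cameras' true
noise is not characterized, so this is a generator convention). The
default calibration is 0.1 μm/px with 300² px cell fields; amplitudes
(DNA 2000, tubulin 4000, background 100) put shot noise at realistic
few-percent levels.

Key constructions:

- *Bipolar cells*: equatorial and pole-proximal blob clusters whose
  amplitudes are solved linearly so the noiseless band-integrated
  central fraction equals the requested value exactly on the pixel
  grid. A `layout_seed` decouples blob geometry from the noise stream so
  condition pairs (e.g. density ratios) share geometry.
- *Monopolar cells*: inner blob + annulus mixed by bisection to the
  requested pole-proximal/distal ratio of the noiseless scene (the
  achieved value is recorded as truth).
- *Kinetochore and partition scenes* use a hard-edged chromatin disc so
  region membership is exact; spots and foci keep a minimum separation
  so they remain resolvable as distinct prominence maxima — clustered
  real kinetochores would partially merge, which is why live-cell
  counting tolerates ±1 spot.
- *Droplet fields*: jittered-grid placement (non-overlapping by
  construction) with a droplet-free buffer strip; probe intensity inside
  is `P ×` the buffer level above background.
- *Filament fields*: segment centres sampled on a margin-extended domain
  so in-frame line density is uniform; truth lengths come from analytic
  segment–disc/rectangle clipping. The tomogram fixture is a sphere in a
  5 nm-voxel volume with polylines clipped analytically against slab and
  sphere.
- *FRAP series*: the bleached spot follows
  `bg + β^t·pre·[(1−d) + d·m·(1−2^{−t/τ})]`; surrounding chromatin stays
  at the (β-bleached) pre-level, i.e. recovery is drawn from the large
  pool outside the measured region. The measured whole-region trace is
  therefore self-depleted by the ROI's own deficit (~2 % of region
  area), a bias well inside the stated recovery tolerances.
- *FRET triplets* set FRET = r × CFP above channel backgrounds inside
  the nucleus, so the true in-mask ratio map is exactly r.

What passing these tests shows: the pipelines compute their defining
quantities correctly, are invariant where they claim to be, and recover
known parameters at realistic noise. What it does not show: robustness
to optical artefacts absent from the model (spectral bleed-through, full
3D PSFs, uneven illumination beyond slow ramps, motion), to touching or
clustered objects beyond the separations generated, or to segmentation
regimes where Otsu's bimodality assumption fails.

## Validation problem sizes

The shipped validation uses 20 images per segmentation-oracle
comparison (≤ 64² px), 20 congression scenes across central fractions
0.1–0.9, three seeds per partition variant and ratio, a 3 × 3 FRAP grid
(m ∈ {0.3, 0.6, 0.9}, τ ∈ {0.5, 2, 8} s) with 10–20 seeds per cell and
per-τ frame intervals of τ/8 over 80 post-bleach frames, six uniform
filament fields of 400 segments, and 100 random Mann–Whitney datasets
with n ≤ 8 per group. These sizes give medians stable enough for the
stated bands while keeping the whole validation in the minutes range on
a single CPU.

## Known limitations

- The prominence-maxima tie rule (earlier raster-order peak survives)
  and Fiji's "strict" edge semantics may differ in corner cases; the
  convention here is documented and deterministic, not a claim of
  bit-compatibility with Fiji.
- The coarse-grid rolling-ball path is an approximation at large radii;
  thin structures survive it, but residual background near frame edges
  can be a few per cent of a strong ramp.
- `partition_circle` requires a cell outline; automatic outline
  estimation from a DIC channel is out of scope.
- FRAP fitting assumes a single-exponential (base-2) recovery; reaction–
  diffusion kinetics and bleach-spot profile corrections are not
  modelled.
- The generator's droplet and filament placements avoid overlaps and
  near-contacts; measurement behaviour on merging objects is untested.
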