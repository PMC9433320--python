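# mitoquant

Quantitative image analysis of mitotic chromatin for fluorescence
microscopy: chromatin compaction and congression, microtubule exclusion,
macromolecular partitioning, Ki-67 surface confinement, and chromatin
dynamics (FRAP, FRET) — together with a synthetic microscopy-scene
generator that provides exact ground truth for every metric.

## Who this is for

Mitotic chromosomes behave as a membraneless compartment: they exclude
large cytoplasmic macromolecules (including soluble tubulin), confine
Ki-67 to their surface, and their material state changes with condensin
activity and histone acetylation. Quantifying these phenomena from
calibrated multi-channel stacks requires a consistent set of image
measurements — global and local thresholds, prominence-based spot
detection, physical-unit morphology, line and radial profiles, skeleton
lengths — composed into per-assay pipelines. This package implements
those pipelines as a tested, scriptable library for cell biologists and
image analysts working on mitotic chromosome organization.

## The measurements

With `I(x)` a background-corrected channel and `M` the chromatin mask
(Gaussian blur σ = 2 px, Otsu threshold with dark background):

- **Congression fraction** — along the pole-to-pole axis (poles from the
  highest tubulin prominence maxima), a band profile of 22.5 μm × 7.06 μm
  is integrated; the fraction is `Σ I` over the central 5 μm window
  divided by `Σ I` over the whole band.
- **Chromatin density** — mean DNA intensity within `M`, normalized to a
  control mean; also a line-peak variant (mean in a 200 nm window around
  the profile peak).
- **Radial displacement** (monopolar spindles) — with R the radius
  containing 99 % of the cumulative radial signal around the pole, the
  ratio `Σ I(r ≤ 0.3R) / Σ I(0.3R < r ≤ R)`.
- **Kinetochore displacement** — fraction of centromere spots
  (prominence maxima) whose signed Euclidean distance to the surface of
  `M` exceeds +0.5 μm.
- **Partition coefficient** `P = (I_in − bg) / (I_out − bg)` in four
  geometries: line profiles across the chromatin boundary (values 1 μm
  inside / outside), shrunk mask vs. extended ring (0.2 / 1.5 / 0.5 μm),
  chromatin regions vs. a 5 μm cytoplasmic disc (≥ 1 μm clearance), and
  droplet interiors (concentric disc, 25 % of droplet area) vs. buffer.
- **Ki-67 surface confinement** — line profiles across the chromatid
  surface aligned at the first fluorescence peak (or at the DNA 50 %-of-
  max edge), scored as surface/interior intensity ratio at
  control-defined positions.
- **FRAP** — double normalization
  `N(t) = [(I_roi − bg)/(I_tot − bg)] · [(I_tot,pre − bg)/(I_roi,pre − bg)]`
  followed by a bounded fit of `N(t) = F₀ + m (1−F₀)(1 − 2^(−t/τ))`
  for mobile fraction m and half-time τ.
- **FRET** — background-corrected, σ = 5 denoised FRET/CFP emission
  ratio within the YFP-derived nuclear mask.
- **Microtubule density** — fluorescence route: denoise → rolling-ball
  background removal → Phansalkar local threshold → skeletonize; skeleton
  length inside chromatin regions vs. buffer. Tomography route: annotated
  polylines clipped against a voxelized chromatin domain; length per unit
  volume per domain.
- **Condensation CV** (σ/μ of a field), background-corrected channel
  ratios, γH2A.X focus counts, apoptotic index (markers > 1.2 × control
  median), and a two-tailed Mann–Whitney U utility for group comparison.

Because raw microscopy for the published experiments is not
redistributed, the package ships a first-class generator
(`mitoquant.synthdata`) that renders bipolar/monopolar cells, droplet and
filament fields, FRAP series, FRET triplets and tomogram fixtures from an
explicit continuous model, with Poisson + Gaussian noise and a
`SceneTruth` record of every true parameter. All validation is parameter
recovery against that truth; the segmentation primitives are additionally
held to exact agreement with brute-force oracles.

## Worked example

```python
from mitoquant import synthdata, partition
from mitoquant.imgio import BinaryMask
from mitoquant.segcore import gaussian_denoise, otsu_dark_mask, regions_from_mask

# a field of chromatin droplets, probe partitioned at P = 5
stack, truth = synthdata.make_droplet_field(partition_ratio=5.0, seed=1)

mask = otsu_dark_mask(gaussian_denoise(stack.channel("dna"), 2.0))
regions = regions_from_mask(BinaryMask(mask.values, stack.calibration), min_size_px=5)
m = partition.partition_droplet(
    stack.channel("probe"), regions,
    buffer_rect=tuple(truth.true_params["buffer_rect"]),
    background=truth.true_params["background"],
)
print(f"measured coefficient : {m.coefficient:.3f}")
print(f"droplets analysed    : {m.geometry['n_droplets']}")
print(f"inside / buffer mean : {m.inside_mean:.1f} / {m.outside_mean:.1f}")
```

prints

```
measured coefficient : 5.004
droplets analysed    : 20
inside / buffer mean : 3080.9 / 679.7
```

i.e. the probe is measured 5.0× enriched in the droplets over buffer —
recovering the generator's true partition ratio from the noisy rendered
field. The same pattern (generate → segment → measure → compare with
`SceneTruth`) applies to every metric; for instance a bipolar scene built
with 60 % of its DNA in the central 5 μm window yields
`congression_fraction = 0.601`.

A CLI wraps the same pipelines (`mitoquant simulate|congression|density|
displacement|kinetochores|partition|ki67|frap|fret|filaments|tomogram|
classify|cv`), each writing a metrics CSV plus a JSON log of all
parameters, seeds and input hashes.

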