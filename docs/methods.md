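# Methods

This note records the model behind `autorif`, the parameters that matter,
the numerical conventions, and the design choices made where the problem
left the design genuinely open.

## Processing model

A field of view is a pair of z-stacks: a nuclear counterstain (DAPI) and
a focus-marker channel. The pipeline assumes foci are compact intensity
peaks riding on a smoother background confined to nuclei, and that the
stack is sampled finely enough axially (≈0.5 µm) that a focus spans at
least one slice.

1. **Nucleus segmentation** operates on the MIP of the nuclear stack:
   projecting first makes the Otsu threshold robust to slices that
   contain only noise. The single 2D mask is applied to every slice; no
   3D nuclear segmentation is attempted. Touching nuclei are *not* split
   (no watershed) — closely bounding nuclei are a known failure mode and
   should be excluded upstream by screening (`autorif contact-sheet`
   renders a grid of nuclear MIPs for exactly this purpose; `dump_stages`
   writes a per-stage TIFF audit trail of the filter chain).
2. **Focus detection** converts each per-nucleus stack to per-slice
   binary masks via smoothing → Laplacian(+1500) → Crimmins →
   stack-global Kapur threshold → 3×3 closing. After the Laplacian, foci
   are troughs; the chain negates the filtered stack before histogramming
   so "above threshold" uniformly means "focus".
3. **Measurement** uses binary image moments only (no intensity
   weighting); intensities are reported from the raw focus channel within
   each region.
4. **3D linking** takes the transitive closure of the centre-containment
   predicate over adjacent slices. Branching merges (one focus under two
   unlinked foci above) are merged and flagged `junction` for audit.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pixel_scale_um` | 0.07 | lateral µm per pixel (100× objective) |
| `z_step_um` | 0.5 | axial slice spacing in µm |
| `min_nucleus_px` | 1000 | nuclei below this area are excluded (strict `<`) |
| `pre_iterations` | 3 | 3×3 mean smoothing passes before the Laplacian |
| `post_iterations` | 3 | Crimmins iterations after the Laplacian |
| `laplacian_sensitivity` | `low` | kernel choice, see below |
| `normalisation_value` | 1500 | offset added after the Laplacian |
| `histogram_scope` | `stack` | pool the threshold histogram per stack or per folder |
| `min_focus_px` | 4 | drop binary components smaller than this |
| `min_separation_sd` | 10 | class-separation guard, see below |

Smoothing iterations are experiment-specific and should be set with the
batch-optimisation scan (`optimise_batch` / `autorif optimise`), which
scores a seeded ~10% sample of nuclei per grid point by salt-and-pepper
count (isolated 1-px components — the signature of under-filtering) and
by focus-count drift against the lightest setting, then recommends the
lightest acceptable setting that still detects foci.

### Laplacian sensitivity

`low` and `medium` are the classic 4- and 8-neighbour Laplacians, matched
to diffraction-scale foci (≲1 µm). `high` is a Laplacian-of-Gaussian at
σ = 3 px. The LoG is gain-normalised so a broad bright plateau of height
h responds at −0.6 h, which keeps every response within the +1500 offset
(the clamp at zero rarely engages) and keeps the histogram well
conditioned. The motivation is response equalisation: curvature scales as
peak/σ², so with a 3×3 kernel a 1.5 µm-FWHM focus responds ~16× weaker
than a 0.3 µm focus of the same peak, and no single global threshold can
hold both. A σ = 3 px LoG responds within a ~2× band across that size
range. The σ of the `high` kernel is a fixed documented convention, not
auto-scaled from calibration.

This is a single-scale detector: one sensitivity per run. Experiments
whose foci span the full 0.3–1.5 µm range *within one nucleus* will size
the class far from the chosen scale poorly (typically: broad foci
fragmented or shrunk under `low`; small foci inflated under `high`).
Choosing sensitivity per experiment during batch optimisation — sensible
because focus-size distributions shift with time after irradiation — is
the supported workflow; multi-scale detection is out of scope.

### Boundary margin

Masking zeroes all signal outside the nucleus, so the mask edge is a
large intensity step that rings under smoothing and the Laplacian. A band
of width `pre_iterations + kernel_radius + 1` px, eroded from the mask,
is excluded from both the threshold histogram and the binary output.
Without it the ring dominates the histogram tail and the threshold
separates ring-vs-noise instead of foci-vs-noise. Consequence: foci whose
centres lie within ~0.5–1 µm of the nuclear boundary are not detectable.

### Class-separation guard

A maximum-entropy threshold always splits a histogram, even a pure-noise
one — the same pathology that motivates stack-global (vs per-slice)
histograms reappears at stack scope when a stack contains no foci at all.
Detection therefore requires the split to expose a *distinct* class:
(mean_fg − mean_bg)/max(sd_bg, 1 gray level) ≥ `min_separation_sd`,
else the scope reports zero foci. The 1-level floor covers the
broad-kernel regime where noise compresses below the bin width. The
default of 10 sits in a wide empirical gap: noise-only stacks measure ≲6,
the weakest genuine focus class ≳18. Histograms bin one integer level per
bin over the observed range; float filter outputs are binned by rounding
half away from zero.

## Numerical conventions

- Coordinates are 0-based; (u, v) = (column x, row y), so x̄ = m₁₀/m₀₀
  matches u as x. µm conversions happen only in 3D geometry and reports.
- Convolutions use reflective borders; Crimmins uses edge replication.
  Crimmins sub-steps update synchronously (vectorised); the four
  directional passes run sequentially, so exact symmetry of symmetric
  inputs holds only to within the ±1 step size.
- Threshold tie-breaks: the lowest maximising level; candidate thresholds
  are restricted to occupied levels (raising t across empty bins changes
  nothing), which makes the tie-break exact under floating point.
- θ uses the two-argument arctangent, θ = ½·atan2(2μ₁₁, μ₂₀−μ₀₂), with
  θ = 0 when μ₁₁ = 0 and μ₂₀ = μ₀₂. Eccentricity is reported as the
  eigenvalue ratio λ₁/λ₂ ≥ 1 (`ecc_ratio`; equals the squared axis
  ratio), with the plain axis ratio also emitted; degenerate regions
  (λ₂ = 0) report infinity and r_b = 0 without raising.
- The containment test rounds centroids half-up to a pixel and tests
  membership in the other focus's binary region (not its fitted ellipse).
- Volume is primarily the voxel sum Σ area·pixel_scale²·z_step; an
  ellipsoid-model volume (4/3·π·r_a·r_b·(z_extent·z_step/2), largest
  slice's radii) is emitted as a secondary column. Size categories use
  the equivalent-circle diameter of the largest member slice, mirroring
  the manual convention of sizing a focus on its most in-focus plane;
  the 0.5 and 1.0 µm boundaries belong to `medium`.
- The nuclear centre is the 2D mask centroid laterally and the midpoint
  of the acquired z-range axially (stacks are acquired about the central
  focal plane; no 3D nuclear model exists).
- Degenerate inputs: single-level histograms raise in the threshold
  selectors; at pipeline level they produce zero nuclei / zero foci with
  a logged warning rather than failure.

## Synthetic data

The generator emulates the target acquisition: 22-slice stacks, 14-bit,
0.07 µm/pixel, 0.5 µm z-step (smaller presets are used in fast tests).
Nuclei are filled ellipses, constant across z; foci are 3D Gaussians
(σ_xy from the size class, σ_z = 1 slice) clipped to their nucleus, on a
flat background of 400 counts with Poisson shot noise plus Gaussian read
noise (sd 20). The default peak intensity is 2000 counts for every size
class — deliberately conservative, since real large foci tend to be
brighter — giving SNR well above 5. Focus centres keep ≥3σ pairwise
separation and ≥3σ clearance from the nuclear boundary; ground-truth
"diameter" is the lateral FWHM (2.355·σ_xy) in µm, so size-category truth
aligns with the detector's equivalent-diameter convention.

What the generator does **not** emulate: a realistic optical PSF
(Gibson–Lanni), spectral bleed-through, photobleaching, intranuclear
background texture (heterochromatin), clustered high-LET track structure,
or touching nuclei. Passing tests therefore demonstrate the correctness
of the algorithmic chain under its stated assumptions, not performance on
arbitrary real material — on real data the batch-optimisation step and
visual screening of previews remain essential.

The recovery benchmark (`autorif.benchmark`) renders experiments per
size class (every focus at one FWHM of 0.3, 0.7 or 1.5 µm), emulating
time-point experiments whose characteristic focus size differs, and
analyses each with the sensitivity the per-experiment optimisation
selects (`low`, `low`, `high` respectively). Problem sizes — 512×512×22
voxel fields, one nucleus per field, two replicates of each (class, K)
condition with K ∈ {0, 5, 15, 40} — keep a full run to a few minutes on
one CPU while giving 24 nuclei and several hundred foci per run.

## Known limitations

- Single-scale detection per run (see above).
- No declumping of touching nuclei or merged foci; foci closer than
  roughly their detected radius merge (at the benchmark's 3σ separation
  floor this occasionally costs one count).
- The 2D nuclear mask ignores axial nuclear extent; the nuclear-centre z
  is a convention, so centre distances along z are approximate.
- Foci within the boundary margin of the nuclear edge are invisible.
- Folder-scope histogram pooling assumes all nuclei of a folder share
  illumination and staining; mixing conditions in one folder biases the
  common threshold.
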