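# autorif

Automated detection, sizing and 3D localisation of radiation-induced foci
(RIF) in two-channel fluorescence microscopy z-stacks.

DNA double-strand breaks recruit damage-response proteins (γ-H2AX, 53BP1)
into punctate nuclear foci that immunofluorescence renders as bright spots
on a noisy background. Counting them per nucleus — and, for mechanistic
questions, measuring their sizes, volumes and relative 3D positions — is
tedious and operator-dependent by eye. `autorif` is a batch pipeline for
this task: it takes folders of TIFF z-series (one folder per field of
view; a DAPI counterstain channel and a focus-marker channel), segments
nuclei, detects foci per nucleus in every slice, links them across slices
into 3D foci, and writes per-focus, per-nucleus and distance tables as
CSV. It is aimed at radiation-biology labs quantifying DSB induction and
repair kinetics, and ships a synthetic-stack generator with ground truth
so the whole chain is testable without microscope data.

## Method

**Nucleus segmentation.** The maximum-intensity projection (MIP) of the
DAPI stack is thresholded with Otsu's method — the threshold *t*
maximising the between-class variance σ²_B(t) = w₀w₁(μ₀−μ₁)² of the
gray-level histogram. 8-connected components become nuclei; components
smaller than 1000 px or touching the frame edge are excluded. Each
nucleus's bounding box crops the focus channel, and pixels outside the
nuclear mask are zeroed in every slice.

**Focus detection.** Each per-nucleus stack passes through a five-stage
chain: (1) iterated 3×3 mean pre-smoothing; (2) a Laplacian whose kernel
is chosen by a *sensitivity* setting (4-neighbour, 8-neighbour, or a
broad Laplacian-of-Gaussian for coarse foci), plus a normalisation offset
of 1500 so intensity peaks become non-negative troughs; (3) the Crimmins
geometric speckle filter; (4) a maximum-entropy (Kapur) threshold — the
level maximising H_background(t) + H_foreground(t) — computed from the
*global* histogram of the whole stack (optionally all nuclei of a
folder), so slices without foci are not split into "strong vs weak
noise"; (5) 3×3 morphological closing.

**2D descriptors.** Each binary focus region R is summarised by its image
moments m_pq = Σ_{(u,v)∈R} uᵖvᵠ: area m₀₀, centroid (m₁₀/m₀₀, m₀₁/m₀₀),
and second-order central moments μ₂₀, μ₀₂, μ₁₁ whose eigenvalues λ₁ ≥ λ₂
give the moment ellipse — orientation θ = ½·atan2(2μ₁₁, μ₂₀−μ₀₂), radii
r_a = 2√(λ₁/m₀₀), r_b = 2√(λ₂/m₀₀) and eccentricity ratio λ₁/λ₂.

**3D reconstruction.** Foci on adjacent slices merge when the rounded
centroid of either lies within the other's pixel region; a slice gap
always separates. Each 3D focus gets an area-weighted centroid,
voxel-sum volume, an equivalent-circle diameter from its largest slice,
and a size category (small < 0.5 µm ≤ medium ≤ 1.0 µm < large), plus
pairwise and focus-to-nuclear-centre distances in µm.

## Worked example

`python examples/detect_foci.py` renders a 22-slice 14-bit field
(0.07 µm/pixel, 0.5 µm z-step) with one nucleus and eight 0.7 µm-FWHM
foci, then detects and scores them:

```
detected 8 foci (ground truth: 8)
  focus 1: ( 5.48, 14.25,  2.39) um, d_eq=0.78 um (medium), volume=0.728 um^3, 4 slices
  focus 2: (20.78, 19.72,  2.80) um, d_eq=0.79 um (medium), volume=0.786 um^3, 4 slices
  ...
matched 8/8, 3D localisation RMSE 33 nm
```

All eight foci are recovered, each categorised *medium* (equivalent
diameter ≈ 0.78 µm against the rendered 0.7 µm FWHM), with sub-pixel 3D
localisation error.

Other examples: `moment_ellipse.py` (descriptor recovery on a rasterised
ellipse), `link_3d.py` (the centre-containment linking cases),
`run_experiment.py` (folder-of-TIFFs to CSV tables),
`optimise_settings.py` (batch optimisation of filter iterations).

## Command line

```sh
autorif synth         --output exp/ --fields 3 --foci-per-nucleus 5 --seed 1
autorif contact-sheet --input exp/ --output qc.png
autorif optimise      --input exp/ --output opt/ --grid-pre 0,1,3,5
autorif run           --input exp/ --output out/ --pre-iters 3 --sensitivity low
autorif score         --input exp/ --results out/
```

`run` writes `foci.csv`, `nuclei.csv`, `distances.csv`, a run log and the
resolved configuration next to the outputs.

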