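# Methods

This note documents the models, algorithms and numerical choices behind
`cfosmap`, and what its synthetic benchmarks do and do not demonstrate.

## Problem setting

Whole-brain activity mapping counts immediate-early-gene (c-Fos) labelled
nuclei in 3D light-sheet volumes, assigns them to brain regions of a
hierarchical atlas, and compares per-region counts between experimental
groups. Real datasets are dual-channel: a signal channel carrying the c-Fos
immunofluorescence and an autofluorescence channel in which broadband
structures (notably blood vessels) are visible in both channels. Voxels are
strongly anisotropic; the package default is (dz, dy, dx) = (3.5, 1, 1) µm,
and all physical computations (distances, volumes, separations) are carried
out in micrometres using the per-axis voxel size.

## Segmentation network

The segmenter is a U-shaped hybrid of a convolutional front-end and a 3D
shifted-window transformer, producing per-voxel two-class probabilities.

* **Dilated convolution front-end.** Three parallel 3×3×3 convolutions at
  dilation rates 1/2/3, concatenated and fused by a 1×1×1 convolution, give
  multi-scale local context before tokenisation. Branch width and rates are
  configurable (`conv_channels`, `dilation_rates`). The ablated variant
  (`dilated_block: false`) tokenises the raw volume directly; it exists for
  the hybrid-vs-plain comparison.
* **Tokenisation.** Non-overlapping 2×2×2 patches are linearly embedded to
  `embed_dim = C` channels (default 32; the scaled-down benchmark uses 16).
* **Encoder.** Four stages of shifted-window transformer blocks with block
  counts `depths = (2, 2, 6, 2)` and head counts (2, 4, 8, 16). Patch
  merging between stages halves each axis of the token grid and doubles the
  width, so stage widths are C, 2C, 4C, 8C. The deepest stage doubles as the
  bottleneck.
* **Attention.** Multi-head self-attention inside non-overlapping 3D windows
  (default 4×4×4 tokens); alternating blocks shift the grid by half a window
  via a cyclic roll and mask attention between voxels that are not spatial
  neighbours after the wrap-around. When the token grid at a deep stage is
  smaller than the window, the window is clamped to the grid and the shift
  disabled, the usual convention. Window size must divide the (clamped)
  token grid on every axis; violations are reported with the offending axis.
  No relative-position bias is used — at the window sizes this package runs,
  its benefit is marginal and it simplifies the attention kernel.
* **Decoder.** Three patch-expanding steps mirror the encoder; each is fused
  with the matching encoder stage by channel concatenation + linear
  reduction (3 skip connections). A final expansion restores voxel
  resolution and a linear projection + softmax yields probabilities.
* **Voxel-resolution head skip.** The front-end's full-resolution feature
  map (for the ablated variant, the raw voxel intensity) is concatenated to
  the expanded token features just before the final projection. Token
  features alone are constant over each 2×2×2 block; without this skip the
  network needs far more training than the desk-scale budget to learn
  sub-token boundaries.

The network is implemented on a small reverse-mode automatic-differentiation
core over numpy arrays (`cfosmap.nn.autodiff`). Every primitive carries a
hand-written backward rule and is checked against central differences in the
test suite; the shifted-window masking is verified against a brute-force
per-token attention oracle on a 4³ token grid.

### Training

* **Input normalisation**: per-patch min–max to [0, 1].
* **Loss**: voxel cross-entropy + soft Dice with equal weights. Foreground
  voxels are rare (≈0.5 %), so the CE term is class-balanced; the foreground
  weight anneals geometrically from 100 to 1 over the run. The large early
  weight pulls the model off the all-background local optimum; the final
  unweighted CE places the argmax decision boundary near the 50 % posterior.
  The Dice term is smoothed (+1) so all-background patches remain defined.
* **Optimiser**: AdamW, default peak learning rate 3e-3 with a short warmup
  and cosine decay to 1/20 of the peak. The small model tolerates (and
  needs) a much larger learning rate than full-scale transformer training.
* **Validation**: a disjoint 20 % patch split; Dice (micro-averaged over all
  validation voxels, argmax segmentation) is computed each epoch and the
  best-epoch weights are restored.
* **Determinism**: initialisation, split and batch order all derive from one
  seed; on a single thread a fixed seed reproduces the loss trajectory
  bit-for-bit, and checkpoints embed the full hyperparameter config.

## Training-mask generation

Labels are produced without manual annotation: the intensity threshold is
`mean + k·SD` (population SD, default k = 3) of voxels pooled over
representative sample boxes; bright 26-neighbourhood local maxima above the
threshold are detected and greedily suppressed to a minimum separation
(default 5 µm, descending intensity, lexicographic tie-break, micrometre
distances); each accepted peak is rendered as an ellipsoid of fixed physical
radius. The default spot radius is **4 µm**: at a 3.5 µm axial voxel a
smaller radius renders as a single-plane disc, which misrepresents the
axial extent of a soma and, at desk scale, makes the voxel-wise training
target nearly unlearnable (the label then disagrees with the visible
axial intensity structure). An alternative in the literature is to take the
thresholded component shape itself as the mask; the fixed-radius rule is
kept because it yields size-calibrated, reproducible labels.

## Post-processing filters

Inference runs patch-wise (reflect-padded halo, default core 64³ and halo 8)
and only halo-cropped cores are stitched, so tiled and whole-volume
inference agree voxel-exactly for any voxel-wise decision rule. The same
checkpoint segments both channels; only the signal-channel mask proceeds to
cell extraction. Components are 26-connected. Filters run in a fixed order
and each removal is attributed to the first filter that claims it:

1. **Autofluorescence filter** — remove components whose fraction of voxels
   positive in the autofluorescence mask is ≥ θ (default 0.5).
2. **No-soma filter** — remove components with physical volume outside
   [50, 5000] µm³ (closed bounds; somata are ~5–20 µm across). The exact
   rule behind the published "no-soma" filter is not specified; this
   size-band is a documented stand-in.
3. **Intensity filter** — remove components whose mean raw intensity is
   below `median + k·1.4826·MAD` (default k = 3) of the voxels outside the
   mask. The robust estimator is used instead of mean + SD because the
   background sample may retain bright voxels missed by segmentation.

Each filter is idempotent, the chain never adds voxels, and the accounting
identity `before − Σ removed = after` is asserted on every run. Cell
centroids are intensity-weighted centres of mass; rows are ordered by
centroid (z, y, x) for determinism.

## Atlas quantification

Registration is an input: an invertible 4×4 affine maps image micrometre
coordinates to atlas voxel indices (deformable registration is out of
scope). Labels are looked up at the nearest voxel without interpolation;
cells outside the annotation get region 0 and are excluded from counts but
reported as "unassigned" so totals balance. Hemispheres split at the
midline index of the mediolateral axis (index < midline = L, ≥ = R, midline
ties to R). Counts aggregate by the ontology's explicit `level` tags;
anterior–posterior profiles use half-open equal bins over the region's
annotated extent with a closed last bin; layer metrics report counts,
densities (mm⁻³) and the volume ratio (mask-positive fraction of the layer's
voxels). All aggregations satisfy exact conservation identities, which are
property-tested.

## Group statistics

Two-sided pooled-variance Student's t (Welch by flag), Benjamini–Hochberg
FDR across regions, signed fold change `(m_a+ε)/(m_b+ε)` reported as −1/r
below 1 with a pseudo-count ε = 0.5 to guard zero-mean regions, and a
volcano classification with strict cuts |fc| > 1.4 and q < 0.05. Relative
z-scores normalise each region by the mean and sample SD over all animals
pooled (a control-only baseline is a switch); zero-variance regions are
flagged and set to 0. The coefficient of variation uses sample SD (ddof 1).
Between-region structure uses Spearman correlation with tie-averaged ranks;
each region's "best partner" maximises |ρ| with ties to the lower region id,
and pair q-values are BH-adjusted over the pair set.

## Synthetic data

The generator emulates the study conditions at desk scale:

* **Phantoms** (default 64×160×160 voxels at 3.5×1×1 µm): 200 cells rendered
  as Gaussians isotropic in micrometres (σ = radius/2, radii 2.5–4 µm, peaks
  800–2000 a.u. over a background of 100), placed with ≥ 1 radius border
  margin and a mutual separation of 4× the maximum radius so each cell is a
  distinct local maximum; 10 vessels as smoothed random-walk tubes (radius
  4 µm, intensity 1500) present in both channels with 60 % bleed-through
  into the signal channel; vessels are placed first and cells are kept ~3
  radii away from them (somata are not inside vessels), so the planted
  ground truth is exactly recoverable; Gaussian read noise (SD 10) is added
  last. Not emulated: optics PSF, stitching seams, bleaching, tissue
  autofluorescence gradients — so passing phantom tests demonstrates the
  pipeline's bookkeeping and filter logic exactly, but not robustness to
  real-data artefacts.
* **Toy atlas**: a nested rectangular partition with a root → superregion →
  leaf ontology (optional L1–L6 layer slabs along the mediolateral axis),
  annotation labels in bijection with the deepest nodes, midline at the
  middle of the x axis.
* **Cohort count tables**: `count ~ round(lognormal(log(µ_r·f_gr), σ))`.
  Lognormal rather than negative-binomial: it matches the heavy right tail
  of real per-region counts and keeps recovery analysis analytic; the choice
  is isolated in one function and swappable. The standard recovery benchmark
  plants 20 of 100 regions with multiplicative effects drawn uniformly from
  [2, 3] (every effect at least twofold) at n = 6 per group and σ = 0.25. At
  a uniform factor of exactly 2.0, the pooled t-test through the BH/volcano
  gate has ≈ 87 % power under these conditions, so the mixed-strength design
  is used as the benchmark's positive control.

## Benchmark problem sizes

The scaled-down training benchmark uses a C = 16, window-4³ model on 200
cell-only 32³ patches for 20 epochs (batch 8); vessels are excluded from
training patches because they carry no spot-mask ground truth (they are
removed downstream by the dual-channel filters, and are exercised by the
phantom-recovery benchmark instead). The end-to-end pipeline smoke test uses
a 32×96×96 phantom with core 32³/halo 16 tiles. These sizes were chosen so
the full suite runs comfortably on a single CPU; they are deliberately far
below the published workload (terabyte whole-brain volumes on GPUs), and the
benchmark Dice is a property of this synthetic task, not a reproduction of
the published accuracy figures.

## Known limitations

* Touching cells are not split (no watershed/instance segmentation);
  connected components are the unit of counting.
* The numpy autodiff core is single-threaded and meant for desk-scale
  training only.
* The toy atlas is rectangular; real atlas geometry (curved boundaries,
  partial voxels) is not emulated.
* Level numbering in real ontologies is configurable but the package does
  not ship a real atlas; it reads Allen-structure-graph-style JSON.
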