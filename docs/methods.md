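# Methods

This note documents the models, parameter semantics, numerical choices and
known limitations of `rsnmap`. All defaults named here are the package
defaults; everything is overridable through `SectionConfig`,
`PipelineConfig` and the per-operation configuration objects.

## Data model

A section is a flat list of `SegmentedObject`s — cells (`cDC1`, `CD8T`,
`CD4T`), pseudo-cells (`vessel`, `tumour`) and probe surfaces
(`probe_Cxcl9`, `probe_Il12b`) — each reduced to a centroid (µm), a volume
(µm³) and optional channel intensities and categorical labels. Analysis is
strictly two-dimensional: sections are 10–30 µm thick against a lateral
extent of millimetres, so a Z coordinate is read when present but ignored.
Extended structures (vessel networks, contiguous tumour areas) are tiled
into square pseudo-cells (default 50 µm, the grid anchored at the region's
bbox lower-left) so that "density of vessel" becomes countable; a tile is
kept when more than half its area intersects the structure, and its volume
is the intersection area at unit depth. The half-area rule and the tile
size are conventions of this package — segmentation tools that perform the
equivalent splitting do not document theirs — and both are configurable.

## Raster-scanned neighbourhoods and regions

Neighbourhoods are circles of radius r = 50 µm centred on a regular grid
(spacing default = r, so neighbourhoods overlap; an object may be counted
by several). Counting is by centroid with an inclusive boundary (distance
≤ r), a deterministic convention that makes boundary behaviour testable.
Cell-level region assignment uses the unique nearest grid centre (ties to
the lowest index), which partitions the plane into the grid's square cells.

Composition vectors are normalised per class before clustering; the
default divides each class column by its 95th percentile and clips at 1
(`p95`), which caps the influence of extreme pockets while keeping the
scale interpretable. `none`, `max` and `zscore` modes exist.

Clustering is a 1×k batch self-organising map: nodes on a line, batch
best-matching-unit assignment, node re-estimation as Gaussian
lattice-kernel weighted means, kernel width annealed geometrically from
k/2 to 0.05 over 200 epochs, followed by Lloyd refinement (the σ → 0
limit of the batch update). Because a wide annealing phase erases the
initialisation, the trainer runs restarts: one canonical annealed run
initialised at evenly spaced quantiles along the first principal axis,
plus three k-means++-seeded σ → 0 runs; the restart with the lowest
quantisation error wins. All restarts are driven by one seed, so the
result is deterministic. k-means (scikit-learn) is available as an
alternative and serves as the independent cross-check in the tests (on
well-separated archetypes the two agree with ARI ≥ 0.95).

The number of regions is selected from Davies-Bouldin
(DB = (1/k)·Σᵢ maxⱼ≠ᵢ (Sᵢ+Sⱼ)/Mᵢⱼ, Sᵢ the mean within-cluster distance to
the centroid, Mᵢⱼ the centroid distance; lower is better) and
Calinski-Harabasz (CH = (B/(k−1))/(W/(n−k)); higher is better), both
implemented from their definitions. The elbow is formalised as a plateau
rule: the chosen k is the smallest k with DB(k) ≤ (1+δ)·min_{k'≥k} DB and
CH(k) ≥ (1−δ)·max_{k'≥k} CH, δ = 0.10. The largest k in the scan is not
eligible (the forward extrema over {k} alone would make it qualify
trivially); monotone featureless curves therefore return the DB minimiser
with an explicit warning flag instead of a silent choice. Index curves can
be averaged over several clustering seeds.

Region summaries: the composition table is the mean *raw* count per class
per region; the interaction matrix counts 4-adjacent lattice edges — entry
(i, j≠i) is the percentage of region-i-touching edges shared with region
j, the diagonal the percentage internal to i, so rows sum to 100.

## State calling

**Probe overlap.** Cells are discs: effective radius √(V/π) from the
stored volume at unit depth. A probe object contributes its whole volume
to every cell whose disc contains its centroid. A cell's state is the
probe with overlap above threshold (default: any positive overlap); cells
above threshold for both probes are left unclassified by default
(`tie_rule="argmax"` resolves them instead). Limitation: with
point-process placement, discs of neighbouring cells overlap in dense
pockets, so a punctum can be captured by two cells and force a tie —
under the default rule ~30% of synthetic cDC1s abstain while the calls
actually made are >99% correct; `argmax` classifies ~98% of cells at
~95% accuracy. Real segmentation produces non-overlapping surfaces and
does not have this failure mode; the disc approximation trades that
fidelity for not needing meshes.

**Intensity tiers.** Two cutoffs, left-closed: v < low → "low",
v < high → "int", else "high". Cutoffs are data-set specific (visual gates
in practice) and always user-supplied.

**MERFISH counts.** Lineage gates first: XCR1 ≥ 3 keeps cDC1 candidates,
CD3E > 5 keeps T cells (both thresholds on raw counts; the filters are
exact set operations). Each branch is log1p-transformed and k-means
clustered (default 4 clusters, seeded). A cluster is called `CCR7_cDC1`
when its mean CCR7 exceeds both its mean CXCL9 and the branch-wide CCR7
mean (symmetrically for `CXCL9_cDC1`); T clusters with above-branch-mean
TCF7 are `TCF1pos_T`, remaining clusters with above-mean CD8 are
`TCF1neg_CD8T`. This replaces by an explicit rule what is a manual
cluster-inspection step in interactive workflows. Cells passing both
gates receive the cDC1-branch label.

## Density masks and distances

The density of a point set is the isotropic Gaussian kernel estimate
f(g) = (1/n)·Σᵢ N(g; xᵢ, h²I), bandwidth h = 100 µm, evaluated on a
10 µm grid (kept at or below the 10 µm association distance so the
association rule is resolvable). Boundary correction mirrors every point
across each of the four bbox edges before summation; this conserves the
probability mass plain truncation loses, except near corners, which would
need double reflections that the 4-mirror scheme deliberately omits. The
field is computed through the x/y-separable factorisation of the Gaussian
(two small exponential matrices and one matrix product), which equals the
brute-force double sum to floating-point accuracy at a fraction of the
cost.

Masks threshold the field. The default is relative: density >
0.2 × max(density). An absolute mode exists for users who know their
field's scale, and a quantile mode thresholds at a quantile of the
positive densities; the tool this emulates thresholds at an absolute
value in an undocumented output scaling (a probability density per µm²
cannot reach the 10⁷ magnitude that scaling produces), so no absolute
default is pretended. An optional count-scaling (×n) accommodates
density-times-n conventions. Mask area is monotone non-increasing in the
threshold by construction.

Distance to a mask treats the mask as a union of square grid elements and
returns the exact Euclidean distance from a point to the nearest element
(0 inside one); the only error is the grid discretisation of the mask
itself. The association statistic is the percentage of cells with
distance ≤ d (default 10 µm), monotone non-decreasing in d.

The tumour border is the contour of a tumour mask (built from tumour
pseudo-cells by the same KDE machinery, or supplied). Signed distances
(negative inside) come from two Euclidean distance transforms with a
half-spacing correction so values reference the pixel-edge contour; zones
are inside (< −g), at-the-border (|d| ≤ g) and outside (> g), gate
g = 50 µm by default.

## Registration

The warp family is the thin-plate spline: f(x) = c + Ax + Σᵢ wᵢ U(‖x−pᵢ‖),
U(r) = r² log r, with the standard side conditions (Σwᵢ = 0, Σwᵢpᵢ = 0)
solved as one augmented linear system. λ = 0 (default) interpolates the
landmarks exactly — the natural semantics for manually placed
correspondence points — and reproduces any affine map with vanishing
radial coefficients; λ > 0 trades fidelity for smoothness. Collinear
source landmarks and duplicate sources with conflicting targets are
rejected. Registration quality is the RMSE over held-out pairs; the
suggested exclusion cutoff is 50 µm (sections above it should not enter
cross-section analyses — the choice of cutoff is a config default, since
no numeric criterion exists in practice beyond "the registration looked
poor"). `transfer_across_sections` maps points through a fitted warp and
annotates them on the target section (region labels or mask distances).

## The synthetic world

The generator emulates what the pipeline assumes about real sections, not
the sections themselves (no pixels, no 3D, no transcript diffusion).

Geometry: a 4000×4000 µm section with a centred tumour ellipse
(semi-axes 1300×1000 µm), a border band of width 300 µm straddling the
ellipse outline, and stroma outside. The band is 3× the neighbourhood
diameter: a thinner band cannot be resolved by 50 µm-radius
neighbourhoods — nearly every band neighbourhood would mix core and
stroma and the border archetype would smear into its neighbours — so the
band width is set by the measurement scale, which is also why border
regions recovered from real 50 µm rasters appear at least this wide.

Archetypes: six, assigned by geometry and by seeded pockets on a 1500 µm
block grid — tumour core blocks are poorly infiltrated tumour or
infiltrated tumour (50/50), the band is the border mix, stroma blocks are
CD8-only, cDC1-only or vessel-rich pockets (1/3 each). Mean counts per
50 µm-radius neighbourhood (cDC1, CD8, vessel, tumour): CD8 pocket
(0.6, 30, 1, 0.6); cDC1 pocket (30, 0.6, 1, 0.6); vessel (1, 9, 30, 1);
tumour (0.6, 1, 1.5, 36); border (24, 24, 18, 12); infiltrated tumour
(1.5, 21, 9, 30); plus 0.05 uniform background per class. These densities
(~10⁻³–5×10⁻³ cells/µm²) are typical of lymphocyte-dense tumour tissue
and give archetypes that are recoverable but not trivially separated
(Poisson noise at count ~30 is ~18% per class). CD4 T cells default to
zero everywhere because the four-class imaging panel that defines the
regions does not include them; the class is fully supported when
configured. Placement is an inhomogeneous Poisson process per class
(exact, by thinning a homogeneous proposal), so expected totals are
analytic and tested.

States: a border-band cDC1 is *Il12b* with probability 0.75 and a
non-band cDC1 is *Cxcl9* with probability 0.75 (CD8 TCF1+ analogously).
These are conditional probabilities given location — the formulation that
preserves the Poisson class placement while planting the association the
pipeline should detect; with both set to 0.5 the world is exactly null,
which is what the type-I-error calibration uses. TCF1 status is written
onto the CD8 objects (it is an antibody stain in the emulated workflow);
cDC1 states are *not* written onto the objects — they exist in the ground
truth and must be recovered from the planted probe puncta (Poisson count
with mean 5 for the matched probe, 0.05 off-target, placed uniformly in
the cell disc, 1 µm³ each).

Serial pairs: section B is section A thinned (keep 0.8), jittered
(σ = 5 µm, the biological non-correspondence of adjacent sections) and
pushed through a known warp — a mild affine (2° rotation, 1.01 scale,
(40, −30) µm offset) plus sinusoidal displacement of amplitude 30 µm and
wavelength 4000 µm. Landmarks (6×6 grid) lie exactly on the warp; their
spacing samples the deformation at ≥ 4 points per period, without which
no interpolant could recover it (Nyquist).

MERFISH: cells from five latent types (two cDC1 states, TCF1+ T,
TCF1− CD8 T, other; 10/10/20/20/40%), counts negative-binomial
(gamma-Poisson, dispersion 10; ∞ gives the exact Poisson limit) with each
marker's mean ≥ 10 in its own type and ≤ 1 elsewhere, coordinates with
the same border/parenchyma biases.

What a green test does not establish: the generator has no imaging noise,
no segmentation errors, no cell shapes (discs only), no 3D, no spatial
correlation between serial sections beyond the planted warp, and
archetype boundaries are axis-aligned blocks rather than organic shapes.
Recovery results on it validate the pipeline's logic and numerics, not
its robustness to real acquisition artefacts.

## Statistics

The headline comparison is per-section and paired: for each section the
TCF1+ CD8 density mask is built, each called cDC1 state's percentage
within 10 µm of the mask is measured, and the per-section paired
percentages are compared with a two-tailed paired t-test implemented from
its definition (t = mean(d)/(sd(d)/√n), df = n−1; p from the t
distribution). Zero-variance differences raise a degenerate-input error
rather than returning p = 0. Sections are treated as independent paired
units; no pooling across experiments and no hierarchical model. On the
null synthetic world the test's empirical rejection rate at α = 0.05 is
consistent with 5% (checked over 200 replicates); on the default biased
world the *Il12b* > *Cxcl9* direction with p < 0.05 is obtained in
≥ 18/20 replicates of eight sections.

## Numerical notes

- All stochastic code uses `numpy.random.default_rng` with caller-supplied
  seeds; same seed ⇒ identical output, including CSV bytes.
- Nearest-centre assignment compares exact squared distances and breaks
  ties toward the lower index, matching `argmin` first-occurrence.
- `davies_bouldin` raises on empty clusters and coincident centroids
  (undefined ratio); `calinski_harabasz` returns +inf when the
  within-cluster scatter is zero.
- CSV round-trips write `repr` floats and read with round-trip float
  precision, so coordinates survive exactly.
- Grid distance fields use `scipy.ndimage.distance_transform_edt`;
  point-to-mask distances avoid the transform entirely and use exact
  point-to-square geometry via a KD-tree candidate search.
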