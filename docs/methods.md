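# Methods

This note documents the models and procedures implemented in `vesselquant`,
the parameter choices that matter, what the synthetic phantoms do and do
not emulate, and the numerical conventions the results depend on.

## Coordinate and data conventions

Stacks are `(channel, z, y, x)` arrays with per-axis voxel spacing in μm.
All physical coordinates are `(z, y, x)` μm measured from the corner of
voxel `(0, 0, 0)`; the center of voxel *i* along an axis with spacing *d*
is at `(i + 0.5)·d`.  This single convention is applied in contour
extraction, lofting, rasterization and centroid computation, so no stage
introduces half-voxel offsets relative to another.  Indexing is 0-based
throughout; clinical days are 1-based (day 1 is the first scored day).

## Vessel surfaces

The vessel boundary is traced per z-slice from a membrane channel
(default: CD31 for the endothelial surface, laminin-1 for the parenchymal
surface, since laminin labels both basement membranes and its outer
boundary after largest-component selection and hole filling is the
parenchymal BM).  Per slice: in-plane Gaussian smoothing (default
σ = 0.3 μm), thresholding (global Otsu over the smoothed channel, or a
fixed value), largest 4-connected foreground component, hole filling, and
the sub-pixel outer iso-boundary as the contour polygon.  Slices without
foreground are skipped; the longest consecutive run of usable slices is
kept.  User-supplied contour JSON files bypass extraction entirely, which
preserves compatibility with manually traced contours.

Lofting resamples each polygon to *M* vertices by arc length (default
M = 64), orients all rings counter-clockwise, aligns consecutive rings by
the cyclic vertex offset minimizing total squared displacement, joins
neighbouring rings with 2M triangles and caps the first and last rings
with centroid fans.  The mesh is watertight by construction and validated
as such.  **End caps are included in the surface area.**  Whether an
interactive contour-surface area includes caps is not standardised; the
cap-inclusive convention is fixed here and documented, and it cancels in
all density *ratios*.  Note that a surface lofted from *n* slices spans
`(n−1)·dz` μm (ring planes sit at slice centers).

Surface area is the sum of triangle areas.  Point-in-mesh queries use a
vectorised ray-parity (Möller–Trumbore) test along a fixed oblique
direction; points within 1e-9 μm of the surface count as inside
(deterministic tie rule), and rays that graze a triangle edge are recast
along alternative fixed directions.  The small z-component of the ray
direction bounds how far a ray can drift in z, which allows pruning
triangles by their z extent; this makes 10,000 queries against a
~7,700-triangle mesh run in well under a second.  For voxel masks, lofted
meshes carry their rings, and each z-plane is rasterised from the matching
ring polygon — exact for loft geometry; meshes without rings fall back to
the generic ray test.

On a lofted circular cylinder (r = 10 μm, L = 60 μm, M = 64) the area is
within 0.1 % of 2πrL + 2πr² (the inscribed-polygon deficit; it shrinks
monotonically as M grows) and the inside test agrees with analytic
membership on ≥ 99.9 % of random points, the residual being mesh
discretisation at the curved boundary.

## CLN-5 density

Density = (Σ intensity of voxels inside the endothelial surface with
intensity ≥ threshold) / surface area.  The interactive original renders
an isosurface and reads off total intensity; summation over
above-threshold voxels is the non-interactive equivalent of that
threshold step, and the quantity used downstream is the same total
intensity.  The default threshold is Otsu computed **inside the mesh
only** (the original tool's isosurface threshold is not published; a
data-driven default with a fixed-value override keeps runs reproducible).
A voxel belongs to the vessel iff its center is inside the mesh — no
partial-voxel weighting.  Group comparison: one-way ANOVA over per-vessel
densities plus pairwise t-tests with Bonferroni adjustment
(p_adj = min(1, m·p)), reported with group means ± SEM.

Colocalization is summarised as an asymmetric overlap fraction: the share
of above-threshold channel-a voxels also above threshold in channel b.
This is a deliberate simplification for qualitative claims
(e.g. CCL2–CD31 vs CCL2–GFAP); Pearson/Manders coefficients are out of
scope.

## Nucleus spots and compartments

Detection: Gaussian smoothing at σ = 0.5 μm isotropic in physical space,
Otsu (or fixed) threshold, 26-connected component labelling, optional
watershed splitting of touching nuclei (off by default — determinism over
completeness; the flag enables distance-transform watershed), then the
volume-equivalent sphere diameter d = (6V/π)^{1/3} with V = voxel count ×
voxel volume.  Spots with d strictly greater than 3 μm are retained: the
filter is a literal strict inequality, so d = 3.0 μm is excluded.  The
volume-equivalent diameter is a documented substitute for an interactive
spot-size parameter; it makes the filter exactly testable.

Classification is by centroid only (spots are a point abstraction):
inside the endothelial BM mesh → luminal; inside the parenchymal BM mesh
only → perivascular; outside both → parenchymal.  Parenchymal spots are
reported but excluded from vessel-associated counts.  Nesting of the two
meshes is validated before classification.  Spread profiles report, per
compartment and axis, the median centroid coordinate and max/min spread
from the median in μm.

## Synthetic phantoms

The phantom emulates the acquisition geometry the analysis assumes: a
straight venule imaged as 60 z-slices at 1 μm steps with sub-micron xy
sampling (default grid 60×144×144 at (1.0, 0.3, 0.3) μm; the xy field is
43.2 μm so that all three compartments can hold nuclei with ≥1 μm
margins).  Geometry is two nested coaxial tubes — endothelial BM (default
r = 7 μm) and parenchymal BM (r = 16 μm, a distended perivascular space as
seen with perivascular cuffing) — both rendered in Lam1, the endothelial
tube also in CD31.

CLN-5 is a junctional lattice on the endothelial tube: 12 longitudinal
lines plus circumferential rings every 5 μm, line width 0.6 μm — a
honeycomb-like proxy for tight-junction strands.  Barrier damage is the
*coverage fraction* f: lattice voxels are partitioned into segments (node
voxels belong to the longitudinal line), and exactly round(f·n) segments
per type are retained, chosen by a seeded permutation.  Removing whole
segments produces contiguous gaps resembling focal junctional
fragmentation, and exact-count stratified selection makes realised voxel
coverage track f to within ~1 %, which is what makes density-recovery
tests sharp.

Nuclei are spheres in physical space (diameter ~ N(5, 0.3²) μm, clipped at
±2 SD), placed by rejection sampling so that each nucleus plus a 1 μm
margin lies strictly inside its compartment's radial band and any two
nuclei keep ≥2 μm surface clearance — blurred nuclei then never merge, so
detection and classification ground truth is unambiguous.  Rendering
order: geometry × per-channel gain + background (default 5) → Gaussian
blur (default σ = (0.5, 0.3, 0.3) μm) → noise (Poisson on
signal+background by default; additive Gaussian or none selectable).
Identical spec+seed gives bit-identical stacks.

The phantom does **not** emulate: realistic PSFs (only Gaussian blur),
vessel curvature or branching, photobleaching, intensity statistics of
any real staining (no such statistics are published — gains and noise
levels are free parameters and documented as such), parenchymal texture,
or nucleus shape variability.  Passing recovery tests therefore shows the
*pipeline* is correct under the stated imaging model, not that the model
captures every property of real tissue.

Presets encode the qualitative disease regimes studied: junctional
coverage naive = 1.0, wt_d9 = 0.40, wt_d16 = 0.20, astro_ko_d16 = 0.40,
endo_ko_d16 = 0.30 (WT loses ~60 % of density by d9 and ~80 % by d16, the
astrocyte-CCL2 knockout ~60 % by d16, and the endothelial knockout sits
between the astrocyte knockout and WT, following the reported
most-intact-to-least-intact ranking Astro KO > Endo KO > WT at d16);
perivascular nucleus counts rise with disease (0 → 12), and only the
endothelial knockout places nuclei in the lumen (4), modelling stalled
transmigration.  Presets differ only in coverage and nucleus counts.

## Clinical metrics

The 0–5 integer scale is enforced at ingestion (half-points rejected);
score 5 (death) is absorbing.  Onset is the first day of two consecutive
days with score ≥ 1; mice without onset enter the mean as T+1.  The
disease index is 100 × (Σ over days of the cohort's daily mean score) /
mean day of onset — note it is sensitive to appending extra scored days
(they extend the daily-mean sum), which is inherent to the definition.
The ascending-slope window runs from ceil(mean day of onset) to the first
day the daily-mean series attains its maximum; when that window is a
single day (flat plateau immediately at onset) it is extended along the
consecutive plateau, and a window shorter than 2 days returns an explicit
undefined marker.

Severity comparisons use Mann–Whitney U on per-mouse *maximum* scores
(the severity statistic is not otherwise pinned down; maxima match
"disease severity" and are robust to course length).  For ≤ 8 mice per
group the two-sided p is computed by exact permutation enumeration over
the pooled observations — necessary because clinical scores are heavily
tied, and standard exact implementations decline ties; with larger groups
the normal approximation with tie correction is used.  Incidence uses χ²
without Yates correction, with Fisher's exact test when any expected cell
is below 5.  Onset uses ANOVA with Bonferroni-adjusted pairwise t-tests.

The cohort simulator draws per-mouse onset ~ N(profile mean, 1.5²) days
and a plateau score, then ramps at the profile rate: wild type (onset ≈
d10, plateau 3–4, 1 score/day), astrocyte-CCL2 knockout (onset ≈ d11,
plateau 2–3, 0.5/day — milder, slower disease), endothelial-CCL2 knockout
(onset ≈ d16, otherwise wild-type-like — delayed but normal course).
Mortality is not simulated; the absorbing-death rule is exercised by
constructed courses in the tests.

## CFSE metrics

With generation counts N_i and precursor cohorts P_i = N_i/2^i:
% divided = 100·ΣP_{i≥1}/ΣP_i, division index = Σi·P_i/ΣP_i,
proliferation index = Σi·P_i/ΣP_{i≥1}, expansion index = ΣN_i/ΣP_i,
replication index = ΣN_{i≥1}/ΣP_{i≥1}.  Inputs are resolved integer
generation counts as a gating tool exports them; intensity-histogram
deconvolution is out of scope.  Ratios whose denominator is zero (no
responders) return an explicit `None` marker, never 0 and never an
exception, so "no responders" is distinguishable from "no proliferation".
The generation simulator draws responders with probability p and division
counts from a ≥1-truncated Poisson, contributing 2^k cells to generation
k, which conserves precursors exactly.

## Problem sizes and tolerances

Default analyses run on the 60×144×144 grid (≈1.2 M voxels per channel);
a full per-vessel analysis takes ~1–2 s and the bundled studies use 6–12
vessels per group, which is ample for the large simulated effect sizes.
Recovery tolerances used in the test suite: lofted-cylinder area within
2 % of the closed form; density ratios within ±7 % of coverage (the
threshold step and blur interact with gap boundaries); detected spot
diameter within 10 % and centroid within 0.5 μm; vessel-associated counts
within ±10 % of ground truth.  Ties and degenerate cases (all-background
Otsu, zero-variance groups, empty compartments) return explicit
documented values rather than raising.

## Known limitations

* Straight, unbranched vessels only; open surfaces are not handled.
* Densities are comparable across conditions but are not calibrated to
  any real staining intensity scale; absolute values from real images are
  out of reach by design.
* The overlap fraction is a one-directional, threshold-dependent
  colocalization proxy.
* Classification is centroid-based; a nucleus straddling a BM surface is
  assigned wholly to the side containing its centroid.
* The clinical simulator produces monotone ramp-to-plateau courses;
  remission/relapse dynamics are not modelled.
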