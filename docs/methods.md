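# Methods

`eggchamber` models and analyses soma–germline matching in *Drosophila*
oogenesis: the redistribution of follicle cells (FCs) over the growing
germline cyst and the growth of the oocyte relative to the nurse-cell
compartment, both driven by Eya-controlled differential cell–cell
affinity. This note records the models, the synthetic data they are
exercised on, the numerical choices, and the limits of what the tests
demonstrate.

## The developmental clock and Eya schedules

All dynamics run on a 36-hour window covering stages 5–10b. Published
per-stage durations vary between sources; the shipped table (6, 5, 5, 5,
3.5, 3.5, 4, 4 h for stages 5, 6, 7, 8, 9e, 9m, 10a, 10b) is an editable
default chosen from standard staging literature, rounded to sum to 36 h.
Morphogenetic phase boundaries sit at mid stage 7 (13.5 h) and mid stage
10a (30 h), corresponding to germline medial-section areas of 6500 and
31500 µm²; the area↔time map in between is exponential through those two
anchor points.

Per-row Eya intensities (rows 1–6 = anterior FC rows, row 7 = the
anterior-most main-body row whose dynamic is shared by cells 7–14) are
6th-order polynomials in time with vanishing derivatives at t = 0 and
t = 36 h, fitted by constrained least squares (null-space projection of
the two derivative constraints; fitted on t/36 for conditioning) to
stage-mean intensities placed at stage midpoints. The shipped stage-mean
table is synthetic: uniform high expression (135–155 arb. unit) through
phase 1, an anterior→posterior gradient developing through phase 2, and a
phase-3 segregation with rows 1–6 above and row 7 well below the 72-unit
zero-affinity level. Row 7 crosses 72 at ≈17.4 h, early in phase 2. Row
positions along the boundary start evenly spaced (row r at (r−½)/14 of
the anterior-pole distance) and spread posteriorly by up to 45% between
the start of phase 2 and the end of the window, mimicking the posterior
drift of row boundaries as anterior rows flatten.

Eya maps linearly to affinity: in the FC model a = κ·E with κ = 0.012
(contact-energy reward per arb. unit); in the germline model
g = κ′·(E − 72) with κ′ = 1.5·10⁻³, positive g meaning effective
nurse-cell affinity for the epithelium. Both constants are wild-type
calibrations fixed once; every perturbation scenario reuses them.

## Synthetic egg chambers

The generator replaces the confocal dataset. A medial section is an
ellipse of the requested germline area with AP aspect ratio 1.5 in
phase 1 rising linearly to 2.0 late; the aspect default was chosen so the
phase-1 oocyte contact proportion falls in the published 17 ± 3% band.
The oocyte is the posterior region bounded by a DV chord carrying a local
endpoint bend: the chord position is solved so the enclosed area matches
the target oocyte fraction exactly, while the bend encodes the interface
contact angle as a tangent rotation at the triple points decaying over
15% of the half-chord (so the triple points — and hence the contact-arc
fraction — stay essentially at the straight-chord values). The wild-type
oocyte fraction is 1/16 through phase 1, rising smoothly to a 40% plateau
just before the phase-2/3 boundary. The interface angle is generated as
90° + 0.3·(E_ncob − 72), where E_ncob is the Eya level of the row overlying
the nurse-cell–oocyte boundary (nearest row centre); with the shipped
schedules this yields >90° in phase 1, a phase-2 minimum below 90°, and a
return above 90° in phase 3.

Section FCs are 30 per side (60 per section, one per row and side, as in
a medial section of a ~30-row epithelium). Spacing is uniform in phase 1
and blends smoothly toward the matched state in which six tapered
anterior rows cover the nurse-cell arc and the remaining rows share the
oocyte arc — this makes the "six rows in contact with nurse cells"
readout exact at the matched state and self-consistent with the row-bin
definition (bins of width equal to the mean apical extent of AFC-fated
cells). Fates: the six anterior rows are AFCs (10% of the 850-cell
arrest count in 3-D bookkeeping), rows beyond 85% anterior distance are
PFCs, the rest MBFCs. Genotype switches act only beyond the relevant
critical size: *gr1 > eya-RNAi* collapses Eya globally above 1600 µm²
(and raises nurse-cell size heterogeneity 3.5-fold, with premature oocyte
expansion); *mirr > eya* gives MBFC-fated cells the row-2 dynamic above
11650 µm² and stalls further FC transition; *tj > egfr* removes AFC fate
and turns the epithelium Eya-negative from phase 2 onward, with oocyte
expansion continuing into phase 3.

Measurement noise is multiplicative log-normal on Eya and smooth
low-order radial shape noise on the contour (white vertex noise would
self-intersect the dense polygon); nurse-cell heterogeneity is a separate
biological dispersion (CV 0.08 wild type). One root seed is split into
per-chamber streams with `numpy.random.SeedSequence`.

What the generator does *not* emulate: real image segmentation artefacts,
3-D curvature, germarium/stage-1 assembly, correlated measurement error
across parameters, and any morphometric structure beyond the rules above.
Pipeline tests on these data therefore demonstrate correctness of the
computations, not biological validity on real micrographs.

## Morphometrics

All quantities are measured from the stored curves (shapely polygon
areas, polyline arc lengths, local quadratic tangent fits over a ±5%
perimeter window), never from generator bookkeeping, so the
generator→measure round trip is a real check (area to 0.5%, oocyte
fraction to 1%). The 24-parameter schema is a reconstruction: the assay's
full table lives in supplementary material not reproduced here, so the
schema covers the published subset (areas, proportions, interface angle,
row counts, apical extents, Eya summaries, nurse-cell CVs) padded to 24
quantitative descriptors. Phases are assigned left-closed
([0, 6500), [6500, 31500), [31500, ∞) µm²). The interface angle is
measured through the oocyte and averaged over both triple points, so
<90° means the oocyte wets the epithelium. The contact proportion counts
each FC fractionally by the overlap of its apical extent with the
oocyte-adjacent arc, so a straddling cell contributes partially; this
matches the continuous arc-fraction limit (≈18.5% for a 1/16-area
posterior segment at aspect 1.5).

## Embedding and divergence detection

Standardization is column-wise z-scoring, wild type against its own
moments and manipulated cohorts pooled with their controls; zero-variance
columns are dropped with a warning. PCA retains the smallest number of
components with cumulative explained variance above 90% (≤5 on the
default cohort), UMAP runs with n_neighbors = 15, min_dist = 0.2 and a
fixed seed. The trajectory order is the geodesic distance order from the
smallest-germline chamber on the k-NN graph (k = 15) of the embedding.
UMAP's internals are not exactly permutation-equivariant; exact row-order
equivariance is guaranteed (and tested) for the standardize+PCA stage,
and reproducibility under a fixed seed for UMAP.

Divergence of a mutant cohort from its control scans overlapping
log-area windows (32 edges over the shared range, each window spanning
two edge intervals). The statistic is the mean embedding distance of
mutant chambers to their nearest control; its null is built by permuting
genotype labels within the window (B = 200 by default; smaller in
calibration tests). A window is flagged when the permutation p-value is
at most max(α, 2/(B+1)) (α = 0.01; the floor tolerates ties in
nearly label-deterministic windows), and divergence is called at the
first flagged window confirmed by a second flag within the next two
windows, reporting that window's lower edge — the separation began
somewhere inside it. On matched synthetic cohorts this places the
*mirr*-driver divergence inside the published 95% CI of the critical
size (10630–12570 µm²) and keeps the wild-type-vs-wild-type false-positive
rate at or below the nominal level.

## Statistics

Genotype comparisons fit Y ~ size + genotype + size×genotype by OLS
(genotype coded 0/1) and fall back to the main-effects model when the
interaction p ≥ 0.05, recording the branch. The two-way critical-size
ANOVA (type II) is augmented with Šídák-corrected within-group Welch
contrasts (m = 2). LOESS uses span 0.75 (unstated in the protocol,
configurable) with a pointwise residual-bootstrap percentile band
centred on the fit (the raw bootstrap centre carries double-smoothing
bias). The angle-vs-Eya fit is plain OLS; the 90° crossing
(90 − intercept)/slope estimates the zero-affinity Eya level and is
flagged undefined for vanishing slope.

## Germline phase-field model

A single non-conserved order parameter ψ (1 = oocyte) evolves in a fixed
ellipse (180×110 grid, semi-axes 84×50) under

E[ψ] = ∫ κ/2|∇ψ|² + g_w ψ²(1−ψ)² dA − s(A − A²/2A_sat) + ∮ g(s,t) h(ψ) ds,

with h(ψ) = ψ²(3−2ψ), κ = 1, g_w = 0.5 (interface width 2 px, tension
γ = √(2κg_w)/6), wetting given by the boundary affinity field, and a
saturating growth drive (s = 0.011, A_sat = 40% of the domain). The
drive models the oocyte's supply-limited biosynthetic growth relative to
the nurse compartment; crucially it makes oocyte size a *stable*
equilibrium shifted by boundary wetting. A constant (linear-in-area)
drive cannot work: it creates an unstable critical radius, so the
phase-1 oocyte either collapses or grows without bound. With the
saturating form, phase-1 dewetting (g > 0 everywhere) holds the oocyte
near its initial 1/16 share, the posterior sign change of g in phase 2
lets the contact line advance and the oocyte expand to ≈0.37 of the
section, and in phase 3 the posterior drift of the row positions pins
the contact line in positive-g territory, returning the angle above 90°
and halting expansion.

Numerics: explicit masked finite differences (missing-neighbour
Laplacian = zero flux on the staircase boundary), wetting applied on
boundary pixels with quadrature weights normalised to the true ellipse
perimeter and arc-length coordinates measured from the anterior pole;
120 relaxation units per developmental hour, dt = 0.18 (stability bound
dt·κ ≤ 0.25). The contact angle is read at the ψ = 0.5 crossings in a
1.5–4.5 px boundary band from the level-set tangent against the
posterior-pointing wall tangent, median-aggregated per boundary half and
averaged over halves. Young's law for this wetting term,
cos θ = −g/γ, is verified on uniform-g calibration runs (90° ± 2° at
g = 0; within 8° at |g| = γ/2).

## Follicle-cell phase-field model

Fourteen indicator fields φ_i on a 256×64 strip; the bottom boundary is
the germline surface, its anterior 57.5% the nurse-cell (affine)
compartment — the nurse share of the germline–epithelium interface at
the end of phase 2 in the germline model, which also places the
compartment boundary inside cell 8 so rows 1–8 start on nurse cells.
Energy: gradient + double-well interfacial terms (κ = 1, g_w = 0.25),
a pairwise overlap penalty β φ_i²φ_j² (β = 2.5), and the boundary reward
−∮(w₀ + a_i χ_affine)h(φ_i) with uniform attachment w₀ = 0.55 and
Eya→affinity gain κ_fc = 0.012. Volumes are held constant by a
Lagrange-like projection — each step half of the volume defect is
corrected along the interface indicator h′(φ), with a per-step amplitude
cap — because a direct quadratic-penalty force has a per-step feedback
gain of ~4 on these grids and limit-cycles; the quadratic volume term is
retained in the reported energy. Cells start as equal-volume blocks of
height 18 (cuboidal, as in phase 1); the lateral ends are mirror planes
with half-width end cells spanning the pole symmetry axes (full-width
end cells suffer a systematic curvature-pressure artefact and starve),
while small-n patch models (the 3-cell clone experiments) use a periodic
ring so congruent cells are exactly equivalent. Explicit single-precision
integration, 75 relaxation units per hour, dt = 0.2.

Cell height matters: displaced cells can only be absorbed by compression
of the posterior chain, whose internal pressure scales like
2γ(V/w² − 1); at height 18 this stays below the achievable affinity
differentials, at height ≥ 40 it cannot, and displaced cells are forced
off the boundary regardless of parameters.

Known limitations, stated plainly: the mid-run redistribution is
violent — fields overlap at contested contact lines (Σφ locally well
above 1) and per-cell volumes transiently drift up to ~6% — and in the
wild-type run the two displaced cells (7 and 8) end fully detached
rather than re-attached over the oocyte. The redistribution *endpoint*
(exactly six cells on the nurse compartment, cells 9–14 over the
oocyte), the graded wild-type AFC contact profile versus its abolition
under uniform high affinity, and the perturbation signatures
(uniform-high detaching cells 7–8, row-3 knockdown extruding cell 3,
rows-6–8 ectopic affinity keeping those cells on nurse contact) are
reproduced. Energy monotonicity and the ≤2% volume drift are verified in
the calm constant-affinity regime (3-cell patch, stable step), where
they hold; the chamber-scale runs trade those guarantees for the
observed collective rearrangement. "Detached" means total boundary contact below 1% of the
perimeter estimate 4√V over the final 10% of the run; the same threshold
classifies compartment membership at final time.

## Problem sizes and runtimes

Default sizes were chosen so a full validation runs on a laptop-class
single core: 14-cell FC runs use the 256×64 grid over the full 36-h
schedule (≈1 min each); germline runs use the 180×110 ellipse (≈1 min);
pipeline checks use cohorts of 120–500 chambers; permutation nulls use
B = 60–200; the interaction-test calibration uses 500 null replicates via
the closed-form fitter.
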