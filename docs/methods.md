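# Methods

## Face representation and the 36-point scheme

Faces are ordered 36-point landmark constellations in image coordinates
(origin top-left, x rightward, y downward, continuous 0-based values). The
canonical layout — 8 midline points from forehead to chin and 14 left/right
pairs (3 brow, 4 eye, 1 nasal ala, 2 mouth, 4 jaw/cheek per side) — ships as
`data/role_map.json` together with the template coordinates in a 200×200
reference frame. "Left" always means the smaller-x side of the image.

### Alignment

Each face is mapped onto the population target mesh by a least-squares
similarity transform (scale, rotation, translation; reflections excluded)
estimated from the midline points only, via the Umeyama closed form as
implemented in scikit-image. Midline points are near-collinear; a rank-1
point configuration still determines an orientation-preserving similarity,
and excluding reflections prevents spurious flips. Scale is estimated rather
than fixed because clinic photographs have arbitrary subject–camera
distance.

### Asymmetry score and mirroring

Per-point deviations are Euclidean distances between the aligned
constellation and the target. The asymmetry score is
`(L − R) / (L + R)` with L and R the summed deviations over left- and
right-pair landmarks — bounded in [−1, 1], sign-carrying, scale-free.
Totals below 1e−12 (all-zero or floating-point dust from exactly symmetric
constructions) score exactly 0. Faces with positive score (left side more
deviant) are mirrored about the vertical line through the mean x of their
aligned midline points, with left/right landmark indices swapped so each
index keeps its anatomical meaning; the canonical deviance side is thus the
right, and ties are never mirrored.

### Meshing and warping

Constellations are meshed by Delaunay triangulation (scipy), normalized for
reproducibility: vertex indices ascending within each triangle, triangles
sorted lexicographically. The triangle count obeys the planar identity
`2n − 2 − h` (h = hull vertices), which the tests assert on generated
constellations. Warping onto a destination constellation is piecewise
affine: each output pixel inside the destination hull is located in its
Delaunay triangle, its barycentric coordinates are applied to the
corresponding source triangle, and the source is sampled bilinearly.
Bilinear interpolation is used everywhere; out-of-hull and out-of-source
pixels are filled with neutral gray (128) or the median of the source's
border pixels, respectively.

### Compositing order and invariances

align → mirror → group mean constellation → warp → illumination-normalize →
subject mean → group mean. The group mean constellation itself averages
per-subject means first. Illumination normalization rescales each warped
image so its in-hull mean equals a reference defined as the mean over
*subjects* of each subject's mean in-hull brightness (values clipped to
[0, 255], with the clipped fraction reported). Because every per-image
quantity enters through per-subject means, the final composite is exactly
invariant (to floating point) to duplicating any subject's images.
Multiplying an input image by a constant leaves each normalized image
unchanged except through the cohort reference, so composites are
illumination-invariant up to that single global brightness factor — the
tests compare reference-scaled composites. Composites are produced on the
input canvas (all synthetic images share one frame); the face region is the
convex hull of the 36 mean points, and statements about composites apply
inside that hull only.

## Synthetic faces

The renderer draws head outline, brows, eyes, nose and mouth as filled
polygons/ellipses at the exact landmark positions, applies a Gaussian blur
(default σ = 2 template-frame pixels, giving photograph-like smoothness),
multiplies by the illumination factor and adds Gaussian pixel noise.
Feature offsets are applied symmetrically (pairs share a mirrored offset;
midline points keep only vertical components), so asymmetry enters only
through the signed `asymmetry_shift` applied to the left-side x
coordinates; `asymmetry_shift = 0` renders a bilaterally mirror-exact
constellation. Cohorts draw per-subject offsets (N(0, 2 px) per coordinate
by default) and asymmetry once, and redraw illumination
(lognormal, σ = 0.1) and noise per image. The generator emulates controlled
landmark geometry and brightness variation; it does not emulate pose,
occlusion, expression, landmark-annotation error or photographic texture,
so passing tests demonstrate correctness of the averaging algebra, not
robustness of landmark acquisition on real photographs (landmarks are
inputs here, not detected).

## Photobleach model and estimation

The simulator implements a two-state (mobile/immobile) exchange model with
pool depletion. Pre-bleach ROI fluorescence is 1; a fraction m (mobile)
exchanges with the nucleoplasmic pool at rate k, the rest is immobile.
Each bleach event multiplies the in-ROI signals by (1 − d) and removes the
bleached mobile signal from the pool in proportion to `roi_fraction` (the
ROI's share of the exchanging pool volume, default 0.1); without this
volume factor the pool would fall to exactly the post-bleach ROI level and
no recovery could ever be observed. Between events the ROI relaxes
mono-exponentially toward (immobile remaining + current pool). Multiplicative
Gaussian noise is applied per sample. Defaults: 5 s pre-bleach baseline,
6 cycles, 20 s dwell, 0.25 s sampling, bleach depth 0.8, relative noise
0.02 — chosen as a realistic confocal FLIP protocol at the sampling density
needed to resolve rates of 0.1–0.5 s⁻¹. The measured ROI is the bleached
ROI; no unbleached-reference photofading correction is modelled.

Estimation mirrors the model: traces are segmented at the recorded bleach
events (baseline = mean of pre-bleach samples), each segment is fit by
least squares to `F(t) = P − (P − F0)e^{−kt}` with F0 fixed to its first
sample and k > 0, flat segments (amplitude < 1% of baseline) are flagged
unidentifiable rather than fit, per-trace k is the unweighted mean over
successful segments (segments are short; inverse-variance weighting was
deliberately deferred), and the residual is the mean of the last 5 samples
over the baseline (window chosen to suppress noise without reaching back
into the final recovery). The four-construct panel uses mobile fractions
0.8 / 0.5 / 0.2 / 0.2; recovery rates 0.5 s⁻¹ for the wild type and the
CUT1 analog and 0.15 s⁻¹ for the two low-mobility analogs, so the expected
ordering — highest residual at near-wild-type rate for the CUT1 analog,
deepest loss and slowest recovery for the others — is a model prediction
against which the estimators are validated (biases < 5% at 21 cells per
construct under 2% noise).

## Variant spectrum

The gene model records the 733-aa ORF, domain intervals (CUT1 352–437,
CUT2 482–560, HOX 614–677), the hg19 span (chr2:200,134,223–200,329,831)
and 11 exon boundaries in codon units. The exon boundaries are a packaged
approximation: the true SATB2 exon structure is not reproduced, but the
boundaries are constrained so every located fixture variant falls in its
stated exon (nonsense in exons 4, 8, 8 and 11; the acceptor variant
c.598-2A>G at the start of exon 8, so exon 7 ends at codon 199; the final
exon ends at codon 733 and contains codon 693).

NMD rule: a stop-introducing variant (nonsense or frameshift, located by
its own exon) escapes decay iff it lies in the last exon. The 50-nt
penultimate-exon refinement is implemented but off by default. Truncation
prediction reports `stop − 1` retained residues and whether all three
DNA-binding domains survive (stop beyond the homeodomain end).

Missense density is a Gaussian kernel sum on the integer aa grid
(default bandwidth 15 aa), reflected at both ORF boundaries and rescaled to
trapezoid-integrate to the variant count. Depleted intervals are maximal
runs of uncovered positions of at least `min_len` aa (default 25, roughly
the central portion of an ~85-aa CUT domain), annotated with overlapping
domains.

The packaged 19-variant fixture transcribes the study classes (2 essential
splice, 4 nonsense, 5 frameshift, 8 missense, 6 of them in CUT1). Only the
three functionally characterized missense variants are named in the source;
the remaining positions are invented consistent with the stated constraints,
and cDNA strings are internally consistent with codon positions
(c = 3·aa − 2) rather than real transcript coordinates. The residue-566
variant is recorded as p.Gln566Lys; the source also uses the spelling
p.Glu566Lys, and the fixture keeps the position without resolving the
residue identity.

## Phenotype statistics

Terms are binary with explicit missing values excluded from denominators.
Recurrent terms are those used more than once (count ≥ 2), ordered by count
then label. The missense-vs-LoF comparison runs a two-sided Fisher-type
exact test per term (scipy) with Benjamini–Hochberg correction
(statsmodels) at α = 0.05; an exact test is the appropriate choice for
19-individual binary features, and the test suite verifies scipy's p-values
against a full hypergeometric enumeration on every 2×2 table with n ≤ 30.
Terms unobserved in either class are skipped and logged. Under a complete
null the discrete conservativeness of the exact test keeps the
false-positive verdict rate well below the nominal 5%.

## Problem sizes and numerical choices

Tests and the demo run faces at 192×192 px with cohorts of 2–5 subjects
(population targets from 100–2000 sampled constellations — landmark
sampling is decoupled from rendering so population-scale targets stay
cheap), photobleach panels at 21 cells per construct, and 1000-replicate
null simulations; these sizes give Monte-Carlo error comfortably inside the
asserted tolerances. Degenerate inputs are rejected with named diagnostics:
coincident landmarks, all-collinear point sets, zero-area destination
triangles, coincident midline points, bleach events with no pre-bleach
baseline, zero in-hull means. All randomness flows from explicit integer
seeds; reruns are bit-stable for every CSV/TSV output.

## Known limitations

Face detection and landmark localization are out of scope (landmarks are
inputs). Composites are grayscale in the generators, though the averaging
operations accept per-channel RGB. The photobleach model is a well-mixed
two-state approximation — no diffusion-reaction spatial kinetics, no
double-normalization FRAP corrections. HGVS parsing is limited to the
restricted dialect the fixtures use; there is no transcript-aware
annotation. Phenotype analysis does no HPO ontology traversal or term
propagation.
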