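# Methods

## The measurement model

A transverse section of the larval zebrafish eye shows the RPE as a
half-annular band spanning dorsal → ventral. After nitroreductase
ablation and partial regeneration, the band carries a light
(depigmented) central zone bounded by two recovery fronts; pigment
recovery moves the fronts toward the center (≈ 90°, the injury
epicenter). The pipeline's coordinate for "position along the band" is
the **unsigned angle** θ between the dorsal reference direction
(row-decreasing in image coordinates; dorsal must be up in the input
images) and the vector from the eye center to the pixel:
θ = atan2(|Δcol|, −Δrow), in degrees, θ ∈ [0, 180]. Unsigned means the
coordinate is side-agnostic — a left-facing and a right-facing section
produce the same profile — and consequently the reduction is mirror
symmetric but deliberately **not** rotation invariant.

The eye center is not an input; it is fitted to the ROI pixel cloud by
an algebraic (Kåsa) circle fit followed by a geometric Gauss–Newton
refinement of the radial residuals. The refinement matters: on a thick
one-sided annular band the algebraic fit is biased a few pixels toward
the arc, while the refined fit recovers a synthetic eye's center to well
under a pixel. A circle fit is used rather than the ROI centroid
because the centroid of a half-annulus sits far from the eye center.

### Angular profiles

Per larva, ROI pixels are binned by θ into [k·b, (k+1)·b) with b = 1°
for statistics and b = 5° for display (θ = 180 joins the last bin), and
the per-bin **median** 8-bit intensity is taken over the pooled ROI
pixels of that larva. An even pixel count takes the mean of the two
central order statistics (numpy's convention). Empty bins are reported
as missing, never imputed. Group-level heatmaps pool raw (θ, intensity)
pixel pairs in 5° × 5-gray cells; their total count equals the total
number of ROI pixels, a conservation property the tests assert.

### Normalization

Each image is shifted by a uniform additive offset so its mean gray
value hits a dataset-wide target — by default the unweighted mean of the
per-image means, the analogue of adjusting every image to the dataset
average (196/255 in the screen this package models). Pixels are offset,
**rounded, then clipped** to [0, 255]; if clipping leaves the achieved
mean more than 0.5 gray values off target, one corrective pass
re-offsets from the achieved mean. The report records pre/post means,
the total offset, and the clipped fraction; the guarantee
|post-mean − target| ≤ 0.5 holds whenever clipping stays below 1%.

A consequence worth knowing: because normalization enforces a common
whole-image mean, a genuine pigment difference in one region is
mass-balanced by a small opposite shift everywhere else in the image
(a few gray values for the synthetic geometry). This is a property of
the normalization protocol itself, not of this implementation; it is
statistically invisible as long as between-larva biological variability
exceeds it, which holds for the generator's defaults and for real
cohorts.

## The permutation comparison

Larvae — not pixels — are the exchangeable biological replicates. Per
informative 1° bin the statistic is

Δ = median over knockout larvae of the per-larva bin medians − the same
over controls,

and the null is built by permuting **whole-larva** group labels, one
permutation applied to every bin of a draw, preserving within-larva
spatial correlation. When C(n₁+n₂, n₂) ≤ 200,000 all label assignments
are enumerated and p = #{|Δ*| ≥ |Δ|}/N is exact (8v8 → 12,870
assignments); otherwise 20,000 assignments are sampled and the add-one
estimator p = (1 + #{|Δ*| ≥ |Δ|})/(1 + n) keeps p ≥ 1/(n+1). The
"95% CI" plotted alongside Δ is the 2.5–97.5 percentile band of the
permutation-null statistic (recentred at zero by construction), which
is the natural band to pair with a permutation test.

Bins are excluded when they fall in the omitted peripheral ranges
(defaults 0–30° and 150–180°, because ablation is confined to the
central two-thirds of the arc — leaving 120 informative bins) or when
fewer than 3 larvae per group have data there.

### Phenotype calling

A run is a maximal set of consecutive informative bins with p ≤ 0.05
and constant sign of Δ; an excluded, missing, non-significant,
zero-difference or opposite-sign bin breaks it. Runs spanning
**strictly more than 20 degrees** (≥ 21 one-degree bins) become blocks;
block intervals are printed with first and last significant degree
inclusive ("101 to 121" = 21 bins). Only-lighter blocks classify the
gene a positive regulator, only-darker a negative regulator, both
mixed, none no-phenotype. No per-bin multiplicity correction is
applied: the contiguity-span requirement is the multiplicity guard.

### Power properties of the median statistic

Two structural facts, both verified numerically and asserted in tests:

- The group median is unchanged by minority label mixing, so for
  well-separated groups, label swaps among extreme larvae reproduce the
  observed Δ exactly. These tie families floor the attainable per-bin
  p at ≈ 0.057 for 4v4 (per-bin significance is *unreachable*), make
  5v5 fragile (floor ≈ 0.04 with jumps above 0.05), and leave designs
  of 6v6 and larger robust (floor ≈ 0.013 at 6v6). A screen should
  field at least 6 larvae per group; the design this package models
  uses 16 controls vs ≥ 8 knockouts.
- For the same reason, an extreme shift does not drive the sampled p to
  its 1/(n+1) floor — identity, complement, and near-swap assignments
  reproduce |Δ| — but p still saturates near 0.003 for 8v8, far below
  any reasonable α.

## The synthetic-data generator

`generate_eye` renders: uniform background (gray 210), a filled eye
disc (gray 190), and the RPE band — pixels with radius within
[R − t, R] of the fitted geometry, θ within the arc, on the distal
side — shaded by the two-logistic-front model

E(θ) = dark + (light − dark) · σ((θ − d)/s) · σ((v − θ)/s),

σ the logistic function, d/v the dorsal/ventral front positions and s a
transition scale in degrees (default 3°). The product-of-fronts form
makes effect size (front shift) and front shape independent dials; its
one degenerate corner is d = v, where E at the front sits at
dark + (light − dark)/4 rather than exactly dark. The ROI polygon
traces the band's outer then inner edge with vertices every 2°, and a
half-pixel rendering margin guarantees every rasterized ROI pixel lies
on band shading.

Knockout larvae move the fronts outward (positive shift, impaired
recovery) or inward by `knockout_front_shift_deg` per side. Per-larva
nuisance variation has three sources, applied in this order:

| parameter | default | what it emulates |
|---|---|---|
| `level_jitter_sd` | 6 gray | smooth per-larva angular pigment texture (harmonics to k = 18, ~10° correlation length) — biological between-larva variability that survives normalization |
| `illumination_offset_sd` | 6 gray | per-image additive illumination; removed by normalization, exercising that stage |
| `noise_sd` | 8 gray | per-pixel sensor/texture noise |

plus a 2% geometric jitter of radius and center. Determinism: per-larva
seeds derive from `SeedSequence(spec.seed, spawn_key=(index,))`, so
adding or removing one larva never perturbs the others, and identical
(spec, seed) reproduce bit-identical images.

The texture field's form matters for calibration. A *global* per-larva
level shift would make all 120 informative bins share essentially one
assignment-level statistic — per-bin null p-values become perfectly
correlated across bins and cohort-level rates degenerate. A field with
~10° correlation length keeps between-larva variance at every bin
(which suppresses the normalization mass-balance artifact described
above) while distant bins stay nearly independent; with it, the pooled
per-bin false-positive rate over 50 seeded null cohorts measures ≈ 0.047
and no null cohort is called a phenotype.

What the generator does **not** emulate: real histology (no
photoreceptor layers or fluorescence channels), section-to-section
variability within a larva (one composite image per larva, matching the
one-ROI-per-larva quantification), ROI drawing error, and tissue
artifacts such as RPE tearing (in real data those images are excluded
upstream via manifest curation). Passing tests therefore validate the
*statistical machinery* — calibration, exactness, recovery operating
characteristics — not robustness to histological artifacts.

## Scalar assays

- **Mutagenic rate** = 100 × (headloop⁺ ∧ standard⁺)/standard⁺ embryos;
  standard-PCR failures drop out of numerator and denominator. The
  validation gate passes only rates strictly above 70%.
- **Livak**: technical replicates are averaged on the Ct scale per
  group (not per-replicate fold averaging), ΔCt = target − housekeeping,
  ΔΔCt = knockout − control, fold = 2^−ΔΔCt. Swapping groups inverts
  the fold exactly. The housekeeping gene is metadata, not logic.
- **Percent area** counts ROI pixels with intensity ≥ threshold
  (default 40/255); the inequality direction is a documented choice, and
  the measure is monotone non-increasing in the threshold.
- **Counts**: BrdU → mean, TUNEL → sum, over exactly three consecutive
  central sections per larva (configurable count, enforced).
- **Endpoint tree**: with two groups, D'Agostino–Pearson on each (groups
  under 8 values skip straight to the non-parametric branch, since the
  omnibus test's kurtosis term needs n ≥ 8); both normal → Welch's
  unequal-variance t, else Mann–Whitney U. More than two groups →
  Kruskal–Wallis, then Dunn's pairwise z tests on pooled ranks with the
  tie correction Σ(t³−t)/(12(N−1)) and Bonferroni-adjusted p-values
  (written in-house; no pre-packaged Dunn implementation is available
  in the dependency set).

## Numerical conventions

- Coordinates are 0-based (row, col) with pixel-center semantics;
  ImageJ `.roi` files are read/written with integer coordinates (the
  JSON ROI writer preserves sub-pixel vertices exactly).
- Rasterization includes a pixel iff its center lies in the closed
  polygon (boundary centers count as inside); tested against an
  independent pure-Python ray-casting oracle away from edges.
- 16-bit images are linearly rescaled to 8-bit with a warning; RGB
  input is rejected rather than silently converted.
- Ties in |Δ*| ≥ |Δ| count toward p (the conservative convention).
- Problem sizes: synthetic eyes default to 200 × 200 px (radius 80,
  band 18, ≈ 4,000 ROI pixels, ≈ 33 pixels per 1° bin); calibration
  suites use 50 seeded 8v8 null cohorts and 20-seed recovery batteries.
  These sizes give the calibration estimates quoted above while keeping
  a full validation run around a minute.

## Known limitations

- The enumeration threshold (200,000 assignments) trades memory for
  exactness; 16v8 designs (C(24,8) = 735,471) therefore use sampled
  permutations, where p-values carry Monte-Carlo error ≈ √(p(1−p)/n).
- Small balanced designs are tie-limited (see power properties above).
- The angular coordinate assumes dorsal-up imaging; there is no
  automatic orientation detection.
- Block direction uses the sign of Δ only; a block with biologically
  trivial |Δ| but consistent sign still qualifies if every bin reaches
  p ≤ α — no effect-size floor is imposed, matching the screen's
  criterion.
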