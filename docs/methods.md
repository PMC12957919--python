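# Methods

## Acquisition geometry and units

Two stack geometries are modelled, matching the two assays: synapse mode
(9 equidistant planes, 0.25 µm apart) and glia mode (22 equidistant
planes, 1 µm apart). Coordinates are 0-based voxel indices with physical
positions at voxel centers; the axial extent uses the span convention
(n − 1)·Δz, which makes a 10 µm × 10 µm synapse crop exactly
10 × 10 × 2 µm = 200 µm³ — the volume in which synapse counts are
reported. In-plane sampling is 0.25 µm/px in synapse mode and 0.4 µm/px
in glia mode, ordinary confocal sampling for a 63×/1.4 NA objective at
the respective zooms.

## Distance binning

All proximity metrics use concentric shells measured from the plaque
*border*, not the centroid, which generalizes "concentric circles" to
irregular outlines: the Euclidean distance transform of the mask
complement gives each outside pixel its distance to the nearest mask
pixel, minus half a pixel so distances refer to the geometric mask edge
(without this correction thin-annulus areas are biased outward by
~px/2; with it, pixel-count areas of 10 µm shells around a disc agree
with π[(r+d₂)² − (r+d₁)²] to well under 2% at 0.2 µm pixels). Bins are
half-open (lo, hi], so a point exactly on an edge belongs to the inner
bin — the same convention as the cell-counting tie-break. Presets:
`microglia_10um` (plaque + 10 µm shells to 50 µm), `astrocyte_25um`
(plaque + 0–25/25–50), `synapse_excitatory` (shells from 0),
`synapse_inhibitory` (shells from 10 µm, avoiding the vGAT/LAMP1
co-aggregation zone next to the border). Wild-type and pre-plaque-age
images receive a centrally placed reference disc (default radius equal
to the cohort's plaque radius; the radius is not critical because every
metric is normalized to the WT mean across bins). Annuli clipped by the
image border are flagged; their available area keeps densities well
defined.

## Synthetic scenes

The generator is the package's study-condition definition, not a fixture.
One RNG stream per stack, derived from (cohort seed, genotype, animal,
slice, image) via `SeedSequence`, makes cohorts bit-reproducible.

**Puncta.** Synapses are paired pre/post puncta: pair centers follow an
inhomogeneous 2D Poisson process (baseline 0.3 pairs/µm³ — 60 per
200 µm³ crop, a typical confocal-detected excitatory density in CA1
stratum radiatum) thinned by a per-bin multiplier (the *deficit*; the
in-plaque multiplier defaults to 0.3). The post partner sits at a uniform
offset inside a ball of 0.4 µm = 0.8 × the detector's co-localization
radius; the margin keeps boundary pairs detectable once centroid noise
(~0.1 µm) is added, preserving the intent that generated pairs are
detectable by construction. A quarter of each channel's puncta are
unpaired. Points are deposited with trilinear weights and blurred once
per channel with an anisotropic Gaussian PSF (σ_xy = 0.15 µm,
σ_z = 0.5 µm), which is exactly equivalent to stamping a PSF kernel per
point; the blur uses a constant (absorbing) boundary so sources near the
volume edge lose light rather than having it mirrored back, mirroring
real sectioning. Peak intensities are lognormal (median 40, σ_log 0.2)
over a background of 5 with Gaussian read noise σ = 3 (the background
and noise levels of the source images are not published; these give an
SNR ≈ 13, a mid-range confocal setting, and the WT-mean normalization
makes all recovered percentages insensitive to the absolute scale).

**Plaques.** Discs with a tanh edge: diffuse plaques get a soft 2 µm
fall-off and no Thio-S signal; non-diffuse plaques a sharper 0.7 µm edge
plus a bright compact core (half the plaque radius by default) rendered
into both the plaque and Thio-S channels.

**Glia.** Somata follow a thinned 2D Poisson process (baseline
1.2 × 10⁻³ cells/µm², i.e. ~1200 cells/mm² in a 21 µm projected slab);
each soma is a wide Gaussian blob with a co-localized nuclear blob, and
its processes are random-walk strokes of small stamps. Per-bin gains act
separately on soma density, stroke count (coverage) and amplitude
(intensity), so the three measured metrics are independently
controllable. The nuclear channel also carries unrelated background
nuclei (2 × 10⁻³/µm²) so that nuclear-marker co-localization is a real
gate, not a tautology.

**What the generator does not emulate:** photorealistic optics, spectral
bleed-through, tissue autofluorescence gradients, astrocyte territory
tiling, vascular structures, or section-to-section thickness variation.
Passing recovery tests therefore demonstrates the correctness and
approximate linearity of the measurement chain under controlled
conditions, not robustness to every real-tissue artifact.

## Plaque segmentation and classification

Plaques are segmented on the max projection of the plaque channel with a
per-image automatic threshold (Otsu; fixed-threshold override available).
Two guards reject degenerate thresholdings: images whose "foreground"
exceeds 25% of pixels (Otsu splitting pure noise) yield no plaque, and
components under 20 µm² are speckle. The largest component is the focal
plaque; when none is found the caller falls back to the reference disc.
Classification is non-diffuse iff ≥ 20 thresholded Thio-S pixels overlap
the plaque mask. The Thio-S threshold is median + 8·MAD — higher than
the spot-detection multiplier because the classification image is a
22-plane maximum projection whose noise ceiling sits ≈ 2σ above the
per-plane background; a dense core outshines that ceiling several-fold,
so the decision is monotone in core brightness with no sensitivity cost.
Morphology-only classification (no Thio-S channel) is reported as
`unavailable`, never guessed.

## Synapse counting

Six consecutive 10 µm crops run along a ray from the plaque centre
outward: one just inside the border ("core", excluded from
quantification) and five tiling (0,10]…(40,50] µm. The ray direction is
uniform by seed (recorded in the output) and resampled, up to a bounded
number of retries, until the outermost crop fits in the image; crops are
extracted in the rotated ray frame by bilinear resampling so consecutive
crops are exactly disjoint for any direction. Wild-type images use the
reference disc with a random ray, which on a homogeneous field is
equivalent to the random-area convention.

Puncta are detected per crop: a robust background threshold, local
maxima seeding a watershed (so touching puncta split along intensity
valleys), and a [4 voxel, 2 µm³] volume gate whose upper bound rejects
the large aggregates seen near plaques. The threshold estimates the
background mean and spread from the 5th–25th percentiles rather than the
median/MAD: in crowded crops the median itself rises with spot density,
which would make detection efficiency density-dependent; the lower
quantiles are essentially signal-free. The multiplier (k = 5
MAD-equivalents) matches the conventional "median + 5·MAD" scale on
clean background.

Puncta closer than the PSF can resolve — axially above all, with
σ_z ≈ 0.5 µm against mean same-channel spacing ≈ 1.3 µm at the baseline
density — fuse into one component, and the resulting undercount grows
with density, compressing any imposed deficit toward 100%. Each
component is therefore *photometrically deblended*: its multiplicity is
the rounded ratio of its background-subtracted flux to the crop's median
component flux (capped at 3). Calibration on homogeneous fields puts
detection efficiency at ≈ 0.98 for 0.15 pairs/µm³ and ≈ 0.94 at
0.3 pairs/µm³ (ratio 1.05, against 1.20 without deblending); the few
points of residual compression are visible in the recovery studies,
which read a 50% deficit at ≈ 54–58%.

A synapse is a pre/post pair within 0.5 µm (3D centroid distance),
matched greedily in ascending distance with deterministic (distance,
pre, post) tie-break; each punctum is used at most once, components
contribute their multiplicity. The count equals the mutually-nearest
matching produced by taking the globally closest available pair first,
is symmetric in the channels, and is bounded by the smaller punctum
count.

## Glial metrics

Measured on 2D maximum projections. Coverage and intensity use one fixed
marker threshold per cohort — Otsu on the pooled wild-type projections,
frozen before any measurement — so values are comparable across images;
coverage is the positive-pixel fraction per region × 100 and mean
intensity is averaged over positive pixels (the all-pixel convention is
a one-line change; positive-pixel is the default because the original
procedure thresholds before measuring). Somata are nuclear blobs
(per-image Otsu on the nuclear projection, ≥ 4 µm²) with at least 30% of
their pixels marker-positive; each soma is counted once, in the
innermost region its body touches (plaque interior counts as innermost).
This tie-break conserves totals exactly but transfers border-straddling
cells inward, inflating the small in-plaque region's density by a factor
set by the soma radius and region perimeter (≈ +40% for a 13 µm disc at
the default soma scale) — in *all* groups, so WT-normalized folds remain
accurate: a generator-imposed 4× in-plaque elevation reads back at
≈ 395–420%.

## Comparative Ct

Replicates collapse by arithmetic mean (SD > 0.5 cycles flagged, never
excluded); ΔCt subtracts the per-sample arithmetic mean of the three
reference-gene Cts, which on the 2^−Ct scale is geometric-mean
normalization (asserted numerically in the tests); ΔΔCt subtracts the
control-group mean ΔCt, making the control's geometric-mean fold exactly
1; fold = 2^−ΔΔCt with amplification efficiency fixed at 2 (an
efficiency-corrected base is available but off by default, matching
plain comparative-Ct semantics). Samples missing a reference gene are
excluded with a logged reason. Folds are invariant under any per-sample
global Ct shift (RNA input, global efficiency), also asserted as a
property test.

## Statistics

`two_group_test` gates on Shapiro–Wilk per group at α = 0.05: both
normal → unpaired two-tailed t; otherwise Mann-Whitney U. The gate trail
is part of the result. Realized type-I error on normal nulls at n = 8 per
group is ≈ 0.05.

`factorial_distance_test` (one between factor, one repeated within
factor — the F1-LD-F1 layout) always computes both branches and lets a
Shapiro–Wilk gate on cell-centered residuals mark the primary:

- *Parametric*: mixed-design repeated-measures ANOVA; per-bin genotype
  comparisons with Holm step-down across the bin family (the
  family-corrected style of standard post-hoc multiple-comparison
  procedures).
- *Rank-based*: global mid-ranks over all N·t observations, relative
  treatment effects p̂_ik = (R̄_ik − ½)/(N·t), and the ANOVA-type
  statistic with Box approximation. Within-subject effects (distance,
  interaction) use the F(f̂, ∞) reference — the convention of the
  standard nonparametric-longitudinal-data software — and the
  between-subject effect F(f̂, f̂₀) with the Box denominator. Post-hoc:
  Dunn's per-bin rank z with tie correction and Bonferroni within the
  procedure. Ranks are invariant under strictly monotone response
  transforms, hence so is the whole branch.

Numerical caveats, measured and accepted: the asymptotic F(f̂, ∞)
reference runs slightly liberal at 6 animals per group (realized level
≈ 0.07 at nominal 0.05 under label permutation; the Box F(f̂, f̂₀)
alternative is conservative at ≈ 0.02), and rank compression caps the
relative-effect deviation a single fully separated bin can produce, so
the rank interaction has modest power for effects confined to one of
five bins at n = 6. Degrees of freedom of the rank tests follow the Box
approximation and need not equal those printed by other software for the
same design. The unit of analysis is always the animal — slices and
images are averaged first — and animals with missing bins are dropped
with a logged reason.

## Normalization

Every metric table carries `normalized_pct` = 100 × value / (mean over
all wild-type animals and all distance bins of the animal-level values).
This is the convention that lets deficits read directly as percentages
(50% deficit → 50); it requires at least one WT animal, otherwise the
raw table is emitted with the normalized column undefined.

## Problem sizes

The recovery studies run at the design's own sizes: n = 6 animals per
genotype, 2 slices × 3 images per animal (72 stacks per cohort), with 20
independent cohorts for the synapse-deficit ensemble, 50 fields for
plaque classification, and 1000 replicates for test calibration. Fields
are 130 × 130 µm (synapse mode, 0.25 µm/px) and 140 × 140 µm (glia mode,
0.4 µm/px) — the smallest extents that hold a central plaque plus the
full 50 µm bin scheme with crop clearance. One full acceptance run takes
≈ 15 minutes on a single CPU.

## Known limitations

- Deblending assumes roughly unimodal single-punctum fluxes; at very low
  densities (a handful of puncta per crop) the median flux reference is
  noisy and a bright singleton can count as two. The volume gate, not
  deblending, handles the near-plaque aggregate artifact.
- Diffuse plaques have no objective border; segmented area depends on
  the automatic threshold (a fraction of a micron of edge placement,
  ~5–8% of area for a 15 µm object). Size comparisons should therefore
  use one threshold method per cohort.
- The glial coverage and intensity gains compose with the soma-density
  gain (more cells also cover more area), so only the density fold is a
  pure single-parameter recovery.
- Image-border-truncated annuli are flagged but not area-weighted in the
  animal-level averages; fields are sized so this does not occur in the
  default studies.
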