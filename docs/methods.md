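# Methods

This note documents the models, conventions and design choices behind
`oatpquant`: what the synthetic generator simulates, how the masks and
measures are defined, and which conventions the statistics follow.

## Synthetic case model (`simgen`)

A *case* is one simulated tissue field per patient, rendered in the six
channels of the OATP panel. The generator's defaults encode the study
conditions the analysis is designed for: two cohorts (25 GBM, 8
non-tumor control), 512×512 px fields at 0.325 µm/px (a 20× slide-scan
scale), and a per-compartment GBM:control OATP fold change.

**Geometry.** Cells are filled disks with a co-located nuclear disk
(radius fraction 0.6); vessels are random-walk tubes of fixed width
carrying lectin, with a 2 px PDGFRβ⁺ pericyte rim. Default densities are
2000 astrocyte/tumor, 800 myeloid and 300 stromal cells per mm² with
radii of roughly 2–3 µm, and 5 vessels per field. Somata are placed by
hard-core rejection sampling: no two somata overlap, and somata avoid
vessel lumina and the necrotic core. This is the simplest geometry that
exercises mask construction, object splitting and per-object intensity
measurement; overlapping or touching morphology is deliberately out of
scope (rendering still uses a replace-not-add rule, so any overlap that
is configured in has deterministic ground truth). When expected object
counts exceed one per 4 px² the configuration is rejected as overcrowded.

**Intensity model.** For object *i* of type *t* in case *c*, channel *k*:

    value = mean_t,k · fold_t(group) · case_c,k · object_i,k

where `mean_t,k` are the control-group per-type channel means (e.g.
myeloid IBA1 1500 a.u., myeloid OATP 400 a.u., background 100 a.u.),
`fold_t(gbm) = oatp_fold["tissue"] · oatp_fold[t]` on the OATP channel
(1 otherwise and for controls), and `case` and `object` are unit-mean
lognormal multipliers with coefficients of variation 0.10 and 0.20. The
case factor models staining/sectioning variability shared by all objects
of a case in one channel; the object factor models per-cell expression
spread. Unit-mean parametrization (`σ² = ln(1+cv²)`, `µ = −σ²/2`) makes
ratios of group means equal the configured fold in expectation, which is
what the recovery experiments measure back. The dispersion defaults were
chosen once as values under which a 25-vs-8 cohort can resolve the
published effect sizes with sampling error of a few percent; they are
smaller than the case-to-case spread of real IHC cohorts, which is one
reason synthetic recovery is tighter than patient data would be.

**Imaging model.** The noiseless scene (objects replace background) is
Gaussian-blurred (σ = 1 px), then Poisson shot noise is applied, then
Gaussian read noise (σ = 20 a.u.), then the result is clipped at zero.
Float values are kept internally and quantized to 16 bit only on TIFF
export. Ground-truth per-object channel means are measured on the
noiseless, unblurred scene over the final label map, so they are exact
for every rendering order and every overlap configuration.

**Necrosis model** (GBM only, off by default). A disk-shaped acellular
core whose area is a configurable fraction of the field; around it a
pseudo-palisading band (PPN, default 25 px) with doubled cell density,
then an equally wide peri-necrotic zone (PNZ), then cellular tumor (CT).
When the panel's isoform is OATP4A1, each object's OATP intensity is
multiplied by `1 + A·exp(−d/λ)` with `d` the distance from the core edge
(defaults A = 3, λ = 40 px), producing immunoreactivity that is greatest
directly adjacent to the core and decays toward the periphery.

**Seeding.** Per-case seeds are `SeedSequence([config.seed, group_code,
case_index])`, a documented stable hash: cases are individually
reproducible and mutually independent, and identical configs and seeds
give bit-identical rasters and tables.

**Expression tables.** The niche stage is driven by a latent-factor
model: expression of gene *g* in sample *s* is
`baseline_g · exp(loading_g · factor_s + ε)`, where the hypoxia factor is
normal with mean 0 in CT and mean 2 in PPN/PNZ (SD 1) and
`ε ~ N(0, 0.3)`. Default loadings put the hypoxia program genes (CA9,
VEGFA, BNIP3, PDK1, CXCL8, NDRG1, ANGPTL4, TREM1, ATF3, EGLN3, IL1R1)
and SLCO4A1 — but not the other SLCO genes — on the factor, so SLCO4A1
co-varies with the hypoxia cluster by construction.

## Segmentation (`segment`)

The mask stage is an explicit, parameterized re-implementation of a
slide-scanner quantification workflow (the original commercial pipeline
is not reproducible from any published description, so this module is
tested against generator ground truth rather than against the original
software).

* **Background estimation.** Per channel, the background population is
  the lowest local peak of the lightly smoothed intensity histogram
  holding ≥ 20% of the maximum count (so a bright population never wins
  merely by covering most of the frame); its noise scale is the one-sided
  MAD of pixels below the peak. "Above background" means exceeding the
  peak by 4 robust SDs.
* **Tissue mask** = union of per-channel above-background pixels,
  morphologically closed (with edge padding so border objects are not
  eroded) and hole-filled. It is the ROI area used to normalize
  integrated intensities.
* **Otsu thresholds** are computed by exhaustive scan of every candidate
  split of the value histogram, maximizing between-class variance;
  foreground is strictly greater than the threshold. In `marker_objects`
  the Otsu value is floored at the above-background criterion, so a
  markerless channel (unimodal noise) yields no objects instead of split
  noise. A single-valued histogram is degenerate: Otsu raises, and
  marker segmentation falls back to a fixed threshold if one is
  configured. A `control_percentile` mode (thresholds as a quantile of
  pooled control-cohort pixels) is provided for batch-consistent
  positivity calls.
* **Nuclei**: Gaussian smoothing (σ = 1) → Otsu → optional watershed on
  the distance transform, seeded at local maxima at least one minimum
  nucleus radius apart → area filter.
* **Marker objects**: threshold within tissue → opening (radius 1) →
  8-connected components → area filter (default 30 px ≈ 3 µm² at
  0.325 µm/px, excluding sub-nuclear fragments).
* **Vessel priority.** Pixels positive for both IBA1 and lectin are
  assigned to vessels before myeloid labeling, so peri-vascular myeloid
  signal is not double-counted; the rule is configurable.
* Conventions: 8-connectivity, strict `>` positivity, 0-based (row, col)
  coordinates with origin top-left, labels contiguous from 1.

## Quantification (`quantify`)

*Integrated intensity* is the channel sum over the OATP-positive mask;
the *mean* form divides by tissue (ROI) area — both are reported because
the naming in the field is ambiguous. Per-object means are averaged per
case (equal weight per image when a case has repeated sections), and
group fold changes are ratios of group means (medians available) with a
two-sided Mann–Whitney test on the per-case values. The OATP positivity
threshold for single cells defaults to the 99th percentile of pooled
control-cohort per-object OATP means, computed per compartment. Regional
means (CT/PPN/PNZ) exclude background and necrotic-core pixels; a region
absent from a case is missing (NaN), never zero, and missing values are
excluded from group summaries.

## Statistics (`stats`)

Ranking, the *U* statistic, Spearman's ρ and the BH adjustment are
implemented from their definitions so the group comparisons are
auditable at the rank level; only normal/t tail probabilities come from
scipy (scipy and statsmodels serve as independent oracles in the tests,
never as the implementation).

* **Mann–Whitney.** Mid-ranks throughout. Exact mode enumerates all
  C(n, n1) group assignments (automatic when n1+n2 ≤ 12 without ties;
  forced exact mode also handles ties). The two-sided exact p doubles the
  smaller tail probability, capped at 1 — with ties the permutation
  distribution need not be symmetric, so both tails are evaluated.
  Otherwise a normal approximation with tie-corrected variance and a
  0.5 continuity correction is used. Two groups with all values identical
  are degenerate: U = n1·n2/2, p = 1, flagged.
* **Spearman.** Pearson correlation of mid-ranks; two-sided p from the
  t approximation with n−2 df, flagged approximate when n < 10. Zero
  rank variance leaves ρ undefined (NaN, flagged) rather than zero.
* **BH.** Step-up `q_(i) = p_(i)·m/i`, monotone from the top, capped at
  1, returned in input order; applied across the upper triangle of
  correlation matrices (each unordered pair once) and mirrored.
* Normality screening is deliberately not a gatekeeper: two-group
  comparisons always report Mann–Whitney, which is the test the analysis
  design actually uses.

## Niche expression (`niche`)

The differential statistic is fully specified and self-contained:
`log2FC = log2(mean(region)+1) − log2(mean(CT)+1)`, a two-sided
Mann–Whitney across samples, BH across genes, and conjunctive selection
at adjusted p < 0.01 (the FDR cutoff) and raw p < 0.1. This replaces a
negative-binomial RNAseq model (edgeR/limma-class fits) on purpose: the
stage is meant to be verifiable against the latent-factor generator, and
no claim is made that its DEG lists would match a count-model fit on
real atlas data. The two cutoffs are applied together as configured even
though the FDR cutoff is the stricter of the two; both are parameters.
The "top DEGs" used for the OATP correlation matrix are the *n* selected
genes with smallest adjusted p (default n = 40; the count is a
parameter). Correlation matrices are ordered by average-linkage
clustering on 1−ρ with genes pre-sorted by name, so the order is
deterministic given the matrix.

## Pipeline (`pipeline`, `cli`)

`run_pipeline` chains simulate/ingest → segment → quantify → stats →
niche behind one structured config; a single `--seed` overrides every
source of randomness, and identical config + seed gives byte-identical
CSVs. Ingest mode reads one multi-page TIFF per case (or six
single-channel TIFFs) plus `cases_manifest.csv` (case_id, group,
isoform); a missing channel aborts with the case and channel named.
Repeated images of one case are averaged into a single cohort row, so
each case enters group statistics exactly once.

## Problem sizes and what the tests show

Recovery tests and the acceptance script run the full study design
(25 + 8 cases at 512×512 px); generator-level convergence is checked at
a 10× cohort (250 + 80) on 256×256 px fields, where rendering is cheap
and the measured compartment fold lands within 5% of the configured
value. Unit tests use 128–256 px fields with small cohorts. Passing
recovery at these settings shows the pipeline is unbiased under the
generator's assumptions — disk geometry, unimodal background,
shared-batch intensity scale, case CV ≈ 10% — not that it would recover
effects of this size from real cohorts, whose between-case variability
is larger and whose backgrounds are structured (autofluorescence,
section artifacts, bleed-through are all out of scope).

## Known limitations

* 2D only; no spectral bleed-through, stitching artifacts or
  autofluorescence structure; cell shapes are disks.
* Per-case Otsu thresholds make the OATP⁺ mask sensitive to quantization
  and noise on very small, dim fields; the `control_percentile` mode is
  the stable alternative when a pooled control batch exists.
* Fold changes of means are reported without confidence intervals; the
  Mann–Whitney p refers to the rank comparison, not to the ratio.
* The niche DEG statistic ignores count dispersion and library size; it
  is calibrated for the latent-factor generator, not for raw RNAseq
  counts.
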