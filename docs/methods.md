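# Methods

`epicrosstalk` analyses the coordination between DNA 5-methylcytosine
(5mC) and RNA N6-methyladenosine (m6A) in a multi-omics developmental
study: RNA-seq expression across developmental stages, WGBS-style
per-CpG methylomes, and MeRIP-seq m6A peaks with paired IP/input read
counts. This note documents the models, the numerical conventions, the
synthetic-data generator that the test suite plants its truths in, and
the design decisions taken where the procedure was genuinely open.

## Coordinates and formats

All intervals are 0-based half-open internally. BED input is consumed
natively; per-CpG methylation tables are assumed 1-based (CX-report
style) and shifted on read. Every writer emits a `#`-prefixed header
line and write→read round-trips are the identity, so no downstream
stage needs to know which file it came from. FPKM is consumed, never
computed. Peaks are treated as generic intervals on named sequences;
whether they live in transcript or genome space is irrelevant to every
operation in the package.

## Module eigengenes, kME and the EME

A module eigengene is the first right-singular vector (sample space) of
the gene set's standardized expression submatrix on the log2(FPKM+1)
scale; standardization uses the n−1 standard deviation so the values
are exactly reproducible. Module membership (kME) is the Pearson
correlation of a gene's profile with the eigengene.

The epigenetic module eigengene (EME) treats a curated 41-gene list of
5mC/m6A regulators (21 + 20: writers, readers and erasers of each mark;
packaged, fully overridable) as one module, keeps hub regulators with
|kME| > 0.7, and recomputes the eigengene from the hubs.

Numerical conventions:

- **Orientation.** An eigengene's sign is chosen so that the mean kME
  of its source genes is ≥ 0; an exact tie (a gene set closed under
  negation) is broken toward a positive first component, so output is
  deterministic.
- **Hub cut on |kME|, not signed kME.** Eraser enzymes anticorrelate
  with writers yet belong to the module; a signed cut would silently
  discard them. `mode="signed"` is available.
- **Near-degenerate leading singular pair** (relative gap < 1e-6)
  triggers a warning, not an error: the eigengene is still a valid
  summary, only its identity among near-tied directions is unstable.
- Correlation p-values use the classical two-sided t test,
  t = r·sqrt((n−2)/(1−r²)) on n−2 df; |r| = 1 reports p = 0.

## Co-expression modules and the EME screen

Genes are first filtered to the top 25 % by log2(FPKM+1) variance (ties
at the boundary kept). The detector is a compact weighted
correlation-network pipeline: unsigned adjacency |r|^6, unsigned
topological overlap (TOM), average-linkage clustering of 1−TOM, a
static cut at 0.995 × the maximum merge height, minimum module size 30,
modules labeled 1..K by decreasing size and 0 for unassigned. The
static cut is a deliberate simplification of dynamic tree cutting; the
supported contract is recovery of planted block structure, and the
detector is pluggable behind `ModuleAssignment`.

Module eigengenes reuse the one eigengene implementation. A module is
EME-correlated when |r| > 0.8 and p < 0.05; the magnitude reading is
used because strongly *anti*-correlated modules are biologically the
interesting repression candidates, and the direction is reported
alongside.

## CpG methylation around m6A peaks

**Replicate merging.** A peak is reproducible iff it overlaps (≥ 1 bp,
half-open) a peak of the other biological replicate; surviving
intervals covering a contiguous base run are unioned. This equals a
per-base union oracle and is property-tested against one.

**Metagene profile.** Upstream 5 kb, peak body and downstream 5 kb are
split into 20, 10 and 20 bins (250 bp flank bins at defaults). Body
bins use floor-based equal splitting with the remainder folded into the
last bin, so bin lengths always sum exactly to the region length. Minus
strand peaks are flipped so bin 0 is transcript-upstream; '.' is
treated as '+'. A (peak, sample, bin) instance contributes only when it
contains ≥ 20 CpGs; whether that filter was meant per instance or on
pooled bins is ambiguous in the field, so both are shipped
(`aggregation="mean_of_instances"` is the default, `"pooled"` the
alternative; with a 1-CpG threshold the pooled body mean provably
equals the plain in-peak CpG mean). The instance-mean default prevents
CpG-dense peaks from dominating the profile.

**Per-peak 5mC (the GLM's Y)** is the unweighted mean CpG level inside
the peak (coverage-weighted optional), undefined below a configurable
CpG count. **Global methylation** averages per-replicate means rather
than pooled records so unequal CpG counts per replicate do not bias
stage summaries.

## Enrichment and the interaction model

RPM = count × 10⁶ / library_total; Escore = RPM_IP / RPM_Input, NaN
(flagged, not raised) when the input RPM is zero. Library totals are
*total mapped reads*: the synthetic generator therefore adds an
off-peak background constant to the per-sample peak sums — with
peak-only totals the normalization would divide out the mean planted
enrichment and turn Escore into a purely relative quantity.

For each m6A region on a gene, ordinary least squares fits

    log2(FPKM + 1) = b0 + bS·S + bX·X + bY·Y + bXY·(X·Y) + e

with S the postnatal stage in days (numeric, one coefficient), X the
region's Escore, Y its CpG methylation level. The solver uses pivoted
QR; rank-deficient columns are dropped and flagged, standard errors
come from the residual variance on n − rank df, p-values are two-sided
t. Residual variance < 1e-12 is reported as a perfect fit with NaN
p-values and a warning. Regions with undefined X or Y, perfect fits, or
a dropped interaction column are excluded from the screen and listed
with reason codes. A region is significant when the interaction
p-value is below α = 0.05 (raw by default, matching common practice for
this screen; Benjamini–Hochberg available); a gene is significant when
any of its regions is, and the gene counts once.

**Observation design.** Observations are (stage, replicate) pairs where
an RNA sample matches a WGBS sample; X joins per stage or per
(stage, replicate) depending on the enrichment table. With four
postnatal stages and two replicates (n = 8, residual df = 3), a
stage-pooled X is constant within stage, so the interaction column is
identified only through within-stage methylation wiggle and the test
has almost no power. The synthetic study is therefore generated and
screened with replicate-level Escores — biological replicates are
different animals, and their enrichment genuinely differs.
`escore_table` keeps `stage_pooled` as its API default for users whose
replicates are technical.

## The synthetic-data generator

The generators emulate the study design the analysis assumes and plant
recoverable ground truth. The paper-scale conditions are the defaults:

- **Expression**: 27 developmental stages × 3 replicates (81 RNA
  samples). Stages live on one days-post-conception axis (embryonic
  days as-is; postnatal day d → 114 + d, the pig gestation length)
  because sample metadata requires positive stage ages, including
  postnatal day 0. The 41 regulators are generated as
  sqrt(ρ)·z + sqrt(1−ρ)·ε around a standardized smooth latent stage
  profile z, so the planted pairwise correlation is exactly ρ
  (default 0.9). Planted co-expression modules use the same
  construction around per-module latents; a module latent may be tied
  to +z, −z (the EME-anticorrelated module) or be independent —
  independent latents are Gram–Schmidt-orthogonalized against all
  latents already in use, because two smooth trends on the same stage
  axis are otherwise far from uncorrelated. Background genes are
  heteroskedastic noise. FPKM = 2^v − 1 with v the log2 profile.
- **Methylome + peaks**: one synthetic chromosome; consensus peaks
  spaced so flanks never touch a neighbor; CpG positions from a seeded
  uniform point process shared across the 4 stages × 2 replicates
  (default density 0.1/bp, roughly RRBS-dense); per-CpG levels
  Beta(μκ, (1−μ)κ) with κ = 50, μ = 0.5 outside peaks and 0.5 + δ
  inside (default δ = 0.3) — Beta keeps levels in [0, 1] without the
  mean bias clipping a Gaussian would introduce. Replicate peak sets
  jitter the consensus boundaries by ±30 bp.
- **MeRIP counts**: per-peak abundances lognormal around 100 reads;
  input counts Poisson(abundance), IP counts
  Poisson(abundance × multiplier); library totals add 10⁶ background
  reads.
- **Interaction study**: one region per gene, 4 postnatal stages × 2
  replicates matched across RNA/WGBS/MeRIP. Enrichment multipliers are
  log-uniform on (2, 16) per (peak, stage, replicate) — merged
  reproducible peaks are the highly-enriched subset of MeRIP peaks —
  and target peak methylation is uniform on (0.1, 0.9), the realistic
  span of regional CpG methylation. These ranges were fixed once from a
  power analysis of the df = 3 interaction t-test: they give the
  planted |bXY| = 2, σ = 0.2 effect a per-gene power around 0.97, i.e.
  the planted signal is genuinely recoverable rather than borderline.
  Planted genes' responses are written exactly from the model using the
  *realized* X (computed Escore) and Y (computed peak methylation), so
  coefficient recovery is a closed loop; null genes share every
  coefficient except bXY = 0.

Every generator draws from named substreams of one root seed and is
byte-deterministic. What the generator does **not** emulate: read-level
sampling, transcript structure, bimodal CpG methylation landscapes,
genomic correlation of methylation, count overdispersion beyond
Poisson, or prenatal methylomes. Passing tests therefore demonstrate
that the estimators recover the structure they model, under that model
— not that the model captures every property of real muscle
multi-omics data.

## Problem sizes in the checks

The acceptance checks run at sizes where the statistical assertions are
sharp but cheap: 200 random matrices (≤ 20 genes × 12 samples) for the
eigengene oracle, 50 seeds for hub recovery, 20 seeds for module
recovery and for the end-to-end screen (105 genes each), 2000 null
fits for GLM calibration, 500 random instances against the
normal-equations oracle, and 1000 random peaks for the bin-partition
property. These sizes are the package's own choice of test scale.

## Known limitations

- The module detector's static cut is cruder than dynamic tree cutting
  and will fragment or merge modules on data with nested correlation
  structure.
- Reusing a gene's expression as the response for each of its regions
  double-counts genes with many peaks in the screen's region-level
  counts (the gene-level rollup is unaffected).
- Raw p < 0.05 region screening without multiplicity correction is
  anti-conservative by construction; BH is one flag away.
- With n = 8 and df = 3 the interaction test is honest but weak;
  studies with more stages or replicates should prefer them.
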