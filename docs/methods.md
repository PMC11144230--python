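# Methods

`mdmrkit` implements a pan-cancer whole-genome bisulfite sequencing (WGBS)
differential-methylation workflow: per-sample tumor-vs-normal DMR calling,
cohort-level consensus region derivation (mDMRs), tissue/cfDNA concordance,
megabase-scale hypomethylated domain detection, and tumor/normal
classification — together with a synthetic cohort generator that provides
ground truth for every stage.

## The measurement model

The unit observation is a CpG site with methylated count $m$ and
unmethylated count $u$; its beta value is $\beta = m/(m+u)$, undefined at
zero coverage. All region summaries are unweighted means of per-CpG betas
(each qualifying CpG contributes equally, matching array-style averaging; a
coverage-weighted variant is available via `region_mean_beta(...,
weighted=True)`). Coverage files use the Bismark dialect (1-based
inclusive); all internal coordinates and all BED output are 0-based
half-open.

## Synthetic cohorts (`simcohort`)

The generator emulates the data structure of a tumor / matched-normal /
plasma WGBS cohort without modeling reads:

- **CpG grid.** Clustered islands (default 20 per chromosome, ~1 kb wide,
  holding 20% of CpGs at ~16 bp spacing) over a uniform open-sea
  background. The grid is shared by all samples of a cohort and is a
  deterministic function of the seed.
- **Mean beta surface.** Open sea defaults to 0.75, islands to 0.15 —
  the canonical methylated-genome / unmethylated-island profile. Planted
  shared regions assign `beta_normal` to every sample and `beta_tumor` to
  carrier tumors (carrier fraction configurable); planted domains lower
  tumor betas across megabase blocks; private per-tumor regions are
  Poisson-seeded decoys.
- **Noise.** Coverage is negative-binomial with mean 30 and dispersion 10
  (variance $\mu + \mu^2/10$, i.e. sd ≈ 11 at 30x — typical WGBS spread).
  Counts are beta-binomial: the latent per-CpG proportion is drawn from
  Beta$(\beta c, (1-\beta)c)$ with concentration $c = 100$, giving a
  between-sample beta sd of ≈ 0.05 at $\beta = 0.5$ on top of binomial
  sampling — the overdispersion seen in good-quality, reasonably pure
  tissue WGBS. Both knobs are configurable.
- **Planted DMR placement.** `design_shared_regions` snaps planted events
  to dense CpG runs (all internal gaps ≤ 100 bp, i.e. island-like
  sequence) separated by ≥ 5 kb. This mirrors reality — callable DMRs
  require locally dense CpGs — and guarantees that the caller's 300 bp
  gap rule can traverse a planted region. Default planted beta levels are
  the cohort's observed means: hypomethylated events 0.732 → 0.406,
  hypermethylated events 0.308 → 0.643.
- **cfDNA.** A plasma track is a per-CpG mixture
  $\beta_{cf} = f\,\beta_{tumor} + (1-f)\,\beta_{leukocyte}$ with counts
  redrawn beta-binomially. Inside tumor-hypermethylated regions the tumor
  contribution can be scaled by $(1-a)$ with an attenuation knob $a$
  (default 0); this reproduces, without explaining, the empirical loss of
  hypermethylated tissue signal in plasma. It is a phenomenological
  stand-in, not a mechanistic claim.

What the generator does **not** emulate: read-level artifacts (bisulfite
conversion error, mapping bias, strand effects), copy-number interaction
with coverage, fragment-length structure of cfDNA, inter-patient baseline
variation, and realistic genome-scale CpG landscapes. Passing tests
demonstrate the pipeline's correctness and statistical behavior under the
declared noise model, not performance on real libraries.

## DMR calling (`dmrcall`)

A transparent two-stage caller:

1. **Candidate segmentation.** On the shared CpG universe (intersection of
   case and control positions), per-CpG group betas are computed by
   count-summing reads within each group (pooled controls are combined at
   the read level, not as a mean of means — this stabilizes low-coverage
   CpGs). Candidates are maximal runs of consecutive CpGs whose
   case−control difference keeps a constant sign and exceeds a per-CpG
   seed threshold (0.10), with consecutive members ≤ 300 bp apart.
2. **Scoring and retention.** Each candidate gets a two-sided
   Mann–Whitney U p-value comparing all per-CpG per-track betas of the
   case group against the control group inside the region (exact method
   when either group has < 8 values, tie-corrected normal approximation
   otherwise). Retained DMRs satisfy p < 0.05, |Δβ| > 0.15 (Δβ = case −
   control on count-pooled per-CpG betas), ≥ 3 CpGs, and exclude X/Y.

Comparator choice per tumor: matched normal where the patient has one,
else the pool of same-diagnosis normals, else all normals.

A consequence of the exact rank test worth knowing: with one case and one
control track a 3-CpG candidate can never reach p < 0.05 (minimum
two-sided exact p for 3 vs 3 is 0.10), so the effective minimum size in
1-vs-1 comparisons is 4 CpGs.

This caller is deliberately simpler than kernel/HMM segmentation callers;
its defining contract is the retention filter set, and every emitted DMR
is re-asserted against those filters on output.

## Consensus mDMRs (`mdmr`)

Each CpG locus is scored by the number of samples with a same-direction
DMR overlapping it; a sample contributes at most one unit per
locus-direction regardless of how many of its DMRs overlap (support counts
samples, not calls). The support threshold is $\lceil f \cdot n \rceil$
(70% of 31 → 22; a small numeric tolerance prevents exact products like
0.7 × 10 from ceiling up). Kept loci are chain-merged transitively while
consecutive kept loci are ≤ 500 bp apart, so a consensus region may span
far more than 500 bp; boundaries are anchored at the first/last member CpG
(no padding), and single-CpG regions are kept by default. Hypo- and
hypermethylated consensus sets are derived independently and may collide
positionally; collisions are left visible rather than resolved.

The support curve reports, for every threshold 1..n, both the consensus
region count and the kept-CpG count. Only the latter is guaranteed
monotone non-increasing: region counts can transiently rise when a region
splits.

Variable-region selection ranks regions by across-sample variance of mean
beta (NaN-aware, ddof = 1) and returns the top ⌈fraction × n⌉ (default
2.5%).

## Tissue/cfDNA concordance (`concord`)

Two DMRs overlap when they share ≥ 3 CpG loci — loci present with coverage
in **both** samples — inside their positional intersection, with equal
direction. The percent overlap is numerator-relative with the cfDNA set as
numerator by default (a flag switches it); the report also pairs the Δβ of
every overlap call (one point per call, so an A-region matching two
B-regions contributes twice) and fits tissue Δβ on cfDNA Δβ by ordinary
least squares with intercept (R²) plus Spearman correlation. Fewer than
three pairs → correlations are NaN, counts still reported. An empty
numerator set reports 0% rather than NaN so that fraction sweeps remain
comparable.

## Domains (`pmdscan`)

The scanner tiles each chromosome into 10 kb bins, marks bins with mean
CpG beta < 0.7 (and ≥ 5 covered CpGs) as low, and joins maximal low-bin
runs tolerating ≤ 2 interrupting bins. Run boundaries must be anchored on
≥ 3 consecutive low bins (`min_anchor_bins`): unmethylated CpG islands are
low-beta everywhere, so a lone island bin near a run edge carries no
domain evidence and would otherwise extend the boundary by up to the
interruption tolerance. Runs ≥ 1 Mb become domains; the
domain mean/sd are computed over member CpG betas, not bin means. Class
assignment is a pure function of the domain mean: < 0.2 methylation
desert, [0.2, 0.7) PMD, ≥ 0.7 dropped — deserts are carved out of the
domain universe, never double-reported as PMDs. Boundary behavior is
asserted: exactly 0.2 → PMD, exactly 0.7 → excluded. Bins with too few
covered CpGs count as interruptions. This binned scanner is not equivalent
to HMM-based PMD callers and is validated on planted-domain recovery
(boundary error ≤ 1 bin on 2 Mb/1.5 Mb planted blocks).

Consensus domain regions are maximal intervals where the per-base fraction
of samples with a domain call is strictly greater than the threshold
(default 0.5), computed by an event sweep and verified against per-base
counting.

## Classification (`classify`)

The feature matrix is regions × samples mean beta. Evaluation is repeated
(10×) stratified 3-fold cross-validation of a random forest (500 trees,
sklearn defaults otherwise, per-split derived seeds). Missing betas are
imputed with the **training fold's** per-region median (features entirely
missing in a fold fall back to 0.5), so no test information leaks.
Out-of-fold tumor-probability scores are pooled across all repeats into a
single ROC/AUC — one printed number per dataset — with per-fold AUCs
retained and a 200-replicate percentile bootstrap CI over the pooled
score/truth pairs. `subset_and_apply` emulates restricting the region
panel to an external probe set: matrix regions with ≥ 1 bp positional
intersection are kept and the model is retrained and re-cross-validated
on the reduced panel (retraining, rather than feature-masked application,
is the default because tree ensembles do not marginalize absent features).

## Pipeline (`pipeline` / `mdmrkit` CLI)

Stages (simulate → call-dmrs → mdmr → matrix → classify; concord and
pmdscan as standalone subcommands) run in dependency order, each writing
its outputs under the run directory and skipping itself when outputs are
already present, so deleting only a late stage's outputs and rerunning
regenerates exactly those. A JSON manifest records per-stage parameters
and output SHA-256 hashes. All randomness derives from one global seed via
per-stage seeds `(seed · 2654435761 + crc32(stage)) mod 2^31`.

## Fixture sizes and numerical choices

Tests and the acceptance script run scaled-down cohorts chosen as the
package's standard fixtures: 2 chromosomes × 6000 CpGs with 12
tumor/normal pairs and 20 planted regions per direction for the
recovery/classification chain; 2 × 6000 CpGs with 80 planted regions for
cfDNA sweeps; one 10 Mb chromosome × 50k CpGs for domain scanning. At
these sizes the planted-recovery chain recovers 20/20 regions per
direction with base-level Jaccard ≥ 0.9, null cohorts yield zero consensus
regions, and the classifier reaches AUC 1.0 with a permutation null at
0.5.

Degenerate inputs are handled explicitly: zero-coverage CpGs are undefined
(never beta 0), empty DMR sets give NaN directionality fractions, an
all-constant beta matrix yields an empty variable-region selection with a
warning, and missing annotation sets label regions as unannotated rather
than open sea.

## Known limitations

- The DMR caller's seed threshold (0.10) and gap (300 bp) are declared
  approximations of kernel-caller granularity, not a reimplementation of
  any specific tool; absolute DMR counts are not comparable across
  callers.
- Sparse-CpG regions (open sea at < 1 CpG / 300 bp) are structurally
  uncallable under the gap rule — a property shared with CpG-run-based
  callers generally.
- The cfDNA model is a two-component mixture with a single global tumor
  fraction; no fragmentomics, no multi-tissue deconvolution.
- Domain detection assumes roughly uniform CpG density per bin; long
  CpG-free gaps register as interruptions, which can clip domain ends by
  up to one bin.
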