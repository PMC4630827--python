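# Methods

This note documents the models and procedures implemented in
`multicnv`, the choices made where the design was genuinely open, and
what the synthetic cohorts do and do not establish about real data.

## Problem setting

A multiallelic CNV is a genomic segment whose diploid copy number N
varies between individuals over many recurrent states (at the human
beta-defensin locus, commonly 2–8). Given exome sequencing of a cohort,
two questions are asked per sample: (i) what is N, and (ii) at each
variable nucleotide site inside the region, how many of the N copies
carry the alternate base (j out of N)? The read-depth signal answers
(i); the alternate-read fraction, interpreted at ploidy N, answers (ii).

## Targets and depth

Exon intervals (0-based half-open internally; 1-based GFF input is
converted on load) are extended by `flank` = 300 bp on each side; exon
pairs whose genomic gap is strictly less than `merge_gap` = 600 bp are
merged into one contiguous target, unioning their gene attributions.
The strict inequality means two flank-extended exons that exactly abut
(gap = 600) remain separate targets; users wanting looser merging raise
`merge_gap`. Flanks clip at coordinate 0; right ends are not clipped,
which keeps the module free of any assembly-length dependency.
Identical intervals are deduplicated before flanking (overlapping
transcript annotations otherwise double-count depth).

## Normalization: RPKM → ZRPKM → SVD-ZRPKM

RPKM(t, s) = counts(t, s) / (length_kb(t) · total_reads(s)/10⁶).
Samples whose mean RPKM over all targets is strictly below 50 are
discarded before anything else (order chosen because the depth-QC cut
precedes calling in the workflow this package automates). Within one
batch — samples sharing a sequencing centre and continental group —
each target row is standardized: location = median, scale = sample
standard deviation across the batch (the robust-location/sd convention
of exome SRD pipelines; no log transform). Zero-scale targets carry no
dosage information and are excluded with a warning rather than imputed.

The standardized matrix Z is decomposed by SVD and rebuilt with its k
largest singular values zeroed. The leading components capture
centre-specific enrichment structure shared across targets; the dosage
signal of a compact CNV block, confined to a minority of targets,
survives removal. Singular vectors are sign-fixed (largest-magnitude
entry of each left vector positive) so reported components are
reproducible; the reconstruction is unaffected.

**Choosing k.** The scree heuristic takes k at the largest relative
drop (σᵢ − σᵢ₊₁)/σ₁, capped at `max_components` (default 5) — a
reproducible stand-in for reading the scree plot's shoulder by eye.
This heuristic can mis-fire when the CNV signal itself is a large
variance component (few targets outside the block): it then proposes
removing the dosage component. The default mode therefore validates k
against anchors: every k in 1..max_components is fitted and the k with
the best anchor agreement wins, ties broken by the batch's
confident-call proportion (a quantitative stand-in for judging cluster
sharpness by eye), then by smaller k. k = 0 is never a candidate in
this mode — removing at least one component is what makes the
normalization batch-portable. A fixed integer or per-batch mapping
overrides both modes.

## Mixture model

For one batch, the per-sample dosage signal x (mean SVD-ZRPKM over all
targets of the block genes, each target weighted once — genes with more
exons contribute proportionally more evidence) is modelled as a mixture
over integer copy numbers c ∈ [c_min, c_max] = [2, 8]:

    x | c ~ Normal(β₀ + β₁·c, σ²),  weights w_c.

Means linear in c with a shared σ keep seven components identifiable on
batches of ~100–300 samples; richer variance structures are not
supported (the choice is recorded in the model JSON). EM maximizes the
constrained likelihood; the M-step for (β₀, β₁) is a
responsibility-weighted least-squares of x on c. Ten restarts (child
seeds from the master seed) guard against local optima; restarts that
collapse (σ → 0) or fit β₁ ≤ 0 are discarded; all restarts failing is
an error carrying diagnostics. Batches below `min_batch_size` (10) are
flagged and skipped rather than crashing a run.

Component indices are relative until anchored. With anchor samples
(copy numbers known from an orthogonal assay such as a triplex
paralogue ratio test), the integer offset maximizing anchor agreement
is applied; agreement below 50% raises "anchoring failed". Without
anchors, the highest-weight component is aligned to `modal_cn`
(default 4, the locus's modal copy number in most continental groups;
a batch of predominantly sub-Saharan African ancestry should pass 5).
Posterior ties break to the lower copy number. A call is *confident*
iff its posterior is strictly greater than 0.95.

Batches must not be pooled across centres: the per-target
standardization slope and offset differ between centres, so a pooled
fit smears the clusters. The package reproduces this as a measurable
drop in the confident-call proportion when two simulated centre batches
are fitted jointly.

## Boundary delineation

Per gene, the mean SVD-ZRPKM over its targets gives one value per
sample; genes on the CNV block co-vary. The genes × genes matrix of
squared Pearson correlations is always emitted in genomic order for
visual inspection; the reproducible block rule declares a gene in-block
when its mean r² against a set of seed genes (block members known a
priori) reaches `r2_threshold` (default 0.5). Zero-variance genes get
missing entries, excluded from means rather than counted as 0. r² is
sign-blind by construction; a gene anti-correlated with the block would
be admitted, which is the intended behaviour for a dosage metric.
Cross-mapping contamination (reads from segmental duplications mixing
an unrelated dosage signal into a gene) attenuates r² monotonically in
the contamination weight — the expected signature of genes at block
edges inside repeat-rich sequence.

## Ploidy-aware genotyping

At a site with ref/alt tallies (n_ref, n_alt) surviving the read
filters (base quality ≥ 30 AND mapping quality ≥ 50, both inclusive —
"minimum" thresholds are read as inclusive), the likelihood of j
alternate copies out of N is

    L(j) = Binomial(n_alt; n_alt + n_ref, p_j),
    p_j = (j/N)(1 − ε) + (1 − j/N)·ε,

with a flat prior over j and ε the post-filter per-read error rate
(default 0.005, roughly the residual error expected after a q30 base
filter; configurable). The MAP j is reported, ties to lower j. This is
a deliberate site-level simplification of haplotype-based callers: the
package reproduces the ploidy-awareness and the evidence thresholds —
a variant needs n_alt ≥ 10 and n_alt/(n_alt+n_ref) ≥ 0.10 — not
haplotype-window realignment. The fraction filter's design consequence
is visible at high copy number: one alternate copy in 8 predicts
0.125 ≥ 0.10 and passes, while sub-threshold contamination does not.
Genotypes serialize to VCF 4.2 with per-sample `CN` (ploidy) and `ACN`
(j) FORMAT fields; multi-allelic sites decompose into per-alt biallelic
records.

## Clone-count validation

Cloning a PCR product across a variant site and scoring single-molecule
clones by restriction digest yields (uncut, cut) counts per
sample/variant; uncut marks the variant allele. The uncut proportion
gets an exact binomial (Clopper-Pearson) CI from beta quantiles:
lower = 0 at x = 0, upper = 1 at x = n, otherwise the equal-tailed
bounds. Printed tables round to 2 dp half-away-from-zero; consistency
checks always use unrounded values. The exome genotype is consistent
when j/N lies inside the CI. Samples homozygous for the cut allele
estimate the background digest-failure rate (pooled across controls);
that rate floors the expected fraction, so a control's own residual
uncut clones do not count against it. When clone data disagree with the
exome copy number, `best_supported_n` reports the candidate N (exome
call plus any recorded orthogonal-assay call) whose nearest attainable
fraction j'/N is closest to the observed proportion. On the packaged
validation table, strict CI membership flags three rows: the known
copy-number miscall (0.11 observed vs 0.25 expected; best supported by
N = 6), and two one-copy-of-many genotypes (expected 1/5 and 1/6) whose
clone proportions run low — a looser verbal notion of consistency would
pass them, the exact criterion does not; both verdicts are reported so
the reader can apply either standard.

## Frequency-spectrum selection screen

Variant frequency in a multicopy region is copy-weighted:
f = Σ_s j_s / Σ_s N_s over a group's samples — the natural analogue of
allele frequency when samples contribute different copy numbers. Per
continental group, the non-synonymous and synonymous frequency lists
(pooled across the block's genes; effect labels arrive as input) are
compared with the k-sample Anderson-Darling test in the tie-adjusted
midrank form — frequencies tie heavily at low counts, making the
midrank version essential. The statistic is standardized by the
published variance formula. The default p-value is from label
permutations (10,000; exact enumeration is substituted automatically
when the number of distinct assignments is smaller), deterministic
given the seed; an asymptotic interpolation of the published percentile
table is available but unreliable at single-gene-family sample sizes.
Groups with fewer than two variants in either class are flagged
untestable rather than erroring.

## Synthetic cohorts

The generator emulates a multi-centre exome cohort over the locus:

- **Copy-number states** 2–8 with per-group frequencies shaped like the
  locus's published distribution (mode 4; mode 5 for the African-like
  group; upper tail thinning to 8). The frequencies are configuration,
  not claims.
- **Geometry**: 6 block genes × 4 targets and 30 diploid genes × 5
  targets by default (~174 merged targets) — a desk-scale stand-in for
  "all chromosome 8 exons" that keeps the dosage component subordinate
  to the artifact component in the SVD, as in the full-size data.
- **Expected counts**: depth_scale (default 100, the expected RPKM of a
  diploid target) × target length × library size × (dosage/2 for block
  targets, 1 otherwise) × per-(centre, target) gain
  (log-sd 0.15) × exp(artifact), with a rank-1 (configurable) artifact
  field exp(strength·u_t·v_s), strength 0.25. Multiplicative artifacts
  become approximately additive after per-target standardization —
  exactly the structure SVD removal targets — and the per-centre gains
  give pooled batches the slope/offset mismatch that degrades merged
  fits.
- **Noise**: the dominant term is a per-sample continuous dosage jitter
  of sd 0.15 copy-number units (biological/technical dosage noise);
  counts are negative-binomial with dispersion 0.005 (Poisson at 0),
  contributing ~0.07 CN after averaging over the block. 3% of samples
  are simulated at deep-undercoverage and exercise the RPKM filter.
- **Allele reads and clones** are binomial draws at p_j and at
  fraction + (1 − fraction)·background respectively.

Everything is deterministic given the master seed; per-batch and
per-sample streams derive from it.

**What passing tests show, and what they do not.** The simulator
realizes the variance structure the method assumes: low-rank
multiplicative artifacts, count noise, dosage jitter, a compact block.
Real exome data add GC- and bait-dependent enrichment bias (not
modelled, and not corrected by the pipeline), cross-mapping from
segmental duplications (modelled only as an abstract contamination
mixture in the boundary tests), alignment ambiguity, and batches whose
artifact structure is not low-rank. Recovery rates measured here
(≥ 95% correct integer CN at 170-sample batches with ~0.15-CN dosage
noise) are therefore a statement about the estimator under its own
assumptions, not a field accuracy claim.

## Problem sizes and numerical choices

Test and acceptance runs use two batches of 170 samples (typical of
per-centre/per-group batch sizes for this locus), 200 genotype
replicates per (j, N) at depth 150, and 500 replicates × 999
permutations for the null-calibration of the frequency-spectrum test —
sizes chosen so the full suite completes in about a minute on one CPU.
EM convergence is |Δ log L| < 10⁻⁸(1 + |log L|) with ≤ 500 iterations;
underflow in the genotype posterior falls back to log-space
normalization; degenerate inputs (zero matrices, constant targets,
empty groups) return defined results or named errors as documented per
function.

## Known limitations

- No GC/mappability correction; enrichment bias propagates into the
  signal and is only partially absorbed by component removal.
- The caller is site-level; linked sites are genotyped independently
  and no haplotypes are reconstructed.
- Absolute anchoring without controls rests entirely on the modal-CN
  assumption; a batch whose true mode differs will be offset by an
  integer.
- The boundary rule assumes the seed genes are truly on the block;
  seeding with an off-block gene inverts the test's meaning.
- Copy numbers outside [c_min, c_max] are forced to the nearest
  modelled state.
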