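# Methods

## The statistic and its null model

The test treats an LD block — a connected component of the r² > 0.1 graph on
a pathway's SNPs — as one unit of evidence. Each block contributes the
upper-tail χ²(1 df) quantile of its minimum SNP P-value, and the pathway
score S_obs is the sum over its n blocks. Taking a block minimum without a
within-block multiplicity adjustment biases every block statistic upward;
this is intentional. The permutation pool is built from the block statistics
of *all* analyzed pathways, produced by the identical mapping → blocking →
scoring procedure, so pool draws carry exactly the same min-P bias and block
size mixture. Significance is the tail probability of S_obs among sums of n
pool draws, estimated as (n_exceed + 1)/(N + 1).

For the same reason no analytic null is offered: under n independent blocks
with uniform representative P-values, S would be χ²(n) (verified by the
moment tests), but realized block minima are not uniform — the analytic null
would be anti-conservative, and only the permutation pool defines the test.

Design choices where the procedure was genuinely open:

* **Blocking rule.** "Pairwise r² above threshold joins a block" is read as
  single-linkage transitive closure (union–find over the edge list). The
  comparison is strict (r² = 0.1 does not join at threshold 0.1).
  Cross-chromosome r² is forced to 0; SNPs absent from the LD source become
  singleton blocks (absence is no evidence of LD, and dropping them would
  bias against sparsely genotyped regions). No physical-distance window is
  imposed — locality is the LD input's job.
* **Pool sampling.** Within one permutation, blocks are drawn *without*
  replacement (a pathway cannot contain the same block twice); permutations
  are independent redraws. A genomic block reached through several pathways
  sits in the pool once per pathway, weighting the pool by usage. A
  `sampling_mode="with"` switch exists for pathways larger than the pool.
* **Adaptive stopping.** The estimate is checked only at stage boundaries
  (10³, 10⁴, 10⁵, 10⁶ draws); stopping within a stage would bias the
  estimator. Stopping once the interim estimate exceeds 0.05 is safe for
  genuinely significant pathways: at the first boundary a pathway with true
  tail probability ≤ 0.025 trips the rule with probability ≈ 2 × 10⁻⁶.
* **Determinism.** Each pathway draws from a substream seeded by a SHA-256
  hash of (master seed, pathway id), so results are independent of
  iteration order and safe to parallelize. Representative-SNP ties break to
  the lexicographically smallest id.
* **Gene scope.** The `scope="gene"` variant blocks each member gene's SNPs
  separately and concatenates; a SNP mapped to two member genes contributes
  to both genes' blocks. Its pool is rebuilt at gene scope — observed scores
  are never compared against a pool from the other scope.

## Mapping parameters

| parameter | default | meaning |
|---|---|---|
| `flank_bp` | 15,000 | window extension on both sides of the merged gene span (the distance within which most eQTL SNPs fall); strand-independent because both extensions are equal |
| `r2_threshold` | 0.1 | strict lower bound for an LD edge |
| `min_genes`, `max_genes` | 5, 300 | pathway-size filter, counted **after** intersecting with mappable genes (unmappable symbols cannot contribute SNPs) |
| `bin_cutpoints` | (10, 17, 37) | size-quartile edges of the reference collection, bins [5,9], [10,16], [17,36], [37,300]; `None` uses the current collection's empirical quartiles |
| `alpha_stop` | 0.05 | adaptive early-stop level (`None` disables) |

Isoform handling: intervals sharing at least one base pair are unioned
(abutting intervals are not); when disjoint clusters remain, the cluster
whose flanked window holds the lowest-P SNP is kept, with ties going to the
longer then leftmost cluster, and the longest cluster kept when no window
contains a SNP. Coordinates are 1-based closed throughout; BED input is
converted on read. P = 0 is rejected by default (the χ² conversion diverges)
or clamped to 1e-300 with `clamp_zero`; the same floor caps underflow inside
the conversion, keeping S_obs finite.

r² from genotypes is the squared Pearson correlation of dosage columns.
Haplotype-phase (EM) r², as genotype tools compute by default, is not
reproducible from dosages alone; squared dosage correlation is the standard
deterministic approximation and is the definition used throughout.

## Evaluation designs

**Type I error.** Random pathways are assembled by sampling genes uniformly
without replacement, with sizes resampled from an empirical size
distribution so all four size bins are populated. This breaks biological
gene groupings while leaving the LD structure and every SNP's P-value
untouched; the fraction of random pathways with association P below a
nominal level is the empirical type I error, reported per size bin with
Wilson 95% intervals.

**Power.** Each pathway's SNP P-values are multiplied by the single factor
f = 0.05/p₍ₖ₎ · (1 − 10⁻⁹), k = ⌈fraction · n_SNPs⌉, making the smallest
attainable fraction ≥ the target strictly significant (scaled values capped
at 1; the 10⁻⁹ nudge keeps the k-th value strictly below 0.05). Blocking
depends only on LD, so blocks are reused; the rescored S_obs is tested
against the **unscaled** pool. Scaling the pool too would cancel the
experiment, and the ceiling rule means even a 5% target slightly enriches
small pathways — the low-fraction end of a power curve is not an exact null.

## The synthetic-data generator

Fixtures emulate the statistical shape of real inputs, not their biology:

* **Genotypes.** Each latent block copies a Bernoulli(½) haplotype pair with
  per-SNP flip probability e = (1 − w^{1/4})/2, giving expected within-block
  dosage r² = w (realized mean within ±0.1 at 300 samples); between-block r²
  is sampling noise (~1/n_samples). A configurable fraction of adjacent gene
  pairs share one boundary-spanning block — the feature that makes pathway
  and gene scope differ.
* **Null statistics.** Either i.i.d. uniform, or "ld_coupled": a one-factor
  Gaussian copula per true block with loading √ρ (default ρ = 0.5), so block
  members share their signal the way LD couples real association statistics
  while marginals stay exactly uniform.
* **Enriched statistics.** Each enriched pathway's SNPs are redrawn from a
  mixture: with probability equal to the target fraction, from a
  concentrated small-P component on (0, 0.05); otherwise uniform on
  (0.05, 1). The expected significant fraction equals the target exactly.

What the generator does **not** model: allele-frequency spectra, distance-
decaying LD, overlapping genes on real genomic scales, or signed effect
sizes. Passing calibration tests on these fixtures shows the *procedure* is
exchangeability-calibrated and LD-robust in the stylized regime; it does not
certify behavior under real LD panels.

## The calibration experiment and problem sizes

The standard experiment (`reference_null_experiment`, also what
`scripts/acceptance.py` runs) uses a 2-chromosome, 200-gene genome with 4–10
SNPs per gene (~1,400 SNPs, ~2,800 blocks), within-block r² 0.5, 20%
cross-gene shared blocks, ld_coupled null statistics, 500 random pathways
with log-uniform sizes 5–200, and 10,000-draw permutation stages. Because
all random pathways of one dataset share a single realization of the block
statistics, one dataset estimates only a dataset-conditional rate, with an
irreducible spread of a percentage point or more; the experiment therefore
pools 8 independent replicates (4,000 random pathways total), which brings
the Monte-Carlo standard error of per-bin rates well under half a
percentage point. At these sizes the experiment runs in about two minutes
on one CPU.

The test is mildly conservative by construction: pool sampling can draw
duplicate copies of one genomic block, inflating permuted-score variance
relative to an observed pathway of distinct blocks, so the empirical type I
error at nominal 0.05 lands near 2–3% rather than 5%. The effect grows with
the fraction of the genome a pathway covers; on the 200-gene desk-scale
genome the largest size bin (37–200 genes) is therefore the most
conservative (~1.5%). On a realistically sized genome (tens of thousands of
genes) pathways cover a tiny genome fraction and the bins flatten.

## Known limitations

* Gene symbols must match between the annotation table and the GMT file; no
  alias resolution.
* No VCF input, no liftover, no haplotype-based r² or D′/Gabriel block
  definitions.
* The multiple-testing helper is plain Bonferroni (family alpha divided by
  the pathway count — 0.05/5764 ≈ 8.7 × 10⁻⁶ for the reference collection);
  no FDR variant.
* Pathways whose genes map no SNPs are reported as non-testable rather than
  scored.
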