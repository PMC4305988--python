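# Methods

## Coordinates, promoters and profiles

All genomic coordinates are handled internally as 1-based inclusive
intervals (the GFF convention); BED input is converted from 0-based
half-open on read and the conversion is exposed (and property-tested) as
a bijection. TF and gene identifiers are upper-cased on read because
curated regulation evidence mixes capitalization styles.

A gene's **promoter** is the intergenic interval between the gene and
its nearest upstream gene whose *coding span* does not overlap the
focal gene's, taken in the focal gene's direction of transcription:
`[neighbor.cds_end + 1, cds_start − 1]` for a forward-strand gene and
`[cds_end + 1, neighbor.cds_start − 1]` for a reverse-strand gene. The
neighbor's own strand is irrelevant. A gene with no upstream neighbor is
bounded by position 1 (forward) or by the chromosome length (reverse);
when no chromosome length is supplied, the last annotated coordinate on
the chromosome stands in, which gives the chromosome's final
reverse-strand gene an empty promoter rather than an arbitrary one.
Zero-length promoters are retained; such genes can never receive a site
and drop out of evaluation with the other site-less genes. There is no
default cap on promoter length; `max_length` truncates the upstream
(far) end when set.

Two genes form a **head-to-head pair** when they are divergently
transcribed on the same chromosome (the reverse-strand gene on the
lower-coordinate side) and their promoter intervals overlap by ≥ 1 bp.
Such pairs share regulatory sequence, so their similarity is trivially
inflated and they are excluded from pair-level evaluation.

A TFBS is assigned to every promoter containing its **midpoint**
(`floor((start+end)/2)`); the anchor is switchable to the interval start
or end for sensitivity analysis, since nothing in the method pins down
which point of a site should carry its position. Midpoint containment
(rather than full containment) avoids discarding sites that straddle a
promoter edge; midpoint anchoring is symmetric and robust to site
length. A site in a shared (head-to-head) intergenic interval belongs to
both flanking promoters, each with its own offset — the two genes share
the promoter, so the assigned-placement count can exceed the input site
count. The **offset** of a site is the distance in bp from the
translation start site to the anchor point, increasing toward the
upstream end; offsets therefore lie in [1, L]. TFBS strand is ignored
throughout.

## The location-aware RS measure

With promoters aligned at their start codons, for each TF common to the
two profiles the **offset distance** d_i is the minimum |o_a − o_b| over
that TF's site offsets in the two promoters (computed by a linear merge
of the sorted offset lists). The score is

    RS(a, b) = (1 / |TF_a ∪ TF_b|) · Σ_{i ∈ TF_a ∩ TF_b} (L − d_i)/L,
    L = max(L_a, L_b).

Properties relied on by tests: RS ∈ [0, 1]; RS = Jaccard(TF_a, TF_b)
iff every common TF has d_i = 0, and RS ≤ Jaccard otherwise; RS is
non-increasing in each d_i; shifting both offset lists by a constant
leaves RS unchanged. When both TF sets are empty the configurable
`empty_union_score` (default 0) is returned — evaluation never produces
this case because site-less genes are dropped first, but user queries
can. The common-TF sum runs in sorted TF order so results are
bit-reproducible and exactly symmetric in the two genes.

## Baseline measures

* **Hypergeometric overlap** (`garten`): −log₁₀ of the cumulative
  hypergeometric tail P(X ≥ k) for overlap k between TF sets of sizes m
  and n drawn from a population of N TFs (scipy's `hypergeom.sf`). The
  log base is a convention — the measure is rank-equivalent under any
  base — and is configurable. N defaults to the number of distinct TFs
  observed in the loaded data, overridable in `RSConfig`. k = 0 gives
  p = 1 and score 0; p is floored at the smallest positive double before
  the log.
* **Jaccard** (`jaccard`) and **min-normalized overlap** (`shalgi`):
  |∩|/|∪| and |∩|/min(|TF_a|,|TF_b|). Shalgi ≥ Jaccard always.
* **Copy-weighted agreement** (`park`): per TF with site counts N1, N2
  and shared copies C = min(N1, N2),
  `γ Σ_{C>0} [(f − ½)² (N1+N2) + α C] − β Σ_{C=0} (N1+N2)` with
  f = N1/(N1+N2); defaults α = 1, β = 0.5, γ = 1. The published rendering
  of this measure is typographically ambiguous; this package implements
  its stated intent — copy-number-weighted agreement with a penalty for
  one-sided TFs, the condition index collapsed for single-condition
  data — and asserts only symmetry and the closed-form corner cases, not
  numeric equivalence to the original.
* **Poisson similarity/dissimilarity** (`vanhelden`):
  M_ab = S_ab − α·D_ab + β. The background model is not uniquely
  determined in the literature; here each TF gets a genome-wide per-bp
  rate λ_t = (its total assigned sites)/(total promoter length), a
  promoter of length L contains it with probability 1 − exp(−λ_t L), the
  expected common-TF count of a pair is the sum over TFs of the product
  of the two presence probabilities, S_ab = P(X < c) for the observed
  common count c under a Poisson with that mean, and D_ab = |p_a − p_b|
  with p_g the Poisson upper tail of promoter g's own site count at the
  summed rate. Defaults α = 1, β = 0 make M = S − D.

All six are exactly symmetric in the gene order, verified by property
tests over random profiles.

## Evaluation protocols

**Bucket analysis.** For each TF t and each unordered pair of genes
whose promoters both carry t, the tuple ⟨t, a, b⟩ lands in the bucket of
its offset distance. The per-bucket co-regulation ratio is the fraction
of tuples for which the evidence set contains both (t, a) and (t, b).
Defaults: 1-bp buckets, buckets with fewer than 30 tuples dropped
(sparse distant buckets are dominated by sampling noise). The
distance–ratio relation is summarized by an OLS fit (slope, intercept,
R²), using each bucket's left edge as its abscissa.

**Binned calibration.** Pairs are sampled without replacement
(default 10⁶, falling back to the full set with a warning when fewer
exist; the sample is trimmed to a multiple of the bin count so bins stay
equal), sorted by score with a stable sort, and split into 50
equal-occupancy bins; each bin contributes (mean score, fraction of
co-regulated pairs). A pair is **co-regulated** when at least one TF
common to both promoters has evidence for both genes. Points are
averaged over replicates (default 100); replicate r draws from the
deterministic stream seeded by (seed, r), so runs are bit-reproducible
and two measures evaluated with the same seed on the same pair universe
see identical samples — a paired design. The curve's quality is the
squared Spearman rank correlation of its 50 points (squaring discards
the sign, so a perfectly decreasing curve also scores 1; ties get
average ranks). Per-replicate R² values are retained and compared
between measures with a two-sided paired Wilcoxon signed-rank test
(paired t-test available); all-zero differences are reported as p = 1
with an `all_tied` flag rather than an error.

**Quality sweep.** For each posterior cutoff (inclusive, matching the
read-time filter): sites retained, genes with ≥ 1 assigned site, and
density = sites/genes rounded to one decimal. Site counts are
non-increasing in the cutoff by construction.

**Regulatory neighborhood and CES.** The RN of a target is the n genes
with the highest RS to it, ties at the boundary broken lexicographically
so results are deterministic. CES is the mean pairwise Pearson
correlation of the members' expression vectors (Spearman optional);
pairs involving a constant vector are excluded with a warning. Pearson
was chosen because the co-expression literature's default is linear
correlation on log-scale expression; CES inherits Pearson's invariance
to per-gene affine rescaling.

## Synthetic data generator

The generator emulates the four inputs (annotation, TFBS with
posteriors, evidence pairs, expression) with the structure the method
assumes, and exposes the ground truth for recovery tests.

* **Layout** — genes are placed left to right per chromosome with
  alternating strands (reverse first), lengths uniform in 500–1500 bp
  and intergenic gaps uniform in 400–1200 bp, so every other adjacent
  pair is a divergent head-to-head pair sharing its gap. An optional
  `chromosome_length` budget turns an overflowing layout into a
  validation error.
* **Sites** — each TF receives a preferred position uniform in
  100–350 bp upstream of the start codon. Per TF × gene, with
  probability 0.15 a *functional* site is planted at the preferred
  position plus N(0, 120 bp) noise, clipped into the promoter; the
  (TF, gene) pair is recorded as regulating. Decoys are planted
  uniformly, Poisson(0.75) per promoter. Posteriors are Beta(5, 2) for
  functional sites and Beta(2, 5) for decoys, so posterior cutoffs
  preferentially remove decoys.
* **Evidence** — a regulating pair survives into the evidence set with
  probability exp(−2·|offset − center|/scale), scale 1000 bp. Evidence
  is a (TF, gene) set, so a literal pairwise retention rule is
  ill-defined; this per-gene decay from the TF's preferred position
  makes two planted sites at offset distance d keep *joint* evidence
  with probability ≈ exp(−Θ(d)/scale), which is the mechanism the
  bucket analysis measures. Membership is then flipped uniformly at
  rate 0.02 (label noise). The decay scale is large relative to the
  spread of planted distances, so the decline is locally linear over
  the distance range where buckets retain ≥ 30 tuples — the sparse
  decoy-dominated tail falls below that threshold and is dropped —
  giving bucket tables whose OLS fit has negative slope and R² ≈
  0.72–0.84 across seeds.
* **Expression** — each TF is assigned to one of 8 latent modules with
  N(0, 1) condition programs (20 conditions); a gene inherits the
  program of one of its regulating TFs plus N(0, 0.5) noise, genes with
  no regulating TF get pure noise around 0. Co-regulated genes thereby
  share expression programs, which is what CES rewards.

Everything is a deterministic function of the config seed, including
file bytes written by `write_fixture`.

**What passing on synthetic data does and does not show.** The generator
plants exactly the structure the location-aware measure assumes — a
single positional window per TF, independent sites, evidence decaying
with displacement. Real promoter biology has TF-dependent window shapes,
nucleosome and conservation effects, correlated sites, strand and
distance preferences that vary by TF family, and evidence whose
ascertainment is biased toward well-studied genes. Passing recovery
tests shows the implementation is correct and the measure exploits
positional signal when it exists; it does not show how much such signal
real data carries, and published R² values obtained on specific
annotation/TFBS/evidence snapshots are not reproduced here.

## Numerical and degenerate-input choices

* Posterior cutoff is inclusive (keep ≥ cutoff).
* Empty promoters are legal (L = 0, p_start > p_end); a common TF with
  L = 0 is impossible by construction and asserted.
* `score_all_pairs` drops empty profiles first, then forms all
  unordered pairs minus exclusions; `count_only=True` does the
  arithmetic without scoring, so counting a 6,604-gene universe is
  instant.
* Calibration with constant scores yields seed-dependent bin membership;
  replicate averaging converges to the global co-regulation rate, and
  undefined rank correlations are recorded as 0.
* Hypergeometric p-values are floored at the smallest positive double;
  Wilcoxon on all-tied replicates reports p = 1 with a flag.

## Problem sizes used in tests and the acceptance script

Tests and the acceptance script run on 300-gene, 12-TF genomes (the
generator default), 20 seeds, calibration with 20,000 sampled pairs ×
50 bins × 10 replicates. These sizes were chosen as the smallest at
which the planted signal is comfortably above sampling noise; the
machinery itself is linear in sites and quadratic in genes per
chromosome and handles genome-scale inputs (the 19.5-million-pair
universe is exercised in count mode).

## Known limitations

* The copy-weighted (`park`) and Poisson (`vanhelden`) baselines are
  interpretations of ambiguously published formulas; only their
  rank-level behaviour should be compared across implementations.
* Offsets are anchored at the translation start codon, not the
  transcription start site; 5′ UTR lengths are not modeled.
* The per-TF Poisson background treats sites as independent, which
  underestimates clumping of real binding sites.
* `detect_head_to_head` keys on promoter-interval overlap; annotations
  with nested or overlapping coding spans may yield divergent pairs
  whose shared sequence is not flagged when a promoter is empty.
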