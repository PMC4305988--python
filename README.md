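# regsim

Location-aware **regulatory similarity** (RS) scoring of gene pairs from
promoter maps of transcription-factor binding sites (TFBSs).

## The problem

Identifying co-regulated genes usually starts from a pairwise regulatory
similarity score. Classic TFBS-based scores treat a promoter as a *set*
of bound transcription factors (TFs) and compare sets — by hypergeometric
overlap significance, Jaccard index, minimum-normalized overlap, or
copy-count variants. They ignore *where* in the promoter each TF binds,
even though functional binding sites of many TFs (in budding yeast in
particular) cluster in characteristic positional windows upstream of the
translation start site.

`regsim` implements a location-aware score. Promoters of two genes *a*
and *b* are aligned at their start codons; for each common TF *i*, let
*d_i* be the smallest distance between any of its sites in the two
promoters (the *TFBS offset distance*), and let *L* = max(*L_a*, *L_b*)
be the longer promoter length. Then

```
RS(a, b) = (1 / |TF_a ∪ TF_b|) · Σ_{i ∈ TF_a ∩ TF_b} (L − d_i) / L
```

A common TF whose sites sit in the same positional window contributes
nearly 1/|union|; one whose sites are far apart contributes little. The
score lives in [0, 1], equals the Jaccard index exactly when every
common TF has *d‚Çç* = 0, and is never larger than it.

The package also ships the five set-based baselines (`garten`,
`jaccard`, `shalgi`, `park`, `vanhelden`), the evaluation protocols used
to compare them (offset-distance bucket analysis, equal-occupancy binned
calibration with Spearman rank R², paired significance tests,
posterior-cutoff sweeps), regulatory-neighborhood extraction with a
co-expression score (CES), and a synthetic-genome generator that plants
positional regulatory signal so the whole pipeline is testable without
downloading annotation, SwissRegulon-style TFBS, or YEASTRACT-style
evidence snapshots — though parsers for all of those formats are
included.

## Worked example

```python
import regsim as rs

# a 300-gene, 12-TF genome with planted positional preference
ds = rs.generate(rs.SyntheticConfig(seed=1))

promoters = rs.extract_promoters(ds.genes)
profiles = rs.build_profiles(promoters, ds.tfbs)
head_to_head = rs.detect_head_to_head(promoters)   # divergent pairs sharing a promoter
table = rs.score_all_pairs(profiles, ["proposed", "jaccard"], exclusions=head_to_head)
print(len(table), "gene pairs scored")

labels = rs.label_coregulation(table, profiles, ds.evidence)
curve = rs.binned_calibration(table["proposed"].to_numpy(float), labels,
                              sample_size=20_000, n_replicates=10, seed=1)
print("Spearman R^2 (proposed):", round(rs.spearman_r2(curve), 3))

buckets = rs.bucket_analysis(profiles, ds.evidence)
slope, intercept, r2 = rs.fit_linear_r2(buckets)
print("bucket decline: slope", f"{slope:.2e}", "linear R^2", round(r2, 3))
```

prints

```
44700 gene pairs scored
Spearman R^2 (proposed): 0.985
bucket decline: slope -3.92e-04 linear R^2 0.807
```

44,700 is C(300, 2) minus the 150 divergent head-to-head pairs. The
calibration curve sorts sampled pairs by score into 50 equal bins and
plots each bin's mean score against its fraction of literature-supported
co-regulated pairs: a Spearman R² near 1 means the score ranks pairs by
co-regulation probability almost perfectly. The bucket analysis shows
the co-regulation fraction of (TF, gene-pair) tuples falling roughly
linearly with the TFBS offset distance — the positional signal the
measure exploits.

The same pipeline runs from the shell:

```sh
regsim make-fixture --seed 1 --out fixture/
regsim score --genes fixture/genes.gff3 --tfbs fixture/tfbs.bed \
             --min-posterior 0.0 --out run/
regsim evaluate --genes fixture/genes.gff3 --tfbs fixture/tfbs.bed \
                --evidence fixture/evidence.tsv --min-posterior 0.0 \
                --seed 1 --sample-size 20000 --n-replicates 10 \
                --random-baseline --out eval/
regsim neighborhood --genes fixture/genes.gff3 --tfbs fixture/tfbs.bed \
                    --min-posterior 0.0 --target G0007 --n 30 \
                    --expression fixture/expression.tsv --out rn.tsv
```

Every run writes a `manifest.json` (versions, parameters, seed, counts)
sufficient to reproduce its outputs byte-for-byte.

## Layout

| module | contents |
| --- | --- |
| `regsim.genome_io` | GFF3/TSV genes, BED/GFF TFBSs, evidence and expression TSVs, pair-score I/O |
| `regsim.promoter_model` | intergenic promoter extraction, head-to-head detection, TF→offset profiles |
| `regsim.rs_measures` | the location-aware RS and the five set-based baselines |
| `regsim.evaluation` | bucket analysis, binned calibration, measure comparison, quality sweep |
| `regsim.neighborhood` | regulatory neighborhoods and the co-expression score |
| `regsim.synthetic_data` | synthetic genomes with planted positional signal and ground truth |
| `regsim.cli` | `regsim score / evaluate / neighborhood / make-fixture` |

See `docs/methods.md` for the model, its assumptions, and the design
choices behind the defaults.
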