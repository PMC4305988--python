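"""Synthetic genomes with planted positional regulatory signal.

The generator emulates the four external inputs of the pipeline — gene
annotation, TFBS locations with posterior qualities, TF→gene regulation
evidence, and an expression matrix — with the statistical structure the
location-aware RS measure assumes:

* genes are laid out chromosome by chromosome with alternating strands
  and sampled intergenic gaps, so divergent (head-to-head) pairs occur;
* each TF has a preferred promoter position; functional sites are
  planted near it, so sites of the same TF in two co-regulated promoters
  sit at small offset distances;
* uniformly placed decoy sites carry no regulatory meaning and their
  posteriors are drawn from a lower-quality distribution (Beta(2,5) vs
  Beta(5,2) for functional sites), so posterior cutoffs preferentially
  remove decoys;
* literature evidence derives from the planted regulating pairs and is
  retained with a probability that decays exponentially with the site's
  displacement from the TF's preferred position — two planted sites at
  offset distance d therefore keep joint evidence with probability
  ~exp(-d/evidence_decay_scale), the mechanism behind the declining
  bucket-analysis curve;
* genes in the same regulatory module share a latent expression program
  plus noise.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import itertools
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import (
    FORWARD,
    REVERSE,
    UNKNOWN,
    GeneRecord,
    RegulationEvidence,
    TFBSRecord,
    ValidationError,
    internal_to_bed,
)

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults give a 300-gene, 12-TF genome.

    ``preference_center_range`` bounds the per-TF preferred position
    (bp upstream of the start codon) and ``preference_width`` is the
    standard deviation of planted sites around it. ``site_presence_prob``
    is the chance a TF plants a functional site in a given promoter;
    ``decoy_rate`` is the expected number of uniform decoy sites per
    promoter. ``evidence_decay_scale`` (bp) controls how fast joint
    evidence decays with offset distance; ``label_noise`` flips evidence
    membership uniformly at random.
    """

    seed: int = 0
    n_genes: int = 300
    n_tfs: int = 12
    n_chromosomes: int = 3
    gene_length_range: tuple[int, int] = (500, 1500)
    intergenic_range: tuple[int, int] = (400, 1200)
    preference_center_range: tuple[int, int] = (100, 350)
    preference_width: float = 120.0
    site_presence_prob: float = 0.15
    decoy_rate: float = 0.75
    evidence_decay_scale: float = 1000.0
    label_noise: float = 0.02
    n_conditions: int = 20
    module_count: int = 8
    site_length_range: tuple[int, int] = (7, 12)
    expression_noise_sd: float = 0.5
    chromosome_length: int | None = None

    def validate(self) -> None:
        for name in ("site_presence_prob", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name in (
            "gene_length_range",
            "intergenic_range",
            "preference_center_range",
            "site_length_range",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValidationError(f"{name}={(lo, hi)} is not a positive range")
        if self.decoy_rate < 0 or self.preference_width < 0:
            raise ValidationError("decoy_rate and preference_width must be >= 0")
        if min(self.n_genes, self.n_tfs, self.n_chromosomes, self.n_conditions) < 0:
            raise ValidationError("counts must be non-negative")
        if self.module_count < 1:
            raise ValidationError("module_count must be >= 1")
        if self.evidence_decay_scale <= 0:
            raise ValidationError("evidence_decay_scale must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic dataset.

    ``regulating_pairs`` are the (TF, gene) relations realized as planted
    functional sites (before evidence decay and label noise);
    ``coregulated_pairs`` are the gene pairs sharing >= 1 regulating TF;
    ``functional_flags`` aligns with the TFBS list (True = planted,
    False = decoy).
    """

    regulating_pairs: frozenset[tuple[str, str]]
    coregulated_pairs: frozenset[tuple[str, str]]
    functional_flags: np.ndarray


@dataclass
class SyntheticDataset:
    genes: list[GeneRecord]
    tfbs: list[TFBSRecord]
    evidence: RegulationEvidence
    expression: pd.DataFrame
    truth: SyntheticTruth
    config: SyntheticConfig = field(repr=False, default_factory=SyntheticConfig)


def _promoter_interval(
    idx: int, genes: list[GeneRecord], right_limit: int
) -> tuple[int, int]:
    """Intergenic promoter of genes[idx] within one chromosome layout
    (genes non-overlapping, sorted by coordinate)."""
    g = genes[idx]
    if g.strand == FORWARD:
        left = genes[idx - 1].cds_end + 1 if idx > 0 else 1
        return left, g.cds_start - 1
    right = genes[idx + 1].cds_start - 1 if idx + 1 < len(genes) else right_limit
    return g.cds_end + 1, right


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset; deterministic given config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- gene layout: alternating strands, sampled gaps -------------------
    genes: list[GeneRecord] = []
    per_chrom: list[list[GeneRecord]] = []
    counts = [len(chunk) for chunk in np.array_split(np.arange(config.n_genes), max(config.n_chromosomes, 1))]
    gene_no = 0
    for c, n_on_chrom in enumerate(counts, start=1):
        chrom = f"chr{c}"
        cursor = int(rng.integers(config.intergenic_range[0], config.intergenic_range[1] + 1))
        chrom_genes = []
        for i in range(n_on_chrom):
            length = int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
            strand = REVERSE if i % 2 == 0 else FORWARD
            gene_no += 1
            g = GeneRecord(
                gene_id=f"G{gene_no:04d}",
                chrom=chrom,
                strand=strand,
                cds_start=cursor,
                cds_end=cursor + length - 1,
            )
            chrom_genes.append(g)
            gap = int(rng.integers(config.intergenic_range[0], config.intergenic_range[1] + 1))
            cursor += length + gap
        if config.chromosome_length is not None and chrom_genes and chrom_genes[-1].cds_end > config.chromosome_length:
            raise ValidationError(
                f"layout infeasible: {chrom} needs {chrom_genes[-1].cds_end} bp, "
                f"budget is {config.chromosome_length}"
            )
        genes.extend(chrom_genes)
        per_chrom.append(chrom_genes)

    tf_names = [f"TF{i + 1:02d}" for i in range(config.n_tfs)]
    centers = {
        tf: int(rng.integers(config.preference_center_range[0], config.preference_center_range[1] + 1))
        for tf in tf_names
    }

    # --- planted functional sites and decoys ------------------------------
    tfbs: list[TFBSRecord] = []
    functional: list[bool] = []
    regulating: set[tuple[str, str]] = set()
    site_offsets: dict[tuple[str, str], int] = {}
    for chrom_genes in per_chrom:
        if not chrom_genes:
            continue
        right_limit = (
            config.chromosome_length
            if config.chromosome_length is not None
            else chrom_genes[-1].cds_end
        )
        for idx, g in enumerate(chrom_genes):
            p_start, p_end = _promoter_interval(idx, chrom_genes, right_limit)
            L = p_end - p_start + 1
            if L < 1:
                continue
            tss = g.cds_start if g.strand == FORWARD else g.cds_end
            for tf in tf_names:
                if rng.random() >= config.site_presence_prob:
                    continue
                offset = int(round(rng.normal(centers[tf], config.preference_width)))
                offset = min(max(offset, 1), L)
                tfbs.append(
                    _site_at_offset(g, tss, offset, tf, rng, config, posterior_ab=(5.0, 2.0))
                )
                functional.append(True)
                regulating.add((tf, g.gene_id))
                site_offsets[(tf, g.gene_id)] = offset
            for _ in range(rng.poisson(config.decoy_rate)):
                offset = int(rng.integers(1, L + 1))
                tf = tf_names[int(rng.integers(config.n_tfs))] if config.n_tfs else "TF00"
                tfbs.append(
                    _site_at_offset(g, tss, offset, tf, rng, config, posterior_ab=(2.0, 5.0))
                )
                functional.append(False)

    # --- evidence: distance decay then label noise ------------------------
    evidence_pairs: set[tuple[str, str]] = set()
    for (tf, gene_id), offset in sorted(site_offsets.items()):
        displacement = abs(offset - centers[tf])
        if rng.random() < np.exp(-2.0 * displacement / config.evidence_decay_scale):
            evidence_pairs.add((tf, gene_id))
    if config.label_noise > 0:
        for tf in tf_names:
            for g in genes:
                if rng.random() < config.label_noise:
                    evidence_pairs.symmetric_difference_update({(tf, g.gene_id)})

    coregulated = set()
    by_tf: dict[str, list[str]] = {}
    for tf, gene_id in regulating:
        by_tf.setdefault(tf, []).append(gene_id)
    for members in by_tf.values():
        members.sort()
        for a, b in itertools.combinations(members, 2):
            coregulated.add((a, b))

    # --- expression: module programs plus noise ----------------------------
    tf_module = {tf: int(rng.integers(config.module_count)) for tf in tf_names}
    latent = rng.normal(size=(config.module_count, config.n_conditions))
    rows = []
    for g in genes:
        tfs_of_g = sorted(tf for tf, gid in regulating if gid == g.gene_id)
        if tfs_of_g:
            module = tf_module[tfs_of_g[int(rng.integers(len(tfs_of_g)))]]
            base = latent[module]
        else:
            base = np.zeros(config.n_conditions)
        rows.append(base + rng.normal(0.0, config.expression_noise_sd, config.n_conditions))
    expression = pd.DataFrame(
        np.array(rows).reshape(len(genes), config.n_conditions),
        index=[g.gene_id for g in genes],
        columns=[f"C{j + 1:02d}" for j in range(config.n_conditions)],
    )

    truth = SyntheticTruth(
        regulating_pairs=frozenset(regulating),
        coregulated_pairs=frozenset(coregulated),
        functional_flags=np.array(functional, dtype=bool),
    )
    logger.info(
        "synthetic genome: %d genes, %d sites (%d functional), %d evidence pairs",
        len(genes), len(tfbs), int(truth.functional_flags.sum()), len(evidence_pairs),
    )
    return SyntheticDataset(
        genes=genes,
        tfbs=tfbs,
        evidence=RegulationEvidence(frozenset(evidence_pairs)),
        expression=expression,
        truth=truth,
        config=config,
    )


def _site_at_offset(
    gene: GeneRecord,
    tss: int,
    offset: int,
    tf: str,
    rng: np.random.Generator,
    config: SyntheticConfig,
    posterior_ab: tuple[float, float],
) -> TFBSRecord:
    """Place a site whose midpoint sits ``offset`` bp upstream of the TSS."""
    mid = tss - offset if gene.strand == FORWARD else tss + offset
    slen = int(rng.integers(config.site_length_range[0], config.site_length_range[1] + 1))
    start = mid - (slen - 1) // 2
    if start < 1:
        start = 1
    end = start + slen - 1
    posterior = float(rng.beta(*posterior_ab))
    return TFBSRecord(
        tf_name=tf, chrom=gene.chrom, strand=UNKNOWN, start=start, end=end, posterior=posterior
    )


# ---------------------------------------------------------------------------
# fixture files
# ---------------------------------------------------------------------------


def write_fixture(dataset: SyntheticDataset, directory: str) -> dict[str, str]:
    """Write the dataset in the exact external formats the readers accept.

    Emits genes.gff3 (1-based), tfbs.bed (0-based half-open, TF name and
    posterior in the name/score columns), evidence.tsv and
    expression.tsv; returns the path of each file.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "genes": os.path.join(directory, "genes.gff3"),
        "tfbs": os.path.join(directory, "tfbs.bed"),
        "evidence": os.path.join(directory, "evidence.tsv"),
        "expression": os.path.join(directory, "expression.tsv"),
    }
    with open(paths["genes"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in dataset.genes:
            fh.write(
                f"{g.chrom}\tregsim\tgene\t{g.cds_start}\t{g.cds_end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
    with open(paths["tfbs"], "w") as fh:
        for s in dataset.tfbs:
            b_start, b_end = internal_to_bed(s.start, s.end)
            fh.write(f"{s.chrom}\t{b_start}\t{b_end}\t{s.tf_name}\t{s.posterior!r}\n")
    with open(paths["evidence"], "w") as fh:
        for tf, gene_id in sorted(dataset.evidence.pairs):
            fh.write(f"{tf}\t{gene_id}\n")
    dataset.expression.to_csv(paths["expression"], sep="\t")
    return paths
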