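"""Promoter extraction and promoter-relative TFBS profiles.

A gene's promoter is the intergenic region between the gene and its
nearest non-overlapping upstream gene, where "upstream" is taken in the
gene's own direction of transcription and the promoter abuts the
translation start site (start codon). A binding site is assigned to a
promoter when its anchor point (midpoint by default) falls inside the
promoter interval, and its offset is the distance in bp from the
translation start site to that anchor, growing toward the upstream end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .genome_io import FORWARD, REVERSE, GeneRecord, TFBSRecord, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Promoter:
    """Per-gene upstream intergenic interval (1-based inclusive).

    An empty promoter (the coding spans abut) is represented with
    ``p_start > p_end`` and has ``length_L == 0``.
    """

    gene_id: str
    chrom: str
    strand: str
    p_start: int
    p_end: int
    upstream_neighbor_id: str | None = None

    @property
    def length_L(self) -> int:
        return max(0, self.p_end - self.p_start + 1)

    @property
    def tss(self) -> int:
        """Genomic coordinate of the translation start site the interval abuts."""
        return self.p_end + 1 if self.strand == FORWARD else self.p_start - 1


@dataclass
class PromoterProfile:
    """Per gene: promoter length and TF -> sorted promoter-relative offsets."""

    gene_id: str
    length_L: int
    sites: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def tf_set(self) -> frozenset[str]:
        return frozenset(self.sites)

    @property
    def n_sites(self) -> int:
        return sum(len(v) for v in self.sites.values())

    @property
    def is_empty(self) -> bool:
        return not self.sites


def _coding_overlap(a: GeneRecord, b: GeneRecord) -> bool:
    return a.cds_start <= b.cds_end and b.cds_start <= a.cds_end


def extract_promoters(
    genes: list[GeneRecord],
    chrom_lengths: dict[str, int] | None = None,
    max_length: int | None = None,
) -> list[Promoter]:
    """Derive one promoter per gene from the annotation.

    For a forward-strand gene the promoter is
    ``[upstream_neighbor.cds_end + 1, cds_start - 1]``; for a
    reverse-strand gene it is ``[cds_end + 1, neighbor.cds_start - 1]``
    with the neighbor taken on the higher-coordinate side (upstream in
    transcription direction). Neighbors whose coding span overlaps the
    focal gene's are skipped. With no upstream neighbor the promoter is
    bounded by position 1 (forward) or by the chromosome length if
    provided, else by the last annotated coordinate on the chromosome
    (reverse). ``max_length`` optionally truncates the far (upstream) end.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    promoters = []
    for chrom, chrom_genes in by_chrom.items():
        if chrom_lengths and chrom in chrom_lengths:
            right_limit = chrom_lengths[chrom]
        else:
            right_limit = max(g.cds_end for g in chrom_genes)
        for focal in chrom_genes:
            candidates = [
                g for g in chrom_genes if g is not focal and not _coding_overlap(g, focal)
            ]
            if focal.strand == FORWARD:
                ups = [g for g in candidates if g.cds_end < focal.cds_start]
                neighbor = max(ups, key=lambda g: g.cds_end, default=None)
                p_start = neighbor.cds_end + 1 if neighbor else 1
                p_end = focal.cds_start - 1
                if max_length is not None:
                    p_start = max(p_start, p_end - max_length + 1)
            else:
                downs = [g for g in candidates if g.cds_start > focal.cds_end]
                neighbor = min(downs, key=lambda g: g.cds_start, default=None)
                p_start = focal.cds_end + 1
                p_end = neighbor.cds_start - 1 if neighbor else right_limit
                if max_length is not None:
                    p_end = min(p_end, p_start + max_length - 1)
            promoter = Promoter(
                gene_id=focal.gene_id,
                chrom=chrom,
                strand=focal.strand,
                p_start=p_start,
                p_end=p_end,
                upstream_neighbor_id=neighbor.gene_id if neighbor else None,
            )
            if promoter.length_L == 0:
                logger.debug("gene %s has a zero-length promoter", focal.gene_id)
            promoters.append(promoter)
    logger.info(
        "extracted %d promoters (%d zero-length)",
        len(promoters), sum(1 for p in promoters if p.length_L == 0),
    )
    return promoters


def detect_head_to_head(promoters: list[Promoter]) -> set[tuple[str, str]]:
    """Find divergently transcribed gene pairs sharing a promoter region.

    A pair is head-to-head when the two genes lie on the same chromosome
    on opposite strands, the reverse-strand gene on the lower-coordinate
    side, and their promoter intervals overlap by at least 1 bp.
    """
    pairs: set[tuple[str, str]] = set()
    by_chrom: dict[str, list[Promoter]] = {}
    for p in promoters:
        if p.length_L > 0:
            by_chrom.setdefault(p.chrom, []).append(p)
    for chrom_promoters in by_chrom.values():
        tree = IntervalTree()
        for idx, p in enumerate(chrom_promoters):
            tree[p.p_start : p.p_end + 1] = idx
        for p in chrom_promoters:
            if p.strand != REVERSE:
                continue
            for hit in tree[p.p_start : p.p_end + 1]:
                q = chrom_promoters[hit.data]
                if q.strand == FORWARD and p.tss < q.tss:
                    pairs.add(tuple(sorted((p.gene_id, q.gene_id))))
    return pairs


_ANCHORS = ("midpoint", "start", "end")


def _anchor_point(site: TFBSRecord, anchor: str) -> int:
    if anchor == "midpoint":
        return site.midpoint
    if anchor == "start":
        return site.start
    if anchor == "end":
        return site.end
    raise ValidationError(f"anchor must be one of {_ANCHORS}, got {anchor!r}")


def build_profiles(
    promoters: list[Promoter],
    tfbs: list[TFBSRecord],
    anchor: str = "midpoint",
) -> list[PromoterProfile]:
    """Assign TFBSs to promoters and build per-TF offset lists.

    A site is assigned to every promoter (they may overlap in shared
    intergenic regions) containing its anchor point; the offset is the
    distance from the translation start site to the anchor. TFBS strand
    is ignored. Genes whose promoter receives no site get an empty
    profile, which downstream scoring excludes.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, p in enumerate(promoters):
        if p.length_L == 0:
            continue
        trees.setdefault(p.chrom, IntervalTree())[p.p_start : p.p_end + 1] = idx
    raw: dict[int, dict[str, list[int]]] = {}
    assigned = 0
    for site in tfbs:
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        point = _anchor_point(site, anchor)
        for hit in tree[point]:
            p = promoters[hit.data]
            offset = p.tss - point if p.strand == FORWARD else point - p.tss
            raw.setdefault(hit.data, {}).setdefault(site.tf_name, []).append(offset)
            assigned += 1
    profiles = []
    for idx, p in enumerate(promoters):
        sites = {
            tf: np.array(sorted(offs), dtype=np.int64)
            for tf, offs in sorted(raw.get(idx, {}).items())
        }
        profiles.append(PromoterProfile(gene_id=p.gene_id, length_L=p.length_L, sites=sites))
    n_empty = sum(1 for pr in profiles if pr.is_empty)
    logger.info(
        "assigned %d site placements; %d of %d genes have no TFBSs",
        assigned, n_empty, len(profiles),
    )
    return profiles


def write_promoters_bed(promoters: list[Promoter], path: str) -> None:
    """Export promoters as BED6 for inspection in a genome browser."""
    from .genome_io import internal_to_bed

    with open(path, "w") as fh:
        for p in promoters:
            if p.length_L == 0:
                continue
            b_start, b_end = internal_to_bed(p.p_start, p.p_end)
            fh.write(f"{p.chrom}\t{b_start}\t{b_end}\t{p.gene_id}\t{p.length_L}\t{p.strand}\n")


def mirror_genes(genes: list[GeneRecord], axis: int) -> list[GeneRecord]:
    """Reflect coordinates about ``axis`` and flip strands (test utility
    for the strand-symmetry property of promoter extraction)."""
    flipped = []
    for g in genes:
        flipped.append(
            GeneRecord(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand=REVERSE if g.strand == FORWARD else FORWARD,
                cds_start=axis - g.cds_end,
                cds_end=axis - g.cds_start,
            )
        )
    return flipped


def count_unassigned(promoters: list[Promoter], profiles: list[PromoterProfile]) -> int:
    """Number of genes with no assigned TFBS (reported, then excluded)."""
    return sum(1 for pr in profiles if pr.is_empty)
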