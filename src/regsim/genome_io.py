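"""Readers and writers for the external formats the pipeline consumes.

All coordinates are normalized on read to the internal convention:
1-based, inclusive on both ends (the GFF convention). BED input is
0-based half-open and is converted on the fly; :func:`bed_to_internal`
and :func:`internal_to_bed` expose the conversion so it can be reused
(and property-tested) elsewhere.

Identifiers (TF names and gene ids) are upper-cased on read, because
curated regulation evidence mixes capitalization styles (``Abf1`` vs
``ABF1``) while binding-site and annotation files usually use one of
them consistently.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"
UNKNOWN = "."

_STRAND_ALIASES = {
    "+": FORWARD,
    "-": REVERSE,
    ".": UNKNOWN,
    "forward": FORWARD,
    "reverse": REVERSE,
    "f": FORWARD,
    "r": REVERSE,
    "w": FORWARD,
    "c": REVERSE,
}


class ParseError(ValueError):
    """A malformed row in an input file; the message names the line."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One annotated gene: coding span (start to stop codon) and strand."""

    gene_id: str
    chrom: str
    strand: str
    cds_start: int  # 1-based inclusive
    cds_end: int  # 1-based inclusive

    def __post_init__(self) -> None:
        if self.cds_start > self.cds_end:
            raise ValidationError(
                f"gene {self.gene_id}: cds_start {self.cds_start} > cds_end {self.cds_end}"
            )
        if not self.chrom:
            raise ValidationError(f"gene {self.gene_id}: empty chromosome name")
        if self.strand not in (FORWARD, REVERSE):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class TFBSRecord:
    """A predicted TF binding site with a posterior-probability quality score."""

    tf_name: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    posterior: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"TFBS {self.tf_name}@{self.chrom}: start {self.start} > end {self.end}"
            )
        if not 0.0 <= self.posterior <= 1.0:
            raise ValidationError(
                f"TFBS {self.tf_name}@{self.chrom}: posterior {self.posterior} outside [0, 1]"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class RegulationEvidence:
    """Literature-curated (TF, target gene) regulation pairs."""

    pairs: frozenset[tuple[str, str]]

    def __len__(self) -> int:
        return len(self.pairs)

    def contains(self, tf_name: str, gene_id: str) -> bool:
        return (tf_name.upper(), gene_id.upper()) in self.pairs

    def targets_of(self, tf_name: str) -> frozenset[str]:
        tf = tf_name.upper()
        return frozenset(g for t, g in self.pairs if t == tf)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "RegulationEvidence":
        return cls(frozenset((t.upper(), g.upper()) for t, g in pairs))


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------


def bed_to_internal(bed_start: int, bed_end: int) -> tuple[int, int]:
    """Convert a 0-based half-open BED interval to 1-based inclusive."""
    return bed_start + 1, bed_end


def internal_to_bed(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open BED."""
    return start - 1, end


def _normalize_strand(raw: str, line_no: int, path: str) -> str:
    try:
        return _STRAND_ALIASES[raw.strip().lower()]
    except KeyError:
        raise ParseError(f"{path}:{line_no}: unrecognized strand {raw!r}") from None


def _data_lines(path: str) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields), skipping blanks and # comments."""
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.startswith("#"):
                continue
            yield line_no, stripped.split("\t")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------


def _genes_from_tsv(path: str) -> list[GeneRecord]:
    records = []
    for line_no, fields in _data_lines(path):
        if len(fields) != 5:
            raise ParseError(f"{path}:{line_no}: expected 5 columns, got {len(fields)}")
        gene_id, chrom, strand_raw, start_raw, end_raw = fields
        # a header row is tolerated: detected by non-numeric coordinates on line 1
        if line_no == 1 and not (start_raw.strip().isdigit() and end_raw.strip().isdigit()):
            continue
        try:
            start, end = int(start_raw), int(end_raw)
        except ValueError:
            raise ParseError(f"{path}:{line_no}: non-integer coordinates") from None
        strand = _normalize_strand(strand_raw, line_no, path)
        if strand == UNKNOWN:
            raise ParseError(f"{path}:{line_no}: gene strand must be + or -")
        try:
            records.append(GeneRecord(gene_id.strip().upper(), chrom.strip(), strand, start, end))
        except ValidationError as exc:
            raise ParseError(f"{path}:{line_no}: {exc}") from None
    return records


_GFF_ID_KEYS = ("ID", "gene_id", "Name", "locus_tag")


def _genes_from_gff3(path: str) -> list[GeneRecord]:
    import gffutils

    spans: dict[str, list] = {}
    for feature in gffutils.iterators.DataIterator(path):
        if feature.featuretype not in ("gene", "CDS"):
            continue
        gene_id = None
        for key in _GFF_ID_KEYS + ("Parent",):
            if key in feature.attributes and feature.attributes[key]:
                gene_id = feature.attributes[key][0]
                break
        if gene_id is None:
            raise ParseError(f"{path}: {feature.featuretype} feature without an identifier")
        gene_id = gene_id.upper()
        entry = spans.get(gene_id)
        if entry is None:
            spans[gene_id] = [feature.seqid, feature.strand, feature.start, feature.end]
        else:
            # CDS segments of one gene are merged into the full coding span
            if entry[0] != feature.seqid:
                raise ValidationError(f"gene {gene_id}: features on multiple chromosomes")
            entry[2] = min(entry[2], feature.start)
            entry[3] = max(entry[3], feature.end)
    records = []
    for gene_id, (chrom, strand, start, end) in spans.items():
        if strand not in (FORWARD, REVERSE):
            raise ParseError(f"{path}: gene {gene_id} lacks a +/- strand")
        records.append(GeneRecord(gene_id, chrom, strand, start, end))
    return records


def read_genes(path: str, format: str = "auto") -> list[GeneRecord]:
    """Read gene annotations from GFF3 or a 5-column TSV.

    TSV columns: gene_id, chrom, strand, start, end (header optional).
    Returns records sorted by (chrom, cds_start); duplicate gene ids are
    rejected.
    """
    if format == "auto":
        format = "gff3" if os.path.splitext(path)[1].lower() in (".gff", ".gff3") else "tsv"
    if format == "gff3":
        records = _genes_from_gff3(path)
    elif format == "tsv":
        records = _genes_from_tsv(path)
    else:
        raise ValidationError(f"unknown gene annotation format {format!r}")
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ValidationError(f"duplicate gene_id {rec.gene_id} in {path}")
        seen.add(rec.gene_id)
    records.sort(key=lambda r: (r.chrom, r.cds_start, r.gene_id))
    logger.info("read %d genes from %s", len(records), path)
    return records


# ---------------------------------------------------------------------------
# TFBS locations
# ---------------------------------------------------------------------------


def _tfbs_from_bed(path: str) -> list[TFBSRecord]:
    records = []
    for line_no, fields in _data_lines(path):
        if fields[0] in ("track", "browser"):
            continue
        if len(fields) < 5:
            raise ParseError(f"{path}:{line_no}: expected ≥5 BED columns, got {len(fields)}")
        chrom, start_raw, end_raw, name, score_raw = fields[:5]
        try:
            start, end = bed_to_internal(int(start_raw), int(end_raw))
        except ValueError:
            raise ParseError(f"{path}:{line_no}: non-integer BED coordinates") from None
        try:
            posterior = float(score_raw)
        except ValueError:
            raise ParseError(f"{path}:{line_no}: non-numeric score column") from None
        strand = UNKNOWN
        if len(fields) >= 6:
            strand = _normalize_strand(fields[5], line_no, path)
        try:
            records.append(TFBSRecord(name.strip().upper(), chrom.strip(), strand, start, end, posterior))
        except ValidationError as exc:
            raise ParseError(f"{path}:{line_no}: {exc}") from None
    return records


def _tfbs_from_gff(path: str) -> list[TFBSRecord]:
    """SwissRegulon-style GFF: TF name from attribute ``Name`` if present,
    else the feature (3rd) column; posterior from the score column if
    numeric, else an attribute ``posterior``."""
    records = []
    for line_no, fields in _data_lines(path):
        if len(fields) < 8:
            raise ParseError(f"{path}:{line_no}: expected ≥8 GFF columns, got {len(fields)}")
        chrom, _source, feature, start_raw, end_raw, score_raw, strand_raw = fields[:7]
        attrs = _parse_gff_attributes(fields[8]) if len(fields) > 8 else {}
        tf_name = attrs.get("Name", feature).strip()
        posterior_raw = score_raw
        try:
            posterior = float(posterior_raw)
        except ValueError:
            if "posterior" not in attrs:
                raise ParseError(f"{path}:{line_no}: no numeric posterior") from None
            posterior = float(attrs["posterior"])
        try:
            start, end = int(start_raw), int(end_raw)
        except ValueError:
            raise ParseError(f"{path}:{line_no}: non-integer coordinates") from None
        strand = _normalize_strand(strand_raw, line_no, path)
        try:
            records.append(TFBSRecord(tf_name.upper(), chrom.strip(), strand, start, end, posterior))
        except ValidationError as exc:
            raise ParseError(f"{path}:{line_no}: {exc}") from None
    return records


def _parse_gff_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in raw.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, value = chunk.split("=", 1)
        elif " " in chunk:
            key, value = chunk.split(" ", 1)
        else:
            continue
        attrs[key.strip()] = value.strip().strip('"')
    return attrs


def read_tfbs(path: str, format: str = "auto", min_posterior: float = 0.0) -> list[TFBSRecord]:
    """Read TFBS locations from BED (0-based half-open) or GFF (1-based).

    Only sites with posterior >= ``min_posterior`` are returned; the
    cutoff is inclusive.
    """
    if not 0.0 <= min_posterior <= 1.0:
        raise ValidationError(f"min_posterior {min_posterior} outside [0, 1]")
    if format == "auto":
        format = "bed" if os.path.splitext(path)[1].lower() == ".bed" else "gff"
    if format == "bed":
        records = _tfbs_from_bed(path)
    elif format == "gff":
        records = _tfbs_from_gff(path)
    else:
        raise ValidationError(f"unknown TFBS format {format!r}")
    kept = [r for r in records if r.posterior >= min_posterior]
    logger.info(
        "read %d TFBSs from %s (%d kept at posterior >= %g)",
        len(records), path, len(kept), min_posterior,
    )
    return kept


# ---------------------------------------------------------------------------
# regulation evidence, expression, pair scores
# ---------------------------------------------------------------------------


def read_evidence(path: str) -> RegulationEvidence:
    """Read two-column (TF, target gene) TSV; duplicates collapse."""
    pairs: set[tuple[str, str]] = set()
    for line_no, fields in _data_lines(path):
        if len(fields) != 2:
            raise ParseError(f"{path}:{line_no}: expected 2 columns, got {len(fields)}")
        tf, gene = fields
        pairs.add((tf.strip().upper(), gene.strip().upper()))
    logger.info("read %d distinct regulation pairs from %s", len(pairs), path)
    return RegulationEvidence(frozenset(pairs))


def read_expression(path: str) -> pd.DataFrame:
    """Read a genes x conditions expression matrix (TSV, header row)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    matrix.index = matrix.index.astype(str).str.upper()
    return matrix


def write_scores(scores: pd.DataFrame, path: str) -> None:
    """Write a pair-score table as TSV, one row per unordered gene pair.

    The first two columns must be ``gene_a`` and ``gene_b``; rows are
    normalized so gene_a < gene_b lexicographically.
    """
    if list(scores.columns[:2]) != ["gene_a", "gene_b"]:
        raise ValidationError("score table must start with gene_a, gene_b columns")
    out = scores.copy()
    flip = out["gene_a"] > out["gene_b"]
    if flip.any():
        a = out.loc[flip, "gene_a"].copy()
        out.loc[flip, "gene_a"] = out.loc[flip, "gene_b"]
        out.loc[flip, "gene_b"] = a
    out.to_csv(path, sep="\t", index=False)


def read_scores(path: str) -> pd.DataFrame:
    """Read back a pair-score TSV written by :func:`write_scores`."""
    return pd.read_csv(path, sep="\t")
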