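"""Regulatory neighborhoods and the co-expression score (CES).

The regulatory neighborhood (RN) of a target gene is the n genes with
the highest RS to it. CES evaluates an RN on an expression matrix as
the average pairwise correlation of its members' expression profiles —
high CES means the neighborhood behaves like a co-expressed module.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryNeighborhood:
    """Top-n genes by RS to a target, with their scores (descending)."""

    target_gene: str
    members: list[str]
    scores: list[float]

    def __len__(self) -> int:
        return len(self.members)


def regulatory_neighborhood(
    target: str,
    pair_scores: pd.DataFrame,
    n: int,
    measure: str | None = None,
) -> RegulatoryNeighborhood:
    """Extract the RN of ``target`` from an all-pairs score table.

    ``measure`` names the score column; defaults to the single score
    column when only one is present. Ties at the boundary are broken
    lexicographically by gene id, so the result is deterministic.
    """
    if n < 1:
        raise ValidationError("neighborhood size n must be >= 1")
    target = target.upper()
    if measure is None:
        score_cols = [c for c in pair_scores.columns if c not in ("gene_a", "gene_b")]
        if len(score_cols) != 1:
            raise ValidationError(
                f"measure must be named when the table has {len(score_cols)} score columns"
            )
        measure = score_cols[0]
    if measure not in pair_scores.columns:
        raise ValidationError(f"no column {measure!r} in the score table")
    mask_a = pair_scores["gene_a"] == target
    mask_b = pair_scores["gene_b"] == target
    if not (mask_a.any() or mask_b.any()):
        raise ValidationError(f"target gene {target!r} absent from the score table")
    others = pd.concat(
        [
            pair_scores.loc[mask_a, ["gene_b", measure]].rename(columns={"gene_b": "gene"}),
            pair_scores.loc[mask_b, ["gene_a", measure]].rename(columns={"gene_a": "gene"}),
        ],
        ignore_index=True,
    )
    others = others.sort_values(["gene"]).sort_values(
        [measure], ascending=False, kind="stable"
    )
    if len(others) < n:
        logger.warning(
            "only %d scored genes for target %s (requested %d)", len(others), target, n
        )
    top = others.head(n)
    return RegulatoryNeighborhood(
        target_gene=target,
        members=top["gene"].tolist(),
        scores=[float(v) for v in top[measure]],
    )


def ces(
    neighborhood: RegulatoryNeighborhood,
    expression: pd.DataFrame,
    method: str = "pearson",
) -> float:
    """Co-expression score: mean pairwise correlation within the RN.

    ``expression`` is genes x conditions. Pairs involving a constant
    expression vector have undefined correlation and are excluded with a
    warning. ``method`` is ``pearson`` (default) or ``spearman``.
    """
    members = [m.upper() for m in neighborhood.members]
    missing = [m for m in members if m not in expression.index]
    if missing:
        raise ValidationError(f"genes absent from the expression matrix: {missing[:5]}")
    if len(members) < 2:
        raise ValidationError("CES needs >= 2 neighborhood members")
    if expression.shape[1] < 3:
        raise ValidationError("CES needs >= 3 conditions")
    mat = expression.loc[members].to_numpy(dtype=float)
    if method == "spearman":
        mat = np.apply_along_axis(lambda r: pd.Series(r).rank().to_numpy(), 1, mat)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    constant = mat.std(axis=1) == 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(mat)
    values = []
    n_skipped = 0
    for i, j in itertools.combinations(range(len(members)), 2):
        if constant[i] or constant[j]:
            n_skipped += 1
            continue
        values.append(corr[i, j])
    if n_skipped:
        logger.warning("excluded %d pairs with constant expression vectors", n_skipped)
    if not values:
        raise ValidationError("no pair with defined expression correlation")
    return float(np.mean(values))


def neighborhood_report(
    neighborhood: RegulatoryNeighborhood,
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tabular RN report (rank, gene, score), plus CES metadata if an
    expression matrix is supplied."""
    report = pd.DataFrame(
        {
            "rank": np.arange(1, len(neighborhood) + 1),
            "gene": neighborhood.members,
            "score": neighborhood.scores,
        }
    )
    report.attrs["target_gene"] = neighborhood.target_gene
    if expression is not None:
        report.attrs["ces"] = ces(neighborhood, expression)
    return report
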