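"""Evaluation protocols for RS measures against literature evidence.

Two protocols are implemented:

* the offset-distance bucket analysis — every (TF, gene pair) tuple with
  the TF bound in both promoters is placed in the bucket of its TFBS
  offset distance, and the per-bucket fraction of tuples where the
  literature records the TF regulating both genes is related to distance
  by an ordinary least-squares fit;

* the binned calibration curve — gene pairs are sampled, sorted by RS
  score and split into equal-occupancy bins (50 bins of 2% by default);
  each bin contributes one point (mean score, fraction of co-regulated
  pairs), averaged over replicates, and the curve's quality is the
  squared Spearman rank correlation of its 50 points.

A pair counts as co-regulated when at least one TF common to both
promoters has literature evidence for both genes.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GeneRecord, RegulationEvidence, TFBSRecord, ValidationError
from .promoter_model import PromoterProfile, build_profiles, extract_promoters
from .rs_measures import _min_abs_diff

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# co-regulation labels
# ---------------------------------------------------------------------------


def coregulated_pairs(
    profiles: list[PromoterProfile], evidence: RegulationEvidence
) -> set[tuple[str, str]]:
    """Gene pairs co-regulated by >= 1 common TF with evidence for both."""
    by_tf: dict[str, list[str]] = {}
    for pr in profiles:
        for tf in pr.sites:
            if evidence.contains(tf, pr.gene_id):
                by_tf.setdefault(tf, []).append(pr.gene_id)
    pairs: set[tuple[str, str]] = set()
    for genes in by_tf.values():
        genes.sort()
        for a, b in itertools.combinations(genes, 2):
            pairs.add((a, b))
    return pairs


def label_coregulation(
    pair_table: pd.DataFrame,
    profiles: list[PromoterProfile],
    evidence: RegulationEvidence,
) -> np.ndarray:
    """Boolean vector aligned with ``pair_table`` rows (gene_a, gene_b)."""
    positives = coregulated_pairs(profiles, evidence)
    return np.fromiter(
        (
            (min(a, b), max(a, b)) in positives
            for a, b in zip(pair_table["gene_a"], pair_table["gene_b"])
        ),
        dtype=bool,
        count=len(pair_table),
    )


# ---------------------------------------------------------------------------
# offset-distance bucket analysis
# ---------------------------------------------------------------------------


def bucket_analysis(
    profiles: list[PromoterProfile],
    evidence: RegulationEvidence,
    bin_width: int = 1,
    min_tuples: int = 30,
) -> pd.DataFrame:
    """Relate TFBS offset distance to the co-regulation fraction.

    For every TF t and every unordered pair of genes whose promoters
    both carry a site of t, the tuple <t, a, b> falls into the bucket of
    its offset distance d. Each surviving bucket yields a row
    (distance_bin, n_tuples, n_regulated, ratio); ``distance_bin`` is the
    bucket's left edge and buckets with fewer than ``min_tuples`` tuples
    are dropped.
    """
    if bin_width < 1:
        raise ValidationError("bin_width must be >= 1")
    by_tf: dict[str, list[PromoterProfile]] = {}
    for pr in profiles:
        for tf in pr.sites:
            by_tf.setdefault(tf, []).append(pr)
    n_tuples: dict[int, int] = {}
    n_regulated: dict[int, int] = {}
    for tf, members in by_tf.items():
        evidenced = {pr.gene_id for pr in members if evidence.contains(tf, pr.gene_id)}
        for pa, pb in itertools.combinations(members, 2):
            d = _min_abs_diff(pa.sites[tf], pb.sites[tf])
            b = d // bin_width
            n_tuples[b] = n_tuples.get(b, 0) + 1
            if pa.gene_id in evidenced and pb.gene_id in evidenced:
                n_regulated[b] = n_regulated.get(b, 0) + 1
    rows = [
        (b * bin_width, n, n_regulated.get(b, 0), n_regulated.get(b, 0) / n)
        for b, n in sorted(n_tuples.items())
        if n >= min_tuples
    ]
    table = pd.DataFrame(rows, columns=["distance_bin", "n_tuples", "n_regulated", "ratio"])
    table.attrs["bin_width"] = bin_width
    return table


def fit_linear_r2(table: pd.DataFrame) -> tuple[float, float, float]:
    """OLS of bucket ratio on bucket distance -> (slope, intercept, R^2)."""
    if len(table) < 3:
        raise ValidationError(f"need >= 3 buckets for a linear fit, got {len(table)}")
    fit = stats.linregress(table["distance_bin"].to_numpy(float), table["ratio"].to_numpy(float))
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


# ---------------------------------------------------------------------------
# binned calibration
# ---------------------------------------------------------------------------


@dataclass
class BinnedCurve:
    """Replicate-averaged calibration curve of one RS measure.

    ``points`` has one row per score bin — (mean_rs, frac_coregulated) —
    ordered by mean_rs; ``per_replicate_r2`` holds the squared Spearman
    rank correlation of each replicate's own curve, kept for paired
    between-measure significance tests.
    """

    points: pd.DataFrame
    n_replicates: int
    sample_size: int
    per_replicate_r2: np.ndarray


def binned_calibration(
    scores: np.ndarray,
    coregulated: np.ndarray,
    sample_size: int = 1_000_000,
    n_bins: int = 50,
    n_replicates: int = 100,
    seed: int = 0,
) -> BinnedCurve:
    """Build the equal-occupancy calibration curve of one measure.

    Per replicate, ``sample_size`` pairs are drawn without replacement,
    sorted by score and split into ``n_bins`` equal bins; each bin
    records its mean score and co-regulated fraction. Points are
    averaged across replicates. Replicate r uses the deterministic
    stream seeded by (seed, r), so results are bit-reproducible and two
    measures evaluated with the same seed over the same pair universe
    see identical replicate samples (paired design).
    """
    scores = np.asarray(scores, dtype=float)
    coregulated = np.asarray(coregulated, dtype=float)
    if len(scores) != len(coregulated):
        raise ValidationError("scores and labels differ in length")
    n_avail = len(scores)
    if sample_size > n_avail:
        logger.warning(
            "sample_size %d exceeds the %d available pairs; using the full set",
            sample_size, n_avail,
        )
        sample_size = n_avail
    sample_size -= sample_size % n_bins  # equal-occupancy bins need divisibility
    if sample_size < n_bins:
        raise ValidationError("fewer sampled pairs than bins")
    bin_size = sample_size // n_bins
    mean_rs = np.zeros(n_bins)
    frac = np.zeros(n_bins)
    r2 = np.zeros(n_replicates)
    for r in range(n_replicates):
        rng = np.random.default_rng([seed, r])
        idx = rng.choice(n_avail, size=sample_size, replace=False)
        order = np.argsort(scores[idx], kind="stable")
        s = scores[idx][order].reshape(n_bins, bin_size)
        c = coregulated[idx][order].reshape(n_bins, bin_size)
        xs, ys = s.mean(axis=1), c.mean(axis=1)
        mean_rs += xs
        frac += ys
        with warnings.catch_warnings():
            # constant scores make the rank correlation undefined; treated as 0
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho = stats.spearmanr(xs, ys).statistic
        r2[r] = 0.0 if np.isnan(rho) else rho**2
    points = pd.DataFrame(
        {"mean_rs": mean_rs / n_replicates, "frac_coregulated": frac / n_replicates}
    )
    points = points.sort_values("mean_rs", kind="stable", ignore_index=True)
    return BinnedCurve(
        points=points,
        n_replicates=n_replicates,
        sample_size=sample_size,
        per_replicate_r2=r2,
    )


def spearman_r2(curve: BinnedCurve) -> float:
    """Squared Spearman rank correlation of the averaged curve's points.

    The square discards the sign: a strictly decreasing curve also
    scores 1. Ties receive average ranks.
    """
    rho = stats.spearmanr(
        curve.points["mean_rs"], curve.points["frac_coregulated"]
    ).statistic
    return float(rho**2)


def random_scores(n: int, seed: int = 0) -> np.ndarray:
    """Uniform random scores — the random-predictor baseline curve."""
    return np.random.default_rng([seed, 0x5EED]).random(n)


# ---------------------------------------------------------------------------
# between-measure significance
# ---------------------------------------------------------------------------


def compare_measures(
    per_replicate_r2: dict[str, np.ndarray],
    baseline: str = "proposed",
    method: str = "wilcoxon",
) -> pd.DataFrame:
    """Paired two-sided test of the baseline measure's per-replicate R^2
    against every other measure's. Replicates must be paired by shared
    samples (same calibration seed over the same pair universe).

    Returns a table (measure, p_value, all_tied); when every paired
    difference is zero the test is undefined and p_value is set to 1
    with ``all_tied`` flagged.
    """
    if baseline not in per_replicate_r2:
        raise ValidationError(f"baseline measure {baseline!r} missing from input")
    ref = np.asarray(per_replicate_r2[baseline], dtype=float)
    if len(ref) < 2:
        raise ValidationError("need >= 2 replicates for a paired test")
    rows = []
    for name, values in per_replicate_r2.items():
        if name == baseline:
            continue
        other = np.asarray(values, dtype=float)
        if len(other) != len(ref):
            raise ValidationError(f"unequal replicate counts for {name!r}")
        diffs = ref - other
        if np.all(diffs == 0):
            rows.append((name, 1.0, True))
            continue
        if method == "wilcoxon":
            p = float(stats.wilcoxon(ref, other).pvalue)
        elif method == "ttest":
            p = float(stats.ttest_rel(ref, other).pvalue)
        else:
            raise ValidationError(f"unknown test {method!r}; use wilcoxon or ttest")
        rows.append((name, p, False))
    return pd.DataFrame(rows, columns=["measure", "p_value", "all_tied"])


# ---------------------------------------------------------------------------
# quality / quantity sweep
# ---------------------------------------------------------------------------


def site_density(n_sites: int, n_genes: int) -> float:
    """Sites per gene with sites, rounded to one decimal."""
    if n_genes == 0:
        return float("nan")
    return round(n_sites / n_genes, 1)


def quality_sweep(
    genes: list[GeneRecord],
    tfbs_unfiltered: list[TFBSRecord],
    cutoffs: list[float],
) -> pd.DataFrame:
    """Posterior-cutoff sweep: sites retained, genes with >= 1 assigned
    site, and density (sites per gene with sites) per cutoff."""
    promoters = extract_promoters(genes)
    rows = []
    for cutoff in cutoffs:
        retained = [s for s in tfbs_unfiltered if s.posterior >= cutoff]
        profiles = build_profiles(promoters, retained)
        n_with = sum(1 for pr in profiles if not pr.is_empty)
        rows.append((cutoff, len(retained), n_with, site_density(len(retained), n_with)))
    return pd.DataFrame(rows, columns=["cutoff", "n_sites", "n_genes_with_sites", "density"])
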