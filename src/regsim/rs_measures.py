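"""Regulatory-similarity (RS) measures for gene pairs.

Six measures are implemented. Five are literature baselines that treat
the TF repertoire of a promoter as a set (or multiset) of TFs:

* ``garten`` — minus log of the cumulative hypergeometric tail
  probability of the observed overlap between the two TF sets;
* ``jaccard`` — |intersection| / |union| of the TF sets;
* ``shalgi`` — |intersection| / min(|set a|, |set b|);
* ``park`` — copy-number-weighted agreement with a penalty for TFs
  whose sites appear in only one promoter;
* ``vanhelden`` — a Poisson similarity-minus-dissimilarity score built
  on genome-wide per-bp site rates.

The sixth, ``proposed``, is the location-aware measure: promoters are
aligned at their translation start sites and each common TF contributes
(L - d_i)/L where d_i is the smallest offset distance between any of
its sites in the two promoters and L is the longer promoter length:

    RS(a, b) = (1 / |TF_a ∪ TF_b|) · Σ_{i ∈ TF_a ∩ TF_b} (L - d_i) / L
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import ValidationError
from .promoter_model import PromoterProfile

logger = logging.getLogger(__name__)

MEASURES = ("proposed", "garten", "jaccard", "shalgi", "park", "vanhelden")


@dataclass
class RSConfig:
    """Tunable constants of the RS measures.

    ``total_tf_count_N`` is the TF population size of the hypergeometric
    overlap test; ``None`` means "infer from the data" (number of
    distinct TFs across all profiles). ``empty_union_score`` is returned
    by the set-based measures when both TF sets are empty — that case
    only arises on user data, since evaluation drops TFBS-less genes.
    """

    log_base_eq1: float = 10.0
    park_alpha: float = 1.0
    park_beta: float = 0.5
    park_gamma: float = 1.0
    vanhelden_alpha: float = 1.0
    vanhelden_beta: float = 0.0
    empty_union_score: float = 0.0
    total_tf_count_N: int | None = None


DEFAULT_CONFIG = RSConfig()


# ---------------------------------------------------------------------------
# offset distance and the location-aware measure
# ---------------------------------------------------------------------------


def offset_distance(
    profile_a: PromoterProfile, profile_b: PromoterProfile, tf: str
) -> int | None:
    """Smallest |offset_a - offset_b| over the TF's sites in the two
    promoters, or None if the TF is absent from either."""
    a = profile_a.sites.get(tf)
    b = profile_b.sites.get(tf)
    if a is None or b is None:
        return None
    return _min_abs_diff(a, b)


def _min_abs_diff(a: np.ndarray, b: np.ndarray) -> int:
    # both sorted ascending; linear merge beats the quadratic broadcast
    best = np.inf
    i = j = 0
    while i < len(a) and j < len(b):
        diff = int(a[i]) - int(b[j])
        if abs(diff) < best:
            best = abs(diff)
        if diff <= 0:
            i += 1
        else:
            j += 1
    return int(best)


def rs_proposed(
    profile_a: PromoterProfile,
    profile_b: PromoterProfile,
    cfg: RSConfig = DEFAULT_CONFIG,
) -> float:
    tfs_a, tfs_b = profile_a.tf_set, profile_b.tf_set
    union = len(tfs_a | tfs_b)
    if union == 0:
        return cfg.empty_union_score
    common = tfs_a & tfs_b
    if not common:
        return 0.0
    L = max(profile_a.length_L, profile_b.length_L)
    assert L > 0, "a common TF requires a non-empty promoter"
    total = 0.0
    for tf in sorted(common):  # fixed order keeps summation bit-reproducible
        d = _min_abs_diff(profile_a.sites[tf], profile_b.sites[tf])
        total += (L - d) / L
    return total / union


# ---------------------------------------------------------------------------
# set-overlap baselines
# ---------------------------------------------------------------------------


def rs_garten(
    tfset_a: frozenset[str] | set[str],
    tfset_b: frozenset[str] | set[str],
    N: int,
    cfg: RSConfig = DEFAULT_CONFIG,
) -> float:
    """-log of the cumulative hypergeometric tail P(X >= k) for the
    overlap k between TF sets of sizes m and n drawn from N TFs."""
    m, n = len(tfset_a), len(tfset_b)
    if N < m or N < n:
        raise ValidationError(f"total TF count N={N} smaller than a set size ({m}, {n})")
    k = len(set(tfset_a) & set(tfset_b))
    if k == 0:
        return 0.0
    p = float(stats.hypergeom.sf(k - 1, N, m, n))
    p = min(max(p, 5e-324), 1.0)
    return -math.log(p) / math.log(cfg.log_base_eq1)


def rs_jaccard(
    tfset_a: frozenset[str] | set[str],
    tfset_b: frozenset[str] | set[str],
    cfg: RSConfig = DEFAULT_CONFIG,
) -> float:
    a, b = set(tfset_a), set(tfset_b)
    union = a | b
    if not union:
        return cfg.empty_union_score
    return len(a & b) / len(union)


def rs_shalgi(
    tfset_a: frozenset[str] | set[str],
    tfset_b: frozenset[str] | set[str],
    cfg: RSConfig = DEFAULT_CONFIG,
) -> float:
    a, b = set(tfset_a), set(tfset_b)
    if not a or not b:
        return cfg.empty_union_score
    return len(a & b) / min(len(a), len(b))


# ---------------------------------------------------------------------------
# copy-count baselines
# ---------------------------------------------------------------------------


def rs_park(
    profile_a: PromoterProfile,
    profile_b: PromoterProfile,
    cfg: RSConfig = DEFAULT_CONFIG,
) -> float:
    """Copy-number-weighted agreement with a one-sidedness penalty.

    Per TF i with site counts N1_i, N2_i in the two promoters and shared
    copies C_i = min(N1_i, N2_i):

        γ · Σ_{C_i>0} [ (f_i - 1/2)^2 (N1_i + N2_i) + α C_i ]
          - β · Σ_{C_i=0} (N1_i + N2_i),        f_i = N1_i / (N1_i + N2_i).

    Balanced shared TFs (f_i = 1/2) contribute α·C_i; TFs present in one
    promoter only are penalized in proportion to their copies.
    """
    score = 0.0
    for tf in profile_a.tf_set | profile_b.tf_set:
        n1 = len(profile_a.sites.get(tf, ()))
        n2 = len(profile_b.sites.get(tf, ()))
        total = n1 + n2
        shared = min(n1, n2)
        if shared > 0:
            f = n1 / total
            score += cfg.park_gamma * ((f - 0.5) ** 2 * total + cfg.park_alpha * shared)
        else:
            score -= cfg.park_beta * total
    return score


@dataclass
class PoissonBackground:
    """Genome-wide per-bp occurrence rates used by the van Helden measure.

    ``per_tf_rate[tf]`` is the TF's site count across all promoters
    divided by the total promoter length; ``total_rate`` is their sum.
    """

    per_tf_rate: dict[str, float] = field(default_factory=dict)
    total_rate: float = 0.0

    @classmethod
    def from_profiles(cls, profiles: Iterable[PromoterProfile]) -> "PoissonBackground":
        counts: dict[str, int] = {}
        total_len = 0
        for pr in profiles:
            total_len += pr.length_L
            for tf, offs in pr.sites.items():
                counts[tf] = counts.get(tf, 0) + len(offs)
        if total_len == 0:
            return cls()
        rates = {tf: c / total_len for tf, c in counts.items()}
        return cls(per_tf_rate=rates, total_rate=sum(rates.values()))

    def presence_prob(self, tf: str, length: int) -> float:
        """P(at least one site of ``tf`` in a promoter of this length)."""
        return 1.0 - math.exp(-self.per_tf_rate.get(tf, 0.0) * length)


def rs_vanhelden(
    profile_a: PromoterProfile,
    profile_b: PromoterProfile,
    background: PoissonBackground,
    cfg: RSConfig = DEFAULT_CONFIG,
) -> float:
    """M_ab = S_ab - α·D_ab + β.

    S_ab = 1 - P(X >= c) with c the observed common-TF count and X
    Poisson with mean equal to the expected number of TFs present in
    both promoters under the background rates. D_ab = |p_a - p_b| where
    p_g is the Poisson upper-tail p-value of promoter g's own total site
    count at the genome-wide rate.
    """
    c = len(profile_a.tf_set & profile_b.tf_set)
    mu = sum(
        background.presence_prob(tf, profile_a.length_L)
        * background.presence_prob(tf, profile_b.length_L)
        for tf in background.per_tf_rate
    )
    s_ab = float(stats.poisson.cdf(c - 1, mu)) if c > 0 else 0.0
    p_a = float(stats.poisson.sf(profile_a.n_sites - 1, background.total_rate * profile_a.length_L))
    p_b = float(stats.poisson.sf(profile_b.n_sites - 1, background.total_rate * profile_b.length_L))
    d_ab = abs(p_a - p_b)
    return s_ab - cfg.vanhelden_alpha * d_ab + cfg.vanhelden_beta


# ---------------------------------------------------------------------------
# all-pairs scoring
# ---------------------------------------------------------------------------


def infer_total_tf_count(profiles: Iterable[PromoterProfile]) -> int:
    tfs: set[str] = set()
    for pr in profiles:
        tfs |= pr.tf_set
    return len(tfs)


def score_all_pairs(
    profiles: list[PromoterProfile],
    measures: Iterable[str] = MEASURES,
    cfg: RSConfig = DEFAULT_CONFIG,
    exclusions: set[tuple[str, str]] | frozenset = frozenset(),
    count_only: bool = False,
) -> pd.DataFrame | int:
    """Score every unordered pair of genes with a non-empty profile.

    Genes with no assigned TFBS are dropped first; pairs listed in
    ``exclusions`` (e.g. head-to-head pairs, as sorted id tuples) are
    removed. With ``count_only=True`` only the number of surviving pairs
    is returned, without scoring — the pair universe of an evaluation
    run.
    """
    measures = list(measures)
    for m in measures:
        if m not in MEASURES:
            raise ValidationError(f"unknown measure {m!r}; choose from {MEASURES}")
    kept = sorted((p for p in profiles if not p.is_empty), key=lambda p: p.gene_id)
    kept_ids = {p.gene_id for p in kept}
    n = len(kept)
    excluded = {tuple(sorted(pair)) for pair in exclusions}
    n_excluded = sum(1 for a, b in excluded if a in kept_ids and b in kept_ids and a != b)
    n_pairs = n * (n - 1) // 2 - n_excluded
    logger.info(
        "%d genes with sites; %d pairs after removing %d excluded pairs",
        n, n_pairs, n_excluded,
    )
    if count_only:
        return n_pairs

    N = cfg.total_tf_count_N if cfg.total_tf_count_N is not None else infer_total_tf_count(kept)
    background = PoissonBackground.from_profiles(kept) if "vanhelden" in measures else None

    rows_a: list[str] = []
    rows_b: list[str] = []
    columns: dict[str, list[float]] = {m: [] for m in measures}
    for pa, pb in itertools.combinations(kept, 2):
        if (pa.gene_id, pb.gene_id) in excluded:
            continue
        rows_a.append(pa.gene_id)
        rows_b.append(pb.gene_id)
        for m in measures:
            if m == "proposed":
                val = rs_proposed(pa, pb, cfg)
            elif m == "garten":
                val = rs_garten(pa.tf_set, pb.tf_set, N, cfg)
            elif m == "jaccard":
                val = rs_jaccard(pa.tf_set, pb.tf_set, cfg)
            elif m == "shalgi":
                val = rs_shalgi(pa.tf_set, pb.tf_set, cfg)
            elif m == "park":
                val = rs_park(pa, pb, cfg)
            else:
                val = rs_vanhelden(pa, pb, background, cfg)
            columns[m].append(val)
    out = pd.DataFrame({"gene_a": rows_a, "gene_b": rows_b, **columns})
    assert len(out) == n_pairs
    return out
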