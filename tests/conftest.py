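import numpy as np
import pytest
from hypothesis import settings

import regsim as rs

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic genome shared by read-only tests."""
    return rs.generate(rs.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline(dataset):
    """Promoters, profiles and head-to-head pairs of the shared genome."""
    promoters = rs.extract_promoters(dataset.genes)
    profiles = rs.build_profiles(promoters, dataset.tfbs)
    head_to_head = rs.detect_head_to_head(promoters)
    return {
        "dataset": dataset,
        "promoters": promoters,
        "profiles": profiles,
        "head_to_head": head_to_head,
    }


@pytest.fixture(scope="session")
def scored(pipeline):
    """Proposed + Jaccard scores with co-regulation labels."""
    table = rs.score_all_pairs(
        pipeline["profiles"], ["proposed", "jaccard"],
        exclusions=pipeline["head_to_head"],
    )
    labels = rs.label_coregulation(
        table, pipeline["profiles"], pipeline["dataset"].evidence
    )
    return table, labels


def make_profile(rng, gene_id, tf_pool, length=1000, max_tfs=6, max_sites=3):
    """Random promoter profile for property tests."""
    n_tfs = int(rng.integers(0, max_tfs + 1))
    tfs = rng.choice(tf_pool, size=n_tfs, replace=False)
    sites = {}
    for tf in tfs:
        k = int(rng.integers(1, max_sites + 1))
        sites[str(tf)] = np.sort(rng.integers(1, length + 1, size=k)).astype(np.int64)
    return rs.PromoterProfile(gene_id=gene_id, length_L=length, sites=sites)
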