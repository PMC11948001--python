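import numpy as np
import pandas as pd
import pytest

from gliores import synthetic


@pytest.fixture(scope="session")
def truth():
    return synthetic.default_truth(n_genes=300, seed=3)


@pytest.fixture(scope="session")
def sc_data(truth):
    counts, cells, positions = synthetic.gen_sc_dataset(300, 300, truth, seed=4)
    return counts, cells, positions


@pytest.fixture(scope="session")
def flat_truth():
    """Truth whose tumor and reference profiles are identical (CNV aside)."""
    base = synthetic.default_truth(n_genes=300, seed=9)
    genes = list(base.cluster_profiles.columns)
    rng = np.random.default_rng(9)
    profile = rng.lognormal(1.0, 0.5, size=len(genes))
    clusters = ["NT1", "T1"]
    profiles = pd.DataFrame([profile, profile], index=clusters, columns=genes)
    per_chrom = 300 // 6
    return synthetic.SyntheticTruth(
        resistance_genes=dict(base.resistance_genes),
        driver_gene=base.driver_gene,
        cnv_segments=[("chr2", per_chrom + 2, per_chrom + 2 + 40, 0.58)],
        cluster_profiles=profiles,
        spot_mixtures=base.spot_mixtures,
        synergy_magnitude=0.0,
        stem_frequency={"control": 0.1},
        seed=9,
        reference_clusters=("NT1",),
        tumor_clusters=("T1",),
        resistant_cluster="T1",
        spot_regions=base.spot_regions,
    )
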