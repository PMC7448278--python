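import numpy as np
import pandas as pd
import pytest

from gcfkit.records import ClusterRecord
from gcfkit.simulate import SimulationConfig, simulate_families


@pytest.fixture
def rng():
    return np.random.default_rng(20200825)


@pytest.fixture
def toy_clusters():
    """Two near-identical NRPS clusters and one unrelated PKS cluster."""
    a_seq = "MKTLAEQWRDFVNAGHELTPLQERILHYIKDNPGAVAVEDSWGE" * 5
    a_mut = a_seq[:50] + "G" + a_seq[51:]
    pks = "MSDVLITGAGGFLGSHLAERLVKQGHEVIGLDNFATGRRENIAHL" * 5
    return [
        ClusterRecord(
            cluster_id="bgc1",
            genome_id="g1",
            product_class="NRPS",
            domain_array=["AMP-binding", "PCP", "Condensation", "p450"],
            backbone_domains={"AMP-binding": [a_seq], "PCP": [a_seq[:80]]},
            proteins=[("bgc1_p1", a_seq)],
        ),
        ClusterRecord(
            cluster_id="bgc2",
            genome_id="g2",
            product_class="NRPS",
            domain_array=["AMP-binding", "PCP", "Condensation", "MFS_1"],
            backbone_domains={"AMP-binding": [a_mut], "PCP": [a_seq[:80]]},
            proteins=[("bgc2_p1", a_mut)],
        ),
        ClusterRecord(
            cluster_id="bgc3",
            genome_id="g3",
            product_class="PKS",
            domain_array=["PKS_KS", "PKS_AT", "TE"],
            backbone_domains={"PKS_KS": [pks]},
            proteins=[("bgc3_p1", pks)],
        ),
    ]


@pytest.fixture(scope="session")
def two_family_sim():
    """The standard two-families-plus-two-singletons simulation (seed 7)."""
    config = SimulationConfig(seed=7)
    clusters, truth = simulate_families(config)
    return config, clusters, truth


@pytest.fixture
def upgma_hand_matrix():
    """Three leaves with a worked-by-hand UPGMA solution."""
    return pd.DataFrame(
        [[0.0, 0.2, 0.6], [0.2, 0.0, 0.8], [0.6, 0.8, 0.0]],
        index=list("ABC"),
        columns=list("ABC"),
    )
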