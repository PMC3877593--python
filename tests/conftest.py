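import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

import splicecons as sc


def make_pair(gene, seq_a, seq_b, intron_index=1):
    return sc.OrthologousIntronPair(
        gene_id=gene, intron_index=intron_index, seq_a=seq_a, seq_b=seq_b
    )


@pytest.fixture
def toy_pairs():
    """Four hand-built canonical couples, 20 nt each."""
    return [
        make_pair("G1", "GTAAGT" + "ACGTACGT" + "TTTCAG", "GTAAGT" + "ACGTACGT" + "TTTCAG"),
        make_pair("G2", "GTGAGT" + "ACGTACGT" + "CTGCAG", "GTAAGT" + "ACGTACGT" + "CTGCAG"),
        make_pair("G3", "GTGAGA" + "AAAAAAAA" + "TTTTAG", "GTGAGA" + "CCCCCCCC" + "CTCCAG"),
        make_pair("G4", "GTAAGA" + "ACGTACGT" + "TTCTAG", "GTAAGG" + "ACGTACGT" + "TTCTAG"),
    ]


@pytest.fixture(scope="session")
def sim_pairs_and_truth():
    """A moderately sized seeded synthetic couple set shared across tests."""
    cfg = sc.GeneratorConfig(n_pairs=400, seed=11, intron_length_range=(120, 160))
    return sc.generate_pairs(cfg)


@pytest.fixture(scope="session")
def sim_pairs(sim_pairs_and_truth):
    return sim_pairs_and_truth[0]
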