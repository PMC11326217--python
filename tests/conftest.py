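import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_truth():
    """A small but fully featured synthetic pangenome (SVs, conversion, CNV)."""
    from pacn.simulate import SimConfig, simulate_pangenome

    cfg = SimConfig(
        seed=5,
        n_haplotypes=6,
        n_families=3,
        n_paralog_loci=2,
        gene_length_bp=1200,
        ortholog_divergence=0.005,
        sv_rate=0.1,
        conversion_rate=0.05,
        cnv_rate=0.2,
        cnv_max_extra=2,
        spacer_len_bp=1200,
        coverage=30.0,
        error_rate=0.0,
    )
    return simulate_pangenome(cfg)


@pytest.fixture(scope="session")
def desk_db_config():
    """Extraction parameters scaled to kilobase-sized simulated genes."""
    from pacn.pipeline import DatabaseConfig

    return DatabaseConfig(
        k=21, merge_gap_bp=500, flank_bp=150, min_len_bp=400, min_nonrepeat_bp=0
    )


@pytest.fixture(scope="session")
def small_db(small_truth, desk_db_config):
    from pacn.pipeline import build_database

    return build_database(small_truth.assemblies, small_truth.exons, desk_db_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
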