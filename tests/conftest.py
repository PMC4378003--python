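import pytest

from repolish.simulate import (
    SimConfig,
    degrade_assembly,
    generate_truth_region,
    simulate_read_pairs,
)


def small_config(**overrides) -> SimConfig:
    """A 30-kb region with a 4-gene cluster: fast enough for unit tests."""
    base = dict(
        region_len=30_000,
        n_cluster_genes=4,
        n_subclusters=2,
        gap_count=6,
        redundant_contig_count=2,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """One degraded 30-kb region with reads, shared across unit tests."""
    cfg = small_config()
    truth, models, cluster_map = generate_truth_region(cfg)
    draft, ledger = degrade_assembly(truth, cfg)
    reads = simulate_read_pairs(truth, cfg)
    return dict(
        cfg=cfg, truth=truth, models=models, cluster_map=cluster_map,
        draft=draft, ledger=ledger, reads=reads,
    )


@pytest.fixture(scope="session")
def clean_sim():
    """Same region with every degradation rate at zero and error-free reads."""
    cfg = small_config(
        gap_count=0, exact20_fraction=0.0, substitution_error_rate=0.0,
        homopolymer_indel_rate=0.0, redundant_contig_count=0, base_error_rate=0.0,
    )
    truth, models, cluster_map = generate_truth_region(cfg)
    draft, ledger = degrade_assembly(truth, cfg)
    reads = simulate_read_pairs(truth, cfg)
    return dict(
        cfg=cfg, truth=truth, models=models, cluster_map=cluster_map,
        draft=draft, ledger=ledger, reads=reads,
    )
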