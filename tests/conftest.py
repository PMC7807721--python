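import pytest

from splicecore.synthetic_data import SyntheticConfig, generate, orf_fixture_bank


@pytest.fixture(scope="session")
def bank():
    """Two-strand ORF-impact fixture bank: (models, events, labels, nmd)."""
    return orf_fixture_bank(seed=0)


@pytest.fixture(scope="session")
def noisefree_ds():
    """Small noise-free dataset: planted sets are exactly recoverable."""
    cfg = SyntheticConfig(seed=11, n_tissue_as=12, n_stress_as=12, n_panas=8,
                          n_null_events=90, n_ge_stress=10, n_ge_tissue=10,
                          n_lowexpr_genes=5, psi_noise_sd=0.0,
                          coverage_dropout_rate=0.0, ir_imbalance_rate=0.0,
                          expr_noise_sd=0.0)
    return generate(cfg)


@pytest.fixture(scope="session")
def noisy_ds():
    """Small dataset under the default noise/dropout conditions."""
    cfg = SyntheticConfig(seed=7, n_tissue_as=12, n_stress_as=12, n_panas=8,
                          n_null_events=90, n_ge_stress=10, n_ge_tissue=10,
                          n_lowexpr_genes=5)
    return generate(cfg)
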