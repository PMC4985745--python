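import pytest

from f2map import simcross


@pytest.fixture(scope="session")
def small_config():
    return simcross.SimConfig(
        scaffolds=[simcross.Scaffold("sc01", 1_000_000, 60.0)],
        n_progeny=30,
        snp_density=1e-4,
        mean_depth=10.0,
        per_read_error=0.005,
        missing_rate=0.02,
        trait_locus=("sc01", 300_000),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    founders = simcross.simulate_founders(small_config)
    truth = simcross.simulate_f2(founders, small_config)
    return small_config, founders, truth


@pytest.fixture(scope="session")
def small_vcf_dir(small_sim, tmp_path_factory):
    config, founders, truth = small_sim
    out = tmp_path_factory.mktemp("vcf")
    observations, paths = simcross.observe(truth, founders, config, out_dir=out)
    return config, founders, truth, observations, paths


def simulate_truth_matrix(
    n_progeny=60,
    length_cm=100.0,
    n_loci=120,
    seed=0,
    length_bp=1_000_000,
    trait_pos=None,
):
    """Error-free corrected-state matrix straight from simulated truth.

    Convenience for tests that exercise downstream stages without the
    observation noise layer.
    """
    config = simcross.SimConfig(
        scaffolds=[simcross.Scaffold("chr1", length_bp, length_cm)],
        n_progeny=n_progeny,
        snp_density=n_loci / length_bp,
        trait_locus=("chr1", trait_pos) if trait_pos else None,
        seed=seed,
    )
    founders = simcross.simulate_founders(config)
    truth = simcross.simulate_f2(founders, config)
    return config, founders, truth
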