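import pytest

from contextomics import synthetic


@pytest.fixture(scope="session")
def default_truth():
    """The default emulated cellular state (noise on)."""
    return synthetic.generate_truth(seed=11)


@pytest.fixture(scope="session")
def noiseless_truth():
    """Noise-free state: exact closure of the full pipeline is expected."""
    return synthetic.generate_truth(
        {"noise_cv": 0.0, "response_factor_sigma": 0.0, "lod_amol": 0.0}, seed=11
    )


@pytest.fixture(scope="session")
def noiseless_run(noiseless_truth):
    """Simulated lysate + AP designs at zero noise, as (rows, samples) pairs."""
    lys_rows, lys_samples = synthetic.simulate_lysate_quant(noiseless_truth, seed=21)
    ap_rows, ap_samples = synthetic.simulate_ap_quant(noiseless_truth, seed=22)
    return {
        "lysate": (lys_rows, {s.sample_id: s for s in lys_samples}),
        "ap": (ap_rows, {s.sample_id: s for s in ap_samples}),
    }
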