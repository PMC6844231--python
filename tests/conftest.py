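import numpy as np
import pytest

from vcdfit import (
    BroadeningConfig,
    ConformerRecord,
    Ensemble,
    StickSpectrum,
    SynthConfig,
    generate_ensemble,
    generate_experiment,
)


@pytest.fixture(scope="session")
def broadening():
    return BroadeningConfig()


@pytest.fixture(scope="session")
def tiny_ensemble():
    """Two hand-built conformers with distinct, partially opposing sticks."""
    s1 = StickSpectrum([1000.0, 1200.0, 1450.0], [1.0, 2.0, 0.5], [0.3, -0.4, 0.2])
    s2 = StickSpectrum([1050.0, 1200.0, 1500.0], [1.5, 1.0, 1.0], [-0.2, 0.4, -0.3])
    return Ensemble([ConformerRecord("a", 0.0, s1), ConformerRecord("b", 0.4, s2)])


@pytest.fixture(scope="session")
def clean_synth():
    """Noise-free synthetic data: experiment exactly explainable."""
    cfg = SynthConfig(n_conformers=4, baseline_noise=0.0, freq_perturbation_sigma=0.0, seed=77)
    ensemble, truth = generate_ensemble(cfg)
    exp_va, exp_vcd = generate_experiment(truth, cfg)
    return ensemble, truth, exp_va, exp_vcd


@pytest.fixture(scope="session")
def noisy_synth():
    """Default-noise synthetic data with energy corruption."""
    cfg = SynthConfig(n_conformers=6, energy_error_sigma=0.5, seed=78)
    ensemble, truth = generate_ensemble(cfg)
    exp_va, exp_vcd = generate_experiment(truth, cfg)
    return ensemble, truth, exp_va, exp_vcd
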