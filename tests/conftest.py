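"""Shared fixtures: wavelet banks and a small planted-truth study."""

import numpy as np
import pytest

from crossfreq import pipeline, synth
from crossfreq.spectral import WaveletBank


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bank600():
    return WaveletBank(sampling_rate=600.0, frequencies=np.asarray([10.0, 20.0, 30.0, 40.0]))


@pytest.fixture(scope="session")
def small_study():
    """A small study with one planted CFS, one load-slope and one PAC edge.

    Shared (read-only) across tests that exercise the analysis chain.
    """
    cfg = synth.StudyConfig(
        n_subjects=6,
        n_loads=6,
        n_trials_per_load=24,
        n_parcels=5,
        snr=2.0,
        seed=2024,
    )
    truth = [
        synth.CouplingSpec(0, 1, 10.0, 3, 0.8, "cfs", retention_only=True),
        synth.CouplingSpec(2, 3, 10.0, 2, 0.0, "cfs", load_slope=0.16, retention_only=True),
        synth.CouplingSpec(1, 4, 10.0, 4, 0.7, "pac", retention_only=True),
    ]
    return synth.generate_study(cfg, truth)


@pytest.fixture(scope="session")
def small_analysis():
    return pipeline.AnalysisConfig(f_lows=(10.0,), ratios=(2, 3, 4), fdr_method="bh")


@pytest.fixture(scope="session")
def small_tensors(small_study, small_analysis):
    return pipeline.compute_coupling(small_study, small_analysis)


@pytest.fixture(scope="session")
def small_stats(small_tensors, small_analysis):
    return pipeline.run_group_stats(small_tensors, small_analysis)
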