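import numpy as np
import pytest

from gss_hdemg.pipeline import BenchmarkSpec, SimConfig, run_benchmark
from gss_hdemg.preprocess import ConvolutiveSphering, bandpass, make_single_differential
from gss_hdemg.simulate import ElectrodeGrid


@pytest.fixture(scope="session")
def desk_sim():
    return SimConfig()


@pytest.fixture(scope="session")
def clean_signal(desk_sim):
    """One 30 dB / 10% MVC desk-scale contraction with ground truth."""
    return desk_sim.simulate(10.0, 30.0, seed=42)


@pytest.fixture(scope="session")
def whitened_obs(clean_signal):
    rec, _ = clean_signal
    sd = make_single_differential(bandpass(rec))
    sd = sd.copy_with(data=sd.data.astype(np.float32))
    obs = ConvolutiveSphering(R=30).fit_transform(sd)
    return sd, obs


@pytest.fixture(scope="session")
def tiny_grid():
    return ElectrodeGrid(rows=5, cols=4, ied_mm=5.0, fs_hz=4096.0)


@pytest.fixture(scope="session")
def benchmark_report():
    """The scaled-down 3-SNR × 3-MVC benchmark shared by the acceptance tests.

    Two seeded replicates per condition, guided method plus the gradient-CKC
    comparator on the same signals, and a no-Kalman re-run of the 30 dB
    signals for the iteration-ratio comparison.
    """
    spec = BenchmarkSpec(
        snr_list=(10.0, 20.0, 30.0),
        mvc_list=(10.0, 30.0, 50.0),
        replicates=2,
        seed=1,
        kalman_compare_snr=30.0,
    )
    return run_benchmark(spec, baseline=True)
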