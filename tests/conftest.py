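import numpy as np
import pytest

import peakdeconv as pdc


@pytest.fixture(scope="session")
def kernel340():
    """A mid-width Gamma kernel (shape 3, scale 40 bp, 10-bp bins)."""
    return pdc.discretize_kernel(3.0, 40.0, bin_size=10)


@pytest.fixture()
def sizes1():
    return {"chr1": 100_000}


def place_kernel(signal, kernel, shift, coef):
    """Add coef x kernel at a shift (in bins) to a signal vector, in place."""
    m = len(kernel.values)
    signal[shift : shift + m] += coef * kernel.values
    return signal


@pytest.fixture(scope="session")
def tf_simulation():
    """Transcription-factor-like simulation: 100 strong sites, fragment
    length 200 +/- 20, 36-bp reads, sparse background.  Shared by the
    fragment-length tests."""
    rng = np.random.default_rng(1)
    sites = pdc.random_sites(
        rng, 2_000_000, 100, min_height=500, max_height=500,
        min_separation=8000, margin=3000,
    )
    spec = pdc.SimulationSpec(
        length=2_000_000, sites=sites, fragment_len_mean=200.0,
        fragment_len_sd=20.0, read_len=36, background_rate=0.5, seed=1,
    )
    ip, ctrl, truth = pdc.simulate_reads(spec)
    return spec, ip, ctrl, truth


@pytest.fixture(scope="session")
def small_pipeline_run():
    """A small but complete peak-calling run (30 sites on 1 Mb) used by the
    pipeline smoke/contract tests; returns (spec, ip, ctrl, config, result)."""
    rng = np.random.default_rng(5)
    sites = pdc.random_sites(
        rng, 1_000_000, 30, min_height=30, max_height=80,
        min_separation=8000, margin=5000,
    )
    spec = pdc.SimulationSpec(length=1_000_000, sites=sites, seed=5)
    ip, ctrl, _ = pdc.simulate_reads(spec)
    cfg = pdc.RunConfig(elongation=200, n_boot=30, seed=5, quantile=0.995, min_regions=20)
    result = pdc.call_peaks(ip, spec.sizes, control_reads=ctrl, config=cfg)
    return spec, ip, ctrl, cfg, result
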