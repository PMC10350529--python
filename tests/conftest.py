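import numpy as np
import pytest

import hemospec as hs


@pytest.fixture(scope="session")
def chrom():
    return hs.load_chromophore_table()


@pytest.fixture(scope="session")
def scat():
    return hs.load_scattering_table()


@pytest.fixture(scope="session")
def tissue():
    return hs.TissueConfig()


@pytest.fixture(scope="session")
def instrument():
    return hs.InstrumentModel()


@pytest.fixture(scope="session")
def grid():
    return hs.default_grid()


@pytest.fixture(scope="session")
def model(tissue, chrom, scat, grid):
    """Forward model precompiled on the fit-window grid."""
    return hs.SpectralModel(tissue, chrom, scat, grid)


@pytest.fixture(scope="session")
def run_session(instrument, tissue, chrom, scat):
    """Factory: simulate a scenario end-to-end and fit it.

    Returns (truth, fitted series). Cached per (scenario, seed, params) so
    tests sharing a session do not re-fit it.
    """
    cache = {}

    def _run(scenario, seed, params=None, noise=True):
        key = (scenario, seed, params, noise)
        if key not in cache:
            truth = hs.make_trajectory(scenario, params, seed=seed if noise else None)
            spectra, cal, _ = hs.simulate_session(
                truth, instrument, tissue, chrom, scat, seed=seed, noise=noise
            )
            ms = [hs.calibrate(s, cal) for s in spectra]
            series = hs.fit_timeseries(ms, hs.FitOptions(), tissue, chrom, scat)
            cache[key] = (truth, series)
        return cache[key]

    return _run


def truth_series(truth):
    """Wrap a ground-truth trajectory as a perfect fitted series (for
    protocol-level tests that do not need the inversion)."""
    n = len(truth.timestamps_s)
    return hs.HemodynamicTimeSeries(
        timestamps_s=truth.timestamps_s,
        cbvf_percent=truth.cbvf * 100.0,
        so2_fraction=truth.so2.copy(),
        quality=np.array(["ok"] * n, dtype=object),
        rel_residual=np.zeros(n),
    )
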