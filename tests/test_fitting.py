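"""Spectral inversion: round trips, invariances, time series, decoupling."""

import dataclasses

import numpy as np
import pytest

import hemospec as hs


def synthetic_m(model, cbvf, so2, k=1.0, grid=None, timestamp=0.0):
    g = model.grid if grid is None else grid
    return hs.CalibratedSpectrum(g, k * model.rp(cbvf, so2), timestamp)


class TestFitSpectrum:
    @pytest.mark.parametrize(
        "cbvf,so2,k",
        [(0.019, 0.35, 1.0), (0.05, 0.8, 0.4), (0.008, 0.15, 3.0), (0.035, 0.6, 1.7)],
    )
    def test_noiseless_round_trip(self, model, tissue, chrom, scat, cbvf, so2, k):
        m = synthetic_m(model, cbvf, so2, k)
        fr = hs.fit_spectrum(m, hs.FitOptions(), tissue, chrom, scat)
        assert fr.converged
        assert fr.state.cbvf == pytest.approx(cbvf, abs=1e-3)
        assert fr.state.so2 == pytest.approx(so2, abs=1e-3)

    def test_k_absorbs_global_scale(self, model, tissue, chrom, scat):
        m1 = synthetic_m(model, 0.019, 0.35, 1.0)
        m2 = hs.CalibratedSpectrum(m1.wavelength_nm, 2.0 * m1.m)
        f1 = hs.fit_spectrum(m1, hs.FitOptions(), tissue, chrom, scat)
        f2 = hs.fit_spectrum(m2, hs.FitOptions(), tissue, chrom, scat)
        assert f2.state.cbvf == pytest.approx(f1.state.cbvf, abs=1e-4)
        assert f2.state.so2 == pytest.approx(f1.state.so2, abs=1e-4)
        assert f2.state.k == pytest.approx(2.0 * f1.state.k, rel=1e-3)

    def test_basin_robustness_from_dispersed_starts(self, model, tissue, chrom, scat):
        m = synthetic_m(model, 0.05, 0.8)
        starts = [(0.005, 0.1), (0.005, 0.9), (0.1, 0.2), (0.08, 0.95), (0.02, 0.5)]
        fits = [
            hs.fit_spectrum(
                m, hs.FitOptions(), tissue, chrom, scat,
                init=hs.HemodynamicState(c0, s0),
            )
            for c0, s0 in starts
        ]
        for fr in fits:
            assert fr.state.cbvf == pytest.approx(0.05, abs=1e-3)
            assert fr.state.so2 == pytest.approx(0.8, abs=1e-3)

    def test_objective_self_consistency(self, model, tissue, chrom, scat):
        """Reported SSE equals an independent residual recomputation."""
        rng = np.random.default_rng(2)
        m = hs.CalibratedSpectrum(
            model.grid, model.rp(0.02, 0.4) * (1 + 0.01 * rng.normal(size=len(model.grid)))
        )
        fr = hs.fit_spectrum(m, hs.FitOptions(), tissue, chrom, scat)
        resid = m.m - fr.state.k * model.rp(fr.state.cbvf, fr.state.so2)
        assert fr.sse == pytest.approx(float(resid @ resid), abs=1e-10)

    def test_invariant_to_wavelength_shuffle(self, model, tissue, chrom, scat):
        m = synthetic_m(model, 0.03, 0.6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(m.wavelength_nm))
        shuffled = hs.CalibratedSpectrum(m.wavelength_nm[perm], m.m[perm])
        f1 = hs.fit_spectrum(m, hs.FitOptions(), tissue, chrom, scat)
        f2 = hs.fit_spectrum(shuffled, hs.FitOptions(), tissue, chrom, scat)
        assert f2.state.cbvf == pytest.approx(f1.state.cbvf, abs=1e-5)
        assert f2.state.so2 == pytest.approx(f1.state.so2, abs=1e-5)

    def test_out_of_window_wavelengths_ignored(self, tissue, chrom, scat):
        wide = hs.default_grid(500.0, 700.0)
        model = hs.SpectralModel(tissue, chrom, scat, wide)
        m_wide = synthetic_m(model, 0.025, 0.45, grid=wide)
        m_window = m_wide.window(540.0, 650.0)
        f1 = hs.fit_spectrum(m_wide, hs.FitOptions(), tissue, chrom, scat)
        f2 = hs.fit_spectrum(m_window, hs.FitOptions(), tissue, chrom, scat)
        assert f1.state.cbvf == f2.state.cbvf
        assert f1.state.so2 == f2.state.so2

    def test_nonfinite_input_rejected(self, model, tissue, chrom, scat):
        m = synthetic_m(model, 0.02, 0.5)
        bad = hs.CalibratedSpectrum(m.wavelength_nm, np.where(
            m.wavelength_nm == 600.0, np.nan, m.m))
        with pytest.raises(ValueError, match="non-finite"):
            hs.fit_spectrum(bad, hs.FitOptions(), tissue, chrom, scat)

    def test_noisy_parameter_recovery(self, tissue, chrom, scat):
        """200 shot-noise spectra at the resting state: median |error| below
        0.1 pp (CBVF) and 2 pp (SO2); estimator bias within one standard
        error or below display precision (0.005 pp CBVF, 0.05 pp SO2).

        A leak-free instrument isolates the estimator: leak light adds a
        separate, QC-bounded model-mismatch offset tested elsewhere."""
        instrument = hs.InstrumentModel(leak_fraction=0.0)
        rng = np.random.default_rng(11)
        grid = hs.default_grid(500.0, 700.0)
        truth = hs.HemodynamicState(0.019, 0.35)
        cal = hs.make_calibration_pair(instrument, grid=grid)  # noiseless reference
        opts = hs.FitOptions(warm_start=False)
        errs_c, errs_s = [], []
        for _ in range(200):
            raw = hs.simulate_acquisition(
                truth, instrument, tissue, chrom, scat, grid=grid, rng=rng
            )
            fr = hs.fit_spectrum(hs.calibrate(raw, cal), opts, tissue, chrom, scat)
            errs_c.append(fr.state.cbvf - truth.cbvf)
            errs_s.append(fr.state.so2 - truth.so2)
        errs_c, errs_s = np.array(errs_c), np.array(errs_s)
        assert np.median(np.abs(errs_c)) < 0.001      # 0.1 percentage points
        assert np.median(np.abs(errs_s)) < 0.02       # 2 percentage points
        assert abs(errs_c.mean()) <= max(errs_c.std() / np.sqrt(len(errs_c)), 5e-5)
        assert abs(errs_s.mean()) <= max(errs_s.std() / np.sqrt(len(errs_s)), 5e-4)


class TestFitTimeseries:
    def test_single_spectrum_series(self, model, tissue, chrom, scat):
        m = synthetic_m(model, 0.02, 0.5)
        series = hs.fit_timeseries([m], hs.FitOptions(), tissue, chrom, scat)
        fr = hs.fit_spectrum(m, hs.FitOptions(), tissue, chrom, scat)
        assert len(series.timestamps_s) == 1
        assert series.cbvf_percent[0] == pytest.approx(100 * fr.state.cbvf, abs=1e-9)

    def test_step_change_located(self, model, tissue, chrom, scat):
        """Noiseless CBVF step 0.019 -> 0.025 at t=60 lands on that sample."""
        ms = [
            synthetic_m(model, 0.019 if t < 60 else 0.025, 0.35, timestamp=float(t))
            for t in range(120)
        ]
        series = hs.fit_timeseries(ms, hs.FitOptions(), tissue, chrom, scat)
        stepped = series.cbvf_percent > 2.2
        assert not stepped[:60].any()
        assert stepped[60:].all()

    def test_constant_session_low_variation(self, run_session):
        """Noisy constant-state session: fitted CV stays near shot-noise scale."""
        _, series = run_session("resting", seed=5,
                                params=hs.TrajectoryParams(duration_s=120.0,
                                                           jitter_rel_sd=0.0))
        cv = series.cbvf_percent.std() / series.cbvf_percent.mean()
        assert cv < 0.02
        assert series.ok.all()

    def test_empty_sequence_rejected(self, tissue, chrom, scat):
        with pytest.raises(ValueError, match="empty"):
            hs.fit_timeseries([], hs.FitOptions(), tissue, chrom, scat)


class TestDecoupling:
    def test_injected_interval_flagged(self, run_session):
        """Leak-dominated spectra over [100, 110] s are flagged (edge +/- 1)."""
        truth, series = run_session("decoupling", seed=3)
        flagged = set(series.timestamps_s[series.quality == "decoupled"])
        expected = set(truth.timestamps_s[truth.decoupled])
        assert expected <= flagged
        extras = flagged - expected
        assert all(min(abs(t - e) for e in expected) <= 1.0 for t in extras)

    def test_clean_session_unflagged(self, run_session):
        _, series = run_session("resting", seed=4,
                                params=hs.TrajectoryParams(duration_s=120.0))
        assert not (series.quality == "decoupled").any()

    def test_all_leak_session_fully_flagged(self, instrument, tissue, chrom, scat):
        params = hs.TrajectoryParams(duration_s=60.0,
                                     decouple_interval_s=(0.0, 60.0))
        truth = hs.make_trajectory("decoupling", params, seed=9)
        spectra, cal, _ = hs.simulate_session(
            truth, instrument, tissue, chrom, scat, seed=9
        )
        ms = [hs.calibrate(s, cal) for s in spectra]
        series = hs.fit_timeseries(ms, hs.FitOptions(), tissue, chrom, scat)
        assert (series.quality == "decoupled").all()
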