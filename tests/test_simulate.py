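"""Synthetic acquisition chain and ground-truth trajectory generator."""

import dataclasses

import numpy as np
import pytest

import hemospec as hs


class TestAcquisition:
    def test_full_chain_identity_without_noise_or_leak(self, tissue, chrom, scat):
        """Noise/leak off: calibrate(simulate(s)) is K*Rp up to a flat constant."""
        inst = hs.InstrumentModel(leak_fraction=0.0)
        grid = hs.default_grid(500.0, 700.0)
        state = hs.HemodynamicState(0.019, 0.35)
        raw = hs.simulate_acquisition(state, inst, tissue, chrom, scat, grid=grid)
        cal = hs.make_calibration_pair(inst, grid=grid)
        m = hs.calibrate(raw, cal)
        rp = hs.predicted_reflectance(state, tissue, chrom, scat, grid)
        # out-of-window channels may saturate (as on the real sensor); the
        # identity holds over the analysis window
        sel = (grid >= 540.0) & (grid <= 650.0)
        ratio = m.m[sel] / rp[sel]
        assert np.ptp(ratio) / ratio.mean() < 1e-10

    @pytest.mark.parametrize("temp_K", [2400.0, 3000.0, 3600.0])
    def test_auto_exposure_rule(self, tissue, chrom, scat, temp_K):
        """Windowed max expected count sits in [0.70, 0.90] of saturation for
        any lamp shape/brightness."""
        inst = hs.InstrumentModel(lamp_temperature_K=temp_K)
        grid = hs.default_grid(500.0, 700.0)
        raw = hs.simulate_acquisition(
            hs.HemodynamicState(0.019, 0.35), inst, tissue, chrom, scat, grid=grid
        )
        lo, hi = inst.exposure_window_nm
        sel = (grid >= lo) & (grid <= hi)
        frac = raw.counts[sel].max() / inst.saturation_level
        assert 0.70 <= frac <= 0.90

    def test_seeded_determinism(self, instrument, tissue, chrom, scat):
        state = hs.HemodynamicState(0.02, 0.5)
        kw = dict(grid=hs.default_grid(500.0, 700.0))
        a = hs.simulate_acquisition(state, instrument, tissue, chrom, scat,
                                    rng=np.random.default_rng(42), **kw)
        b = hs.simulate_acquisition(state, instrument, tissue, chrom, scat,
                                    rng=np.random.default_rng(42), **kw)
        c = hs.simulate_acquisition(state, instrument, tissue, chrom, scat,
                                    rng=np.random.default_rng(43), **kw)
        np.testing.assert_array_equal(a.counts, b.counts)
        assert not np.array_equal(a.counts, c.counts)

    def test_noise_matches_poisson_prediction(self, instrument, tissue, chrom, scat):
        """Empirical SD of repeated acquisitions vs sqrt(signal + read noise)."""
        grid = hs.default_grid(500.0, 700.0)
        state = hs.HemodynamicState(0.019, 0.35)
        expected = hs.simulate_acquisition(state, instrument, tissue, chrom, scat,
                                           grid=grid).counts
        rng = np.random.default_rng(8)
        reps = np.array([
            hs.simulate_acquisition(state, instrument, tissue, chrom, scat,
                                    grid=grid, rng=rng).counts
            for _ in range(400)
        ])
        signal = expected - instrument.dark_mean
        mid = (signal > 0.2 * signal.max()) & (signal < 0.8 * signal.max())
        predicted_sd = np.sqrt(signal[mid] + instrument.dark_sd**2)
        ratio = reps[:, mid].std(axis=0) / predicted_sd
        assert abs(ratio.mean() - 1.0) < 0.1

    def test_saturated_dark_rejected(self, tissue, chrom, scat):
        inst = hs.InstrumentModel(dark_mean=60000.0, saturation_level=65535.0)
        with pytest.raises(RuntimeError, match="satur"):
            hs.simulate_acquisition(
                hs.HemodynamicState(0.02, 0.5), inst, tissue, chrom, scat
            )

    def test_two_instruments_same_fitted_state(self, tissue, chrom, scat):
        """Calibration cancels lamp/detector shape: two different instruments
        yield the same fitted hemodynamics."""
        state = hs.HemodynamicState(0.024, 0.55)
        grid = hs.default_grid(500.0, 700.0)
        states = []
        for inst in (
            hs.InstrumentModel(leak_fraction=0.0, lamp_temperature_K=3000.0),
            hs.InstrumentModel(leak_fraction=0.0, lamp_temperature_K=2500.0,
                               detector_center_nm=560.0, detector_floor=0.6),
        ):
            raw = hs.simulate_acquisition(state, inst, tissue, chrom, scat, grid=grid)
            cal = hs.make_calibration_pair(inst, grid=grid)
            fr = hs.fit_spectrum(hs.calibrate(raw, cal), hs.FitOptions(),
                                 tissue, chrom, scat)
            states.append(fr.state)
        assert states[0].cbvf == pytest.approx(states[1].cbvf, abs=1e-6)
        assert states[0].so2 == pytest.approx(states[1].so2, abs=1e-6)

    def test_qc_ratio_passes_for_default_probe(self, instrument, tissue, chrom, scat):
        r1, r2 = hs.qc_counts(hs.HemodynamicState(0.019, 0.35),
                              instrument, tissue, chrom, scat)
        ratio, ok = hs.leak_snr(r1, r2)
        assert ok and ratio > 60


class TestTrajectories:
    def test_resting_constant_without_jitter(self):
        tr = hs.make_trajectory("resting", hs.TrajectoryParams(jitter_rel_sd=0.0))
        assert np.all(tr.cbvf == 0.019)
        assert np.all(tr.so2 == 0.35)
        assert not tr.decoupled.any()

    def test_hypercapnia_peak_exact_before_jitter(self):
        tr = hs.make_trajectory("hypercapnia", hs.TrajectoryParams(jitter_rel_sd=0.0))
        sel = (tr.timestamps_s >= 60) & (tr.timestamps_s <= 300)
        assert tr.cbvf[sel].max() == pytest.approx(0.019 * 1.169, rel=1e-9)
        assert tr.so2[sel].min() == pytest.approx(0.35 * 0.682, rel=1e-9)

    def test_rotarod_peak_exact_before_jitter(self):
        tr = hs.make_trajectory("rotarod", hs.TrajectoryParams(jitter_rel_sd=0.0))
        sel = (tr.timestamps_s >= 60) & (tr.timestamps_s <= 240)
        assert tr.cbvf[sel].max() == pytest.approx(0.019 * 1.052, rel=1e-9)
        assert tr.so2[sel].max() == pytest.approx(0.35 * 1.175, rel=1e-9)

    def test_decoupling_interval_exact(self):
        tr = hs.make_trajectory("decoupling", hs.TrajectoryParams())
        on = (tr.timestamps_s >= 100) & (tr.timestamps_s <= 110)
        np.testing.assert_array_equal(tr.decoupled, on)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            hs.make_trajectory("swimming")

    def test_unphysical_peak_rejected(self):
        with pytest.raises(ValueError):
            hs.make_trajectory(
                "hypercapnia",
                hs.TrajectoryParams(baseline_so2=0.9, so2_trough_pct=30.0,
                                    jitter_rel_sd=0.0),
            )


class TestSession:
    def test_session_shape(self, instrument, tissue, chrom, scat):
        tr = hs.make_trajectory("resting", hs.TrajectoryParams(duration_s=30.0))
        spectra, cal, truth = hs.simulate_session(
            tr, instrument, tissue, chrom, scat, seed=1
        )
        assert len(spectra) == 30
        ts = [s.timestamp_s for s in spectra]
        assert ts == sorted(ts)
        assert isinstance(cal, hs.CalibrationPair)

    def test_end_to_end_hypercapnia_recovery(self, run_session):
        """Full pipeline on one noisy hypercapnia session: summary tracks the
        injected response."""
        truth, series = run_session("hypercapnia", seed=21)
        s = hs.summarize_hypercapnia(series)
        assert s.max_cbvf_change_pct == pytest.approx(16.9, abs=2.0)
        assert s.min_so2_change_pct == pytest.approx(-31.8, abs=3.5)

    def test_recovery_scoring_against_injected_truth(self, run_session):
        """Across 20 seeded hypercapnia sessions, the mean recovered peak CBVF
        change stays within one standard error of the truth-trajectory value
        computed by the same summary; CBVF time-to-baseline is observable
        (uncensored, inside the recovery window) in the large majority of
        sessions."""
        from conftest import truth_series

        diffs, ttb, censored = [], [], 0
        for seed in range(100, 120):
            truth, series = run_session("hypercapnia", seed)
            s = hs.summarize_hypercapnia(series)
            true_peak = hs.summarize_hypercapnia(truth_series(truth)).max_cbvf_change_pct
            diffs.append(s.max_cbvf_change_pct - true_peak)
            censored += s.time_to_baseline_censored
            if not s.time_to_baseline_censored:
                ttb.append(s.time_to_baseline_s)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= max(se, 0.05)
        assert censored <= 6  # noisy tails may censor occasionally
        assert 20.0 < np.median(ttb) < 59.0

    def test_decoupled_samples_leak_dominated(self, run_session):
        """Fits on detached-probe samples deviate grossly, as in the
        instrument's decoupling readout."""
        truth, series = run_session("decoupling", seed=12)
        dec = truth.decoupled
        assert np.all(np.abs(series.cbvf_percent[dec] - 1.9) > 1.0)
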