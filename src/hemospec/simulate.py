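"""Synthetic acquisition chain and ground-truth physiology for testing.

Emulates the full measurement stack with no hardware: a broadband lamp and
detector response shape the expected photon counts,

    counts(lambda) = gain * lamp * detector * [(1-leak)*Rp + leak] + dark,

where ``Rp`` is the diffusion-model reflectance of the current hemodynamic
state, ``leak`` the fraction of source light reaching the detector directly
(magnetic-coupling leak), and ``gain`` an integration gain auto-scaled so
the maximum expected in-window count sits between 70% and 90% of the
detector saturation level, as the real spectrometer does. Shot noise is
Poisson on the signal counts plus Gaussian read noise on the dark level.

Ground-truth (CBVF, SO2) trajectories reproduce the study protocols:
resting, rotarod running (rise during the 60-240 s run window), hypercapnia
(exponential CBVF rise and slow SO2 decline over 60-300 s, rapid SO2
normalization and a transient CBVF overshoot after CO2 release) and probe
decoupling (leak-dominated spectra over a stated interval). The peak
percent changes are hit exactly at the end of the challenge window before
physiological jitter is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from numpy.typing import NDArray

from .calibration import CalibrationPair, CalibratedSpectrum, RawSpectrum
from .fitting import SpectralModel
from .optics import ChromophoreTable, ScatteringTable, TissueConfig, default_grid
from .state import HemodynamicState

__all__ = [
    "InstrumentModel",
    "TrajectoryParams",
    "TruthTrajectory",
    "simulate_acquisition",
    "make_calibration_pair",
    "qc_counts",
    "make_trajectory",
    "simulate_session",
]

SCENARIOS = ("resting", "rotarod", "hypercapnia", "decoupling")


@dataclass(frozen=True)
class InstrumentModel:
    """Simulated lamp + detector + spectrometer.

    The lamp is a blackbody-like broadband shape (temperature in K) and the
    detector response a smooth positive bump; their exact shapes are
    immaterial because calibration cancels them. ``leak_fraction`` is
    expressed on the scale of the diffuse reflectance Rp.
    """

    lamp_temperature_K: float = 3000.0
    detector_center_nm: float = 620.0
    detector_width_nm: float = 220.0
    detector_floor: float = 0.35
    dark_mean: float = 150.0
    dark_sd: float = 4.0
    saturation_level: float = 65535.0
    leak_fraction: float = 2e-4
    exposure_target: float = 0.80  # fraction of saturation for the windowed max
    exposure_window_nm: Tuple[float, float] = (540.0, 650.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.leak_fraction < 1.0):
            raise ValueError("leak_fraction must lie in [0, 1)")
        if self.saturation_level <= self.dark_mean:
            raise ValueError("saturation level must exceed the dark level")
        if not (0.70 <= self.exposure_target <= 0.90):
            raise ValueError("exposure target must lie in [0.70, 0.90]")

    def lamp_spectrum(self, grid: NDArray[np.float64]) -> NDArray[np.float64]:
        lam_m = np.asarray(grid, dtype=float) * 1e-9
        hc_over_kT = 1.4388e-2 / self.lamp_temperature_K  # m*K
        shape = lam_m**-5 / np.expm1(hc_over_kT / lam_m)
        return shape / shape.max()

    def detector_response(self, grid: NDArray[np.float64]) -> NDArray[np.float64]:
        grid = np.asarray(grid, dtype=float)
        bump = np.exp(-0.5 * ((grid - self.detector_center_nm) / self.detector_width_nm) ** 2)
        return self.detector_floor + (1.0 - self.detector_floor) * bump


def _chain(instrument: InstrumentModel, grid: NDArray[np.float64]) -> NDArray[np.float64]:
    return instrument.lamp_spectrum(grid) * instrument.detector_response(grid)


def _auto_gain(instrument: InstrumentModel, grid: NDArray[np.float64],
               signal_shape: NDArray[np.float64]) -> float:
    """Integration gain putting the windowed max expected count at the target."""
    lo, hi = instrument.exposure_window_nm
    sel = (grid >= lo) & (grid <= hi)
    peak = float(signal_shape[sel].max()) if sel.any() else float(signal_shape.max())
    headroom = instrument.exposure_target * instrument.saturation_level - instrument.dark_mean
    if headroom <= 0:
        raise RuntimeError("saturated dark level: exposure target unattainable")
    if peak <= 0:
        raise RuntimeError("no signal to expose on")
    return headroom / peak


def _counts(
    instrument: InstrumentModel,
    grid: NDArray[np.float64],
    reflectance: NDArray[np.float64],
    gain: Optional[float],
    rng: Optional[np.random.Generator],
) -> Tuple[NDArray[np.float64], float]:
    shape = _chain(instrument, grid) * reflectance
    if gain is None:
        gain = _auto_gain(instrument, grid, shape)
    expected_signal = gain * shape
    if rng is None:
        counts = expected_signal + instrument.dark_mean
    else:
        counts = rng.poisson(expected_signal).astype(float)
        counts += rng.normal(instrument.dark_mean, instrument.dark_sd, size=grid.shape)
        counts = np.clip(counts, 0.0, None)
    return np.minimum(counts, instrument.saturation_level), gain


def _effective_reflectance(
    rp: NDArray[np.float64], leak: float, decoupled: bool,
    tissue_suppression: float = 1e-4,
) -> NDArray[np.float64]:
    """Detachment breaks the fiber path almost completely: the decoupled
    spectrum is leak light plus a vestigial tissue term."""
    tissue = rp * (tissue_suppression if decoupled else 1.0)
    return (1.0 - leak) * tissue + leak


def simulate_acquisition(
    state: HemodynamicState,
    instrument: InstrumentModel,
    config: TissueConfig,
    chromophores: ChromophoreTable,
    scattering: ScatteringTable,
    grid: Optional[NDArray[np.float64]] = None,
    rng: Optional[np.random.Generator] = None,
    timestamp_s: float = 0.0,
    gain: Optional[float] = None,
    decoupled: bool = False,
    model: Optional[SpectralModel] = None,
) -> RawSpectrum:
    """Simulate one raw tissue spectrum at a hemodynamic state.

    ``rng=None`` disables noise (expected counts); ``gain=None`` auto-exposes
    this acquisition, otherwise the supplied session gain is reused.
    """
    grid = default_grid(500.0, 700.0) if grid is None else np.asarray(grid, dtype=float)
    if model is None or not np.array_equal(model.grid, grid):
        model = SpectralModel(config, chromophores, scattering, grid)
    rp = model.rp(state.cbvf, state.so2)
    refl = _effective_reflectance(rp, instrument.leak_fraction, decoupled)
    counts, _ = _counts(instrument, grid, refl, gain, rng)
    return RawSpectrum(grid, counts, timestamp_s=timestamp_s)


def make_calibration_pair(
    instrument: InstrumentModel,
    grid: Optional[NDArray[np.float64]] = None,
    rng: Optional[np.random.Generator] = None,
    standard_reflectance: float = 0.99,
) -> CalibrationPair:
    """Simulated calibration pair: 99% reflectance standard plus dark frame."""
    grid = default_grid(500.0, 700.0) if grid is None else np.asarray(grid, dtype=float)
    leak = instrument.leak_fraction
    refl = np.full_like(grid, (1.0 - leak) * standard_reflectance + leak)
    ref_counts, _ = _counts(instrument, grid, refl, None, rng)
    if rng is None:
        dark_counts = np.full_like(grid, instrument.dark_mean)
    else:
        dark_counts = np.clip(
            rng.normal(instrument.dark_mean, instrument.dark_sd, size=grid.shape), 0.0, None
        )
    return CalibrationPair(
        reference=RawSpectrum(grid, ref_counts),
        dark=RawSpectrum(grid, dark_counts),
    )


def qc_counts(
    state: HemodynamicState,
    instrument: InstrumentModel,
    config: TissueConfig,
    chromophores: ChromophoreTable,
    scattering: ScatteringTable,
    anchor_nm: float = 650.0,
) -> Tuple[float, float]:
    """Expected dark-subtracted counts at the QC anchor wavelength for the
    black-target (R1, pure leak) and on-tissue (R2) measurements, at a
    common gain set by the tissue exposure."""
    grid = default_grid(500.0, 700.0)
    model = SpectralModel(config, chromophores, scattering, grid)
    rp = model.rp(state.cbvf, state.so2)
    leak = instrument.leak_fraction
    chain = _chain(instrument, grid)
    tissue_shape = chain * ((1.0 - leak) * rp + leak)
    gain = _auto_gain(instrument, grid, tissue_shape)
    i = int(np.argmin(np.abs(grid - anchor_nm)))
    r1 = gain * chain[i] * leak
    r2 = gain * tissue_shape[i]
    return float(r1), float(r2)


@dataclass(frozen=True)
class TrajectoryParams:
    """Scenario parameters for ground-truth trajectories.

    Baseline levels are the study's resting cortical values (CBVF 1.9%,
    SO2 35%). Peak percent changes default to the reported group means:
    hypercapnia +16.9% CBVF / -31.8% SO2, rotarod +5.2% CBVF / +17.5% SO2.
    Time constants: CBVF rise 30 s, SO2 decline 120 s, post-release
    normalization 10 s.
    """

    baseline_cbvf: float = 0.019
    baseline_so2: float = 0.35
    duration_s: float = 360.0
    sampling_hz: float = 1.0
    # physiological jitter (relative SD, AR(1) correlation time)
    jitter_rel_sd: float = 0.003
    jitter_tau_s: float = 10.0
    # challenge windows
    t_on_s: float = 60.0
    t_off_s: float = 300.0          # hypercapnia CO2 release
    t_run_end_s: float = 240.0      # rotarod run end
    # hypercapnia response
    cbvf_peak_pct: float = 16.9
    so2_trough_pct: float = -31.8
    tau_cbvf_s: float = 30.0
    tau_so2_s: float = 120.0
    tau_release_s: float = 10.0
    overshoot_frac: float = 0.25    # post-release CBVF overshoot, fraction of peak rise
    overshoot_tau_s: float = 5.0
    cbvf_return_tau_s: float = 15.0  # fast enough to re-reach baseline in-session
    # rotarod response
    rotarod_cbvf_peak_pct: float = 5.2
    rotarod_so2_peak_pct: float = 17.5
    # decoupling scenario
    decouple_interval_s: Tuple[float, float] = (100.0, 110.0)


@dataclass
class TruthTrajectory:
    """Ground-truth physiology: (CBVF, SO2) and decoupling vs time."""

    timestamps_s: NDArray[np.float64]
    cbvf: NDArray[np.float64]
    so2: NDArray[np.float64]
    decoupled: NDArray[np.bool_]
    behavior: Optional[NDArray[np.str_]] = None
    scenario: str = "resting"

    def __post_init__(self) -> None:
        n = len(self.timestamps_s)
        if not (len(self.cbvf) == len(self.so2) == len(self.decoupled) == n):
            raise ValueError("trajectory columns must share a length")
        if np.any((self.cbvf < 0) | (self.cbvf > 1) | (self.so2 < 0) | (self.so2 > 1)):
            raise ValueError("cbvf and so2 must stay within [0, 1]")


def _saturating_rise(t: NDArray, t_on: float, t_off: float, tau: float) -> NDArray:
    """0 before t_on, exponential approach normalized to reach exactly 1 at t_off."""
    shape = np.zeros_like(t)
    rising = (t >= t_on) & (t <= t_off)
    denom = -np.expm1(-(t_off - t_on) / tau)
    shape[rising] = -np.expm1(-(t[rising] - t_on) / tau) / denom
    return shape


def _ar1_jitter(rng: np.random.Generator, n: int, dt: float, tau: float) -> NDArray:
    rho = np.exp(-dt / tau)
    x = np.empty(n)
    x[0] = rng.normal()
    innov = rng.normal(size=n - 1) * np.sqrt(1.0 - rho**2) if n > 1 else []
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i - 1]
    return x


def make_trajectory(
    scenario: str,
    params: Optional[TrajectoryParams] = None,
    seed: Optional[int] = None,
) -> TruthTrajectory:
    """Build a ground-truth trajectory for one of the study scenarios.

    Before jitter, the injected peak percent change is attained exactly at
    the end of the challenge window. ``seed=None`` with zero
    ``jitter_rel_sd`` gives a noise-free trajectory.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    p = params or TrajectoryParams()
    dt = 1.0 / p.sampling_hz
    t = np.arange(0.0, p.duration_s, dt)
    base_c, base_s = p.baseline_cbvf, p.baseline_so2
    cbvf = np.full_like(t, base_c)
    so2 = np.full_like(t, base_s)
    decoupled = np.zeros(len(t), dtype=bool)
    behavior = np.full(len(t), "resting", dtype=object)

    if scenario == "rotarod":
        rise_c = _saturating_rise(t, p.t_on_s, p.t_run_end_s, p.tau_cbvf_s)
        rise_s = _saturating_rise(t, p.t_on_s, p.t_run_end_s, p.tau_cbvf_s)
        after = t > p.t_run_end_s
        decay = np.exp(-(t[after] - p.t_run_end_s) / p.cbvf_return_tau_s)
        cbvf = base_c * (1.0 + p.rotarod_cbvf_peak_pct / 100.0 * rise_c)
        so2 = base_s * (1.0 + p.rotarod_so2_peak_pct / 100.0 * rise_s)
        cbvf[after] = base_c * (1.0 + p.rotarod_cbvf_peak_pct / 100.0 * decay)
        so2[after] = base_s * (1.0 + p.rotarod_so2_peak_pct / 100.0 * decay)
        behavior[(t >= p.t_on_s) & (t <= p.t_run_end_s)] = "running"
    elif scenario == "hypercapnia":
        rise_c = _saturating_rise(t, p.t_on_s, p.t_off_s, p.tau_cbvf_s)
        fall_s = _saturating_rise(t, p.t_on_s, p.t_off_s, p.tau_so2_s)
        cbvf = base_c * (1.0 + p.cbvf_peak_pct / 100.0 * rise_c)
        so2 = base_s * (1.0 + p.so2_trough_pct / 100.0 * fall_s)
        after = t > p.t_off_s
        ta = t[after] - p.t_off_s
        # CBVF: brief overshoot above the release level, then return to baseline
        peak_rise = p.cbvf_peak_pct / 100.0
        over = 1.0 + p.overshoot_frac * -np.expm1(-ta / p.overshoot_tau_s)
        cbvf[after] = base_c * (1.0 + peak_rise * over * np.exp(-ta / p.cbvf_return_tau_s))
        # SO2: rapid normalization from the full trough reached at release
        trough_dev = base_s * p.so2_trough_pct / 100.0
        so2[after] = base_s + trough_dev * np.exp(-ta / p.tau_release_s)
    elif scenario == "decoupling":
        lo, hi = p.decouple_interval_s
        decoupled = (t >= lo) & (t <= hi)

    if seed is not None and p.jitter_rel_sd > 0:
        rng = np.random.default_rng(seed)
        cbvf = cbvf * (1.0 + p.jitter_rel_sd * _ar1_jitter(rng, len(t), dt, p.jitter_tau_s))
        so2 = so2 * (1.0 + p.jitter_rel_sd * _ar1_jitter(rng, len(t), dt, p.jitter_tau_s))

    cbvf = np.clip(cbvf, 0.0, 1.0)
    so2 = np.clip(so2, 0.0, 1.0)
    if np.any(cbvf >= 1.0) or np.any(so2 >= 1.0):
        raise ValueError("scenario parameters push cbvf/so2 outside [0, 1]")
    return TruthTrajectory(t, cbvf, so2, decoupled, behavior, scenario)


def simulate_session(
    trajectory: TruthTrajectory,
    instrument: InstrumentModel,
    config: TissueConfig,
    chromophores: ChromophoreTable,
    scattering: ScatteringTable,
    grid: Optional[NDArray[np.float64]] = None,
    seed: Optional[int] = None,
    noise: bool = True,
) -> Tuple[List[RawSpectrum], CalibrationPair, TruthTrajectory]:
    """Acquire one raw spectrum per trajectory sample plus a calibration pair.

    The integration gain is auto-exposed once at session start (first
    trajectory state) and held, as with the real spectrometer's iterative
    auto-integration; decoupled samples are produced leak-dominated (tissue
    term suppressed) at that same gain.
    """
    grid = default_grid(500.0, 700.0) if grid is None else np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed) if noise else None
    model = SpectralModel(config, chromophores, scattering, grid)

    rp0 = model.rp(trajectory.cbvf[0], trajectory.so2[0])
    shape0 = _chain(instrument, grid) * _effective_reflectance(
        rp0, instrument.leak_fraction, decoupled=False)
    gain = _auto_gain(instrument, grid, shape0)

    spectra: List[RawSpectrum] = []
    for i, ts in enumerate(trajectory.timestamps_s):
        state = HemodynamicState(trajectory.cbvf[i], trajectory.so2[i], 1.0)
        spectra.append(
            simulate_acquisition(
                state, instrument, config, chromophores, scattering,
                grid=grid, rng=rng, timestamp_s=float(ts), gain=gain,
                decoupled=bool(trajectory.decoupled[i]), model=model,
            )
        )
    cal = make_calibration_pair(instrument, grid=grid, rng=rng)
    return spectra, cal, trajectory
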