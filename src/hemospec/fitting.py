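"""Per-spectrum spectral inversion and time-series fitting.

Each calibrated spectrum M(lambda) over the 540-650 nm window is inverted
for (CBVF, SO2, K) by minimizing the unweighted sum of squared residuals
between M and the diffusion-model prediction K*Rp(lambda; CBVF, SO2) with a
Nelder-Mead simplex. The simplex itself is unconstrained; physical bounds
are kept by optimizing transformed coordinates (logistic for the two
fractions, log for K) and reporting natural units.

Time-series fitting warm-starts each spectrum from the previous accepted
fit and flags decoupling events (magnetic probe detachment) from the fit
residuals: a sample is decoupled when its relative residual exceeds a
multiple of its rolling median, or when the fitted blood volume fraction
pins at a bound for several consecutive samples. Decoupled samples are
excluded from all protocol summaries downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy.optimize import minimize
from scipy.special import expit, logit

from .calibration import CalibratedSpectrum
from .forward import boundary_params
from .optics import ChromophoreTable, ScatteringTable, TissueConfig, mixed_scattering
from .state import HemodynamicState

__all__ = [
    "FitOptions",
    "FitResult",
    "HemodynamicTimeSeries",
    "SpectralModel",
    "fit_spectrum",
    "fit_timeseries",
    "detect_decoupling",
]


@dataclass(frozen=True)
class FitOptions:
    """Inversion settings (window, initialization, simplex tolerances)."""

    fit_window_nm: Tuple[float, float] = (540.0, 650.0)
    initial_cbvf: float = 0.02
    initial_so2: float = 0.5
    xtol: float = 1e-6          # simplex spread tolerance, transformed coords
    ftol: float = 1e-9          # objective spread tolerance (SSE units)
    max_iter_per_param: int = 400
    warm_start: bool = True
    # decoupling detection
    decouple_factor: float = 3.0       # rel-residual vs rolling median
    decouple_window: int = 31          # rolling-median width, samples
    decouple_min_residual: float = 1e-4  # ratio rule floor: below this a fit is clean
    pin_run_length: int = 3            # consecutive pinned samples
    pin_tol: float = 1e-3              # distance from a [0,1] bound that counts as pinned

    def __post_init__(self) -> None:
        lo, hi = self.fit_window_nm
        if not lo < hi:
            raise ValueError("fit window must be a nonempty interval")
        if self.xtol <= 0 or self.ftol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one spectral inversion."""

    state: HemodynamicState
    sse: float
    rel_residual: float
    iterations: int
    converged: bool
    quality: str = "ok"  # ok | suspect | decoupled


@dataclass
class HemodynamicTimeSeries:
    """Fitted (CBVF, SO2) vs time, in the readout units of the instrument
    display: CBVF x 100 (percent) and SO2 as a fraction."""

    timestamps_s: NDArray[np.float64]
    cbvf_percent: NDArray[np.float64]
    so2_fraction: NDArray[np.float64]
    quality: NDArray[np.str_]
    rel_residual: NDArray[np.float64]
    fits: List[FitResult] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        n = len(self.timestamps_s)
        if not all(len(a) == n for a in (self.cbvf_percent, self.so2_fraction,
                                         self.quality, self.rel_residual)):
            raise ValueError("time-series columns must have equal length")
        if n > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def ok(self) -> NDArray[np.bool_]:
        return np.asarray(self.quality) == "ok"

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp_s": self.timestamps_s,
                "cbvf_percent": self.cbvf_percent,
                "so2_fraction": self.so2_fraction,
                "quality": self.quality,
                "rel_residual": self.rel_residual,
            }
        )


class SpectralModel:
    """Forward model specialized to one wavelength grid (precomputed tables).

    Holds the interpolated chromophore/scattering columns so that the
    objective evaluated inside the simplex loop is a handful of vector ops.
    """

    def __init__(
        self,
        config: TissueConfig,
        chromophores: ChromophoreTable,
        scattering: ScatteringTable,
        grid: NDArray[np.float64],
    ) -> None:
        self.grid = np.asarray(grid, dtype=float)
        self.config = config
        oxy, deoxy, water = chromophores.interp(self.grid)
        self._oxy = oxy
        self._deoxy = deoxy
        self._w_water = config.w * water
        _, _, self._musp = mixed_scattering(scattering, self.grid)
        _, self._A = boundary_params(config.n_rel)
        self._r2sep = config.r_cm**2

    def rp(self, cbvf: float, so2: float) -> NDArray[np.float64]:
        """Diffuse reflectance Rp(lambda) at a hemodynamic state."""
        mu_a = cbvf * (so2 * self._oxy + (1.0 - so2) * self._deoxy) + self._w_water
        z0 = 1.0 / (mu_a + self._musp)
        D = z0 / 3.0
        mu_eff = np.sqrt(mu_a / D)
        zb = z0 + 4.0 * self._A * D
        r1 = np.sqrt(z0 * z0 + self._r2sep)
        r2 = np.sqrt(zb * zb + self._r2sep)
        c = z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / (r1 * r1)
        d = zb * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / (r2 * r2)
        return (c + d) / (4.0 * np.pi)


def _windowed(m: CalibratedSpectrum, opts: FitOptions) -> CalibratedSpectrum:
    lo, hi = opts.fit_window_nm
    win = m.window(lo, hi)
    if win.m.size == 0:
        raise ValueError("spectrum does not cover the fit window")
    if not np.all(np.isfinite(win.m)):
        raise ValueError("non-finite calibrated values inside the fit window")
    return win


def fit_spectrum(
    m: CalibratedSpectrum,
    opts: FitOptions,
    config: TissueConfig,
    chromophores: ChromophoreTable,
    scattering: ScatteringTable,
    model: Optional[SpectralModel] = None,
    init: Optional[HemodynamicState] = None,
) -> FitResult:
    """Invert one calibrated spectrum for (CBVF, SO2, K).

    ``model`` may be passed to reuse precomputed tables across many spectra
    sharing a grid; ``init`` overrides the default initial state (used for
    warm starts).
    """
    win = _windowed(m, opts)
    if model is None or not np.array_equal(model.grid, win.wavelength_nm):
        model = SpectralModel(config, chromophores, scattering, win.wavelength_nm)
    y = win.m
    y_norm = float(np.linalg.norm(y))

    cbvf0 = init.cbvf if init is not None else opts.initial_cbvf
    so20 = init.so2 if init is not None else opts.initial_so2
    cbvf0 = float(np.clip(cbvf0, 1e-6, 1.0 - 1e-6))
    so20 = float(np.clip(so20, 1e-6, 1.0 - 1e-6))
    rp0 = model.rp(cbvf0, so20)
    if init is not None:
        k0 = init.k
    else:
        k0 = float(np.median(y / rp0))
    if not np.isfinite(k0) or k0 <= 0:
        k0 = max(float(np.mean(np.abs(y)) / np.mean(rp0)), 1e-12)

    def objective(u: NDArray[np.float64]) -> float:
        cbvf = expit(u[0])
        so2 = expit(u[1])
        k = np.exp(u[2])
        resid = y - k * model.rp(cbvf, so2)
        return float(resid @ resid)

    u0 = np.array([logit(cbvf0), logit(so20), np.log(k0)])
    res = minimize(
        objective,
        u0,
        method="Nelder-Mead",
        options={
            "xatol": opts.xtol,
            "fatol": opts.ftol,
            "maxiter": opts.max_iter_per_param * 3,
            "maxfev": opts.max_iter_per_param * 3 * 2,
        },
    )
    cbvf, so2, k = float(expit(res.x[0])), float(expit(res.x[1])), float(np.exp(res.x[2]))
    sse = float(res.fun)
    rel = np.sqrt(sse) / y_norm if y_norm > 0 else np.inf
    converged = bool(res.success)
    return FitResult(
        state=HemodynamicState(cbvf, so2, k),
        sse=sse,
        rel_residual=float(rel),
        iterations=int(res.nit),
        converged=converged,
        quality="ok" if converged else "suspect",
    )


def fit_timeseries(
    spectra: Sequence[CalibratedSpectrum],
    opts: FitOptions,
    config: TissueConfig,
    chromophores: ChromophoreTable,
    scattering: ScatteringTable,
    flag_decoupling: bool = True,
) -> HemodynamicTimeSeries:
    """Fit a session of calibrated spectra into a hemodynamic time series.

    Spectra must share a wavelength grid and have strictly increasing
    timestamps. Each fit is warm-started from the previous accepted fit when
    ``opts.warm_start`` is on. Decoupling flags are applied at the end unless
    ``flag_decoupling`` is disabled.
    """
    if len(spectra) == 0:
        raise ValueError("empty spectrum sequence")
    grid0 = spectra[0].wavelength_nm
    for s in spectra[1:]:
        if not np.array_equal(s.wavelength_nm, grid0):
            raise ValueError("spectra in a session must share a wavelength grid")

    win0 = _windowed(spectra[0], opts)
    model = SpectralModel(config, chromophores, scattering, win0.wavelength_nm)

    fits: List[FitResult] = []
    prev: Optional[HemodynamicState] = None
    for s in spectra:
        fr = fit_spectrum(s, opts, config, chromophores, scattering,
                          model=model, init=prev if opts.warm_start else None)
        fits.append(fr)
        if fr.quality == "ok":
            prev = fr.state

    series = HemodynamicTimeSeries(
        timestamps_s=np.array([s.timestamp_s for s in spectra], dtype=float),
        cbvf_percent=np.array([f.state.cbvf * 100.0 for f in fits]),
        so2_fraction=np.array([f.state.so2 for f in fits]),
        quality=np.array([f.quality for f in fits], dtype=object),
        rel_residual=np.array([f.rel_residual for f in fits]),
        fits=fits,
    )
    if flag_decoupling:
        flags = detect_decoupling(series, opts=opts)
        series.quality[flags] = "decoupled"
        series.fits = [replace(f, quality="decoupled") if d else f
                       for f, d in zip(series.fits, flags)]
    return series


def detect_decoupling(
    series: HemodynamicTimeSeries,
    residuals: Optional[NDArray[np.float64]] = None,
    opts: Optional[FitOptions] = None,
) -> NDArray[np.bool_]:
    """Flag probe-decoupling samples in a fitted series.

    A sample is flagged when its relative fit residual exceeds
    ``decouple_factor`` times the rolling median of residuals, or when the
    fitted CBVF sits within ``pin_tol`` of a [0, 1] bound for at least
    ``pin_run_length`` consecutive samples (leak-dominated spectra drive the
    blood fraction to a bound).
    """
    opts = opts or FitOptions()
    resid = np.asarray(residuals if residuals is not None else series.rel_residual,
                       dtype=float)
    if len(resid) != len(series.timestamps_s):
        raise ValueError("residuals are not aligned to the series")

    rolling = (
        pd.Series(resid)
        .rolling(opts.decouple_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    flags = (resid > opts.decouple_factor * rolling) & (resid > opts.decouple_min_residual)

    cbvf = series.cbvf_percent / 100.0
    pinned = (cbvf <= opts.pin_tol) | (cbvf >= 1.0 - opts.pin_tol)
    run = 0
    for i, p in enumerate(pinned):
        run = run + 1 if p else 0
        if run == opts.pin_run_length:
            flags[i - run + 1 : i + 1] = True
        elif run > opts.pin_run_length:
            flags[i] = True
    return flags
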