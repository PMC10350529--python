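"""Packaged tissue optical properties and their composition rules.

The package ships reference tables (delimited text under ``hemospec/data``)
for whole-blood hemoglobin absorption at the 150 g/L reference concentration,
pure-water absorption, and white/gray-matter scattering. This module loads
them and composes the tissue-level coefficients used by the diffusion forward
model:

* absorption as a chromophore mixture
  ``mu_a = CBVF*[SO2*mu_a_oxy + (1-SO2)*mu_a_deoxy] + W*mu_a_water``,
* scattering as a 1/3 white : 2/3 gray weighted sum of ``mu_s`` and ``g``,
  with reduced scattering ``mu_s' = mu_s*(1-g)``,
* the transport scattering mean free path ``MFP' = 1/mu_s'``.

All coefficients are per cm on wavelength grids in nm; interpolation is
linear and strictly refused outside the shipped [500, 700] nm coverage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Tuple

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .state import HemodynamicState

__all__ = [
    "ChromophoreTable",
    "ScatteringTable",
    "TissueConfig",
    "load_chromophore_table",
    "load_scattering_table",
    "load_manifest",
    "absorption_coefficient",
    "mixed_scattering",
    "transport_mfp",
    "isosbestic_points",
    "default_grid",
]

#: Default working grid: the 540-650 nm fit window at 1 nm steps.
FIT_WINDOW_NM = (540.0, 650.0)


def default_grid(start: float = FIT_WINDOW_NM[0], stop: float = FIT_WINDOW_NM[1],
                 step: float = 1.0) -> NDArray[np.float64]:
    """Working wavelength grid in nm (inclusive of both endpoints)."""
    return np.arange(start, stop + 0.5 * step, step, dtype=float)


def _check_coverage(grid: ArrayLike, table_wl: NDArray[np.float64], what: str) -> NDArray[np.float64]:
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if grid.min() < table_wl[0] or grid.max() > table_wl[-1]:
        raise ValueError(
            f"requested wavelengths [{grid.min():g}, {grid.max():g}] nm fall outside "
            f"the {what} table coverage [{table_wl[0]:g}, {table_wl[-1]:g}] nm; "
            "extrapolation is refused"
        )
    return grid


@dataclass(frozen=True)
class ChromophoreTable:
    """Absorption spectra of the three chromophores, per cm.

    ``mu_a_oxy``/``mu_a_deoxy`` are for fully oxygenated/deoxygenated whole
    blood at 150 g/L hemoglobin; ``mu_a_water`` is pure water.
    """

    wavelength_nm: NDArray[np.float64]
    mu_a_oxy: NDArray[np.float64]
    mu_a_deoxy: NDArray[np.float64]
    mu_a_water: NDArray[np.float64]

    def __post_init__(self) -> None:
        wl = self.wavelength_nm
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        for name in ("mu_a_oxy", "mu_a_deoxy", "mu_a_water"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative")

    def interp(self, grid: ArrayLike) -> Tuple[NDArray, NDArray, NDArray]:
        grid = _check_coverage(grid, self.wavelength_nm, "chromophore")
        return (
            np.interp(grid, self.wavelength_nm, self.mu_a_oxy),
            np.interp(grid, self.wavelength_nm, self.mu_a_deoxy),
            np.interp(grid, self.wavelength_nm, self.mu_a_water),
        )


@dataclass(frozen=True)
class ScatteringTable:
    """White/gray-matter scattering spectra and the tissue mixture weights."""

    wavelength_nm: NDArray[np.float64]
    mu_s_white: NDArray[np.float64]
    mu_s_gray: NDArray[np.float64]
    g_white: NDArray[np.float64]
    g_gray: NDArray[np.float64]
    white_fraction: float = 1.0 / 3.0
    gray_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if not np.isclose(self.white_fraction + self.gray_fraction, 1.0):
            raise ValueError("mixture weights must sum to 1")
        if not np.all(np.diff(self.wavelength_nm) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.mu_s_white <= 0) or np.any(self.mu_s_gray <= 0):
            raise ValueError("mu_s must be strictly positive")
        for g in (self.g_white, self.g_gray):
            if np.any((g <= 0) | (g >= 1)):
                raise ValueError("anisotropy g must lie in (0, 1)")

    def interp(self, grid: ArrayLike) -> Tuple[NDArray, NDArray, NDArray, NDArray]:
        grid = _check_coverage(grid, self.wavelength_nm, "scattering")
        wl = self.wavelength_nm
        return (
            np.interp(grid, wl, self.mu_s_white),
            np.interp(grid, wl, self.mu_s_gray),
            np.interp(grid, wl, self.g_white),
            np.interp(grid, wl, self.g_gray),
        )


@dataclass(frozen=True)
class TissueConfig:
    """Fixed tissue and probe-geometry constants.

    ``w`` is the fractional tissue water content (0.78 for mouse cortex);
    ``r_cm`` the source-detector fiber separation; the refractive indices set
    the boundary mismatch n = n_fiber / n_tissue (glass 1.52 or polymer 1.49
    against tissue 1.4).
    """

    w: float = 0.78
    n_fiber: float = 1.52
    n_tissue: float = 1.4
    r_cm: float = 0.25
    hb_reference_g_per_L: float = 150.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise ValueError("water fraction w must lie in [0, 1]")
        if self.n_fiber <= self.n_tissue:
            raise ValueError("n_fiber / n_tissue must exceed 1")
        if self.r_cm <= 0:
            raise ValueError("fiber separation r_cm must be positive")

    @property
    def n_rel(self) -> float:
        return self.n_fiber / self.n_tissue


def _read_tsv(name: str) -> dict[str, NDArray[np.float64]]:
    with resources.files("hemospec.data").joinpath(name).open() as fh:
        header = fh.readline().strip().split("\t")
        rows = [[float(v) for v in line.split("\t")] for line in fh if line.strip()]
    data = np.array(rows, dtype=float)
    return {col: data[:, i] for i, col in enumerate(header)}


def load_chromophore_table() -> ChromophoreTable:
    """Load the packaged hemoglobin + water absorption tables."""
    hb = _read_tsv("hemoglobin_whole_blood.tsv")
    water = _read_tsv("water_absorption.tsv")
    if not np.array_equal(hb["wavelength_nm"], water["wavelength_nm"]):
        raise ValueError("packaged chromophore tables disagree on wavelength grid")
    return ChromophoreTable(
        wavelength_nm=hb["wavelength_nm"],
        mu_a_oxy=hb["mu_a_oxy_per_cm"],
        mu_a_deoxy=hb["mu_a_deoxy_per_cm"],
        mu_a_water=water["mu_a_per_cm"],
    )


def load_scattering_table() -> ScatteringTable:
    """Load the packaged white/gray brain scattering table."""
    sc = _read_tsv("scattering_brain.tsv")
    return ScatteringTable(
        wavelength_nm=sc["wavelength_nm"],
        mu_s_white=sc["mu_s_white_per_cm"],
        mu_s_gray=sc["mu_s_gray_per_cm"],
        g_white=sc["g_white"],
        g_gray=sc["g_gray"],
    )


def load_manifest() -> dict:
    """Provenance/units manifest for the packaged tables."""
    return json.loads(resources.files("hemospec.data").joinpath("manifest.json").read_text())


def absorption_coefficient(
    state: HemodynamicState,
    config: TissueConfig,
    table: ChromophoreTable,
    grid: ArrayLike,
) -> NDArray[np.float64]:
    """Tissue absorption coefficient mu_a(lambda), per cm.

    Chromophore mixture: blood at volume fraction ``cbvf`` split between oxy-
    and deoxyhemoglobin by ``so2``, plus water at fixed fraction ``config.w``.
    """
    oxy, deoxy, water = table.interp(grid)
    blood = state.cbvf * (state.so2 * oxy + (1.0 - state.so2) * deoxy)
    return blood + config.w * water


def mixed_scattering(
    table: ScatteringTable, grid: ArrayLike
) -> Tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]]:
    """Tissue-level (mu_s, g, mu_s') from the white/gray weighted sum."""
    mus_w, mus_g, g_w, g_g = table.interp(grid)
    fw, fg = table.white_fraction, table.gray_fraction
    mus = fw * mus_w + fg * mus_g
    g = fw * g_w + fg * g_g
    return mus, g, mus * (1.0 - g)


def transport_mfp(table: ScatteringTable, wavelength_nm: float) -> float:
    """Transport scattering mean free path 1/mu_s' at one wavelength, in mm."""
    _, _, musp = mixed_scattering(table, [wavelength_nm])
    return float(10.0 / musp[0])  # cm -> mm


def isosbestic_points(
    table: ChromophoreTable, lo_nm: float = 500.0, hi_nm: float = 700.0
) -> NDArray[np.float64]:
    """Wavelengths where the linearly interpolated oxy and deoxy whole-blood
    absorption curves cross (absorption independent of saturation)."""
    wl = table.wavelength_nm
    diff = table.mu_a_oxy - table.mu_a_deoxy
    crossings = []
    for i in range(len(wl) - 1):
        a, b = diff[i], diff[i + 1]
        if a == 0.0:
            crossings.append(wl[i])
        elif a * b < 0:
            crossings.append(wl[i] - a * (wl[i + 1] - wl[i]) / (b - a))
    pts = np.array([w for w in crossings if lo_nm <= w <= hi_nm])
    return pts
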