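"""Steady-state diffusion-theory forward model of fiberoptic diffuse reflectance.

The probe is modeled as a point illumination on a semi-infinite tissue
half-space with a detector at lateral separation ``r``. Diffuse light behaves
as if emitted by an equivalent point source at depth ``z0 = 1/(mu_a + mu_s')``
paired with an image (dipole) source above the boundary at height
``z0 + 4AD``, where ``A`` is the internal-reflection parameter for the
fiber/tissue refractive-index mismatch and ``D = z0/3`` the diffusion
constant. The predicted reflectance at the detector is the standard
two-source sum

    Rp = [c + d] / (4 pi),
    c = z0 (mu_eff + 1/r1) exp(-mu_eff r1) / r1^2,
    d = (z0 + 4AD)(mu_eff + 1/r2) exp(-mu_eff r2) / r2^2,

with r1, r2 the distances from the two sources to the detector and
``mu_eff = sqrt(mu_a / D) = sqrt(3 mu_a (mu_a + mu_s'))`` the effective
attenuation coefficient (its inverse is the effective penetration depth).
The measured, calibrated spectrum is modeled as ``Mp = K * Rp`` with a free
instrument scale K.

All lengths are in cm and coefficients per cm. Everything is vectorized
over wavelength.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .optics import (
    ChromophoreTable,
    ScatteringTable,
    TissueConfig,
    absorption_coefficient,
    mixed_scattering,
)
from .state import HemodynamicState

__all__ = [
    "boundary_params",
    "diffusion_parameters",
    "dipole_reflectance",
    "predicted_reflectance",
    "predicted_measurement",
]


def boundary_params(n: float) -> Tuple[float, float]:
    """Internal reflection coefficient ri and parameter A for relative index n.

    Uses the empirical polynomial ri = 0.668 + 0.0636 n + 0.710/n - 1.440/n^2;
    A = (1 + ri)/(1 - ri). A = 1 for a matched boundary (ri = 0).
    """
    if n <= 0:
        raise ValueError("relative refractive index must be positive")
    ri = 0.668 + 0.0636 * n + 0.710 / n - 1.440 / n**2
    if ri >= 1.0:
        raise ValueError(f"unphysical internal reflection coefficient ri={ri:.3f} >= 1")
    return ri, (1.0 + ri) / (1.0 - ri)


def diffusion_parameters(
    mu_a: ArrayLike, mu_s_prime: ArrayLike
) -> Tuple[NDArray[np.float64], NDArray[np.float64], NDArray[np.float64]]:
    """Equivalent source depth z0, diffusion constant D and mu_eff (all cm-based).

    z0 = 1/(mu_a + mu_s'), D = z0/3, mu_eff = sqrt(mu_a/D).
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    if np.any(mu_s_prime <= 0):
        raise ValueError("reduced scattering mu_s' must be strictly positive")
    if np.any(mu_a < 0):
        raise ValueError("absorption mu_a must be nonnegative")
    z0 = 1.0 / (mu_a + mu_s_prime)
    D = z0 / 3.0
    mu_eff = np.sqrt(mu_a / D)
    return z0, D, mu_eff


def dipole_reflectance(
    mu_a: ArrayLike, mu_s_prime: ArrayLike, r_cm: float, n_rel: float
) -> NDArray[np.float64]:
    """Diffuse reflectance Rp at separation r for given optical coefficients."""
    z0, D, mu_eff = diffusion_parameters(mu_a, mu_s_prime)
    _, A = boundary_params(n_rel)
    zb = z0 + 4.0 * A * D  # image-source height above the boundary
    r1 = np.sqrt(z0**2 + r_cm**2)
    r2 = np.sqrt(zb**2 + r_cm**2)
    # exp(-r/Delta) with Delta = 1/mu_eff (penetration depth); exp -> 1 as mu_a -> 0
    c = z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
    d = zb * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2
    return (c + d) / (4.0 * np.pi)


def predicted_reflectance(
    state: HemodynamicState,
    config: TissueConfig,
    chromophores: ChromophoreTable,
    scattering: ScatteringTable,
    grid: ArrayLike,
) -> NDArray[np.float64]:
    """Predicted diffuse reflectance spectrum Rp(lambda) for a hemodynamic state."""
    mu_a = absorption_coefficient(state, config, chromophores, grid)
    _, _, musp = mixed_scattering(scattering, grid)
    return dipole_reflectance(mu_a, musp, config.r_cm, config.n_rel)


def predicted_measurement(k: float, rp: ArrayLike) -> NDArray[np.float64]:
    """Predicted calibrated measurement Mp = K * Rp."""
    if not (np.isfinite(k) and k > 0):
        raise ValueError("instrument scale K must be finite and positive")
    return k * np.asarray(rp, dtype=float)
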