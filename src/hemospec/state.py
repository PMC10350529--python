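"""Core hemodynamic state shared by the optics, forward-model and fitting layers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HemodynamicState:
    """The per-spectrum endpoint triple.

    Parameters
    ----------
    cbvf
        Cerebral blood volume fraction in [0, 1]. ``cbvf = 1`` corresponds to
        pure whole blood at the 150 g/L hemoglobin reference concentration.
    so2
        Hemoglobin oxygen saturation fraction in [0, 1] of the probed mixed
        arterial/venous blood.
    k
        Dimensionless instrument scaling factor (> 0) mapping predicted
        diffuse reflectance onto the calibrated measurement.
    """

    cbvf: float
    so2: float
    k: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cbvf <= 1.0):
            raise ValueError(f"cbvf must lie in [0, 1], got {self.cbvf}")
        if not (0.0 <= self.so2 <= 1.0):
            raise ValueError(f"so2 must lie in [0, 1], got {self.so2}")
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError(f"k must be finite and positive, got {self.k}")
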