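"""Seawater equation of state at atmospheric pressure.

Implements the EOS-80 one-atmosphere density polynomial of Millero &
Poisson (1981), rho(S, T) in kg m-3 with T in degC (IPTS-68 scale
differences are negligible at the millikelvin precisions handled here)
and S in practical salinity units. Used to derive potential density
anomaly (sigma-0) from CTD temperature/salinity when the cast does not
carry a density channel.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike


def density_at_surface(salinity: ArrayLike, temperature_C: ArrayLike) -> np.ndarray:
    """Seawater density (kg m-3) at 0 dbar from practical salinity and ITS temperature."""
    S = np.asarray(salinity, dtype=float)
    T = np.asarray(temperature_C, dtype=float)
    # pure-water part
    rho_w = (
        999.842594
        + 6.793952e-2 * T
        - 9.095290e-3 * T**2
        + 1.001685e-4 * T**3
        - 1.120083e-6 * T**4
        + 6.536332e-9 * T**5
    )
    A = (
        0.824493
        - 4.0899e-3 * T
        + 7.6438e-5 * T**2
        - 8.2467e-7 * T**3
        + 5.3875e-9 * T**4
    )
    B = -5.72466e-3 + 1.0227e-4 * T - 1.6546e-6 * T**2
    C = 4.8314e-4
    return rho_w + A * S + B * S**1.5 + C * S**2


def sigma0(salinity: ArrayLike, temperature_C: ArrayLike) -> np.ndarray:
    """Potential density anomaly sigma-0 (kg m-3), referenced to the surface."""
    return density_at_surface(salinity, temperature_C) - 1000.0
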