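"""Manning counterion condensation for linear poly-ions.

A nucleic acid is a linear poly-ion with average axial charge (phosphate)
spacing b.  Its dimensionless charge density is

    xi = l_B / b,    l_B = e^2 / (4 pi eps0 eps_r k T)   (Bjerrum length)

(equivalently xi = e^2/(eps k T b) in Gaussian units).  The thermodynamic
contribution of counterions bound per poly-ion charge splits into a
condensation part and a Debye-screening part:

    psi = psi_c + psi_sc = 1 - 1/(2 xi),   psi_c = 1 - 1/xi,  psi_sc = 1/(2 xi)

Condensation proper requires xi > 1; below that psi_c is clipped to zero and
the record is flagged invalid, though psi itself is still reported by the
same formula.

Because psi is linear in b at fixed dielectric and temperature, the change
in bound fraction between a structured state (spacing b_s) and an
unstructured one (b_u) is

    delta_psi = psi_s - psi_u = -C eps delta_b,  C = kT/(2 e^2),  delta_b = b_s - b_u

i.e. -delta_b/(2 l_B).  A compact fold (b_s < b_u) binds more counterions
than the extended coil, so delta_psi > 0.  The inversion delta_b =
-2 l_B delta_psi recovers the spacing change implied by an observed change
in bound fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    BOLTZMANN_J_PER_K,
    ELEMENTARY_CHARGE_C,
    VACUUM_PERMITTIVITY_F_PER_M,
)

__all__ = [
    "PolyionParams",
    "bjerrum_length_A",
    "manning_xi",
    "manning_xi_gaussian",
    "bound_fraction",
    "polyion_params",
    "delta_psi",
    "infer_delta_b",
    "psi_grid",
]

_ANGSTROM = 1e-10


@dataclass(frozen=True)
class PolyionParams:
    """Manning parameters for one (b, eps_r, T) state.

    b in Angstrom; psi = psi_c + psi_sc = 1 - 1/(2 xi); valid is False in
    the no-condensation regime xi <= 1, where the formula is applied outside
    Manning theory's domain.
    """

    b_A: float
    epsilon_r: float
    T: float
    xi: float
    psi: float
    psi_c: float
    psi_sc: float
    valid: bool

    def __post_init__(self):
        if self.xi <= 0:
            raise ValueError("xi must be positive")
        if abs(self.psi - (self.psi_c + self.psi_sc)) > 1e-12:
            raise ValueError("psi must equal psi_c + psi_sc")


def _positive(name: str, value: float) -> None:
    if not (value > 0 and math.isfinite(value)):
        raise ValueError(f"{name} must be positive and finite, got {value}")


def bjerrum_length_A(epsilon_r: float, T: float) -> float:
    """Bjerrum length e^2/(4 pi eps0 eps_r k T) in Angstrom."""
    _positive("epsilon_r", epsilon_r)
    _positive("T", T)
    lb_m = ELEMENTARY_CHARGE_C**2 / (
        4.0 * math.pi * VACUUM_PERMITTIVITY_F_PER_M
        * epsilon_r * BOLTZMANN_J_PER_K * T
    )
    return lb_m / _ANGSTROM


def manning_xi(b_A: float, epsilon_r: float, T: float) -> float:
    """Charge-density parameter xi = l_B / b (dimensionless)."""
    _positive("b", b_A)
    return bjerrum_length_A(epsilon_r, T) / b_A


def manning_xi_gaussian(b_A: float, epsilon_r: float, T: float) -> float:
    """xi = e^2/(eps k T b) evaluated in Gaussian (cgs-esu) units.

    Identical to manning_xi up to floating-point rounding; kept as an
    explicit cross-check that the SI Bjerrum-length route reproduces the
    Gaussian-units expression.
    """
    _positive("b", b_A)
    _positive("epsilon_r", epsilon_r)
    _positive("T", T)
    # esu charge is defined by a prefactor-free Coulomb law, so the exact
    # conversion is e_esu^2 [erg cm] = e^2/(4 pi eps0) [J m] * 1e9.  (The
    # nominal 10*c coulomb-to-statC factor assumes 1/(4 pi eps0) = 1e-7 c^2,
    # which since the 2019 SI redefinition holds only to ~5e-10 relative.)
    e_esu_sq = (
        ELEMENTARY_CHARGE_C**2
        / (4.0 * math.pi * VACUUM_PERMITTIVITY_F_PER_M)
        * 1e9
    )
    k_erg = BOLTZMANN_J_PER_K * 1e7  # erg/K
    b_cm = b_A * 1e-8
    return e_esu_sq / (epsilon_r * k_erg * T * b_cm)


def bound_fraction(xi: float) -> dict:
    """Counterion bound fraction psi and its condensation/screening split.

    Returns {"psi", "psi_c", "psi_sc", "valid"}; valid is False for
    xi <= 1 (no condensation: psi_c clipped to 0, psi still computed by the
    same formula).
    """
    if not (xi > 0 and math.isfinite(xi)):
        raise ValueError(f"xi must be positive and finite, got {xi}")
    psi = 1.0 - 1.0 / (2.0 * xi)
    psi_c = max(1.0 - 1.0 / xi, 0.0)
    return {"psi": psi, "psi_c": psi_c, "psi_sc": psi - psi_c, "valid": xi > 1.0}


def polyion_params(b_A: float, epsilon_r: float, T: float) -> PolyionParams:
    """Full Manning record for one inter-phosphate spacing."""
    xi = manning_xi(b_A, epsilon_r, T)
    frac = bound_fraction(xi)
    return PolyionParams(
        b_A=b_A, epsilon_r=epsilon_r, T=T, xi=xi,
        psi=frac["psi"], psi_c=frac["psi_c"], psi_sc=frac["psi_sc"],
        valid=frac["valid"],
    )


def delta_psi(epsilon_r: float, T: float, b_s_A: float, b_u_A: float) -> float:
    """Change in bound fraction between structured (b_s) and unstructured
    (b_u) states: -delta_b/(2 l_B), positive when the fold is more compact
    than the coil."""
    _positive("b_s", b_s_A)
    _positive("b_u", b_u_A)
    lb = bjerrum_length_A(epsilon_r, T)
    return -(b_s_A - b_u_A) / (2.0 * lb)


def infer_delta_b(dpsi: float, epsilon_r: float, T: float) -> float:
    """Invert delta_psi: the spacing change delta_b = b_s - b_u (Angstrom)
    implied by an observed change in bound counterion fraction."""
    if not math.isfinite(dpsi):
        raise ValueError("delta_psi must be finite")
    return -2.0 * bjerrum_length_A(epsilon_r, T) * dpsi


def psi_grid(
    b_values_A, epsilon_r: float, T: float
) -> pd.DataFrame:
    """Tabulate xi, psi and its split over a grid of spacings (for the CLI)."""
    rows = []
    for b in np.asarray(b_values_A, dtype=float):
        p = polyion_params(float(b), epsilon_r, T)
        rows.append({
            "b_A": p.b_A, "xi": p.xi, "psi": p.psi,
            "psi_c": p.psi_c, "psi_sc": p.psi_sc, "valid": p.valid,
        })
    return pd.DataFrame(rows)
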