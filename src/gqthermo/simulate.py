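"""Seeded synthetic-data generators for every pipeline stage.

The generators emulate the experimental design of a CD melting study of
membrane-anchored G-quadruplexes: two-state melting curves with linear
folded/unfolded baselines and independent Gaussian noise per point
(amplitude-relative standard deviation), a lipid-titration series whose
per-level truth values reproduce the published monotone destabilization
trend, and enthalpy-entropy compensation point clouds around a known line.

Everything is deterministic under a fixed seed, and every output feeds the
corresponding downstream stage (fitting, table building, compensation
regression) without coercion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .constants import TREF_25C, celsius_to_kelvin
from .melting import ConditionLabel, MeltingCurve, TwoStateFit, predict_signal

__all__ = [
    "CurveDesign",
    "SeriesDesign",
    "TABLE2_POPC_TRUTH",
    "simulate_curve",
    "simulate_series",
    "simulate_compensation_set",
]

# Published POPC-titration truth values for the 1cG_3 human-telomeric
# G-quadruplex: lipid concentration (mM) -> (dH, TdS at 25 degC), kcal/mol.
# The per-level Tm is taken as the closed form Tref*dH/TdS so the truth set
# is thermodynamically self-consistent (dG25 = dH - TdS holds exactly).
TABLE2_POPC_TRUTH: dict[float, tuple[float, float]] = {
    0.0: (-40.0, -36.9),
    0.5: (-30.7, -28.4),
    1.0: (-23.3, -21.9),
    2.0: (-22.1, -20.9),
}

# Default CD-like baselines (signal arbitrary units, slopes per K): a
# positive folded band that drifts down slightly with temperature and a
# small unfolded residual.
_DEFAULT_BASELINES = (1.0, -1.0e-3, 0.05, 2.0e-4)


@dataclass(frozen=True)
class CurveDesign:
    """Design of one synthetic melting curve.

    noise_sd is the Gaussian noise standard deviation as a fraction of the
    transition amplitude |base_f(Tm) - base_u(Tm)|.  The temperature grid is
    specified in Celsius (start, stop, step) to mirror instrument settings;
    the default 0-90 degC at 0.5 degC matches a typical slow melt.
    """

    dH_true: float = -40.0
    Tm_true: float = 323.2
    baselines: tuple[float, float, float, float] = _DEFAULT_BASELINES
    noise_sd: float = 0.0
    T_start_C: float = 0.0
    T_stop_C: float = 90.0
    T_step_C: float = 0.5
    seed: int = 0
    condition: ConditionLabel = field(default_factory=ConditionLabel)
    wavelength_nm: float = 295.0
    strand_conc_uM: float = 20.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.T_step_C <= 0:
            raise ValueError("T_step_C must be positive")
        lo, hi = celsius_to_kelvin(self.T_start_C), celsius_to_kelvin(self.T_stop_C)
        if not (lo <= self.Tm_true - 15.0 and self.Tm_true + 15.0 <= hi):
            raise ValueError(
                f"grid [{lo:.1f}, {hi:.1f}] K must span Tm_true +- 15 K "
                f"({self.Tm_true:.1f} K)"
            )

    def as_fit(self) -> TwoStateFit:
        """The noiseless generating parameters, packaged as a fit object."""
        bf0, bf1, bu0, bu1 = self.baselines
        return TwoStateFit(
            dH=self.dH_true, Tm=self.Tm_true,
            baseline_folded=(bf0, bf1), baseline_unfolded=(bu0, bu1),
        )


@dataclass(frozen=True)
class SeriesDesign:
    """Design of a lipid-titration series with replicates.

    truth maps each design level (lipid concentration, mM) to its
    (dH, TdS at Tref) pair; Tm per level is Tref*dH/TdS.
    """

    truth: Mapping[float, tuple[float, float]] = field(
        default_factory=lambda: dict(TABLE2_POPC_TRUTH)
    )
    n_replicates: int = 1
    noise_sd: float = 0.0
    seed: int = 0
    Tref: float = TREF_25C
    sequence: str = "1cG3"
    lipid_mixture: str = "POPC"

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(set(self.truth)) != len(self.truth):
            raise ValueError("design levels must be distinct")


def simulate_curve(design: CurveDesign) -> MeltingCurve:
    """Generate one melting curve: two-state model signal plus seeded
    Gaussian noise.  Identical designs (same seed) give bit-identical
    output."""
    t_c = np.arange(
        design.T_start_C, design.T_stop_C + 0.5 * design.T_step_C, design.T_step_C
    )
    T = celsius_to_kelvin(t_c)
    fit = design.as_fit()
    signal = predict_signal(fit, T)
    if design.noise_sd > 0:
        bf0, bf1, bu0, bu1 = design.baselines
        amplitude = abs(
            (bf0 + bf1 * design.Tm_true) - (bu0 + bu1 * design.Tm_true)
        )
        rng = np.random.default_rng(design.seed)
        signal = signal + rng.normal(0.0, design.noise_sd * amplitude, T.size)
    return MeltingCurve(
        temperatures=T,
        signals=signal,
        wavelength_nm=design.wavelength_nm,
        condition=design.condition,
        strand_conc_uM=design.strand_conc_uM,
    )


def simulate_series(design: SeriesDesign) -> list[MeltingCurve]:
    """Generate the full titration series (levels x replicates) of curves.

    Per-curve seeds are spawned deterministically from the design seed, so
    the output is independent of the iteration order of the truth map.
    """
    curves = []
    for conc in sorted(design.truth):
        dH, TdS = design.truth[conc]
        Tm = design.Tref * dH / TdS
        label = ConditionLabel(
            sequence=design.sequence,
            lipid_mixture=design.lipid_mixture,
            lipid_conc_mM=float(conc),
        )
        for rep in range(design.n_replicates):
            # stable per-(level, replicate) seed, independent of dict order
            sub_seed = (design.seed * 1_000_003 + hash((round(conc * 1000), rep))) % (
                2**31 - 1
            )
            curves.append(simulate_curve(CurveDesign(
                dH_true=dH, Tm_true=Tm,
                noise_sd=design.noise_sd, seed=sub_seed, condition=label,
            )))
    return curves


def simulate_compensation_set(
    slope: float,
    intercept: float,
    n: int,
    dH_range: tuple[float, float] = (-45.0, -15.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """(dH, TdS) pairs on the line TdS = slope*dH + intercept plus seeded
    Gaussian noise (kcal/mol) on TdS.  At noise_sd = 0 the compensation
    regression recovers (slope, intercept) exactly."""
    if n < 2:
        raise ValueError("need n >= 2 points")
    rng = np.random.default_rng(seed)
    dh = np.linspace(dH_range[0], dH_range[1], n)
    tds = slope * dh + intercept
    if noise_sd > 0:
        tds = tds + rng.normal(0.0, noise_sd, n)
    return np.column_stack([dh, tds])
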