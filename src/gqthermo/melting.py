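"""Two-state unimolecular melting model and van't Hoff curve fitting.

A circular-dichroism (or UV) melting curve records an optical signal as a
function of temperature while a folded nucleic-acid structure (here an
intramolecular G-quadruplex or hairpin) unfolds.  Under the two-state
assumption the signal is a population-weighted mix of two linear baselines:

    signal(T) = base_f(T) * theta(T) + base_u(T) * (1 - theta(T))

with the fraction folded given by the van't Hoff model

    dG(T) = dH * (1 - T / Tm),   K = exp(-dG / (R T)),   theta = K / (1 + K)

dH is the folding enthalpy (kcal/mol, negative for a stable fold) and Tm the
temperature at which theta = 0.5.  The transition is unimolecular, so the
equilibrium constant carries no strand-concentration term; strand
concentration is kept as metadata only.

Fitting a measured curve to this six-parameter model (dH, Tm and two linear
baselines) yields the van't Hoff parameters that downstream modules turn into
thermodynamic tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import isotonic_regression, least_squares
from scipy.special import expit

from .constants import R_KCAL

__all__ = [
    "ConditionLabel",
    "MeltingCurve",
    "TwoStateFit",
    "NormalizedProfile",
    "MeltingError",
    "NoTransitionError",
    "FitConvergenceError",
    "BaselineCrossingError",
    "fraction_folded",
    "predict_signal",
    "fit_two_state",
    "normalize_curve",
    "tm_median",
]


class MeltingError(ValueError):
    """Base class for melting-analysis failures."""


class NoTransitionError(MeltingError):
    """The curve shows no resolvable folded-to-unfolded transition."""


class FitConvergenceError(MeltingError):
    """The nonlinear fit failed to converge; carries optimizer diagnostics."""


class BaselineCrossingError(MeltingError):
    """Folded and unfolded baselines cross inside the data range, so the
    normalized fraction folded is undefined there."""


@dataclass(frozen=True)
class ConditionLabel:
    """Experimental condition attached to a melting curve.

    lipid_conc_mM is the design variable of the liposome-titration series;
    spacer_m counts the tether spacers between the oligonucleotide and its
    membrane anchor.
    """

    sequence: str = ""
    lipid_mixture: str = "none"
    lipid_conc_mM: float = 0.0
    spacer_m: int = 1

    def __str__(self) -> str:
        return (
            f"{self.sequence or 'seq'}|{self.lipid_mixture}|"
            f"{self.lipid_conc_mM:g}mM|m{self.spacer_m}"
        )


@dataclass(frozen=True)
class MeltingCurve:
    """A temperature/signal series with its condition metadata.

    Temperatures are Kelvin internally (I/O accepts Celsius and converts),
    strictly increasing, at least 8 points; signals are finite, arbitrary
    optical units.
    """

    temperatures: np.ndarray
    signals: np.ndarray
    wavelength_nm: float = 295.0
    condition: ConditionLabel = field(default_factory=ConditionLabel)
    strand_conc_uM: float = 20.0

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "signals", s)
        if t.ndim != 1 or s.shape != t.shape:
            raise MeltingError("temperatures and signals must be 1-D and equal length")
        if t.size < 8:
            raise MeltingError(f"need >= 8 points, got {t.size}")
        if not np.all(np.diff(t) > 0):
            raise MeltingError("temperatures must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(s))):
            raise MeltingError("temperatures and signals must be finite")
        if np.any(t <= 0):
            raise MeltingError("temperatures must be positive Kelvin")

    def __len__(self) -> int:
        return int(self.temperatures.size)


@dataclass(frozen=True)
class TwoStateFit:
    """Result of fitting the six-parameter two-state model to one curve.

    dH in kcal/mol (negative = stable fold), Tm in Kelvin, baselines as
    (intercept, slope-per-K) pairs evaluated against absolute temperature.
    std_errors are from the local curvature of the least-squares objective.
    """

    dH: float
    Tm: float
    baseline_folded: tuple[float, float]
    baseline_unfolded: tuple[float, float]
    residual_sd: float = 0.0
    std_errors: dict[str, float] = field(default_factory=dict)
    converged: bool = True

    def __post_init__(self):
        if self.residual_sd < 0:
            raise MeltingError("residual_sd must be >= 0")

    def to_dict(self) -> dict:
        return {
            "dH_kcal_per_mol": self.dH,
            "Tm_K": self.Tm,
            "baseline_folded_intercept": self.baseline_folded[0],
            "baseline_folded_slope_per_K": self.baseline_folded[1],
            "baseline_unfolded_intercept": self.baseline_unfolded[0],
            "baseline_unfolded_slope_per_K": self.baseline_unfolded[1],
            "residual_sd_signal": self.residual_sd,
            "std_errors": dict(self.std_errors),
            "converged": self.converged,
        }


@dataclass(frozen=True)
class NormalizedProfile:
    """Baseline-corrected melting profile: fraction folded vs temperature.

    theta holds the raw baseline-corrected values (which may stray slightly
    outside [0, 1] under noise); theta_clipped is for reporting/plotting.
    """

    temperatures: np.ndarray
    theta: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "temperatures", np.asarray(self.temperatures, float))
        object.__setattr__(self, "theta", np.asarray(self.theta, float))

    @property
    def theta_clipped(self) -> np.ndarray:
        return np.clip(self.theta, 0.0, 1.0)


def fraction_folded(dH: float, Tm: float, T):
    """Fraction folded theta(T) of the two-state unimolecular model.

    Parameters
    ----------
    dH : folding enthalpy, kcal/mol (nonzero; negative for a stable fold).
    Tm : melting temperature, Kelvin (theta(Tm) = 0.5 exactly).
    T : temperature(s), Kelvin.

    Returns a scalar or array in (0, 1), strictly monotone in T.
    """
    T = np.asarray(T, dtype=float)
    if Tm <= 0:
        raise MeltingError(f"Tm must be positive Kelvin, got {Tm}")
    if np.any(T <= 0):
        raise MeltingError("temperature must be positive Kelvin")
    if dH == 0:
        raise MeltingError("dH must be nonzero")
    dG = dH * (1.0 - T / Tm)                 # kcal/mol
    theta = expit(-dG / (R_KCAL * T))        # K/(1+K) computed stably
    return theta if theta.ndim else float(theta)


def _model_signal(params: Sequence[float], T: np.ndarray) -> np.ndarray:
    dH, Tm, bf0, bf1, bu0, bu1 = params
    theta = fraction_folded(dH, Tm, T)
    return (bf0 + bf1 * T) * theta + (bu0 + bu1 * T) * (1.0 - theta)


def predict_signal(fit: TwoStateFit, T):
    """Noiseless model signal at temperature(s) T (Kelvin) for a fit."""
    T = np.asarray(T, dtype=float)
    out = _model_signal(
        (fit.dH, fit.Tm, *fit.baseline_folded, *fit.baseline_unfolded), T
    )
    return out if out.ndim else float(out)


def _noise_estimate(signals: np.ndarray) -> float:
    # robust local-noise estimate from second differences; a linear or
    # smoothly curved trend contributes ~nothing, point noise contributes
    # sd*sqrt(6)
    d2 = np.diff(signals, n=2)
    if d2.size == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d2)) / np.sqrt(6.0))


def _initial_guess(curve: MeltingCurve) -> np.ndarray:
    T, s = curve.temperatures, curve.signals
    n = T.size
    k = max(2, int(round(0.15 * n)))
    # terminal baselines by OLS; the low-T end is the folded state for a
    # fold that melts on heating
    bf1, bf0 = np.polyfit(T[:k], s[:k], 1)
    bu1, bu0 = np.polyfit(T[-k:], s[-k:], 1)
    # Tm0 from the extremum of a smoothed derivative
    w = min(5, n if n % 2 else n - 1)
    kernel = np.ones(w) / w
    smooth = np.convolve(s, kernel, mode="same")
    grad = np.gradient(smooth, T)
    interior = slice(w, n - w) if n > 2 * w + 2 else slice(None)
    idx = np.argmax(np.abs(grad[interior]))
    Tm0 = float(T[interior][idx])
    Tm0 = float(np.clip(Tm0, T[0] + 1.0, T[-1] - 1.0))
    return np.array([-40.0, Tm0, bf0, bf1, bu0, bu1])


def fit_two_state(
    curve: MeltingCurve,
    init: TwoStateFit | None = None,
    n_restarts: int = 3,
    seed: int = 0,
) -> TwoStateFit:
    """Least-squares fit of the six-parameter two-state melting model.

    Runs the trust-region solver from an automatic initial guess plus
    ``n_restarts`` jittered restarts (seeded) and keeps the solution with the
    lowest residual sum of squares.  Standard errors come from the Jacobian at
    the optimum.

    Raises
    ------
    NoTransitionError
        if the signal range does not exceed 3x the local noise estimate.
    FitConvergenceError
        if no restart converges.
    """
    T, s = curve.temperatures, curve.signals
    noise = _noise_estimate(s)
    amplitude = float(np.ptp(s))
    if amplitude <= max(3.0 * noise, 1e-300):
        raise NoTransitionError(
            f"no transition detected: signal range {amplitude:.3g} <= "
            f"3x noise estimate {noise:.3g}"
        )

    if init is not None:
        x0 = np.array(
            [init.dH, init.Tm, *init.baseline_folded, *init.baseline_unfolded]
        )
    else:
        x0 = _initial_guess(curve)

    lo = np.array([-np.inf, T[0] - 20.0, -np.inf, -np.inf, -np.inf, -np.inf])
    hi = np.array([np.inf, T[-1] + 20.0, np.inf, np.inf, np.inf, np.inf])
    x0[1] = np.clip(x0[1], lo[1] + 1e-6, hi[1] - 1e-6)

    def residuals(p):
        return _model_signal(p, T) - s

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(n_restarts):
        jit = x0.copy()
        jit[0] *= rng.uniform(0.5, 1.5)
        jit[1] = np.clip(jit[1] + rng.uniform(-3.0, 3.0), lo[1] + 1e-6, hi[1] - 1e-6)
        starts.append(jit)

    best = None
    diagnostics = []
    for start in starts:
        try:
            res = least_squares(
                residuals, start, bounds=(lo, hi),
                ftol=1e-10, xtol=1e-12, gtol=1e-12, max_nfev=10_000,
            )
        except Exception as exc:  # singular model at a pathological start
            diagnostics.append(str(exc))
            continue
        if not res.success:
            diagnostics.append(res.message)
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitConvergenceError(
            "two-state fit did not converge from any start: " + "; ".join(diagnostics)
        )

    p = best.x
    ssr = float(2.0 * best.cost)
    dof = max(T.size - p.size, 1)
    resid_sd = float(np.sqrt(ssr / dof))
    # covariance from local curvature J'J; pinv guards near-degenerate baselines
    jtj = best.jac.T @ best.jac
    cov = np.linalg.pinv(jtj) * ssr / dof
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    names = ["dH", "Tm", "bf0", "bf1", "bu0", "bu1"]
    return TwoStateFit(
        dH=float(p[0]),
        Tm=float(p[1]),
        baseline_folded=(float(p[2]), float(p[3])),
        baseline_unfolded=(float(p[4]), float(p[5])),
        residual_sd=resid_sd,
        std_errors={k: float(v) for k, v in zip(names, se)},
        converged=True,
    )


def normalize_curve(curve: MeltingCurve, fit: TwoStateFit) -> NormalizedProfile:
    """Baseline-correct a curve into a fraction-folded profile.

    theta(T) = (signal - base_u(T)) / (base_f(T) - base_u(T)).  Raw values are
    retained (clipping to [0, 1] is for reporting only, via theta_clipped).
    """
    if not fit.converged:
        raise MeltingError("normalize_curve requires a converged fit")
    T, s = curve.temperatures, curve.signals
    bf = fit.baseline_folded[0] + fit.baseline_folded[1] * T
    bu = fit.baseline_unfolded[0] + fit.baseline_unfolded[1] * T
    sep = bf - bu
    # sep is linear in T: a sign change or zero inside the range means the
    # baselines cross there
    if sep[0] * sep[-1] <= 0:
        raise BaselineCrossingError(
            "folded and unfolded baselines cross within the data range"
        )
    return NormalizedProfile(temperatures=T, theta=(s - bu) / sep)


def tm_median(profile: NormalizedProfile) -> float:
    """Model-free melting temperature: the theta = 0.5 crossing (Kelvin).

    The profile is first projected onto a monotone non-increasing sequence
    (isotonic regression in the melting direction), which leaves noiseless
    two-state profiles untouched but makes the half-transition point well
    defined under noise.  The crossing is located by linear interpolation.
    """
    T = profile.temperatures
    y = isotonic_regression(profile.theta, increasing=False).x
    above = y >= 0.5
    if above.all() or not above.any():
        raise MeltingError(
            f"profile does not cross theta=0.5 (range {y.min():.3f}..{y.max():.3f})"
        )
    # non-increasing sequence: all >=0.5 points precede all <0.5 points, so
    # the crossing bracket is unique; scan defensively and report otherwise
    brackets = np.flatnonzero(above[:-1] & ~above[1:])
    if brackets.size != 1:
        temps = ", ".join(f"{T[i]:.2f}" for i in brackets)
        raise MeltingError(f"multiple theta=0.5 crossings after smoothing at: {temps}")
    i = int(brackets[0])
    y0, y1 = y[i], y[i + 1]
    if y0 == 0.5:
        # plateau exactly at 0.5: report the centre of the flat stretch
        j = i
        while j > 0 and y[j - 1] == 0.5:
            j -= 1
        return float(0.5 * (T[j] + T[i]))
    return float(T[i] + (0.5 - y0) * (T[i + 1] - T[i]) / (y1 - y0))
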