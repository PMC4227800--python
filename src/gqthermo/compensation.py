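"""Enthalpy-entropy compensation analysis.

Across families of related molecular events (folding of homologous
structures, host-guest binding, protein-protein association) TdS and dH are
often linearly correlated.  The slope of the TdS-vs-dH line is a
dimensionless temperature: below unity the favourable enthalpy outruns the
entropic penalty, above unity it does not.  The intercept is the entropic
contribution to the free energy at dH = 0 ("intrinsic stability"): a
positive intercept means the association is stable without enthalpic help, a
negative one that the process requires enthalpic stabilization (for
G-quadruplexes, cation binding to the quartet core).

The line is fitted by ordinary (y-on-x) least squares of TdS on dH; the
slope/intercept reading above is a y-on-x statement.  Compensation
literature sometimes prefers errors-in-variables fits; that is a caveat, not
an option here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompensationFit",
    "fit_compensation",
    "interpret_fit",
    "compare_events",
]


@dataclass(frozen=True)
class CompensationFit:
    """TdS = slope * dH + intercept for one class of molecular events."""

    slope: float            # dimensionless temperature
    intercept: float        # kcal/mol
    r_squared: float
    n: int
    event_label: str = ""

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("compensation fit needs n >= 2 points")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared out of [0,1]: {self.r_squared}")


def fit_compensation(
    points: Iterable[tuple[float, float]] | np.ndarray,
    event_label: str = "",
) -> CompensationFit:
    """Ordinary least squares of TdS on dH.

    points: sequence of (dH, TdS) pairs in kcal/mol.  Requires n >= 2 and a
    non-degenerate abscissa (not all dH identical).
    """
    arr = np.asarray(list(points) if not isinstance(points, np.ndarray) else points,
                     dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (n, 2) pairs of (dH, TdS)")
    if arr.shape[0] < 2:
        raise ValueError("need at least two (dH, TdS) points")
    dh, tds = arr[:, 0], arr[:, 1]
    if np.ptp(dh) == 0:
        raise ValueError("degenerate abscissa: all dH values identical")
    res = stats.linregress(dh, tds)
    return CompensationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(np.clip(res.rvalue**2, 0.0, 1.0)),
        n=arr.shape[0],
        event_label=event_label,
    )


def interpret_fit(fit: CompensationFit, near_unity_tol: float = 0.02) -> dict:
    """Categorical reading of a compensation line.

    slope_regime: below_unity / near_unity / above_unity (band of
    +-near_unity_tol around 1); intercept_regime: intrinsically_stable for a
    positive intercept, requires_enthalpic_stabilization for a negative one.
    An intercept of exactly zero and a slope inside the band are flagged as
    boundary cases.
    """
    if abs(fit.slope - 1.0) <= near_unity_tol:
        slope_regime = "near_unity"
    elif fit.slope < 1.0:
        slope_regime = "below_unity"
    else:
        slope_regime = "above_unity"
    if fit.intercept > 0:
        intercept_regime = "intrinsically_stable"
    elif fit.intercept < 0:
        intercept_regime = "requires_enthalpic_stabilization"
    else:
        intercept_regime = "boundary"
    return {
        "event_label": fit.event_label,
        "slope": fit.slope,
        "intercept_kcal": fit.intercept,
        "slope_regime": slope_regime,
        "intercept_regime": intercept_regime,
        "boundary": slope_regime == "near_unity" or intercept_regime == "boundary",
        "near_unity_tol": near_unity_tol,
    }


def compare_events(fits: Sequence[CompensationFit]) -> pd.DataFrame:
    """Comparison table of compensation lines, sorted by intercept
    (ascending, stable tie order by event label)."""
    if not fits:
        raise ValueError("need at least one fit to compare")
    df = pd.DataFrame([
        {
            "event": f.event_label,
            "slope": f.slope,
            "intercept_kcal": f.intercept,
            "r_squared": f.r_squared,
            "n": f.n,
        }
        for f in fits
    ])
    df = df.sort_values(["intercept_kcal", "event"], kind="stable")
    return df.reset_index(drop=True)
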