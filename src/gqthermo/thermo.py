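"""Thermodynamic parameter tables and condition-difference quantities.

Per condition the folding thermodynamics are summarized as dH (kcal/mol),
TdS at a reference temperature (default 25 degC), dG at that reference, and
Tm.  With temperature-independent dH (no heat-capacity correction) these are
linked by

    dS = dH / Tm,   TdS_ref = Tref * dH / Tm,   dG_ref = dH * (1 - Tref / Tm)

so dG_ref = dH - TdS_ref exactly.

Sign conventions for condition differences (destabilization at a membrane
surface shows up as POSITIVE values under both):

    ddX  = X(condition) - X(reference)   for X in {dH, TdS, dG}
    dTm  = Tm(reference) - Tm(condition)

Note the two conventions deliberately point in opposite directions; both are
the field's standard way of quoting destabilization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import TREF_25C, kelvin_to_celsius
from .melting import ConditionLabel, TwoStateFit

__all__ = [
    "ThermoParams",
    "ConditionDelta",
    "delta_g",
    "thermo_from_fit",
    "condition_deltas",
    "build_param_table",
    "params_from_table",
]

# one-decimal printed tables round to +-0.05; allow half an ulp of print
_PRINT_TOL = 0.051


@dataclass(frozen=True)
class ThermoParams:
    """One row of a thermodynamic parameter table (one condition)."""

    label: str
    dH: float          # kcal/mol
    TdS_ref: float     # kcal/mol at Tref
    dG_ref: float      # kcal/mol at Tref
    Tm: float          # Kelvin
    Tref: float = TREF_25C
    sds: Mapping[str, float] | None = None

    def __post_init__(self):
        if self.Tref <= 0:
            raise ValueError("Tref must be positive Kelvin")
        gap = abs(self.dG_ref - (self.dH - self.TdS_ref))
        if gap > _PRINT_TOL:
            raise ValueError(
                f"dG_ref inconsistent with dH - TdS_ref by {gap:.3f} kcal/mol "
                f"(tolerance {_PRINT_TOL} for one-decimal rounding)"
            )


@dataclass(frozen=True)
class ConditionDelta:
    """Differences between a condition and its reference.

    ddH, dTdS, ddG are condition minus reference; dTm is reference minus
    condition (both in the destabilization-positive convention).
    """

    condition: str
    reference: str
    ddH: float
    dTdS: float
    ddG: float
    dTm: float
    sds: Mapping[str, float] | None = None


def delta_g(dH: float, TdS: float) -> float:
    """Gibbs free energy dG = dH - TdS (all kcal/mol, same temperature)."""
    if not (math.isfinite(dH) and math.isfinite(TdS)):
        raise ValueError("dH and TdS must be finite")
    return dH - TdS


def thermo_from_fit(
    fit: TwoStateFit, Tref: float = TREF_25C, label: str = ""
) -> ThermoParams:
    """Van't Hoff parameters at Tref from a two-state fit.

    Uses dS = dH/Tm (dG(Tm) = 0 with temperature-independent dH).
    """
    if fit.Tm <= 0:
        raise ValueError(f"Tm must be positive Kelvin, got {fit.Tm}")
    TdS_ref = Tref * fit.dH / fit.Tm
    dG_ref = fit.dH * (1.0 - Tref / fit.Tm)
    sds = None
    if fit.std_errors:
        se_dH = fit.std_errors.get("dH")
        if se_dH is not None:
            # first-order propagation treating Tm as exact dominates in
            # practice; kept deliberately simple
            sds = {"dH": se_dH, "TdS_ref": abs(Tref / fit.Tm) * se_dH,
                   "dG_ref": abs(1.0 - Tref / fit.Tm) * se_dH}
    return ThermoParams(
        label=label, dH=fit.dH, TdS_ref=TdS_ref, dG_ref=dG_ref,
        Tm=fit.Tm, Tref=Tref, sds=sds,
    )


def _rss(a: float | None, b: float | None) -> float | None:
    if a is None or b is None:
        return None
    return math.hypot(a, b)


def condition_deltas(cond: ThermoParams, ref: ThermoParams) -> ConditionDelta:
    """ddX = cond - ref for dH/TdS/dG; dTm = ref.Tm - cond.Tm.

    Standard deviations, when present on both sides, combine as the
    root-sum-square of the two conditions' values.
    """
    if cond.Tref != ref.Tref:
        raise ValueError(
            f"mismatched reference temperatures: {cond.Tref} vs {ref.Tref}"
        )
    sds = None
    if cond.sds and ref.sds:
        pairs = {
            "ddH": _rss(cond.sds.get("dH"), ref.sds.get("dH")),
            "dTdS": _rss(cond.sds.get("TdS_ref"), ref.sds.get("TdS_ref")),
            "ddG": _rss(cond.sds.get("dG_ref"), ref.sds.get("dG_ref")),
        }
        sds = {k: v for k, v in pairs.items() if v is not None} or None
    return ConditionDelta(
        condition=cond.label,
        reference=ref.label,
        ddH=cond.dH - ref.dH,
        dTdS=cond.TdS_ref - ref.TdS_ref,
        ddG=cond.dG_ref - ref.dG_ref,
        dTm=ref.Tm - cond.Tm,
        sds=sds,
    )


def build_param_table(
    fits: Iterable[tuple[ConditionLabel, TwoStateFit]],
    Tref: float = TREF_25C,
) -> pd.DataFrame:
    """Aggregate replicate fits into a per-condition parameter table.

    Rows are ordered by the design variable (lipid concentration, then
    spacer count, then sequence); replicates of the same condition are
    reported as mean +- standard deviation (ddof=1).  Two Tm variants are
    kept: the curve-fit Tm and the closed-form Tm = Tref*dH/TdS implied by
    the mean parameters.

    Columns: condition, sequence, lipid_mixture, lipid_conc_mM, spacer_m,
    n_replicates, dH_kcal, TdS_kcal, dG25_kcal, Tm_C, Tm_closed_C and *_sd.
    """
    records: dict[ConditionLabel, list[TwoStateFit]] = {}
    for label, fit in fits:
        records.setdefault(label, []).append(fit)
    if not records:
        raise ValueError("no fits supplied")

    rows = []
    for label, reps in records.items():
        tps = [thermo_from_fit(f, Tref=Tref, label=str(label)) for f in reps]
        dH = np.array([t.dH for t in tps])
        TdS = np.array([t.TdS_ref for t in tps])
        dG = np.array([t.dG_ref for t in tps])
        TmC = np.array([kelvin_to_celsius(t.Tm) for t in tps])
        ddof = 1 if len(reps) > 1 else 0
        rows.append({
            "condition": str(label),
            "sequence": label.sequence,
            "lipid_mixture": label.lipid_mixture,
            "lipid_conc_mM": label.lipid_conc_mM,
            "spacer_m": label.spacer_m,
            "n_replicates": len(reps),
            "dH_kcal": dH.mean(),
            "dH_kcal_sd": dH.std(ddof=ddof),
            "TdS_kcal": TdS.mean(),
            "TdS_kcal_sd": TdS.std(ddof=ddof),
            "dG25_kcal": dG.mean(),
            "dG25_kcal_sd": dG.std(ddof=ddof),
            "Tm_C": TmC.mean(),
            "Tm_C_sd": TmC.std(ddof=ddof),
            "Tm_closed_C": kelvin_to_celsius(Tref * dH.mean() / TdS.mean()),
            "Tref_K": Tref,
        })
    df = pd.DataFrame(rows).sort_values(
        ["lipid_conc_mM", "spacer_m", "sequence"], kind="stable"
    )
    return df.reset_index(drop=True)


def params_from_table(df: pd.DataFrame) -> list[ThermoParams]:
    """Rehydrate ThermoParams rows from a parameter table (build_param_table
    output or a hand-entered published table with the same columns)."""
    out = []
    for _, row in df.iterrows():
        tref = float(row.get("Tref_K", TREF_25C))
        sds = None
        if "dH_kcal_sd" in row and pd.notna(row["dH_kcal_sd"]):
            sds = {
                "dH": float(row["dH_kcal_sd"]),
                "TdS_ref": float(row.get("TdS_kcal_sd", np.nan)),
                "dG_ref": float(row.get("dG25_kcal_sd", np.nan)),
            }
        out.append(ThermoParams(
            label=str(row["condition"]),
            dH=float(row["dH_kcal"]),
            TdS_ref=float(row["TdS_kcal"]),
            dG_ref=float(row["dG25_kcal"]),
            Tm=float(row["Tm_C"]) + 273.15,
            Tref=tref,
            sds=sds,
        ))
    return out
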