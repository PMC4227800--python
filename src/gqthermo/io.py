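"""Readers and writers for the pipeline's on-disk formats.

Melting curves travel as CSV with a ``# key: value`` metadata header
(sequence, lipid_mixture, lipid_conc_mM, spacer_m, wavelength_nm,
strand_conc_uM) followed by ``temperature_C,signal[,replicate]`` rows.
Parameter tables, condition deltas and compensation tables are TSV with
units in the column names; fits are JSON records.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin, kelvin_to_celsius
from .melting import ConditionLabel, MeltingCurve, TwoStateFit

__all__ = [
    "MeltingFormatError",
    "read_melting_csv",
    "write_melting_csv",
    "write_fits_json",
    "read_fits_json",
    "write_table_tsv",
    "read_table_tsv",
]

_META_KEYS = {
    "sequence": str,
    "lipid_mixture": str,
    "lipid_conc_mM": float,
    "spacer_m": int,
    "wavelength_nm": float,
    "strand_conc_uM": float,
}


class MeltingFormatError(ValueError):
    """Malformed melting-curve file; message carries the offending line."""


def read_melting_csv(path: str | Path) -> MeltingCurve:
    """Read one condition's melting curve.

    Temperatures are Celsius on disk and converted to Kelvin.  Rows out of
    temperature order are sorted with a warning; malformed cells raise
    MeltingFormatError naming the line number.
    """
    path = Path(path)
    meta: dict = {}
    temps: list[float] = []
    sigs: list[float] = []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    key = key.strip()
                    if key in _META_KEYS:
                        try:
                            meta[key] = _META_KEYS[key](val.strip())
                        except ValueError as exc:
                            raise MeltingFormatError(
                                f"{path}:{lineno}: bad metadata value for "
                                f"'{key}': {val.strip()!r}"
                            ) from exc
                continue
            cells = [c.strip() for c in line.split(",")]
            if not header_seen:
                if cells[:2] != ["temperature_C", "signal"]:
                    raise MeltingFormatError(
                        f"{path}:{lineno}: expected header "
                        f"'temperature_C,signal[,replicate]', got {line!r}"
                    )
                header_seen = True
                continue
            if len(cells) < 2:
                raise MeltingFormatError(f"{path}:{lineno}: expected >= 2 columns")
            try:
                temps.append(float(cells[0]))
                sigs.append(float(cells[1]))
            except ValueError as exc:
                raise MeltingFormatError(
                    f"{path}:{lineno}: non-numeric cell in {line!r}"
                ) from exc
    if not header_seen:
        raise MeltingFormatError(f"{path}: missing 'temperature_C,signal' header")

    t = np.asarray(temps)
    s = np.asarray(sigs)
    if t.size and np.any(np.diff(t) < 0):
        warnings.warn(
            f"{path}: temperature rows out of order; sorting", stacklevel=2
        )
        order = np.argsort(t, kind="stable")
        t, s = t[order], s[order]
    if np.any(np.diff(t) == 0):
        raise MeltingFormatError(f"{path}: duplicate temperature values")

    condition = ConditionLabel(
        sequence=meta.get("sequence", ""),
        lipid_mixture=meta.get("lipid_mixture", "none"),
        lipid_conc_mM=meta.get("lipid_conc_mM", 0.0),
        spacer_m=meta.get("spacer_m", 1),
    )
    return MeltingCurve(
        temperatures=celsius_to_kelvin(t),
        signals=s,
        wavelength_nm=meta.get("wavelength_nm", 295.0),
        condition=condition,
        strand_conc_uM=meta.get("strand_conc_uM", 20.0),
    )


def write_melting_csv(curve: MeltingCurve, path: str | Path) -> Path:
    """Write a curve in the dialect read_melting_csv consumes (Celsius)."""
    path = Path(path)
    c = curve.condition
    lines = [
        f"# sequence: {c.sequence}",
        f"# lipid_mixture: {c.lipid_mixture}",
        f"# lipid_conc_mM: {c.lipid_conc_mM:g}",
        f"# spacer_m: {c.spacer_m}",
        f"# wavelength_nm: {curve.wavelength_nm:g}",
        f"# strand_conc_uM: {curve.strand_conc_uM:g}",
        "temperature_C,signal",
    ]
    for t, s in zip(kelvin_to_celsius(curve.temperatures), curve.signals):
        lines.append(f"{t:.6g},{s:.10g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_fits_json(
    fits: Sequence[tuple[ConditionLabel, TwoStateFit]], path: str | Path
) -> Path:
    path = Path(path)
    records = []
    for label, fit in fits:
        rec = fit.to_dict()
        rec["condition"] = {
            "sequence": label.sequence,
            "lipid_mixture": label.lipid_mixture,
            "lipid_conc_mM": label.lipid_conc_mM,
            "spacer_m": label.spacer_m,
        }
        records.append(rec)
    path.write_text(json.dumps(records, indent=2, sort_keys=True) + "\n")
    return path


def read_fits_json(path: str | Path) -> list[tuple[ConditionLabel, TwoStateFit]]:
    records = json.loads(Path(path).read_text())
    out = []
    for rec in records:
        c = rec.get("condition", {})
        label = ConditionLabel(
            sequence=c.get("sequence", ""),
            lipid_mixture=c.get("lipid_mixture", "none"),
            lipid_conc_mM=c.get("lipid_conc_mM", 0.0),
            spacer_m=c.get("spacer_m", 1),
        )
        fit = TwoStateFit(
            dH=rec["dH_kcal_per_mol"],
            Tm=rec["Tm_K"],
            baseline_folded=(
                rec["baseline_folded_intercept"],
                rec["baseline_folded_slope_per_K"],
            ),
            baseline_unfolded=(
                rec["baseline_unfolded_intercept"],
                rec["baseline_unfolded_slope_per_K"],
            ),
            residual_sd=rec.get("residual_sd_signal", 0.0),
            std_errors=rec.get("std_errors", {}),
            converged=rec.get("converged", True),
        )
        out.append((label, fit))
    return out


def write_table_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    """Write any of the pipeline's tables as TSV (units live in the column
    names, e.g. dH_kcal, Tm_C)."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
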