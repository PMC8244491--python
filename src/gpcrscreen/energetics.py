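"""MM-GBSA aggregation arithmetic.

Two input shapes are supported (auto-detected from the CSV header):

* per-snapshot rows ``complex_id, frame, G_com, G_rec, G_lig`` — averaged
  into a binding free energy with its standard error;
* per-complex component rows ``complex_id, dE_vdW, dE_Ele, dE_Sol`` —
  combined into the gas-phase and final binding energies.

All energies are kcal/mol. Reported values are rounded to 2 decimals,
half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (unlike Python's banker's rounding).

    Uses decimal arithmetic on the shortest repr so printed-decimal inputs
    behave as a human rounding them would (2.675 -> 2.68).
    """
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SnapshotEnergies:
    index: int
    g_com: float
    g_rec: float
    g_lig: float

    def __post_init__(self) -> None:
        for v in (self.g_com, self.g_rec, self.g_lig):
            if not math.isfinite(v):
                raise ValueError(f"snapshot {self.index}: non-finite energy")

    @property
    def dg_bind(self) -> float:
        return self.g_com - self.g_rec - self.g_lig


def mmgbsa_mean(snapshots: Sequence[SnapshotEnergies]) -> tuple[float, float]:
    """Mean binding free energy over snapshots and its standard error."""
    if not snapshots:
        raise ValueError("no snapshots")
    diffs = np.array([s.dg_bind for s in snapshots])
    mean = float(diffs.mean())
    if len(diffs) == 1:
        sem = 0.0
    else:
        sem = float(diffs.std(ddof=1) / math.sqrt(len(diffs)))
    return mean, sem


@dataclass(frozen=True)
class EnergyComponents:
    """Component decomposition of one complex's binding free energy."""

    complex_id: str
    dE_vdW: float
    dE_Ele: float
    dE_Sol: float
    dG_gas: float
    dG_bind: float

    def audit(self, tol_gas: float = 0.01, tol_bind: float = 0.02) -> bool:
        """Internal-consistency check against the summation identities."""
        ok_gas = abs(self.dG_gas - (self.dE_vdW + self.dE_Ele)) <= tol_gas
        ok_bind = abs(self.dG_bind - (self.dG_gas + self.dE_Sol)) <= tol_bind
        return ok_gas and ok_bind


def combine_components(
    dE_vdW: float, dE_Ele: float, dE_Sol: float, complex_id: str = ""
) -> EnergyComponents:
    """Gas-phase and final binding free energies from printed components.

    ``dG_gas = dE_vdW + dE_Ele`` and ``dG_bind = dG_gas + dE_Sol``; the two
    derived values are rounded to 2 decimals for reporting.
    """
    for v in (dE_vdW, dE_Ele, dE_Sol):
        if not math.isfinite(v):
            raise ValueError("non-finite energy component")
    gas = dE_vdW + dE_Ele
    bind = gas + dE_Sol
    return EnergyComponents(
        complex_id=complex_id,
        dE_vdW=dE_vdW,
        dE_Ele=dE_Ele,
        dE_Sol=dE_Sol,
        dG_gas=round_half_away(gas),
        dG_bind=round_half_away(bind),
    )


def read_energy_csv(path: str | Path) -> pd.DataFrame:
    """Load an energy CSV; the layout is auto-detected from the header."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"complex_id", "frame", "G_com", "G_rec", "G_lig"} <= cols:
        df.attrs["layout"] = "snapshots"
    elif {"complex_id", "dE_vdW", "dE_Ele", "dE_Sol"} <= cols:
        df.attrs["layout"] = "components"
    else:
        raise ValueError(f"{path}: unrecognised energy CSV header: {sorted(cols)}")
    return df


def summarise_energy_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-complex summary for either input layout."""
    layout = df.attrs.get("layout")
    rows = []
    if layout == "snapshots":
        for cid, grp in df.groupby("complex_id", sort=True):
            snaps = [
                SnapshotEnergies(int(r.frame), r.G_com, r.G_rec, r.G_lig)
                for r in grp.itertuples()
            ]
            mean, sem = mmgbsa_mean(snaps)
            rows.append(
                {
                    "complex_id": cid,
                    "n_snapshots": len(snaps),
                    "dG_bind": round_half_away(mean),
                    "sem": round_half_away(sem, 3),
                }
            )
    elif layout == "components":
        for r in df.itertuples():
            ec = combine_components(r.dE_vdW, r.dE_Ele, r.dE_Sol, str(r.complex_id))
            rows.append(
                {
                    "complex_id": ec.complex_id,
                    "dE_vdW": ec.dE_vdW,
                    "dE_Ele": ec.dE_Ele,
                    "dE_Sol": ec.dE_Sol,
                    "dG_gas": ec.dG_gas,
                    "dG_bind": ec.dG_bind,
                }
            )
    else:
        raise ValueError("dataframe lacks a recognised layout")
    return pd.DataFrame(rows)
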