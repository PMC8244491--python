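"""Moving-window hydrophobicity profiles and per-helix correspondence
scoring.

A profile assigns to each window centre ``n`` the mean hydrophobicity of
the 11 residues ``n-5..n+5`` (only full windows are evaluated, so a helix
of length L yields L-10 values). Two helices are compared by summing the
squared profile differences over centre positions paired by the
centre-tethered helix alignment; the per-residue value (SSD / number of
paired positions) above 0.1 flags poor hydrophobicity correspondence.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequences import (
    HELIX_IDS,
    ReceptorSequence,
    SequenceError,
    TMAnnotation,
    center_tether_align,
    helix_residues,
    tm_by_id,
)

WINDOW = 11
POOR_CORRESPONDENCE_THRESHOLD = 0.1


@dataclass(frozen=True)
class HydroScale:
    """Residue -> hydrophobicity lookup table."""

    values: Mapping[str, float]
    name: str = "custom"

    def __post_init__(self) -> None:
        missing = set("ACDEFGHIKLMNPQRSTVWY") - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


def load_eisenberg_scale() -> HydroScale:
    """The embedded Eisenberg (1984) normalized consensus scale."""
    text = resources.files("gpcrscreen.data").joinpath("eisenberg.tsv").read_text()
    values: dict[str, float] = {}
    for row in csv.reader(
        (l for l in text.splitlines() if l and not l.startswith("#")), delimiter="\t"
    ):
        if row[0] == "residue":
            continue
        values[row[0]] = float(row[1])
    return HydroScale(values=values, name="eisenberg-1984-consensus")


@dataclass(frozen=True)
class HydroProfile:
    """Windowed profile for one helix; ``values[k]`` is H at centre k+6
    (1-based position within the helix)."""

    helix_id: str
    values: tuple[float, ...]
    window: int = WINDOW

    @property
    def first_center(self) -> int:
        return self.window // 2 + 1

    def value_at_center(self, position: int) -> float:
        """H_n for 1-based helix position ``position``; KeyError if no full
        window is centred there."""
        k = position - self.first_center
        if not (0 <= k < len(self.values)):
            raise KeyError(f"no full window centred at position {position}")
        return self.values[k]


def windowed_profile(
    helix: str, scale: HydroScale, helix_id: str = "TM?", window: int = WINDOW
) -> HydroProfile:
    """Mean hydrophobicity over each full ``window``-residue window."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if len(helix) < window:
        raise SequenceError(
            f"{helix_id}: helix length {len(helix)} < window {window}"
        )
    h = np.array([scale[r] for r in helix], dtype=float)
    kernel = np.ones(window) / window
    values = np.convolve(h, kernel, mode="valid")
    return HydroProfile(helix_id=helix_id, values=tuple(values), window=window)


@dataclass(frozen=True)
class SSDReport:
    helix_id: str
    n: int
    ssd: float
    ssd_per_residue: float
    poor_correspondence: bool


def ssd(
    profile_template: HydroProfile,
    profile_target: HydroProfile,
    pairing: Sequence[tuple[int, int]],
) -> SSDReport:
    """Sum of squared profile differences over tethered positions.

    ``pairing`` holds 1-based (template_helix_pos, target_helix_pos) pairs
    from :func:`center_tether_align` on the *full helices*; only pairs where
    both profiles have a full window are used.
    """
    if not pairing:
        raise ValueError("empty pairing")
    total = 0.0
    n = 0
    for i, j in pairing:
        try:
            a = profile_template.value_at_center(i)
            b = profile_target.value_at_center(j)
        except KeyError:
            continue
        total += (a - b) ** 2
        n += 1
    if n == 0:
        raise ValueError("pairing has no positions with full windows on both sides")
    per_res = total / n
    return SSDReport(
        helix_id=profile_template.helix_id,
        n=n,
        ssd=total,
        ssd_per_residue=per_res,
        poor_correspondence=per_res > POOR_CORRESPONDENCE_THRESHOLD,
    )


def helix_ssd(
    template_helix: str,
    target_helix: str,
    scale: HydroScale,
    helix_id: str = "TM?",
) -> SSDReport:
    """Convenience: profile both helices and score their correspondence."""
    pt = windowed_profile(template_helix, scale, helix_id)
    pq = windowed_profile(target_helix, scale, helix_id)
    pairing = center_tether_align(template_helix, target_helix)
    return ssd(pt, pq, pairing)


def correspondence_table(
    target: tuple[ReceptorSequence, Sequence[TMAnnotation]],
    templates: Sequence[tuple[ReceptorSequence, Sequence[TMAnnotation]]],
    scale: HydroScale | None = None,
    identities: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-helix SSD/residue of each template against the target.

    Rows are ordered by template id; columns TM1..TM7 hold per-residue SSD,
    plus ``identity_pct`` when ``identities`` is given (or computed from the
    sequences otherwise).
    """
    from .sequences import global_identity  # local import to avoid cycle noise

    scale = scale or load_eisenberg_scale()
    tseq, ttms = target
    for hid in HELIX_IDS:
        tm_by_id(ttms, hid)  # raises if missing
    rows = {}
    for seq, tms in sorted(templates, key=lambda p: p[0].id):
        row: dict[str, float] = {}
        for hid in HELIX_IDS:
            tpl_tm = tm_by_id(tms, hid)
            tgt_tm = tm_by_id(ttms, hid)
            rep = helix_ssd(
                helix_residues(seq, tpl_tm),
                helix_residues(tseq, tgt_tm),
                scale,
                helix_id=hid,
            )
            row[hid] = rep.ssd_per_residue
        if identities is not None:
            row["identity_pct"] = identities[seq.id]
        else:
            row["identity_pct"] = global_identity(tseq, seq)
        rows[seq.id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "template_id"
    return df
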