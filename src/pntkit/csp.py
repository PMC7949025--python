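"""Chemical shift perturbation (CSP) mapping of binding interfaces.

Combined amide perturbations between a free and a bound state are computed as

    ddelta = sqrt(ddelta_H^2 + (w * ddelta_N)^2),   w = 0.14 by default,

where the nitrogen weight compensates for the larger 15N shift dispersion.
Residues whose combined perturbation exceeds a threshold (0.2 ppm by default)
are flagged as interface candidates.  Binding here is slow-exchange
(nanomolar K_D), so free and bound peaks are distinct assignments rather than
a titration series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .structures import InterfaceAnnotation

__all__ = [
    "ShiftTable",
    "CspRecord",
    "read_shift_table",
    "compute_csp",
    "classify_interface",
    "interface_overlap",
    "csp_frame",
]

DEFAULT_NITROGEN_WEIGHT = 0.14
DEFAULT_CSP_THRESHOLD = 0.2  # ppm


@dataclass
class ShiftTable:
    """Per-residue amide 1H/15N chemical shifts for one protein state."""

    shifts: pd.DataFrame    # columns: residue, delta_H_ppm, delta_N_ppm
    state: str = ""
    pH: float | None = None

    def __post_init__(self) -> None:
        df = self.shifts
        required = {"residue", "delta_H_ppm", "delta_N_ppm"}
        if not required.issubset(df.columns):
            raise ValueError(f"shift table must have columns {sorted(required)}")
        if df["residue"].duplicated().any():
            dup = df.loc[df["residue"].duplicated(), "residue"].tolist()
            raise ValueError(f"duplicate residue rows in shift table: {dup}")
        if not (df[["delta_H_ppm", "delta_N_ppm"]].map(math.isfinite)).all().all():
            raise ValueError("non-finite chemical shifts in table")
        self.warnings: list[str] = []
        odd_n = df[(df["delta_N_ppm"] < 100) | (df["delta_N_ppm"] > 135)]
        odd_h = df[(df["delta_H_ppm"] < 5) | (df["delta_H_ppm"] > 12)]
        for _, row in odd_n.iterrows():
            self.warnings.append(f"residue {int(row.residue)}: delta_N {row.delta_N_ppm:.2f} ppm "
                                 "outside typical amide range 100-135")
        for _, row in odd_h.iterrows():
            self.warnings.append(f"residue {int(row.residue)}: delta_H {row.delta_H_ppm:.2f} ppm "
                                 "outside typical amide range 5-12")

    @property
    def residues(self) -> set[int]:
        return set(self.shifts["residue"].astype(int))


def read_shift_table(path_or_buffer, state: str = "", pH: float | None = None) -> ShiftTable:
    """Load a TSV shift table with columns residue, delta_H_ppm, delta_N_ppm."""
    df = pd.read_csv(path_or_buffer, sep="\t")
    return ShiftTable(shifts=df, state=state, pH=pH)


@dataclass
class CspRecord:
    residue: int
    delta_H: float | None   # ppm, bound - free
    delta_N: float | None   # ppm, bound - free
    csp: float | None       # combined ddelta, ppm; None when missing
    missing: bool = False   # residue assigned in only one state


def compute_csp(
    free: ShiftTable,
    bound: ShiftTable,
    nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
) -> list[CspRecord]:
    """Combined CSPs per residue; one-state-only residues flagged missing, never dropped."""
    f = free.shifts.assign(residue=free.shifts["residue"].astype(int))
    b = bound.shifts.assign(residue=bound.shifts["residue"].astype(int))
    merged = f.merge(b, on="residue", how="outer", suffixes=("_free", "_bound"),
                     indicator="origin").sort_values("residue")
    if not (merged["origin"] == "both").any():
        raise ValueError("shift tables share no residues: cannot join free and bound states")
    records: list[CspRecord] = []
    for row in merged.itertuples(index=False):
        if row.origin != "both":
            records.append(CspRecord(int(row.residue), None, None, None, missing=True))
            continue
        dh = float(row.delta_H_ppm_bound - row.delta_H_ppm_free)
        dn = float(row.delta_N_ppm_bound - row.delta_N_ppm_free)
        records.append(CspRecord(int(row.residue), dh, dn, math.hypot(dh, nitrogen_weight * dn)))
    return records


def classify_interface(
    records: list[CspRecord],
    threshold: float = DEFAULT_CSP_THRESHOLD,
) -> list[int]:
    """Residues with combined CSP strictly greater than the threshold, sorted."""
    return sorted(r.residue for r in records if r.csp is not None and r.csp > threshold)


def interface_overlap(
    flagged: set[int] | list[int],
    annotation: InterfaceAnnotation,
    construct: set[int] | None = None,
) -> dict:
    """Fraction of flagged residues inside the annotated surface, plus 2x2 counts.

    The contingency table is over the construct residue set (defaults to
    flagged | annotated): rows flagged/not, columns annotated/not.
    """
    flagged = set(flagged)
    annotated = set(annotation.residues)
    if not annotated:
        raise ValueError("empty interface annotation")
    universe = set(construct) if construct is not None else (flagged | annotated)
    both = len(flagged & annotated)
    counts = {
        "flagged_annotated": both,
        "flagged_other": len(flagged - annotated),
        "unflagged_annotated": len(annotated - flagged),
        "unflagged_other": len(universe - flagged - annotated),
    }
    fraction = both / len(flagged) if flagged else None
    return {"fraction": fraction, "counts": counts}


def csp_frame(records: list[CspRecord]) -> pd.DataFrame:
    """CSP records as a tidy DataFrame (TSV-ready)."""
    return pd.DataFrame(
        [
            {
                "residue": r.residue,
                "delta_H_ppm": r.delta_H,
                "delta_N_ppm": r.delta_N,
                "csp_ppm": r.csp,
                "missing": r.missing,
            }
            for r in records
        ]
    )
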