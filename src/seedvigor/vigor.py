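"""Germination-test statistics and vigor grading.

After a standardized seven-day germination test, each seed's embryonic shoot
length (cm) determines its vigor grade:

* HV (high vigor)   — shoot length > 7 cm
* MV (medium vigor) — 3 cm ≤ length ≤ 7 cm
* LV (low vigor)    — 1 cm ≤ length < 3 cm
* NV (no vigor)     — length < 1 cm

A seed is considered germinated (viable) when its grade is not NV, i.e. its
shoot exceeds the 1 cm criterion.  The published bin edges overlap at 3 and
7 cm; this module assigns both endpoints to MV, and 1 cm to LV, so that the
"germinated" predicate coincides exactly with ``grade != NV``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

VIGOR_GRADES = ("HV", "MV", "LV", "NV")
AGING_GROUPS = ("A", "B", "C", "D")


@dataclass(frozen=True)
class GerminationRecord:
    """One seed's germination-test outcome."""

    seed_id: int
    group: str  # aging group A (0 h) .. D (24 h)
    shoot_length_cm: float

    def __post_init__(self) -> None:
        if not (self.shoot_length_cm >= 0.0):  # also rejects NaN
            raise ValueError(
                f"shoot length must be finite and >= 0, got {self.shoot_length_cm}"
            )
        if self.group not in AGING_GROUPS:
            raise ValueError(f"unknown aging group {self.group!r}")


def classify_vigor(shoot_length_cm: float) -> str:
    """Map a shoot length in cm to a vigor grade HV/MV/LV/NV."""
    if not (shoot_length_cm >= 0.0):
        raise ValueError(f"shoot length must be >= 0, got {shoot_length_cm}")
    if shoot_length_cm > 7.0:
        return "HV"
    if shoot_length_cm >= 3.0:
        return "MV"
    if shoot_length_cm >= 1.0:
        return "LV"
    return "NV"


def germination_percentage(germinated: int, total: int) -> float:
    """Germination rate as a percentage rounded half-up to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= germinated <= total:
        raise ValueError("germinated count must lie in [0, total]")
    pct = Decimal(100 * germinated) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def tabulate(records: Sequence[GerminationRecord] | Iterable[GerminationRecord]) -> pd.DataFrame:
    """Cross-tabulate vigor grades by aging group, with margins.

    Returns a DataFrame indexed by grade (HV, MV, LV, NV) plus rows
    ``Germinated`` (total minus NV) and ``Total``; columns are the aging
    groups A–D plus a ``Total`` margin.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    counts = pd.DataFrame(0, index=list(VIGOR_GRADES), columns=list(AGING_GROUPS))
    for rec in records:
        counts.loc[classify_vigor(rec.shoot_length_cm), rec.group] += 1
    counts["Total"] = counts.sum(axis=1)
    totals = counts.sum(axis=0)
    germinated = totals - counts.loc["NV"]
    table = pd.concat(
        [counts, pd.DataFrame({"Germinated": germinated, "Total": totals}).T]
    )
    return table


def germination_summary(table: pd.DataFrame) -> pd.Series:
    """Per-group germination percentages from a :func:`tabulate` table."""
    return pd.Series(
        {
            col: germination_percentage(
                int(table.loc["Germinated", col]), int(table.loc["Total", col])
            )
            for col in table.columns
            if int(table.loc["Total", col]) > 0
        },
        name="germination_pct",
    )


def read_germination_csv(path) -> list[GerminationRecord]:
    df = pd.read_csv(path)
    return [
        GerminationRecord(int(r.seed_id), str(r.group), float(r.shoot_length_cm))
        for r in df.itertuples()
    ]


def write_germination_csv(records: Sequence[GerminationRecord], path) -> None:
    pd.DataFrame(
        {
            "seed_id": [r.seed_id for r in records],
            "group": [r.group for r in records],
            "shoot_length_cm": [r.shoot_length_cm for r in records],
        }
    ).to_csv(path, index=False)
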