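"""Three-type cristae-health classification and LGG/HGG grade grouping.

Type 1: dense, abundant cristae with intact outer membrane.
Type 2: sparse cristae, occasionally incomplete outer membrane.
Type 3: severely damaged or vanished cristae, often ruptured membrane.

The original typing is a human visual judgment; the thresholded proxy here
(defaults t_low = 0.10, t_high = 0.50 on cristae occupancy) operationalizes
it for synthetic pipelines and must not be read as the clinical criterion.
Human-assigned type labels, when present on a record, always override the
proxy.  Boundary values classify upward (toward the healthier type).
"""

from __future__ import annotations

from enum import IntEnum
from typing import Iterable, Optional

import pandas as pd


class MRCType(IntEnum):
    TYPE1 = 1
    TYPE2 = 2
    TYPE3 = 3


LGG = "LGG"
HGG = "HGG"

DEFAULT_T_LOW = 0.10
DEFAULT_T_HIGH = 0.50


def classify_mrc_type(
    occupancy: Optional[float],
    omm_intact: Optional[bool],
    t_low: float = DEFAULT_T_LOW,
    t_high: float = DEFAULT_T_HIGH,
) -> Optional[MRCType]:
    """Rule-based proxy type from occupancy and membrane integrity.

    Decision table (boundary values go to the healthier type):

    ==================  ============  ======
    occupancy           omm_intact    type
    ==================  ============  ======
    >= t_high           True/unknown  TYPE1
    >= t_high           False         TYPE2
    (t_low, t_high)     True/unknown  TYPE2
    (t_low, t_high)     False         TYPE3
    <= t_low            any           TYPE3
    ==================  ============  ======

    Returns None when both inputs are absent.
    """
    if not (0.0 <= t_low < t_high <= 1.0):
        raise ValueError(
            f"thresholds must satisfy 0 <= t_low < t_high <= 1, got "
            f"({t_low}, {t_high})"
        )
    if occupancy is None and omm_intact is None:
        return None
    if occupancy is None:
        return MRCType.TYPE1 if omm_intact else MRCType.TYPE3
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError(f"occupancy {occupancy} outside [0, 1]")
    intact = omm_intact is not False  # unknown membrane treated as intact
    if occupancy >= t_high:
        return MRCType.TYPE1 if intact else MRCType.TYPE2
    if occupancy > t_low:
        return MRCType.TYPE2 if intact else MRCType.TYPE3
    return MRCType.TYPE3


def assign_grade_group(grade: int) -> str:
    """WHO grade 1-2 -> LGG, grade 3-4 -> HGG."""
    if grade in (1, 2):
        return LGG
    if grade in (3, 4):
        return HGG
    raise ValueError(f"grade must be in 1..4, got {grade}")


def record_type(record, t_low: float = DEFAULT_T_LOW,
                t_high: float = DEFAULT_T_HIGH) -> Optional[MRCType]:
    """Type for a MorphometryRecord: human label if present, else proxy."""
    if getattr(record, "mrc_type", None) is not None:
        return MRCType(record.mrc_type)
    return classify_mrc_type(
        getattr(record, "cristae_occupancy", None),
        getattr(record, "omm_intact", None),
        t_low,
        t_high,
    )


def type_composition(
    records: Iterable, grouping: str = "group"
) -> pd.DataFrame:
    """Per-group proportions of Types 1-3 (rows sum to 1).

    ``grouping``: "grade" for per-WHO-grade rows, "group" for LGG/HGG.
    Untyped records raise; empty groups are simply absent from the table.
    """
    rows = []
    for rec in records:
        t = record_type(rec)
        if t is None:
            raise ValueError(
                f"record {getattr(rec, 'instance_id', '?')} cannot be typed"
            )
        grade = getattr(rec, "grade", None)
        if grouping == "grade":
            key = grade
        elif grouping == "group":
            key = assign_grade_group(grade) if grade is not None else None
        else:
            raise ValueError(f"unknown grouping {grouping!r}")
        rows.append({"group": key, "type": int(t)})
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=[1, 2, 3])
    counts = df.pivot_table(
        index="group", columns="type", aggfunc="size", fill_value=0
    )
    for t in (1, 2, 3):
        if t not in counts.columns:
            counts[t] = 0
    counts = counts[[1, 2, 3]]
    return counts.div(counts.sum(axis=1), axis=0)
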