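"""Serum-pharmacology microplate statistics.

An MTT plate read at 570 nm gives one optical density (OD) per well,
proportional to viable-cell mass. Each treatment group's effect versus
the control group is the inhibition ratio

    IR(%) = (OD_control - OD_treated) / (OD_control - OD_blank) * 100

which may be negative (growth stimulation) and is not clamped. Group
means use the sample standard deviation (n-1 denominator) and are
compared to control with a two-sample Student t-test (equal variances
by default; a Welch variant is available). The blank OD defaults to 0
when a plate does not record one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONTROL = "control"


@dataclass
class PlateAssay:
    """Replicate OD readings keyed by group label.

    ``groups`` must contain a ``"control"`` entry; every reading is a
    non-negative absorbance.
    """

    groups: dict[str, list[float]] = field(default_factory=dict)
    od_blank: float = 0.0

    def __post_init__(self) -> None:
        if self.od_blank < 0:
            raise ValueError("blank OD must be non-negative")
        for name, readings in self.groups.items():
            if len(readings) == 0:
                raise ValueError(f"group {name!r} has no replicates")
            if any(od < 0 for od in readings):
                raise ValueError(f"group {name!r} contains a negative OD")


def read_plate(path: str | Path, od_blank: float = 0.0) -> PlateAssay:
    """Read a long-format plate table (columns: well, group, od)."""
    df = pd.read_csv(Path(path), sep="\t")
    for col in ("well", "group", "od"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing plate column {col!r}")
    groups = {
        str(g): sub["od"].astype(float).tolist() for g, sub in df.groupby("group")
    }
    return PlateAssay(groups=groups, od_blank=od_blank)


def inhibition_ratio(od_control: float, od_treated: float, od_blank: float = 0.0) -> float:
    """Percent growth inhibition of a treated group relative to control.

    Requires ``od_control > od_blank`` (otherwise the denominator is
    degenerate); returns 0 exactly when treated equals control.
    """
    if od_control <= od_blank:
        raise ValueError(
            f"control OD ({od_control}) must exceed blank OD ({od_blank})"
        )
    return (od_control - od_treated) / (od_control - od_blank) * 100.0


def summarize_plate(
    plate: PlateAssay,
    control_group: str = CONTROL,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-group mean/SD, inhibition ratio from group means, and t-test
    p-value versus the control group.

    Inhibition ratios are computed from the group mean ODs, matching
    how plate tables report them. The control row has IR 0 by
    definition and no p-value. Groups with a single replicate report
    no SD and skip the test with a warning.
    """
    if control_group not in plate.groups:
        raise ValueError(f"plate has no control group {control_group!r}")
    control = np.asarray(plate.groups[control_group], dtype=float)
    od_control = float(control.mean())
    rows = []
    for name, readings in plate.groups.items():
        arr = np.asarray(readings, dtype=float)
        n = arr.size
        mean_od = float(arr.mean())
        sd_od = float(arr.std(ddof=1)) if n >= 2 else math.nan
        if name == control_group:
            ir, p = 0.0, math.nan
        else:
            ir = inhibition_ratio(od_control, mean_od, plate.od_blank)
            if n < 2 or control.size < 2:
                logger.warning(
                    "group %r: fewer than 2 replicates, t-test skipped", name
                )
                p = math.nan
            else:
                p = float(
                    stats.ttest_ind(arr, control, equal_var=equal_var).pvalue
                )
        rows.append(
            {
                "group": name,
                "n": n,
                "mean_od": mean_od,
                "sd_od": sd_od,
                "inhibition_ratio_pct": ir,
                "p_value": p,
                "significant": bool(p < alpha) if not math.isnan(p) else False,
            }
        )
    order = [control_group] + sorted(g for g in plate.groups if g != control_group)
    df = pd.DataFrame(rows).set_index("group").loc[order].reset_index()
    return df
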