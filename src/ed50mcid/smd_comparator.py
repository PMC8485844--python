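"""Traditional MCID comparator: group change summaries and standardized
mean differences.

The classical anchor-based estimate contrasts patients *feeling slightly
better* with those *feeling about the same*: the crude difference in mean
change and the standardized mean difference (SMD)

    SMD = (mean_better - mean_same) / sqrt((sd_better^2 + sd_same^2) / 2).

The average-variance pooling (not the df-weighted pooled SD) is the
convention of standard descriptive-table software and is what published
group summaries from the PANDA trial reproduce exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ed50mcid.data_model import ObservationRecord, records_to_frame

__all__ = ["GroupChangeSummary", "SmdResult", "group_summaries", "crude_and_smd"]


@dataclass(frozen=True)
class GroupChangeSummary:
    """Mean/SD of change for one GRC category within a stratum."""

    scale: str
    study_id: str
    interval_index: int
    grc: str
    n: int
    mean_change: float
    sd_change: float  # sample SD (n-1); NaN when n == 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if not math.isnan(self.sd_change) and self.sd_change < 0:
            raise ValueError("SD must be non-negative")


@dataclass(frozen=True)
class SmdResult:
    """Crude and standardized mean difference between two GRC groups."""

    stratum: str
    mean_better: float
    sd_better: float
    mean_same: float
    sd_same: float
    crude_difference: float
    smd: float


def group_summaries(records: Sequence[ObservationRecord]) -> list[GroupChangeSummary]:
    """Per (scale, study, interval, GRC category) mean/SD/n of change.

    SD uses the n-1 denominator; single-record groups get ``sd = NaN``.
    Empty groups are simply absent.
    """
    frame = records_to_frame(records)
    out = []
    for (scale, study, interval, grc), grp in frame.groupby(
        ["scale", "study_id", "interval_index", "grc_raw"], sort=True
    ):
        changes = grp["change"].to_numpy(dtype=float)
        out.append(
            GroupChangeSummary(
                scale=str(scale),
                study_id=str(study),
                interval_index=int(interval),
                grc=str(grc),
                n=len(changes),
                mean_change=round(float(np.mean(changes)), 2),
                sd_change=round(float(np.std(changes, ddof=1)), 2)
                if len(changes) > 1
                else float("nan"),
            )
        )
    return out


def crude_and_smd(
    better: GroupChangeSummary, same: GroupChangeSummary, stratum: str | None = None
) -> SmdResult:
    """Crude difference and SMD between a *better* and a *same* group.

    Requires both groups to have n >= 2 (an SD).  A zero pooled SD yields
    ``smd = NaN`` (flagged, not fatal) unless the crude difference is also
    zero, in which case the SMD is 0 by convention.
    """
    for grp, name in ((better, "better"), (same, "same")):
        if grp.n < 2 or math.isnan(grp.sd_change):
            raise ValueError(f"group '{name}' needs n >= 2 with a defined SD")
    crude = better.mean_change - same.mean_change
    pooled = math.sqrt((better.sd_change**2 + same.sd_change**2) / 2.0)
    if pooled == 0:
        smd = 0.0 if crude == 0 else float("nan")
    else:
        smd = crude / pooled
    return SmdResult(
        stratum=stratum
        or f"{better.scale}/{better.study_id}/interval{better.interval_index}",
        mean_better=better.mean_change,
        sd_better=better.sd_change,
        mean_same=same.mean_change,
        sd_same=same.sd_change,
        crude_difference=round(crude, 2),
        smd=round(smd, 2) if not math.isnan(smd) else smd,
    )


def summaries_frame(summaries: Sequence[GroupChangeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scale": [s.scale for s in summaries],
            "study_id": [s.study_id for s in summaries],
            "interval_index": [s.interval_index for s in summaries],
            "grc": [s.grc for s in summaries],
            "n": [s.n for s in summaries],
            "mean_change": [s.mean_change for s in summaries],
            "sd_change": [s.sd_change for s in summaries],
        }
    )


def smd_frame(results: Sequence[SmdResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stratum": [r.stratum for r in results],
            "mean_better": [r.mean_better for r in results],
            "sd_better": [r.sd_better for r in results],
            "mean_same": [r.mean_same for r in results],
            "sd_same": [r.sd_same for r in results],
            "crude_difference": [r.crude_difference for r in results],
            "smd": [r.smd for r in results],
        }
    )
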