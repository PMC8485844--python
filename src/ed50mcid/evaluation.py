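"""Sensitivity, specificity, and disagreement of an ED-based MCID rule.

Each observation interval is classified as meeting the MCID when its change
reaches the ED50 at its rolling baseline; the dichotomized Global Rating of
Change is the reference standard.  By default performance is apparent
(classified on the same records the surface was fitted to).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from ed50mcid.data_model import BETTER, ObservationRecord
from ed50mcid.ed_extraction import EDTable

__all__ = ["MET", "NOT_MET", "ClassificationMetrics", "classify_mcid", "compute_metrics"]

MET = "met"
NOT_MET = "not_met"


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion-matrix summary of an MCID rule against the anchor.

    ``sensitivity = tp/(tp+fn)``, ``specificity = tn/(tn+fp)``,
    ``disagreement_percent = 100*(fp+fn)/n``.  Undefined ratios (empty
    margin) are reported as NaN.
    """

    stratum: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    @property
    def disagreement_percent(self) -> float:
        return 100.0 * (self.fp + self.fn) / self.n if self.n else float("nan")


def classify_mcid(record: ObservationRecord, ed_table: EDTable, p: float = 0.5) -> str | None:
    """``met`` iff the interval's change reaches the ED at its baseline.

    Uses the continuous ED at threshold probability ``p`` (the ED50 by
    default).  At baselines where the ED floor is 0, any non-deterioration
    (change >= 0) counts as met.  Returns None (record excluded) when the
    baseline has no table row (baseline 0) or its ED is unattainable.
    """
    try:
        ed = ed_table.ed(p, record.baseline_score)
    except KeyError:
        return None
    if isinstance(ed, str):  # unattainable
        return None
    return MET if record.change >= ed else NOT_MET


def compute_metrics(
    records: Sequence[ObservationRecord],
    ed_table: EDTable,
    by_study: bool = True,
    p: float = 0.5,
    log: list[str] | None = None,
) -> list[ClassificationMetrics]:
    """Confusion metrics of the ED rule vs the anchor, overall and per study.

    Records whose ED is unattainable (or whose baseline has no table row)
    are excluded; the exclusion count and any use of the zero-ED edge rule
    are noted in ``log``.
    """
    rows = []
    n_excluded = 0
    n_zero_floor = 0
    for r in records:
        verdict = classify_mcid(r, ed_table, p=p)
        if verdict is None:
            n_excluded += 1
            continue
        ed50 = ed_table.ed(p, r.baseline_score)
        if ed50 == 0:
            n_zero_floor += 1
        rows.append(
            {"stratum": r.study_id, "met": verdict == MET, "better": r.grc_binary == BETTER}
        )
    if log is not None:
        log.append(f"evaluation: excluded {n_excluded} records with unattainable ED50")
        if n_zero_floor:
            log.append(
                f"evaluation: {n_zero_floor} records classified under the "
                "zero-ED50 edge rule (change >= 0 counts as met)"
            )
    frame = pd.DataFrame(rows)
    if frame.empty:
        raise ValueError("no classifiable records (all excluded)")

    def confusion(sub: pd.DataFrame, stratum: str) -> ClassificationMetrics:
        return ClassificationMetrics(
            stratum=stratum,
            tp=int((sub["met"] & sub["better"]).sum()),
            fp=int((sub["met"] & ~sub["better"]).sum()),
            tn=int((~sub["met"] & ~sub["better"]).sum()),
            fn=int((~sub["met"] & sub["better"]).sum()),
        )

    out = [confusion(frame, "overall")]
    if by_study:
        for study, sub in frame.groupby("stratum", sort=True):
            out.append(confusion(sub, str(study)))
    return out


def metrics_frame(metrics: Sequence[ClassificationMetrics], scale_name: str) -> pd.DataFrame:
    """Flatten metrics into a display table (stratum, scale, rates, counts)."""
    return pd.DataFrame(
        {
            "stratum": [m.stratum for m in metrics],
            "scale": scale_name,
            "sensitivity": [round(m.sensitivity, 2) for m in metrics],
            "specificity": [round(m.specificity, 2) for m in metrics],
            "disagreement_percent": [round(m.disagreement_percent, 1) for m in metrics],
            "tp": [m.tp for m in metrics],
            "fp": [m.fp for m in metrics],
            "tn": [m.tn for m in metrics],
            "fn": [m.fn for m in metrics],
            "n": [m.n for m in metrics],
        }
    )
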