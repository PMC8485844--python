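"""ED inversion: from the probability surface to the per-baseline MCID table.

The ED50 at a baseline score b is the smallest change c in [0, b] whose
modelled probability of *feeling better* reaches 50%; ED25 and ED75 are the
25%/75% analogues bracketing it.  A floor of zero change is imposed (a
deterioration is never an improvement) and EDs that would require more
change than the scale allows (c > b) are flagged unattainable.  Absolute EDs
are also expressed as percent of baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd

from ed50mcid.data_model import ObservationRecord, ScaleSpec

__all__ = [
    "UNATTAINABLE",
    "ProbabilitySurface",
    "EDTable",
    "effective_dose",
    "ed_percent",
    "round_half_up",
    "build_ed_table",
]

#: Sentinel for EDs beyond the maximum possible improvement at a baseline.
UNATTAINABLE = "N.A."

_GRID_STEP = 0.01
_BISECT_TOL = 1e-8


class ProbabilitySurface(Protocol):
    """Anything exposing P(better | change, baseline) and a scale."""

    scale: ScaleSpec

    def predict(self, change, baseline, mode: str = "population") -> np.ndarray: ...


def effective_dose(
    surface: ProbabilitySurface, p: float, baseline: int
) -> float | str:
    """Smallest change c in [0, baseline] with P(better | c, baseline) >= p.

    Scans a 0.01-resolution grid and refines the bracketing pair by
    bisection.  Returns 0.0 when the probability already reaches ``p`` at
    zero change (the floor), and :data:`UNATTAINABLE` when even the maximum
    possible improvement (c = baseline, i.e. a follow-up score at the scale
    minimum) stays below ``p``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability p must be in (0, 1), got {p}")
    lo_b = max(surface.scale.min_score, 1)
    if not lo_b <= baseline <= surface.scale.max_score:
        raise ValueError(
            f"baseline must be an integer in [{lo_b}, {surface.scale.max_score}] "
            f"(no improvement is possible at baseline 0), got {baseline}"
        )
    b = float(baseline)
    if float(surface.predict(0.0, b)) >= p:
        return 0.0
    if float(surface.predict(b, b)) < p:
        return UNATTAINABLE

    grid = np.arange(0.0, b + _GRID_STEP / 2, _GRID_STEP)
    grid[-1] = b
    probs = np.asarray(surface.predict(grid, np.full_like(grid, b))).ravel()
    k = int(np.argmax(probs >= p))  # first grid point at/above threshold
    lo, hi = grid[k - 1], grid[k]
    # bisection on the monotone section between the bracketing grid points
    while hi - lo > _BISECT_TOL:
        mid = 0.5 * (lo + hi)
        if float(surface.predict(mid, b)) >= p:
            hi = mid
        else:
            lo = mid
    return float(hi)


def round_half_up(value: float, digits: int = 0) -> float:
    """Round with .5 going away from zero (table display convention)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def ed_percent(ed: float | str, baseline: int) -> float | str:
    """Express an absolute ED as percent change from baseline.

    An unattainable ED propagates; baseline must be >= 1.
    """
    if isinstance(ed, str):
        if ed == UNATTAINABLE:
            return UNATTAINABLE
        raise ValueError(f"unrecognized ED value {ed!r}")
    if baseline < 1:
        raise ValueError("percent change from a zero baseline is undefined")
    return 100.0 * float(ed) / float(baseline)


def _ceil_points(ed: float | str) -> float | str:
    """Smallest whole-point change achieving the threshold (0 stays 0)."""
    if isinstance(ed, str):
        return ed
    # tolerance absorbs the bisection bracket so an exact integer crossing
    # is not pushed up a whole point
    return float(math.ceil(ed - 1e-6)) if ed > 1e-6 else 0.0


@dataclass
class EDTable:
    """Per-integer-baseline ED25/ED50/ED75 MCID table plus sample averages.

    ``table`` has one row per baseline 1..max_score with continuous EDs
    (2 d.p. display), whole-point EDs (ceiling), ED50 as percent of
    baseline, and the severity band label.  ``averages`` holds the
    sample-average row (mean ED over observation intervals, each evaluated
    at its own rolling baseline); it is None when no records were supplied.
    """

    scale: ScaleSpec
    probabilities: tuple[float, ...]
    table: pd.DataFrame
    averages: dict[str, float] | None
    average_mode: str = "per_observation"
    n_excluded_baseline0: int = 0

    def ed(self, p: float, baseline: int) -> float | str:
        row = self.table.loc[self.table["baseline"] == baseline]
        if row.empty:
            raise KeyError(f"no table row for baseline {baseline}")
        col = f"ED{int(round(100 * p))}"
        val = row.iloc[0][col]
        return UNATTAINABLE if isinstance(val, str) else float(val)

    def to_csv_frame(self, clinical_display: bool = False) -> pd.DataFrame:
        """Display table; optionally substitute 100% for unattainable percents."""
        disp = self.table.copy()
        if clinical_display:
            disp["ED50_percent"] = [
                100.0 if isinstance(v, str) else v for v in disp["ED50_percent"]
            ]
        if self.averages is not None:
            avg = {c: "" for c in disp.columns}
            avg.update({"baseline": "average_across_sample", **self.averages})
            disp = pd.concat([disp, pd.DataFrame([avg])], ignore_index=True)
        return disp


def build_ed_table(
    surface: ProbabilitySurface,
    scale: ScaleSpec | None = None,
    records: Sequence[ObservationRecord] | None = None,
    probabilities: Iterable[float] = (0.25, 0.5, 0.75),
    average_mode: str = "per_observation",
) -> EDTable:
    """Invert the surface at every integer baseline and average over the sample.

    ``average_mode="per_observation"`` weights every observation interval
    equally; ``"per_patient"`` first averages within patient.  Records with
    rolling baseline 0 (no improvement possible, no table row) are excluded
    from averaging with a count kept on the result.
    """
    scale = scale or surface.scale
    probs = tuple(sorted(float(p) for p in probabilities))
    if any(not 0 < p < 1 for p in probs):
        raise ValueError("ED probabilities must be strictly inside (0, 1)")

    rows = []
    ed_by_baseline: dict[float, dict[int, float | str]] = {p: {} for p in probs}
    for b in range(max(scale.min_score, 1), scale.max_score + 1):
        row: dict[str, object] = {"baseline": b, "band": scale.band_label(b)}
        for p in probs:
            ed = effective_dose(surface, p, b)
            ed_by_baseline[p][b] = ed
            key = f"ED{int(round(100 * p))}"
            row[key] = ed if isinstance(ed, str) else round(ed, 2)
            row[f"{key}_points"] = _ceil_points(ed)
            if math.isclose(p, 0.5):
                pct = ed_percent(ed, b)
                row["ED50_percent"] = pct if isinstance(pct, str) else round(pct, 2)
        rows.append(row)
    table = pd.DataFrame(rows)

    averages = None
    n_excluded = 0
    if records:
        baselines = np.array([r.baseline_score for r in records])
        patients = np.array([r.patient_id for r in records])
        keep = baselines >= max(scale.min_score, 1)
        n_excluded = int((~keep).sum())
        averages = {}
        for p in probs:
            per_obs = np.array(
                [
                    np.nan if isinstance(ed_by_baseline[p][b], str) else ed_by_baseline[p][b]
                    for b in baselines[keep]
                ],
                dtype=float,
            )
            key = f"ED{int(round(100 * p))}"
            averages[key] = _average(per_obs, patients[keep], average_mode)
            if math.isclose(p, 0.5):
                pct = 100.0 * per_obs / baselines[keep]
                averages["ED50_percent"] = _average(pct, patients[keep], average_mode)
    else:
        warnings.warn(
            "no records supplied; ED table built without the sample-average row",
            UserWarning,
            stacklevel=2,
        )
    return EDTable(
        scale=scale,
        probabilities=probs,
        table=table,
        averages=averages,
        average_mode=average_mode,
        n_excluded_baseline0=n_excluded,
    )


def _average(values: np.ndarray, patients: np.ndarray, mode: str) -> float:
    ok = ~np.isnan(values)
    if mode == "per_observation":
        return float(np.round(np.mean(values[ok]), 2))
    if mode == "per_patient":
        frame = pd.DataFrame({"patient": patients[ok], "value": values[ok]})
        return float(np.round(frame.groupby("patient")["value"].mean().mean(), 2))
    raise ValueError(f"unknown average_mode {mode!r}")
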