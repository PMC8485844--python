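"""Observation data model: rolling-baseline change scores and the GRC anchor.

Visits are long-format rows (patient, study, visit index, scale, score, GRC).
Each consecutive pair of non-missing visits with a Global Rating of Change
(GRC) response at the later visit yields one observation interval.  The
change for the interval ending at time t is ``x_(t-1) - x_t`` (a rolling
baseline), so positive changes are symptom improvements and negative changes
are deteriorations.

The ordinal GRC is dichotomized into *better* vs *not better* ("not better"
pools *same* and all *worse* levels).  Anchor validity is checked with
Spearman rank correlations between the full ordinal GRC and the change
score; |rho| >= 0.30 is the conventional adequacy gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PHQ9",
    "GAD7",
    "BETTER",
    "NOT_BETTER",
    "ScaleSpec",
    "ObservationRecord",
    "GrcMapping",
    "GRC_5_LEVEL",
    "GRC_3_LEVEL",
    "ValidationError",
    "compute_changes",
    "dichotomize_grc",
    "anchor_validity",
    "records_to_frame",
]

BETTER = "better"
NOT_BETTER = "not_better"


class ValidationError(ValueError):
    """Raised when input visit data violate the scale or ordering contract."""


@dataclass(frozen=True)
class ScaleSpec:
    """A bounded integer symptom scale with ordered severity bands.

    ``severity_bands`` maps band labels to their lower-bound score, e.g. the
    conventional PHQ-9 clinical cut-offs Minimal/Mild/Moderate/Severe at
    1/5/10/15.
    """

    name: str
    min_score: int = 0
    max_score: int = 27
    severity_bands: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.min_score >= self.max_score:
            raise ValidationError(
                f"scale {self.name}: min_score {self.min_score} must be < "
                f"max_score {self.max_score}"
            )
        bounds = [b for _, b in self.severity_bands]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValidationError(
                f"scale {self.name}: severity band bounds must be strictly increasing"
            )
        if bounds and not (self.min_score <= bounds[0] and bounds[-1] <= self.max_score):
            raise ValidationError(
                f"scale {self.name}: severity band bounds must lie in "
                f"[{self.min_score}, {self.max_score}]"
            )

    def in_bounds(self, score: float) -> bool:
        return self.min_score <= score <= self.max_score

    def band_label(self, score: int) -> str:
        """Severity band containing ``score`` (empty string below the first band)."""
        label = ""
        for name, lower in self.severity_bands:
            if score >= lower:
                label = name
        return label


#: 9-item Patient Health Questionnaire (depression), scores 0-27.
PHQ9 = ScaleSpec(
    name="PHQ9",
    min_score=0,
    max_score=27,
    severity_bands=(("Minimal", 1), ("Mild", 5), ("Moderate", 10), ("Severe", 15)),
)

#: 7-item Generalized Anxiety Disorder scale, scores 0-21.
GAD7 = ScaleSpec(
    name="GAD7",
    min_score=0,
    max_score=21,
    severity_bands=(("Minimal", 1), ("Mild", 5), ("Moderate", 10), ("Severe", 15)),
)


@dataclass(frozen=True)
class GrcMapping:
    """Binary collapse of an ordinal GRC plus its ordinal coding.

    ``binary`` maps each raw label to ``better``/``not_better``; ``ordinal``
    assigns the rank used for anchor-validity correlations.  Ranks are coded
    with "a lot better" lowest (1) and "a lot worse" highest, so correlations
    against improvement come out negative.
    """

    binary: Mapping[str, str]
    ordinal: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.binary) != set(self.ordinal):
            raise ValidationError("binary and ordinal mappings must cover the same labels")
        bad = {v for v in self.binary.values()} - {BETTER, NOT_BETTER}
        if bad:
            raise ValidationError(f"binary targets must be better/not_better, got {bad}")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.ordinal, key=self.ordinal.__getitem__))

    def to_binary(self, label: str) -> str:
        try:
            return self.binary[label]
        except KeyError:
            raise ValidationError(
                f"unknown GRC label {label!r}; accepted labels: {list(self.labels)}"
            ) from None

    def to_ordinal(self, label: str) -> int:
        try:
            return self.ordinal[label]
        except KeyError:
            raise ValidationError(
                f"unknown GRC label {label!r}; accepted labels: {list(self.labels)}"
            ) from None


#: 5-level GRC as used in the PANDA trial.
GRC_5_LEVEL = GrcMapping(
    binary={
        "I feel a lot better": BETTER,
        "I feel slightly better": BETTER,
        "I feel about the same": NOT_BETTER,
        "I feel slightly worse": NOT_BETTER,
        "I feel a lot worse": NOT_BETTER,
    },
    ordinal={
        "I feel a lot better": 1,
        "I feel slightly better": 2,
        "I feel about the same": 3,
        "I feel slightly worse": 4,
        "I feel a lot worse": 5,
    },
)

#: 3-level GRC as used in the CoBalT trial.
GRC_3_LEVEL = GrcMapping(
    binary={
        "I feel better": BETTER,
        "I feel about the same": NOT_BETTER,
        "I feel worse": NOT_BETTER,
    },
    ordinal={
        "I feel better": 1,
        "I feel about the same": 2,
        "I feel worse": 3,
    },
)


@dataclass(frozen=True)
class ObservationRecord:
    """One follow-up interval for one patient.

    ``baseline_score`` is the rolling baseline (score at the start of the
    interval), ``change = baseline_score - followup_score`` so that positive
    values are improvements.
    """

    patient_id: str
    study_id: str
    interval_index: int
    scale: ScaleSpec
    baseline_score: int
    followup_score: int
    change: int
    grc_raw: str
    grc_binary: str
    grc_ordinal: int = field(default=0)

    def __post_init__(self) -> None:
        if self.interval_index < 1:
            raise ValidationError(
                f"patient {self.patient_id}: interval_index must be >= 1"
            )
        for what, score in (
            ("baseline", self.baseline_score),
            ("follow-up", self.followup_score),
        ):
            if not self.scale.in_bounds(score):
                raise ValidationError(
                    f"patient {self.patient_id} interval {self.interval_index}: "
                    f"{what} score {score} outside scale "
                    f"[{self.scale.min_score}, {self.scale.max_score}]"
                )
        if self.change != self.baseline_score - self.followup_score:
            raise ValidationError(
                f"patient {self.patient_id} interval {self.interval_index}: "
                "change must equal baseline_score - followup_score"
            )
        if self.grc_binary not in (BETTER, NOT_BETTER):
            raise ValidationError(
                f"patient {self.patient_id}: grc_binary must be better/not_better"
            )

    @property
    def improved(self) -> bool:
        return self.grc_binary == BETTER


def dichotomize_grc(grc_raw: str, mapping: GrcMapping) -> str:
    """Collapse an ordinal GRC label into ``better`` / ``not_better``."""
    return mapping.to_binary(grc_raw)


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and not value.strip():
        return True
    return pd.isna(value)


def compute_changes(
    visits: pd.DataFrame,
    scale: ScaleSpec,
    mappings: Mapping[str, GrcMapping],
    log: list[str] | None = None,
) -> list[ObservationRecord]:
    """Turn per-patient ordered visit sequences into observation intervals.

    Parameters
    ----------
    visits
        Long-format table with columns ``patient_id``, ``study_id``,
        ``visit_index``, ``scale``, ``score``, ``grc``.  The first visit of a
        patient carries no GRC.  Scores or GRC may be missing (empty / NaN).
    scale
        The questionnaire to process; rows for other scales are ignored, so
        scales with different follow-up schedules are handled independently.
    mappings
        Per-study GRC mapping (5-level and 3-level GRC can coexist).
    log
        Optional list collecting human-readable notes (dropped-interval
        counts).

    Returns
    -------
    One :class:`ObservationRecord` per consecutive pair of non-missing scores
    whose later visit has a GRC response.  Intervals with a missing endpoint
    or missing GRC are dropped (complete-interval analysis).
    """
    required = {"patient_id", "study_id", "visit_index", "scale", "score", "grc"}
    missing_cols = required - set(visits.columns)
    if missing_cols:
        raise ValidationError(f"visit table missing columns: {sorted(missing_cols)}")

    sub = visits[visits["scale"] == scale.name]
    records: list[ObservationRecord] = []
    n_dropped = 0

    for (patient_id, study_id), grp in sub.groupby(["patient_id", "study_id"], sort=True):
        idx = grp["visit_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise ValidationError(f"patient {patient_id}: duplicated visit indices")
        if not np.all(np.diff(idx) > 0):
            # accept unordered input only if sortable without ties
            grp = grp.sort_values("visit_index")
            idx = grp["visit_index"].to_numpy()
            if not np.all(np.diff(idx) > 0):
                raise ValidationError(f"patient {patient_id}: unordered visit indices")
        try:
            mapping = mappings[str(study_id)]
        except KeyError:
            raise ValidationError(
                f"no GRC mapping configured for study {study_id!r}"
            ) from None

        scores = list(grp["score"])
        grcs = list(grp["grc"])
        for v, score in enumerate(scores):
            if not _is_missing(score) and not scale.in_bounds(float(score)):
                raise ValidationError(
                    f"patient {patient_id} visit {idx[v]}: score {score} outside "
                    f"scale [{scale.min_score}, {scale.max_score}]"
                )
        interval = 0
        for v in range(1, len(scores)):
            prev_s, cur_s, grc = scores[v - 1], scores[v], grcs[v]
            interval += 1
            if _is_missing(prev_s) or _is_missing(cur_s) or _is_missing(grc):
                n_dropped += 1
                continue
            baseline = int(prev_s)
            followup = int(cur_s)
            grc = str(grc)
            records.append(
                ObservationRecord(
                    patient_id=str(patient_id),
                    study_id=str(study_id),
                    interval_index=interval,
                    scale=scale,
                    baseline_score=baseline,
                    followup_score=followup,
                    change=baseline - followup,
                    grc_raw=grc,
                    grc_binary=mapping.to_binary(grc),
                    grc_ordinal=mapping.to_ordinal(grc),
                )
            )
    if log is not None:
        log.append(
            f"{scale.name}: kept {len(records)} complete intervals, "
            f"dropped {n_dropped} incomplete"
        )
    return records


def records_to_frame(records: Sequence[ObservationRecord]) -> pd.DataFrame:
    """Flatten observation records into a DataFrame (one row per interval)."""
    return pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "study_id": [r.study_id for r in records],
            "interval_index": [r.interval_index for r in records],
            "scale": [r.scale.name for r in records],
            "baseline_score": [r.baseline_score for r in records],
            "followup_score": [r.followup_score for r in records],
            "change": [r.change for r in records],
            "grc_raw": [r.grc_raw for r in records],
            "grc_ordinal": [r.grc_ordinal for r in records],
            "grc_binary": [r.grc_binary for r in records],
        }
    )


def anchor_validity(
    records: Iterable[ObservationRecord],
    threshold: float = 0.30,
) -> pd.DataFrame:
    """Spearman correlation of ordinal GRC with change, per study x interval.

    GRC ranks code "better" lowest, so an informative anchor yields negative
    rho against improvement; adequacy is judged on |rho| >= ``threshold``.
    Degenerate groups (constant GRC or constant change, or fewer than 3
    records) get ``rho = NaN`` and ``pass = False`` but are not fatal.

    Returns a DataFrame with columns ``study_id``, ``interval_index``, ``n``,
    ``rho``, ``passes``.
    """
    frame = records_to_frame(list(records))
    rows = []
    for (study, interval), grp in frame.groupby(["study_id", "interval_index"], sort=True):
        n = len(grp)
        rho = float("nan")
        if n >= 3:
            ordinal = grp["grc_ordinal"].to_numpy(dtype=float)
            change = grp["change"].to_numpy(dtype=float)
            if np.ptp(ordinal) > 0 and np.ptp(change) > 0:
                rho = float(stats.spearmanr(ordinal, change).statistic)
        passes = bool(abs(rho) >= threshold) if not math.isnan(rho) else False
        rows.append(
            {
                "study_id": study,
                "interval_index": interval,
                "n": n,
                "rho": rho,
                "passes": passes,
            }
        )
    return pd.DataFrame(rows)
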