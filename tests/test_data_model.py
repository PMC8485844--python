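"""Rolling-baseline change computation, GRC dichotomization, anchor validity."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ed50mcid.data_model import (
    BETTER,
    GAD7,
    GRC_3_LEVEL,
    GRC_5_LEVEL,
    NOT_BETTER,
    PHQ9,
    ObservationRecord,
    ScaleSpec,
    ValidationError,
    anchor_validity,
    compute_changes,
    dichotomize_grc,
)


def visit_frame(scores, grcs=None, patient="p1", study="PANDA", scale="PHQ9"):
    grcs = grcs or [""] + ["I feel slightly better"] * (len(scores) - 1)
    return pd.DataFrame(
        {
            "patient_id": patient,
            "study_id": study,
            "visit_index": range(len(scores)),
            "scale": scale,
            "score": scores,
            "grc": grcs,
        }
    )


MAPS = {"PANDA": GRC_5_LEVEL, "COBALT": GRC_3_LEVEL}


class TestComputeChanges:
    @pytest.mark.parametrize(
        "scores, expected",
        [
            ([12, 8], [(12, 4)]),  # improvement: positive change
            ([8, 12], [(8, -4)]),  # deterioration: negative change
            ([12, 8, 9], [(12, 4), (8, -1)]),  # rolling baseline follows the previous visit
        ],
    )
    def test_rolling_baseline_changes(self, scores, expected):
        records = compute_changes(visit_frame(scores), PHQ9, MAPS)
        assert [(r.baseline_score, r.change) for r in records] == expected
        for r in records:
            assert r.change + r.followup_score == r.baseline_score

    def test_incomplete_intervals_dropped_not_patients(self):
        # missing middle score kills both adjacent intervals; missing GRC kills its own
        frame = visit_frame(
            [12, None, 9, 7, 6],
            ["", "I feel slightly better", "I feel slightly better", "", "I feel a lot better"],
        )
        log: list[str] = []
        records = compute_changes(frame, PHQ9, MAPS, log=log)
        assert [(r.baseline_score, r.followup_score) for r in records] == [(7, 6)]
        assert "dropped 3" in log[0]

    def test_scales_processed_independently(self):
        phq = visit_frame([12, 8])
        gad = visit_frame([9, 5], scale="GAD7")
        both = pd.concat([phq, gad], ignore_index=True)
        assert len(compute_changes(both, PHQ9, MAPS)) == 1
        assert len(compute_changes(both, GAD7, MAPS)) == 1

    def test_out_of_bounds_score_names_patient_and_visit(self):
        with pytest.raises(ValidationError, match="p1 visit 1.*28"):
            compute_changes(visit_frame([12, 28]), PHQ9, MAPS)

    def test_duplicate_visit_index_rejected(self):
        frame = visit_frame([12, 8])
        frame["visit_index"] = [1, 1]
        with pytest.raises(ValidationError, match="duplicated"):
            compute_changes(frame, PHQ9, MAPS)

    def test_unknown_grc_label_lists_accepted(self):
        frame = visit_frame([12, 8], ["", "feeling groovy"])
        with pytest.raises(ValidationError, match="feeling groovy.*a lot better"):
            compute_changes(frame, PHQ9, MAPS)

    @given(
        scores=st.lists(st.integers(min_value=0, max_value=27), min_size=2, max_size=6)
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_change_conservation_and_count(self, scores):
        records = compute_changes(visit_frame(scores), PHQ9, MAPS)
        assert len(records) <= len(scores) - 1
        for r in records:
            assert r.change + r.followup_score == r.baseline_score
            assert r.baseline_score - 27 <= r.change <= r.baseline_score


class TestGrcMapping:
    @pytest.mark.parametrize(
        "label, expected",
        [
            ("I feel a lot better", BETTER),
            ("I feel slightly better", BETTER),
            ("I feel about the same", NOT_BETTER),
            ("I feel slightly worse", NOT_BETTER),
            ("I feel a lot worse", NOT_BETTER),
        ],
    )
    def test_five_level_collapse(self, label, expected):
        assert dichotomize_grc(label, GRC_5_LEVEL) == expected

    def test_three_level_collapse(self):
        assert dichotomize_grc("I feel better", GRC_3_LEVEL) == BETTER
        assert dichotomize_grc("I feel worse", GRC_3_LEVEL) == NOT_BETTER

    def test_unknown_label_raises(self):
        with pytest.raises(ValidationError, match="accepted labels"):
            dichotomize_grc("meh", GRC_5_LEVEL)


def make_record(change, grc_ordinal, grc_label, baseline=20, **kw):
    defaults = dict(
        patient_id=kw.pop("patient_id", "p1"),
        study_id=kw.pop("study_id", "PANDA"),
        interval_index=kw.pop("interval_index", 1),
        scale=PHQ9,
        baseline_score=baseline,
        followup_score=baseline - change,
        change=change,
        grc_raw=grc_label,
        grc_binary=GRC_5_LEVEL.to_binary(grc_label),
        grc_ordinal=grc_ordinal,
    )
    return ObservationRecord(**defaults)


LABELS = list(GRC_5_LEVEL.labels)  # ordered best -> worst


class TestAnchorValidity:
    def _records(self, changes, ordinal_fn):
        out = []
        for i, c in enumerate(changes):
            o = ordinal_fn(c)
            out.append(make_record(c, o, LABELS[o - 1], patient_id=f"p{i}"))
        return out

    def test_perfect_monotone_association_passes(self):
        # GRC rank decreasing in change -> rho = -1 under the better-lowest coding
        changes = [-4, -2, 0, 2, 4]
        records = self._records(changes, lambda c: {-4: 5, -2: 4, 0: 3, 2: 2, 4: 1}[c])
        table = anchor_validity(records)
        assert table.loc[0, "rho"] == pytest.approx(-1.0)
        assert bool(table.loc[0, "passes"])

    def test_independent_anchor_fails(self):
        rng = np.random.default_rng(7)
        records = [
            make_record(int(c), int(o), LABELS[int(o) - 1], patient_id=f"p{i}")
            for i, (c, o) in enumerate(
                zip(rng.integers(-5, 6, 400), rng.integers(1, 6, 400))
            )
        ]
        table = anchor_validity(records)
        assert abs(table.loc[0, "rho"]) < 0.30
        assert not bool(table.loc[0, "passes"])

    def test_threshold_is_inclusive_of_0_30_magnitude(self):
        # a negative correlation of magnitude exactly >= 0.30 is adequate
        frame = anchor_validity(
            self._records([-4, -2, 0, 2, 4], lambda c: {-4: 5, -2: 4, 0: 3, 2: 2, 4: 1}[c])
        )
        assert bool(frame.loc[0, "passes"])  # |rho| = 1 case
        assert 0.30 <= abs(-0.32)  # documented sign convention: reported rho is negative

    def test_degenerate_group_flagged_not_fatal(self):
        records = [
            make_record(2, 2, LABELS[1], patient_id=f"p{i}") for i in range(5)
        ]  # constant GRC and constant change
        table = anchor_validity(records)
        assert math.isnan(table.loc[0, "rho"])
        assert not bool(table.loc[0, "passes"])

    def test_invariant_under_monotone_transform_of_change(self):
        changes = [-2, -1, 0, 1, 2]
        ordinals = [5, 4, 3, 2, 2]
        rec_lin = [
            make_record(c, o, LABELS[o - 1], baseline=19, patient_id=f"p{i}")
            for i, (c, o) in enumerate(zip(changes, ordinals))
        ]
        rec_cub = [
            make_record(c**3, o, LABELS[o - 1], baseline=19, patient_id=f"p{i}")
            for i, (c, o) in enumerate(zip(changes, ordinals))
        ]
        rho_lin = anchor_validity(rec_lin).loc[0, "rho"]
        rho_cub = anchor_validity(rec_cub).loc[0, "rho"]
        assert rho_lin == pytest.approx(rho_cub)


class TestScaleSpec:
    def test_band_labels(self):
        assert PHQ9.band_label(12) == "Moderate"
        assert PHQ9.band_label(0) == ""
        assert GAD7.band_label(21) == "Severe"

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValidationError):
            ScaleSpec("bad", 0, 10, severity_bands=(("A", 5), ("B", 3)))
        with pytest.raises(ValidationError):
            ScaleSpec("bad", 10, 10)

    def test_record_change_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="change"):
            ObservationRecord(
                patient_id="p",
                study_id="s",
                interval_index=1,
                scale=PHQ9,
                baseline_score=10,
                followup_score=8,
                change=3,
                grc_raw="x",
                grc_binary=BETTER,
            )
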