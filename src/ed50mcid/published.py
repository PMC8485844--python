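"""Published group-level change summaries from the PANDA trial.

Per-interval mean (SD) change in PHQ-9 and GAD-7 scores for patients
reporting *feeling slightly better* vs *feeling about the same* on the
Global Rating of Change, as reported for the PANDA primary-care trial
(sertraline vs placebo; 5-level GRC).  Individual-level data are not
publicly deposited; these group summaries are the inputs the traditional
crude/standardized mean-difference comparator works from.
"""

from __future__ import annotations

from ed50mcid.smd_comparator import GroupChangeSummary

__all__ = ["PANDA_SLIGHTLY_BETTER_VS_SAME"]


def _pair(scale, interval, better_n, better_mean, better_sd, same_n, same_mean, same_sd):
    better = GroupChangeSummary(
        scale=scale,
        study_id="PANDA",
        interval_index=interval,
        grc="I feel slightly better",
        n=better_n,
        mean_change=better_mean,
        sd_change=better_sd,
    )
    same = GroupChangeSummary(
        scale=scale,
        study_id="PANDA",
        interval_index=interval,
        grc="I feel about the same",
        n=same_n,
        mean_change=same_mean,
        sd_change=same_sd,
    )
    return better, same


#: (slightly better, about the same) summary pairs per scale and interval.
PANDA_SLIGHTLY_BETTER_VS_SAME: tuple[tuple[GroupChangeSummary, GroupChangeSummary], ...] = (
    _pair("PHQ9", 1, 164, 3.57, 4.52, 291, 0.95, 3.62),
    _pair("PHQ9", 2, 168, 2.70, 4.46, 172, 0.42, 3.35),
    _pair("PHQ9", 3, 143, 2.10, 3.55, 174, 0.22, 3.24),
    _pair("GAD7", 1, 163, 2.96, 4.55, 292, 0.59, 3.62),
    _pair("GAD7", 2, 166, 2.28, 3.69, 171, 0.58, 3.61),
    _pair("GAD7", 3, 143, 1.69, 3.71, 172, -0.01, 3.01),
)
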