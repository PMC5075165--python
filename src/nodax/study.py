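"""Reference cohort counts from the motivating axillary-LN PDUS study.

The package was designed around a published proof-of-concept study of 40
csDMARD-refractory RA patients and 20 healthy controls undergoing parallel
power-Doppler ultrasound of the hand/wrist joints and axillary lymph nodes,
with a 24-week follow-up on TNF-inhibitor treatment. Individual-level data
were not deposited; what is reproducible from the publication are the raw
counts below and the percentages they imply. They are kept here as reference
inputs for consistency checks and for anchoring the synthetic-cohort
generator's marginals.

Each entry maps a short name to ``(numerator, denominator)``.
"""

from __future__ import annotations

__all__ = ["STUDY_COUNTS", "percentage", "study_percentages"]

STUDY_COUNTS: dict[str, tuple[int, int]] = {
    # palpable axillary LNs on physical examination
    "palpable_ln_ra": (9, 40),
    "palpable_ln_control": (3, 20),
    # at least one LN measurable by ultrasound on the same day
    "measurable_ln_ra": (36, 40),
    "measurable_ln_control": (17, 20),
    # RA subgroup with any LN parameter exceeding the control-derived threshold
    "ln_abnormal_ra": (16, 40),
    # RA patients with active (PD+) synovitis at baseline
    "pd_synovitis_ra": (25, 40),
    # good EULAR responders at week 24 among patients with outcome labels
    "good_eular_response": (17, 31),
    # DAS28 remission among good responders
    "remission_among_good": (11, 17),
    # moderate-to-high joint PD (pd12 >= 4) patients with LN parameters
    # strictly below the normality cutoff
    "ln_normal_among_high_joint_pd": (6, 14),
}


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """Percentage implied by a count, rounded to the printed precision."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must lie in 0..denominator")
    return round(100.0 * numerator / denominator, ndigits)


def study_percentages(ndigits: int = 1) -> dict[str, float]:
    """All study proportions recomputed from the raw counts."""
    return {k: percentage(n, d, ndigits) for k, (n, d) in STUDY_COUNTS.items()}
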