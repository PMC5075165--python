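"""Clinical composite scores and treatment-response classification.

Implements the four-variable DAS28-ESR disease activity score,

    DAS28 = 0.56*sqrt(TJC28) + 0.28*sqrt(SJC28) + 0.70*ln(ESR) + 0.014*VAS,

with TJC28/SJC28 the 28-joint tender and swollen counts, ESR the erythrocyte
sedimentation rate (mm/1h) and VAS the patient's global assessment (0-100 mm),
and the EULAR response classification from baseline and follow-up DAS28:
good response requires follow-up DAS28 ≤ 3.2 *and* an improvement > 1.2;
no response is improvement ≤ 0.6, or ≤ 1.2 with follow-up DAS28 > 5.1;
everything else is a moderate response. Remission is follow-up DAS28 < 2.6.
For outcome analyses the label is collapsed to good vs moderate/non-responder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClinicalValidationError", "ResponseLabel", "das28_esr", "eular_response"]


class ClinicalValidationError(ValueError):
    """A clinical measurement is outside its admissible range."""


@dataclass(frozen=True)
class ResponseLabel:
    category: str  # good | moderate | none
    collapsed: str  # good | moderate/non-responder
    remission: bool


def das28_esr(tjc28, sjc28, esr_mm_h, vas_ptga_mm):
    """Four-variable DAS28-ESR. Accepts scalars or numpy arrays."""
    tjc = np.asarray(tjc28, dtype=float)
    sjc = np.asarray(sjc28, dtype=float)
    esr = np.asarray(esr_mm_h, dtype=float)
    vas = np.asarray(vas_ptga_mm, dtype=float)
    if np.any((tjc < 0) | (tjc > 28)) or np.any((sjc < 0) | (sjc > 28)):
        raise ClinicalValidationError("joint counts must lie in 0..28")
    if np.any(~(esr > 0)):
        raise ClinicalValidationError("esr_mm_h must be > 0")
    if np.any((vas < 0) | (vas > 100)):
        raise ClinicalValidationError("vas_ptga_mm must lie in 0..100")
    score = 0.56 * np.sqrt(tjc) + 0.28 * np.sqrt(sjc) + 0.70 * np.log(esr) + 0.014 * vas
    if np.ndim(score) == 0:
        return float(score)
    return score


def eular_response(das28_baseline: float, das28_followup: float) -> ResponseLabel:
    """EULAR response category from baseline and follow-up DAS28."""
    if das28_baseline is None or das28_followup is None:
        raise ClinicalValidationError("both baseline and follow-up DAS28 are required")
    baseline = float(das28_baseline)
    followup = float(das28_followup)
    if not (np.isfinite(baseline) and np.isfinite(followup)):
        raise ClinicalValidationError("DAS28 scores must be finite")
    improvement = baseline - followup
    if followup <= 3.2 and improvement > 1.2:
        category = "good"
    elif improvement <= 0.6 or (improvement <= 1.2 and followup > 5.1):
        category = "none"
    else:
        category = "moderate"
    return ResponseLabel(
        category=category,
        collapsed="good" if category == "good" else "moderate/non-responder",
        remission=followup < 2.6,
    )
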