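"""Inter- and intra-rater reliability of ordinal 0-3 gradings.

Two raters (or two sessions of the same rater) grade the same items on the
fixed four-point scale. Agreement is summarized by exact agreement (percent
identical) and by weighted kappa,

    kappa_w = 1 - sum(w_ij * O_ij) / sum(w_ij * E_ij),

where ``O`` is the observed joint proportion table, ``E`` the
chance-expected table from the marginal products, and ``w_ij`` disagreement
weights: ``|i-j|/(k-1)`` (linear, the default for short ordinal clinical
scales) or its square (quadratic). Marginals are always taken over the full
0-3 category set even when some grades are unobserved. When the
chance-corrected denominator is zero (e.g. both raters constant) kappa is
*undefined* and reported as such rather than as a silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ReliabilityError",
    "UndefinedKappaError",
    "RatingPair",
    "ReliabilityResult",
    "N_CATEGORIES",
    "exact_agreement",
    "contingency_table",
    "weighted_kappa",
    "kappa_from_table",
    "rescore_protocol",
]

N_CATEGORIES = 4  # the fixed 0-3 grade scale
_CATS = np.arange(N_CATEGORIES)
_LINEAR_W = np.abs(_CATS[:, None] - _CATS[None, :]) / (N_CATEGORIES - 1)
_WEIGHTS = {"linear": _LINEAR_W, "quadratic": _LINEAR_W**2}


class ReliabilityError(ValueError):
    """Invalid rating input."""


class UndefinedKappaError(ReliabilityError):
    """Chance-corrected denominator is zero; kappa has no defined value."""


@dataclass(frozen=True)
class RatingPair:
    item_id: object
    rater_a_grade: int
    rater_b_grade: int

    def __post_init__(self) -> None:
        for name in ("rater_a_grade", "rater_b_grade"):
            g = getattr(self, name)
            if int(g) != g or not (0 <= g < N_CATEGORIES):
                raise ReliabilityError(f"{name} must be an integer in 0..3, got {g!r}")


@dataclass(frozen=True)
class ReliabilityResult:
    n_items: int
    exact_agreement_pct: float
    weighted_kappa: Optional[float]
    weight_scheme: str
    kappa_undefined_reason: Optional[str] = None


def _grades(pairs: Iterable) -> Tuple[np.ndarray, np.ndarray]:
    a, b = [], []
    for p in pairs:
        if isinstance(p, RatingPair):
            a.append(p.rater_a_grade)
            b.append(p.rater_b_grade)
        else:
            ga, gb = p
            RatingPair(None, ga, gb)  # validation
            a.append(ga)
            b.append(gb)
    return np.asarray(a, dtype=int), np.asarray(b, dtype=int)


def exact_agreement(pairs: Sequence) -> float:
    """Percent of items graded identically by the two raters (0-100)."""
    a, b = _grades(pairs)
    if a.size == 0:
        raise ReliabilityError("exact_agreement requires at least one pair")
    return float(100.0 * np.mean(a == b))


def contingency_table(pairs: Sequence) -> np.ndarray:
    """4x4 count table over the full grade scale (rows rater A, columns rater B)."""
    a, b = _grades(pairs)
    table = np.zeros((N_CATEGORIES, N_CATEGORIES), dtype=int)
    np.add.at(table, (a, b), 1)
    return table


def kappa_from_table(table: np.ndarray, weight_scheme: str = "linear") -> float:
    """Weighted kappa from an explicit 4x4 contingency table of counts."""
    if weight_scheme not in _WEIGHTS:
        raise ReliabilityError(f"weight_scheme must be linear|quadratic, got {weight_scheme!r}")
    t = np.asarray(table, dtype=float)
    if t.shape != (N_CATEGORIES, N_CATEGORIES) or np.any(t < 0):
        raise ReliabilityError("table must be a nonnegative 4x4 count table")
    n = t.sum()
    if n < 2:
        raise ReliabilityError("weighted kappa requires at least two rated items")
    w = _WEIGHTS[weight_scheme]
    obs = t / n
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    de = float((w * expected).sum())
    if de == 0.0:
        raise UndefinedKappaError(
            "chance-expected weighted disagreement is zero (degenerate marginals)"
        )
    return float(1.0 - (w * obs).sum() / de)


def weighted_kappa(pairs: Sequence, weight_scheme: str = "linear") -> float:
    """Weighted kappa between two raters' 0-3 grades of the same items.

    Requires at least two pairs and at least two distinct categories overall.
    Raises :class:`UndefinedKappaError` when the chance-corrected denominator
    is zero.
    """
    a, b = _grades(pairs)
    if a.size < 2:
        raise ReliabilityError("weighted kappa requires at least two pairs")
    if np.unique(np.concatenate([a, b])).size < 2:
        raise UndefinedKappaError(
            "only one grade category observed across both raters"
        )
    return kappa_from_table(contingency_table(pairs), weight_scheme)


def rescore_protocol(
    grades_t1: Dict[object, int],
    grades_t2: Dict[object, int],
    weight_scheme: str = "linear",
) -> ReliabilityResult:
    """Reliability of a blinded rescoring exercise on the same item set.

    ``grades_t1`` / ``grades_t2`` map item id to grade for the two sessions
    (or the two raters). Item sets must match exactly; a mismatch raises with
    the symmetric difference listed.
    """
    missing_t2 = sorted(set(grades_t1) - set(grades_t2), key=repr)
    missing_t1 = sorted(set(grades_t2) - set(grades_t1), key=repr)
    if missing_t1 or missing_t2:
        raise ReliabilityError(
            "item sets differ between sessions: "
            f"only in session 1: {missing_t2}; only in session 2: {missing_t1}"
        )
    pairs = [RatingPair(item, grades_t1[item], grades_t2[item]) for item in grades_t1]
    if not pairs:
        raise ReliabilityError("no items to compare")
    agreement = exact_agreement(pairs)
    try:
        kappa: Optional[float] = weighted_kappa(pairs, weight_scheme)
        reason = None
    except UndefinedKappaError as exc:
        kappa, reason = None, str(exc)
    return ReliabilityResult(
        n_items=len(pairs),
        exact_agreement_pct=agreement,
        weighted_kappa=kappa,
        weight_scheme=weight_scheme,
        kappa_undefined_reason=reason,
    )
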