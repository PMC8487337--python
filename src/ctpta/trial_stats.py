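"""Clinical-outcome statistics for the renal-subgroup comparison.

Covers the Cockcroft–Gault creatinine-clearance estimate (sex-specific, actual
body weight), renal categorization (normal 80–130 mL/min vs augmented renal
clearance > 130 mL/min), Wilson score intervals for single proportions, the
Newcombe method-10 interval for a difference of two independent proportions,
and inversion of printed 1-decimal percentages back to integer counts.

The Newcombe difference interval combines the two Wilson intervals
(l_i, u_i) around the point difference d = p1 − p2:

    [d − √((p1−l1)² + (u2−p2)²),  d + √((u1−p1)² + (p2−l2)²)]

Displayed values are percentage points rounded half-away-from-zero to one
decimal, matching clinical-trial reporting conventions; unrounded values are
retained on the objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import norm

from ._errors import AmbiguityError, InconsistencyError, InputError, ParameterError

__all__ = [
    "ProportionComparison",
    "RenalCategory",
    "cockcroft_gault",
    "categorize_renal",
    "wilson_interval",
    "newcombe_diff_ci",
    "recover_count",
    "round_half_away",
    "build_outcome_table",
]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (0.15 → 0.2, −0.15 → −0.2)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RenalCategory:
    """normal: CrCl in [80, 130]; ARC: CrCl > 130; other: CrCl < 80 (excluded)."""

    label: str


NORMAL = RenalCategory("normal")
ARC = RenalCategory("ARC")
OTHER = RenalCategory("other")


@dataclass(frozen=True)
class ProportionComparison:
    """Two-group binary-outcome comparison with Newcombe 95 % CI.

    ``diff_pp`` and the CI bounds are unrounded percentage points for
    group 1 minus group 2; ``direction`` documents which groups those are.
    """

    label: str
    x1: int
    n1: int
    x2: int
    n2: int
    direction: str
    diff_pp: float
    ci_low_pp: float
    ci_high_pp: float
    alpha: float = 0.05

    @property
    def display(self) -> tuple[float, float, float]:
        """(diff, low, high) rounded half-away-from-zero to 1 decimal place."""
        return (
            round_half_away(self.diff_pp),
            round_half_away(self.ci_low_pp),
            round_half_away(self.ci_high_pp),
        )


def cockcroft_gault(age: float, weight: float, scr: float, sex: str) -> float:
    """Creatinine clearance (mL/min) by Cockcroft–Gault with actual body weight.

    CrCl = (140 − age)·weight / (72·SCr), ×0.85 for females; age in years,
    weight in kg, serum creatinine in mg/dL.
    """
    if scr <= 0:
        raise InputError(f"serum creatinine must be positive, got {scr}")
    if weight <= 0:
        raise InputError(f"weight must be positive, got {weight}")
    if age < 18:
        raise InputError(f"adult formula requires age >= 18, got {age}")
    if age >= 140:
        raise ParameterError(f"age {age} outside the formula's domain (< 140)")
    sex_l = sex.lower()
    if sex_l not in ("male", "female", "m", "f"):
        raise InputError(f"sex must be male/female, got {sex!r}")
    crcl = (140.0 - age) * weight / (72.0 * scr)
    if sex_l in ("female", "f"):
        crcl *= 0.85
    return crcl


def categorize_renal(crcl: float) -> RenalCategory:
    """Classify CrCl: [80, 130] normal, (130, ∞) ARC, [0, 80) other."""
    if crcl < 0:
        raise InputError(f"CrCl must be non-negative, got {crcl}")
    if crcl > 130.0:
        return ARC
    if crcl >= 80.0:
        return NORMAL
    return OTHER


def wilson_interval(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    if not 0 <= x <= n:
        raise InputError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not 0 < alpha < 1:
        raise InputError(f"alpha must lie in (0, 1), got {alpha}")
    z = norm.ppf(1.0 - alpha / 2.0)
    p = x / n
    denom = 1.0 + z * z / n
    center = (p + z * z / (2.0 * n)) / denom
    half = z * np.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n)) / denom
    # endpoints are exactly 0/1 at the boundary counts; avoid round-off residue
    lo = 0.0 if x == 0 else max(0.0, center - half)
    hi = 1.0 if x == n else min(1.0, center + half)
    return (lo, hi)


def newcombe_diff_ci(
    x1: int,
    n1: int,
    x2: int,
    n2: int,
    alpha: float = 0.05,
    label: str = "",
    direction: str = "g1_minus_g2",
) -> ProportionComparison:
    """Newcombe method-10 CI for p1 − p2 from two independent binomials."""
    l1, u1 = wilson_interval(x1, n1, alpha)  # validates counts
    l2, u2 = wilson_interval(x2, n2, alpha)
    p1, p2 = x1 / n1, x2 / n2
    d = p1 - p2
    lo = d - np.sqrt((p1 - l1) ** 2 + (u2 - p2) ** 2)
    hi = d + np.sqrt((u1 - p1) ** 2 + (p2 - l2) ** 2)
    return ProportionComparison(
        label=label,
        x1=x1,
        n1=n1,
        x2=x2,
        n2=n2,
        direction=direction,
        diff_pp=100.0 * d,
        ci_low_pp=100.0 * lo,
        ci_high_pp=100.0 * hi,
        alpha=alpha,
    )


def recover_count(rate_pct: float, n: int) -> int:
    """Invert a printed 1-dp percentage to the unique consistent integer count.

    Raises if no count in [0, n] rounds to ``rate_pct``, or if several do.
    """
    if n < 1:
        raise InputError(f"n must be >= 1, got {n}")
    if not 0 <= rate_pct <= 100:
        raise InputError(f"rate_pct must lie in [0, 100], got {rate_pct}")
    target = round_half_away(rate_pct, 1)
    candidates = [x for x in range(n + 1) if round_half_away(100.0 * x / n, 1) == target]
    if not candidates:
        raise InconsistencyError(f"no count x in [0, {n}] prints as {target}%")
    if len(candidates) > 1:
        raise AmbiguityError(
            f"{target}% of {n} is consistent with several counts: {candidates}"
        )
    return candidates[0]


def build_outcome_table(
    rows: list[dict],
    alpha: float = 0.05,
) -> list[ProportionComparison]:
    """One Newcombe comparison per input row.

    Each row needs keys ``label, x1, n1, x2, n2, direction``; ``direction``
    is a human-readable statement of what group 1 minus group 2 means (for
    example ``"ARC_minus_normal"``).  Rows with an empty group are skipped.
    """
    out = []
    for i, row in enumerate(rows):
        try:
            x1, n1, x2, n2 = (int(row[k]) for k in ("x1", "n1", "x2", "n2"))
        except KeyError as exc:
            raise InputError(f"row {i}: missing column {exc}") from None
        if n1 == 0 or n2 == 0:
            continue
        if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
            raise InputError(f"row {i} ({row.get('label')}): counts exceed group size")
        out.append(
            newcombe_diff_ci(
                x1,
                n1,
                x2,
                n2,
                alpha=alpha,
                label=str(row.get("label", f"row{i}")),
                direction=str(row.get("direction", "g1_minus_g2")),
            )
        )
    return out
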