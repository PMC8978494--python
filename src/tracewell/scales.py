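"""Scoring, normalization and discretization of the two well-being scales.

SWLS (Satisfaction with Life Scale) totals range over 5-35 and WHO-5
(WHO Well-Being Index) totals over 5-30.  Both are mapped onto [0, 1] by
subtracting the common shift of 5 and dividing by the scale-specific span
(30 for SWLS, 25 for WHO-5).  Normalized WHO-5 scores are further
discretized into risk classes at configurable cutoffs; the defaults are the
validated binary cutoff 0.51 and the trinary cutoffs (0.35, 0.59).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScaleSpec",
    "SWLS",
    "WHO5",
    "CutoffSet",
    "BINARY_DEFAULT",
    "TRINARY_DEFAULT",
    "normalize_score",
    "cronbach_alpha",
    "assign_class",
    "round4",
]


@dataclass(frozen=True)
class ScaleSpec:
    """Endpoints and affine normalization constants of a well-being scale."""

    name: str
    raw_min: float
    raw_max: float
    shift: float
    divisor: float

    def __post_init__(self) -> None:
        if self.divisor <= 0:
            raise ValueError(f"divisor must be positive, got {self.divisor}")
        # the affine map must send the endpoints to exactly 0 and 1
        if not np.isclose((self.raw_min - self.shift) / self.divisor, 0.0):
            raise ValueError(f"{self.name}: raw_min does not normalize to 0")
        if not np.isclose((self.raw_max - self.shift) / self.divisor, 1.0):
            raise ValueError(f"{self.name}: raw_max does not normalize to 1")


#: Satisfaction with Life Scale, 5 items scored 1-7.
SWLS = ScaleSpec("SWLS", raw_min=5, raw_max=35, shift=5, divisor=30)
#: WHO-5 Well-Being Index with totals coded on a 5-30 range.
WHO5 = ScaleSpec("WHO5", raw_min=5, raw_max=30, shift=5, divisor=25)


def normalize_score(spec: ScaleSpec, raw):
    """Map a raw scale total onto [0, 1] via ``(raw - shift) / divisor``.

    Accepts scalars or array-likes.  Raises :class:`ValueError` when any
    value lies outside ``[raw_min, raw_max]``.
    """
    arr = np.asarray(raw, dtype=float)
    if np.any(arr < spec.raw_min) or np.any(arr > spec.raw_max):
        raise ValueError(
            f"{spec.name} raw score outside [{spec.raw_min}, {spec.raw_max}]"
        )
    out = (arr - spec.shift) / spec.divisor
    return float(out) if np.isscalar(raw) else out


def round4(x) -> float:
    """Round half-even to 4 decimals, the precision used for reported stats."""
    return float(np.round(x, 4))


def cronbach_alpha(item_scores) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    ``alpha = k/(k-1) * (1 - sum(item variances) / variance(total score))``
    with unbiased (ddof=1) variances over users (rows) x items (columns).
    """
    items = np.asarray(item_scores, dtype=float)
    if items.ndim != 2:
        raise ValueError("item_scores must be a 2-D users x items table")
    n, k = items.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 items and 2 users")
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    item_var = items.var(axis=0, ddof=1).sum()
    return k / (k - 1) * (1.0 - item_var / total_var)


@dataclass(frozen=True)
class CutoffSet:
    """One (binary) or two ascending (trinary) cutoffs on the [0, 1] scale."""

    mode: str  # "binary" | "trinary"
    cutoffs: tuple

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "trinary"):
            raise ValueError(f"unknown mode {self.mode!r}")
        expected = 1 if self.mode == "binary" else 2
        if len(self.cutoffs) != expected:
            raise ValueError(f"{self.mode} mode needs {expected} cutoff(s)")
        cs = list(self.cutoffs)
        if any(not (0.0 < c < 1.0) for c in cs):
            raise ValueError("cutoffs must lie strictly inside (0, 1)")
        if cs != sorted(cs) or len(set(cs)) != len(cs):
            raise ValueError("cutoffs must be strictly ascending")


BINARY_DEFAULT = CutoffSet("binary", (0.51,))
TRINARY_DEFAULT = CutoffSet("trinary", (0.35, 0.59))


def assign_class(norm_score: float, cutoffs: CutoffSet = BINARY_DEFAULT) -> str:
    """Assign a normalized score to a well-being class.

    Boundary convention: a score equal to a cutoff belongs to the upper
    class (``score >= cutoff -> upper``).  Binary classes are
    ``{"low", "high"}``, trinary ``{"low", "medium", "high"}``.
    """
    if not 0.0 <= norm_score <= 1.0:
        raise ValueError("normalized score must lie in [0, 1]")
    if cutoffs.mode == "binary":
        return "low" if norm_score < cutoffs.cutoffs[0] else "high"
    lower, upper = cutoffs.cutoffs
    if norm_score < lower:
        return "low"
    if norm_score >= upper:
        return "high"
    return "medium"
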