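"""Per-report warning signal lambda = (lambda_s, lambda_t).

The signal compares the model's causality assessment Y with a recorded human
assessment Y0 (by default the reporter-institute assessment) and weights the
comparison by event severity:

* ``d`` encodes agreement: with the "possible" midpoint 3 as pivot,
  d = |Y - Y0| when both assessments fall on the same side of 3 (agreement,
  positive), d = Y + Y0 - 6 when either equals 3, and d = -|Y - Y0| when
  they fall on opposite sides (disagreement, negative).
* ``r`` is the severity weight: 1 for a normal ADE, 4 for a serious one, so
  serious-report scores never overlap normal-report scores.
* ``s`` combines them.  Two published variants of the combining formula are
  shipped because they disagree on negative d:

  - ``eq8_literal``: s = r * (d + 1) for every d (the formula as printed);
  - ``table3_consistent`` (default): s = r * (d + 1) for d >= 0 but
    s = r * d for d < 0 — the only reading that reproduces the published
    worked examples (s = -12 for (Y, Y0) = (4, 1) serious, s = -16 for
    (5, 1) serious) and the stated serious-side extreme of +/-16.

* ``t = Y - Y0`` is the raw signed difference.

A missing assessment (code -1) yields an undefined signal rather than an
error; undefined signals are excluded from triage filters by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

__all__ = [
    "VARIANTS",
    "DEFAULT_VARIANT",
    "WarningSignal",
    "compute_d",
    "compute_r",
    "compute_s",
    "compute_t",
    "compute_signal",
    "attainable_values",
]

VARIANTS = ("eq8_literal", "table3_consistent")
DEFAULT_VARIANT = "table3_consistent"
_MISSING = -1
_LEVELS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class WarningSignal:
    """The tuple (s, t) with its intermediates; ``defined`` is False when
    either assessment is missing, in which case all components are None."""

    s: int | None
    t: int | None
    d: int | None
    r: int
    variant: str
    y: int
    y0: int
    y0_source: str = "ri_assess"

    @property
    def defined(self) -> bool:
        return self.s is not None


def _check_level(value: int, name: str) -> None:
    if value not in _LEVELS:
        raise ValueError(f"{name} must lie in 1..5, got {value}")


def compute_d(y: int, y0: int) -> int:
    """Agreement score pivoting on the midpoint category 3."""
    _check_level(y, "y")
    _check_level(y0, "y0")
    side = (y - 3) * (y0 - 3)
    if side > 0:
        return abs(y - y0)
    if side == 0:
        return y + y0 - 6
    return -abs(y - y0)


def compute_r(serious: bool) -> int:
    """Severity weight: 1 for a normal ADE, 4 for a serious ADE."""
    return 4 if serious else 1


def compute_s(d: int, r: int, variant: str = DEFAULT_VARIANT) -> int:
    if variant == "eq8_literal":
        return r * (d + 1)
    if variant == "table3_consistent":
        return r * (d + 1) if d >= 0 else r * d
    raise ValueError(f"unknown signal variant {variant!r}")


def compute_t(y: int, y0: int) -> int:
    """Raw signed difference Y - Y0."""
    _check_level(y, "y")
    _check_level(y0, "y0")
    return y - y0


def compute_signal(
    y: int,
    y0: int,
    serious: bool,
    variant: str = DEFAULT_VARIANT,
    y0_source: str = "ri_assess",
) -> WarningSignal:
    """Compose d, r, s and t into the full signal.

    Returns an undefined signal (all components None) when either assessment
    carries the missing code -1.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown signal variant {variant!r}")
    r = compute_r(serious)
    if y == _MISSING or y0 == _MISSING:
        return WarningSignal(None, None, None, r, variant, y, y0, y0_source)
    d = compute_d(y, y0)
    return WarningSignal(
        compute_s(d, r, variant), compute_t(y, y0), d, r, variant, y, y0, y0_source
    )


def attainable_values(variant: str = DEFAULT_VARIANT, serious: bool = False) -> frozenset[int]:
    """Exact set of s over all 25 assessment pairs (Y, Y0) in {1..5}^2."""
    r = compute_r(serious)
    return frozenset(
        compute_s(compute_d(y, y0), r, variant) for y, y0 in product(_LEVELS, _LEVELS)
    )
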