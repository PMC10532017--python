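"""Funneling slice selection.

Edge slices of a lesion's slice range carry loose bounding boxes: the single
annotation rectangle is sized for the central cross-section, while the lesion
shrinks toward the range extremities, so most of the box there is background.
Training a detector on those slices injects label noise.

The funneling rule keeps

    n_keep = ceil(n_total * a * ln(b))

central slices of an ``n_total``-slice lesion and removes the rest from the
two ends.  With the default coefficients ``a = 0.75`` and ``b = 1.9625`` the
asymptotic keep fraction is ``a * ln(b) ~= 0.5057``: large lesions lose about
half their slices, while the ceiling protects small ones (a 2-slice lesion
keeps both slices).  When the removal total is odd, the extra slice comes off
the end of the range (floor at the start, ceil at the end).

Selection applies to training patients only; test patients keep every slice
so a detector can be scored on the whole stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .types import Annotation3D

__all__ = [
    "FunnelParams",
    "SelectionResult",
    "funnel_keep_count",
    "removal_counts",
    "select_training_slices",
    "funnel_table",
]


@dataclass(frozen=True)
class FunnelParams:
    """Coefficients of the funneling rule; defaults are the validated ones.

    Both are heuristic dials: ``a`` scales the keep fraction linearly and
    ``b`` feeds the logarithm.  The product ``a * ln(b)`` is the asymptotic
    keep fraction and must stay in (0, 1].
    """

    a: float = 0.75
    b: float = 1.9625

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        if self.b <= 1:
            raise ValueError(f"b must be > 1 so ln(b) > 0, got {self.b}")
        if self.keep_fraction > 1:
            raise ValueError(
                f"a*ln(b) = {self.keep_fraction:.4f} > 1 would keep more "
                "slices than exist"
            )

    @property
    def keep_fraction(self) -> float:
        return self.a * math.log(self.b)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of funneling one lesion's slice range."""

    n_total: int
    n_keep: int
    remove_start: int
    remove_end: int
    kept_start: int  # first kept slice index (inclusive)
    kept_end: int    # last kept slice index (inclusive)

    @property
    def kept_range(self) -> range:
        return range(self.kept_start, self.kept_end + 1)


def funnel_keep_count(n_total: int, params: FunnelParams | None = None) -> int:
    """Number of central slices to keep for an ``n_total``-slice lesion.

    ``ceil(n_total * a * ln(b))`` — the ceiling guarantees at least one kept
    slice and spares small lesions (n_total=2 keeps 2).
    """
    params = params or FunnelParams()
    if n_total < 1:
        raise ValueError(f"n_total must be >= 1, got {n_total}")
    return math.ceil(n_total * params.keep_fraction)


def removal_counts(
    n_total: int, params: FunnelParams | None = None
) -> tuple[int, int]:
    """Slices to drop from the start and from the end of the lesion range.

    The removal total ``R = n_total - funnel_keep_count(n_total)`` is split
    as ``(floor(R/2), ceil(R/2))``: an odd remainder removes one extra slice
    from the end.
    """
    n_keep = funnel_keep_count(n_total, params)
    r = n_total - n_keep
    return r // 2, r - r // 2


def select_training_slices(
    annotation: Annotation3D, params: FunnelParams | None = None
) -> SelectionResult:
    """Apply funneling to one annotation, returning the kept contiguous range."""
    n_total = annotation.n_slices
    n_keep = funnel_keep_count(n_total, params)
    rs, re = removal_counts(n_total, params)
    return SelectionResult(
        n_total=n_total,
        n_keep=n_keep,
        remove_start=rs,
        remove_end=re,
        kept_start=annotation.slice_start + rs,
        kept_end=annotation.slice_end - re,
    )


def funnel_table(
    n_max: int, params: FunnelParams | None = None
) -> list[dict[str, int]]:
    """Audit table of the funneling rule for every lesion size 1..n_max."""
    rows = []
    for n in range(1, n_max + 1):
        rs, re = removal_counts(n, params)
        rows.append(
            {
                "n_total": n,
                "n_remove": rs + re,
                "remove_start": rs,
                "remove_end": re,
                "n_keep": funnel_keep_count(n, params),
            }
        )
    return rows
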