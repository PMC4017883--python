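"""Minimum trapping effort (MTE).

The MTE is the smallest sampling effort at which the expected species
count reaches a target proportion p_s of the species pool S_max:
invert the rarefaction curve at f(D) = p_s * S_max.  Effort is measured
in monitoring days (one calendar day of the whole array) and converted
to camera days by multiplying by the number of simultaneously active
cameras.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .events import IncidenceMatrix
from .richness import chao_richness, rarefy_exact

__all__ = [
    "MTEResult",
    "InsufficientSurveyError",
    "common_species_proportion",
    "invert_curve",
    "minimum_trapping_effort",
    "mte",
]


class InsufficientSurveyError(ValueError):
    """The survey is too short for the target species count to be reached."""


@dataclass
class MTEResult:
    """Minimum trapping effort at a target proportion of the species pool.

    ``monitoring_days`` is the smallest integer effort d with
    E[S(d)] >= ``target_s`` = p_s * S_max, on the continuous expected-
    richness scale (no rounding of the target).  ``camera_days`` is
    ``monitoring_days * n_cameras``.
    """

    p_s: float
    s_max: float
    target_s: float
    monitoring_days: int
    camera_days: int
    n_cameras: int

    def __post_init__(self) -> None:
        if self.camera_days != self.monitoring_days * self.n_cameras:
            raise ValueError("camera_days must equal monitoring_days * n_cameras")


def common_species_proportion(summary: pd.DataFrame, threshold_percent: float = 1.0) -> float:
    """Proportion p_s of resident species that are common.

    A resident species is common when its share P2 of resident
    independent photographs exceeds ``threshold_percent``.  ``summary``
    is the table produced by :func:`~trapeffort.events.summarize_species`.
    """
    resident = summary.loc[summary["resident"]]
    if resident.empty:
        raise ValueError("summary contains no resident species")
    return float((resident["p2"] > threshold_percent).sum() / len(resident))


def invert_curve(curve_fn: Callable, target_s: float, max_effort: int) -> int:
    """Smallest integer effort with curve_fn(effort) >= target_s.

    ``curve_fn`` must be nondecreasing over 1..max_effort; bisection on
    that monotone curve.  An unreachable target raises
    :class:`InsufficientSurveyError` rather than clamping.
    """
    if max_effort < 1:
        raise ValueError("max_effort must be >= 1")
    if not curve_fn(max_effort) >= target_s:
        raise InsufficientSurveyError(
            f"target {target_s:.4g} not reached within {max_effort} units "
            f"(curve tops out at {curve_fn(max_effort):.4g})"
        )
    lo, hi = 1, max_effort  # invariant: curve(hi) >= target
    while lo < hi:
        mid = (lo + hi) // 2
        if curve_fn(mid) >= target_s:
            hi = mid
        else:
            lo = mid + 1
    return int(hi)


def minimum_trapping_effort(
    incidence: IncidenceMatrix,
    summary: pd.DataFrame | None = None,
    n_cameras: int = 19,
    p_s: float | None = None,
    threshold_percent: float = 1.0,
) -> MTEResult:
    """Minimum trapping effort from an incidence matrix.

    Composes the Chao species-pool estimate, the common-species
    proportion p_s (from ``summary`` unless overridden), the exact
    rarefaction curve and its inversion.  Both monitoring days and
    camera days are reported; the conversion assumes all ``n_cameras``
    cameras active on every monitoring day.
    """
    if p_s is None:
        if summary is None:
            raise ValueError("either a species summary or an explicit p_s is required")
        p_s = common_species_proportion(summary, threshold_percent)
    if not 0.0 < p_s <= 1.0:
        raise ValueError("p_s must lie in (0, 1]")
    s_max = chao_richness(incidence).s_max
    target_s = p_s * s_max
    monitoring_days = invert_curve(
        lambda d: rarefy_exact(incidence, d), target_s, incidence.n_units
    )
    return MTEResult(
        p_s=float(p_s),
        s_max=s_max,
        target_s=float(target_s),
        monitoring_days=monitoring_days,
        camera_days=monitoring_days * n_cameras,
        n_cameras=n_cameras,
    )


#: short alias used throughout the CLI
mte = minimum_trapping_effort
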