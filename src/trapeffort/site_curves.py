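"""Per-camera-site accumulation curves and the rotation criterion.

To decide how long a camera should stay at one site before being moved,
each site gets its own accumulation curve — expected cumulative species
against monitoring days at that site, or against independent
photographs (individual-based rarefaction over that site's events).
The cross-site mean curve with a 95% across-site band summarizes the
community; the rotation point is where the mean curve's rate of new
species falls and stays below an explicit threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = ["SiteCurveSet", "NoPlateauError", "per_site_curves", "optimal_period"]


class NoPlateauError(ValueError):
    """The mean curve never falls below the detection-rate threshold."""


@dataclass
class SiteCurveSet:
    """Per-site accumulation curves plus their cross-site summary.

    ``site_curves[site]`` is that site's full curve over efforts
    1..(its own maximum).  The mean curve and 2.5/97.5 percentile band
    are computed only at efforts available at at least half the sites
    (``cut_effort`` is that largest common effort); sites with zero
    events are flagged in ``zero_sites`` and carry all-zero curves.
    """

    effort_kind: str  # "days" or "photographs"
    site_curves: dict[str, np.ndarray]
    efforts: np.ndarray
    mean_curve: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    cut_effort: int
    method: str = "exact"
    zero_sites: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for site, curve in self.site_curves.items():
            rows.append(
                pd.DataFrame(
                    {"site_id": site, "effort": np.arange(1, len(curve) + 1), "mean_s": curve}
                )
            )
        return pd.concat(rows, ignore_index=True)

    def mean_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effort": self.efforts,
                "mean_s": self.mean_curve,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(k > n, -np.inf, out)


def _exact_curve(occ: np.ndarray, n_units: int) -> np.ndarray:
    """E[S(d)] for d = 1..n_units given species occurrence counts."""
    if n_units == 0:
        return np.zeros(0)
    d = np.arange(1, n_units + 1)
    log_miss = _log_choose((n_units - occ)[:, None], d[None, :]) - _log_choose(n_units, d)[None, :]
    return (1.0 - np.exp(log_miss)).sum(axis=0)


def _permutation_curve(units_species: list[set], n_permutations: int, rng) -> np.ndarray:
    """Mean cumulative richness over random orderings of units."""
    n = len(units_species)
    total = np.zeros(n)
    for _ in range(n_permutations):
        order = rng.permutation(n)
        seen: set = set()
        for j, u in enumerate(order):
            seen |= units_species[u]
            total[j] += len(seen)
    return total / n_permutations


def per_site_curves(
    events: pd.DataFrame,
    effort_kind: str = "days",
    survey_span: tuple | None = None,
    *,
    sites=None,
    method: str = "exact",
    n_permutations: int = 100,
    seed: int | None = None,
    min_site_fraction: float = 0.5,
) -> SiteCurveSet:
    """Accumulation curve for every camera site.

    For ``effort_kind="days"`` each site's curve is the exact
    sample-based rarefaction over that site's day units (the full survey
    span, zero days included).  For ``effort_kind="photographs"`` it is
    individual-based rarefaction over the site's independent events, so
    sites differ in maximum effort; the cross-site mean is cut at the
    largest effort available at at least ``min_site_fraction`` of sites.
    """
    if effort_kind not in ("days", "photographs"):
        raise ValueError("effort_kind must be 'days' or 'photographs'")
    if method not in ("exact", "permutation"):
        raise ValueError("method must be 'exact' or 'permutation'")
    site_index = sorted(set(events["site_id"]) if sites is None else set(sites))
    if not site_index:
        raise ValueError("no camera sites")
    rng = np.random.default_rng(seed)

    curves: dict[str, np.ndarray] = {}
    zero_sites: list = []
    for site in site_index:
        ev = events.loc[events["site_id"] == site]
        if ev.empty:
            zero_sites.append(site)
        if effort_kind == "days":
            if survey_span is None:
                raise ValueError("survey_span is required for day-based curves")
            start, end = (pd.Timestamp(t).normalize() for t in survey_span)
            n_units = (end - start).days + 1
            if ev.empty:
                curves[site] = np.zeros(n_units)
                continue
            day_idx = (ev["event_start"].dt.normalize() - start).dt.days
            if (day_idx < 0).any() or (day_idx >= n_units).any():
                raise ValueError("event outside the declared survey span")
            if method == "exact":
                occ = ev.groupby("species")["event_start"].apply(
                    lambda t: t.dt.normalize().nunique()
                )
                curves[site] = _exact_curve(occ.to_numpy(), n_units)
            else:
                per_day: dict[int, set] = {}
                for di, sp in zip(day_idx, ev["species"]):
                    per_day.setdefault(int(di), set()).add(sp)
                units = [per_day.get(d, set()) for d in range(n_units)]
                curves[site] = _permutation_curve(units, n_permutations, rng)
        else:
            n_units = len(ev)
            if n_units == 0:
                curves[site] = np.zeros(0)
                continue
            if method == "exact":
                occ = ev.groupby("species").size().to_numpy()
                curves[site] = _exact_curve(occ, n_units)
            else:
                units = [{sp} for sp in ev["species"]]
                curves[site] = _permutation_curve(units, n_permutations, rng)

    lengths = np.array([len(c) for c in curves.values()])
    need = int(np.ceil(min_site_fraction * len(site_index)))
    available = np.array(
        [int((lengths >= e).sum()) for e in range(1, int(lengths.max(initial=0)) + 1)]
    )
    cut = int(np.max(np.nonzero(available >= need)[0]) + 1) if (available >= need).any() else 0
    if cut == 0:
        raise ValueError("no common effort available at the requested site fraction")
    efforts = np.arange(1, cut + 1)
    stack = [np.pad(c[:cut], (0, cut - min(len(c), cut)), constant_values=np.nan) for c in curves.values()]
    arr = np.vstack(stack)
    mean_curve = np.nanmean(arr, axis=0)
    lower = np.nanpercentile(arr, 2.5, axis=0)
    upper = np.nanpercentile(arr, 97.5, axis=0)
    return SiteCurveSet(
        effort_kind=effort_kind,
        site_curves=curves,
        efforts=efforts,
        mean_curve=mean_curve,
        lower=lower,
        upper=upper,
        cut_effort=cut,
        method=method,
        zero_sites=zero_sites,
    )


def optimal_period(curves: SiteCurveSet, rate_threshold: float) -> int:
    """Rotation point: where the mean detection rate stays below threshold.

    Returns the smallest effort e such that every forward first
    difference of the mean curve from e onward is below
    ``rate_threshold`` (species per unit effort).  The threshold is
    explicit because "the rate of new species declines" is otherwise a
    visual judgment.  Raises :class:`NoPlateauError` when the rate never
    settles below the threshold within the curve's range.
    """
    if rate_threshold <= 0:
        raise ValueError("rate_threshold must be positive")
    m = np.asarray(curves.mean_curve, dtype=float)
    if m.size < 2:
        raise ValueError("mean curve too short to assess a detection rate")
    diffs = np.diff(m)
    below = diffs < rate_threshold
    if not below[-1] or not below.any():
        raise NoPlateauError(
            f"detection rate never settles below {rate_threshold} within the surveyed range"
        )
    # last index where the rate was still >= threshold; optimum is the next effort
    above = np.nonzero(~below)[0]
    j0 = int(above.max() + 1) if above.size else 0
    return int(curves.efforts[j0])
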