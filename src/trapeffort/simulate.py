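"""Synthetic camera-trap surveys with known ground truth.

The generator emulates a two-year fixed-array survey: 19 cameras
stratified over 5 habitat types running for 730 days, watching a
community of about 20 species with strongly skewed detection rates
(the three commonest species account for roughly three quarters of all
independent detections).  Independent events at each site arrive as a
Poisson count per camera-day; each event produces a burst of one or
more photographs whose internal gaps are under 30 minutes, while the
gaps between events are always over 30 minutes — so the downstream
independence filter recovers the generated event count exactly, which
is what makes every later stage testable against ground truth.

Draw order is fixed: one child seed per (species, site) pair, spawned
in species-major order from the design seed, so results are
reproducible regardless of iteration details.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["SpeciesProfile", "SurveyDesign", "default_community", "simulate_survey"]

SECONDS_PER_DAY = 86_400
#: last usable second of a day for a photograph; leaves a > 30-min gap
#: to the earliest possible photograph of the next day
DAY_CUTOFF = SECONDS_PER_DAY - 1_860
#: within-burst photo gaps are uniform on [1 s, 29 min]
MAX_BURST_GAP = 29 * 60
#: minimum separation enforced between photographs of consecutive events
EVENT_MARGIN = 1_860


@dataclass
class SpeciesProfile:
    """Detection profile of one species.

    Parameters
    ----------
    name : str
    guild : {"resident_terrestrial", "arboreal", "transient"}
    site_rates : array of float
        Expected independent events per camera-day at each site (>= 0).
    burst_mean : float
        Expected photographs per independent event (>= 1); the photo
        count per event is geometric with this mean.
    active_window : (int, int)
        Inclusive 1-based day range in which the species can be
        detected; the whole survey for residents, a short calendar
        window for transients.
    """

    name: str
    guild: str
    site_rates: np.ndarray
    burst_mean: float = 1.0
    active_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        from .events import GUILDS

        if self.guild not in GUILDS:
            raise ValueError(f"unknown guild {self.guild!r}; expected one of {GUILDS}")
        self.site_rates = np.asarray(self.site_rates, dtype=float)
        if not np.all(np.isfinite(self.site_rates)) or (self.site_rates < 0).any():
            raise ValueError(f"{self.name}: site rates must be finite and >= 0")
        if self.burst_mean < 1:
            raise ValueError(f"{self.name}: burst_mean must be >= 1")


@dataclass
class SurveyDesign:
    """Layout and duration of a simulated survey."""

    n_sites: int = 19
    n_days: int = 730
    sites_per_stratum: Sequence[int] = (7, 7, 2, 1, 2)
    seed: int | None = None
    start_date: str = "2009-06-01"

    def __post_init__(self) -> None:
        if sum(self.sites_per_stratum) != self.n_sites:
            raise ValueError(
                f"sites_per_stratum {tuple(self.sites_per_stratum)} must sum to {self.n_sites}"
            )
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")

    @property
    def site_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_sites)]


def default_community(seed: int | None, design: SurveyDesign | None = None) -> list[SpeciesProfile]:
    """A 20-species community shaped like a subtropical-forest plot.

    Ten resident terrestrial species with log-normal (strongly skewed)
    relative detection rates rescaled so the top three hold 75% of
    expected events and the total resident detection intensity is
    ~0.125 events per camera-day; seven arboreal species that only
    rarely trigger ground-level cameras; three transients detectable
    only inside a window of at most one month.  Deterministic given the
    seed.
    """
    design = design or SurveyDesign()
    rng = np.random.default_rng(seed)
    n_sites, n_days = design.n_sites, design.n_days

    # resident rate profile: log-normal shares, top-3 pinned at 75%
    shares = np.sort(rng.lognormal(mean=0.0, sigma=1.6, size=10))[::-1]
    shares /= shares.sum()
    top3 = shares[:3].sum()
    shares[:3] *= 0.75 / top3
    shares[3:] *= 0.25 / (1.0 - top3)
    total_rate = 0.125  # resident events per camera-day, community-wide

    def site_factors() -> np.ndarray:
        f = rng.lognormal(mean=0.0, sigma=0.5, size=n_sites)
        return f / f.mean()

    community: list[SpeciesProfile] = []
    for i, share in enumerate(shares):
        community.append(
            SpeciesProfile(
                name=f"resident_{i + 1:02d}",
                guild="resident_terrestrial",
                site_rates=total_rate * share * site_factors(),
                burst_mean=float(rng.uniform(1.2, 3.0)),
                active_window=(1, n_days),
            )
        )
    for i in range(7):
        community.append(
            SpeciesProfile(
                name=f"arboreal_{i + 1:02d}",
                guild="arboreal",
                site_rates=rng.uniform(1e-4, 6e-4) * site_factors(),
                burst_mean=float(rng.uniform(1.0, 1.5)),
                active_window=(1, n_days),
            )
        )
    for i in range(3):
        length = int(rng.integers(14, 32))  # at most one month
        start = int(rng.integers(1, max(2, n_days - length + 1)))
        community.append(
            SpeciesProfile(
                name=f"transient_{i + 1:02d}",
                guild="transient",
                site_rates=rng.uniform(0.002, 0.02) * site_factors(),
                burst_mean=float(rng.uniform(1.0, 2.0)),
                active_window=(start, min(start + length - 1, n_days)),
            )
        )
    return community


def _place_events(n_events: int, burst_mean: float, rng) -> list[list[int]]:
    """Photograph offsets (seconds within the day) for each event.

    The usable day is split into ``n_events`` equal segments; each
    event's burst is placed inside its segment with enough slack that
    the last photo of one event precedes the first photo of the next by
    more than 30 minutes, and never spills past 23:29 so the gap across
    midnight also exceeds 30 minutes.
    """
    # a day cannot hold more events than fit 30 min apart
    n_events = min(n_events, DAY_CUTOFF // (EVENT_MARGIN + 2))
    segment = DAY_CUTOFF / n_events
    bursts = []
    for e in range(n_events):
        n_photos = int(rng.geometric(1.0 / burst_mean))
        max_span = max(int(segment) - EVENT_MARGIN - 1, 0)
        n_photos = max(1, min(n_photos, max_span + 1))
        gaps = rng.integers(1, MAX_BURST_GAP + 1, size=n_photos - 1)
        span = int(gaps.sum())
        if span > max_span:  # shrink gaps proportionally, keeping >= 1 s
            gaps = np.maximum(1, (gaps * (max_span / span)).astype(int))
            # drop trailing photos if rounding still overflows the segment
            gaps = gaps[np.cumsum(gaps) <= max_span]
            span = int(gaps.sum())
        start = e * segment + rng.uniform(0, max(segment - span - EVENT_MARGIN, 1))
        offsets = np.concatenate([[0], np.cumsum(gaps)]) + start
        bursts.append([int(t) for t in offsets])
    return bursts


def simulate_survey(
    design: SurveyDesign, community: Sequence[SpeciesProfile]
) -> tuple[pd.DataFrame, dict]:
    """Simulate a survey; return (photo records, ground truth).

    Records carry ``site_id``, ``species``, ``timestamp`` (1-second
    resolution) sorted by site and time.  The ground truth reports the
    community richness by guild, the per-species independent-event
    counts actually generated, and the rate parameters.
    """
    if design.seed is None:
        raise ValueError("a seed is required for a reproducible survey")
    for sp in community:
        if len(sp.site_rates) != design.n_sites:
            raise ValueError(f"{sp.name}: site_rates length != n_sites")
    children = np.random.SeedSequence(design.seed).spawn(len(community) * design.n_sites)
    site_ids = design.site_ids
    start = pd.Timestamp(design.start_date)

    rows: list[tuple[str, str, int]] = []  # (site, species, seconds since start)
    event_counts = {sp.name: 0 for sp in community}
    for s_idx, sp in enumerate(community):
        lo, hi = sp.active_window or (1, design.n_days)
        if not 1 <= lo <= hi <= design.n_days:
            raise ValueError(f"{sp.name}: active_window outside [1, {design.n_days}]")
        for j, site in enumerate(site_ids):
            rate = sp.site_rates[j]
            rng = np.random.default_rng(children[s_idx * design.n_sites + j])
            if rate == 0:
                continue
            counts = rng.poisson(rate, size=hi - lo + 1)
            for day_off, c in zip(np.nonzero(counts)[0], counts[np.nonzero(counts)[0]]):
                day = lo - 1 + int(day_off)
                for burst in _place_events(int(c), sp.burst_mean, rng):
                    event_counts[sp.name] += 1
                    for t in burst:
                        rows.append((site, sp.name, day * SECONDS_PER_DAY + t))

    records = pd.DataFrame(rows, columns=["site_id", "species", "seconds"])
    records["timestamp"] = start + pd.to_timedelta(records["seconds"], unit="s")
    records = (
        records.drop(columns="seconds")
        .sort_values(["site_id", "timestamp"], kind="mergesort")
        .reset_index(drop=True)
    )
    truth = {
        "seed": design.seed,
        "n_species": len(community),
        "richness_by_guild": {
            g: sum(1 for sp in community if sp.guild == g)
            for g in sorted({sp.guild for sp in community})
        },
        "event_counts": event_counts,
        "species": {
            sp.name: {
                "guild": sp.guild,
                "mean_site_rate": float(np.mean(sp.site_rates)),
                "burst_mean": float(sp.burst_mean),
                "active_window": list(sp.active_window or (1, design.n_days)),
            }
            for sp in community
        },
    }
    return records, truth
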