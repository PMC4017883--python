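"""Sites-versus-days effort allocation by Monte Carlo resampling.

For each trapping effort (k camera sites running for w contiguous
monitoring days) the analysis draws k of the N sites uniformly without
replacement and one contiguous window of w days with uniform start,
counts the distinct species detected in that site-window block, and
averages the detected proportion of the species pool over replicates.
The resulting grid over (k, w) is the contour map used to weigh adding
sites against running cameras longer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["SiteDayOccupancy", "ContourGrid", "site_day_occupancy", "sample_effort", "contour_grid"]


@dataclass
class SiteDayOccupancy:
    """Site-resolved daily detection structure.

    ``detected[s, d, i]`` is True when species i was detected at site s
    on day d.  This is richer than a day x species matrix — the
    site-window resampling needs per-site resolution, so it must be
    built from photo records or simulation, not from a pooled daily
    matrix.
    """

    sites: pd.Index
    days: pd.Index
    species: pd.Index
    detected: np.ndarray  # (n_sites, n_days, n_species) bool

    def __post_init__(self) -> None:
        expected = (len(self.sites), len(self.days), len(self.species))
        if self.detected.shape != expected:
            raise ValueError(f"detected has shape {self.detected.shape}, expected {expected}")
        self.detected = self.detected.astype(bool)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_days(self) -> int:
        return len(self.days)

    @property
    def s_obs(self) -> int:
        return int(self.detected.any(axis=(0, 1)).sum())

    def day_matrix(self) -> pd.DataFrame:
        """Pooled day x species matrix (number of sites detecting)."""
        return pd.DataFrame(
            self.detected.sum(axis=0), index=self.days, columns=self.species
        )


def site_day_occupancy(
    events: pd.DataFrame,
    survey_span: tuple,
    sites: Iterable[str] | None = None,
) -> SiteDayOccupancy:
    """Build the site x day x species detection array from an event table."""
    start, end = (pd.Timestamp(t).normalize() for t in survey_span)
    days = pd.date_range(start, end, freq="D")
    site_index = pd.Index(
        sorted(set(events["site_id"]) if sites is None else set(sites)), name="site_id"
    )
    species = pd.Index(sorted(set(events["species"])), name="species")
    detected = np.zeros((len(site_index), len(days), len(species)), dtype=bool)
    if not events.empty:
        day_of = events["event_start"].dt.normalize()
        if (day_of < start).any() or (day_of > end).any():
            raise ValueError("event outside the declared survey span")
        s_idx = site_index.get_indexer(events["site_id"])
        if (s_idx < 0).any():
            raise ValueError("event at a site not in the declared site list")
        d_idx = (day_of - start).dt.days.to_numpy()
        i_idx = species.get_indexer(events["species"])
        detected[s_idx, d_idx, i_idx] = True
    return SiteDayOccupancy(
        sites=site_index, days=pd.Index(days.date, name="day"), species=species, detected=detected
    )


@dataclass
class ContourGrid:
    """Mean detected-species proportion over a (sites x window) grid."""

    site_counts: np.ndarray
    window_lengths: np.ndarray
    mean_proportion: np.ndarray  # (len(site_counts), len(window_lengths))
    n_replicates: int
    seed: int | None
    denominator: float

    def camera_days(self) -> np.ndarray:
        """Iso-effort annotation: k * w camera days per grid cell."""
        return np.outer(self.site_counts, self.window_lengths)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (k, w, camera_days, mean_proportion, n_reps)."""
        k, w = np.meshgrid(self.site_counts, self.window_lengths, indexing="ij")
        return pd.DataFrame(
            {
                "n_sites": k.ravel(),
                "window_days": w.ravel(),
                "camera_days": (k * w).ravel(),
                "mean_proportion": self.mean_proportion.ravel(),
                "n_replicates": self.n_replicates,
            }
        )


def _window_detection_counts(data: SiteDayOccupancy) -> np.ndarray:
    """Per-site per-species cumulative detection-day counts.

    ``cum[s, i, d]`` counts detection days of species i at site s among
    the first d days, so a window [a, b) has a detection iff
    cum[s, i, b] - cum[s, i, a] > 0.
    """
    counts = data.detected.astype(np.int32).cumsum(axis=1)
    cum = np.zeros((data.n_sites, data.detected.shape[2], data.n_days + 1), dtype=np.int32)
    cum[:, :, 1:] = counts.transpose(0, 2, 1)
    return cum


def sample_effort(
    data: SiteDayOccupancy,
    k: int,
    w: int,
    n_reps: int = 1000,
    seed=None,
    denominator: float | None = None,
    *,
    contiguous: bool = True,
    _cum: np.ndarray | None = None,
) -> float:
    """Mean proportion of the species pool detected by k sites over w days.

    Each replicate draws k sites uniformly without replacement and one
    contiguous window of w days with uniform start (with replacement
    across replicates).  ``denominator`` defaults to the observed
    richness of ``data``; pass the estimated pool S_max to standardize
    against it.  ``contiguous=False`` draws w days uniformly without
    replacement instead of a calendar block.
    """
    if not 1 <= k <= data.n_sites:
        raise ValueError(f"k must lie in [1, {data.n_sites}]")
    if not 1 <= w <= data.n_days:
        raise ValueError(f"w must lie in [1, {data.n_days}]")
    denom = float(data.s_obs if denominator is None else denominator)
    if denom <= 0:
        raise ValueError("denominator richness must be positive")
    rng = np.random.default_rng(seed)
    sites = np.array([rng.choice(data.n_sites, size=k, replace=False) for _ in range(n_reps)])
    if contiguous:
        cum = _window_detection_counts(data) if _cum is None else _cum
        starts = rng.integers(0, data.n_days - w + 1, size=n_reps)
        # (n_reps, k, n_species): detections of each species in each block
        in_window = (
            cum[sites[:, :, None], np.arange(cum.shape[1])[None, None, :], (starts + w)[:, None, None]]
            - cum[sites[:, :, None], np.arange(cum.shape[1])[None, None, :], starts[:, None, None]]
        ) > 0
    else:
        richness = np.empty(n_reps)
        for r in range(n_reps):
            day_pick = rng.choice(data.n_days, size=w, replace=False)
            block = data.detected[np.ix_(sites[r], day_pick)]
            richness[r] = block.any(axis=(0, 1)).sum()
        return float(richness.mean() / denom)
    richness = in_window.any(axis=1).sum(axis=1)
    return float(richness.mean() / denom)


def contour_grid(
    data: SiteDayOccupancy,
    site_counts: Sequence[int],
    window_lengths: Sequence[int],
    n_reps: int = 1000,
    seed: int | None = None,
    denominator: float | None = None,
) -> ContourGrid:
    """Fill the (sites x window) grid of mean detected proportions.

    Each cell gets an independent child seed spawned from ``seed`` in
    row-major (site-axis first) order, so replicate draws are
    independent across cells and the whole grid is reproducible.
    """
    site_counts = np.asarray(sorted(site_counts), dtype=int)
    window_lengths = np.asarray(sorted(window_lengths), dtype=int)
    if site_counts.size == 0 or window_lengths.size == 0:
        raise ValueError("grid axes must be nonempty")
    denom = float(data.s_obs if denominator is None else denominator)
    cum = _window_detection_counts(data)
    children = np.random.SeedSequence(seed).spawn(site_counts.size * window_lengths.size)
    grid = np.empty((site_counts.size, window_lengths.size))
    cell = 0
    for i, k in enumerate(site_counts):
        for j, w in enumerate(window_lengths):
            grid[i, j] = sample_effort(
                data, int(k), int(w), n_reps=n_reps, seed=children[cell],
                denominator=denom, _cum=cum,
            )
            cell += 1
    return ContourGrid(
        site_counts=site_counts,
        window_lengths=window_lengths,
        mean_proportion=grid,
        n_replicates=n_reps,
        seed=seed,
        denominator=denom,
    )
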