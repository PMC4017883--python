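"""Sample-based rarefaction and Chao incidence-based richness estimation.

The species–effort relationship S = f(D) is the expected number of
species found in d sampling units drawn uniformly without replacement
from the D units surveyed:

    E[S(d)] = sum_i [ 1 - C(D - D_i, d) / C(D, d) ]

where D_i is the number of units in which species i occurs.  The species
pool is extrapolated with the Chao incidence estimator

    S_max = S_obs + a1^2 / (2 a2)

with a1 and a2 the numbers of species occurring in exactly one and
exactly two units (uniques and duplicates); when a2 = 0 the
bias-corrected form S_obs + a1 (a1 - 1) / (2 (a2 + 1)) is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .events import IncidenceMatrix

__all__ = ["RarefactionCurve", "ChaoEstimate", "rarefy_exact", "rarefaction_curve", "chao_richness"]


@dataclass
class RarefactionCurve:
    """Expected species count against sampling effort, with a 95% band.

    ``efforts`` runs 1..D in sampling units.  ``expected_s`` is the mean
    species count at each effort; for ``method="exact"`` it is the
    analytic hypergeometric expectation, for ``method="permutation"``
    the mean over random unit orderings.  The band is the 2.5/97.5
    percentile of richness over permutations in either case (the
    analytic expectation has no sampling band of its own).
    """

    efforts: np.ndarray
    expected_s: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    method: str
    n_permutations: int | None = None

    def __post_init__(self) -> None:
        for name in ("efforts", "expected_s", "lower", "upper"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.efforts = self.efforts.astype(int)

    def __call__(self, d):
        """Expected species count at effort d (d may be an array)."""
        d = np.asarray(d)
        idx = np.searchsorted(self.efforts, d)
        if (idx >= len(self.efforts)).any() or (self.efforts[idx] != d).any():
            raise ValueError("effort outside the tabulated range")
        out = self.expected_s[idx]
        return float(out) if out.ndim == 0 else out


@dataclass
class ChaoEstimate:
    """Chao incidence-based species-pool estimate."""

    s_obs: int
    a1: int
    a2: int
    s_max: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.a1 < 0 or self.a2 < 0 or self.a1 + self.a2 > self.s_obs:
            raise ValueError("inconsistent unique/duplicate counts")
        if self.s_max < self.s_obs:
            raise ValueError("extrapolated richness below observed richness")


def _log_choose(n: np.ndarray, k) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(k > n, -np.inf, out)


def rarefy_exact(incidence: IncidenceMatrix, d) -> float | np.ndarray:
    """Exact expected species count in ``d`` sampling units.

    Uses the closed-form hypergeometric expectation (log-gamma
    implementation, stable for D well beyond 10^4).  ``d`` may be a
    scalar or an array of efforts; each must satisfy 1 <= d <= D.
    """
    d_arr = np.atleast_1d(np.asarray(d, dtype=int))
    D = incidence.n_units
    if D == 0:
        raise ValueError("incidence matrix has no sampling units")
    if (d_arr < 1).any() or (d_arr > D).any():
        raise ValueError(f"effort must lie in [1, {D}]")
    Di = incidence.occurrence_counts().to_numpy()
    # P(species i missed by d units) = C(D - D_i, d) / C(D, d)
    log_miss = _log_choose((D - Di)[:, None], d_arr[None, :]) - _log_choose(D, d_arr)[None, :]
    expected = (1.0 - np.exp(log_miss)).sum(axis=0)
    return float(expected[0]) if np.isscalar(d) or np.ndim(d) == 0 else expected


def _permutation_richness(
    incidence: IncidenceMatrix, n_permutations: int, seed
) -> np.ndarray:
    """Cumulative richness curves over random unit orderings.

    Returns an (n_permutations, D) array; row p column j is the number
    of distinct species in the first j+1 units of ordering p.
    """
    B = incidence.binarized()
    D = B.shape[0]
    rng = np.random.default_rng(seed)
    curves = np.empty((n_permutations, D), dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(D)
        curves[p] = np.maximum.accumulate(B[order], axis=0).sum(axis=1)
    return curves


def rarefaction_curve(
    incidence: IncidenceMatrix,
    method: str = "exact",
    n_permutations: int = 1000,
    seed: int | None = None,
    ci: float = 0.95,
) -> RarefactionCurve:
    """Full rarefaction curve over efforts 1..D.

    ``method="exact"`` uses the analytic expectation for the mean curve;
    ``method="permutation"`` uses the mean over ``n_permutations`` random
    unit orderings.  Both report a percentile band over permutations.
    """
    if method not in ("exact", "permutation"):
        raise ValueError(f"method must be 'exact' or 'permutation', got {method!r}")
    if n_permutations < 2:
        raise ValueError("n_permutations must be >= 2")
    D = incidence.n_units
    efforts = np.arange(1, D + 1)
    curves = _permutation_richness(incidence, n_permutations, seed)
    alpha = 100.0 * (1.0 - ci) / 2.0
    lower = np.percentile(curves, alpha, axis=0)
    upper = np.percentile(curves, 100.0 - alpha, axis=0)
    if method == "exact":
        expected = rarefy_exact(incidence, efforts)
    else:
        expected = curves.mean(axis=0)
    lower = np.minimum(lower, expected)
    upper = np.maximum(upper, expected)
    return RarefactionCurve(
        efforts=efforts,
        expected_s=expected,
        lower=lower,
        upper=upper,
        method=method,
        n_permutations=n_permutations,
    )


def chao_richness(incidence: IncidenceMatrix) -> ChaoEstimate:
    """Chao incidence-based estimate of the species pool.

    S_max = S_obs + a1^2 / (2 a2); when no species occurs in exactly two
    units the bias-corrected fallback S_obs + a1 (a1 - 1) / (2 (a2 + 1))
    is used and flagged.  A survey with no uniques (a1 = 0) extrapolates
    nothing: S_max = S_obs.
    """
    if incidence.n_units == 0:
        raise ValueError("incidence matrix has no sampling units")
    Di = incidence.occurrence_counts().to_numpy()
    s_obs = int((Di > 0).sum())
    a1 = int((Di == 1).sum())
    a2 = int((Di == 2).sum())
    if a1 == 0:
        s_max, corrected = float(s_obs), False
    elif a2 > 0:
        s_max, corrected = s_obs + a1 * a1 / (2.0 * a2), False
    else:
        s_max, corrected = s_obs + a1 * (a1 - 1) / (2.0 * (a2 + 1)), True
    return ChaoEstimate(s_obs=s_obs, a1=a1, a2=a2, s_max=s_max, corrected=corrected)
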