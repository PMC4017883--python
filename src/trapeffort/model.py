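"""Model/results interface for the species–effort analysis.

:class:`SpeciesAccumulationModel` wraps an incidence matrix (sampling
units x species) and, on :meth:`~SpeciesAccumulationModel.fit`, produces
a :class:`SpeciesAccumulationResults` holding the Chao species-pool
estimate, the rarefaction curve with its uncertainty band, the
common-species proportion p_s and the minimum trapping effort, plus a
``summary()`` table.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .events import IncidenceMatrix, build_incidence
from .mte import MTEResult, common_species_proportion, minimum_trapping_effort
from .richness import ChaoEstimate, RarefactionCurve, chao_richness, rarefaction_curve

__all__ = ["SpeciesAccumulationModel", "SpeciesAccumulationResults"]


class SpeciesAccumulationModel:
    """Species accumulation against trapping effort.

    Parameters
    ----------
    incidence : IncidenceMatrix
        Sampling-units x species occurrence matrix; the unit is normally
        one monitoring day of the whole camera array.
    species_summary : DataFrame, optional
        Per-species RP/IP/P1/P2 table (see
        :func:`~trapeffort.events.summarize_species`); required for
        ``p_s="auto"``.
    n_cameras : int
        Cameras active per monitoring day; converts monitoring days to
        camera days.

    Examples
    --------
    >>> from trapeffort.datasets import synthetic_daily_matrix, gutianshan_summary
    >>> model = SpeciesAccumulationModel(
    ...     synthetic_daily_matrix(), species_summary=gutianshan_summary()
    ... )
    >>> res = model.fit(seed=0)
    >>> res.mte.monitoring_days, res.mte.camera_days
    (49, 931)
    """

    def __init__(
        self,
        incidence: IncidenceMatrix,
        species_summary: pd.DataFrame | None = None,
        n_cameras: int = 19,
    ) -> None:
        if incidence.n_units == 0:
            raise ValueError("incidence matrix has no sampling units")
        self.incidence = incidence
        self.species_summary = species_summary
        self.n_cameras = int(n_cameras)

    @classmethod
    def from_events(
        cls,
        events: pd.DataFrame,
        survey_span: tuple,
        species_summary: pd.DataFrame | None = None,
        n_cameras: int = 19,
        sites: Iterable[str] | None = None,
    ) -> "SpeciesAccumulationModel":
        """Build the model directly from a resident event table."""
        incidence = build_incidence(events, "day", survey_span, sites=sites)
        return cls(incidence, species_summary=species_summary, n_cameras=n_cameras)

    def fit(
        self,
        p_s: float | str = "auto",
        common_threshold: float = 1.0,
        method: str = "exact",
        n_permutations: int = 1000,
        seed: int | None = None,
    ) -> "SpeciesAccumulationResults":
        """Estimate the pool, the curve, and the minimum trapping effort.

        ``p_s="auto"`` derives the target proportion from the species
        summary as the fraction of resident species whose share P2 of
        resident detections exceeds ``common_threshold`` percent.
        """
        if p_s == "auto":
            if self.species_summary is None:
                raise ValueError('p_s="auto" requires a species summary')
            p_s_value = common_species_proportion(self.species_summary, common_threshold)
        else:
            p_s_value = float(p_s)
        chao = chao_richness(self.incidence)
        curve = rarefaction_curve(
            self.incidence, method=method, n_permutations=n_permutations, seed=seed
        )
        mte_result = minimum_trapping_effort(
            self.incidence, summary=None, n_cameras=self.n_cameras, p_s=p_s_value
        )
        return SpeciesAccumulationResults(self, chao, curve, p_s_value, mte_result)


class SpeciesAccumulationResults:
    """Fitted species–effort relationship and its minimum trapping effort."""

    def __init__(
        self,
        model: SpeciesAccumulationModel,
        chao: ChaoEstimate,
        curve: RarefactionCurve,
        p_s: float,
        mte: MTEResult,
    ) -> None:
        self.model = model
        self.chao = chao
        self.curve = curve
        self.p_s = p_s
        self.mte = mte

    @property
    def s_obs(self) -> int:
        return self.chao.s_obs

    @property
    def s_max(self) -> float:
        return self.chao.s_max

    def predict(self, d) -> float | np.ndarray:
        """Expected species count at effort ``d`` monitoring days."""
        return self.curve(d)

    def curve_frame(self) -> pd.DataFrame:
        """Curve as a table (effort, camera_days, expected_s, lower, upper)."""
        return pd.DataFrame(
            {
                "effort": self.curve.efforts,
                "camera_days": self.curve.efforts * self.model.n_cameras,
                "expected_s": self.curve.expected_s,
                "lower": self.curve.lower,
                "upper": self.curve.upper,
            }
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        c, m = self.chao, self.mte
        lines = [
            "Species accumulation against trapping effort",
            "=" * 52,
            f"Sampling units (monitoring days)   {self.model.incidence.n_units:>10d}",
            f"Cameras per monitoring day         {self.model.n_cameras:>10d}",
            f"Observed richness S_obs            {c.s_obs:>10d}",
            f"Uniques a1 / duplicates a2         {c.a1:>6d} / {c.a2:<d}",
            f"Chao species pool S_max            {c.s_max:>10.2f}"
            + ("  (bias-corrected)" if c.corrected else ""),
            f"Target proportion p_s              {self.p_s:>10.2f}",
            f"Target richness p_s * S_max        {m.target_s:>10.2f}",
            "-" * 52,
            f"Minimum trapping effort            {m.monitoring_days:>6d} monitoring days",
            f"                                   {m.camera_days:>6d} camera days",
            "=" * 52,
            f"Rarefaction method: {self.curve.method}"
            + (
                f" ({self.curve.n_permutations} permutations for the 95% band)"
                if self.curve.n_permutations
                else ""
            ),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the curve, its band, and the MTE target lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.curve.efforts * self.model.n_cameras
        ax.plot(d, self.curve.expected_s, color="black", label="expected richness")
        ax.plot(d, self.curve.lower, color="black", ls="--", lw=0.8)
        ax.plot(d, self.curve.upper, color="black", ls="--", lw=0.8, label="95% band")
        ax.axhline(self.mte.target_s, color="tab:red", lw=0.8)
        ax.axvline(self.mte.camera_days, color="tab:red", lw=0.8, label=f"MTE = {self.mte.camera_days} camera days")
        ax.set_xlabel("camera days")
        ax.set_ylabel("expected number of species")
        ax.legend(frameon=False)
        return ax
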