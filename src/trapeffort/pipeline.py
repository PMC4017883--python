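"""End-to-end pipeline: configuration, orchestration and logging.

A :class:`PipelineConfig` (YAML-serializable) drives either the full
photo-record path — independence filter, exclusions, summary, daily
incidence, rarefaction + MTE, effort-allocation contour, per-site
curves — or a shortened path starting from a pooled daily matrix (which
lacks site resolution, so the contour and site-curve stages are skipped
and p_s must be given explicitly unless a summary table is supplied).
Every output file records the seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .allocation import contour_grid, site_day_occupancy
from .events import (
    apply_exclusions,
    build_incidence,
    filter_independent,
    read_classification,
    read_daily_matrix,
    read_photo_records,
    summarize_species,
)
from .model import SpeciesAccumulationModel
from .site_curves import per_site_curves

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("trapeffort")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    # inputs: either records+classification, or a pooled daily matrix
    records: str | None = None
    classification: str | None = None
    daily_matrix: str | None = None
    survey_start: str = "2009-06-01"
    survey_days: int = 730
    # processing
    interval_minutes: float = 30.0
    common_threshold_percent: float = 1.0
    p_s: float | str = "auto"
    n_cameras: int = 19
    # resampling
    n_permutations: int = 1000
    contour_site_counts: list[int] = field(default_factory=lambda: [1, 3, 7, 13, 19])
    contour_window_lengths: list[int] = field(
        default_factory=lambda: [10, 25, 50, 100, 200, 400, 730]
    )
    contour_replicates: int = 1000
    site_curve_permutations: int = 100
    seed: int = 0
    output_dir: str = "trapeffort_out"

    def __post_init__(self) -> None:
        if self.interval_minutes < 0:
            raise ValueError("interval_minutes must be >= 0")
        if self.survey_days < 1:
            raise ValueError("survey_days must be >= 1")
        if self.p_s != "auto" and not 0 < float(self.p_s) <= 1:
            raise ValueError('p_s must be "auto" or a proportion in (0, 1]')
        if self.records is None and self.daily_matrix is None:
            raise ValueError("either photo records or a daily matrix must be given")
        if self.records is not None and self.classification is None:
            raise ValueError("photo records require a species classification table")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]


def _survey_span(config: PipelineConfig) -> tuple[pd.Timestamp, pd.Timestamp]:
    start = pd.Timestamp(config.survey_start)
    return start, start + pd.Timedelta(days=config.survey_days - 1)


def _stamp(config: PipelineConfig) -> str:
    return f"# trapeffort {__version__}  seed={config.seed}  config={config.config_hash()}\n"


def _write_tsv(frame: pd.DataFrame, path: Path, config: PipelineConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        frame.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured analysis; return the paths and key results.

    Any stage failure aborts with the stage name attached to the error.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    span = _survey_span(config)
    results: dict = {"output_dir": str(out), "seed": config.seed, "config_hash": config.config_hash()}
    stage = "configuration"
    try:
        summary = None
        if config.records is not None:
            stage = "event processing"
            log.info("reading photo records from %s", config.records)
            records = read_photo_records(config.records)
            classification = read_classification(config.classification)
            events = filter_independent(records, config.interval_minutes)
            resident, removal_log = apply_exclusions(events, classification)
            summary = summarize_species(events, resident)
            _write_tsv(summary.round({"p1": 2, "p2": 2}), out / "species_summary.tsv", config, index=True)
            _write_tsv(removal_log, out / "removed_species.tsv", config)
            stage = "incidence"
            incidence = build_incidence(resident, "day", span)
        else:
            stage = "daily matrix"
            log.info("reading daily matrix from %s", config.daily_matrix)
            incidence = read_daily_matrix(config.daily_matrix, max_cameras=config.n_cameras)

        stage = "rarefaction and minimum trapping effort"
        if config.p_s == "auto" and summary is None:
            raise ValueError(
                "a pooled daily matrix carries no species summary; set p_s explicitly"
            )
        model = SpeciesAccumulationModel(incidence, species_summary=summary, n_cameras=config.n_cameras)
        fitted = model.fit(
            p_s=config.p_s,
            common_threshold=config.common_threshold_percent,
            n_permutations=config.n_permutations,
            seed=config.seed,
        )
        _write_tsv(fitted.curve_frame(), out / "rarefaction_curve.tsv", config)
        mte_payload = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "p_s": fitted.p_s,
            "s_obs": fitted.s_obs,
            "s_max": fitted.s_max,
            "target_s": fitted.mte.target_s,
            "monitoring_days": fitted.mte.monitoring_days,
            "camera_days": fitted.mte.camera_days,
            "n_cameras": fitted.mte.n_cameras,
        }
        (out / "mte.json").write_text(json.dumps(mte_payload, indent=2) + "\n")
        (out / "summary.txt").write_text(fitted.summary() + "\n")
        results["mte"] = mte_payload

        if config.records is not None:
            stage = "effort allocation"
            occupancy = site_day_occupancy(resident, span)
            grid = contour_grid(
                occupancy,
                site_counts=[k for k in config.contour_site_counts if k <= occupancy.n_sites],
                window_lengths=[w for w in config.contour_window_lengths if w <= occupancy.n_days],
                n_reps=config.contour_replicates,
                seed=config.seed,
                denominator=fitted.s_max,
            )
            _write_tsv(grid.to_frame(), out / "contour_grid.tsv", config)
            stage = "site curves"
            for kind in ("days", "photographs"):
                curves = per_site_curves(
                    resident,
                    effort_kind=kind,
                    survey_span=span,
                    n_permutations=config.site_curve_permutations,
                    seed=config.seed,
                )
                _write_tsv(curves.to_frame(), out / f"site_curves_{kind}.tsv", config)
                _write_tsv(curves.mean_frame(), out / f"site_curves_{kind}_mean.tsv", config)

        stage = "run log"
        (out / "run_log.txt").write_text(
            _stamp(config) + "stages complete\n" + config.to_yaml()
        )
    except Exception as err:
        raise RuntimeError(f"pipeline failed during {stage}: {err}") from err
    return results
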