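"""End-to-end analysis pipeline.

Runs the full study from one config: weighted tabulation (if given a
respondent-level survey CSV) or a precomputed adoption series, the
introduction-year sensitivity analysis, the last-year-omitted stability
check, the policy-target curve (if milestones are supplied), forward
projections and scenario comparison — writing CSV artifacts plus one
machine-readable JSON summary.  Reruns with an identical config produce
byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import forecast as fc
from .model import FitConfig, fit_policy_targets, sensitivity_analysis, stability_check
from .survey import AdoptionSeries, adoption_series, load_survey, tabulate_all_years

__all__ = ["PipelineConfig", "PipelineError", "ReportBundle", "run_pipeline"]

logger = logging.getLogger("phrdiffusion")


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are flagged in the summary."""


@dataclass(frozen=True)
class PipelineConfig:
    """Full-pipeline configuration.

    Exactly one of ``survey_csv`` (respondent-level records) or
    ``series_csv`` (precomputed ``year,fraction`` series) must be given.
    """

    survey_csv: str | None = None
    series_csv: str | None = None
    targets_csv: str | None = None
    start_years: tuple[int, ...] = (2001, 2004, 2007)
    mu_start_year: int = 2004
    constraint_band: float = 0.02
    horizon_year: int = 2020
    missing_policy: str = "exclude"
    stability_start_year: int | None = None
    output_dir: str = "phr_report"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.survey_csv is None) == (self.series_csv is None):
            raise ValueError("provide exactly one of survey_csv or series_csv")
        if not self.start_years:
            raise ValueError("start_years must be nonempty")
        if self.horizon_year <= max(self.start_years):
            raise ValueError("horizon_year must be after every start year")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a JSON or YAML config file."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        if "start_years" in data:
            data["start_years"] = tuple(data["start_years"])
        return cls(**data)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["start_years"] = list(self.start_years)
        return data


@dataclass
class ReportBundle:
    """Paths of written artifacts plus the in-memory summary."""

    output_dir: Path
    artifacts: dict[str, Path] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute tabulate → fit → sensitivity → stability → forecast → compare."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    logger.info("pipeline config: %s", json.dumps(config.to_dict(), sort_keys=True))
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(output_dir=out_dir)
    summary: dict = {"config": config.to_dict(), "stages": {}, "scenarios": {}}
    bundle.summary = summary

    def finish(stage: str, status: str) -> None:
        summary["stages"][stage] = status
        logger.info("stage %s: %s", stage, status)

    try:
        # --- observed series -------------------------------------------------
        if config.survey_csv is not None:
            records = load_survey(config.survey_csv)
            tables = tabulate_all_years(records, config.missing_policy)
            import pandas as pd

            tab_frame = pd.concat([t.to_frame() for t in tables], ignore_index=True)
            tab_path = out_dir / "tabulation.csv"
            tab_frame.to_csv(tab_path, index=False)
            tab_json = out_dir / "tabulation.json"
            tab_json.write_text(
                json.dumps([t.to_dict() for t in tables], indent=2, sort_keys=True)
            )
            bundle.artifacts["tabulation"] = tab_path
            bundle.artifacts["tabulation_json"] = tab_json
            series = adoption_series(tables)
            summary["tabulation"] = [t.to_dict() for t in tables]
            finish("tabulate", "ok")
        else:
            series = AdoptionSeries.from_csv(config.series_csv)
            finish("load_series", "ok")
        summary["observed_series"] = {
            str(y): f for y, f in zip(series.years.tolist(), series.fractions.tolist())
        }

        # --- sensitivity analysis -------------------------------------------
        base_cfg = FitConfig(
            start_year=min(config.start_years),
            constraint_band=config.constraint_band,
            seed=config.seed,
        )
        table = sensitivity_analysis(series, config.start_years, base_cfg)
        coef_path = out_dir / "coefficients.csv"
        table.frame.to_csv(coef_path, index=False)
        bundle.artifacts["coefficients"] = coef_path
        if table.errors and not table.results:
            raise PipelineError(f"all start years failed: {table.errors}")
        finish("sensitivity", "ok" if not table.errors else f"partial: {table.errors}")

        import pandas as pd

        fit_frame = pd.DataFrame({"year": series.years, "observed": series.fractions})
        for start, res in table.results.items():
            fit_frame[f"predicted_{start}"] = res.fittedvalues
            fit_frame[f"difference_pp_{start}"] = res.resid_pp
            summary["scenarios"][res.label] = res.to_dict()
        fits_path = out_dir / "observed_vs_predicted.csv"
        fit_frame.to_csv(fits_path, index=False)
        bundle.artifacts["observed_vs_predicted"] = fits_path
        finish("fit_table", "ok")

        # --- stability check -------------------------------------------------
        if len(series) >= 3:
            stab_start = config.stability_start_year or config.mu_start_year
            stab_cfg = dataclasses.replace(base_cfg, start_year=stab_start)
            stab = stability_check(series, stab_cfg, config.horizon_year)
            summary["stability"] = {
                "start_year": stab_start,
                "horizon_year": config.horizon_year,
                "full_forecast": stab.full_forecast,
                "reduced_forecast": stab.reduced_forecast,
                "abs_difference": stab.abs_difference,
            }
            finish("stability", "ok")
        else:
            finish("stability", "skipped: fewer than 3 observations")

        # --- policy-target curve ---------------------------------------------
        forecasts = []
        for start, res in table.results.items():
            forecasts.append(fc.project(res, config.horizon_year))
        reference_label = None
        if config.targets_csv is not None:
            targets = AdoptionSeries.from_csv(config.targets_csv)
            mu_cfg = dataclasses.replace(base_cfg, start_year=config.mu_start_year)
            mu_result = fit_policy_targets(targets, mu_cfg)
            summary["scenarios"][mu_result.label] = mu_result.to_dict()
            forecasts.append(fc.project(mu_result, config.horizon_year))
            reference_label = mu_result.label
            finish("policy_targets", "ok")

        # --- trajectories and comparison --------------------------------------
        traj_frame = pd.concat([f.to_frame() for f in forecasts], ignore_index=True)
        traj_path = out_dir / "trajectories.csv"
        traj_frame.to_csv(traj_path, index=False)
        bundle.artifacts["trajectories"] = traj_path
        summary["horizon_year"] = config.horizon_year
        summary["horizon_values"] = {
            f.label: f.value_at(config.horizon_year) for f in forecasts
        }
        if len(forecasts) >= 2:
            reference_label = reference_label or forecasts[0].label
            comparison = fc.compare_scenarios(forecasts, reference_label)
            comp_path = out_dir / "comparison.csv"
            comparison.to_csv(comp_path, index=False)
            bundle.artifacts["comparison"] = comp_path
            summary["comparison"] = {
                "reference": reference_label,
                "dominant_at_horizon": comparison.attrs["dominant"],
            }
        finish("forecast", "ok")
    except PipelineError:
        raise
    except Exception as exc:
        summary["stages"]["error"] = str(exc)
        _write_summary(out_dir, summary, bundle)
        raise PipelineError(str(exc)) from exc

    _write_summary(out_dir, summary, bundle)
    return bundle


def _write_summary(out_dir: Path, summary: dict, bundle: ReportBundle) -> None:
    path = out_dir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    bundle.artifacts["summary"] = path
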