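"""Scenario forecasting and comparison.

Each fitted scenario (an introduction-year fit or the policy-target curve) is
projected forward as an annual trajectory of cumulative adoption, evaluated
with the continuous closed form at integer calendar years.  Scenarios are
compared on calendar years — years before a scenario's introduction count as
zero adoption — and threshold-crossing years report when each scenario first
reaches a target penetration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bass import BassParams, Trajectory, bass_cdf, time_to_threshold

__all__ = [
    "ScenarioForecast",
    "project",
    "threshold_year",
    "compare_scenarios",
    "plot_scenarios",
]


@dataclass(frozen=True)
class ScenarioForecast:
    """A labelled annual adoption trajectory for one fitted scenario."""

    label: str
    params: BassParams
    trajectory: Trajectory

    @property
    def horizon_year(self) -> int:
        return int(self.trajectory.years[-1])

    def value_at(self, year: int) -> float:
        """Cumulative fraction at ``year`` (zero before the start year)."""
        return self.trajectory.value_at(year, before_start=0.0)

    def to_frame(self) -> pd.DataFrame:
        df = self.trajectory.to_frame()
        df.insert(0, "label", self.label)
        return df


def project(result, horizon_year: int) -> ScenarioForecast:
    """Project a fitted model annually from its start year to ``horizon_year``.

    ``result`` is a :class:`~phrdiffusion.model.BassDiffusionResults` (or any
    object with ``params`` and ``label``).  Trajectory values are exactly
    ``bass_cdf(params, year - start_year)``.
    """
    params: BassParams = result.params
    if horizon_year <= params.start_year:
        raise ValueError(
            f"horizon {horizon_year} must be after start year {params.start_year}"
        )
    years = np.arange(params.start_year, horizon_year + 1)
    fractions = np.asarray(bass_cdf(params, (years - params.start_year).astype(float)))
    label = getattr(result, "label", None) or f"start {params.start_year}"
    return ScenarioForecast(label=label, params=params, trajectory=Trajectory(years, fractions))


def threshold_year(forecast: ScenarioForecast, target_fraction: float) -> int | None:
    """First calendar year the trajectory reaches ``target_fraction``.

    Returns ``None`` if the target is not reached by the horizon; a target at
    or above the market potential is unreachable and raises.
    """
    if target_fraction >= forecast.params.m:
        raise ValueError(
            f"target {target_fraction} is unreachable: market potential is "
            f"{forecast.params.m}"
        )
    if target_fraction <= 0:
        raise ValueError("target fraction must be positive")
    hits = np.nonzero(forecast.trajectory.fractions >= target_fraction)[0]
    if len(hits) == 0:
        return None
    return int(forecast.trajectory.years[hits[0]])


def threshold_year_exact(params: BassParams, target_fraction: float) -> float:
    """Continuous-time calendar date at which the curve reaches the target."""
    return params.start_year + time_to_threshold(params, target_fraction)


def compare_scenarios(
    forecasts: list[ScenarioForecast], reference_label: str
) -> pd.DataFrame:
    """Per-year differences of each scenario minus the reference scenario.

    Scenarios are aligned on calendar years over the common range — from the
    earliest start year to the earliest horizon — with years before a
    scenario's start counted as zero.  The frame carries a ``dominant``
    attribute: the label with the highest adoption at the common horizon.
    """
    if len(forecasts) < 2:
        raise ValueError("need at least 2 scenarios to compare")
    labels = [f.label for f in forecasts]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique")
    if reference_label not in labels:
        raise ValueError(f"reference label {reference_label!r} not among {labels}")
    reference = next(f for f in forecasts if f.label == reference_label)
    first_year = min(int(f.trajectory.years[0]) for f in forecasts)
    last_year = min(f.horizon_year for f in forecasts)
    years = np.arange(first_year, last_year + 1)
    rows = []
    for fc in forecasts:
        for year in years:
            rows.append(
                {
                    "year": int(year),
                    "label": fc.label,
                    "difference_vs_reference": fc.value_at(year) - reference.value_at(year),
                }
            )
    df = pd.DataFrame(rows)
    final = {fc.label: fc.value_at(last_year) for fc in forecasts}
    df.attrs["dominant"] = max(final, key=final.get)
    df.attrs["horizon_values"] = final
    return df


def plot_scenarios(forecasts, targets: ScenarioForecast | None = None, ax=None):
    """Plot cumulative adoption (%) per scenario against calendar year."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for fc in forecasts:
        ax.plot(fc.trajectory.years, 100 * fc.trajectory.fractions, label=fc.label)
    if targets is not None:
        ax.plot(
            targets.trajectory.years,
            100 * targets.trajectory.fractions,
            "--",
            label=targets.label,
        )
    ax.set_xlabel("year")
    ax.set_ylabel("cumulative adoption (%)")
    ax.legend()
    return ax
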