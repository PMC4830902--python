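"""Weighted tabulation of the two-item PHR survey.

PHR (personal health record) use is measured by two yes/no survey items:
whether the respondent tracked personal health information online in the last
12 months, and whether they communicated with a doctor or doctor's office by
email/Internet.  Respondents answering yes to both are counted as using basic
PHR functionality.  Records carry population-scaling sampling weights (as in
HINTS, the Health Information National Trends Survey), so all tabulations are
weighted: the four joint categories (both yes / communication only / tracking
only / both no) are summed by weight and reported as counts and percentages
per survey year, and the both-yes fraction per year forms the adoption series
the diffusion model is fitted to.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SurveyRecord",
    "AdoptionTable",
    "AdoptionSeries",
    "SchemaError",
    "EmptyYearError",
    "load_survey",
    "tabulate_adoption",
    "tabulate_all_years",
    "adoption_series",
    "CATEGORIES",
]

REQUIRED_COLUMNS = ("respondent_id", "survey_year", "weight", "item_track", "item_comm")
CATEGORIES = ("both_yes", "comm_only", "track_only", "both_no")
_ITEM_VALUES = frozenset({"yes", "no", "missing"})


class SchemaError(ValueError):
    """Input file does not declare the required columns."""


class EmptyYearError(ValueError):
    """No usable records for a requested survey year."""


@dataclass(frozen=True)
class SurveyRecord:
    """One respondent: survey year, sampling weight, and the two PHR items.

    Item responses are normalized to ``"yes"``, ``"no"`` or ``"missing"``.
    """

    respondent_id: str
    survey_year: int
    weight: float
    item_track: str
    item_comm: str

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(
                f"respondent {self.respondent_id}: weight must be >= 0, got {self.weight}"
            )
        for field in ("item_track", "item_comm"):
            value = getattr(self, field)
            if value not in _ITEM_VALUES:
                raise ValueError(
                    f"respondent {self.respondent_id}: {field} must be one of "
                    f"{sorted(_ITEM_VALUES)}, got {value!r}"
                )


@dataclass(frozen=True)
class AdoptionTable:
    """Weighted joint-category tabulation for one survey year.

    The four weighted counts always sum to ``total`` (exactly, for integer
    weights).  Percentages are ``100 * count / total``, kept at full precision
    internally; use :meth:`to_frame` for 2-dp display.
    """

    survey_year: int
    both_yes: float
    comm_only: float
    track_only: float
    both_no: float

    @property
    def total(self) -> float:
        return self.both_yes + self.comm_only + self.track_only + self.both_no

    def count(self, category: str) -> float:
        if category not in CATEGORIES:
            raise KeyError(category)
        return getattr(self, category)

    def percent(self, category: str) -> float:
        return 100.0 * self.count(category) / self.total

    @property
    def adoption_fraction(self) -> float:
        """Fraction answering yes to both items — the PHR adoption rate."""
        return self.both_yes / self.total

    def to_frame(self) -> pd.DataFrame:
        """Long format: survey_year, category, weighted_count, percent (2 dp)."""
        return pd.DataFrame(
            {
                "survey_year": self.survey_year,
                "category": CATEGORIES,
                "weighted_count": [self.count(c) for c in CATEGORIES],
                "percent": [round(self.percent(c), 2) for c in CATEGORIES],
            }
        )

    def to_dict(self) -> dict:
        return {
            "survey_year": self.survey_year,
            "weighted_counts": {c: self.count(c) for c in CATEGORIES},
            "total": self.total,
            "percent": {c: self.percent(c) for c in CATEGORIES},
        }


class AdoptionSeries:
    """Ordered (year, adoption fraction) observations — the fitting target."""

    def __init__(self, years: Sequence[int], fractions: Sequence[float]):
        years_arr = np.asarray(years, dtype=int)
        fractions_arr = np.asarray(fractions, dtype=float)
        if years_arr.shape != fractions_arr.shape or years_arr.ndim != 1:
            raise ValueError("years and fractions must be 1-d with matching length")
        if len(years_arr) == 0:
            raise ValueError("adoption series must contain at least one point")
        if len(np.unique(years_arr)) != len(years_arr):
            raise ValueError("years must be unique")
        order = np.argsort(years_arr)
        years_arr = years_arr[order]
        fractions_arr = fractions_arr[order]
        if np.any((fractions_arr < 0) | (fractions_arr > 1)):
            raise ValueError("adoption fractions must lie in [0, 1]")
        self.years = years_arr
        self.fractions = fractions_arr

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, float]]) -> "AdoptionSeries":
        pairs = list(pairs)
        return cls([y for y, _ in pairs], [f for _, f in pairs])

    @classmethod
    def from_csv(cls, path) -> "AdoptionSeries":
        """Read a ``year,fraction`` CSV."""
        df = pd.read_csv(path)
        missing = {"year", "fraction"} - set(df.columns)
        if missing:
            raise SchemaError(f"series file {path} missing columns: {sorted(missing)}")
        return cls(df["year"].to_numpy(), df["fraction"].to_numpy())

    def __len__(self) -> int:
        return len(self.years)

    def __iter__(self):
        return iter(zip(self.years.tolist(), self.fractions.tolist()))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AdoptionSeries)
            and np.array_equal(self.years, other.years)
            and np.array_equal(self.fractions, other.fractions)
        )

    def drop_last(self) -> "AdoptionSeries":
        """The series without its most recent observation."""
        if len(self) < 2:
            raise ValueError("cannot drop the only observation")
        return AdoptionSeries(self.years[:-1], self.fractions[:-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "fraction": self.fractions})

    def __repr__(self) -> str:
        pts = ", ".join(f"({y}, {f:.4f})" for y, f in self)
        return f"AdoptionSeries([{pts}])"


def _normalize_item(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "missing"
    text = str(value).strip().lower()
    if text in ("", "nan", "na", "missing", "."):
        return "missing"
    if text in ("yes", "y", "1", "true"):
        return "yes"
    if text in ("no", "n", "0", "false"):
        return "no"
    raise ValueError(f"unrecognized item response {value!r}")


def load_survey(path, valid_years: tuple[int, int] = (1990, 2100)) -> list[SurveyRecord]:
    """Read respondent-level records from a CSV.

    The header must declare ``respondent_id,survey_year,weight,item_track,
    item_comm``.  Item responses are normalized case-insensitively to
    yes/no/missing; empty cells are missing.  Negative weights and years
    outside ``valid_years`` raise a ``ValueError`` naming the offending row.
    """
    df = pd.read_csv(path, dtype={"respondent_id": str, "item_track": str, "item_comm": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"survey file {path} missing required columns: {sorted(missing)}")
    lo, hi = valid_years
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        year = int(row.survey_year)
        if not lo <= year <= hi:
            raise ValueError(f"row {idx}: survey_year {year} outside [{lo}, {hi}]")
        weight = float(row.weight)
        if weight < 0:
            raise ValueError(f"row {idx}: negative weight {weight}")
        records.append(
            SurveyRecord(
                respondent_id=str(row.respondent_id),
                survey_year=year,
                weight=weight,
                item_track=_normalize_item(row.item_track),
                item_comm=_normalize_item(row.item_comm),
            )
        )
    return records


def _classify(record: SurveyRecord, missing_policy: str) -> str | None:
    track, comm = record.item_track, record.item_comm
    if "missing" in (track, comm):
        if missing_policy == "exclude":
            return None
        track = "no" if track == "missing" else track
        comm = "no" if comm == "missing" else comm
    if track == "yes" and comm == "yes":
        return "both_yes"
    if comm == "yes":
        return "comm_only"
    if track == "yes":
        return "track_only"
    return "both_no"


def tabulate_adoption(
    records: Iterable[SurveyRecord], year: int, missing_policy: str = "exclude"
) -> AdoptionTable:
    """Weighted joint-category tabulation for one survey year.

    ``missing_policy`` is either ``"exclude"`` (listwise deletion of
    respondents missing either item — the default) or ``"treat_as_no"``.
    """
    if missing_policy not in ("exclude", "treat_as_no"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    counts = dict.fromkeys(CATEGORIES, 0.0)
    n_used = 0
    for record in records:
        if record.survey_year != year:
            continue
        category = _classify(record, missing_policy)
        if category is None:
            continue
        counts[category] += record.weight
        n_used += 1
    if n_used == 0:
        raise EmptyYearError(f"no usable records for survey year {year}")
    return AdoptionTable(survey_year=year, **counts)


def tabulate_all_years(
    records: Sequence[SurveyRecord], missing_policy: str = "exclude"
) -> list[AdoptionTable]:
    """One :class:`AdoptionTable` per survey year present, year-sorted."""
    years = sorted({r.survey_year for r in records})
    return [tabulate_adoption(records, y, missing_policy) for y in years]


def adoption_series(tables: Iterable[AdoptionTable]) -> AdoptionSeries:
    """Both-yes adoption fraction per year, year-sorted."""
    tables = list(tables)
    years = [t.survey_year for t in tables]
    if len(set(years)) != len(years):
        raise ValueError("duplicate survey years in tabulation")
    return AdoptionSeries(years, [t.adoption_fraction for t in tables])
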