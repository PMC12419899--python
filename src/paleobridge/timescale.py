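"""Geological timescale intervals (stages and periods).

The package ships a versioned fixture derived from the International
Chronostratigraphic Chart (stage and period boundaries in Ma). All stage
and period assignments go through :class:`GeoTimescale`; nothing else in
the package hard-codes interval boundaries.

Age-to-interval convention: an interval spans ``[age_younger, age_older)``
in age (so an age falling exactly on the boundary between two intervals is
assigned to the *older* one, whose younger edge it equals); the oldest
interval is closed at its older edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["GeoTimescale", "TimescaleError", "load_default_timescale"]


class TimescaleError(ValueError):
    """Raised for malformed or non-contiguous timescale tables."""


@dataclass(frozen=True)
class Interval:
    name: str
    level: str
    age_older: float
    age_younger: float


class GeoTimescale:
    """Ordered, contiguous geological intervals at two levels (stage, period).

    Parameters
    ----------
    table:
        DataFrame with columns ``name, level, age_older, age_younger``,
        ``level`` in ``{"stage", "period"}``. Intervals at each level must be
        non-overlapping and contiguous over the span they cover.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"name", "level", "age_older", "age_younger"}
        missing = required - set(table.columns)
        if missing:
            raise TimescaleError(f"timescale table missing columns: {sorted(missing)}")
        self._levels: dict[str, pd.DataFrame] = {}
        for level, sub in table.groupby("level"):
            sub = sub.sort_values("age_younger").reset_index(drop=True)
            if (sub["age_older"] <= sub["age_younger"]).any():
                bad = sub.loc[sub["age_older"] <= sub["age_younger"], "name"].tolist()
                raise TimescaleError(f"intervals with age_older <= age_younger: {bad}")
            older = sub["age_older"].to_numpy()[:-1]
            younger = sub["age_younger"].to_numpy()[1:]
            if not np.allclose(older, younger, atol=1e-9):
                raise TimescaleError(f"{level}-level intervals not contiguous")
            self._levels[level] = sub

    def intervals(self, level: str) -> list[Interval]:
        sub = self._level(level)
        return [
            Interval(r.name, level, float(r.age_older), float(r.age_younger))
            for r in sub.itertuples(index=False)
        ]

    def span(self, level: str) -> tuple[float, float]:
        sub = self._level(level)
        return float(sub["age_older"].max()), float(sub["age_younger"].min())

    def interval_at(self, age: float, level: str) -> Interval:
        """Interval containing ``age`` (ties on boundaries go to the older one)."""
        sub = self._level(level)
        older_max, younger_min = self.span(level)
        if age > older_max or age < younger_min:
            raise TimescaleError(
                f"age {age} Ma outside the {level}-level span "
                f"[{younger_min}, {older_max}] Ma"
            )
        younger = sub["age_younger"].to_numpy()
        older = sub["age_older"].to_numpy()
        # [younger, older) with the oldest interval closed at its older edge
        hits = (age >= younger) & (age < older)
        if age == older_max:
            hits = hits | (older == older_max)
        idx = int(np.argmax(hits))
        row = sub.iloc[idx]
        return Interval(str(row["name"]), level, float(row["age_older"]), float(row["age_younger"]))

    def stage_at(self, age: float) -> Interval:
        return self.interval_at(age, "stage")

    def period_at(self, age: float) -> Interval:
        return self.interval_at(age, "period")

    def period_names(self) -> list[str]:
        return [iv.name for iv in self.intervals("period")]

    def _level(self, level: str) -> pd.DataFrame:
        if level not in self._levels:
            raise TimescaleError(f"no intervals at level {level!r}")
        return self._levels[level]

    @classmethod
    def from_csv(cls, path) -> "GeoTimescale":
        return cls(pd.read_csv(path))


def load_default_timescale() -> GeoTimescale:
    """Load the packaged chronostratigraphic-chart fixture (Devonian to present)."""
    ref = resources.files("paleobridge.data").joinpath("ics_timescale.csv")
    with resources.as_file(ref) as path:
        return GeoTimescale.from_csv(path)
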