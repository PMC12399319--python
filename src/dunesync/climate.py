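"""Monthly climate anomalies and absolute climate windows.

Raw station data arrive as one row per (year, month) with one column per
climate variable (total precipitation, min/mean/max temperature, and
optionally a pre-computed drought index).  Each variable is converted to
per-calendar-month z-scores against a reference period: the reference value
for, say, January is the mean (and SD) of all Januaries in the reference
years.  Candidate climate windows are "absolute": anchored to a fixed census
date (30 June by default) and expressed as month offsets counted backwards
from that anchor, so offset 0 is the census month itself and offset 12 is
June of the previous year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnomalySeries",
    "WindowSpec",
    "monthly_anomalies",
    "window_mean",
    "offset_to_month",
]

#: Calendar month of the annual census anchor (late June / early July census).
DEFAULT_ANCHOR_MONTH = 6


@dataclass(frozen=True)
class WindowSpec:
    """A contiguous block of months counted backwards from the census month.

    ``open`` is the earliest offset (furthest back in time) and ``close`` the
    latest; the window contains every month with ``close <= offset <= open``.
    Offset 0 is the census month (June of the census year), offset k is k
    months earlier.
    """

    open: int
    close: int

    def __post_init__(self) -> None:
        if not (0 <= self.close <= self.open):
            raise ValueError(
                f"require 0 <= close <= open, got open={self.open}, close={self.close}"
            )

    @property
    def n_months(self) -> int:
        return self.open - self.close + 1

    def offsets(self) -> range:
        return range(self.close, self.open + 1)


def offset_to_month(census_year: int, offset: int,
                    anchor_month: int = DEFAULT_ANCHOR_MONTH) -> tuple[int, int]:
    """Resolve a month offset to a calendar (year, month).

    Offset 0 is ``anchor_month`` of ``census_year``; offset k is k months
    earlier, rolling back through previous years.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")
    month = anchor_month - offset
    year = census_year
    while month <= 0:
        month += 12
        year -= 1
    return year, month


@dataclass
class AnomalySeries:
    """Per-calendar-month standardized anomalies for one climate variable."""

    variable: str
    data: pd.DataFrame  # columns: year, month, z
    reference: pd.DataFrame  # index: month 1..12; columns: mean, sd
    reference_period: tuple[int, int]
    _lookup: dict[tuple[int, int], float] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if not self._lookup:
            self._lookup = {
                (int(y), int(m)): float(z)
                for y, m, z in zip(self.data["year"], self.data["month"], self.data["z"])
            }

    def z(self, year: int, month: int) -> float:
        try:
            return self._lookup[(year, month)]
        except KeyError:
            raise KeyError(
                f"no {self.variable} anomaly for {year}-{month:02d}"
            ) from None

    def has(self, year: int, month: int) -> bool:
        return (year, month) in self._lookup

    def to_csv(self, path) -> None:
        """Write the anomaly table, with the reference statistics in a
        sidecar ``<path>.reference.csv`` so the standardization is
        reproducible from the export alone."""
        from pathlib import Path

        path = Path(path)
        self.data.to_csv(path, index=False)
        ref = self.reference.copy()
        ref.insert(0, "variable", self.variable)
        ref.insert(1, "ref_start", self.reference_period[0])
        ref.insert(2, "ref_end", self.reference_period[1])
        ref.to_csv(path.with_suffix(path.suffix + ".reference.csv"),
                   index_label="month")


def monthly_anomalies(raw: pd.DataFrame, variable: str,
                      reference_period: tuple[int, int]) -> AnomalySeries:
    """Standardize a monthly series to per-calendar-month z-scores.

    ``z = (value - ref_mean[month]) / ref_sd[month]`` where the reference
    mean/SD for each calendar month are computed over ``reference_period``
    (inclusive year range) with the sample (n-1) SD.  Rows outside the
    reference period are standardized against the same reference statistics.

    Raises ``ValueError`` if any calendar month has fewer than two reference
    observations or zero reference SD, and flags duplicated (year, month)
    rows.
    """
    for col in ("year", "month", variable):
        if col not in raw.columns:
            raise ValueError(f"climate table lacks required column {col!r}")
    if raw.duplicated(subset=["year", "month"]).any():
        raise ValueError("duplicate (year, month) rows in climate table")
    y0, y1 = reference_period
    ref_rows = raw[(raw["year"] >= y0) & (raw["year"] <= y1)]
    counts = ref_rows.groupby("month")[variable].count()
    missing = sorted(set(range(1, 13)) - set(counts.index))
    if missing:
        raise ValueError(f"reference period has no data for months {missing}")
    thin = counts[counts < 2]
    if len(thin):
        raise ValueError(
            f"reference period needs >=2 observations per calendar month; "
            f"months {sorted(thin.index)} have fewer"
        )
    grp = ref_rows.groupby("month")[variable]
    ref = pd.DataFrame({"mean": grp.mean(), "sd": grp.std(ddof=1)})
    if (ref["sd"] <= 0).any():
        bad = sorted(ref.index[ref["sd"] <= 0])
        raise ValueError(f"zero reference SD for calendar months {bad}")
    z = (raw[variable].to_numpy(float)
         - ref["mean"].reindex(raw["month"]).to_numpy()) \
        / ref["sd"].reindex(raw["month"]).to_numpy()
    data = pd.DataFrame({
        "year": raw["year"].astype(int).to_numpy(),
        "month": raw["month"].astype(int).to_numpy(),
        "z": z,
    })
    return AnomalySeries(variable=variable, data=data, reference=ref,
                         reference_period=(int(y0), int(y1)))


def window_mean(anoms: AnomalySeries, census_year: int, window: WindowSpec,
                anchor_month: int = DEFAULT_ANCHOR_MONTH) -> float:
    """Mean anomaly over a window anchored at the census month.

    Months are resolved backwards from ``anchor_month`` of ``census_year``;
    a month missing from the series is an error (silent skips would bias the
    mean), raised as ``KeyError``.
    """
    vals = [
        anoms.z(*offset_to_month(census_year, off, anchor_month))
        for off in window.offsets()
    ]
    return float(np.mean(vals))
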