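"""Pixel-level interpretation records and their aggregation to binomial counts.

A sample plot is one interpreted 30 m pixel whose yearly spectral trajectory has
been subdivided into linear segments bounded by vertices.  Each vertex carries
the calendar year plus the interpreted land use and land cover; each segment is
labelled with a change process (stable, canopy mortality, regrowth).  Mortality
segments become discrete mortality events, classified as stand-replacing when
no live trees remain after the event (non-treed end cover) and
non-stand-replacing otherwise.

Aggregating the events over a stratified sample yields, per country and year,
the binomial data (plots at risk, plots with a mortality event) that the trend
model consumes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LandUse",
    "LandCover",
    "Process",
    "Severity",
    "Vertex",
    "Segment",
    "SamplePlot",
    "MortalityEvent",
    "ValidationError",
    "read_samples",
    "write_samples",
    "classify_severity",
    "extract_events",
    "aggregate_counts",
    "COUNTS_COLUMNS",
]


class ValidationError(ValueError):
    """Raised when interpretation records violate the documented schema."""


class LandUse(str, enum.Enum):
    FOREST = "forest"
    NON_FOREST = "non_forest"


class LandCover(str, enum.Enum):
    TREED = "treed"
    NON_TREED = "non_treed"


class Process(str, enum.Enum):
    STABLE = "stable"
    MORTALITY = "mortality"
    REGROWTH = "regrowth"


class Severity(str, enum.Enum):
    STAND_REPLACING = "stand_replacing"
    NON_STAND_REPLACING = "non_stand_replacing"


@dataclass(frozen=True)
class Vertex:
    year: int
    land_use: LandUse
    land_cover: LandCover


@dataclass(frozen=True)
class Segment:
    start: Vertex
    end: Vertex
    process: Process

    def __post_init__(self) -> None:
        if self.start.year >= self.end.year:
            raise ValidationError(
                f"segment years not increasing: {self.start.year} >= {self.end.year}"
            )


@dataclass(frozen=True)
class SamplePlot:
    """One interpreted pixel: a country stratum and contiguous segments."""

    plot_id: str
    country: str
    segments: tuple[Segment, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError(f"plot {self.plot_id}: no segments")
        for a, b in zip(self.segments, self.segments[1:]):
            if a.end != b.start:
                raise ValidationError(
                    f"plot {self.plot_id}: segments not contiguous at year "
                    f"{a.end.year} -> {b.start.year}"
                )

    @property
    def start_year(self) -> int:
        return self.segments[0].start.year

    @property
    def end_year(self) -> int:
        return self.segments[-1].end.year

    def vertices(self) -> tuple[Vertex, ...]:
        verts = [self.segments[0].start]
        verts.extend(s.end for s in self.segments)
        return tuple(verts)

    def land_use_in_year(self, year: int) -> LandUse:
        """Land use governing calendar year `year`.

        The vertex bounding the year from below applies: land use persists
        through a segment until the interpreter records a change.
        """
        if year < self.start_year or year > self.end_year:
            raise ValidationError(
                f"plot {self.plot_id}: year {year} outside {self.start_year}-{self.end_year}"
            )
        use = self.segments[0].start.land_use
        for seg in self.segments:
            if seg.start.year <= year:
                use = seg.start.land_use
            else:
                break
        return use


@dataclass(frozen=True)
class MortalityEvent:
    plot_id: str
    event_year: int
    severity: Severity


def classify_severity(segment: Segment) -> Severity:
    """Severity of a mortality segment from its end-vertex land cover.

    Stand-replacing events leave no live trees at pixel scale (non-treed end
    cover); events with residual live trees (treed end cover) are
    non-stand-replacing.
    """
    if segment.process is not Process.MORTALITY:
        raise ValidationError("classify_severity requires a mortality segment")
    if segment.end.land_cover is LandCover.NON_TREED:
        return Severity.STAND_REPLACING
    return Severity.NON_STAND_REPLACING


def extract_events(plot: SamplePlot) -> list[MortalityEvent]:
    """Mortality events of one plot, one per mortality segment.

    The event is booked to start.year + 1, the first observation year on the
    declining segment (the start vertex is the last pre-disturbance
    observation).  At most one event per calendar year per plot.
    """
    events: list[MortalityEvent] = []
    seen_years: set[int] = set()
    for seg in plot.segments:
        if seg.process is not Process.MORTALITY:
            continue
        if seg.start.land_use is not LandUse.FOREST:
            raise ValidationError(
                f"plot {plot.plot_id}: mortality segment starting {seg.start.year} "
                "on non-forest land use"
            )
        year = seg.start.year + 1
        if year in seen_years:
            raise ValidationError(
                f"plot {plot.plot_id}: multiple mortality events in year {year}"
            )
        seen_years.add(year)
        events.append(
            MortalityEvent(plot.plot_id, year, classify_severity(seg))
        )
    return events


COUNTS_COLUMNS = ["country", "year", "n_forest", "n_mortality", "n_sr", "n_nsr"]


def aggregate_counts(plots: Iterable[SamplePlot]) -> pd.DataFrame:
    """Per country x year binomial mortality counts.

    For each calendar year in which events can occur (start+1 .. end of the
    study period), ``n_forest`` counts the plots whose land use is forest
    entering that year (the at-risk denominator) and ``n_mortality`` the plots
    with a mortality event that year, split into stand-replacing (``n_sr``)
    and non-stand-replacing (``n_nsr``) counts.
    """
    plots = list(plots)
    if not plots:
        return pd.DataFrame(columns=COUNTS_COLUMNS).astype(
            {c: int for c in COUNTS_COLUMNS[2:]}
        )

    rows = []
    by_country: dict[str, list[SamplePlot]] = {}
    for p in plots:
        by_country.setdefault(p.country, []).append(p)

    for country in sorted(by_country):
        cplots = by_country[country]
        y0 = min(p.start_year for p in cplots)
        y1 = max(p.end_year for p in cplots)
        years = range(y0 + 1, y1 + 1)
        n_forest = {y: 0 for y in years}
        n_sr = {y: 0 for y in years}
        n_nsr = {y: 0 for y in years}
        for p in cplots:
            for y in range(p.start_year + 1, p.end_year + 1):
                if p.land_use_in_year(y - 1) is LandUse.FOREST:
                    n_forest[y] += 1
            for ev in extract_events(p):
                if ev.severity is Severity.STAND_REPLACING:
                    n_sr[ev.event_year] += 1
                else:
                    n_nsr[ev.event_year] += 1
        for y in years:
            rows.append(
                {
                    "country": country,
                    "year": y,
                    "n_forest": n_forest[y],
                    "n_mortality": n_sr[y] + n_nsr[y],
                    "n_sr": n_sr[y],
                    "n_nsr": n_nsr[y],
                }
            )
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


# --- CSV I/O: one row per segment ------------------------------------------

_SAMPLE_COLUMNS = [
    "plot_id",
    "country",
    "start_year",
    "start_land_use",
    "start_land_cover",
    "end_year",
    "end_land_use",
    "end_land_cover",
    "process",
]


def _parse_enum(enum_cls, value: str, plot_id: str, column: str):
    try:
        return enum_cls(value)
    except ValueError:
        raise ValidationError(
            f"plot {plot_id}: unknown {column} value {value!r}"
        ) from None


def read_samples(path: str | Path) -> list[SamplePlot]:
    """Read interpreted sample plots from a segment-per-row CSV file."""
    df = pd.read_csv(path, dtype={"plot_id": str, "country": str})
    missing = [c for c in _SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns: {missing}")
    plots: list[SamplePlot] = []
    if df.empty:
        return plots
    for (plot_id, country), g in df.groupby(["plot_id", "country"], sort=True):
        g = g.sort_values("start_year")
        segments = []
        for row in g.itertuples(index=False):
            start = Vertex(
                int(row.start_year),
                _parse_enum(LandUse, row.start_land_use, plot_id, "land_use"),
                _parse_enum(LandCover, row.start_land_cover, plot_id, "land_cover"),
            )
            end = Vertex(
                int(row.end_year),
                _parse_enum(LandUse, row.end_land_use, plot_id, "land_use"),
                _parse_enum(LandCover, row.end_land_cover, plot_id, "land_cover"),
            )
            if start.year >= end.year:
                raise ValidationError(
                    f"plot {plot_id}: segment years not increasing "
                    f"({start.year} >= {end.year})"
                )
            segments.append(
                Segment(start, end, _parse_enum(Process, row.process, plot_id, "process"))
            )
        try:
            plots.append(SamplePlot(str(plot_id), str(country), tuple(segments)))
        except ValidationError as exc:
            raise ValidationError(str(exc)) from None
    return plots


def write_samples(plots: Sequence[SamplePlot], path: str | Path) -> None:
    """Write sample plots to the segment-per-row CSV schema."""
    rows = []
    for p in plots:
        for seg in p.segments:
            rows.append(
                {
                    "plot_id": p.plot_id,
                    "country": p.country,
                    "start_year": seg.start.year,
                    "start_land_use": seg.start.land_use.value,
                    "start_land_cover": seg.start.land_cover.value,
                    "end_year": seg.end.year,
                    "end_land_use": seg.end.land_use.value,
                    "end_land_cover": seg.end.land_cover.value,
                    "process": seg.process.value,
                }
            )
    pd.DataFrame(rows, columns=_SAMPLE_COLUMNS).to_csv(path, index=False)
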