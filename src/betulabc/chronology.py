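"""Generation-to-calendar conversion and paleo-interval comparison.

Event ages inferred by the coalescent analysis come out in generations.
Dwarf birch generation time is poorly constrained (clonal growth, episodic
recruitment), so ages are reported under a bracketing pair of generation
times — 10 and 14 years — and formatted to 3 significant figures in ka
(thousand years) or mya (million years).  Converted intervals can be
intersected with a user-editable table of named paleo intervals (Marine
Isotope Stages, ice-free-corridor windows, Bering Land Bridge emergence);
a cited default table ships with the package.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "TimeEstimate",
    "CalendarInterval",
    "PaleoInterval",
    "to_calendar",
    "overlap_report",
    "load_paleo_table",
    "round_sig",
    "format_age_ka",
]

DEFAULT_GEN_TIMES = (10.0, 14.0)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


def format_age_ka(years: float, sig: int = 3) -> str:
    """Format an age in years as '588 ka' / '1.26 mya' with 3 s.f."""
    if years == 0:
        return "0 ka"
    ka = years / 1e3
    if ka < 1000:
        v = round_sig(ka, sig)
        return f"{v:g} ka"
    mya = round_sig(years / 1e6, sig)
    return f"{mya:g} mya"


@dataclass(frozen=True)
class TimeEstimate:
    """An event age in generations: posterior median and 95% CI."""

    event: str
    median_generations: float
    ci_low_generations: float
    ci_high_generations: float

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low_generations <= self.median_generations
                <= self.ci_high_generations):
            raise ValueError(f"inconsistent bounds for {self.event!r}")


@dataclass(frozen=True)
class CalendarInterval:
    """Calendar-year conversions of a TimeEstimate at each generation time.

    ``years`` maps generation time -> (median, ci_low, ci_high) in raw years
    (unrounded); ``labels`` holds the matching 3-s.f. formatted strings.
    """

    event: str
    years: dict[float, tuple[float, float, float]]
    labels: dict[float, tuple[str, str, str]]

    @property
    def median_span_ka(self) -> tuple[float, float]:
        """(younger, older) bound of the medians across generation times, ka."""
        meds = [v[0] / 1e3 for v in self.years.values()]
        return min(meds), max(meds)


def to_calendar(t: TimeEstimate,
                gen_times: tuple[float, ...] = DEFAULT_GEN_TIMES) -> CalendarInterval:
    """Convert generations to calendar years for each generation time.

    Raw values are retained; formatted strings use 3 significant figures
    with automatic ka/mya unit selection.
    """
    if any(g <= 0 for g in gen_times):
        raise ValueError("generation times must be positive")
    years = {}
    labels = {}
    for g in gen_times:
        vals = (t.median_generations * g, t.ci_low_generations * g,
                t.ci_high_generations * g)
        years[g] = vals
        labels[g] = tuple(format_age_ka(v) for v in vals)
    return CalendarInterval(t.event, years, labels)


@dataclass(frozen=True)
class PaleoInterval:
    """A named interval of the paleo record, ages in ka before present."""

    name: str
    start_ka: float  # older bound
    end_ka: float    # younger bound
    region: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not self.start_ka > self.end_ka:
            raise ValueError(
                f"{self.name!r}: start_ka must exceed end_ka (ages before present)")


@dataclass(frozen=True)
class Overlap:
    event: str
    interval: PaleoInterval
    span_ka: tuple[float, float]  # (older, younger) bound of the overlap

    @property
    def length_ka(self) -> float:
        return self.span_ka[0] - self.span_ka[1]


def overlap_report(c: CalendarInterval,
                   table: list[PaleoInterval]) -> list[Overlap]:
    """Paleo intervals intersecting the event's median span (across g)."""
    young, old = c.median_span_ka
    out = []
    for iv in table:
        lo = max(young, iv.end_ka)
        hi = min(old, iv.start_ka)
        if hi >= lo:
            out.append(Overlap(c.event, iv, (hi, lo)))
    return out


def load_paleo_table(path=None) -> list[PaleoInterval]:
    """Read a paleo-interval CSV (name, start_ka, end_ka, region, source).

    With no path, loads the packaged default table.
    """
    if path is None:
        ref = resources.files("betulabc").joinpath("data/paleo_intervals.csv")
        with ref.open() as fh:
            return _parse_paleo(fh)
    with open(path) as fh:
        return _parse_paleo(fh)


def _parse_paleo(fh) -> list[PaleoInterval]:
    out = []
    for row in csv.DictReader(fh):
        out.append(PaleoInterval(
            row["name"], float(row["start_ka"]), float(row["end_ka"]),
            row.get("region", ""), row.get("source", "")))
    return out
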