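"""Beached-bird survey records: reading, validation, and event summaries.

Surveys record per-beach carcass counts by species/age class, surveyed
effort (km of beach walked), the fraction of carcasses that were intact,
and the north:south split of where on the island carcasses were found.
The module reproduces the standard event statistics: period totals,
species composition, effort-standardised encounter rates, count-weighted
intactness, and fold-change over a long-term baseline rate.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SurveyRecord",
    "BaselineRate",
    "SchemaError",
    "ValidationError",
    "SPECIES_COLUMNS",
    "read_surveys",
    "table1_path",
    "load_table1",
    "period_summary",
    "intact_weighted",
    "baseline_ratio",
]

#: Species/age count columns in canonical order.  TUPU = Tufted puffin
#: (A adult, J juvenile, AJ age undetermined), HOPU = Horned puffin,
#: CRAU = Crested auklet, MURRE = Common/Thick-billed murre.
SPECIES_COLUMNS = ("TUPU_A", "TUPU_J", "TUPU_AJ", "HOPU", "CRAU", "MURRE")


class SchemaError(ValueError):
    """Input file does not have the expected columns."""


class ValidationError(ValueError):
    """A survey row violates an internal-consistency invariant."""


@dataclass(frozen=True)
class SurveyRecord:
    """One beach survey: date, beaches walked, effort, and counts."""

    date: dt.date
    beaches: tuple[str, ...]
    length_km: float
    counts: Mapping[str, int]
    pct_intact: float
    ns_split: tuple[float, float] | None = None  # (north %, south %)

    def __post_init__(self) -> None:
        if self.length_km <= 0:
            raise ValidationError(f"{self.date}: length_km must be > 0")
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError(f"{self.date}: negative count")
        if not 0.0 <= self.pct_intact <= 100.0:
            raise ValidationError(f"{self.date}: pct_intact outside [0, 100]")
        if self.ns_split is not None:
            if abs(sum(self.ns_split) - 100.0) > 1e-6:
                raise ValidationError(f"{self.date}: ns_split must sum to 100")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def encounter_rate(self) -> float:
        """Carcasses per km for this single survey."""
        return self.total / self.length_km


@dataclass(frozen=True)
class BaselineRate:
    """Long-term baseline encounter rate (carcasses per km) with 95% CI."""

    month: int
    rate: float
    ci_low: float = 0.0
    ci_high: float = float("inf")

    def __post_init__(self) -> None:
        if not self.ci_low <= self.rate <= self.ci_high:
            raise ValidationError("baseline rate must lie within its CI")
        if self.rate < 0:
            raise ValidationError("baseline rate must be >= 0")


def table1_path() -> Path:
    """Path to the packaged event survey table (St. Paul Island 2016/17)."""
    return Path(str(resources.files("carcassdrift").joinpath("data/table1.csv")))


def read_surveys(path: str | Path) -> list[SurveyRecord]:
    """Read and validate a delimited survey table.

    Expected columns: ``date``, ``beaches``, ``length_km``, one column per
    species/age cell (see :data:`SPECIES_COLUMNS`), ``total``,
    ``pct_intact``, ``ns_north``, ``ns_south``.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        If a row's printed total disagrees with the sum of its cells.
    """
    df = pd.read_csv(path)
    required = {"date", "beaches", "length_km", "total", "pct_intact"} | set(
        SPECIES_COLUMNS
    )
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing column(s): {sorted(missing)}")

    records: list[SurveyRecord] = []
    for idx, row in df.iterrows():
        counts = {sp: int(row[sp]) for sp in SPECIES_COLUMNS}
        if sum(counts.values()) != int(row["total"]):
            raise ValidationError(
                f"row {idx} ({row['date']}): total {int(row['total'])} != "
                f"sum of cells {sum(counts.values())}"
            )
        ns = None
        if "ns_north" in df.columns and "ns_south" in df.columns:
            if pd.notna(row["ns_north"]) and pd.notna(row["ns_south"]):
                ns = (float(row["ns_north"]), float(row["ns_south"]))
        records.append(
            SurveyRecord(
                date=pd.Timestamp(row["date"]).date(),
                beaches=tuple(b.strip() for b in str(row["beaches"]).split(",")),
                length_km=float(row["length_km"]),
                counts=counts,
                pct_intact=float(row["pct_intact"]),
                ns_split=ns,
            )
        )
    return records


def load_table1() -> list[SurveyRecord]:
    """The packaged event table as validated records."""
    return read_surveys(table1_path())


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


@dataclass
class PeriodSummary:
    """Aggregate statistics over one survey window."""

    start: dt.date
    end: dt.date
    n_surveys: int
    total: int
    effort_km: float
    species_totals: dict[str, int] = field(default_factory=dict)
    species_fraction_pct: dict[str, int] = field(default_factory=dict)
    encounter_rate_pooled: float = 0.0
    encounter_rate_mean: float = 0.0

    @property
    def tufted_puffin_fraction_pct(self) -> int:
        """Whole-percent Tufted puffin share (all age classes)."""
        tupu = sum(self.species_totals[c] for c in ("TUPU_A", "TUPU_J", "TUPU_AJ"))
        return _round_half_up(100.0 * tupu / self.total) if self.total else 0

    @property
    def adult_tupu_fraction_pct(self) -> int:
        """Adults as whole-percent share of age-determinable Tufted puffins."""
        det = self.species_totals["TUPU_A"] + self.species_totals["TUPU_J"]
        if det == 0:
            return 0
        return _round_half_up(100.0 * self.species_totals["TUPU_A"] / det)

    @property
    def n_age_determinable_tupu(self) -> int:
        return self.species_totals["TUPU_A"] + self.species_totals["TUPU_J"]


def period_summary(
    records: Iterable[SurveyRecord],
    window: tuple[dt.date | str, dt.date | str],
) -> PeriodSummary:
    """Summarise counts, composition, and encounter rates over a window.

    The window is a closed date interval.  Two encounter-rate variants are
    reported: pooled (total carcasses / total km) and the mean of
    per-survey rates; the pooled one is the package default.
    """
    start = pd.Timestamp(window[0]).date()
    end = pd.Timestamp(window[1]).date()
    if end < start:
        raise ValueError("window end precedes start")
    sel = [r for r in records if start <= r.date <= end]
    effort = sum(r.length_km for r in sel)
    if sel and effort <= 0:
        raise ZeroDivisionError("zero survey effort in window: rate undefined")
    totals = {sp: sum(r.counts[sp] for r in sel) for sp in SPECIES_COLUMNS}
    grand = sum(totals.values())
    fractions = {
        sp: (_round_half_up(100.0 * n / grand) if grand else 0)
        for sp, n in totals.items()
    }
    return PeriodSummary(
        start=start,
        end=end,
        n_surveys=len(sel),
        total=grand,
        effort_km=effort,
        species_totals=totals,
        species_fraction_pct=fractions,
        encounter_rate_pooled=(grand / effort) if sel else 0.0,
        encounter_rate_mean=(
            sum(r.encounter_rate for r in sel) / len(sel) if sel else 0.0
        ),
    )


def intact_weighted(records: Sequence[SurveyRecord]) -> float:
    """Count-weighted percent of carcasses intact, to one decimal.

    Each survey contributes ``round(total * pct_intact / 100)`` intact
    carcasses; the result is the summed intact count over the summed total.
    """
    if not records:
        raise ValueError("no survey records")
    grand = sum(r.total for r in records)
    if grand == 0:
        raise ValueError("no carcasses: weighted intactness undefined")
    intact = sum(_round_half_up(r.total * r.pct_intact / 100.0) for r in records)
    return round(100.0 * intact / grand, 1)


def baseline_ratio(event_rate: float, baseline: BaselineRate) -> int:
    """Fold-change of an event encounter rate over baseline, whole-fold."""
    if baseline.rate <= 0:
        raise ZeroDivisionError("baseline rate must be positive")
    return _round_half_up(event_rate / baseline.rate)
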