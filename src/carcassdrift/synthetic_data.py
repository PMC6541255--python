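"""Synthetic events: winds, islands, mortality, drift, and surveys.

Everything the pipeline consumes can be generated here, so every stage is
testable end to end without external data.  The generator emulates the
study conditions of a Bering Sea island mortality event:

* 3-hourly gridded u/v winds on a ~32-km grid with persistent directional
  regimes — multi-day northerly or southerly stanzas with Gaussian
  perturbations and abrupt regime switches;
* a compact island polygon in the planar-km frame, split into north and
  south halves;
* a true daily at-sea mortality series, realised as carcass particles
  released uniformly within ``d_max_true`` of the island, drifted by
  :mod:`carcassdrift.drift_sim`, and retained on beaching with the float
  probability p(f) (Bernoulli);
* an observation layer matching the estimator's count model exactly:
  beached carcasses persist day to day as a Bernoulli chain whose
  marginal is the two-stage persistence rho(tau), and surveys detect
  (with probability phi) and *remove* carcasses on the surveyed frontage.

All generators are bit-reproducible under fixed seeds.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .drift_sim import DriftConfig, Island, _advect_cohort, sample_release
from .float_model import FloatParams, calibrate, float_prob
from .mortality import EventConfig, ObservationParams
from .survey_data import SPECIES_COLUMNS, SurveyRecord
from .winds import WindGrid

__all__ = [
    "WindStanza",
    "WindRegimeSpec",
    "TrueEvent",
    "SurveySlot",
    "gen_wind",
    "gen_event",
    "observe_surveys",
    "toy_island",
    "alternating_regime",
    "default_survey_schedule",
    "default_true_event",
    "synthetic_event_config",
]


@dataclass(frozen=True)
class WindStanza:
    """One wind regime: days [start, end) with a mean direction and speed.

    ``from_deg`` is the compass azimuth the wind blows *from* (0 = from
    the north, i.e. a northerly wind pushing drifters southward).
    """

    start_day: int
    end_day: int
    from_deg: float
    speed: float
    ang_sd: float = 0.0
    speed_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.end_day <= self.start_day:
            raise ValueError("stanza must span at least one day")
        if self.speed < 0 or self.speed_sd < 0:
            raise ValueError("speeds must be non-negative")


@dataclass
class WindRegimeSpec:
    """Stanza sequence plus grid geometry for synthetic winds."""

    stanzas: list[WindStanza]
    grid_spacing_km: float = 32.0
    extent_km: float = 288.0
    step_h: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.stanzas:
            raise ValueError("at least one wind stanza required")
        s = sorted(self.stanzas, key=lambda z: z.start_day)
        for a, b in zip(s[:-1], s[1:]):
            if a.end_day != b.start_day:
                raise ValueError(
                    f"stanzas must be contiguous; gap/overlap at day {a.end_day}"
                )
        self.stanzas = s


def gen_wind(spec: WindRegimeSpec) -> WindGrid:
    """Realise a 3-hourly wind grid from a regime specification."""
    rng = np.random.default_rng(spec.seed)
    xs = np.arange(-spec.extent_km, spec.extent_km + 1e-9, spec.grid_spacing_km)
    ys = xs.copy()
    t0 = spec.stanzas[0].start_day * 24.0
    t1 = spec.stanzas[-1].end_day * 24.0
    times = np.arange(t0, t1, spec.step_h)
    u = np.empty((times.size, ys.size, xs.size))
    v = np.empty_like(u)
    day_of = (times // 24.0).astype(int)
    for k, t in enumerate(times):
        stanza = next(
            z for z in spec.stanzas if z.start_day <= day_of[k] < z.end_day
        )
        az = np.deg2rad(
            stanza.from_deg + rng.normal(0.0, stanza.ang_sd, (ys.size, xs.size))
            if stanza.ang_sd > 0
            else np.full((ys.size, xs.size), stanza.from_deg)
        )
        spd = np.maximum(
            rng.normal(stanza.speed, stanza.speed_sd, (ys.size, xs.size))
            if stanza.speed_sd > 0
            else np.full((ys.size, xs.size), stanza.speed),
            0.0,
        )
        # wind FROM azimuth az blows toward az + 180 deg
        u[k] = -spd * np.sin(az)
        v[k] = -spd * np.cos(az)
    return WindGrid(times, xs, ys, u, v)


def alternating_regime(
    n_days: int,
    stanza_len: int = 4,
    speed: float = 8.0,
    ang_sd: float = 20.0,
    speed_sd: float = 2.0,
    start_from: str = "north",
    seed: int = 0,
    grid_spacing_km: float = 32.0,
    extent_km: float = 288.0,
) -> WindRegimeSpec:
    """Regime-switching spec: northerly/southerly stanzas in alternation.

    Mirrors the event's meteorology, where multi-day northerly stanzas
    (depositing on the island's north shore) alternated with southerly
    ones; both island halves therefore receive deposition over the event.
    """
    first = 0.0 if start_from == "north" else 180.0
    stanzas = []
    d = 0
    k = 0
    while d < n_days:
        stanzas.append(
            WindStanza(
                start_day=d,
                end_day=min(d + stanza_len, n_days),
                from_deg=first + 180.0 * (k % 2),
                speed=speed,
                ang_sd=ang_sd,
                speed_sd=speed_sd,
            )
        )
        d += stanza_len
        k += 1
    return WindRegimeSpec(
        stanzas, seed=seed, grid_spacing_km=grid_spacing_km, extent_km=extent_km
    )


def toy_island(
    name: str = "SPI",
    center: tuple[float, float] = (0.0, 0.0),
    radius_km: float = 5.0,
    n_vertices: int = 24,
) -> Island:
    """A regular-polygon island approximating a circular coastline."""
    th = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius_km * np.cos(th), center[1] + radius_km * np.sin(th)]
    )
    return Island(name=name, polygon=Polygon(pts))


@dataclass
class TrueEvent:
    """Ground truth for a synthetic mortality event.

    ``m_true`` maps event day (0-based on the wind clock) to the number
    of at-sea deaths that day; carcasses are released uniformly within
    ``d_max_true`` km of the island centroid on their death day.
    """

    m_true: dict[int, int]
    d_max_true: float
    islands: list[Island]
    wind: WindGrid
    float_median_days: float = 7.0
    windage: float = 0.025
    float_params: FloatParams | None = None  # overrides the calibrated median

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.m_true.values()):
            raise ValueError("mortality counts must be non-negative")
        if self.d_max_true <= 0:
            raise ValueError("d_max_true must be positive")

    @property
    def total(self) -> int:
        return int(sum(self.m_true.values()))


def gen_event(event: TrueEvent, seed: int = 0) -> pd.DataFrame:
    """Forward-simulate deposited carcasses from a true mortality series.

    For each event day j, ``m_true[j]`` carcass particles are released
    uniformly within ``d_max_true`` of the island, advected by the drift
    model, and each *beached* particle is retained as a deposited carcass
    with probability p(f) from the float function (Bernoulli).  Returns
    one row per deposited carcass: day, island, half, float_hours and
    landing coordinates.
    """
    rng = np.random.default_rng(seed)
    params = event.float_params or calibrate(event.float_median_days)
    cfg = DriftConfig(windage=event.windage, seed=0)
    primary = event.islands[0]
    rows = []
    for j in sorted(event.m_true):
        m = int(event.m_true[j])
        if m == 0:
            continue
        starts = sample_release(primary, event.d_max_true, m, rng)
        beached, isl_idx, f_h, lx, ly = _advect_cohort(
            starts[:, :2], float(j) * 24.0, event.wind, event.islands, cfg
        )
        for gi in np.flatnonzero(beached):
            p = float(float_prob(f_h[gi], params))
            if rng.random() < p:
                isl = event.islands[isl_idx[gi]]
                rows.append(
                    (
                        int(j) + int(f_h[gi] // 24.0),
                        isl.name,
                        isl.half_of_point(lx[gi], ly[gi]),
                        float(f_h[gi]),
                        float(lx[gi]),
                        float(ly[gi]),
                    )
                )
    return pd.DataFrame(
        rows, columns=["day", "island", "half", "float_hours", "x_land", "y_land"]
    )


@dataclass(frozen=True)
class SurveySlot:
    """One scheduled survey of part of an island half's frontage."""

    day: int
    half: str
    length_km: float
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage fraction must be in (0, 1]")
        if self.length_km <= 0:
            raise ValueError("surveyed length must be positive")


def default_survey_schedule(
    n_day: int = 43, interval: int = 6, length_km: float = 10.0
) -> list[SurveySlot]:
    """Alternating north/south surveys every ``interval`` days per half."""
    slots = []
    for d in range(4, n_day):
        if (d - 4) % interval == 0:
            slots.append(SurveySlot(d, "north", length_km))
        if (d - 7) % interval == 0 and d >= 7:
            slots.append(SurveySlot(d, "south", length_km))
    return sorted(slots, key=lambda s: s.day)


def default_true_event(
    deaths_per_day: int = 120,
    n_day: int = 43,
    d_max_true: float = 10.0,
    float_median_days: float = 7.0,
    wind_seed: int = 0,
    stanza_len: int = 4,
    speed: float = 8.0,
) -> TrueEvent:
    """The reference synthetic study conditions.

    Constant mortality (default 120 deaths/day over a 43-day event,
    total 5,160), moribund birds uniform within 10 km of a 5-km-radius
    island, and regime-switching winds so that both island halves receive
    deposition, as during the real event.  Wind covers the event plus the
    14-day float cap.
    """
    spec = alternating_regime(
        n_days=n_day + 15, stanza_len=stanza_len, speed=speed, seed=wind_seed
    )
    return TrueEvent(
        m_true={d: deaths_per_day for d in range(n_day)},
        d_max_true=d_max_true,
        islands=[toy_island()],
        wind=gen_wind(spec),
        float_median_days=float_median_days,
    )


def synthetic_event_config(
    n_day: int = 43,
    n_perm: int = 1000,
    seed: int = 0,
    length_km: float = 10.0,
    L: float = 21.8,
) -> EventConfig:
    """Event bookkeeping matched to the synthetic beach codes N and S."""
    return EventConfig(
        L=L,
        event_start=dt.date(2000, 1, 1),
        n_day=n_day,
        n_perm=n_perm,
        seed=seed,
        beach_half_map={"N": "north", "S": "south"},
        beach_lengths={"N": length_km, "S": length_km},
    )


def observe_surveys(
    deposits: pd.DataFrame,
    schedule: list[SurveySlot],
    params: ObservationParams,
    seed: int = 0,
    frontage_km: float = 21.8,
    island: str | None = None,
    undetected_remain: bool = True,
) -> list[SurveyRecord]:
    """Thin deposited carcasses through persistence, detection, removal.

    Each carcass lands at a uniform position along its half's frontage
    (``frontage_km``) and then persists day to day as a Bernoulli chain
    (first-day survival rho0, thereafter rho1), so its marginal presence
    probability equals the estimator's persistence function rho(tau).  A
    survey covers the first ``length_km * coverage`` km of the half's
    frontage; carcasses there are detected with probability phi and
    removed.  With ``undetected_remain`` False the surveyed stretch is
    cleared entirely (the alternative reading of the count model's
    carryover term).

    Returns one :class:`SurveyRecord` per slot, with the synthetic beach
    code ``N`` or ``S`` and all counts in the adult Tufted puffin column.
    """
    rng = np.random.default_rng(seed)
    dep = deposits if island is None else deposits[deposits["island"] == island]
    if len(schedule) == 0:
        return []
    days = np.array([s.day for s in schedule])
    if len(dep) and dep["day"].min() > days.max():
        raise ValueError("all deposits postdate the survey schedule")

    state = dep[["day", "half"]].copy().reset_index(drop=True)
    state["pos"] = rng.uniform(0.0, frontage_km, len(state))
    state["alive"] = True
    last_day = int(days.max())
    first_day = int(state["day"].min()) if len(state) else 0
    by_day: dict[int, list[SurveySlot]] = {}
    for s in schedule:
        by_day.setdefault(s.day, []).append(s)

    records: list[SurveyRecord] = []
    for d in range(first_day, last_day + 1):
        if len(state):
            res = d - state["day"].to_numpy()
            present = state["alive"].to_numpy() & (res >= 0)
            # survival step for carcasses whose residence just increased
            p_surv = np.where(res == 1, params.rho0, params.rho1)
            roll = rng.random(len(state))
            died = present & (res >= 1) & (roll >= p_surv)
            state.loc[died, "alive"] = False
        for slot in by_day.get(d, []):
            reach = slot.length_km * slot.coverage
            if len(state):
                onb = (
                    state["alive"].to_numpy()
                    & (state["half"].to_numpy() == slot.half)
                    & (state["day"].to_numpy() <= d)
                    & (state["pos"].to_numpy() < reach)
                )
                found = onb & (rng.random(len(state)) < params.phi)
                state.loc[found, "alive"] = False  # collected and removed
                if not undetected_remain:
                    state.loc[onb, "alive"] = False
                n_found = int(found.sum())
            else:
                n_found = 0
            counts = {sp: 0 for sp in SPECIES_COLUMNS}
            counts["TUPU_A"] = n_found
            records.append(
                SurveyRecord(
                    date=dt.date(2000, 1, 1) + dt.timedelta(days=int(d)),
                    beaches=("N",) if slot.half == "north" else ("S",),
                    length_km=slot.length_km * slot.coverage,
                    counts=counts,
                    pct_intact=100.0,
                    ns_split=(100.0, 0.0) if slot.half == "north" else (0.0, 100.0),
                )
            )
    return records
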