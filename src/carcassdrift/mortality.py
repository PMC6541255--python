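"""Total-mortality estimation from beach counts, drift, and detection.

The estimator inverts an observation model for beach-survey counts.  The
expected count on beach ``b`` at survey day ``d`` is

    C_{b,d} = (1 - phi) * rho(d - d') * C_{b,d'}
              + phi * L_b * sum_{i=d'+1..d} rho(d - i) * D_i

(carryover of carcasses missed at the previous survey on day ``d'``, plus
newly deposited carcasses discounted for persistence), where ``phi`` is
detection probability, ``rho(tau)`` is the two-stage persistence function

    rho(tau) = 1 (tau = 0);  rho0 * rho1**(tau - 1)  (tau > 0),

``L_b`` is the surveyed frontage (km), and ``D_i`` the per-km daily
deposition.  Deposition is driven by an effective daily at-sea mortality
M (assumed constant over the releases feeding each count) through the
drift model's proportional deposition P_j(i):

    D_i = (M / L) * sum_{j=i-14..i} P_j(i),

with ``L`` the island frontage presented to the wind (21.8 km).  Solving
the two for M gives the effective-mortality inversion implemented in
:func:`effective_mortality`.  Detection and persistence are uncertain, so
the event total is a Monte Carlo distribution: each permutation draws
(phi, rho0, rho1) from truncated normal priors, inverts every survey
count, averages the daily rate within each island half, multiplies by the
event duration, and sums halves.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catchment import daily_deposition
from .drift_sim import Island
from .float_model import calibrate
from .survey_data import SurveyRecord

log = logging.getLogger(__name__)

__all__ = [
    "ObservationParams",
    "ParamPriors",
    "EventConfig",
    "MortalityEstimate",
    "NoDepositionError",
    "persistence",
    "expected_count",
    "effective_mortality",
    "estimate_event_mortality",
    "scenario_sweep",
]

#: Default beach-to-half assignment for the St. Paul Island survey set
#: (North Beach faces north; Benson, Lukanin and Polovina face south).
DEFAULT_BEACH_HALF = {"NB": "north", "BB": "south", "LB": "south", "PB": "south"}
#: Individual beach frontages (km) implied by the combined survey lengths.
DEFAULT_BEACH_LENGTH = {"NB": 10.0, "BB": 6.5, "LB": 3.1, "PB": 1.9}


class NoDepositionError(RuntimeError):
    """Counts observed where the drift model predicts zero deposition."""


@dataclass(frozen=True)
class ObservationParams:
    """Detection and persistence parameters for one draw."""

    phi: float = 0.53
    rho0: float = 0.755
    rho1: float = 0.895

    def __post_init__(self) -> None:
        for name in ("phi", "rho0", "rho1"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")


@dataclass(frozen=True)
class ParamPriors:
    """Normal priors on detection/persistence, truncated to (0.01, 1].

    Defaults: phi ~ N(0.53, 0.13), rho0 ~ N(0.755, 0.035),
    rho1 ~ N(0.895, 0.045); out-of-range draws are redrawn.
    """

    phi_mean: float = 0.53
    phi_sd: float = 0.13
    rho0_mean: float = 0.755
    rho0_sd: float = 0.035
    rho1_mean: float = 0.895
    rho1_sd: float = 0.045
    lower: float = 0.01
    upper: float = 1.0

    def draw(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        out = {}
        for name, mu, sd in (
            ("phi", self.phi_mean, self.phi_sd),
            ("rho0", self.rho0_mean, self.rho0_sd),
            ("rho1", self.rho1_mean, self.rho1_sd),
        ):
            vals = rng.normal(mu, sd, n)
            bad = (vals <= self.lower) | (vals > self.upper)
            while bad.any():
                vals[bad] = rng.normal(mu, sd, int(bad.sum()))
                bad = (vals <= self.lower) | (vals > self.upper)
            out[name] = vals
        return out


@dataclass
class EventConfig:
    """Event bookkeeping: duration, frontage, halves, permutation count.

    ``event_start`` is day 0 of the shared day clock (the day before the
    first possible deposition day, chosen conservatively); surveys and
    deposition series must be indexed on the same clock.  ``n_day`` is the
    inclusive event duration in days (43 for the 2016 event,
    12 Oct - 23 Nov).
    """

    L: float = 21.8
    event_start: "dt.date | int" = 0
    n_day: int = 43
    n_perm: int = 5000
    seed: int = 0
    beach_half_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_BEACH_HALF)
    )
    beach_lengths: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BEACH_LENGTH)
    )
    weighted_average: bool = False  # effort-weight the per-half mean of M-tilde

    @property
    def event_end_day(self) -> int:
        return self.n_day - 1

    def day_index(self, date: "dt.date | int") -> int:
        if isinstance(date, (int, np.integer)):
            start = self.event_start if isinstance(self.event_start, (int, np.integer)) else 0
            return int(date) - int(start)
        if isinstance(self.event_start, (int, np.integer)):
            raise TypeError("date-based surveys need a date-based event_start")
        return (date - self.event_start).days


@dataclass
class MortalityEstimate:
    """Monte Carlo total-mortality distribution for one scenario."""

    scenario: tuple[float, float]  # (d_max km, float median days)
    draws: np.ndarray
    median: float
    ci50: tuple[float, float]
    ci95: tuple[float, float]
    n_perm: int
    seed: int
    species_scaled: dict[str, float] | None = None

    @classmethod
    def from_draws(cls, draws: np.ndarray, scenario, seed: int,
                   species_fraction: float | None = None) -> "MortalityEstimate":
        q = np.percentile(draws, [2.5, 25, 50, 75, 97.5])
        est = cls(
            scenario=scenario, draws=draws, median=float(q[2]),
            ci50=(float(q[1]), float(q[3])), ci95=(float(q[0]), float(q[4])),
            n_perm=draws.size, seed=seed,
        )
        if species_fraction is not None:
            est.species_scaled = {
                "median": est.median * species_fraction,
                "ci95_low": est.ci95[0] * species_fraction,
                "ci95_high": est.ci95[1] * species_fraction,
            }
        return est


# --------------------------------------------------------------------- #
# persistence and the count model


def persistence(tau, params: ObservationParams):
    """Proportion of beached carcasses still present ``tau`` days on."""
    tau_arr = np.asarray(tau)
    if np.any(tau_arr < 0):
        raise ValueError("residence time must be non-negative")
    out = np.where(
        tau_arr == 0, 1.0, params.rho0 * params.rho1 ** (np.maximum(tau_arr, 1) - 1)
    )
    return float(out) if np.isscalar(tau) or tau_arr.ndim == 0 else out


def expected_count(
    prev_count: float,
    d: int,
    d_prev: int,
    deposition_per_km: Mapping[int, float],
    params: ObservationParams,
    L_b: float,
) -> float:
    """Expected survey count from carryover plus discounted new deposition."""
    if d <= d_prev:
        raise ValueError("survey day must follow the previous survey day")
    carry = (1.0 - params.phi) * persistence(d - d_prev, params) * prev_count
    new = sum(
        persistence(d - i, params) * deposition_per_km.get(i, 0.0)
        for i in range(d_prev + 1, d + 1)
    )
    return carry + params.phi * L_b * new


def effective_mortality(
    count: float,
    prev_count: float,
    d: int,
    d_prev: int,
    dep_daily: Mapping[int, float],
    params: ObservationParams,
    L: float = 21.8,
    L_b: float = 10.0,
) -> float:
    """Invert one survey count to an effective daily at-sea mortality.

    ``dep_daily`` maps deposition day i to sum_j P_j(i) for the half the
    survey belongs to.  Negative numerators (counts below the modelled
    carryover) are floored at zero with a warning.
    """
    carry = (1.0 - params.phi) * persistence(d - d_prev, params) * prev_count
    numer = count - carry
    denom = sum(
        persistence(d - i, params) * dep_daily.get(i, 0.0)
        for i in range(d_prev + 1, d + 1)
    )
    if denom <= 0.0:
        if count > 0 and prev_count == 0:
            raise NoDepositionError(
                f"count {count} on day {d} but modelled deposition is zero"
            )
        return 0.0
    if numer < 0:
        log.warning("day %s: count below modelled carryover; flooring at 0", d)
        numer = 0.0
    return L / (params.phi * L_b) * numer / denom


# --------------------------------------------------------------------- #
# event-level Monte Carlo


@dataclass
class _HalfEntry:
    d: int
    d_prev: int
    count: float
    prev_count: float
    L_b: float


def _survey_half_entries(
    surveys: Sequence[SurveyRecord], config: EventConfig
) -> dict[str, list[_HalfEntry]]:
    """Split surveys into per-half count sequences with chained intervals.

    A survey's count is divided between halves by its recorded N:S split
    when present, otherwise in proportion to the surveyed frontage per
    half; the surveyed frontage itself comes from the per-beach lengths.
    The first survey of a half is anchored at day 0 (event start) with a
    zero previous count.
    """
    entries: dict[str, list[_HalfEntry]] = {"north": [], "south": []}
    last: dict[str, tuple[int, float]] = {}
    for rec in sorted(surveys, key=lambda r: r.date if isinstance(r.date, dt.date) else int(r.date)):
        d = config.day_index(rec.date)
        if d < 1 or d > config.event_end_day:
            continue
        lb = {"north": 0.0, "south": 0.0}
        for b in rec.beaches:
            half = config.beach_half_map.get(b)
            if half is None:
                raise KeyError(f"beach {b!r} missing from beach_half_map")
            lb[half] += config.beach_lengths.get(b, rec.length_km / len(rec.beaches))
        if rec.ns_split is not None:
            frac = {"north": rec.ns_split[0] / 100.0, "south": rec.ns_split[1] / 100.0}
        else:
            tot = lb["north"] + lb["south"]
            frac = {h: lb[h] / tot for h in lb}
        for half in ("north", "south"):
            if lb[half] <= 0.0:
                continue
            d_prev, prev_c = last.get(half, (0, 0.0))
            entries[half].append(
                _HalfEntry(
                    d=d, d_prev=d_prev, count=rec.total * frac[half],
                    prev_count=prev_c, L_b=lb[half],
                )
            )
            last[half] = (d, rec.total * frac[half])
    return entries


def _dep_array(dep: "Mapping[int, float] | pd.Series", n_days: int) -> np.ndarray:
    w = np.zeros(n_days + 1)
    items = dep.items() if hasattr(dep, "items") else dep
    for i, val in items:
        if 0 <= int(i) <= n_days:
            w[int(i)] = float(val)
    return w


def estimate_event_mortality(
    surveys: Sequence[SurveyRecord],
    dep_north: "Mapping[int, float] | pd.Series",
    dep_south: "Mapping[int, float] | pd.Series",
    priors: ParamPriors,
    config: EventConfig,
    scenario: tuple[float, float] = (np.nan, np.nan),
    species_fraction: float | None = None,
) -> MortalityEstimate:
    """Monte Carlo total-mortality estimate for one drift scenario.

    ``dep_north``/``dep_south`` map deposition day (event-clock index) to
    sum_j P_j(i) for each island half.  Each permutation draws detection
    and persistence parameters, inverts every per-half survey count to an
    effective daily mortality, averages within halves, multiplies by the
    event duration, and sums the halves into one total-mortality draw.
    Bit-reproducible for a fixed ``config.seed``.
    """
    if not surveys:
        raise ValueError("no survey records")
    entries = _survey_half_entries(surveys, config)
    if not (entries["north"] or entries["south"]):
        raise ValueError("no surveys fall within the event window")
    rng = np.random.default_rng(config.seed)
    draws = priors.draw(config.n_perm, rng)
    phi, rho0, rho1 = draws["phi"], draws["rho0"], draws["rho1"]

    # persistence matrix over residence times 0..T
    T = config.n_day
    taus = np.arange(T + 1)
    rho_m = np.empty((config.n_perm, T + 1))
    rho_m[:, 0] = 1.0
    rho_m[:, 1:] = rho0[:, None] * rho1[:, None] ** (taus[1:] - 1)

    dep_w = {
        "north": _dep_array(dep_north, config.event_end_day),
        "south": _dep_array(dep_south, config.event_end_day),
    }
    half_mean: dict[str, np.ndarray] = {}
    for half in ("north", "south"):
        if not entries[half]:
            half_mean[half] = np.zeros(config.n_perm)
            continue
        m_rows = []
        weights = []
        for e in entries[half]:
            i_days = np.arange(e.d_prev + 1, e.d + 1)
            w_i = dep_w[half][i_days]
            denom = rho_m[:, e.d - i_days] @ w_i
            carry = (1.0 - phi) * rho_m[:, e.d - e.d_prev] * e.prev_count
            numer = e.count - carry
            if np.all(denom <= 0.0):
                if e.count > 0 and e.prev_count == 0:
                    raise NoDepositionError(
                        f"{half} day {e.d}: count {e.count:.1f} with zero "
                        "modelled deposition"
                    )
                m_rows.append(np.zeros(config.n_perm))
                weights.append(e.L_b)
                continue
            neg = numer < 0
            if neg.any():
                log.debug(
                    "%s day %d: %d/%d permutations floored at 0",
                    half, e.d, int(neg.sum()), config.n_perm,
                )
            numer = np.maximum(numer, 0.0)
            m = config.L / (phi * e.L_b) * numer / denom
            m_rows.append(m)
            weights.append(e.L_b)
        m_arr = np.vstack(m_rows)
        if config.weighted_average:
            w = np.asarray(weights) / np.sum(weights)
            half_mean[half] = w @ m_arr
        else:
            half_mean[half] = m_arr.mean(axis=0)

    total = config.n_day * (half_mean["north"] + half_mean["south"])
    return MortalityEstimate.from_draws(
        total, scenario=scenario, seed=config.seed,
        species_fraction=species_fraction,
    )


def scenario_sweep(
    surveys: Sequence[SurveyRecord],
    particles: pd.DataFrame,
    dmax_list: Iterable[float],
    float_medians: Iterable[float],
    priors: ParamPriors,
    config: EventConfig,
    island: "Island | str" = "SPI",
    split_y: float = 0.0,
    day_offset: int = 0,
    species_fraction: float | None = None,
) -> list[MortalityEstimate]:
    """One mortality estimate per (d_max, float-median) scenario.

    ``day_offset`` converts particle beach days (wind-grid clock) to the
    event clock: event day = beach_day - day_offset.  The same seed is
    used for every scenario (common random draws), so differences between
    scenarios reflect the drift/float inputs, not Monte Carlo noise.
    """
    island_name = island.name if isinstance(island, Island) else island
    if isinstance(island, Island):
        split_y = island.centroid[1]
    out: list[MortalityEstimate] = []
    for fm in float_medians:
        params = calibrate(fm)
        for dmax in dmax_list:
            series = daily_deposition(
                particles, params, dmax, by_half=True, split_y=split_y
            )
            dep_n = {
                int(i) - day_offset: v
                for i, v in series.daily_totals(island_name, "north").items()
            }
            dep_s = {
                int(i) - day_offset: v
                for i, v in series.daily_totals(island_name, "south").items()
            }
            out.append(
                estimate_event_mortality(
                    surveys, dep_n, dep_s, priors, config,
                    scenario=(float(dmax), float(fm)),
                    species_fraction=species_fraction,
                )
            )
    return out
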