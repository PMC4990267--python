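"""Iterative sequential prediction: whole trips from the two-stage model.

A trip is simulated forward: the first-set model chooses the region of the
first set while the vessel is in port; the vessel steams there, and from
then on the switching model is re-evaluated once per day (staying in the
current region is itself a choice) until the trip terminates through
exogenous limits on days at sea, cumulative distance, or hold capacity.

Movement is abstracted.  The steam out to the first-set region runs at a
fixed cruise speed (distance accrues, no sets in transit); thereafter one
switching decision resolves per day: staying means a local roaming hop
within the current region, switching means relocating into the chosen
region within the decision day, so that every set day's observed choice
is an unconditional draw from the model given the previous day's state
(what an estimator reconstructs from the event log).  Catches close the
feedback loop into the trip-state covariates and are drawn from a
pluggable catch model (independent gamma draws by set type and species by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .choice import CoefficientSet, choice_probabilities, size_class
from .features import (
    FeatureConfig,
    FeatureTables,
    TripState,
    month_of,
    update_trip_state,
    x_matrix,
    z_vector,
)
from .regions import GeoPoint, geodesic_km, snap_to_cell_center

#: Default cruise speed: 15 knots for 24 h, ~667 km/day.
CRUISE_KM_PER_DAY = 667.0


@dataclass(frozen=True)
class TerminationRule:
    """Exogenous trip-termination limits.

    ``per_class`` maps a vessel size class to (max_days, max_distance_km);
    a trip also ends when total catch reaches ``capacity_fill_fraction``
    of the vessel's carrying capacity.  Conditions are checked in the
    order days, distance, capacity, and the first one triggered is
    reported as the reason.
    """

    per_class: Mapping[str, tuple[float, float]]
    capacity_fill_fraction: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.capacity_fill_fraction <= 1.0:
            raise ValueError("capacity_fill_fraction must be in (0, 1]")
        for cls_, (d, km) in self.per_class.items():
            if d < 0 or km < 0:
                raise ValueError(f"{cls_}: negative limit")

    def limits(self, capacity_t: float) -> tuple[float, float]:
        return self.per_class[size_class(capacity_t)]


DEFAULT_TERMINATION = TerminationRule(
    per_class={
        "small": (50.0, 12000.0),
        "medium": (75.0, 16000.0),
        "large": (110.0, 20000.0),
        "xlarge": (172.0, 26000.0),
    },
    capacity_fill_fraction=0.9,
)


def should_terminate(
    state: TripState, vessel: Mapping, rule: TerminationRule
) -> tuple[bool, Optional[str]]:
    """Check the termination rule; reason is the first condition triggered."""
    max_days, max_km = rule.limits(float(vessel["capacity_t"]))
    if state.days_since_dep >= max_days:
        return True, "days"
    if state.dist_since_dep >= max_km:
        return True, "distance"
    if state.catch_total() >= rule.capacity_fill_fraction * float(vessel["capacity_t"]):
        return True, "capacity"
    return False, None


class GammaCatchModel:
    """Per-set catch draws: independent gammas by set type and species.

    There is no catch-generation process in the choice model itself; this
    plug-in exists to close the simulation loop for the trip-state
    covariates.  Means are tons per set.
    """

    MEANS = {
        "DEL": {"SKJ": 0.0, "YFT": 16.0, "BET": 0.0},
        "OBJ": {"SKJ": 10.0, "YFT": 1.5, "BET": 2.5},
        "NOA": {"SKJ": 7.0, "YFT": 5.0, "BET": 0.0},
    }
    SHAPE = 3.0

    def sample(self, rng: np.random.Generator, set_type: str) -> dict[str, float]:
        out = {}
        for sp, mean in self.MEANS[set_type].items():
            out[sp] = (
                float(rng.gamma(self.SHAPE, mean / self.SHAPE)) if mean > 0 else 0.0
            )
        return out

    def set_types(self, rng: np.random.Generator, dml: int, n_sets: int) -> list[str]:
        if dml:
            p = {"DEL": 0.7, "OBJ": 0.2, "NOA": 0.1}
        else:
            p = {"DEL": 0.0, "OBJ": 0.65, "NOA": 0.35}
        types = list(p)
        return list(rng.choice(types, size=n_sets, p=[p[t] for t in types]))


def _select(probs: np.ndarray, mode: str, rng: Optional[np.random.Generator]) -> int:
    """Region id per prediction mode; argmax ties break to the lowest id."""
    if mode == "argmax":
        return int(np.argmax(probs)) + 1
    if mode == "sample":
        if rng is None:
            raise ValueError("sample mode needs an rng")
        return int(rng.choice(len(probs), p=probs)) + 1
    raise ValueError(f"unknown mode {mode!r}")


def _utilities(X: np.ndarray, Z: np.ndarray, c: CoefficientSet) -> np.ndarray:
    return X @ c.beta + Z @ c.theta


def predict_first_set(
    vessel: Mapping,
    departure_port: GeoPoint,
    covariates: tuple[np.ndarray, np.ndarray],
    c_first: CoefficientSet,
    mode: str = "argmax",
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, int]:
    """First-set choice probabilities and selected region at departure."""
    X, Z = covariates
    probs = choice_probabilities(_utilities(X, Z, c_first))
    return probs, _select(probs, mode, rng)


def step_switch(
    state: TripState,
    covariates: tuple[np.ndarray, np.ndarray],
    c_switch: CoefficientSet,
    mode: str = "argmax",
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, int]:
    """One switching decision; all R regions (including the current one)."""
    X, Z = covariates
    probs = choice_probabilities(_utilities(X, Z, c_switch))
    return probs, _select(probs, mode, rng)


@dataclass(frozen=True)
class TrajectoryEntry:
    day: int
    date: pd.Timestamp
    region: int
    probabilities: np.ndarray
    position: GeoPoint
    state: TripState


@dataclass
class TripTrajectory:
    """A simulated trip: decisions, daily event-log rows, termination."""

    trip_id: str
    vessel_id: str
    entries: list[TrajectoryEntry] = field(default_factory=list)
    records: list[dict] = field(default_factory=list)
    termination_reason: Optional[str] = None

    @property
    def first_set_region(self) -> int:
        return self.entries[0].region

    @property
    def n_days(self) -> int:
        return len(self.records) - 1

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "trip_id": self.trip_id,
                "day": e.day,
                "region": e.region,
                "lon": e.position.lon,
                "lat": e.position.lat,
                "reason": self.termination_reason if e is self.entries[-1] else "",
            }
            for e in self.entries
        ]
        return pd.DataFrame(rows)


def _day_record(trip_id, vessel_id, date, pos: GeoPoint, hours, sets, catch) -> dict:
    ht, hs, hf = hours
    sd, so, sn = sets
    return {
        "trip_id": trip_id,
        "vessel_id": vessel_id,
        "date": pd.Timestamp(date),
        "lon": pos.lon,
        "lat": pos.lat,
        "hours_travel": ht,
        "hours_search": hs,
        "hours_fish": hf,
        "sets_DEL": sd,
        "sets_OBJ": so,
        "sets_NOA": sn,
        "catch_SKJ_t": catch.get("SKJ", 0.0),
        "catch_YFT_t": catch.get("YFT", 0.0),
        "catch_BET_t": catch.get("BET", 0.0),
    }


def _move_toward(pos: GeoPoint, target: GeoPoint, km: float) -> GeoPoint:
    """Advance up to ``km`` along the straight lon/lat segment to target."""
    d = geodesic_km(pos, target)
    if d <= km:
        return target
    f = km / d
    return GeoPoint(pos.lon + f * (target.lon - pos.lon), pos.lat + f * (target.lat - pos.lat))


def _region_cell_list(rs, rid: int):
    cache = rs.__dict__.get("_cells_cache")
    if cache is None:
        from .regions import region_cells

        cache = rs.__dict__["_cells_cache"] = region_cells(rs)
    return cache[rid]


def _random_cell(rng, rs, rid: int, near: Optional[GeoPoint] = None,
                 radius_deg: float = 2.0) -> GeoPoint:
    """A random 1x1 cell center of region ``rid``, preferring cells near a
    reference position (local roaming / boundary entry)."""
    cells = _region_cell_list(rs, rid)
    if near is not None:
        local = [
            c for c in cells
            if abs(c[0] - near.lon) <= radius_deg and abs(c[1] - near.lat) <= radius_deg
        ]
        if local:
            cells = local
    lon, lat = cells[int(rng.integers(len(cells)))]
    return GeoPoint(lon, lat)


def _fishing_day(rng, catch_model, dml, p_set):
    """(sets tuple, catch dict, hours) for one in-region day."""
    catch = {sp: 0.0 for sp in ("SKJ", "YFT", "BET")}
    sets = [0, 0, 0]
    if rng.random() < p_set:
        n_sets = 1 + int(rng.random() < 0.35)
        for st in catch_model.set_types(rng, dml, n_sets):
            sets[("DEL", "OBJ", "NOA").index(st)] += 1
            for sp, t in catch_model.sample(rng, st).items():
                catch[sp] += t
        hours = (2.0, 10.0, 12.0)
    else:
        hours = (2.0, 22.0, 0.0)
    return tuple(sets), catch, hours


def simulate_trip(
    vessel: Mapping,
    start_date,
    port: GeoPoint,
    tables: FeatureTables,
    c_first: CoefficientSet,
    c_switch: CoefficientSet,
    rule: TerminationRule = DEFAULT_TERMINATION,
    rng: Optional[np.random.Generator] = None,
    catch_model=None,
    mode: str = "sample",
    feature_config: Optional[FeatureConfig] = None,
    trip_id: Optional[str] = None,
    speed_km_day: float = CRUISE_KM_PER_DAY,
    p_set: float = 0.85,
    max_days_guard: int = 400,
) -> TripTrajectory:
    """Simulate one whole trip with the fitted (or ground-truth) models.

    The daily loop re-evaluates the switching model from the previous
    day's trip state, so each set day's observed choice is distributed
    exactly as the conditional logit given the covariates an estimator
    would reconstruct from the emitted event log.  Fully reproducible
    given the rng.
    """
    fc = feature_config or FeatureConfig()
    catch_model = catch_model or GammaCatchModel()
    if mode == "sample" and rng is None:
        raise ValueError("sample mode needs an rng")
    if rng is None:
        rng = np.random.default_rng(0)  # argmax mode: rng only feeds the catch model
    rs = tables.rs
    vid = str(vessel["vessel_id"])
    tid = trip_id or f"{vid}-trip"
    dml = int(vessel["dml"])
    date0 = pd.Timestamp(start_date)
    dep_pos = snap_to_cell_center(port)
    traj = TripTrajectory(trip_id=tid, vessel_id=vid)
    traj.records.append(
        _day_record(tid, vid, date0, dep_pos, (0.0, 0.0, 0.0), (0, 0, 0), {})
    )
    state = TripState.initial(tid, vid, dep_pos, date0)

    m0 = month_of(date0)
    X = x_matrix("first", m0, dep_pos, None, tables, fc)
    Z = z_vector("first", None, date0, tables, fc)
    probs, target = predict_first_set(vessel, dep_pos, (X, Z), c_first, mode, rng)
    traj.entries.append(TrajectoryEntry(0, date0, target, probs, dep_pos, state))

    stop, reason = should_terminate(state, vessel, rule)
    if stop:
        traj.termination_reason = reason
        return traj

    mids = {rid: GeoPoint(*rs.midpoints()[i]) for i, rid in enumerate(rs.region_ids)}
    first_set_done = False
    date = date0
    while True:
        date = date + pd.Timedelta(days=1)
        if not first_set_done:
            # steaming to the first-set region chosen in port
            dist = geodesic_km(state.position, mids[target])
            if dist <= speed_km_day:
                pos = _random_cell(rng, rs, target, near=mids[target], radius_deg=4.0)
                travel_h = 24.0 * dist / speed_km_day
                rest = 24.0 - travel_h
                sets = [0, 0, 0]
                catch = {sp: 0.0 for sp in ("SKJ", "YFT", "BET")}
                n_sets = 1 + int(rng.random() < 0.35)
                for st in catch_model.set_types(rng, dml, n_sets):
                    sets[("DEL", "OBJ", "NOA").index(st)] += 1
                    for sp, t in catch_model.sample(rng, st).items():
                        catch[sp] += t
                rec = _day_record(
                    tid, vid, date, pos, (travel_h, 0.3 * rest, 0.7 * rest), tuple(sets), catch
                )
                first_set_done = True
            else:
                pos = snap_to_cell_center(_move_toward(state.position, mids[target], speed_km_day))
                rec = _day_record(tid, vid, date, pos, (24.0, 0.0, 0.0), (0, 0, 0), {})
        else:
            # daily switching decision from yesterday's state
            X = x_matrix("switch", month_of(date), state.position,
                         snap_to_cell_center(port), tables, fc)
            Z = z_vector("switch", state, date, tables, fc)
            probs, q = step_switch(state, (X, Z), c_switch, mode, rng)
            traj.entries.append(
                TrajectoryEntry(state.day, date, q, probs, state.position, state)
            )
            if q == state.current_region:
                # roam locally within the region, then fish
                pos = _random_cell(rng, rs, q, near=state.position, radius_deg=2.0)
                sets, catch, hours = _fishing_day(rng, catch_model, dml, p_set)
                rec = _day_record(tid, vid, date, pos, hours, sets, catch)
            else:
                # relocate into the chosen region within the decision day
                entry_pos = _random_cell(rng, rs, q, near=mids[q], radius_deg=4.0)
                pos = entry_pos
                sets = [0, 0, 0]
                catch = {sp: 0.0 for sp in ("SKJ", "YFT", "BET")}
                if rng.random() < p_set:
                    n_sets = 1 + int(rng.random() < 0.35)
                    for st in catch_model.set_types(rng, dml, n_sets):
                        sets[("DEL", "OBJ", "NOA").index(st)] += 1
                        for sp, t in catch_model.sample(rng, st).items():
                            catch[sp] += t
                    hours = (14.0, 4.0, 6.0)
                else:
                    hours = (20.0, 4.0, 0.0)
                rec = _day_record(tid, vid, date, pos, hours, tuple(sets), catch)
        state = update_trip_state(state, rec, rs)
        traj.records.append(rec)
        stop, reason = should_terminate(state, vessel, rule)
        if stop:
            traj.termination_reason = reason
            break
        if state.day >= max_days_guard:
            traj.termination_reason = "days"
            break
    return traj
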