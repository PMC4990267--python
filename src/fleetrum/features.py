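"""Covariate construction for the two-stage location-choice models.

Builds every explanatory variable entering the first-set and switching
models from vessel event logs, monthly environmental grids, ex-vessel
prices and the MEI climate series:

* region-varying (``X``) features: lagged log CPUE / RPUE expectations per
  region, log distance cost proxies, and quartile-count environmental
  variables (number of 1x1-degree cells in a region below the first /
  above the third reference quartile of SST, SSH, MLD, O2 at 150 m and
  chlorophyll);
* decision-invariant (``Z``) features: running trip accumulators (distance,
  days, travel/search time, catch by species since departure; travel,
  search, set counts and catch in the last fished region), the monthly MEI
  value and an October-March season dummy.

The same assembly functions are used by the estimation pipeline (building
:class:`ChoiceOccasion` records from logs) and by the forward simulator, so
synthetic data generated by the simulator is, by construction, governed by
exactly the covariates the estimator reconstructs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .regions import (
    GeoPoint,
    RegionSet,
    assign_region,
    expected_distances,
    geodesic_km,
)

ENV_VARS = ("SST", "SSH", "MLD", "O2", "CHLORO")

#: Column order of the quartile-count block, matching the X feature lists.
ENV_COUNT_NAMES = tuple(f"{v}_DEL_{s}" for v in ENV_VARS for s in ("L", "H"))

SPECIES = ("SKJ", "YFT", "BET")
SET_TYPES = ("DEL", "OBJ", "NOA")

#: Event-log CSV schema (one row per vessel-trip-day).
LOG_COLUMNS = [
    "trip_id",
    "vessel_id",
    "date",
    "lon",
    "lat",
    "hours_travel",
    "hours_search",
    "hours_fish",
    "sets_DEL",
    "sets_OBJ",
    "sets_NOA",
    "catch_SKJ_t",
    "catch_YFT_t",
    "catch_BET_t",
]


def month_of(d) -> pd.Period:
    """Calendar month of a date, as a pandas monthly Period."""
    return pd.Period(pd.Timestamp(d), freq="M")


# ---------------------------------------------------------------------------
# Quartile thresholds for the environmental count variables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuartileThresholds:
    """Per-variable (Q1, Q3) reference thresholds, in the variable's units.

    The reference distribution is environmental conditions at
    dolphin-associated (DEL) set locations, which span the fishery widely.
    Cells strictly below Q1 count toward the ``_L`` feature; cells at or
    above Q3 count toward ``_H``.
    """

    thresholds: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for var, (q1, q3) in self.thresholds.items():
            if q1 > q3:
                raise ValueError(f"{var}: q1 {q1} > q3 {q3}")

    def __getitem__(self, var: str) -> tuple[float, float]:
        return self.thresholds[var]

    def __contains__(self, var: str) -> bool:
        return var in self.thresholds

    def merged(self, other: "QuartileThresholds") -> "QuartileThresholds":
        d = dict(self.thresholds)
        d.update(other.thresholds)
        return QuartileThresholds(d)


#: Published reference thresholds (degC, m, m, ml/l).  Chlorophyll has no
#: published thresholds and must be computed from a reference sample via
#: :func:`compute_reference_quartiles`.
DEFAULT_THRESHOLDS = QuartileThresholds(
    {
        "SST": (26.8, 28.7),
        "SSH": (0.6, 0.7),
        "MLD": (18.6, 38.8),
        "O2": (0.4, 1.0),
    }
)


def compute_reference_quartiles(
    env_samples: Mapping[str, Sequence[float]],
) -> QuartileThresholds:
    """(Q1, Q3) per variable from reference samples at DEL-set locations.

    Uses the linear-interpolation quantile convention (NumPy's default,
    "type 7").  Requires at least 4 samples per variable.
    """
    th = {}
    for var, vals in env_samples.items():
        arr = np.asarray(list(vals), dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < 4:
            raise ValueError(f"{var}: need >= 4 samples, got {arr.size}")
        q1, q3 = np.quantile(arr, [0.25, 0.75], method="linear")
        th[var] = (float(q1), float(q3))
    return QuartileThresholds(th)


# ---------------------------------------------------------------------------
# Environmental grids and quartile counts
# ---------------------------------------------------------------------------


@dataclass
class EnvGrid:
    """Monthly 1x1-degree fields, keyed by the cell's lower-left corner."""

    month: pd.Period
    values: dict[str, dict[tuple[int, int], float]]

    @classmethod
    def from_frame(cls, month: pd.Period, frame: pd.DataFrame) -> "EnvGrid":
        """Build from long-format rows (lon, lat, variable, value)."""
        values: dict[str, dict[tuple[int, int], float]] = {}
        for var, sub in frame.groupby("variable"):
            cells = {}
            for lon, lat, val in zip(sub["lon"], sub["lat"], sub["value"]):
                key = (int(math.floor(lon)), int(math.floor(lat)))
                if key in cells:
                    raise ValueError(f"{var} {month}: duplicate cell {key}")
                cells[key] = float(val)
            values[str(var)] = cells
        return cls(month=month, values=values)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, cells in self.values.items():
            for (lon, lat), val in cells.items():
                rows.append((str(self.month), lon, lat, var, val))
        return pd.DataFrame(rows, columns=["month", "lon", "lat", "variable", "value"])


def grids_from_frame(frame: pd.DataFrame) -> dict[pd.Period, EnvGrid]:
    """Split a long-format environment table into per-month grids."""
    out = {}
    frame = frame.copy()
    frame["month"] = frame["month"].map(lambda m: pd.Period(m, freq="M"))
    for month, sub in frame.groupby("month"):
        out[month] = EnvGrid.from_frame(month, sub)
    return out


def _cell_region(lon: int, lat: int, rs: RegionSet) -> Optional[int]:
    """Region of a cell's center, memoized on the RegionSet instance."""
    cache = rs.__dict__.setdefault("_cell_region_cache", {})
    key = (lon, lat)
    if key not in cache:
        cache[key] = assign_region(GeoPoint(lon + 0.5, lat + 0.5), rs)
    return cache[key]


def env_quartile_counts(
    grid: EnvGrid,
    region_id: int,
    rs: RegionSet,
    th: QuartileThresholds,
) -> dict[str, tuple[int, int]]:
    """Per-variable (count_L, count_H) for one region and month.

    count_L counts cells whose center lies in the region with value
    strictly below Q1; count_H counts value >= Q3.  Cells with missing
    values are excluded from both counts.
    """
    out = {}
    for var, cells in grid.values.items():
        if var not in th:
            raise KeyError(f"no thresholds for variable {var!r}")
        q1, q3 = th[var]
        n_lo = n_hi = 0
        for (lon, lat), val in cells.items():
            if not math.isfinite(val):
                continue
            if _cell_region(lon, lat, rs) != region_id:
                continue
            if val < q1:
                n_lo += 1
            elif val >= q3:
                n_hi += 1
        out[var] = (n_lo, n_hi)
    return out


def build_env_count_table(
    grids: Mapping[pd.Period, EnvGrid],
    rs: RegionSet,
    th: QuartileThresholds,
) -> dict[pd.Period, np.ndarray]:
    """Precompute quartile counts: month -> (R, 10) array.

    Columns follow :data:`ENV_COUNT_NAMES`; rows follow region order.
    """
    out = {}
    idx = {rid: i for i, rid in enumerate(rs.region_ids)}
    for month, grid in grids.items():
        tab = np.zeros((rs.R, len(ENV_COUNT_NAMES)))
        for v, var in enumerate(ENV_VARS):
            if var not in grid.values:
                continue
            q1, q3 = th[var]
            for (lon, lat), val in grid.values[var].items():
                if not math.isfinite(val):
                    continue
                rid = _cell_region(lon, lat, rs)
                if rid is None:
                    continue
                if val < q1:
                    tab[idx[rid], 2 * v] += 1
                elif val >= q3:
                    tab[idx[rid], 2 * v + 1] += 1
        out[month] = tab
    return out


# ---------------------------------------------------------------------------
# Prices and lagged CPUE / RPUE regional expectations
# ---------------------------------------------------------------------------


@dataclass
class PriceSeries:
    """Monthly ex-vessel prices ($/t): YFTP and SKJP by month.

    The juvenile bigeye price is not separately quoted; it is taken as
    SKJP + 100 $/t.
    """

    frame: pd.DataFrame  # index: Period[M]; columns YFTP, SKJP

    def __post_init__(self) -> None:
        self.frame = self.frame.copy()
        self.frame.index = pd.PeriodIndex(self.frame.index, freq="M")
        if (self.frame[["YFTP", "SKJP"]] <= 0).any().any():
            raise ValueError("prices must be positive")

    def get(self, month: pd.Period) -> tuple[float, float, float]:
        """(YFTP, SKJP, BETP) for a month; raises KeyError if absent."""
        if month not in self.frame.index:
            raise KeyError(f"no prices for month {month}")
        row = self.frame.loc[month]
        return float(row["YFTP"]), float(row["SKJP"]), float(row["SKJP"]) + 100.0


#: Floor for the RPUE log argument when a region-month had zero revenue.
RPUE_LOG_FLOOR = 1e-12


def lagged_cpue(catch_by_species: Mapping[str, float], days_fished: float,
                month: Optional[pd.Period] = None) -> float:
    """Log regional CPUE expectation: ln((YFT+BET+SKJ)/(DF+1e-4) + 1e-4).

    Computed from one region-month's totals and used as the expectation
    covariate in the *following* month (one-month lag).  The 1e-4 offsets
    guard zero effort and zero catch.
    """
    total = sum(float(catch_by_species.get(sp, 0.0)) for sp in SPECIES)
    if total < 0 or days_fished < 0:
        raise ValueError("catches and days fished must be nonnegative")
    return math.log(total / (days_fished + 1e-4) + 1e-4)


def lagged_rpue(catch_by_species: Mapping[str, float], days_fished: float,
                prices: PriceSeries, month: pd.Period) -> float:
    """Log regional RPUE expectation for the following month.

    ln((YFT*YFTP + BET*(SKJP+100) + SKJ*SKJP)/(DF + 1e-5)); the offset
    guards only the divisor, so a zero-revenue region-month is floored at
    ln(1e-12) rather than raising on log(0).
    """
    yftp, skjp, betp = prices.get(month)
    rev = (
        float(catch_by_species.get("YFT", 0.0)) * yftp
        + float(catch_by_species.get("BET", 0.0)) * betp
        + float(catch_by_species.get("SKJ", 0.0)) * skjp
    )
    if rev < 0 or days_fished < 0:
        raise ValueError("revenue and days fished must be nonnegative")
    return math.log(max(rev / (days_fished + 1e-5), RPUE_LOG_FLOOR))


def region_month_stats(
    logs: pd.DataFrame,
    rs: RegionSet,
    prices: PriceSeries,
) -> pd.DataFrame:
    """Aggregate event logs into lagged regional CPUE/RPUE expectations.

    Returns one row per (month, region_id) with columns ``cpue_lag1`` and
    ``rpue_lag1`` attached to the month *after* the totals were observed,
    plus the source-month totals (``days_fished``, catch by species).
    Region-months with no records yield the degenerate zero-catch values
    of the formulas when looked up via :class:`FeatureTables`.
    """
    logs = logs.copy()
    logs["date"] = pd.to_datetime(logs["date"])
    logs["month"] = logs["date"].dt.to_period("M")
    logs["region_id"] = [
        _cell_region(int(math.floor(lon)), int(math.floor(lat)), rs)
        for lon, lat in zip(logs["lon"], logs["lat"])
    ]
    logs = logs[logs["region_id"].notna()]
    rows = []
    grouped = logs.groupby(["month", "region_id"])
    for (month, rid), sub in grouped:
        catch = {sp: float(sub[f"catch_{sp}_t"].sum()) for sp in SPECIES}
        df_days = float(sub["hours_fish"].sum()) / 24.0
        rows.append(
            {
                "month": month + 1,
                "region_id": int(rid),
                "cpue_lag1": lagged_cpue(catch, df_days),
                "rpue_lag1": lagged_rpue(catch, df_days, prices, month),
                "days_fished": df_days,
                **{f"catch_{sp}_t": catch[sp] for sp in SPECIES},
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Seasonal / climate covariates
# ---------------------------------------------------------------------------


def seasonal_and_climate_covariates(d, mei_series: pd.Series) -> tuple[int, float]:
    """(oct_mar dummy, MEI value) for the month of a date.

    ``oct_mar`` is 1 for October through March inclusive.  ``mei_series``
    is indexed by monthly Period; a missing month raises KeyError.
    """
    ts = pd.Timestamp(d)
    oct_mar = 1 if (ts.month >= 10 or ts.month <= 3) else 0
    m = month_of(ts)
    if m not in mei_series.index:
        raise KeyError(f"no MEI value for month {m}")
    return oct_mar, float(mei_series.loc[m])


# ---------------------------------------------------------------------------
# Trip state accumulators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TripState:
    """Running accumulators for one trip, updated from daily records.

    The ``*_last`` block refers to the region the vessel is currently in
    and resets to zero whenever the region of a new daily record differs
    from the current region.
    """

    trip_id: str
    vessel_id: str
    departure_date: pd.Timestamp
    day: int
    date: pd.Timestamp
    position: GeoPoint
    dist_since_dep: float = 0.0
    days_since_dep: float = 0.0
    travel_days_since_dep: float = 0.0
    search_days_since_dep: float = 0.0
    catch_since_dep: tuple[float, float, float] = (0.0, 0.0, 0.0)  # SKJ, YFT, BET
    travel_days_last: float = 0.0
    search_days_last: float = 0.0
    sets_last: tuple[float, float, float] = (0.0, 0.0, 0.0)  # DEL, OBJ, NOA
    catch_last: tuple[float, float, float] = (0.0, 0.0, 0.0)
    current_region: Optional[int] = None

    @classmethod
    def initial(cls, trip_id, vessel_id, position: GeoPoint, date) -> "TripState":
        ts = pd.Timestamp(date)
        return cls(
            trip_id=str(trip_id),
            vessel_id=str(vessel_id),
            departure_date=ts,
            day=0,
            date=ts,
            position=position,
        )

    def catch_total(self) -> float:
        return float(sum(self.catch_since_dep))


def update_trip_state(s: TripState, day_record: Mapping, rs: RegionSet) -> TripState:
    """Advance a TripState by one daily event-log record.

    Distance accrues between consecutive daily positions via the
    great-circle metric; activity hours convert to days.  The last-region
    block resets iff the record's region differs from the current one.
    Records must advance strictly in time.
    """
    date = pd.Timestamp(day_record["date"])
    if date <= s.date:
        raise ValueError(
            f"trip {s.trip_id}: out-of-order record {date.date()} after {s.date.date()}"
        )
    pos = GeoPoint(float(day_record["lon"]), float(day_record["lat"]))
    step_km = geodesic_km(s.position, pos)
    rid = assign_region(pos, rs)
    changed = rid is not None and rid != s.current_region
    travel_d = float(day_record.get("hours_travel", 0.0)) / 24.0
    search_d = float(day_record.get("hours_search", 0.0)) / 24.0
    catch = tuple(float(day_record.get(f"catch_{sp}_t", 0.0)) for sp in SPECIES)
    sets = tuple(float(day_record.get(f"sets_{st}", 0.0)) for st in SET_TYPES)
    base_last = (
        (0.0, 0.0, 0.0, 0.0, (0.0, 0.0, 0.0), (0.0, 0.0, 0.0))
        if changed
        else (
            s.travel_days_last,
            s.search_days_last,
            0.0,
            0.0,
            s.sets_last,
            s.catch_last,
        )
    )
    return replace(
        s,
        day=s.day + 1,
        date=date,
        position=pos,
        dist_since_dep=s.dist_since_dep + step_km,
        days_since_dep=float((date - s.departure_date).days),
        travel_days_since_dep=s.travel_days_since_dep + travel_d,
        search_days_since_dep=s.search_days_since_dep + search_d,
        catch_since_dep=tuple(
            a + b for a, b in zip(s.catch_since_dep, catch)
        ),
        travel_days_last=base_last[0] + travel_d,
        search_days_last=base_last[1] + search_d,
        sets_last=tuple(a + b for a, b in zip(base_last[4], sets)),
        catch_last=tuple(a + b for a, b in zip(base_last[5], catch)),
        current_region=rid if rid is not None else s.current_region,
    )


# ---------------------------------------------------------------------------
# Feature configuration and occasion assembly
# ---------------------------------------------------------------------------

X_FIRST_DEFAULT = ("CPUE_1", "RPUE_1", "Dist_Exp") + ENV_COUNT_NAMES
X_SWITCH_DEFAULT = ("CPUE_1", "RPUE_1", "Dist_Exp", "Dist_Arr") + ENV_COUNT_NAMES

# Trip accumulators are identically zero at the moment of departure, so the
# default first-stage Z block carries only the covariates that vary across
# departure occasions.  The lists are configurable.
Z_FIRST_DEFAULT = ("MEI", "Oct_Mar")
Z_SWITCH_DEFAULT = (
    "Dist_Dep",
    "DF_Dep",
    "DF_Travel_Dep",
    "MEI",
    "DF_Search_Dep",
    "SKJ_Dep",
    "YFT_Dep",
    "BET_Dep",
    "DF_Travel_Last",
    "DF_Search_Last",
    "DEL_Last",
    "OBJ_Last",
    "NOA_Last",
    "SKJ_Last",
    "YFT_Last",
    "BET_Last",
    "Oct_Mar",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Which X and Z features each stage uses, in design-matrix order."""

    x_first: tuple[str, ...] = X_FIRST_DEFAULT
    z_first: tuple[str, ...] = Z_FIRST_DEFAULT
    x_switch: tuple[str, ...] = X_SWITCH_DEFAULT
    z_switch: tuple[str, ...] = Z_SWITCH_DEFAULT

    def x_names(self, stage: str) -> tuple[str, ...]:
        return self.x_first if stage == "first" else self.x_switch

    def z_names(self, stage: str) -> tuple[str, ...]:
        return self.z_first if stage == "first" else self.z_switch


@dataclass(frozen=True)
class ChoiceOccasion:
    """One decision instance: R alternatives, X/Z covariates, one choice."""

    occasion_id: str
    trip_id: str
    vessel_id: str
    stage: str  # "first" | "switch"
    date: pd.Timestamp
    X: np.ndarray  # (R, K), rows in region order
    x_names: tuple[str, ...]
    Z: np.ndarray  # (J,)
    z_names: tuple[str, ...]
    chosen: int  # region_id with Decision = 1

    @property
    def R(self) -> int:
        return self.X.shape[0]


class FeatureTables:
    """Precomputed per-month lookups shared by estimator and simulator."""

    def __init__(
        self,
        rs: RegionSet,
        stats: pd.DataFrame,
        env_counts: Mapping[pd.Period, np.ndarray],
        mei: pd.Series,
    ):
        self.rs = rs
        self.env_counts = dict(env_counts)
        self.mei = mei
        self._idx = {rid: i for i, rid in enumerate(rs.region_ids)}
        self._cpue: dict[pd.Period, np.ndarray] = {}
        self._rpue: dict[pd.Period, np.ndarray] = {}
        cpue_fill = lagged_cpue({}, 0.0)
        rpue_fill = math.log(RPUE_LOG_FLOOR)
        stats = stats.copy()
        stats["month"] = stats["month"].map(lambda m: pd.Period(m, freq="M"))
        for month, sub in stats.groupby("month"):
            c = np.full(rs.R, cpue_fill)
            r = np.full(rs.R, rpue_fill)
            for rid, cv, rv in zip(sub["region_id"], sub["cpue_lag1"], sub["rpue_lag1"]):
                c[self._idx[int(rid)]] = cv
                r[self._idx[int(rid)]] = rv
            self._cpue[month] = c
            self._rpue[month] = r

    def cpue(self, month: pd.Period) -> np.ndarray:
        if month not in self._cpue:
            raise KeyError(f"no regional CPUE stats for month {month}")
        return self._cpue[month]

    def rpue(self, month: pd.Period) -> np.ndarray:
        return self._rpue[month]

    def counts(self, month: pd.Period) -> np.ndarray:
        if month not in self.env_counts:
            raise KeyError(f"no environmental counts for month {month}")
        return self.env_counts[month]


def x_matrix(
    stage: str,
    month: pd.Period,
    position: GeoPoint,
    arrival_port: Optional[GeoPoint],
    tables: FeatureTables,
    fc: FeatureConfig,
) -> np.ndarray:
    """(R, K) region-varying covariate matrix for one occasion.

    Distances enter as ln(1 + km), consistent with the log specification
    of the models; CPUE/RPUE are already on the log scale; environmental
    quartile counts enter as raw cell counts.
    """
    rs = tables.rs
    names = fc.x_names(stage)
    cols = []
    counts = None
    for name in names:
        if name == "CPUE_1":
            cols.append(tables.cpue(month))
        elif name == "RPUE_1":
            cols.append(tables.rpue(month))
        elif name == "Dist_Exp":
            cols.append(np.log1p(expected_distances(position, rs)))
        elif name == "Dist_Arr":
            if arrival_port is None:
                raise ValueError("Dist_Arr requested but no arrival port given")
            cols.append(np.log1p(expected_distances(arrival_port, rs)))
        elif name in ENV_COUNT_NAMES:
            if counts is None:
                counts = tables.counts(month)
            cols.append(counts[:, ENV_COUNT_NAMES.index(name)])
        else:
            raise KeyError(f"unknown X feature {name!r}")
    return np.column_stack(cols)


def z_vector(
    stage: str,
    state: Optional[TripState],
    d,
    tables: FeatureTables,
    fc: FeatureConfig,
) -> np.ndarray:
    """(J,) decision-invariant covariate vector for one occasion.

    Accumulators with unbounded natural scales (km, days, tons) enter as
    ln(1 + value); small set counts, the MEI and the season dummy enter
    raw.  A ``None`` state (pre-departure) yields zero accumulators.
    """
    oct_mar, mei = seasonal_and_climate_covariates(d, tables.mei)
    vals = []
    for name in fc.z_names(stage):
        if name == "MEI":
            vals.append(mei)
        elif name == "Oct_Mar":
            vals.append(float(oct_mar))
        elif state is None:
            vals.append(0.0)
        elif name == "Dist_Dep":
            vals.append(math.log1p(state.dist_since_dep))
        elif name == "DF_Dep":
            vals.append(math.log1p(state.days_since_dep))
        elif name == "DF_Travel_Dep":
            vals.append(math.log1p(state.travel_days_since_dep))
        elif name == "DF_Search_Dep":
            vals.append(math.log1p(state.search_days_since_dep))
        elif name in ("SKJ_Dep", "YFT_Dep", "BET_Dep"):
            vals.append(math.log1p(state.catch_since_dep[("SKJ_Dep", "YFT_Dep", "BET_Dep").index(name)]))
        elif name == "DF_Travel_Last":
            vals.append(math.log1p(state.travel_days_last))
        elif name == "DF_Search_Last":
            vals.append(math.log1p(state.search_days_last))
        elif name in ("DEL_Last", "OBJ_Last", "NOA_Last"):
            vals.append(state.sets_last[("DEL_Last", "OBJ_Last", "NOA_Last").index(name)])
        elif name in ("SKJ_Last", "YFT_Last", "BET_Last"):
            vals.append(math.log1p(state.catch_last[("SKJ_Last", "YFT_Last", "BET_Last").index(name)]))
        else:
            raise KeyError(f"unknown Z feature {name!r}")
    return np.array(vals, dtype=float)


def build_choice_occasions(
    trip_logs: pd.DataFrame,
    rs: RegionSet,
    grids: Mapping[pd.Period, EnvGrid],
    stats: pd.DataFrame,
    prices: PriceSeries,
    mei: pd.Series,
    registry: pd.DataFrame,
    thresholds: QuartileThresholds = None,
    feature_config: FeatureConfig = None,
    env_counts: Mapping[pd.Period, np.ndarray] = None,
) -> list[ChoiceOccasion]:
    """Turn daily event logs into first-stage and switch-stage occasions.

    Per trip: exactly one first-stage occasion (covariates evaluated at the
    departure position, chosen alternative = region of the trip's first
    set) and one switch-stage occasion per later day carrying at least one
    set, with covariates evaluated from the previous day's
    :class:`TripState`.  Trips with no sets are skipped with a warning.
    """
    fc = feature_config or FeatureConfig()
    th = thresholds or DEFAULT_THRESHOLDS
    if env_counts is None:
        env_counts = build_env_count_table(grids, rs, th)
    tables = FeatureTables(rs, stats, env_counts, mei)
    ports = {
        str(v): GeoPoint(float(lo), float(la))
        for v, lo, la in zip(
            registry["vessel_id"], registry["port_lon"], registry["port_lat"]
        )
    }
    logs = trip_logs.copy()
    logs["date"] = pd.to_datetime(logs["date"])
    logs = logs.sort_values(["trip_id", "date"])
    occasions: list[ChoiceOccasion] = []
    for trip_id, trip in logs.groupby("trip_id", sort=True):
        recs = trip.to_dict("records")
        vessel_id = str(recs[0]["vessel_id"])
        arrival_port = ports[vessel_id]
        sets_total = [
            sum(r.get(f"sets_{st}", 0) for st in SET_TYPES) for r in recs
        ]
        set_days = [i for i, n in enumerate(sets_total) if n > 0]
        if not set_days:
            warnings.warn(f"trip {trip_id}: no sets; skipped")
            continue
        dep = recs[0]
        dep_pos = GeoPoint(float(dep["lon"]), float(dep["lat"]))
        first_i = set_days[0]
        first_rec = recs[first_i]
        chosen_first = assign_region(
            GeoPoint(float(first_rec["lon"]), float(first_rec["lat"])), rs
        )
        if chosen_first is None:
            warnings.warn(f"trip {trip_id}: first set outside partition; skipped")
            continue
        dep_month = month_of(dep["date"])
        occasions.append(
            ChoiceOccasion(
                occasion_id=f"{trip_id}:first",
                trip_id=str(trip_id),
                vessel_id=vessel_id,
                stage="first",
                date=pd.Timestamp(dep["date"]),
                X=x_matrix("first", dep_month, dep_pos, None, tables, fc),
                x_names=fc.x_names("first"),
                Z=z_vector("first", None, dep["date"], tables, fc),
                z_names=fc.z_names("first"),
                chosen=int(chosen_first),
            )
        )
        state = TripState.initial(trip_id, vessel_id, dep_pos, dep["date"])
        for i, rec in enumerate(recs[1:], start=1):
            if i > first_i and sets_total[i] > 0:
                chosen = assign_region(
                    GeoPoint(float(rec["lon"]), float(rec["lat"])), rs
                )
                if chosen is not None:
                    m = month_of(rec["date"])
                    occasions.append(
                        ChoiceOccasion(
                            occasion_id=f"{trip_id}:d{i}",
                            trip_id=str(trip_id),
                            vessel_id=vessel_id,
                            stage="switch",
                            date=pd.Timestamp(rec["date"]),
                            X=x_matrix("switch", m, state.position, arrival_port, tables, fc),
                            x_names=fc.x_names("switch"),
                            Z=z_vector("switch", state, rec["date"], tables, fc),
                            z_names=fc.z_names("switch"),
                            chosen=int(chosen),
                        )
                    )
            state = update_trip_state(state, rec, rs)
    return occasions
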