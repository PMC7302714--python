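"""Survey-data ingestion: reading, validating and aligning the four
observation channels of the deer monitoring programme onto the bimonthly grid.

Channels
--------
road counts
    Deer sighted from a vehicle on fixed route sectors A, B, E; per period
    ``t`` and route ``m`` a total count ``C[t, m]`` over ``O[t, m]`` survey
    occasions.  A route covers a thin strip whose area is a fixed fraction
    ``A_c[m]`` of the forest.
block counts
    Exhaustive December ground counts over contiguous terrain blocks;
    assigned to the winter-transition period the following spring, with the
    surveyed fraction ``A_b`` of the forest.
harvest
    Deer removed by nuisance control per period, with hunting effort
    (hunters x days).  The harvest likelihood starts at ``t = 2``.
carcass counts
    Carcasses found at spring thaw, per winter, with the survey distance and
    the two snow covariates (SD50: days with snow depth > 50 cm; MaxS:
    maximum snow depth in cm).

The canonical on-disk layout is long-format CSV with explicit year / season
columns; winter channels are keyed by the calendar year of the May-Jun
period the winter transitions into (the winter Nov 2007 - Mar 2008 has key
2008).
"""

from __future__ import annotations

import importlib.resources
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .timegrid import Season, TimeIndex

logger = logging.getLogger(__name__)

ROUTES: tuple[str, ...] = ("A", "B", "E")

#: total forest area of the study site (research station + surroundings), km^2
FOREST_AREA_KM2 = 46.12
#: route sector lengths, km
ROUTE_LENGTHS_KM = {"A": 4.7, "B": 3.3, "E": 0.7}
#: assumed census strip width either side of the vehicle, m
CENSUS_WIDTH_M = 15.0
#: total block-count area in a full survey year, ha
BLOCK_AREA_HA = 181.27


@dataclass
class StudyConfig:
    """Geometry and ingestion options for the study site.

    ``carcass_width_m`` is the effective strip width of the thaw carcass
    search; it is not measured by the programme, so only the product of the
    carcass detection rate and the strip area is identified — rescaling the
    width rescales the fitted detection rate inversely.
    """

    forest_area_km2: float = FOREST_AREA_KM2
    route_lengths_km: dict[str, float] = field(
        default_factory=lambda: dict(ROUTE_LENGTHS_KM)
    )
    census_width_m: float = CENSUS_WIDTH_M
    carcass_width_m: float = 50.0
    route_ratio_overrides: dict[str, float] = field(default_factory=dict)
    block_rounding: str = "half-up"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    def route_area_ratios(self) -> dict[str, float]:
        ratios = compute_area_ratios(
            self.route_lengths_km, self.census_width_m, self.forest_area_km2
        )
        ratios.update(self.route_ratio_overrides)
        return ratios


@dataclass
class SurveyData:
    """All observation channels aligned to a :class:`TimeIndex`.

    Road arrays have shape ``(T, M)``; winter arrays have one entry per
    winter-transition period (``time.winter_transitions``), harvest/effort
    are length ``T`` with index 0 (``t = 1``) outside the likelihood.
    """

    time: TimeIndex
    routes: tuple[str, ...]
    road_counts: np.ndarray
    road_occasions: np.ndarray
    route_area_ratio: np.ndarray
    block_counts: np.ndarray
    block_area_ratio: np.ndarray
    harvest: np.ndarray
    effort: np.ndarray
    carcasses: np.ndarray
    carcass_area_ratio: np.ndarray
    snow_days: np.ndarray
    snow_max: np.ndarray

    def __post_init__(self) -> None:
        T, W, M = self.time.T, self.time.n_winters, len(self.routes)
        self.road_counts = np.asarray(self.road_counts, dtype=np.int64)
        self.road_occasions = np.asarray(self.road_occasions, dtype=np.int64)
        self.route_area_ratio = np.asarray(self.route_area_ratio, dtype=float)
        self.block_counts = np.asarray(self.block_counts, dtype=np.int64)
        self.block_area_ratio = np.asarray(self.block_area_ratio, dtype=float)
        self.harvest = np.asarray(self.harvest, dtype=np.int64)
        self.effort = np.asarray(self.effort, dtype=float)
        self.carcasses = np.asarray(self.carcasses, dtype=np.int64)
        self.carcass_area_ratio = np.asarray(self.carcass_area_ratio, dtype=float)
        self.snow_days = np.asarray(self.snow_days, dtype=float)
        self.snow_max = np.asarray(self.snow_max, dtype=float)
        shapes = {
            "road_counts": (self.road_counts, (T, M)),
            "road_occasions": (self.road_occasions, (T, M)),
            "route_area_ratio": (self.route_area_ratio, (M,)),
            "block_counts": (self.block_counts, (W,)),
            "block_area_ratio": (self.block_area_ratio, (W,)),
            "harvest": (self.harvest, (T,)),
            "effort": (self.effort, (T,)),
            "carcasses": (self.carcasses, (W,)),
            "carcass_area_ratio": (self.carcass_area_ratio, (W,)),
            "snow_days": (self.snow_days, (W,)),
            "snow_max": (self.snow_max, (W,)),
        }
        problems = [
            f"{name}: shape {arr.shape} != {want}"
            for name, (arr, want) in shapes.items()
            if arr.shape != want
        ]
        if problems:
            raise ValueError("misaligned SurveyData arrays: " + "; ".join(problems))

    @property
    def winter_index(self) -> np.ndarray:
        """0-based period indices of the winter-transition periods."""
        return np.asarray(self.time.winter_transitions, dtype=np.int64) - 1

    def validate(self) -> None:
        """Raise ``ValueError`` listing every violated invariant at once."""
        errors: list[str] = []
        for name in ("road_counts", "road_occasions", "block_counts", "harvest",
                     "carcasses", "effort", "snow_days", "snow_max"):
            if np.any(getattr(self, name) < 0):
                errors.append(f"negative values in {name}")
        for name in ("route_area_ratio", "block_area_ratio", "carcass_area_ratio"):
            ratio = getattr(self, name)
            if np.any(ratio <= 0.0) or np.any(ratio >= 1.0):
                errors.append(f"{name} must lie strictly in (0, 1)")
        # counts recorded with zero occasions carry no likelihood information
        bad = (self.road_occasions == 0) & (self.road_counts > 0)
        if np.any(bad):
            errors.append(
                f"road counts > 0 with zero survey occasions at {int(bad.sum())} cells"
            )
        if errors:
            raise ValueError("invalid SurveyData: " + "; ".join(errors))


# ---------------------------------------------------------------------------
# geometry helpers


def compute_area_ratios(
    route_lengths_km: Mapping[str, float],
    census_width_m: float,
    forest_area_km2: float,
) -> dict[str, float]:
    """Fraction of forest area covered by each road-count strip.

    ``ratio = length * width / forest_area``; with the study geometry
    (routes 4.7 / 3.3 / 0.7 km, 15 m width, 46.12 km^2 forest) this gives
    0.153%, 0.107% and 0.023% for routes A, B and E.
    """
    if census_width_m <= 0:
        raise ValueError("census width must be positive")
    if forest_area_km2 <= 0:
        raise ValueError("forest area must be positive")
    out: dict[str, float] = {}
    for route, length_km in route_lengths_km.items():
        if length_km <= 0:
            raise ValueError(f"route {route}: length must be positive")
        ratio = (length_km * census_width_m / 1000.0) / forest_area_km2
        if ratio >= 1.0:
            raise ValueError(f"route {route}: strip covers the whole forest")
        out[route] = ratio
    return out


def compute_carcass_area_ratio(
    distance_km: np.ndarray | float,
    carcass_width_m: float,
    forest_area_km2: float,
) -> np.ndarray:
    """Fraction of forest covered by the thaw carcass search each winter."""
    if carcass_width_m <= 0 or forest_area_km2 <= 0:
        raise ValueError("carcass width and forest area must be positive")
    distance_km = np.atleast_1d(np.asarray(distance_km, dtype=float))
    if np.any(distance_km <= 0):
        raise ValueError("survey distance must be positive")
    ratio = distance_km * (carcass_width_m / 1000.0) / forest_area_km2
    if np.any(ratio >= 1.0):
        raise ValueError("carcass survey strip must cover less than the forest")
    return ratio


# ---------------------------------------------------------------------------
# block-count imputation


def impute_block_count(
    series: Mapping[int, float | int | None],
    year: int = 2017,
    rounding: str = "half-up",
) -> dict[int, int]:
    """Fill a single missing block-count year with the mean of its neighbours.

    The December 2017 block count was not conducted; because the neighbouring
    years changed little, the study uses the 2016/2018 mean.  The result is
    rounded to an integer (the block channel is Poisson): 'half-up' (default)
    or 'nearest-even'.
    """
    out = {y: v for y, v in series.items() if v is not None}
    if year in out:
        return {y: int(round(v)) for y, v in out.items()}
    lo, hi = year - 1, year + 1
    if lo not in out or hi not in out:
        raise ValueError(f"cannot impute {year}: need both {lo} and {hi}")
    mean = 0.5 * (out[lo] + out[hi])
    if rounding == "half-up":
        imputed = int(math.floor(mean + 0.5))
    elif rounding == "nearest-even":
        imputed = int(round(mean))
    else:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    out[year] = imputed
    return {y: int(round(v)) for y, v in sorted(out.items())}


# ---------------------------------------------------------------------------
# packaged study tables


def _fixture_path(name: str) -> Path:
    return Path(str(importlib.resources.files("deerssm") / "fixtures" / name))


def load_harvest_table() -> pd.DataFrame:
    """Nuisance-control harvest and effort per period, 2007-2018."""
    return pd.read_csv(_fixture_path("harvest_table.csv"))


def load_winter_table() -> pd.DataFrame:
    """Carcass counts, thaw-survey distance and snow covariates per winter.

    Keyed by the calendar year the winter transitions into (2008..2018).
    """
    return pd.read_csv(_fixture_path("winter_table.csv"))


# ---------------------------------------------------------------------------
# canonical long-format readers / writers


def load_survey_tables(
    road_file: str | Path,
    block_file: str | Path,
    harvest_file: str | Path,
    carcass_file: str | Path,
    config: StudyConfig | None = None,
    time: TimeIndex | None = None,
) -> SurveyData:
    """Read the four channels from long-format CSV and align them.

    Road file: ``year, season, route, count, occasions`` — missing (t, route)
    rows become zero occasions (no survey).  Block file: ``year, count`` plus
    either ``area_ratio`` or ``area_ha``.  Harvest file: ``year, season,
    harvest, effort``.  Carcass file: ``year, carcasses, sd50_days, maxs_cm``
    plus either ``area_ratio`` or ``distance_km``.  Validation problems are
    aggregated and raised together.
    """
    config = config or StudyConfig()
    time = time or TimeIndex(2007, 12)
    T, W = time.T, time.n_winters
    winter_years = [time.year(t) for t in time.winter_transitions]
    errors: list[str] = []

    road = pd.read_csv(road_file)
    C = np.zeros((T, len(ROUTES)), dtype=np.int64)
    O = np.zeros((T, len(ROUTES)), dtype=np.int64)
    if road.empty:
        warnings.warn("road file has no records; all occasions set to 0")
    for _, row in road.iterrows():
        route = str(row["route"]).strip().upper()
        if route not in ROUTES:
            errors.append(f"unknown route label {route!r}")
            continue
        try:
            t = time.t_of(int(row["year"]), Season(str(row["season"])))
        except (ValueError, IndexError) as exc:
            errors.append(f"road row {row.to_dict()}: {exc}")
            continue
        m = ROUTES.index(route)
        C[t - 1, m] = int(row["count"])
        O[t - 1, m] = int(row["occasions"])

    harvest_df = pd.read_csv(harvest_file)
    H = np.zeros(T, dtype=np.int64)
    Ef = np.zeros(T, dtype=float)
    for _, row in harvest_df.iterrows():
        try:
            t = time.t_of(int(row["year"]), Season(str(row["season"])))
        except (ValueError, IndexError) as exc:
            errors.append(f"harvest row {row.to_dict()}: {exc}")
            continue
        H[t - 1] = int(row["harvest"])
        Ef[t - 1] = float(row["effort"])

    block_df = pd.read_csv(block_file).set_index("year")
    B = np.zeros(W, dtype=np.int64)
    A_b = np.zeros(W, dtype=float)
    for w, year in enumerate(winter_years):
        if year not in block_df.index:
            errors.append(f"block file missing winter year {year}")
            continue
        row = block_df.loc[year]
        B[w] = int(row["count"])
        if "area_ratio" in block_df.columns and not pd.isna(row.get("area_ratio")):
            A_b[w] = float(row["area_ratio"])
        else:
            A_b[w] = float(row["area_ha"]) / 100.0 / config.forest_area_km2
    extra = set(block_df.index) - set(winter_years)
    if extra:
        errors.append(f"block counts at non-winter years {sorted(extra)}")

    carcass_df = pd.read_csv(carcass_file).set_index("year")
    D = np.zeros(W, dtype=np.int64)
    A_d = np.zeros(W, dtype=float)
    sd50 = np.zeros(W, dtype=float)
    maxs = np.zeros(W, dtype=float)
    for w, year in enumerate(winter_years):
        if year not in carcass_df.index:
            errors.append(f"carcass file missing winter year {year}")
            continue
        row = carcass_df.loc[year]
        D[w] = int(row["carcasses"])
        sd50[w] = float(row["sd50_days"])
        maxs[w] = float(row["maxs_cm"])
        if "area_ratio" in carcass_df.columns and not pd.isna(row.get("area_ratio")):
            A_d[w] = float(row["area_ratio"])
        else:
            A_d[w] = compute_carcass_area_ratio(
                float(row["distance_km"]), config.carcass_width_m,
                config.forest_area_km2,
            )[0]
    extra = set(carcass_df.index) - set(winter_years)
    if extra:
        errors.append(f"carcass counts at non-winter years {sorted(extra)}")

    if errors:
        raise ValueError("survey table problems: " + "; ".join(errors))

    ratios = config.route_area_ratios()
    data = SurveyData(
        time=time,
        routes=ROUTES,
        road_counts=C,
        road_occasions=O,
        route_area_ratio=np.array([ratios[m] for m in ROUTES]),
        block_counts=B,
        block_area_ratio=A_b,
        harvest=H,
        effort=Ef,
        carcasses=D,
        carcass_area_ratio=A_d,
        snow_days=sd50,
        snow_max=maxs,
    )
    data.validate()
    return data


def write_survey_tables(data: SurveyData, directory: str | Path) -> dict[str, Path]:
    """Write ``data`` to the canonical long-format layout (round-trippable)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    time = data.time
    paths = {name: directory / f"{name}.csv"
             for name in ("road", "block", "harvest", "carcass")}

    rows = []
    for t in range(1, time.T + 1):
        for m, route in enumerate(data.routes):
            if data.road_occasions[t - 1, m] == 0 and data.road_counts[t - 1, m] == 0:
                continue
            rows.append({
                "year": time.year(t), "season": time.season(t).value,
                "route": route, "count": int(data.road_counts[t - 1, m]),
                "occasions": int(data.road_occasions[t - 1, m]),
            })
    pd.DataFrame(rows, columns=["year", "season", "route", "count", "occasions"]).to_csv(
        paths["road"], index=False
    )

    pd.DataFrame({
        "year": [time.year(t) for t in time.winter_transitions],
        "count": data.block_counts,
        "area_ratio": data.block_area_ratio,
    }).to_csv(paths["block"], index=False)

    pd.DataFrame({
        "year": [time.year(t) for t in range(1, time.T + 1)],
        "season": [time.season(t).value for t in range(1, time.T + 1)],
        "harvest": data.harvest,
        "effort": data.effort,
    }).to_csv(paths["harvest"], index=False)

    pd.DataFrame({
        "year": [time.year(t) for t in time.winter_transitions],
        "carcasses": data.carcasses,
        "area_ratio": data.carcass_area_ratio,
        "sd50_days": data.snow_days,
        "maxs_cm": data.snow_max,
    }).to_csv(paths["carcass"], index=False)
    return paths


def study_covariates(time: TimeIndex | None = None) -> dict[str, np.ndarray]:
    """Study harvest/effort and winter covariates aligned to the grid."""
    time = time or TimeIndex(2007, 12)
    harvest_df = load_harvest_table()
    H = np.zeros(time.T, dtype=np.int64)
    Ef = np.zeros(time.T, dtype=float)
    for _, row in harvest_df.iterrows():
        t = time.t_of(int(row["year"]), Season(str(row["season"])))
        H[t - 1] = int(row["harvest"])
        Ef[t - 1] = float(row["effort"])
    winter_df = load_winter_table().set_index("year")
    years = [time.year(t) for t in time.winter_transitions]
    sub = winter_df.loc[years]
    return {
        "harvest": H,
        "effort": Ef,
        "carcasses": sub["carcasses"].to_numpy(dtype=np.int64),
        "distance_km": sub["distance_km"].to_numpy(dtype=float),
        "sd50": sub["sd50_days"].to_numpy(dtype=float),
        "maxs": sub["maxs_cm"].to_numpy(dtype=float),
    }
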