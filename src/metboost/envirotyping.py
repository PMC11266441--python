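"""Environmental feature engineering.

Builds the per-environment feature matrix from six data layers:

==============  =====  =============================================
category        count  construction
==============  =====  =============================================
weather            63  4 variables x 4 season groups x 4 statistics,
                       minus the degenerate rainfall/full-season/min
ec_svd             15  scores of an uncentered truncated SVD of the
                       765 crop-model environmental covariates
lagged_yield        6  summary statistics of the previous year's
                       yield at the same field location
soil                3  nitrate (ppm), nitrogen (lb/acre), calcium (%)
coordinates         2  floor-binned latitude and longitude
management          1  irrigation flag
==============  =====  =============================================

for a default total of 90 features, one row per environment.  The recipe is
declarative (a manifest records every feature's category, units and
aggregation), so alternative season groupings or lag statistics are drop-in
replacements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ImputationRequiredError,
    InvalidStepError,
    KeyMismatchError,
)
from .linalg import svd_scores
from .utils import env_year, field_location

WEATHER_VARIABLES = ("Rainfall", "Solar_Radiation", "Humidity", "Temperature")
SEASON_GROUPS = ("spring", "summer", "fall", "full")
WEATHER_STATS = ("mean", "max", "min", "sd")
# rainfall minimum over the full season is almost surely zero; dropping this
# one cell yields the 63-feature default weather block
WEATHER_DROP = (("Rainfall", "full", "min"),)
LAGGED_STATS = ("mean", "min", "p25", "p50", "p75", "max")

_MONTH_GROUP = {
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
    12: "winter", 1: "winter", 2: "winter",
}

CATEGORY_COUNTS = {
    "weather": 63,
    "ec_svd": 15,
    "lagged_yield": 6,
    "soil": 3,
    "coordinates": 2,
    "management": 1,
}


@dataclass
class EnvirotypingConfig:
    lat_step: float = 1.2
    lon_step: float = 3.6
    n_ec_components: int = 15
    center_ecs: bool = False
    variables: tuple = WEATHER_VARIABLES
    groups: tuple = SEASON_GROUPS
    stats: tuple = WEATHER_STATS
    drop: tuple = WEATHER_DROP
    lagged_stats: tuple = LAGGED_STATS


def _stat(values: np.ndarray, stat: str) -> float:
    if len(values) == 0:
        return float("nan")
    if stat == "mean":
        return float(np.mean(values))
    if stat == "max":
        return float(np.max(values))
    if stat == "min":
        return float(np.min(values))
    if stat == "sd":
        return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    if stat.startswith("p"):
        return float(np.percentile(values, int(stat[1:])))
    raise ValueError(f"unknown statistic {stat!r}")


def weather_feature_names(cfg: EnvirotypingConfig | None = None) -> list[str]:
    cfg = cfg or EnvirotypingConfig()
    names = []
    for var in cfg.variables:
        for group in cfg.groups:
            for stat in cfg.stats:
                if (var, group, stat) in cfg.drop:
                    continue
                names.append(f"wx_{var.lower()}_{group}_{stat}")
    return names


def aggregate_weather(
    series: pd.DataFrame, cfg: EnvirotypingConfig | None = None
) -> pd.Series:
    """Season-grouped summary statistics of one environment's weather series.

    ``series`` holds the 30-minute records of a single environment with a
    ``Timestamp`` column and one column per weather variable.  Timestamps must
    be strictly increasing.  A season group with no records yields missing
    features (with a warning), keeping the schema fixed.
    """
    cfg = cfg or EnvirotypingConfig()
    if len(series) == 0:
        raise ValueError("empty weather series")
    ts = pd.to_datetime(series["Timestamp"])
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise ValueError("weather timestamps must be strictly increasing")
    months = ts.dt.month.map(_MONTH_GROUP)
    out = {}
    for var in cfg.variables:
        col = series[var].to_numpy(dtype=float)
        for group in cfg.groups:
            values = col if group == "full" else col[(months == group).to_numpy()]
            if len(values) == 0:
                warnings.warn(f"no weather records in group {group!r}; features missing")
            for stat in cfg.stats:
                if (var, group, stat) in cfg.drop:
                    continue
                out[f"wx_{var.lower()}_{group}_{stat}"] = _stat(values, stat)
    return pd.Series(out)


def weather_features(
    weather: pd.DataFrame, cfg: EnvirotypingConfig | None = None
) -> pd.DataFrame:
    rows = {
        env: aggregate_weather(g.sort_values("Timestamp"), cfg)
        for env, g in weather.groupby("Env", sort=True)
    }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "Env"
    return out


def lagged_yield_features(
    history: pd.DataFrame,
    envs: pd.DataFrame,
    cfg: EnvirotypingConfig | None = None,
) -> pd.DataFrame:
    """Previous-year yield summaries per environment.

    An environment in year *y* at field location *L* is described by summary
    statistics of the plot yields recorded at *L* in year *y - 1*; if no
    prior-year data exists all six features are missing.
    """
    cfg = cfg or EnvirotypingConfig()
    hist = history.groupby(["Field_Location", "Year"])["Yield_Mg_ha"].apply(
        lambda s: s.dropna().to_numpy()
    )
    rows = {}
    for env in envs["Env"]:
        loc, year = field_location(env), env_year(env)
        values = hist.get((loc, year - 1), np.array([]))
        if len(values) == 0:
            rows[env] = {f"lag_yield_{s}": float("nan") for s in cfg.lagged_stats}
        else:
            rows[env] = {f"lag_yield_{s}": _stat(values, s) for s in cfg.lagged_stats}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "Env"
    return out[[f"lag_yield_{s}" for s in cfg.lagged_stats]]


def bin_coordinate(x, s: float):
    """Floor-based coordinate binning: x' = floor(x / s) * s.

    The floor goes toward negative infinity, so nearby trials collapse onto
    the lower edge of their bin (e.g. latitudes 39.785, 39.824 and 39.927 all
    bin to 39.6 at s = 1.2).
    """
    if s <= 0:
        raise InvalidStepError(f"step must be > 0, got {s}")
    x = np.asarray(x, dtype=float)
    ratio = x / s
    floored = np.floor(ratio)
    # tolerant floor: a ratio within ~1e-9 of the next integer is an already
    # binned value whose division picked up float error; without this nudge
    # binning would not be idempotent
    floored = np.where(np.ceil(ratio) - ratio < 1e-9, np.ceil(ratio), floored)
    out = floored * s
    return float(out) if out.ndim == 0 else out


def coordinate_features(
    coords: pd.DataFrame, cfg: EnvirotypingConfig | None = None
) -> pd.DataFrame:
    cfg = cfg or EnvirotypingConfig()
    out = pd.DataFrame(
        {
            "coord_lat_bin": bin_coordinate(coords["Latitude"].to_numpy(), cfg.lat_step),
            "coord_lon_bin": bin_coordinate(coords["Longitude"].to_numpy(), cfg.lon_step),
        },
        index=pd.Index(coords["Env"], name="Env"),
    )
    return out


def reduce_ecs(
    ecs: pd.DataFrame, k: int = 15, center: bool = False
) -> tuple[pd.DataFrame, np.ndarray]:
    """Truncated SVD of the environmental-covariate matrix.

    Returns per-environment component scores (columns ``ec_svd_01`` ...) and
    the explained-variance ratios of the kept components.  The decomposition
    is uncentered by default; missing cells must be imputed beforehand.
    """
    values = ecs.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ImputationRequiredError("EC matrix contains missing cells; impute first")
    k = int(min(k, *values.shape))
    scores, evr = svd_scores(values, k, center=center)
    cols = [f"ec_svd_{j + 1:02d}" for j in range(scores.shape[1])]
    return pd.DataFrame(scores, index=ecs.index, columns=cols), evr


def soil_features(soil: pd.DataFrame) -> pd.DataFrame:
    out = soil.set_index("Env")[["Nitrate_ppm", "Nitrogen_lb_acre", "Calcium_pct"]]
    return out.rename(
        columns={
            "Nitrate_ppm": "soil_nitrate_ppm",
            "Nitrogen_lb_acre": "soil_nitrogen_lb_acre",
            "Calcium_pct": "soil_calcium_pct",
        }
    )


def management_features(management: pd.DataFrame) -> pd.DataFrame:
    return management.set_index("Env")[["Irrigated"]].rename(
        columns={"Irrigated": "mgmt_irrigated"}
    )


_CATEGORY_UNITS = {
    "weather": "per-variable (mm, W/m^2, %, degC)",
    "ec_svd": "component score",
    "lagged_yield": "Mg/ha",
    "soil": "ppm / lb/acre / %",
    "coordinates": "degrees (binned)",
    "management": "flag",
}


def assemble_environmental_matrix(
    weather_feats: pd.DataFrame,
    ec_scores: pd.DataFrame,
    lagged_feats: pd.DataFrame,
    soil_feats: pd.DataFrame,
    coord_feats: pd.DataFrame,
    management_feats: pd.DataFrame,
) -> tuple[pd.DataFrame, list[dict]]:
    """Column-wise concatenation of the six feature blocks, keyed by Env.

    Raises :class:`KeyMismatchError` naming any environment present in one
    block but absent from another.  Returns the matrix and its manifest
    (feature name, category, units).
    """
    blocks = {
        "weather": weather_feats,
        "ec_svd": ec_scores,
        "lagged_yield": lagged_feats,
        "soil": soil_feats,
        "coordinates": coord_feats,
        "management": management_feats,
    }
    key_sets = {name: set(df.index) for name, df in blocks.items()}
    union = set().union(*key_sets.values())
    offenders = {
        f"{env} (missing from {name})"
        for name, keys in key_sets.items()
        for env in union - keys
    }
    if offenders:
        raise KeyMismatchError("environment keys do not match across blocks", offenders)

    manifest = []
    parts = []
    seen = set()
    for name, df in blocks.items():
        df = df.sort_index()
        for col in df.columns:
            if col in seen:
                raise KeyMismatchError(f"duplicated feature name {col!r}")
            seen.add(col)
            manifest.append(
                {"name": col, "category": name, "units": _CATEGORY_UNITS[name]}
            )
        parts.append(df)
    matrix = pd.concat(parts, axis=1)
    matrix.index.name = "Env"
    return matrix, manifest


def build_environmental_matrix(
    study, cfg: EnvirotypingConfig | None = None
) -> tuple[pd.DataFrame, list[dict]]:
    """Full envirotyping stage for a synthetic (or equivalently shaped) study.

    With the default recipe and at least ``n_ec_components`` environments the
    result has exactly 90 feature columns.
    """
    cfg = cfg or EnvirotypingConfig()
    wf = weather_features(study.weather, cfg)
    ec, _ = reduce_ecs(study.ecs, k=cfg.n_ec_components, center=cfg.center_ecs)
    lf = lagged_yield_features(study.history, study.envs, cfg)
    sf = soil_features(study.soil)
    cf = coordinate_features(study.coords, cfg)
    mf = management_features(study.management)
    return assemble_environmental_matrix(wf, ec, lf, sf, cf, mf)
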