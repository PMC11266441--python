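"""Synthetic multi-environment maize trial generator.

Emulates the shape of a Genomes-to-Fields-style study: parent x tester hybrids
genotyped at biallelic SNPs, evaluated for grain yield (Mg/ha) over three years
of location trials laid out as randomized complete block designs with row and
column effects, accompanied by per-environment weather-station series, soil
assays, crop-model environmental covariates (ECs), coordinates, and historical
yields.  Every random draw descends from a single seed, so an identical
:class:`SimConfig` reproduces the study byte for byte.

The generative model for a plot is

    yield = mu + a(hybrid) + d(hybrid) + E(env) + gxe(hybrid, env)
          + block(rep) + row + col + residual

with additive values ``a`` built from i.i.d. normal marker effects rescaled to
the configured variance, dominance values ``d`` from centered heterozygosity
codes, environment main effects tied to a latent environmental index that also
drives the weather and EC layers (so environmental features are informative),
and genotype-by-environment deviations partially correlated with that index
through a marker-determined plasticity score (so interaction signal is
learnable from genotypes and environments jointly).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, LayoutError

PLOT_COLUMNS = ["Env", "Hybrid", "Replicate", "Block", "Row", "Col", "Yield_Mg_ha"]
TRUTH_EFFECT_COLUMNS = [
    "intercept",
    "g_add",
    "g_dom",
    "env",
    "gxe",
    "block",
    "row",
    "col",
    "resid",
]

# Regional centers for trial coordinates.  Before jittering, each center is
# snapped to the midpoint of its (1.2 deg lat, 3.6 deg lon) bin so that the
# default jitter never crosses a bin boundary and nearby trials collapse to a
# single binned coordinate, as intended by the binning step.
DEFAULT_COORD_CENTERS = (
    (39.8, -95.0),
    (42.2, -93.2),
    (35.3, -80.6),
    (44.6, -90.1),
)


@dataclass(frozen=True)
class VarianceComponents:
    """Ground-truth variance components, all in (Mg/ha)^2."""

    v_g_add: float = 0.30
    v_g_dom: float = 0.05
    v_env: float = 2.00
    v_gxe: float = 0.20
    v_block: float = 0.05
    v_row: float = 0.03
    v_col: float = 0.03
    v_resid: float = 1.00

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise InvalidConfigError(f"variance component {f.name} must be >= 0")


@dataclass
class SimConfig:
    """Configuration of a synthetic three-year study.

    The defaults emulate the study design this package targets: a first year
    with two testers and a half-size hybrid panel, two later years sharing
    four testers (one carried over from the first year) plus a small minor
    tester group, trials laid out as 2-replicate RCBDs on a rows x columns
    field grid, and environments that evaluate an incomplete, overlapping
    subset of the year's hybrid panel.
    """

    n_parents: int = 150
    testers_by_year: Mapping[int, Sequence[str]] | None = None
    minor_testers_by_year: Mapping[int, Sequence[str]] | None = None
    n_minor_parents: int = 5
    n_markers: int = 1000
    n_environments_per_year: int | Sequence[int] = (6, 12, 12)
    years: Sequence[int] = (2019, 2020, 2021)
    reps: int = 2
    field_rows: int = 24
    field_cols: int = 20
    env_hybrid_frac: float = 0.35
    var_components: VarianceComponents = field(default_factory=VarianceComponents)
    maf_range: tuple[float, float] = (0.05, 0.5)
    dup_marker_frac: float = 0.05
    gxe_env_corr: float = 0.5
    intercept: float = 10.0
    season_start: str = "04-15"  # month-day of planting
    season_end: str = "09-30"  # month-day of harvest (exclusive)
    n_chromosomes: int = 10
    coord_centers: Sequence[tuple[float, float]] = DEFAULT_COORD_CENTERS
    coord_jitter: float = 0.25
    missing_plot_frac: float = 0.0
    weather_gap_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        years = tuple(int(y) for y in self.years)
        if len(years) != 3 or any(b - a != 1 for a, b in zip(years, years[1:])):
            raise InvalidConfigError("years must be 3 consecutive increasing integers")
        self.years = years
        if self.n_parents < 1:
            raise InvalidConfigError("n_parents must be >= 1")
        if self.n_markers < 1:
            raise InvalidConfigError("n_markers must be >= 1")
        if self.reps < 1:
            raise InvalidConfigError("reps must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must lie within (0, 0.5]")
        if self.testers_by_year is None:
            y1, y2, y3 = years
            self.testers_by_year = {
                y1: ("T01", "T02"),
                y2: ("T01", "T03", "T04", "T05"),
                y3: ("T01", "T03", "T04", "T05"),
            }
        self.testers_by_year = {
            int(y): tuple(t) for y, t in dict(self.testers_by_year).items()
        }
        for y in years:
            if not self.testers_by_year.get(y):
                raise InvalidConfigError(f"empty tester list for year {y}")
        if self.minor_testers_by_year is None:
            y1, y2, y3 = years
            self.minor_testers_by_year = {y2: ("T90",), y3: ("T90",)}
        self.minor_testers_by_year = {
            int(y): tuple(t) for y, t in dict(self.minor_testers_by_year).items()
        }
        if isinstance(self.n_environments_per_year, int):
            self.n_environments_per_year = (self.n_environments_per_year,) * 3
        else:
            self.n_environments_per_year = tuple(
                int(n) for n in self.n_environments_per_year
            )
        if len(self.n_environments_per_year) != 3:
            raise InvalidConfigError("n_environments_per_year needs one count per year")
        if min(self.n_environments_per_year) < 1:
            raise InvalidConfigError("each year needs at least one environment")
        if not 0 < self.env_hybrid_frac <= 1:
            raise InvalidConfigError("env_hybrid_frac must be in (0, 1]")


@dataclass
class Population:
    """Hybrid genotypes plus the parent x tester pedigree."""

    hybrids: list[str]
    dosage: np.ndarray  # n_hybrids x n_markers, values in {0, 1, 2}
    markers: pd.DataFrame  # columns: Marker, Chrom, Pos, AltFreq
    pedigree: pd.DataFrame  # columns: Hybrid, Parent, Tester
    hybrids_by_year: dict[int, list[str]]

    @property
    def tester_of(self) -> dict[str, str]:
        return dict(zip(self.pedigree["Hybrid"], self.pedigree["Tester"]))


@dataclass
class TruthEffects:
    """Realized simulation truth used by tests and diagnostics."""

    plot_effects: pd.DataFrame  # per-plot decomposition, TRUTH_EFFECT_COLUMNS
    env_effects: pd.DataFrame  # Env, z (latent index), effect
    genetic_values: pd.DataFrame  # Hybrid, additive, dominance, plasticity
    var_components: VarianceComponents


@dataclass
class SyntheticStudy:
    config: SimConfig
    population: Population
    plot_table: pd.DataFrame
    envs: pd.DataFrame  # Env, Field_Location, Year
    weather: pd.DataFrame
    soil: pd.DataFrame
    ecs: pd.DataFrame  # indexed by Env, 765 columns
    coords: pd.DataFrame  # Env, Latitude, Longitude
    management: pd.DataFrame  # Env, Irrigated
    history: pd.DataFrame  # Field_Location, Year, Yield_Mg_ha (plot level)
    truth: TruthEffects

    @property
    def genotypes(self) -> Population:
        return self.population


def _exact_count_alleles(rng, n_slots: int, freqs: np.ndarray) -> np.ndarray:
    """Allele indicator matrix (n_markers x n_slots) with per-marker counts
    fixed at round(freq * n_slots), carriers randomly permuted per marker."""
    n_markers = len(freqs)
    counts = np.rint(freqs * n_slots).astype(int)
    ranks = np.argsort(rng.random((n_markers, n_slots)), axis=1)
    return (ranks < counts[:, None]).astype(np.int8)


def generate_population(cfg: SimConfig) -> Population:
    """Generate parent and tester lines and all hybrids used across years.

    Parents are fully inbred; testers may be heterozygous (their genotypes are
    filled to hit an exact panel-level allele count).  Each hybrid dosage is
    the sum of one parent gamete and one tester gamete.  A configured fraction
    of markers are exact duplicates of their left neighbor, providing perfect
    linkage disequilibrium for the pruning stage to remove.
    """
    ss = np.random.SeedSequence([cfg.seed, 1])
    rng = np.random.default_rng(ss)

    all_testers: list[str] = []
    for y in cfg.years:
        for t in cfg.testers_by_year[y] + cfg.minor_testers_by_year.get(y, ()):
            if t not in all_testers:
                all_testers.append(t)
    minor_testers = sorted(
        {t for ts in cfg.minor_testers_by_year.values() for t in ts}
    )

    n_major = cfg.n_parents
    n_minor = cfg.n_minor_parents if minor_testers else 0
    parents = [f"P{i + 1:04d}" for i in range(n_major)]
    minor_parents = [f"Q{i + 1:03d}" for i in range(n_minor)]

    n_dup = int(round(cfg.dup_marker_frac * cfg.n_markers))
    n_base = cfg.n_markers - n_dup
    if n_base < 1:
        raise InvalidConfigError("dup_marker_frac leaves no independent markers")

    lo, hi = cfg.maf_range
    base_freq = rng.uniform(lo, hi, size=n_base)

    # interleave duplicate columns right after randomly chosen base markers
    dup_after = np.sort(rng.choice(n_base, size=n_dup, replace=False)) if n_dup else []
    order_src: list[int] = []
    is_dup: list[bool] = []
    di = 0
    for i in range(n_base):
        order_src.append(i)
        is_dup.append(False)
        while di < n_dup and dup_after[di] == i:
            order_src.append(i)
            is_dup.append(True)
            di += 1
    order_src = np.asarray(order_src)
    is_dup = np.asarray(is_dup)

    n_parent_lines = n_major + n_minor
    parent_alleles = _exact_count_alleles(rng, n_parent_lines, base_freq).T
    # tester alleles are exact-counted per group (major vs minor) so the
    # hybrid-panel allele frequency, which weights major testers equally,
    # tracks the target frequency within rounding of the group allele count
    major_group = [t for t in all_testers if t not in minor_testers]
    geno_by_tester: dict[str, np.ndarray] = {}
    for group in (major_group, minor_testers):
        if not group:
            continue
        slots = _exact_count_alleles(rng, 2 * len(group), base_freq)
        g = slots.reshape(n_base, len(group), 2).sum(axis=2).T  # {0,1,2}
        for i, t in enumerate(group):
            geno_by_tester[t] = g[i]
    tester_geno = np.vstack([geno_by_tester[t] for t in all_testers])

    # expand to the full marker set (duplicates copy their source column)
    parent_alleles = parent_alleles[:, order_src]
    tester_geno = tester_geno[:, order_src]
    freqs = base_freq[order_src]

    # hybrid roster
    ped_rows: list[tuple[str, str, str]] = []
    hybrids_by_year: dict[int, list[str]] = {}
    seen: dict[str, int] = {}
    for y in cfg.years:
        ids = []
        for t in cfg.testers_by_year[y]:
            for p in parents:
                ids.append((f"{p}/{t}", p, t))
        for t in cfg.minor_testers_by_year.get(y, ()):
            for p in minor_parents:
                ids.append((f"{p}/{t}", p, t))
        hybrids_by_year[y] = [h for h, _, _ in ids]
        for row in ids:
            if row[0] not in seen:
                seen[row[0]] = len(seen)
                ped_rows.append(row)
    pedigree = pd.DataFrame(ped_rows, columns=["Hybrid", "Parent", "Tester"])
    hybrids = list(pedigree["Hybrid"])

    line_index = {p: i for i, p in enumerate(parents + minor_parents)}
    tester_index = {t: i for i, t in enumerate(all_testers)}
    pi = pedigree["Parent"].map(line_index).to_numpy()
    ti = pedigree["Tester"].map(tester_index).to_numpy()

    # gametes are drawn at base-marker resolution and then expanded through
    # order_src, so duplicated columns are exact copies (r^2 = 1 in pruning)
    tg_base = tester_geno[ti][:, np.flatnonzero(~is_dup)]
    het = tg_base == 1
    gametes_base = np.where(het, rng.integers(0, 2, size=tg_base.shape), tg_base // 2)
    parent_base = parent_alleles[pi][:, np.flatnonzero(~is_dup)]
    dosage_base = parent_base + gametes_base
    dosage = dosage_base[:, order_src].astype(np.int8)

    per_chrom = int(np.ceil(cfg.n_markers / cfg.n_chromosomes))
    chrom = np.repeat(np.arange(1, cfg.n_chromosomes + 1), per_chrom)[: cfg.n_markers]
    pos = np.concatenate(
        [np.arange(1, np.sum(chrom == c) + 1) * 100 for c in range(1, cfg.n_chromosomes + 1)]
    )
    markers = pd.DataFrame(
        {
            "Marker": [f"M{i + 1:06d}" for i in range(cfg.n_markers)],
            "Chrom": chrom,
            "Pos": pos,
            "AltFreq": freqs,
            "Duplicated": is_dup,
        }
    )
    return Population(hybrids, dosage, markers, pedigree, hybrids_by_year)


def _scaled_effect(rng, Z: np.ndarray, variance: float) -> np.ndarray:
    """Column-effect value Z @ beta rescaled to an exact population variance."""
    if variance == 0:
        return np.zeros(Z.shape[0])
    vals = Z @ rng.standard_normal(Z.shape[1])
    sd = vals.std()
    if sd == 0:
        return np.zeros(Z.shape[0])
    return vals * (np.sqrt(variance) / sd)


def _env_table(cfg: SimConfig) -> pd.DataFrame:
    max_locs = max(cfg.n_environments_per_year)
    locs = [f"L{i + 1:02d}" for i in range(max_locs)]
    rows = []
    for y, n in zip(cfg.years, cfg.n_environments_per_year):
        for loc in locs[:n]:
            rows.append((f"{loc}_{y}", loc, y))
    return pd.DataFrame(rows, columns=["Env", "Field_Location", "Year"])


def generate_trials(
    cfg: SimConfig, pop: Population
) -> tuple[pd.DataFrame, pd.DataFrame, TruthEffects]:
    """Lay out and phenotype all trials.

    Returns ``(plot_table, envs, truth)``.  Each environment evaluates a
    random fraction of its year's hybrid panel in an RCBD with ``cfg.reps``
    replicates placed in side-by-side column bands; blocks are the field rows
    within a replicate band.
    """
    ss = np.random.SeedSequence([cfg.seed, 2])
    rng = np.random.default_rng(ss)
    vc = cfg.var_components

    envs = _env_table(cfg)
    n_env = len(envs)

    hyb_index = {h: i for i, h in enumerate(pop.hybrids)}
    Zc = pop.dosage - pop.dosage.mean(axis=0, keepdims=True)
    het = (pop.dosage == 1).astype(float)
    Hc = het - het.mean(axis=0, keepdims=True)

    a = _scaled_effect(rng, Zc, vc.v_g_add)
    d = _scaled_effect(rng, Hc, vc.v_g_dom)
    plasticity = _scaled_effect(rng, Zc, 1.0)  # unit-variance GxE sensitivity

    z = rng.standard_normal(n_env)
    env_effect = np.sqrt(vc.v_env) * z

    band_cols = cfg.field_cols // cfg.reps
    if band_cols < 1:
        raise LayoutError(
            f"field_cols={cfg.field_cols} cannot host {cfg.reps} replicate bands"
        )

    rho = cfg.gxe_env_corr
    plot_rows: list[pd.DataFrame] = []
    truth_rows: list[pd.DataFrame] = []
    for e_idx, (env, loc, year) in enumerate(envs.itertuples(index=False)):
        panel = pop.hybrids_by_year[year]
        n_take = max(2, int(round(cfg.env_hybrid_frac * len(panel))))
        chosen = sorted(rng.choice(panel, size=min(n_take, len(panel)), replace=False))
        H = len(chosen)
        if H > cfg.field_rows * band_cols:
            raise LayoutError(
                f"{env}: {H} hybrids x {cfg.reps} reps exceed the "
                f"{cfg.field_rows}x{cfg.field_cols} field with {cfg.reps} bands"
            )
        gi = np.array([hyb_index[h] for h in chosen])
        gxe = np.sqrt(vc.v_gxe) * (
            np.sqrt(rho) * plasticity[gi] * z[e_idx]
            + np.sqrt(1 - rho) * rng.standard_normal(H)
        )
        used_rows = int(np.ceil(H / band_cols))
        row_eff = rng.normal(0, np.sqrt(vc.v_row), cfg.field_rows)
        col_eff = rng.normal(0, np.sqrt(vc.v_col), cfg.field_cols)
        for rep in range(1, cfg.reps + 1):
            order = rng.permutation(H)
            idx = np.arange(H)
            r = idx // band_cols
            c_band = idx % band_cols
            c = (rep - 1) * band_cols + c_band
            block = r + 1  # block nested in replicate = field row of the band
            block_eff = rng.normal(0, np.sqrt(vc.v_block), used_rows)
            resid = rng.normal(0, np.sqrt(vc.v_resid), H)
            hyb = [chosen[k] for k in order]
            g = gi[order]
            tr = pd.DataFrame(
                {
                    "intercept": cfg.intercept,
                    "g_add": a[g],
                    "g_dom": d[g],
                    "env": env_effect[e_idx],
                    "gxe": gxe[order],
                    "block": block_eff[r],
                    "row": row_eff[r],
                    "col": col_eff[c],
                    "resid": resid,
                }
            )
            yield_vals = tr[TRUTH_EFFECT_COLUMNS].sum(axis=1)
            pl = pd.DataFrame(
                {
                    "Env": env,
                    "Hybrid": hyb,
                    "Replicate": rep,
                    "Block": block,
                    "Row": r + 1,
                    "Col": c + 1,
                    "Yield_Mg_ha": yield_vals.to_numpy(),
                }
            )
            plot_rows.append(pl)
            tr.insert(0, "Env", env)
            tr.insert(1, "Hybrid", hyb)
            tr.insert(2, "Replicate", rep)
            truth_rows.append(tr)

    plot_table = pd.concat(plot_rows, ignore_index=True)
    truth_plots = pd.concat(truth_rows, ignore_index=True)

    if cfg.missing_plot_frac > 0:
        n_missing = int(round(cfg.missing_plot_frac * len(plot_table)))
        miss = rng.choice(len(plot_table), size=n_missing, replace=False)
        plot_table.loc[miss, "Yield_Mg_ha"] = np.nan

    truth = TruthEffects(
        plot_effects=truth_plots,
        env_effects=pd.DataFrame(
            {"Env": envs["Env"], "z": z, "effect": env_effect}
        ),
        genetic_values=pd.DataFrame(
            {
                "Hybrid": pop.hybrids,
                "additive": a,
                "dominance": d,
                "plasticity": plasticity,
            }
        ),
        var_components=vc,
    )
    return plot_table, envs, truth


def _season_range(cfg: SimConfig, year: int) -> pd.DatetimeIndex:
    start = pd.Timestamp(f"{year}-{cfg.season_start}")
    end = pd.Timestamp(f"{year}-{cfg.season_end}")
    return pd.date_range(start, end, freq="30min", inclusive="left")


def generate_environment_layers(
    cfg: SimConfig,
    envs: pd.DataFrame,
    env_index: np.ndarray | None = None,
    plot_table: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Weather, soil, EC, coordinate, management, and history layers.

    ``env_index`` is the latent environmental index (one value per row of
    ``envs``); weather means and the leading EC factor are tied to it so the
    derived environmental features carry information about the environment
    main effect.  ``plot_table`` supplies the realized yields from which the
    per-location history is taken; first-year locations have no prior-year
    history, mirroring real lagged-feature gaps.
    """
    ss = np.random.SeedSequence([cfg.seed, 3])
    rng = np.random.default_rng(ss)
    n_env = len(envs)
    if env_index is None:
        env_index = np.zeros(n_env)
    z = np.asarray(env_index, dtype=float)

    # --- weather -----------------------------------------------------------
    weather_frames = []
    for (env, loc, year), ze in zip(envs.itertuples(index=False), z):
        ts = _season_range(cfg, int(year))
        n = len(ts)
        hour = ts.hour + ts.minute / 60.0
        diurnal = np.sin((hour - 9.0) / 24.0 * 2 * np.pi)
        temp = 22.0 + 3.0 * ze + 6.0 * diurnal + rng.normal(0, 2.0, n)
        solar = np.clip(800.0 * np.clip(diurnal, 0, None) * (1 + 0.1 * ze), 0, None)
        solar += rng.normal(0, 20.0, n).clip(min=0) * (solar > 0)
        humidity = np.clip(70.0 - 5.0 * ze + rng.normal(0, 8.0, n), 5, 100)
        rain = np.where(rng.random(n) < 0.04, rng.exponential(2.0, n), 0.0)
        df = pd.DataFrame(
            {
                "Env": env,
                "Timestamp": ts,
                "Rainfall": rain,
                "Solar_Radiation": solar,
                "Humidity": humidity,
                "Temperature": temp,
            }
        )
        if cfg.weather_gap_frac > 0:
            keep = rng.random(n) >= cfg.weather_gap_frac
            df = df.loc[keep]
        weather_frames.append(df)
    weather = pd.concat(weather_frames, ignore_index=True)

    # --- soil --------------------------------------------------------------
    soil = pd.DataFrame(
        {
            "Env": envs["Env"],
            "Nitrate_ppm": np.clip(rng.normal(20, 5, n_env) + 1.0 * z, 0.5, None),
            "Nitrogen_lb_acre": np.clip(rng.normal(50, 10, n_env), 1, None),
            "Calcium_pct": np.clip(rng.normal(1.5, 0.3, n_env), 0.05, None),
        }
    )

    # --- ECs: low-rank signal (leading factor = env index) + small noise ----
    n_ec, rank = 765, 10
    factors = np.column_stack([z] + [rng.standard_normal(n_env) for _ in range(rank - 1)])
    loadings = rng.standard_normal((rank, n_ec)) * (2.0 ** -np.arange(rank))[:, None]
    ec_values = factors @ loadings + rng.normal(0, 1e-3, (n_env, n_ec))
    ecs = pd.DataFrame(
        ec_values, index=pd.Index(envs["Env"], name="Env"),
        columns=[f"EC_{i + 1:04d}" for i in range(n_ec)],
    )

    # --- coordinates: snapped regional centers + jitter ---------------------
    locs = sorted(envs["Field_Location"].unique())
    centers = list(cfg.coord_centers)
    loc_coord = {}
    for i, loc in enumerate(locs):
        lat_c, lon_c = centers[i % len(centers)]
        lat_mid = np.floor(lat_c / 1.2) * 1.2 + 0.6
        lon_mid = np.floor(lon_c / 3.6) * 3.6 + 1.8
        loc_coord[loc] = (
            lat_mid + rng.uniform(-cfg.coord_jitter, cfg.coord_jitter),
            lon_mid + rng.uniform(-cfg.coord_jitter, cfg.coord_jitter),
        )
    coords = pd.DataFrame(
        {
            "Env": envs["Env"],
            "Latitude": [loc_coord[l][0] for l in envs["Field_Location"]],
            "Longitude": [loc_coord[l][1] for l in envs["Field_Location"]],
        }
    )

    # --- management ---------------------------------------------------------
    irrigated = {loc: int(rng.random() < 0.3) for loc in locs}
    management = pd.DataFrame(
        {"Env": envs["Env"], "Irrigated": [irrigated[l] for l in envs["Field_Location"]]}
    )

    # --- history: realized plot yields per location-year ---------------------
    if plot_table is not None and len(plot_table):
        pt = plot_table.dropna(subset=["Yield_Mg_ha"])
        loc_year = pt["Env"].str.rsplit("_", n=1, expand=True)
        history = pd.DataFrame(
            {
                "Field_Location": loc_year[0],
                "Year": loc_year[1].astype(int),
                "Yield_Mg_ha": pt["Yield_Mg_ha"].to_numpy(),
            }
        ).reset_index(drop=True)
    else:
        history = pd.DataFrame(columns=["Field_Location", "Year", "Yield_Mg_ha"])

    return {
        "weather": weather,
        "soil": soil,
        "ecs": ecs,
        "coords": coords,
        "management": management,
        "history": history,
    }


def generate_study(cfg: SimConfig) -> SyntheticStudy:
    """Run the full generator: population -> trials -> environment layers."""
    pop = generate_population(cfg)
    plot_table, envs, truth = generate_trials(cfg, pop)
    layers = generate_environment_layers(
        cfg, envs, env_index=truth.env_effects["z"].to_numpy(), plot_table=plot_table
    )
    return SyntheticStudy(
        config=cfg,
        population=pop,
        plot_table=plot_table,
        envs=envs,
        truth=truth,
        **layers,
    )


def write_vcf(pop: Population, path) -> None:
    """Write hybrid genotypes as a minimal VCF v4.2 (GT field only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=metboost-synthetic\n")
        for c in sorted(pop.markers["Chrom"].unique()):
            length = int(pop.markers.loc[pop.markers["Chrom"] == c, "Pos"].max()) + 1000
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(pop.hybrids)
            + "\n"
        )
        gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
        dosage = pop.dosage
        for j, (marker, chrom, pos) in enumerate(
            zip(pop.markers["Marker"], pop.markers["Chrom"], pop.markers["Pos"])
        ):
            calls = "\t".join(
                gt_code.get(int(dosage[i, j]), "./.") for i in range(len(pop.hybrids))
            )
            fh.write(f"{chrom}\t{pos}\t{marker}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def write_study(study: SyntheticStudy, out_dir) -> None:
    """Persist a study as plain-text files (VCF + CSVs)."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(study.population, out / "genotypes.vcf")
    study.plot_table.to_csv(out / "plot_table.csv", index=False)
    study.weather.to_csv(out / "weather.csv", index=False)
    study.soil.to_csv(out / "soil.csv", index=False)
    study.ecs.to_csv(out / "ecs.csv")
    study.coords.to_csv(out / "coords.csv", index=False)
    study.management.to_csv(out / "management.csv", index=False)
    study.history.to_csv(out / "history.csv", index=False)
    study.population.pedigree.to_csv(out / "pedigree.csv", index=False)
    study.envs.to_csv(out / "envs.csv", index=False)
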