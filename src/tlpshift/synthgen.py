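"""Synthetic region, flora and daily-climate generator.

Emulates the data layout of a regional floristic survey joined to daily
climate-model output: a fine survey grid (3' latitude x 5' longitude cells,
~5.5 x 6.5 km) carrying habitat mosaics and species occurrences, and a
coarser climate grid (~0.10 deg) carrying daily mean temperature and
precipitation. Every generator is a pure function of its arguments and a
seed, and the trait-climate structure is known (``TruthModel``), so each
downstream stage can be tested for parameter recovery without any
third-party downloads.

Conventions
-----------
* 365-day calendar, no leap days.
* All water potentials are in MPa and strictly negative.
* Elevation rises from south to north (alpine belt in the north,
  coastal lowland in the south), which sorts habitats along the gradient.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "HABITATS",
    "ABUNDANCE_WEIGHTS",
    "OCCUPANCY_BY_WEIGHT",
    "ScenarioShift",
    "TruthModel",
    "RegionFixture",
    "SpeciesPool",
    "generate_region",
    "generate_species_pool",
    "generate_daily_climate",
    "generate_occurrences",
    "generate_trait_response",
    "write_fixtures",
]

#: survey cell size: 3 minutes of latitude by 5 minutes of longitude
SURVEY_DLAT = 3.0 / 60.0
SURVEY_DLON = 5.0 / 60.0
#: south-west corner of the synthetic region (NE-Italy-like latitudes)
ORIGIN_LAT = 45.5
ORIGIN_LON = 12.5

DAYS_PER_YEAR = 365

#: habitat -> (elevation optimum m, mean species Psi_tlp MPa). The default
#: truth couples lower (more negative) Psi_tlp to hotter/drier sites:
#: communities of the coastal lowland carry the most drought-tolerant
#: species, the alpine belt the least. The decline steepens toward the
#: xeric end (drought exposure grows nonlinearly along the gradient).
HABITATS: dict[str, tuple[float, float]] = {
    "saltmarsh": (0.0, -3.0),
    "crops": (120.0, -2.55),
    "mesic_grassland": (350.0, -2.25),
    "dry_grassland": (450.0, -2.35),
    "beech_forest": (1000.0, -1.9),
    "conifer_forest": (1550.0, -1.7),
    "alpine_grassland": (2100.0, -1.55),
}

#: phytosociological abundance classes: dominant, co-dominant,
#: characteristic, other characteristic species
ABUNDANCE_WEIGHTS = (1.0, 0.7, 0.4, 0.1)

#: occupancy probability contributed by one habitat unit per weight class
OCCUPANCY_BY_WEIGHT = {1.0: 0.95, 0.7: 0.8, 0.4: 0.5, 0.1: 0.2}

#: canonical predictor column names (unit-suffixed) used across the package
PREDICTORS = (
    "bio1_95_c",
    "bio4_c",
    "cfd_ann_days",
    "cdd_ann_days",
    "bio12_5_mm",
    "bio15_pct",
)


@dataclass(frozen=True)
class ScenarioShift:
    """Additive temperature / multiplicative precipitation scenario offset."""

    d_temp_c: float = 0.0
    precip_factor: float = 1.0


@dataclass(frozen=True)
class TruthModel:
    """Generating parameters: the structure downstream stages must recover.

    ``trait_coefficients`` define the cell-level response
    ``Psi_tlp = trait_intercept + sum_j coef_j * predictor_j + N(0, noise_sd)``
    used by :func:`generate_trait_response` (model-recovery fixtures), while
    ``habitat_psi_mean`` anchors species-level draws used by
    :func:`generate_species_pool` (full-pipeline fixtures).
    """

    trait_intercept: float = -0.8
    trait_coefficients: dict[str, float] = field(
        default_factory=lambda: {"bio1_95_c": -0.06}
    )
    #: optional quadratic terms (coefficient on predictor^2); a negative
    #: curvature on a temperature predictor makes the decline of Psi_tlp
    #: steepen toward the hot end, the convex drought response seen along
    #: thermo-xeric gradients
    trait_curvature: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.05
    habitat_psi_mean: dict[str, float] = field(
        default_factory=lambda: {h: psi for h, (_, psi) in HABITATS.items()}
    )
    habitat_psi_sd: float = 0.25
    lapse_rate_c_per_km: float = 6.5
    seasonal_amplitude_c: float = 10.0
    base_temp_c: float = 15.0
    temp_noise_sd_c: float = 2.5
    wet_persistence: float = 0.70
    dry_persistence: float = 0.75
    #: extra dry-day persistence at the southern edge, decaying northward:
    #: the coastal lowland sees longer dry spells than the alpine belt
    south_dryness: float = 0.08
    gamma_shape: float = 0.8
    gamma_scale_mm: float = 9.0
    north_wet_factor: float = 1.8
    #: seeded cell-level departures from the latitudinal rain gradient
    #: (lognormal sd on amounts; sd of dry-persistence jitter): real
    #: precipitation fields carry orographic structure of their own and
    #: are not a deterministic function of the temperature gradient
    wet_roughness: float = 0.25
    dry_persistence_jitter: float = 0.02

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("wet_persistence", "dry_persistence"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")


@dataclass
class RegionFixture:
    """A synthetic survey region: cells, climate grid and habitat mosaic."""

    cells: pd.DataFrame
    climate_cells: pd.DataFrame
    habitat_fractions: pd.DataFrame
    n_rows: int
    n_cols: int
    coarsening: int

    def habitat_fraction_matrix(self) -> pd.DataFrame:
        """Wide cell x habitat fraction table (missing habitats = 0)."""
        wide = self.habitat_fractions.pivot(
            index="cell_id", columns="habitat", values="fraction"
        ).fillna(0.0)
        return wide.reindex(self.cells["cell_id"].to_numpy())

    def to_geojson(self, path) -> None:
        write_grid_geojson(self.cells, path)


@dataclass
class SpeciesPool:
    """Species metadata + replicate osmotic potentials + abundance classes."""

    species: pd.DataFrame  # species_id, group, growth_form
    replicates: pd.DataFrame  # species_id, individual, replicate, pi0_mpa
    abundance: pd.DataFrame  # species_id, habitat, weight


def _rng(seed: int, *streams) -> np.random.Generator:
    """Deterministic substream keyed by (seed, stream labels)."""
    keys = [int(seed)]
    for s in streams:
        if isinstance(s, str):
            keys.append(zlib.crc32(s.encode()) % (2**31))
        else:
            keys.append(int(s))
    return np.random.default_rng(keys)


def _cell_frame(n_rows: int, n_cols: int, dlat: float, dlon: float,
                prefix: str) -> pd.DataFrame:
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    rows, cols = rows.ravel(), cols.ravel()
    lat_min = ORIGIN_LAT + rows * dlat
    lon_min = ORIGIN_LON + cols * dlon
    return pd.DataFrame(
        {
            "cell_id": [f"{prefix}{r:03d}_{c:03d}" for r, c in zip(rows, cols)],
            "row": rows,
            "col": cols,
            "lat_min": lat_min,
            "lat_max": lat_min + dlat,
            "lon_min": lon_min,
            "lon_max": lon_min + dlon,
            "lat": lat_min + dlat / 2.0,
            "lon": lon_min + dlon / 2.0,
        }
    )


def generate_region(n_rows: int, n_cols: int, coarsening: int,
                    seed: int) -> RegionFixture:
    """Build the survey grid, the coarser climate grid and habitat mosaics.

    Elevation follows a monotone south->north gradient (coast to alpine
    belt) plus seeded roughness; per-cell habitat fractions are drawn from
    a Dirichlet whose concentrations peak at each habitat's elevation
    optimum, so habitats turn over along the gradient.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("n_rows and n_cols must be >= 1")
    if coarsening < 1:
        raise ValueError("coarsening must be >= 1")

    cells = _cell_frame(n_rows, n_cols, SURVEY_DLAT, SURVEY_DLON, "ogu_")
    rng = _rng(seed, "region")
    frac_north = (cells["row"].to_numpy() + 0.5) / n_rows
    base = 2300.0 * frac_north**1.3
    rough = rng.normal(0.0, 120.0, size=len(cells))
    cells["elevation_m"] = np.clip(base + rough, 0.0, None)

    # climate grid: integer coarsening of the survey grid, so each climate
    # cell covers a whole block of survey cells (several survey cells per
    # ~0.10 deg climate cell, as in the real resolution mismatch)
    n_crows = -(-n_rows // coarsening)  # ceil
    n_ccols = -(-n_cols // coarsening)
    climate = _cell_frame(
        n_crows, n_ccols, SURVEY_DLAT * coarsening, SURVEY_DLON * coarsening,
        "clim_",
    )
    member_row = cells["row"] // coarsening
    member_col = cells["col"] // coarsening
    elev = (
        cells["elevation_m"]
        .groupby([member_row.to_numpy(), member_col.to_numpy()])
        .mean()
    )
    climate["elevation_m"] = [
        elev.loc[(r, c)] for r, c in zip(climate["row"], climate["col"])
    ]

    names = list(HABITATS)
    optima = np.array([HABITATS[h][0] for h in names])
    recs = []
    for cid, e in zip(cells["cell_id"], cells["elevation_m"]):
        alpha = 4.0 * np.exp(-(((e - optima) / 450.0) ** 2)) + 0.05
        frac = rng.dirichlet(alpha)
        frac = frac / frac.sum()
        recs.extend(
            {"cell_id": cid, "habitat": h, "fraction": f}
            for h, f in zip(names, frac)
        )
    return RegionFixture(
        cells=cells,
        climate_cells=climate,
        habitat_fractions=pd.DataFrame(recs),
        n_rows=n_rows,
        n_cols=n_cols,
        coarsening=coarsening,
    )


def generate_species_pool(
    n_species: int,
    frac_gymno: float,
    frac_woody: float,
    truth: TruthModel,
    seed: int,
) -> SpeciesPool:
    """Draw a species pool with habitat affiliations and replicate pi_0.

    Each species gets a primary habitat plus up to two secondary ones, an
    abundance class in {1, 0.7, 0.4, 0.1} per habitat, and a target Psi_tlp
    drawn around the weight-averaged mean of its habitats (``truth``).
    Replicate osmotic potentials pi_0 are emitted on the measurement scale:
    three individuals per species, one replicate each for herbaceous and
    three each for woody species.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    for name, f in (("frac_gymno", frac_gymno), ("frac_woody", frac_woody)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {f}")

    # import here: traits must stay import-independent of the generator
    from tlpshift.traits import DEFAULT_CALIBRATION

    rng = _rng(seed, "species")
    n_gym = int(round(frac_gymno * n_species))
    ids = [f"sp{i:04d}" for i in range(n_species)]
    groups = ["gymnosperm"] * n_gym + ["angiosperm"] * (n_species - n_gym)
    n_angio = n_species - n_gym
    n_woody_angio = int(round(frac_woody * n_angio))
    forms = ["woody"] * n_gym + ["woody"] * n_woody_angio + [
        "herbaceous"
    ] * (n_angio - n_woody_angio)

    names = list(HABITATS)
    # gymnosperms concentrate in forest/alpine habitats
    gym_habitats = ["conifer_forest", "beech_forest", "alpine_grassland"]
    weights = np.array(ABUNDANCE_WEIGHTS)
    weight_p = np.array([0.15, 0.25, 0.30, 0.30])

    ab_recs, rep_recs = [], []
    for sid, grp, form in zip(ids, groups, forms):
        pool = gym_habitats if grp == "gymnosperm" else names
        n_hab = 1 + rng.binomial(2, 0.4)
        habs = list(rng.choice(pool, size=min(n_hab, len(pool)), replace=False))
        w = rng.choice(weights, size=len(habs), p=weight_p)
        w[0] = max(w[0], 0.4)  # the primary habitat is at least "characteristic"
        for h, wi in zip(habs, w):
            ab_recs.append({"species_id": sid, "habitat": h, "weight": float(wi)})
        mean_psi = float(
            np.average([truth.habitat_psi_mean[h] for h in habs], weights=w)
        )
        psi = min(rng.normal(mean_psi, truth.habitat_psi_sd), -0.85)
        a, b = DEFAULT_CALIBRATION.a, DEFAULT_CALIBRATION.b
        pi0 = (psi - b) / a
        n_ind, n_rep = 3, (3 if form == "woody" else 1)
        for ind in range(n_ind):
            ind_off = rng.normal(0.0, 0.06)
            for rep in range(n_rep):
                val = min(pi0 + ind_off + rng.normal(0.0, 0.05), -0.05)
                rep_recs.append(
                    {
                        "species_id": sid,
                        "individual": ind,
                        "replicate": rep,
                        "pi0_mpa": val,
                    }
                )

    species = pd.DataFrame(
        {"species_id": ids, "group": groups, "growth_form": forms}
    )
    return SpeciesPool(
        species=species,
        replicates=pd.DataFrame(rep_recs),
        abundance=pd.DataFrame(ab_recs),
    )


def generate_daily_climate(
    region: RegionFixture,
    years: int,
    scenario_shift: ScenarioShift | tuple[float, float] = ScenarioShift(),
    truth: TruthModel = TruthModel(),
    seed: int = 0,
    model_id: str = "gcm_a",
    scenario_id: str = "historical",
) -> xr.Dataset:
    """Generate a daily (time, y, x) cube of tas (degC) and pr (mm/day).

    Temperature = sea-level baseline - lapse_rate x elevation + sinusoidal
    seasonal cycle + Gaussian day-to-day noise. Precipitation follows a
    two-state (wet/dry) first-order chain with gamma wet-day amounts; dry
    spells persist longer toward the southern (coastal) edge and wet-day
    amounts grow northward, giving the south both less rain and longer
    dry runs.

    Scenario shifts: temperature is additive (tas + d_temp_c). A drying
    scenario (precip_factor < 1) thins wet-day *occurrence* - each wet day
    is kept with probability precip_factor - which scales mean
    precipitation by the factor while lengthening dry spells, as drying
    scenarios do in regional projections; a wetting scenario (> 1) scales
    wet-day amounts. An identity shift reproduces the baseline cube bit
    for bit under the same seed.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if not isinstance(scenario_shift, ScenarioShift):
        scenario_shift = ScenarioShift(*scenario_shift)

    clim = region.climate_cells
    n_rows = int(clim["row"].max()) + 1
    n_cols = int(clim["col"].max()) + 1
    n_days = years * DAYS_PER_YEAR
    doy = np.tile(np.arange(DAYS_PER_YEAR), years)
    season = -truth.seasonal_amplitude_c * np.cos(
        2.0 * np.pi * (doy - 15.0) / DAYS_PER_YEAR
    )

    lat_all = clim["lat"].to_numpy()
    lat_lo, lat_hi = lat_all.min(), lat_all.max()
    lat_span = max(lat_hi - lat_lo, 1e-12)

    tas = np.empty((n_days, n_rows, n_cols))
    pr = np.empty((n_days, n_rows, n_cols))
    pf = scenario_shift.precip_factor
    for _, cell in clim.iterrows():
        r, c = int(cell["row"]), int(cell["col"])
        crng = _rng(seed, "climate", model_id, r, c)
        base = truth.base_temp_c - truth.lapse_rate_c_per_km * cell["elevation_m"] / 1000.0
        tas[:, r, c] = base + season + crng.normal(0.0, truth.temp_noise_sd_c, n_days)

        lat_frac = (cell["lat"] - lat_lo) / lat_span  # 0 south .. 1 north
        wet_factor = 1.0 + lat_frac * (truth.north_wet_factor - 1.0)
        wet_factor *= float(np.exp(crng.normal(0.0, truth.wet_roughness)))
        dry_pers = min(
            truth.dry_persistence
            + truth.south_dryness * (1.0 - lat_frac)
            + float(crng.normal(0.0, truth.dry_persistence_jitter)),
            0.98,
        )
        p_wet_stat = (1.0 - dry_pers) / max(
            2.0 - truth.wet_persistence - dry_pers, 1e-12
        )
        u = crng.random(n_days)
        amounts = crng.gamma(truth.gamma_shape, truth.gamma_scale_mm, n_days)
        wet = np.empty(n_days, dtype=bool)
        state = u[0] < p_wet_stat
        wet[0] = state
        for d in range(1, n_days):
            p_stay = truth.wet_persistence if state else 1.0 - dry_pers
            state = u[d] < p_stay
            wet[d] = state
        if pf < 1.0:  # drying: thin wet-day occurrence, keep amounts
            wet &= crng.random(n_days) < pf
        pr[:, r, c] = np.where(wet, amounts * wet_factor, 0.0)

    tas = tas + scenario_shift.d_temp_c
    if pf > 1.0:  # wetting: scale wet-day amounts
        pr = pr * pf

    y_coord = np.sort(clim.loc[clim["col"] == 0, "lat"].to_numpy())
    x_coord = np.sort(clim.loc[clim["row"] == 0, "lon"].to_numpy())
    ds = xr.Dataset(
        {
            "tas": (("time", "y", "x"), tas),
            "pr": (("time", "y", "x"), pr),
        },
        coords={
            "time": np.arange(n_days),
            "year": ("time", np.repeat(np.arange(years), DAYS_PER_YEAR)),
            "doy": ("time", doy),
            "y": y_coord,
            "x": x_coord,
        },
        attrs={
            "scenario": scenario_id,
            "model": model_id,
            "calendar": "365_day",
            "tas_units": "degC",
            "pr_units": "mm/day",
        },
    )
    return ds


def generate_occurrences(
    region: RegionFixture,
    pool: SpeciesPool,
    seed: int,
    occupancy: dict[float, float] = OCCUPANCY_BY_WEIGHT,
) -> pd.DataFrame:
    """Presence/absence matrix (cell x species) from habitat availability.

    Presence probability in a cell is
    ``sum_h fraction(h) * g(weight class of the species in h)`` with
    ``g`` given by ``occupancy`` (default :data:`OCCUPANCY_BY_WEIGHT`);
    a species with no positive weight in any habitat present in the cell
    is deterministically absent.
    """
    missing = set(pool.abundance["species_id"]) - set(pool.species["species_id"])
    if missing:
        raise ValueError(f"abundance table names unknown species: {sorted(missing)}")

    frac = region.habitat_fraction_matrix()  # cells x habitats
    g = pool.abundance.copy()
    g["occupancy"] = g["weight"].map(occupancy)
    occ_by_hab = g.pivot_table(
        index="species_id", columns="habitat", values="occupancy", fill_value=0.0
    ).reindex(pool.species["species_id"].to_numpy(), fill_value=0.0)
    habs = [h for h in frac.columns if h in occ_by_hab.columns]
    prob = frac[habs].to_numpy() @ occ_by_hab[habs].to_numpy().T  # cells x species
    prob = np.clip(prob, 0.0, 1.0)

    rng = _rng(seed, "occurrence")
    present = (rng.random(prob.shape) < prob).astype(int)
    # zero probability is absence regardless of the draw
    present[prob <= 0.0] = 0
    return pd.DataFrame(
        present, index=frac.index, columns=occ_by_hab.index
    ).rename_axis(index="cell_id", columns="species_id")


def generate_trait_response(
    bioclim: pd.DataFrame, truth: TruthModel, seed: int
) -> pd.Series:
    """Cell-level Psi_tlp from the truth's linear response to the predictors.

    This is the model-recovery fixture: with a single nonzero coefficient
    and small ``noise_sd`` the downstream forest must identify that
    predictor as dominant and reach high cross-validated R^2.
    """
    unknown = (
        set(truth.trait_coefficients) | set(truth.trait_curvature)
    ) - set(bioclim.columns)
    if unknown:
        raise ValueError(f"truth references missing predictors: {sorted(unknown)}")
    rng = _rng(seed, "trait-response")
    y = np.full(len(bioclim), truth.trait_intercept)
    for name, coef in truth.trait_coefficients.items():
        y = y + coef * bioclim[name].to_numpy()
    for name, coef in truth.trait_curvature.items():
        y = y + coef * bioclim[name].to_numpy() ** 2
    y = y + rng.normal(0.0, truth.noise_sd, len(bioclim))
    return pd.Series(y, index=bioclim.index, name="psi_tlp_mpa")


def write_grid_geojson(cells: pd.DataFrame, path) -> None:
    """Rectangular cell polygons as a GeoJSON FeatureCollection."""
    features = []
    for _, c in cells.iterrows():
        ring = [
            [c["lon_min"], c["lat_min"]],
            [c["lon_max"], c["lat_min"]],
            [c["lon_max"], c["lat_max"]],
            [c["lon_min"], c["lat_max"]],
            [c["lon_min"], c["lat_min"]],
        ]
        props = {"cell_id": c["cell_id"]}
        if "elevation_m" in cells.columns:
            props["elevation_m"] = float(c["elevation_m"])
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def write_fixtures(region: RegionFixture, pool: SpeciesPool,
                   occurrences: pd.DataFrame, outdir) -> dict[str, str]:
    """Write all tabular fixtures; returns a name -> path manifest."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _csv(name: str, df: pd.DataFrame, **kw) -> None:
        p = out / f"{name}.csv"
        df.to_csv(p, **kw)
        paths[name] = str(p)

    _csv("species_traits", pool.species.merge(pool.replicates, on="species_id"),
         index=False)
    _csv("species_habitat_weights", pool.abundance, index=False)
    _csv("habitat_fractions", region.habitat_fractions, index=False)
    _csv("occurrences", occurrences)
    _csv("survey_cells", region.cells, index=False)
    _csv("climate_cells", region.climate_cells, index=False)
    gj = out / "survey_grid.geojson"
    region.to_geojson(gj)
    paths["survey_grid"] = str(gj)
    return paths
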