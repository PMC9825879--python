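"""End-to-end orchestration: synthetic fixtures -> bioclim predictors ->
trait surfaces -> forests -> projections -> plasticity risk.

Every stage reads its inputs from the run directory if they are not in
memory, so stages can be run individually (CLI subcommands) or all at
once. All randomness descends from the single pipeline seed; two runs
with the same configuration and seed write identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import xarray as xr

from tlpshift import climate as climod
from tlpshift import model as modmod
from tlpshift import project as projmod
from tlpshift import synthgen
from tlpshift import traits as traitmod

__all__ = ["PipelineConfig", "PipelineRunner", "run_pipeline", "STAGES"]

STAGES = ("synth", "bioclim", "upscale", "fit", "project", "risk")


@dataclass
class PipelineConfig:
    """Flat configuration for a full run (synthetic-data mode)."""

    n_rows: int = 6
    n_cols: int = 8
    coarsening: int = 2
    n_species: int = 120
    frac_gymno: float = 0.06
    frac_woody: float = 0.35
    years: int = 20
    scenarios: dict[str, synthgen.ScenarioShift] = field(
        default_factory=lambda: {
            "rcp26": synthgen.ScenarioShift(1.5, 0.95),
            "rcp85": synthgen.ScenarioShift(4.0, 0.8),
        }
    )
    climate_models: tuple[str, ...] = ("gcm_a", "gcm_b", "gcm_c")
    high_emission_scenario: str = "rcp85"
    deltas: tuple[float, ...] = projmod.PLASTICITY_DELTAS
    calibration: traitmod.Calibration = field(
        default_factory=traitmod.Calibration
    )
    truth: synthgen.TruthModel = field(default_factory=synthgen.TruthModel)
    model_config: modmod.ModelConfig = field(default_factory=modmod.ModelConfig)
    groups: tuple[str, ...] = tuple(traitmod.GROUPS)
    n_perm: int = 100
    report_nested_cv: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.deltas):
            raise ValueError("plasticity deltas must be > 0")
        if self.years < 1:
            raise ValueError("years must be >= 1")
        unknown = set(self.groups) - set(traitmod.GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")
        if self.high_emission_scenario not in self.scenarios:
            raise ValueError(
                f"high_emission_scenario {self.high_emission_scenario!r} "
                f"not among scenarios {sorted(self.scenarios)}"
            )

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = {
            k: {"d_temp_c": v.d_temp_c, "precip_factor": v.precip_factor}
            for k, v in self.scenarios.items()
        }
        return d

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        """key = value file; tuples comma-separated, scenarios as
        name:dtemp:pfactor[,name:dtemp:pfactor...]. CLI overrides win."""
        kv: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        kv.update({k: v for k, v in overrides.items() if v is not None})
        kwargs: dict = {}
        ints = {"n_rows", "n_cols", "coarsening", "n_species", "years",
                "n_perm", "seed"}
        floats = {"frac_gymno", "frac_woody"}
        model_ints = {"ntree", "mtry", "min_node_size", "outer_folds",
                      "outer_reps", "inner_folds", "inner_evals"}
        model_kwargs: dict = {}
        for k, v in kv.items():
            if k in model_ints:
                model_kwargs[k] = int(v)
            elif k == "sample_fraction":
                model_kwargs[k] = float(v)
            elif k in ints:
                kwargs[k] = int(v)
            elif k in floats:
                kwargs[k] = float(v)
            elif k == "scenarios":
                sc = {}
                for part in str(v).split(","):
                    name, dt, pf = part.split(":")
                    sc[name.strip()] = synthgen.ScenarioShift(
                        float(dt), float(pf)
                    )
                kwargs[k] = sc
            elif k == "climate_models":
                kwargs[k] = tuple(s.strip() for s in str(v).split(","))
            elif k == "groups":
                kwargs[k] = tuple(s.strip() for s in str(v).split(","))
            elif k == "deltas":
                kwargs[k] = tuple(float(s) for s in str(v).split(","))
            elif k == "high_emission_scenario":
                kwargs[k] = str(v)
            elif k == "report_nested_cv":
                kwargs[k] = str(v).lower() in ("1", "true", "yes")
            elif k in ("calibration_a", "calibration_b"):
                pass  # handled below
            else:
                raise ValueError(f"unknown configuration key {k!r}")
        if model_kwargs:
            model_kwargs.setdefault("seed", int(kv.get("seed", 0)))
            kwargs["model_config"] = modmod.ModelConfig(**model_kwargs)
        if "calibration_a" in kv or "calibration_b" in kv:
            kwargs["calibration"] = traitmod.Calibration(
                a=float(kv.get("calibration_a", traitmod.DEFAULT_CALIBRATION.a)),
                b=float(kv.get("calibration_b", traitmod.DEFAULT_CALIBRATION.b)),
            )
        return cls(**kwargs)


class PipelineRunner:
    """Stage runner over a run directory; see module docstring."""

    def __init__(self, config: PipelineConfig, outdir) -> None:
        self.config = config
        self.out = Path(outdir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, str] = {}
        self._log_path = self.out / "run.log"
        # in-memory state, lazily reloaded from disk by the accessors
        self._region = self._pool = self._occ = None
        self._bioclim = self._surfaces = self._traits = None
        self._fits: dict | None = None

    # ---------------------------------------------------------------- util
    def log(self, msg: str) -> None:
        stamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(self._log_path, "a") as fh:
            fh.write(f"{stamp} {msg}\n")

    def _write_csv(self, name: str, df: pd.DataFrame, index: bool = False) -> Path:
        path = self.out / f"{name}.csv"
        df.to_csv(path, index=index)
        self.manifest[name] = str(path)
        return path

    # -------------------------------------------------------------- stages
    def stage_synth(self) -> None:
        cfg = self.config
        self.log(f"synth: region {cfg.n_rows}x{cfg.n_cols}, "
                 f"{cfg.n_species} species, seed {cfg.seed}")
        region = synthgen.generate_region(
            cfg.n_rows, cfg.n_cols, cfg.coarsening, cfg.seed
        )
        pool = synthgen.generate_species_pool(
            cfg.n_species, cfg.frac_gymno, cfg.frac_woody, cfg.truth, cfg.seed
        )
        occ = synthgen.generate_occurrences(region, pool, cfg.seed)
        fx = self.out / "fixtures"
        paths = synthgen.write_fixtures(region, pool, occ, fx)
        self.manifest.update(paths)

        cubes = self.out / "cubes"
        cubes.mkdir(exist_ok=True)
        for mdl in cfg.climate_models:
            runs = {"historical": synthgen.ScenarioShift()}
            runs.update(cfg.scenarios)
            for scen, shift in runs.items():
                cube = synthgen.generate_daily_climate(
                    region, cfg.years, shift, cfg.truth, cfg.seed,
                    model_id=mdl, scenario_id=scen,
                )
                p = cubes / f"{mdl}_{scen}.nc"
                cube.to_netcdf(p, engine="scipy")
                self.manifest[f"cube_{mdl}_{scen}"] = str(p)
        # disk is the single source of truth: downstream stages reload the
        # written fixtures so staged and single-shot runs are bit-identical
        self._region = self._pool = self._occ = None

    # lazy loaders ---------------------------------------------------------
    def _load_region(self) -> synthgen.RegionFixture:
        if self._region is None:
            fx = self.out / "fixtures"
            self._region = synthgen.RegionFixture(
                cells=pd.read_csv(fx / "survey_cells.csv"),
                climate_cells=pd.read_csv(fx / "climate_cells.csv"),
                habitat_fractions=pd.read_csv(fx / "habitat_fractions.csv"),
                n_rows=self.config.n_rows,
                n_cols=self.config.n_cols,
                coarsening=self.config.coarsening,
            )
        return self._region

    def _load_pool(self) -> synthgen.SpeciesPool:
        if self._pool is None:
            fx = self.out / "fixtures"
            reps = pd.read_csv(fx / "species_traits.csv")
            self._pool = synthgen.SpeciesPool(
                species=reps[["species_id", "group", "growth_form"]]
                .drop_duplicates()
                .reset_index(drop=True),
                replicates=reps,
                abundance=pd.read_csv(fx / "species_habitat_weights.csv"),
            )
        return self._pool

    def _load_occ(self) -> pd.DataFrame:
        if self._occ is None:
            self._occ = pd.read_csv(
                self.out / "fixtures" / "occurrences.csv", index_col="cell_id"
            )
        return self._occ

    def stage_bioclim(self) -> None:
        cfg = self.config
        region = self._load_region()
        weights = climod.overlap_weights(region.cells, region.climate_cells)
        period = {"full": (0, cfg.years - 1)}
        tables = []
        for mdl in cfg.climate_models:
            for scen in ("historical", *cfg.scenarios):
                p = self.out / "cubes" / f"{mdl}_{scen}.nc"
                with xr.open_dataset(p, engine="scipy") as cube:
                    cube.load()
                tab = climod.period_tables(cube, period)
                tables.append(tab)
        clim_table = pd.concat(tables, ignore_index=True)
        self._write_csv("bioclim_climate_grid", clim_table)
        survey = climod.extract_survey_values(
            clim_table.drop(columns=["period"]), weights
        )
        self._write_csv("bioclim_survey", survey)
        self._bioclim = None  # reload parsed CSV downstream
        self.log(f"bioclim: {len(survey)} survey rows "
                 f"({len(cfg.climate_models)} models)")

    def _load_bioclim(self) -> pd.DataFrame:
        if self._bioclim is None:
            self._bioclim = pd.read_csv(self.out / "bioclim_survey.csv")
        return self._bioclim

    def stage_upscale(self) -> None:
        cfg = self.config
        pool = self._load_pool()
        occ = self._load_occ()
        region = self._load_region()
        reps = pool.replicates
        if "group" not in reps.columns:
            reps = reps.merge(pool.species, on="species_id")
        traits = traitmod.species_trait_table(reps, calibration=cfg.calibration)
        self._write_csv("species_psi_tlp", traits)
        self._traits = None

        surfaces = []
        for group in cfg.groups:
            surf = traitmod.ogu_trait_surface(
                region.habitat_fractions, occ, pool.abundance, traits, group
            )
            surfaces.append(surf)
            self.log(f"upscale: group {group}: {len(surf)} cells with values")
        surfaces = pd.concat(surfaces, ignore_index=True)
        self._write_csv("trait_surfaces_measured", surfaces)
        self._write_surface_geojson(
            "trait_surfaces_measured", surfaces, "psi_tlp_mpa"
        )
        self._surfaces = None

        # habitat-level ANOVA on species values mapped through affiliations
        by_hab = pool.abundance.merge(traits, on="species_id")
        try:
            res = traitmod.habitat_anova(by_hab)
            self._write_csv("habitat_tukey", res.tukey)
            summary = {
                "f_statistic": res.f_statistic,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p_value": res.p_value,
                "letters": res.letters,
            }
            with open(self.out / "habitat_anova.json", "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
            self.manifest["habitat_anova"] = str(self.out / "habitat_anova.json")
        except ValueError as exc:
            self.log(f"upscale: habitat ANOVA skipped ({exc})")

    def _load_surfaces(self) -> pd.DataFrame:
        if self._surfaces is None:
            self._surfaces = pd.read_csv(
                self.out / "trait_surfaces_measured.csv"
            )
        return self._surfaces

    def _load_traits(self) -> pd.DataFrame:
        if self._traits is None:
            self._traits = pd.read_csv(self.out / "species_psi_tlp.csv")
        return self._traits

    def stage_fit(self) -> None:
        cfg = self.config
        bioclim = self._load_bioclim()
        surfaces = self._load_surfaces()
        region = self._load_region()
        cells = region.cells.set_index("cell_id")
        predictors = list(synthgen.PREDICTORS)

        fits: dict[tuple[str, str], modmod.ModelFit] = {}
        cv_rows, imp_rows, pd_rows = [], [], []
        trial_rows, fold_rows = [], []
        mdir = self.out / "models"
        mdir.mkdir(exist_ok=True)
        for group in cfg.groups:
            surf = surfaces[surfaces["group"] == group]
            if len(surf) < cfg.model_config.outer_folds:
                self.log(f"fit: group {group} has too few cells, skipped")
                continue
            for mdl in cfg.climate_models:
                hist = bioclim[
                    (bioclim["model"] == mdl)
                    & (bioclim["scenario"] == "historical")
                ].set_index("cell_id")
                rows = surf["cell_id"].to_numpy()
                X = hist.loc[rows, predictors]
                y = surf["psi_tlp_mpa"].to_numpy()
                cent = cells.loc[rows, ["lon", "lat"]].to_numpy()
                cv = None
                if cfg.report_nested_cv:
                    cv = modmod.nested_spatial_cv(X, y, cent, cfg.model_config)
                    for _, r in cv.folds.iterrows():
                        cv_rows.append(
                            {"group": group, "model": mdl, **r.to_dict()}
                        )
                fit = modmod.tune_final_model(
                    X, y, cent, cfg.model_config, group=group,
                    climate_model=mdl, cv=cv,
                )
                fits[(group, mdl)] = fit
                fpath = mdir / f"fit_{group}_{mdl}.joblib"
                modmod.save_fit(fit, fpath)
                self.manifest[f"fit_{group}_{mdl}"] = str(fpath)
                trials = fit.tuning_trials.copy()
                trials["group"] = group
                trials["model"] = mdl
                trial_rows.append(trials)
                fold_rows.append(pd.DataFrame(
                    {"cell_id": rows, "group": group, "model": mdl,
                     "fold": fit.fold_labels}
                ))

                imp = modmod.permutation_importance(
                    fit, X, y, n_perm=cfg.n_perm, seed=cfg.seed
                )
                imp["group"] = group
                imp["model"] = mdl
                imp_rows.append(imp)
                top = imp.iloc[0]["predictor"]
                pdc = modmod.partial_dependence(fit, X, top)
                pdc["group"] = group
                pdc["model"] = mdl
                pdc["predictor"] = top
                pd_rows.append(pdc)
                self.log(
                    f"fit: {group} x {mdl}: params {fit.params}, "
                    f"top predictor {top}"
                )
        self._fits = None  # reload from the persisted files downstream
        if trial_rows:
            self._write_csv(
                "tuning_trials", pd.concat(trial_rows, ignore_index=True)
            )
            self._write_csv(
                "fold_assignments", pd.concat(fold_rows, ignore_index=True)
            )
        if cv_rows:
            self._write_csv("model_cv", pd.DataFrame(cv_rows))
        if imp_rows:
            self._write_csv(
                "variable_importance", pd.concat(imp_rows, ignore_index=True)
            )
            self._write_csv(
                "partial_dependence", pd.concat(pd_rows, ignore_index=True)
            )

    def _load_fits(self) -> dict[tuple[str, str], modmod.ModelFit]:
        if self._fits is None:
            fits = {}
            for p in sorted((self.out / "models").glob("fit_*.joblib")):
                fit = modmod.load_fit(p)
                fits[(fit.group, fit.climate_model)] = fit
            self._fits = fits
        return self._fits

    def stage_project(self) -> None:
        cfg = self.config
        bioclim = self._load_bioclim()
        fits = self._load_fits()
        future = {
            (scen, mdl): bioclim[
                (bioclim["scenario"] == scen) & (bioclim["model"] == mdl)
            ].reset_index(drop=True)
            for scen in cfg.scenarios
            for mdl in cfg.climate_models
        }
        surfaces = self._load_surfaces()
        measured = {
            g: surfaces[surfaces["group"] == g].reset_index(drop=True)
            for g in surfaces["group"].unique()
        }
        result = projmod.run_projection_suite(
            fits,
            future,
            measured,
            self._load_occ(),
            self._load_traits(),
            cfg.high_emission_scenario,
            deltas=cfg.deltas,
        )
        self._suite = result
        self._write_csv("projections_delta_psi", result.projections)
        self._write_csv("ensemble_congruence", result.ensemble)
        high = result.projections[
            result.projections["scenario"] == cfg.high_emission_scenario
        ]
        mean_shift = (
            high.groupby(["cell_id", "group"], as_index=False)
            ["delta_psi_tlp_pct"].mean()
        )
        self._write_surface_geojson(
            "projections_delta_psi", mean_shift, "delta_psi_tlp_pct"
        )
        for line in result.log:
            self.log(f"project: {line}")

    def stage_risk(self) -> None:
        result = getattr(self, "_suite", None)
        if result is None:
            self.stage_project()
            result = self._suite
        self._write_csv("plasticity_risk", result.plasticity)
        self._write_csv("plasticity_regional", result.regional)

    def _write_surface_geojson(self, name: str, table: pd.DataFrame,
                               value_column: str) -> None:
        """Choropleth-ready GeoJSON: cell polygons with per-group values."""
        import json as _json

        cells = self._load_region().cells.set_index("cell_id")
        features = []
        for cell_id, sub in table.groupby("cell_id"):
            c = cells.loc[cell_id]
            ring = [
                [c["lon_min"], c["lat_min"]], [c["lon_max"], c["lat_min"]],
                [c["lon_max"], c["lat_max"]], [c["lon_min"], c["lat_max"]],
                [c["lon_min"], c["lat_min"]],
            ]
            props = {"cell_id": cell_id}
            for _, row in sub.iterrows():
                key = f"{value_column}__{row['group']}" if "group" in sub.columns else value_column
                props[key] = float(row[value_column])
            features.append(
                {"type": "Feature",
                 "geometry": {"type": "Polygon", "coordinates": [ring]},
                 "properties": props}
            )
        path = self.out / f"{name}.geojson"
        with open(path, "w") as fh:
            _json.dump({"type": "FeatureCollection", "features": features}, fh)
        self.manifest[f"{name}_geojson"] = str(path)

    # ----------------------------------------------------------------- run
    def run(self, stages=STAGES) -> dict:
        started = {s: False for s in stages}
        for stage in stages:
            self.log(f"stage {stage}: start")
            try:
                getattr(self, f"stage_{stage}")()
            except Exception as exc:
                self.log(f"stage {stage}: FAILED: {exc}")
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
            started[stage] = True
            self.log(f"stage {stage}: done")
        manifest = {
            "config": self.config.echo(),
            "stages": [s for s in stages if started[s]],
            "artifacts": dict(sorted(self.manifest.items())),
        }
        with open(self.out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def run_pipeline(config: PipelineConfig, outdir, stages=STAGES) -> dict:
    """Run the requested stages under ``outdir`` and return the manifest."""
    return PipelineRunner(config, outdir).run(stages)
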