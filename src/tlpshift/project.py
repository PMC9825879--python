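"""Future Psi_tlp surfaces, shift maps, ensemble congruence and
plasticity-risk simulation.

The shift is reported as the relative deviation of the predicted from the
measured value, Delta_Psi_tlp = (predicted - measured) / measured x 100.
NOTE on sign: measured Psi_tlp is negative, so a shift toward *more
negative* Psi_tlp (greater drought resistance demanded) yields a
*positive* Delta_Psi_tlp. Map legends must state this.

Ensemble congruence is the coefficient of variation (%) of the predicted
Psi_tlp across climate models, computed as 100 * sd / |mean| so the CV of
negative potentials is positive; low CV = high agreement.

The plasticity simulation assumes each species' measured Psi_tlp is the
median of its seasonal plasticity envelope [Psi_s - delta, Psi_s + delta]
(delta = 0.44 MPa high / 0.22 MPa low plasticity). In each cell, species
whose envelope does not include the cell's predicted Psi_tlp are counted
as threatened there; bounds are closed, so a prediction exactly at a
bound counts as within. Species are counted, not abundance-weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tlpshift.model import ModelFit

__all__ = [
    "PLASTICITY_DELTAS",
    "predict_surface",
    "delta_psi_tlp",
    "ensemble_and_congruence",
    "plasticity_risk",
    "run_projection_suite",
    "ProjectionSuiteResult",
]

#: high / low seasonal osmotic-adjustment capacity (MPa)
PLASTICITY_DELTAS = (0.44, 0.22)


def predict_surface(fit: ModelFit, bioclim: pd.DataFrame,
                    cell_column: str = "cell_id") -> pd.DataFrame:
    """Predicted Psi_tlp per cell from a fitted forest and a bioclim table.

    The fit's stored standardisation parameters are applied to the future
    predictors; a missing predictor column is an error.
    """
    preds = fit.predict(bioclim)
    return pd.DataFrame(
        {
            "cell_id": bioclim[cell_column].to_numpy()
            if cell_column in bioclim.columns
            else bioclim.index.to_numpy(),
            "group": fit.group,
            "psi_tlp_mpa": preds,
            "flag": "predicted",
        }
    )


def delta_psi_tlp(measured, predicted):
    """Relative shift (%) of predicted from measured Psi_tlp.

    Evaluates (predicted - measured)/measured * 100 literally; with
    negative measured values a more negative prediction gives a positive
    shift (see module docstring).
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if np.any(m >= 0):
        raise ValueError("measured Psi_tlp must be < 0 MPa")
    out = (p - m) / m * 100.0
    return float(out) if np.isscalar(measured) else out


def ensemble_and_congruence(
    predictions: pd.DataFrame,
    cell_column: str = "cell_id",
    value_column: str = "psi_tlp_mpa",
    model_column: str = "model",
) -> pd.DataFrame:
    """Per-cell ensemble mean and congruence CV (%) across climate models.

    With a single model the ensemble is returned and the congruence is
    missing (a CV over one value is undefined), with a warning.
    """
    n_models = predictions.groupby(cell_column)[model_column].nunique()
    if (n_models < 2).any():
        warnings.warn(
            "single-model ensemble: congruence undefined for some cells",
            stacklevel=2,
        )
    g = predictions.groupby(cell_column)[value_column]
    mean = g.mean()
    sd = g.std(ddof=1)  # NaN where only one model
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = 100.0 * sd / mean.abs()
    out = pd.DataFrame(
        {
            "ensemble_psi_tlp_mpa": mean,
            "congruence_cv_pct": cv,
        }
    ).reset_index()
    return out


def plasticity_risk(species_psi, predicted: float, delta: float) -> dict:
    """Classify each species' plasticity envelope against the prediction.

    Returns the percentage of species whose envelope lies entirely below
    the prediction (predicted > Psi_s + delta), entirely above it
    (predicted < Psi_s - delta), or includes it. ``within`` is computed
    as the complement so the three percentages sum to exactly 100.
    """
    psi = np.asarray(species_psi, dtype=float)
    if psi.size == 0:
        raise ValueError("cell has no measured occurring species")
    if delta <= 0:
        raise ValueError("delta must be > 0 MPa")
    below = int(np.sum(predicted > psi + delta))
    above = int(np.sum(predicted < psi - delta))
    n = psi.size
    pct_below = 100.0 * below / n
    pct_above = 100.0 * above / n
    pct_within = 100.0 - pct_below - pct_above
    return {
        "n_species": n,
        "pct_envelope_below": pct_below,
        "pct_within": pct_within,
        "pct_envelope_above": pct_above,
        "pct_threatened": pct_below + pct_above,
    }


@dataclass
class ProjectionSuiteResult:
    projections: pd.DataFrame  # cell x group x scenario x model shifts
    ensemble: pd.DataFrame  # cell x group x scenario ensemble + congruence
    plasticity: pd.DataFrame  # cell x group x delta percentages
    regional: pd.DataFrame  # group x delta mean +/- SD threatened %
    log: list[str] = field(default_factory=list)


def run_projection_suite(
    fits: dict[tuple[str, str], ModelFit],
    future_bioclim: dict[tuple[str, str], pd.DataFrame],
    measured_surfaces: dict[str, pd.DataFrame],
    occurrences: pd.DataFrame,
    traits: pd.DataFrame,
    high_emission_scenario: str,
    deltas: tuple[float, ...] = PLASTICITY_DELTAS,
) -> ProjectionSuiteResult:
    """Project all (group, scenario, model) combinations and run the
    plasticity simulation on the high-emission ensemble.

    ``fits`` is keyed by (group, climate model); ``future_bioclim`` by
    (scenario, climate model) with survey-cell rows; ``measured_surfaces``
    by group. The plasticity simulation uses pooled angiosperms and
    gymnosperms on the high-emission ensemble prediction, for every delta.
    """
    groups = sorted({g for g, _ in fits})
    models = sorted({m for _, m in fits})
    scenarios = sorted({s for s, _ in future_bioclim})
    gaps = [(g, m) for g in groups for m in models if (g, m) not in fits]
    if gaps:
        raise ValueError(f"missing model fits for group x model: {gaps}")
    if high_emission_scenario not in scenarios:
        raise ValueError(
            f"high-emission scenario {high_emission_scenario!r} not among "
            f"projected scenarios {scenarios}"
        )

    log: list[str] = []
    proj_rows = []
    for (scenario, mdl), bio in future_bioclim.items():
        for group in groups:
            fit = fits[(group, mdl)]
            surf = predict_surface(fit, bio)
            measured = measured_surfaces[group].set_index("cell_id")[
                "psi_tlp_mpa"
            ]
            surf = surf[surf["cell_id"].isin(measured.index)]
            m = measured.loc[surf["cell_id"]].to_numpy()
            proj_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": surf["cell_id"].to_numpy(),
                        "group": group,
                        "scenario": scenario,
                        "model": mdl,
                        "measured_psi_tlp_mpa": m,
                        "predicted_psi_tlp_mpa": surf["psi_tlp_mpa"].to_numpy(),
                        "delta_psi_tlp_pct": delta_psi_tlp(
                            m, surf["psi_tlp_mpa"].to_numpy()
                        ),
                    }
                )
            )
    projections = pd.concat(proj_rows, ignore_index=True).sort_values(
        ["group", "scenario", "model", "cell_id"], ignore_index=True
    )

    ens_rows = []
    for (group, scenario), sub in projections.groupby(["group", "scenario"]):
        ens = ensemble_and_congruence(sub, value_column="predicted_psi_tlp_mpa")
        ens["group"] = group
        ens["scenario"] = scenario
        ens_rows.append(ens)
    ensemble = pd.concat(ens_rows, ignore_index=True)[
        ["cell_id", "group", "scenario", "ensemble_psi_tlp_mpa",
         "congruence_cv_pct"]
    ].sort_values(["group", "scenario", "cell_id"], ignore_index=True)

    # plasticity: pooled angiosperms and gymnosperms, high-emission ensemble
    psi_by_species = traits.set_index("species_id")["psi_tlp_mpa"]
    plast_rows = []
    for group in ("angiosperm", "gymnosperm"):
        if group not in groups:
            log.append(f"plasticity: group {group!r} has no fits, skipped")
            continue
        ens_g = ensemble[
            (ensemble["group"] == group)
            & (ensemble["scenario"] == high_emission_scenario)
        ].set_index("cell_id")["ensemble_psi_tlp_mpa"]
        clade_species = set(traits.loc[traits["group"] == group, "species_id"])
        for cell_id, predicted in ens_g.items():
            occ_row = occurrences.loc[cell_id]
            present = set(occ_row.index[occ_row.to_numpy() > 0])
            sp = sorted((present & clade_species) & set(psi_by_species.index))
            if not sp:
                log.append(f"plasticity: cell {cell_id} has no {group} species")
                continue
            psis = psi_by_species.loc[sp].to_numpy()
            for delta in deltas:
                rec = plasticity_risk(psis, float(predicted), delta)
                rec.update(cell_id=cell_id, group=group, delta_mpa=delta)
                plast_rows.append(rec)
    plasticity = pd.DataFrame(plast_rows)
    if len(plasticity):
        plasticity = plasticity[
            ["cell_id", "group", "delta_mpa", "n_species",
             "pct_envelope_below", "pct_within", "pct_envelope_above",
             "pct_threatened"]
        ].sort_values(["group", "delta_mpa", "cell_id"], ignore_index=True)
        regional = (
            plasticity.groupby(["group", "delta_mpa"])["pct_threatened"]
            .agg(mean_threatened_pct="mean", sd_threatened_pct="std")
            .reset_index()
        )
    else:
        regional = pd.DataFrame(
            columns=["group", "delta_mpa", "mean_threatened_pct",
                     "sd_threatened_pct"]
        )
    return ProjectionSuiteResult(
        projections=projections,
        ensemble=ensemble,
        plasticity=plasticity,
        regional=regional,
        log=log,
    )
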