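"""Turgor-loss-point trait processing and habitat-weighted upscaling.

The leaf water potential at turgor loss (Psi_tlp, MPa, negative) is
estimated from the osmotic potential at full turgor (pi_0) measured with a
dew-point hygrometer, via a linear calibration Psi_tlp = a*pi_0 + b.
Species values are replicate means. Cell-level surfaces are built with a
four-step community-weighted procedure:

1. the fractional cover of each habitat in each grid cell is taken from
   the habitat map;
2. each species carries a per-habitat abundance-class weight
   (dominant 1, co-dominant 0.7, characteristic 0.4, uncommon 0.1);
3. within a cell, species not occurring there are filtered out and each
   habitat's Psi_tlp_hab is the abundance-weighted mean over the
   remaining measured species;
4. the cell value is the cover-weighted mean of the habitat values,
   renormalised over the habitats that actually contributed (habitats
   with no measured species are treated as missing, not zero, and the
   contributing cover is reported as ``coverage``).

Surfaces are produced per group - gymnosperms, angiosperms, herbaceous
angiosperms, woody angiosperms - by filtering the species pool before
step 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "Calibration",
    "DEFAULT_CALIBRATION",
    "GROUPS",
    "psi_tlp_from_pi0",
    "species_trait_table",
    "habitat_trait_value",
    "ogu_trait_surface",
    "habitat_anova",
    "HabitatAnova",
]

VALID_WEIGHTS = frozenset({1.0, 0.7, 0.4, 0.1})


@dataclass(frozen=True)
class Calibration:
    """Linear pi_0 -> Psi_tlp map; coefficients are instrument-specific
    and should be overridden when a lab calibration is available."""

    a: float = 0.832
    b: float = -0.631


#: stand-in coefficients from the osmometer literature, configurable
DEFAULT_CALIBRATION = Calibration()

#: group label -> (clade filter, growth-form filter or None)
GROUPS: dict[str, tuple[str, str | None]] = {
    "gymnosperm": ("gymnosperm", None),
    "angiosperm": ("angiosperm", None),
    "herbaceous-angiosperm": ("angiosperm", "herbaceous"),
    "woody-angiosperm": ("angiosperm", "woody"),
}


def psi_tlp_from_pi0(pi0, calibration: Calibration = DEFAULT_CALIBRATION):
    """Psi_tlp = a*pi_0 + b. pi_0 must be negative (it is a water potential
    at full turgor); non-negative inputs indicate unit or sign errors."""
    arr = np.asarray(pi0, dtype=float)
    if np.any(arr >= 0):
        raise ValueError("pi_0 must be < 0 MPa")
    out = calibration.a * arr + calibration.b
    return float(out) if np.isscalar(pi0) else out


def species_trait_table(
    replicates: pd.DataFrame,
    value_column: str = "pi0_mpa",
    value_type: str = "pi0",
    calibration: Calibration = DEFAULT_CALIBRATION,
    nan_policy: str = "error",
) -> pd.DataFrame:
    """Aggregate replicate measurements to one Psi_tlp per species.

    ``replicates`` must carry species_id, group, growth_form and the
    measurement column (pi_0 or direct Psi_tlp per ``value_type``). The
    species value is the arithmetic mean of replicate Psi_tlp values.
    NaN replicates raise by default (``nan_policy="drop"`` discards them;
    a species losing all replicates is still an error, named).
    """
    if value_type not in ("pi0", "psi_tlp"):
        raise ValueError("value_type must be 'pi0' or 'psi_tlp'")
    if nan_policy not in ("error", "drop"):
        raise ValueError("nan_policy must be 'error' or 'drop'")
    df = replicates.copy()
    bad = df[df[value_column].isna()]
    if len(bad):
        if nan_policy == "error":
            raise ValueError(
                "NaN replicate values for species: "
                + ", ".join(sorted(bad["species_id"].unique()))
            )
        df = df.dropna(subset=[value_column])
    empty = set(replicates["species_id"]) - set(df["species_id"])
    if empty:
        raise ValueError(
            "species with zero usable replicates: " + ", ".join(sorted(empty))
        )
    if value_type == "pi0":
        df["psi_rep"] = psi_tlp_from_pi0(df[value_column].to_numpy(), calibration)
    else:
        if np.any(df[value_column].to_numpy() >= 0):
            raise ValueError("Psi_tlp replicates must be < 0 MPa")
        df["psi_rep"] = df[value_column]
    out = (
        df.groupby(["species_id", "group", "growth_form"], as_index=False)
        .agg(psi_tlp_mpa=("psi_rep", "mean"), n_replicates=("psi_rep", "size"))
    )
    return out


def _check_abundance(abundance: pd.DataFrame) -> None:
    bad_w = set(abundance["weight"].unique()) - VALID_WEIGHTS
    if bad_w:
        raise ValueError(f"invalid abundance weights: {sorted(bad_w)}")
    dup = abundance.duplicated(subset=["species_id", "habitat"])
    if dup.any():
        pairs = abundance.loc[dup, ["species_id", "habitat"]].values.tolist()
        raise ValueError(f"duplicate species-habitat entries: {pairs}")


def habitat_trait_value(
    habitat: str,
    present_species: set[str],
    abundance: pd.DataFrame,
    traits: pd.DataFrame,
) -> float | None:
    """Psi_tlp_hab: abundance-weighted mean over present, measured species.

    Returns None when no species qualifies - the habitat then contributes
    nothing to the cell mean (missing, never zero).
    """
    _check_abundance(abundance)
    sub = abundance[
        (abundance["habitat"] == habitat)
        & (abundance["weight"] > 0)
        & abundance["species_id"].isin(present_species)
    ].merge(traits[["species_id", "psi_tlp_mpa"]], on="species_id", how="inner")
    if sub.empty:
        return None
    return float(np.average(sub["psi_tlp_mpa"], weights=sub["weight"]))


def ogu_trait_surface(
    habitat_fractions: pd.DataFrame,
    occurrences: pd.DataFrame,
    abundance: pd.DataFrame,
    traits: pd.DataFrame,
    group: str,
) -> pd.DataFrame:
    """Per-cell measured Psi_tlp surface for one clade/growth-form group.

    ``habitat_fractions``: long table (cell_id, habitat, fraction);
    ``occurrences``: binary cell x species matrix. Returns one row per
    cell with a defined value: cell_id, group, psi_tlp_mpa, n_species,
    coverage (summed fraction of contributing habitats), flag='measured'.
    Cells where no habitat qualifies are absent from the result.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {list(GROUPS)}")
    _check_abundance(abundance)
    clade, form = GROUPS[group]
    sel = traits["group"] == clade
    if form is not None:
        sel &= traits["growth_form"] == form
    gtraits = traits.loc[sel, ["species_id", "psi_tlp_mpa"]]
    psi_by_sp = gtraits.set_index("species_id")["psi_tlp_mpa"]

    ab = abundance[
        abundance["species_id"].isin(psi_by_sp.index) & (abundance["weight"] > 0)
    ]
    rows = []
    for cell_id, frac in habitat_fractions.groupby("cell_id"):
        occ_row = occurrences.loc[cell_id]
        present = set(occ_row.index[occ_row.to_numpy() > 0])
        num = den = 0.0
        contributing: set[str] = set()
        for _, hrow in frac.iterrows():
            f = hrow["fraction"]
            if f <= 0:
                continue
            sub = ab[(ab["habitat"] == hrow["habitat"])
                     & ab["species_id"].isin(present)]
            if sub.empty:
                continue
            psi_hab = np.average(
                psi_by_sp.loc[sub["species_id"]].to_numpy(),
                weights=sub["weight"].to_numpy(),
            )
            num += f * psi_hab
            den += f
            contributing |= set(sub["species_id"])
        if den > 0:
            rows.append(
                {
                    "cell_id": cell_id,
                    "group": group,
                    "psi_tlp_mpa": num / den,
                    "n_species": len(contributing),
                    "coverage": den,
                    "flag": "measured",
                }
            )
    return pd.DataFrame(
        rows, columns=["cell_id", "group", "psi_tlp_mpa", "n_species",
                       "coverage", "flag"]
    )


@dataclass
class HabitatAnova:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    tukey: pd.DataFrame
    letters: dict[str, str]


def _compact_letters(groups: list[str], significant: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are not significantly different; every
    non-significant pair shares at least one letter.
    """
    columns: list[set[str]] = [set(groups)]
    for pair in significant:
        a, b = tuple(pair)
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                ca, cb = col - {b}, col - {a}
                for c in (ca, cb):
                    if not any(c <= other for other in columns):
                        columns.append(c)
    # absorb columns contained in others
    columns = [c for c in columns if not any(c < o for o in columns)]
    columns.sort(key=lambda c: sorted(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in sorted(col):
            letters[g] += letter
    return letters


def habitat_anova(values: pd.DataFrame, habitat_column: str = "habitat",
                  value_column: str = "psi_tlp_mpa",
                  alpha: float = 0.05) -> HabitatAnova:
    """One-way ANOVA of Psi_tlp across habitats + Tukey HSD letter groups.

    Habitats with fewer than two values are dropped with a warning; at
    least two habitats must remain.
    """
    counts = values.groupby(habitat_column)[value_column].size()
    thin = counts[counts < 2]
    if len(thin):
        warnings.warn(
            f"dropping habitats with <2 values: {sorted(thin.index)}",
            stacklevel=2,
        )
        values = values[~values[habitat_column].isin(thin.index)]
    groups = [g for _, g in values.groupby(habitat_column)[value_column]]
    names = sorted(values[habitat_column].unique())
    if len(groups) < 2:
        raise ValueError("need at least two habitats with >= 2 values each")
    f_stat, p = stats.f_oneway(*[g.to_numpy() for g in groups])
    k = len(groups)
    n = sum(len(g) for g in groups)

    tk = pairwise_tukeyhsd(
        values[value_column].to_numpy(),
        values[habitat_column].to_numpy(),
        alpha=alpha,
    )
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    significant = {
        frozenset((row["group1"], row["group2"]))
        for _, row in tukey.iterrows()
        if bool(row["reject"])
    }
    letters = _compact_letters(names, significant)
    return HabitatAnova(
        f_statistic=float(f_stat),
        df_between=k - 1,
        df_within=n - k,
        p_value=float(p),
        tukey=tukey,
        letters=letters,
    )
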