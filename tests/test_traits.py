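"""Calibration, replicate aggregation, upscaling oracle, habitat ANOVA."""

import numpy as np
import pandas as pd
import pytest

from tlpshift import synthgen, traits
from tests.conftest import brute_force_surface


class TestCalibration:
    def test_identity_calibration(self):
        assert traits.psi_tlp_from_pi0(
            -2.0, traits.Calibration(a=1.0, b=0.0)
        ) == pytest.approx(-2.0)

    def test_default_coefficients(self):
        # 0.832 * (-2.0) - 0.631
        assert traits.psi_tlp_from_pi0(-2.0) == pytest.approx(-2.295)

    def test_positive_pi0_rejected(self):
        with pytest.raises(ValueError):
            traits.psi_tlp_from_pi0(0.5)


def _reps(values, species="sp1", group="angiosperm", form="herbaceous"):
    return pd.DataFrame(
        {
            "species_id": species,
            "group": group,
            "growth_form": form,
            "pi0_mpa": values,
        }
    )


class TestSpeciesTraitTable:
    def test_single_replicate(self):
        out = traits.species_trait_table(
            _reps([-2.0]), value_type="psi_tlp", value_column="pi0_mpa"
        )
        assert out.loc[0, "psi_tlp_mpa"] == pytest.approx(-2.0)

    def test_replicate_mean(self):
        out = traits.species_trait_table(
            _reps([-2.0, -2.2, -1.8]), value_type="psi_tlp"
        )
        assert out.loc[0, "psi_tlp_mpa"] == pytest.approx(-2.0)
        assert out.loc[0, "n_replicates"] == 3

    def test_calibration_commutes_with_mean(self):
        out = traits.species_trait_table(_reps([-2.0, -2.4]))
        assert out.loc[0, "psi_tlp_mpa"] == pytest.approx(
            0.832 * -2.2 - 0.631
        )

    def test_nan_policy(self):
        bad = _reps([-2.0, np.nan])
        with pytest.raises(ValueError, match="sp1"):
            traits.species_trait_table(bad)
        out = traits.species_trait_table(bad, nan_policy="drop")
        assert out.loc[0, "n_replicates"] == 1
        all_nan = _reps([np.nan])
        with pytest.raises(ValueError, match="sp1"):
            traits.species_trait_table(all_nan, nan_policy="drop")


def _ab(rows):
    return pd.DataFrame(
        rows, columns=["species_id", "habitat", "weight"]
    )


def _traits(psi):
    return pd.DataFrame(
        {
            "species_id": list(psi),
            "group": "angiosperm",
            "growth_form": "herbaceous",
            "psi_tlp_mpa": list(psi.values()),
        }
    )


class TestHabitatTraitValue:
    def test_single_species(self):
        v = traits.habitat_trait_value(
            "H", {"a"}, _ab([("a", "H", 1.0)]), _traits({"a": -2.0})
        )
        assert v == pytest.approx(-2.0)

    def test_weighted_average(self):
        v = traits.habitat_trait_value(
            "H",
            {"a", "b"},
            _ab([("a", "H", 1.0), ("b", "H", 0.4)]),
            _traits({"a": -2.0, "b": -1.0}),
        )
        assert v == pytest.approx(-1.714286, abs=1e-6)

    def test_absent_species_filtered(self):
        v = traits.habitat_trait_value(
            "H",
            {"a"},  # b occurs in the table but not in the cell
            _ab([("a", "H", 1.0), ("b", "H", 0.7)]),
            _traits({"a": -2.0, "b": -3.0}),
        )
        assert v == pytest.approx(-2.0)

    def test_no_qualifying_species_is_missing(self):
        v = traits.habitat_trait_value(
            "H", set(), _ab([("a", "H", 1.0)]), _traits({"a": -2.0})
        )
        assert v is None

    def test_duplicate_species_habitat_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            traits.habitat_trait_value(
                "H",
                {"a"},
                _ab([("a", "H", 1.0), ("a", "H", 0.4)]),
                _traits({"a": -2.0}),
            )


def _cell_inputs(fractions, psi, weights):
    hf = pd.DataFrame(
        [{"cell_id": "c1", "habitat": h, "fraction": f}
         for h, f in fractions.items()]
    )
    occ = pd.DataFrame(
        {s: [1] for s in psi}, index=pd.Index(["c1"], name="cell_id")
    )
    return hf, occ, _ab(weights), _traits(psi)


class TestOguTraitSurface:
    def test_single_habitat(self):
        hf, occ, ab, tt = _cell_inputs(
            {"A": 1.0}, {"a": -2.0}, [("a", "A", 1.0)]
        )
        out = traits.ogu_trait_surface(hf, occ, ab, tt, "angiosperm")
        assert out.loc[0, "psi_tlp_mpa"] == pytest.approx(-2.0)

    def test_two_habitat_mix(self):
        hf, occ, ab, tt = _cell_inputs(
            {"A": 0.6, "B": 0.4},
            {"a": -2.0, "b": -1.0},
            [("a", "A", 1.0), ("b", "B", 1.0)],
        )
        out = traits.ogu_trait_surface(hf, occ, ab, tt, "angiosperm")
        assert out.loc[0, "psi_tlp_mpa"] == pytest.approx(-1.6)
        assert out.loc[0, "coverage"] == pytest.approx(1.0)

    def test_renormalization_over_undefined_habitat(self):
        hf, occ, ab, tt = _cell_inputs(
            {"A": 0.6, "B": 0.4}, {"a": -2.0}, [("a", "A", 1.0)]
        )
        out = traits.ogu_trait_surface(hf, occ, ab, tt, "angiosperm")
        assert out.loc[0, "psi_tlp_mpa"] == pytest.approx(-2.0)
        assert out.loc[0, "coverage"] == pytest.approx(0.6)

    def test_unknown_group_rejected(self):
        hf, occ, ab, tt = _cell_inputs(
            {"A": 1.0}, {"a": -2.0}, [("a", "A", 1.0)]
        )
        with pytest.raises(ValueError, match="group"):
            traits.ogu_trait_surface(hf, occ, ab, tt, "bryophyte")

    def test_matches_brute_force_oracle(self, region, pool, occurrences,
                                        trait_table):
        psi = dict(
            zip(trait_table["species_id"], trait_table["psi_tlp_mpa"])
        )
        angio = set(
            trait_table.loc[
                trait_table["group"] == "angiosperm", "species_id"
            ]
        )
        out = traits.ogu_trait_surface(
            region.habitat_fractions, occurrences, pool.abundance,
            trait_table, "angiosperm",
        ).set_index("cell_id")["psi_tlp_mpa"]
        oracle = brute_force_surface(
            region.habitat_fractions,
            occurrences,
            pool.abundance,
            {s: p for s, p in psi.items() if s in angio},
        )
        assert set(out.index) == set(oracle)
        for cid, val in oracle.items():
            assert out[cid] == pytest.approx(val, abs=1e-12)

    def test_scale_equivariance_and_bounds(self, region, pool, occurrences,
                                           trait_table):
        out1 = traits.ogu_trait_surface(
            region.habitat_fractions, occurrences, pool.abundance,
            trait_table, "angiosperm",
        )
        scaled = trait_table.copy()
        scaled["psi_tlp_mpa"] *= 3.0
        out3 = traits.ogu_trait_surface(
            region.habitat_fractions, occurrences, pool.abundance, scaled,
            "angiosperm",
        )
        assert np.allclose(
            out3["psi_tlp_mpa"], 3.0 * out1["psi_tlp_mpa"], atol=1e-12
        )
        lo = trait_table["psi_tlp_mpa"].min()
        hi = trait_table["psi_tlp_mpa"].max()
        assert out1["psi_tlp_mpa"].between(lo, hi).all()

    def test_unobserved_species_is_inert(self, region, pool, occurrences,
                                         trait_table):
        occ = occurrences.copy()
        sp = trait_table.loc[
            trait_table["group"] == "angiosperm", "species_id"
        ].iloc[0]
        occ[sp] = 0  # absent from every cell
        base = traits.ogu_trait_surface(
            region.habitat_fractions, occ, pool.abundance, trait_table,
            "angiosperm",
        )
        dropped = traits.ogu_trait_surface(
            region.habitat_fractions,
            occ,
            pool.abundance[pool.abundance["species_id"] != sp],
            trait_table[trait_table["species_id"] != sp],
            "angiosperm",
        )
        pd.testing.assert_frame_equal(base, dropped)

    def test_group_split_partitions_angiosperms(self, pool, trait_table):
        herb = trait_table[
            (trait_table["group"] == "angiosperm")
            & (trait_table["growth_form"] == "herbaceous")
        ]
        woody = trait_table[
            (trait_table["group"] == "angiosperm")
            & (trait_table["growth_form"] == "woody")
        ]
        angio = trait_table[trait_table["group"] == "angiosperm"]
        assert len(herb) + len(woody) == len(angio)


def anova_oracle(groups):
    """Classical sum-of-squares decomposition, coded independently."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ss_within = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestHabitatAnova:
    def test_identical_groups_give_zero_f(self):
        df = pd.DataFrame(
            {
                "habitat": ["A"] * 3 + ["B"] * 3,
                "psi_tlp_mpa": [-1.0, -2.0, -3.0] * 2,
            }
        )
        res = traits.habitat_anova(df)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_sum_of_squares_oracle(self):
        groups = {"A": [1, 2, 3], "B": [2, 3, 4], "C": [5, 6, 7]}
        df = pd.DataFrame(
            [
                {"habitat": h, "psi_tlp_mpa": v}
                for h, vals in groups.items()
                for v in vals
            ]
        )
        res = traits.habitat_anova(df)
        assert res.f_statistic == pytest.approx(
            anova_oracle(list(groups.values())), abs=1e-10
        )
        assert res.df_between == 2
        assert res.df_within == 6
        # C is clearly separated from A and B at alpha=0.05
        assert res.letters["A"] == res.letters["B"]
        assert res.letters["C"] != res.letters["A"]

    def test_single_habitat_rejected(self):
        df = pd.DataFrame(
            {"habitat": ["A"] * 4, "psi_tlp_mpa": [-1, -2, -3, -4]}
        )
        with pytest.raises(ValueError):
            traits.habitat_anova(df)

    def test_thin_habitat_dropped_with_warning(self):
        df = pd.DataFrame(
            {
                "habitat": ["A"] * 3 + ["B"] * 3 + ["C"],
                "psi_tlp_mpa": [-1.0, -2.0, -3.0, -2.0, -2.5, -3.5, -9.0],
            }
        )
        with pytest.warns(UserWarning, match="C"):
            res = traits.habitat_anova(df)
        assert set(res.letters) == {"A", "B"}

    def test_pipeline_scale_anova_is_significant(self, pool, trait_table):
        by_hab = pool.abundance.merge(trait_table, on="species_id")
        res = traits.habitat_anova(by_hab)
        assert res.df_between == by_hab["habitat"].nunique() - 1
        assert res.p_value < 0.001  # habitat means differ by construction
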