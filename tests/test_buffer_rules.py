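"""Buffer summarization and the three integration rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rnaseprotect import (
    BufferRecipe,
    ComponentFlag,
    IntegratedRecipe,
    Provenance,
    ReactionType,
    emit_stock,
    integrate,
    read_recipes,
    summarize,
)
from rnaseprotect.buffer_rules import canonicalize
from rnaseprotect.resources import example_recipe_table


def _recipes(reaction_type, concs_by_source):
    return [
        BufferRecipe(source, reaction_type, components)
        for source, components in concs_by_source.items()
    ]


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw,canonical",
        [
            ("tris", "Tris-HCl"),
            ("Tris-HCl", "Tris-HCl"),
            ("dithiothreitol", "DTT"),
            ("  MGCL2 ", "MgCl2"),
            ("rNTPs", "NTPs"),
        ],
    )
    def test_synonyms(self, raw, canonical):
        assert canonicalize(raw) == canonical

    def test_unknown_passes_through_with_warning(self):
        with pytest.warns(UserWarning, match="unknown buffer component"):
            assert canonicalize("betaine") == "betaine"

    def test_user_extension(self):
        assert canonicalize("bme", {"bme": "2-mercaptoethanol"}) == "2-mercaptoethanol"


class TestSummarize:
    def test_essential_at_full_frequency(self):
        recipes = _recipes(
            ReactionType.IVT,
            {f"s{i}": {"Tris-HCl": 40.0 + i} for i in range(11)},
        )
        (stats,) = summarize(recipes, ReactionType.IVT)
        assert stats.frequency == 1.0 and stats.essential

    def test_rare_component_not_essential(self):
        recipes = _recipes(
            ReactionType.IVT,
            {f"s{i}": {"Tris-HCl": 40.0} for i in range(10)}
            | {"s10": {"Tris-HCl": 40.0, "KCl": 50.0}},
        )
        stats = {s.component: s for s in summarize(recipes, ReactionType.IVT)}
        assert stats["KCl"].frequency == pytest.approx(1 / 11)
        assert not stats["KCl"].essential

    def test_median_over_containing_recipes_only(self):
        recipes = _recipes(
            ReactionType.IVT,
            {
                "a": {"X": 1.0},
                "b": {"X": 2.0},
                "c": {"X": 100.0},
                "d": {"Y": 5.0},  # X absent: not counted as zero
            },
        )
        stats = {s.component: s for s in summarize(recipes, ReactionType.IVT)}
        assert stats["X"].median_conc == 2.0

    def test_no_recipes_of_type_errors(self):
        recipes = _recipes(ReactionType.IVT, {"a": {"X": 1.0}})
        with pytest.raises(ValueError):
            summarize(recipes, ReactionType.CAPPING)

    @given(st.lists(st.floats(0.01, 1000), min_size=1, max_size=15))
    def test_median_matches_sort_based_oracle(self, values):
        recipes = _recipes(
            ReactionType.IVT,
            {f"s{i}": {"X": v} for i, v in enumerate(values)},
        )
        (stats,) = summarize(recipes, ReactionType.IVT)
        ordered = sorted(values)
        k = len(ordered)
        if k % 2:
            expected = ordered[k // 2]
        else:
            expected = (ordered[k // 2 - 1] + ordered[k // 2]) / 2
        assert stats.median_conc == pytest.approx(expected)


class TestIntegrate:
    def _stats(self, reaction_type, components):
        recipes = _recipes(reaction_type, {"only": components})
        return summarize(recipes, reaction_type)

    def test_rule3_max(self):
        ivt = self._stats(ReactionType.IVT, {"MgCl2": 9.9})
        cap = self._stats(ReactionType.CAPPING, {"MgCl2": 1.0})
        recipe = integrate(ivt, cap)
        assert recipe.components["MgCl2"] == 9.9
        assert recipe.provenance["MgCl2"] is Provenance.RULE3_MAX

    def test_rule3_lowest_equivalent_flag(self):
        ivt = self._stats(ReactionType.IVT, {"DTT": 7.4})
        cap = self._stats(ReactionType.CAPPING, {"DTT": 1.0})
        recipe = integrate(ivt, cap, flags={"DTT": "lowest_equivalent"})
        assert recipe.components["DTT"] == 1.0
        assert recipe.provenance["DTT"] is Provenance.RULE3_LOWEST_EQUIVALENT

    def test_rule3_detrimental_flag_takes_other_side(self):
        ivt = self._stats(ReactionType.IVT, {"NaCl": 50.0})
        cap = self._stats(ReactionType.CAPPING, {"NaCl": 5.0})
        recipe = integrate(ivt, cap, flags={"NaCl": ComponentFlag.DETRIMENTAL})
        assert recipe.components["NaCl"] == 5.0
        assert recipe.provenance["NaCl"] is Provenance.RULE3_DETRIMENTAL

    def test_rule1_essential_one_side_only(self):
        ivt = self._stats(ReactionType.IVT, {"spermidine": 1.8})
        cap = self._stats(ReactionType.CAPPING, {"SAM": 0.1})
        recipe = integrate(ivt, cap)
        assert recipe.components["spermidine"] == 1.8
        assert recipe.provenance["spermidine"] is Provenance.RULE1_INCLUDE_ESSENTIAL
        assert recipe.components["SAM"] == 0.1

    def test_rule2_excludes_rare_one_sided_component(self):
        ivt_recipes = _recipes(
            ReactionType.IVT,
            {"a": {"Tris-HCl": 40.0, "KCl": 50.0}, "b": {"Tris-HCl": 40.0}},
        )
        cap = self._stats(ReactionType.CAPPING, {"Tris-HCl": 50.0})
        recipe = integrate(summarize(ivt_recipes, ReactionType.IVT), cap)
        assert "KCl" not in recipe.components
        assert recipe.provenance["KCl"] is Provenance.RULE2_EXCLUDED

    def test_every_component_tagged_once(self):
        recipes = read_recipes(example_recipe_table())
        recipe = integrate(
            summarize(recipes, ReactionType.IVT),
            summarize(recipes, ReactionType.CAPPING),
            flags={"DTT": "lowest_equivalent"},
        )
        all_components = {"Tris-HCl", "MgCl2", "DTT", "spermidine", "NTPs",
                         "KCl", "NaCl", "Triton X-100", "Tween-20"}
        assert set(recipe.provenance) == all_components
        excluded = {
            c for c, p in recipe.provenance.items() if p is Provenance.RULE2_EXCLUDED
        }
        assert set(recipe.components) == all_components - excluded

    def test_idempotent_on_own_output(self):
        recipes = read_recipes(example_recipe_table())
        recipe = integrate(
            summarize(recipes, ReactionType.IVT),
            summarize(recipes, ReactionType.CAPPING),
        )
        again = BufferRecipe("again", ReactionType.IVT, recipe.components)
        again_cap = BufferRecipe("again", ReactionType.CAPPING, recipe.components)
        rerun = integrate(
            summarize([again], ReactionType.IVT),
            summarize([again_cap], ReactionType.CAPPING),
        )
        assert rerun.components == recipe.components


class TestEmitStock:
    def test_scale_multiplies(self):
        recipe = IntegratedRecipe({"X": 5.0}, {"X": Provenance.RULE3_MAX})
        stock = emit_stock(recipe, 10)
        assert stock.components["X"] == 50.0
        assert stock.scale_factor == 10

    def test_scale_one_is_identity(self):
        recipe = IntegratedRecipe({"X": 5.0}, {"X": Provenance.RULE3_MAX})
        assert emit_stock(recipe, 1).components == recipe.components

    def test_substrates_appended_with_provenance(self):
        recipe = IntegratedRecipe({"X": 5.0}, {"X": Provenance.RULE3_MAX})
        stock = emit_stock(recipe, 10, substrates={"SAM": 1.0, "GTP": 5.0})
        assert stock.components["SAM"] == 1.0
        assert stock.provenance["SAM"] is Provenance.SUBSTRATE_ADDED
        assert stock.provenance["GTP"] is Provenance.SUBSTRATE_ADDED


class TestBundledTable:
    """The synthetic literature-style table reproduces the published
    medians and the IB1 stock composition."""

    def test_ivt_medians(self):
        recipes = read_recipes(example_recipe_table())
        stats = {s.component: s for s in summarize(recipes, ReactionType.IVT)}
        assert stats["Tris-HCl"].median_conc == pytest.approx(41.1)
        assert stats["MgCl2"].median_conc == pytest.approx(9.9)
        assert stats["DTT"].median_conc == pytest.approx(7.4)
        assert stats["spermidine"].median_conc == pytest.approx(1.8)
        assert stats["NTPs"].median_conc == pytest.approx(2.0)
        assert stats["KCl"].frequency == pytest.approx(1 / 11)

    def test_ib1_stock_composition(self):
        recipes = read_recipes(example_recipe_table())
        recipe = integrate(
            summarize(recipes, ReactionType.IVT),
            summarize(recipes, ReactionType.CAPPING),
            flags={"DTT": "lowest_equivalent"},
        )
        stock = emit_stock(recipe, 10, substrates={"SAM": 1.0, "GTP": 5.0})
        assert stock.components == {
            "Tris-HCl": 500.0,
            "MgCl2": 99.0,
            "DTT": 10.0,
            "spermidine": 18.0,
            "NTPs": 20.0,
            "SAM": 1.0,
            "GTP": 5.0,
        }
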