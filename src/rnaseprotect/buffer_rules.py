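"""Empirical single-buffer integration for coupled IVT + capping reactions.

Literature reaction-buffer recipes (in vitro transcription on one side,
Vaccinia-enzyme capping on the other) are summarized per component —
occurrence frequency and median concentration over the recipes that contain
the component (absence is absence, not zero) — and then merged into one
integrated recipe by three rules:

1. *Include* a component that is essential (100% occurrence frequency) for
   either reaction type, at that side's median, even if the other side lacks
   it.
2. *Exclude* a component that is non-essential on its side and absent from
   the other reaction type.
3. For components present on both sides, take the *highest* of the two
   medians — unless the user flags the component ``detrimental`` (the high
   value harms the other reaction; take the lower, other side's value) or
   ``lowest_equivalent`` (evidence that the low value works as well; take
   the minimum).

The detrimental / lowest-equivalent judgments are experimental knowledge
that cannot be inferred from recipe tables, so they are explicit user flags.
Every inclusion or exclusion carries a provenance tag, and the 1x recipe can
be emitted as an Nx stock with reaction substrates (e.g. SAM and extra GTP)
appended.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ReactionType",
    "Provenance",
    "ComponentFlag",
    "BufferRecipe",
    "ComponentStats",
    "IntegratedRecipe",
    "canonicalize",
    "read_recipes",
    "summarize",
    "integrate",
    "emit_stock",
    "recipe_to_frame",
    "write_recipe",
]


class ReactionType(str, Enum):
    IVT = "IVT"
    CAPPING = "capping"


class Provenance(str, Enum):
    RULE1_INCLUDE_ESSENTIAL = "rule1_include_essential"
    RULE2_EXCLUDED = "rule2_excluded"
    RULE3_MAX = "rule3_max"
    RULE3_LOWEST_EQUIVALENT = "rule3_lowest_equivalent"
    RULE3_DETRIMENTAL = "rule3_detrimental"
    SUBSTRATE_ADDED = "substrate_added"


class ComponentFlag(str, Enum):
    NONE = "none"
    DETRIMENTAL = "detrimental"
    LOWEST_EQUIVALENT = "lowest_equivalent"


#: Synonym table for component-name canonicalization; user-extensible via
#: the ``synonyms`` argument of :func:`canonicalize` / :func:`read_recipes`.
SYNONYMS: dict[str, str] = {
    "tris": "Tris-HCl",
    "tris-hcl": "Tris-HCl",
    "tris hcl": "Tris-HCl",
    "trishcl": "Tris-HCl",
    "dtt": "DTT",
    "dithiothreitol": "DTT",
    "mgcl2": "MgCl2",
    "magnesium chloride": "MgCl2",
    "kcl": "KCl",
    "potassium chloride": "KCl",
    "nacl": "NaCl",
    "sodium chloride": "NaCl",
    "spermidine": "spermidine",
    "ntp": "NTPs",
    "ntps": "NTPs",
    "rntps": "NTPs",
    "triton x-100": "Triton X-100",
    "triton": "Triton X-100",
    "tween-20": "Tween-20",
    "tween 20": "Tween-20",
    "sam": "SAM",
    "s-adenosyl methionine": "SAM",
    "s-adenosylmethionine": "SAM",
    "gtp": "GTP",
}


def canonicalize(name: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Map a component name to its canonical form via the synonym table.

    Unknown names pass through verbatim with a warning.
    """
    table = dict(SYNONYMS)
    if synonyms:
        table.update({k.strip().lower(): v for k, v in synonyms.items()})
    key = " ".join(name.strip().split()).lower()
    if key in table:
        return table[key]
    known = set(table.values())
    if name.strip() not in known:
        warnings.warn(
            f"unknown buffer component {name!r}: passing through verbatim",
            stacklevel=2,
        )
    return name.strip()


@dataclass(frozen=True)
class BufferRecipe:
    """One literature/manufacturer recipe on a 1x concentration basis (mM)."""

    source: str
    reaction_type: ReactionType
    components: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "reaction_type", ReactionType(self.reaction_type))
        object.__setattr__(self, "components", dict(self.components))
        for name, conc in self.components.items():
            if conc <= 0:
                raise ValueError(
                    f"recipe {self.source!r}: {name} concentration must be > 0"
                )


@dataclass(frozen=True)
class ComponentStats:
    """Per-component summary over all recipes of one reaction type."""

    component: str
    reaction_type: ReactionType
    n_recipes: int  # total recipes of this reaction type
    frequency: float  # fraction of those containing the component
    median_conc: float  # median over recipes that contain it

    @property
    def essential(self) -> bool:
        return self.frequency == 1.0


@dataclass(frozen=True)
class IntegratedRecipe:
    """Integrated buffer: component concentrations plus rule provenance.

    Excluded components appear in ``provenance`` (tagged rule2) but not in
    ``components``.  ``scale_factor`` is 1 for the working (1x) recipe.
    """

    components: Mapping[str, float]
    provenance: Mapping[str, Provenance]
    scale_factor: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", dict(self.components))
        object.__setattr__(
            self, "provenance", {k: Provenance(v) for k, v in self.provenance.items()}
        )
        for name in self.components:
            if name not in self.provenance:
                raise ValueError(f"component {name!r} lacks a provenance tag")


def read_recipes(
    path: str | Path, synonyms: Mapping[str, str] | None = None
) -> list[BufferRecipe]:
    """Read a delimited recipe table (columns: source, reaction_type,
    component, concentration_mM); component names are canonicalized."""
    frame = pd.read_csv(path, sep=None, engine="python", comment="#")
    required = {"source", "reaction_type", "component", "concentration_mM"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"recipe table missing columns {sorted(missing)}")
    recipes = []
    for (source, rtype), grp in frame.groupby(
        ["source", "reaction_type"], sort=False
    ):
        components = {
            canonicalize(row.component, synonyms): float(row.concentration_mM)
            for row in grp.itertuples()
        }
        recipes.append(
            BufferRecipe(
                source=str(source),
                reaction_type=ReactionType(rtype),
                components=components,
            )
        )
    return recipes


def summarize(
    recipes: Sequence[BufferRecipe], reaction_type: ReactionType | str
) -> list[ComponentStats]:
    """Frequency and median concentration per component for one reaction type.

    Medians run over the recipes that *contain* the component; an even count
    takes the arithmetic mean of the two central values.
    """
    reaction_type = ReactionType(reaction_type)
    selected = [r for r in recipes if r.reaction_type is reaction_type]
    if not selected:
        raise ValueError(f"no recipes of type {reaction_type.value!r}")
    n = len(selected)
    concs: dict[str, list[float]] = {}
    for recipe in selected:
        for name, conc in recipe.components.items():
            concs.setdefault(name, []).append(conc)
    return [
        ComponentStats(
            component=name,
            reaction_type=reaction_type,
            n_recipes=n,
            frequency=len(values) / n,
            median_conc=float(median(values)),
        )
        for name, values in sorted(concs.items())
    ]


def integrate(
    stats_ivt: Sequence[ComponentStats],
    stats_cap: Sequence[ComponentStats],
    flags: Mapping[str, ComponentFlag | str] | None = None,
) -> IntegratedRecipe:
    """Merge the two per-reaction summaries into one integrated 1x recipe.

    Every input component appears exactly once in the provenance map: either
    included under rule 1 or rule 3 (max / detrimental / lowest-equivalent
    branch) or excluded under rule 2.
    """
    flag_map = {k: ComponentFlag(v) for k, v in (flags or {}).items()}
    ivt = {s.component: s for s in stats_ivt}
    cap = {s.component: s for s in stats_cap}
    components: dict[str, float] = {}
    provenance: dict[str, Provenance] = {}
    for name in sorted(set(ivt) | set(cap)):
        flag = flag_map.get(name, ComponentFlag.NONE)
        a, b = ivt.get(name), cap.get(name)
        if a is not None and b is not None:
            if flag is ComponentFlag.DETRIMENTAL:
                components[name] = min(a.median_conc, b.median_conc)
                provenance[name] = Provenance.RULE3_DETRIMENTAL
            elif flag is ComponentFlag.LOWEST_EQUIVALENT:
                components[name] = min(a.median_conc, b.median_conc)
                provenance[name] = Provenance.RULE3_LOWEST_EQUIVALENT
            else:
                components[name] = max(a.median_conc, b.median_conc)
                provenance[name] = Provenance.RULE3_MAX
        else:
            present = a if a is not None else b
            assert present is not None
            if present.essential:
                components[name] = present.median_conc
                provenance[name] = Provenance.RULE1_INCLUDE_ESSENTIAL
            else:
                provenance[name] = Provenance.RULE2_EXCLUDED
    return IntegratedRecipe(components=components, provenance=provenance)


def emit_stock(
    recipe: IntegratedRecipe,
    scale: int,
    substrates: Mapping[str, float] | None = None,
) -> IntegratedRecipe:
    """Nx stock: concentrations multiplied by ``scale``; reaction substrates
    (given at stock concentration) appended with ``substrate_added``
    provenance."""
    if scale < 1:
        raise ValueError("scale must be a positive integer")
    components = {name: conc * scale for name, conc in recipe.components.items()}
    provenance = dict(recipe.provenance)
    for name, conc in (substrates or {}).items():
        name = canonicalize(name)
        components[name] = components.get(name, 0.0) + conc
        provenance[name] = Provenance.SUBSTRATE_ADDED
    return IntegratedRecipe(
        components=components, provenance=provenance, scale_factor=scale
    )


def recipe_to_frame(recipe: IntegratedRecipe) -> pd.DataFrame:
    rows = []
    for name, prov in recipe.provenance.items():
        rows.append(
            {
                "component": name,
                "concentration_mM": recipe.components.get(name),
                "provenance": prov.value,
                "scale_factor": recipe.scale_factor,
            }
        )
    return pd.DataFrame(
        rows, columns=["component", "concentration_mM", "provenance", "scale_factor"]
    )


def write_recipe(recipe: IntegratedRecipe, path: str | Path) -> None:
    """Write TSV (``path``) plus a JSON sidecar (``path`` + '.json')."""
    path = Path(path)
    recipe_to_frame(recipe).to_csv(path, sep="\t", index=False)
    payload = {
        "scale_factor": recipe.scale_factor,
        "components": recipe.components,
        "provenance": {k: v.value for k, v in recipe.provenance.items()},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(payload, indent=2))
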