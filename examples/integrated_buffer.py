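"""Derive a single reaction buffer supporting both IVT and capping.

Literature recipes for T7 in vitro transcription and Vaccinia-enzyme
capping buffers are summarized per component (occurrence frequency, median
concentration over the recipes that contain it) and merged by three rules:
include anything essential (100% frequency) on either side; exclude
non-essential one-sided components; for shared components take the higher
median unless flagged detrimental or lowest-equivalent.  The result is
emitted as a 10x stock with the capping substrates appended.
"""

from rnaseprotect import ReactionType, emit_stock, integrate, read_recipes, summarize
from rnaseprotect.resources import example_recipe_table

recipes = read_recipes(example_recipe_table())
ivt = summarize(recipes, ReactionType.IVT)
cap = summarize(recipes, ReactionType.CAPPING)

print("IVT component survey (11 recipes):")
for s in ivt:
    tag = "essential" if s.essential else f"{s.frequency:.0%} of recipes"
    print(f"  {s.component:<13} median {s.median_conc:7.2f} mM  ({tag})")

recipe = integrate(ivt, cap, flags={"DTT": "lowest_equivalent"})
stock = emit_stock(recipe, 10, substrates={"SAM": 1.0, "GTP": 5.0})

print("\nintegrated 10x stock:")
for name, conc in stock.components.items():
    print(f"  {name:<13} {conc:7.1f} mM   [{stock.provenance[name].value}]")
excluded = [n for n, p in stock.provenance.items() if p.value == "rule2_excluded"]
print(f"\nexcluded by rule 2: {', '.join(excluded)}")
print(
    "\nShared components keep the higher median (rule 3) unless flagged;"
    "\nDTT's lowest-equivalent flag takes the capping-side value instead."
)
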