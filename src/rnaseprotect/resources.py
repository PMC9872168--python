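"""Paths to the small bundled example datasets."""

from importlib.resources import files
from pathlib import Path

__all__ = ["example_recipe_table", "example_target_fasta", "example_probe_fasta"]


def _data(name: str) -> Path:
    return Path(str(files("rnaseprotect") / "data" / name))


def example_recipe_table() -> Path:
    """Synthetic literature-style IVT/capping recipe table (TSV, 1x mM)."""
    return _data("synthetic_buffer_recipes.tsv")


def example_target_fasta() -> Path:
    """An 86-nt synthetic assay target (RNA FASTA)."""
    return _data("example_target.fasta")


def example_probe_fasta() -> Path:
    """The 24-nt antisense DNA probe matching the example target's 5' end."""
    return _data("example_probe.fasta")
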