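"""Theoretical oligoribonucleotide masses and probe-tiling mass mapping.

Replacing the gel readout with mass spectrometry turns the protection assay
into a mass-mapping method: each digestion round protects one probe-sized
region, and a fragment identifies its stretch of the message whenever its
theoretical mass is unique (within instrument tolerance) in that round's
digest.  Tiling probes across the molecule over successive rounds then
accumulates sequence coverage beyond what a plain (probe-free) RNase digest
can identify.

Masses are computed from elemental compositions (via pyteomics) as the sum
of nucleotide-residue masses plus water plus end-chemistry adjustments.  The
baseline is a 5'-monophosphate / 3'-hydroxyl strand; hydrolyzed RNase
products carry 5'-OH / 3'-phosphate ends, and a 2',3'-cyclic phosphate is a
linear phosphate minus one water.  The cap 0 adjustment (m7Gppp) applies to
the 5'-terminal fragment only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .digestion import (
    EdgeRule,
    EnzymeSpec,
    Fragment,
    ProtectionMap,
    build_protection_map,
    digest,
)
from .probe_design import PROBE_MIN_LEN, Probe, design_region_probe
from .seqcore import FivePrime, Interval, Kind, NucleicSequence, ThreePrime

__all__ = [
    "MassTable",
    "DEFAULT_MASS_TABLE",
    "MassMapConfig",
    "fragment_mass",
    "fragment_masses_to_frame",
    "TilingDesign",
    "baseline_mass_map",
    "design_tiling",
]

# Elemental formulas of the free species the residue/adjustment masses are
# derived from.  Residue (chain) mass = nucleoside 5'-monophosphate - water.
_NMP_FORMULAS = {
    "A": "C10H14N5O7P",
    "C": "C9H14N3O8P",
    "G": "C10H14N5O8P",
    "U": "C9H13N2O9P",
}
_WATER = "H2O"
_HPO3 = "HPO3"
_M7G_NUCLEOSIDE = "C11H15N5O5"  # 7-methylguanosine


def _formula_mass(formula: str, average: bool) -> float:
    return float(_pmass.calculate_mass(formula=formula, average=average))


@dataclass(frozen=True)
class MassTable:
    """Residue masses and end-chemistry adjustments, mono + average.

    ``residues[mode][base]`` is the chain-residue mass; ``five_prime`` /
    ``three_prime`` adjustments are relative to the 5'-monophosphate /
    3'-hydroxyl baseline, so a strand's mass is::

        sum(residues) + water + five_prime_adj + three_prime_adj
    """

    residues: Mapping[str, Mapping[str, float]]
    five_prime: Mapping[str, Mapping[FivePrime, float]]
    three_prime: Mapping[str, Mapping[ThreePrime, float]]
    water: Mapping[str, float]

    def __post_init__(self) -> None:
        for mode in ("monoisotopic", "average"):
            cyc = self.three_prime[mode][ThreePrime.CYCLIC_PHOSPHATE]
            lin = self.three_prime[mode][ThreePrime.PHOSPHATE]
            if abs((lin - self.water[mode]) - cyc) > 1e-9:
                raise ValueError("cyclic phosphate must equal linear phosphate - water")


def _build_default_table() -> MassTable:
    residues: dict[str, dict[str, float]] = {}
    five: dict[str, dict[FivePrime, float]] = {}
    three: dict[str, dict[ThreePrime, float]] = {}
    water: dict[str, float] = {}
    for mode, avg in (("monoisotopic", False), ("average", True)):
        w = _formula_mass(_WATER, avg)
        hpo3 = _formula_mass(_HPO3, avg)
        m7g = _formula_mass(_M7G_NUCLEOSIDE, avg)
        residues[mode] = {
            base: _formula_mass(f, avg) - w for base, f in _NMP_FORMULAS.items()
        }
        five[mode] = {
            FivePrime.MONOPHOSPHATE: 0.0,
            FivePrime.HYDROXYL: -hpo3,
            FivePrime.TRIPHOSPHATE: 2 * hpo3,
            # m7Gppp: two extra bridge phosphates plus the m7G nucleoside,
            # minus the water lost forming the 5'-5' anhydride bond
            FivePrime.CAP0: 2 * hpo3 + m7g - w,
        }
        three[mode] = {
            ThreePrime.HYDROXYL: 0.0,
            ThreePrime.PHOSPHATE: hpo3,
            ThreePrime.CYCLIC_PHOSPHATE: hpo3 - w,
        }
        water[mode] = w
    return MassTable(residues=residues, five_prime=five, three_prime=three, water=water)


DEFAULT_MASS_TABLE = _build_default_table()


def fragment_mass(
    fragment: Fragment | NucleicSequence,
    table: MassTable = DEFAULT_MASS_TABLE,
    mode: str = "monoisotopic",
) -> float:
    """Neutral mass in Da of an RNA fragment or strand with its end chemistry."""
    if mode not in ("monoisotopic", "average"):
        raise ValueError(f"unknown mass mode {mode!r}")
    if isinstance(fragment, NucleicSequence) and fragment.kind is not Kind.DNA:
        residues = fragment.residues
    elif isinstance(fragment, Fragment):
        residues = fragment.residues
    else:
        raise ValueError("mass table covers ribonucleotides only (RNA input required)")
    try:
        five = table.five_prime[mode][FivePrime(fragment.five_prime)]
        three = table.three_prime[mode][ThreePrime(fragment.three_prime)]
    except KeyError as exc:  # pragma: no cover - table always complete
        raise ValueError(f"unknown end chemistry {exc}") from exc
    res = table.residues[mode]
    return sum(res[b] for b in residues) + table.water[mode] + five + three


def fragment_masses_to_frame(
    fragments: Sequence[Fragment], table: MassTable = DEFAULT_MASS_TABLE
) -> pd.DataFrame:
    """Mass list (TSV-ready) for a set of digestion fragments."""
    return pd.DataFrame(
        {
            "fragment": [f.species_id for f in fragments],
            "start": [f.interval.start for f in fragments],
            "end": [f.interval.end for f in fragments],
            "sequence": [f.residues for f in fragments],
            "five_prime": [f.five_prime.value for f in fragments],
            "three_prime": [f.three_prime.value for f in fragments],
            "monoisotopic": [fragment_mass(f, table, "monoisotopic") for f in fragments],
            "average": [fragment_mass(f, table, "average") for f in fragments],
        }
    )


@dataclass(frozen=True)
class MassMapConfig:
    """MS detectability limits for digestion fragments.

    Instrument-dependent; defaults assume fragments of >= 3 nt are
    distinguishable from the mono/dinucleotide background and carry usable
    sequence information.
    """

    min_fragment_length: int = 3
    max_fragment_length: int | None = None

    def __post_init__(self) -> None:
        if self.min_fragment_length < 1:
            raise ValueError("min_fragment_length must be >= 1")


@dataclass(frozen=True)
class TilingDesign:
    """Outcome of greedy probe tiling for mass mapping."""

    probes: tuple[Probe, ...]
    covered: frozenset[int]
    coverage: float
    uncovered_intervals: tuple[Interval, ...]
    baseline_coverage: float
    target_id: str
    target_length: int


class _Digester:
    """Vectorized digestion boundaries + masses for one target.

    Mirrors :func:`rnaseprotect.digestion.digest` exactly (a unit test holds
    them together); exists because greedy tiling evaluates thousands of
    candidate protections per target and does not need Fragment objects.
    """

    def __init__(
        self,
        target: NucleicSequence,
        enzymes: Sequence[EnzymeSpec],
        table: MassTable,
        mode: str,
        edge_rule: EdgeRule,
    ):
        from .digestion import _enzyme_index

        self.n = len(target)
        self.edge_rule = EdgeRule(edge_rule)
        enz_idx = _enzyme_index(target.residues, enzymes)
        self.cut_sites = np.nonzero(enz_idx[:-1] >= 0)[0]  # bonds cut when free
        res = table.residues[mode]
        self.cumsum = np.concatenate(
            ([0.0], np.cumsum([res[b] for b in target.residues]))
        )
        self.water = table.water[mode]
        five = table.five_prime[mode]
        three = table.three_prime[mode]
        self.adj5_first = five[target.five_prime]
        self.adj5_cut = five[FivePrime.HYDROXYL]
        self.adj3_last = three[target.three_prime]
        # per-bond 3' adjustment of the cutting enzyme
        prod = np.array(
            [three[e.product_3prime] for e in enzymes] or [0.0], dtype=float
        )
        safe = np.where(enz_idx >= 0, enz_idx, 0)
        self.adj3_at = prod[safe]

    def boundaries(self, intervals: Sequence[Interval]) -> tuple[np.ndarray, np.ndarray]:
        """Fragment (starts, ends) when ``intervals`` are protected."""
        cuts = self.cut_sites
        keep = np.ones(len(cuts), dtype=bool)
        for iv in intervals:
            if self.edge_rule is EdgeRule.EDGE_PERMISSIVE:
                # suppress bonds whose 3' base (i+1) is protected
                lo = np.searchsorted(cuts, iv.start - 1, side="left")
                hi = np.searchsorted(cuts, iv.end - 1, side="left")
            else:
                # suppress bonds touching the interval on either side
                lo = np.searchsorted(cuts, iv.start - 1, side="left")
                hi = np.searchsorted(cuts, iv.end, side="left")
            keep[lo:hi] = False
        cuts = cuts[keep]
        starts = np.concatenate(([0], cuts + 1))
        ends = np.concatenate((cuts + 1, [self.n]))
        return starts, ends

    def masses(self, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        m = self.cumsum[ends] - self.cumsum[starts] + self.water
        m += np.where(starts == 0, self.adj5_first, self.adj5_cut)
        adj3 = self.adj3_at[ends - 1]
        adj3[-1] = self.adj3_last
        return m + adj3

    def fragment_flags(
        self,
        intervals: Sequence[Interval],
        tolerance: float,
        cfg: MassMapConfig,
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, informative): per-fragment flag for fragments that
        are detectable and mass-unique within tolerance in this digest."""
        starts, ends = self.boundaries(intervals)
        masses = self.masses(starts, ends)
        lengths = ends - starts
        det = lengths >= cfg.min_fragment_length
        if cfg.max_fragment_length is not None:
            det &= lengths <= cfg.max_fragment_length
        order = np.argsort(masses)
        sorted_m = masses[order]
        unique_sorted = np.ones(len(masses), dtype=bool)
        if len(masses) > 1:
            close = np.diff(sorted_m) <= tolerance
            unique_sorted[:-1] &= ~close
            unique_sorted[1:] &= ~close
        unique = np.empty(len(masses), dtype=bool)
        unique[order] = unique_sorted
        return starts, ends, det & unique

    def covered_mask(
        self,
        intervals: Sequence[Interval],
        tolerance: float,
        cfg: MassMapConfig,
    ) -> np.ndarray:
        """Positions in fragments that are detectable and mass-unique."""
        starts, ends, good = self.fragment_flags(intervals, tolerance, cfg)
        mask = np.zeros(self.n, dtype=bool)
        for s, e in zip(starts[good], ends[good]):
            mask[s:e] = True
        return mask


def baseline_mass_map(
    target: NucleicSequence,
    enzymes: Sequence[EnzymeSpec],
    tolerance_da: float = 0.01,
    config: MassMapConfig | None = None,
    mode: str = "monoisotopic",
    table: MassTable = DEFAULT_MASS_TABLE,
    edge_rule: EdgeRule | str = EdgeRule.EDGE_PERMISSIVE,
) -> float:
    """Coverage of a traditional (probe-free) RNase mass map.

    A position is covered iff its digestion fragment is detectable and its
    mass is unique within ``tolerance_da`` among all fragments of the
    digest.  An uncut target gives one full-length fragment, which (being
    trivially unique) counts as covered by default — configure
    ``max_fragment_length`` to rule such fragments undetectable.
    """
    if tolerance_da <= 0:
        raise ValueError("tolerance must be > 0")
    cfg = config or MassMapConfig()
    dig = _Digester(target, enzymes, table, mode, EdgeRule(edge_rule))
    return float(dig.covered_mask([], tolerance_da, cfg).mean())


def design_tiling(
    target: NucleicSequence,
    enzymes: Sequence[EnzymeSpec],
    probe_len_range: tuple[int, int] = (16, 20),
    tolerance_da: float = 0.01,
    strategy: str = "greedy",
    config: MassMapConfig | None = None,
    mode: str = "monoisotopic",
    table: MassTable = DEFAULT_MASS_TABLE,
    edge_rule: EdgeRule | str = EdgeRule.EDGE_PERMISSIVE,
    multiplex: bool = False,
    max_rounds: int | None = None,
) -> TilingDesign:
    """Greedy set-cover probe tiling maximizing mass-mapped coverage.

    Each round protects one probe interval (bench format: one probe per
    digestion round; ``multiplex=True`` instead co-incubates all selected
    probes).  A candidate is admissible when its protected fragment is
    detectable and mass-unique within tolerance against every other fragment
    of that round's digest; rounds are chosen to maximize newly covered
    positions (all detectable mass-unique fragments of the round count),
    with a deterministic leftmost-then-shortest tie-break.  Selection stops
    when no candidate adds coverage.
    """
    if strategy != "greedy":
        raise ValueError(f"unknown strategy {strategy!r}")
    if tolerance_da <= 0:
        raise ValueError("tolerance must be > 0")
    lo, hi = probe_len_range
    if not (PROBE_MIN_LEN <= lo <= hi <= 60):
        raise ValueError("probe_len_range outside hard bounds [10, 60]")
    cfg = config or MassMapConfig()
    n = len(target)
    baseline = baseline_mass_map(
        target, enzymes, tolerance_da, cfg, mode, table, edge_rule
    )

    covered = np.zeros(n, dtype=bool)
    chosen: list[Interval] = []
    if n >= lo:
        dig = _Digester(target, enzymes, table, mode, EdgeRule(edge_rule))
        lengths = [L for L in range(lo, min(hi, n) + 1)]
        while max_rounds is None or len(chosen) < max_rounds:
            blocked = np.zeros(n, dtype=bool)
            for iv in chosen:
                blocked[iv.start : iv.end] = True
            blocked_cum = np.concatenate(([0], np.cumsum(blocked)))
            unc_cum = np.concatenate(([0], np.cumsum(~covered)))
            best_gain = 0
            best: Interval | None = None
            # scan leftmost-first, then shortest: first strict improvement
            # wins, making ties resolve to the leftmost interval
            for s in range(0, n - lo + 1):
                for L in lengths:
                    if s + L > n or blocked_cum[s + L] - blocked_cum[s]:
                        continue
                    cand = Interval(s, s + L)
                    protect = chosen + [cand] if multiplex else [cand]
                    starts, ends, good = dig.fragment_flags(
                        protect, tolerance_da, cfg
                    )
                    # the protected fragment must itself be informative
                    j = int(np.searchsorted(starts, s, side="right")) - 1
                    if not good[j]:
                        continue
                    gain = int(np.sum((unc_cum[ends] - unc_cum[starts])[good]))
                    if gain > best_gain:
                        best_gain = gain
                        best = cand
            if best is None:
                break
            chosen.append(best)
            protect = chosen if multiplex else [best]
            covered |= dig.covered_mask(protect, tolerance_da, cfg)

    probes: list[Probe] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for iv in chosen:
            probes.append(design_region_probe(target, iv))

    covered_set = frozenset(np.nonzero(covered)[0].tolist())
    uncovered: list[Interval] = []
    run_start = None
    for i in range(n + 1):
        inside = i < n and not covered[i]
        if inside and run_start is None:
            run_start = i
        elif not inside and run_start is not None:
            uncovered.append(Interval(run_start, i))
            run_start = None
    return TilingDesign(
        probes=tuple(probes),
        covered=covered_set,
        coverage=len(covered_set) / n,
        uncovered_intervals=tuple(uncovered),
        baseline_coverage=baseline,
        target_id=target.id,
        target_length=n,
    )
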