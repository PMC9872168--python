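"""RNase A / RNase T1 digestion of single-stranded RNA under hybrid protection.

Models the protection assay's chemistry: single-strand-specific
endoribonucleases cleave the bond 3' of their recognition bases (RNase A
after pyrimidines C/U, RNase T1 after G), but regions hybridized to an
antisense DNA probe survive — provided the reaction runs in high salt, where
RNase A leaves duplexes intact.  In low salt the enzymes attack duplexes too
and protection is void.

Digestion is modeled as complete (saturating enzyme, infinite time), which is
how the assay's gel lanes are interpreted: every cleavable bond is cut.

Two boundary conventions are provided because gel resolution cannot decide
between them (the choice is surfaced wherever fragments are exported):

``edge_permissive``
    the bond after base ``i`` is cut iff ``i`` is a recognition base and
    ``i + 1`` is unprotected; the bond immediately 3' of a protected region
    is therefore cleavable, and a probe-protected fragment has exactly the
    probe's length.
``free_base_required``
    both ``i`` and ``i + 1`` must be unprotected; the protected fragment
    extends to the next cut site and is >= the probe length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqcore import (
    FivePrime,
    Interval,
    Kind,
    NucleicSequence,
    ThreePrime,
    find_probe_bindings,
    merge_intervals,
    write_fasta,
)

__all__ = [
    "EnzymeSpec",
    "RNASE_A",
    "RNASE_T1",
    "SaltMode",
    "EdgeRule",
    "ProbeBindingReport",
    "ProtectionMap",
    "Fragment",
    "build_protection_map",
    "digest",
    "detectable",
    "fragments_to_frame",
    "fragments_to_tsv",
    "fragments_to_fasta",
]


@dataclass(frozen=True)
class EnzymeSpec:
    """A single-strand-specific endoribonuclease.

    ``recognition`` holds the RNA bases *after* which the enzyme cleaves.
    Products carry a 5'-hydroxyl and, on the 3' side, either a linear
    phosphate (default; the end state after cyclic-intermediate hydrolysis)
    or a 2',3'-cyclic phosphate — the distinction only changes computed
    masses, not fragment boundaries.
    """

    name: str
    recognition: frozenset[str]
    product_3prime: ThreePrime = ThreePrime.PHOSPHATE
    product_5prime: FivePrime = FivePrime.HYDROXYL

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", frozenset(self.recognition))
        bad = self.recognition - set("ACGU")
        if bad:
            raise ValueError(f"{self.name}: recognition bases {sorted(bad)} not RNA")
        if self.product_3prime not in (
            ThreePrime.PHOSPHATE,
            ThreePrime.CYCLIC_PHOSPHATE,
        ):
            raise ValueError(f"{self.name}: product_3prime must be a phosphate form")


#: RNase A — cleaves after pyrimidines (C, U).
RNASE_A = EnzymeSpec(name="RNase A", recognition=frozenset("CU"))
#: RNase T1 — cleaves after guanosine.
RNASE_T1 = EnzymeSpec(name="RNase T1", recognition=frozenset("G"))


class SaltMode(str, Enum):
    """High salt preserves DNA-RNA hybrids; low salt abolishes protection."""

    HIGH_SALT = "high_salt"
    LOW_SALT = "low_salt"


class EdgeRule(str, Enum):
    EDGE_PERMISSIVE = "edge_permissive"
    FREE_BASE_REQUIRED = "free_base_required"


@dataclass(frozen=True)
class ProbeBindingReport:
    probe_id: str
    n_sites: int


@dataclass(frozen=True)
class ProtectionMap:
    """Disjoint, sorted intervals of a target that are probe-protected."""

    target_id: str
    intervals: tuple[Interval, ...]
    salt_mode: SaltMode = SaltMode.HIGH_SALT
    probe_reports: tuple[ProbeBindingReport, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(self.intervals))
        object.__setattr__(self, "salt_mode", SaltMode(self.salt_mode))
        object.__setattr__(self, "probe_reports", tuple(self.probe_reports))
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end:
                raise ValueError("protection intervals must be disjoint and sorted")

    def for_target(self, target_id: str) -> "ProtectionMap":
        """Same map re-addressed to another molecule of identical sequence."""
        return replace(self, target_id=target_id)


@dataclass(frozen=True)
class Fragment:
    """A digestion product, located on its parent molecule.

    ``protected_overlap`` is the number of fragment positions inside
    protected intervals; ``capped`` is set only for the 5'-terminal fragment
    of a cap 0 parent.
    """

    parent_id: str
    interval: Interval
    residues: str
    five_prime: FivePrime
    three_prime: ThreePrime
    protected_overlap: int = 0
    capped: bool = False

    def __post_init__(self) -> None:
        if len(self.residues) != self.interval.length:
            raise ValueError("fragment residues do not match its interval length")
        if self.capped and (
            self.interval.start != 0 or self.five_prime is not FivePrime.CAP0
        ):
            raise ValueError("capped fragment must start at 0 with cap0 5' end")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def species_id(self) -> str:
        """Stable identifier for gel-lane bookkeeping."""
        return (
            f"{self.parent_id}[{self.interval.start}:{self.interval.end}]"
            f"/{self.five_prime.value}"
        )


def build_protection_map(
    target: NucleicSequence,
    probes: Sequence,
    salt_mode: SaltMode | str = SaltMode.HIGH_SALT,
) -> ProtectionMap:
    """Union of all probe binding sites on ``target``, merged where overlapping.

    ``probes`` may be :class:`~rnaseprotect.probe_design.Probe` objects or
    bare DNA :class:`NucleicSequence` strands.  Probes that bind zero or
    multiple sites are recorded in ``probe_reports`` (not fatal: a
    non-complementary probe is the assay's negative control).  In
    ``low_salt`` the interval list is empty regardless of bindings.
    """
    salt_mode = SaltMode(salt_mode)
    intervals: list[Interval] = []
    reports: list[ProbeBindingReport] = []
    for probe in probes:
        seq = getattr(probe, "sequence", probe)
        sites = find_probe_bindings(target, seq)
        reports.append(ProbeBindingReport(probe_id=seq.id, n_sites=len(sites)))
        intervals.extend(sites)
    merged = () if salt_mode is SaltMode.LOW_SALT else tuple(merge_intervals(intervals))
    return ProtectionMap(
        target_id=target.id,
        intervals=merged,
        salt_mode=salt_mode,
        probe_reports=tuple(reports),
    )


def _enzyme_index(residues: str, enzymes: Sequence[EnzymeSpec]) -> np.ndarray:
    """Per-position index of the first enzyme recognizing that base (-1: none)."""
    arr = np.frombuffer(residues.encode("ascii"), dtype="S1")
    idx = np.full(len(residues), -1, dtype=np.int64)
    for k, enz in enumerate(enzymes):
        mask = np.isin(arr, [b.encode("ascii") for b in sorted(enz.recognition)])
        idx[mask & (idx < 0)] = k
    return idx


def digest(
    target: NucleicSequence,
    pmap: ProtectionMap,
    enzymes: Sequence[EnzymeSpec],
    edge_rule: EdgeRule | str = EdgeRule.EDGE_PERMISSIVE,
) -> list[Fragment]:
    """Complete digestion of ``target`` under the given protection map.

    The bond between positions ``i`` and ``i + 1`` is cleaved iff base ``i``
    is recognized by some enzyme and the protection condition of
    ``edge_rule`` holds.  Fragments are the maximal uncut runs, 5'->3'.  The
    first fragment inherits the parent's 5' chemistry (cap0 sets its
    ``capped`` flag), the last the parent's 3' chemistry; every cut-generated
    5' end is a hydroxyl and each cut 3' end carries the cleaving enzyme's
    phosphate form.  An empty enzyme list returns the intact parent as a
    single fragment.
    """
    edge_rule = EdgeRule(edge_rule)
    if target.kind is not Kind.RNA:
        raise ValueError("only RNA can be digested")
    if pmap.target_id != target.id:
        raise ValueError(
            f"protection map addresses {pmap.target_id!r}, not {target.id!r}"
        )
    n = len(target)
    for iv in pmap.intervals:
        if iv.end > n:
            raise ValueError(f"protected interval {iv} outside target of length {n}")

    protected = np.zeros(n, dtype=bool)
    for iv in pmap.intervals:
        protected[iv.start : iv.end] = True
    prot_cum = np.concatenate(([0], np.cumsum(protected)))

    if enzymes:
        enz_idx = _enzyme_index(target.residues, enzymes)
        cleavable = enz_idx[:-1] >= 0
        if edge_rule is EdgeRule.EDGE_PERMISSIVE:
            allowed = ~protected[1:]
        else:
            allowed = ~protected[:-1] & ~protected[1:]
        cuts = np.nonzero(cleavable & allowed)[0]
    else:
        enz_idx = np.full(n, -1, dtype=np.int64)
        cuts = np.empty(0, dtype=np.int64)

    starts = np.concatenate(([0], cuts + 1))
    ends = np.concatenate((cuts + 1, [n]))

    fragments: list[Fragment] = []
    last = len(starts) - 1
    for j, (s, e) in enumerate(zip(starts.tolist(), ends.tolist())):
        five = target.five_prime if j == 0 else FivePrime.HYDROXYL
        if j == last:
            three = target.three_prime
        else:
            three = enzymes[enz_idx[e - 1]].product_3prime
        fragments.append(
            Fragment(
                parent_id=target.id,
                interval=Interval(s, e),
                residues=target.residues[s:e],
                five_prime=five,
                three_prime=three,
                protected_overlap=int(prot_cum[e] - prot_cum[s]),
                capped=(j == 0 and target.five_prime is FivePrime.CAP0),
            )
        )
    return fragments


def detectable(fragments: Iterable[Fragment], min_len: int = 8) -> list[Fragment]:
    """Fragments long enough to show on the gel (default threshold 8 nt)."""
    return [f for f in fragments if len(f) >= min_len]


def fragments_to_frame(
    fragments: Sequence[Fragment], edge_rule: EdgeRule | str | None = None
) -> pd.DataFrame:
    """Tabulate fragments; the digestion boundary convention, when given,
    is recorded in ``frame.attrs['edge_rule']`` and the TSV header."""
    frame = pd.DataFrame(
        {
            "parent_id": [f.parent_id for f in fragments],
            "start": [f.interval.start for f in fragments],
            "end": [f.interval.end for f in fragments],
            "length": [len(f) for f in fragments],
            "sequence": [f.residues for f in fragments],
            "five_prime": [f.five_prime.value for f in fragments],
            "three_prime": [f.three_prime.value for f in fragments],
            "protected_overlap": [f.protected_overlap for f in fragments],
            "capped": [f.capped for f in fragments],
        }
    )
    if edge_rule is not None:
        frame.attrs["edge_rule"] = EdgeRule(edge_rule).value
    return frame


def fragments_to_tsv(
    fragments: Sequence[Fragment],
    path: str | Path,
    edge_rule: EdgeRule | str | None = None,
) -> None:
    frame = fragments_to_frame(fragments, edge_rule)
    with open(path, "w") as handle:
        if edge_rule is not None:
            handle.write(f"# edge_rule={EdgeRule(edge_rule).value}\n")
        frame.to_csv(handle, sep="\t", index=False)


def fragments_to_fasta(fragments: Sequence[Fragment], path: str | Path) -> None:
    seqs = [
        NucleicSequence(
            id=f.species_id,
            kind=Kind.RNA,
            residues=f.residues,
            five_prime=f.five_prime,
            three_prime=f.three_prime,
        )
        for f in fragments
    ]
    write_fasta(seqs, path)
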