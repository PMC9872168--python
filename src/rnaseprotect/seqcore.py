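"""Nucleic-acid domain model, complementarity logic, and FASTA I/O.

The central object is :class:`NucleicSequence`, a single DNA or RNA strand
written 5'->3' with *explicit end chemistry*.  End chemistry matters twice in
this package: the 5' end distinguishes a primary in vitro transcript
(triphosphate) from a cap 0 (m7GpppN) message, and digestion products carry
the 5'-hydroxyl / 3'-phosphate ends characteristic of RNase A / T1 cleavage,
which shifts their computed masses.

Coordinates are 0-based, half-open throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Kind",
    "FivePrime",
    "ThreePrime",
    "NucleicSequence",
    "Interval",
    "merge_intervals",
    "reverse_complement",
    "find_probe_bindings",
    "read_fasta",
    "write_fasta",
]


class Kind(str, Enum):
    """Strand type; fixes the residue alphabet (T for DNA, U for RNA)."""

    DNA = "DNA"
    RNA = "RNA"


class FivePrime(str, Enum):
    """5'-end chemistry.

    ``triphosphate`` is the default for a primary IVT transcript; ``cap0``
    is the m7GpppN cap added by the Vaccinia capping enzyme (RNA only);
    cut-generated ends from RNase A/T1 are ``hydroxyl``.
    """

    TRIPHOSPHATE = "triphosphate"
    MONOPHOSPHATE = "monophosphate"
    HYDROXYL = "hydroxyl"
    CAP0 = "cap0"


class ThreePrime(str, Enum):
    """3'-end chemistry.  RNase A/T1 products carry a 3'-phosphate (via a
    2',3'-cyclic phosphate intermediate, selectable per enzyme)."""

    HYDROXYL = "hydroxyl"
    PHOSPHATE = "phosphate"
    CYCLIC_PHOSPHATE = "cyclic_phosphate"


_ALPHABET = {Kind.DNA: frozenset("ACGT"), Kind.RNA: frozenset("ACGU")}
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass(frozen=True)
class NucleicSequence:
    """A single nucleic-acid strand with explicit end chemistry.

    Parameters
    ----------
    id : str
        Record identifier, preserved verbatim in all I/O.
    kind : Kind
        DNA or RNA; the residue alphabet must match exactly (no mixed T/U).
    residues : str
        Sequence 5'->3', upper-cased on construction.
    five_prime, three_prime
        End chemistries; ``cap0`` is only valid for RNA.
    """

    id: str
    kind: Kind
    residues: str
    five_prime: FivePrime = FivePrime.HYDROXYL
    three_prime: ThreePrime = ThreePrime.HYDROXYL

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", Kind(self.kind))
        object.__setattr__(self, "five_prime", FivePrime(self.five_prime))
        object.__setattr__(self, "three_prime", ThreePrime(self.three_prime))
        object.__setattr__(self, "residues", str(self.residues).upper())
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _ALPHABET[self.kind]
        if bad:
            raise ValueError(
                f"sequence {self.id!r}: illegal {self.kind.value} residues "
                f"{sorted(bad)}"
            )
        if self.five_prime is FivePrime.CAP0 and self.kind is not Kind.RNA:
            raise ValueError(f"sequence {self.id!r}: cap0 is only valid on RNA")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open interval [start, end) in 0-based parent coordinates."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals: merge overlapping or abutting ones, sort by start."""
    ivals = sorted(intervals)
    merged: list[Interval] = []
    for iv in ivals:
        if merged and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = Interval(merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def reverse_complement(seq: NucleicSequence, out_kind: Kind | str) -> NucleicSequence:
    """Reverse complement of ``seq`` in the requested alphabet.

    A pairs with T (DNA output) or U (RNA output).  End chemistries of the
    result are reset to hydroxyl/hydroxyl: the product is a synthetic
    antisense strand, not a transcript.
    """
    out_kind = Kind(out_kind)
    table = _DNA_COMPLEMENT if seq.kind is Kind.DNA else _RNA_COMPLEMENT
    comp = seq.residues.translate(table)[::-1]
    if out_kind is Kind.DNA:
        comp = comp.replace("U", "T")
    else:
        comp = comp.replace("T", "U")
    return NucleicSequence(id=f"{seq.id}_rc", kind=out_kind, residues=comp)


def find_probe_bindings(
    target: NucleicSequence, probe: NucleicSequence
) -> list[Interval]:
    """All intervals of an RNA target perfectly complementary to a DNA probe.

    Binding is all-or-nothing: an interval [s, e) qualifies iff the reverse
    complement of the target subsequence (written as DNA) equals the probe
    over its full length.  Overlapping sites are all reported, sorted by
    start.  The assay readout depends on this strictness: a probe that is not
    perfectly complementary to the target yields no protected fragment at
    all, only the free-probe band.
    """
    if target.kind is not Kind.RNA:
        raise ValueError("target must be RNA")
    if probe.kind is not Kind.DNA:
        raise ValueError("probe must be DNA")
    if len(probe) > len(target):
        raise ValueError(
            f"probe {probe.id!r} ({len(probe)} nt) is longer than target "
            f"{target.id!r} ({len(target)} nt)"
        )
    site = reverse_complement(probe, Kind.RNA).residues
    hits: list[Interval] = []
    pos = target.residues.find(site)
    while pos != -1:
        hits.append(Interval(pos, pos + len(site)))
        pos = target.residues.find(site, pos + 1)
    return hits


def read_fasta(
    path: str | Path,
    kind: Kind | str | None = None,
    rna_five_prime: FivePrime = FivePrime.TRIPHOSPHATE,
    dna_five_prime: FivePrime = FivePrime.HYDROXYL,
) -> list[NucleicSequence]:
    """Read a multi-record FASTA file into :class:`NucleicSequence` objects.

    Strand kind is inferred per record from the presence of U (RNA) versus T
    (DNA); records with neither default to DNA.  Pass ``kind`` to override
    the inference for every record.  Default end chemistry: RNA gets a
    5'-triphosphate (an uncapped primary IVT transcript), DNA a 5'-hydroxyl;
    3' ends are hydroxyl.  Empty records and illegal characters raise an
    error naming the record.
    """
    kind = Kind(kind) if kind is not None else None
    out: list[NucleicSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        residues = str(record.seq).upper()
        if not residues:
            raise ValueError(f"FASTA record {record.id!r} is empty")
        if kind is not None:
            rec_kind = kind
        else:
            has_t, has_u = "T" in residues, "U" in residues
            if has_t and has_u:
                raise ValueError(
                    f"FASTA record {record.id!r} mixes T and U; cannot infer kind"
                )
            rec_kind = Kind.RNA if has_u else Kind.DNA
        five = rna_five_prime if rec_kind is Kind.RNA else dna_five_prime
        out.append(
            NucleicSequence(
                id=record.id, kind=rec_kind, residues=residues, five_prime=five
            )
        )
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(
    seqs: Sequence[NucleicSequence], path: str | Path, width: int = 70
) -> None:
    """Write sequences to FASTA, ids preserved verbatim."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)
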