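"""Antisense DNA probe design and in-silico assay evaluation.

A probe is an antisense DNA oligo, reported 5'->3' as ordered for synthesis.
The assay favors 16-20 nt probes for cap analysis (single-nucleotide gel
resolution without prolonged runs) and tolerates 16-25 nt in general; hard
bounds of 10-60 nt are enforced.  Uniqueness is checked only against the
provided target — the assay is applied to defined IVT material, not a
transcriptome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .digestion import (
    EdgeRule,
    EnzymeSpec,
    SaltMode,
    build_protection_map,
    detectable,
    digest,
)
from .page_model import GelConfig
from .seqcore import (
    Interval,
    Kind,
    NucleicSequence,
    find_probe_bindings,
    reverse_complement,
)

__all__ = [
    "PROBE_MIN_LEN",
    "PROBE_MAX_LEN",
    "DEFAULT_CAP_PROBE_LEN",
    "Probe",
    "ProbeReport",
    "design_five_prime_probe",
    "design_region_probe",
    "evaluate_probe",
]

PROBE_MIN_LEN = 10
PROBE_MAX_LEN = 60
#: The cap-assay default (a 20-nt oligo sits inside the 16-24 nt
#: single-nucleotide resolution window of the gel).
DEFAULT_CAP_PROBE_LEN = 20


@dataclass(frozen=True)
class Probe:
    """An antisense DNA oligo aimed at ``target_id``.

    ``intended_interval`` is the target interval the probe was designed
    against (None for externally supplied probes).
    """

    id: str
    sequence: NucleicSequence
    target_id: str
    intended_interval: Interval | None = None

    def __post_init__(self) -> None:
        if self.sequence.kind is not Kind.DNA:
            raise ValueError(f"probe {self.id!r} must be DNA")
        if not (PROBE_MIN_LEN <= len(self.sequence) <= PROBE_MAX_LEN):
            raise ValueError(
                f"probe {self.id!r} length {len(self.sequence)} outside "
                f"[{PROBE_MIN_LEN}, {PROBE_MAX_LEN}]"
            )
        if (
            self.intended_interval is not None
            and self.intended_interval.length != len(self.sequence)
        ):
            raise ValueError("intended interval does not match probe length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProbeReport:
    """Predicted assay outcome for one probe on one target."""

    probe: Probe
    binding_sites: int
    protected_fragment_length: int | None
    offtarget_detectable_fragments: int
    within_resolution_window: bool
    edge_rule: EdgeRule

    def __post_init__(self) -> None:
        if self.binding_sites < 0 or self.offtarget_detectable_fragments < 0:
            raise ValueError("counts must be nonnegative")


def _make_probe(
    target: NucleicSequence, interval: Interval, probe_id: str | None = None
) -> Probe:
    sub = NucleicSequence(
        id=f"{target.id}[{interval.start}:{interval.end}]",
        kind=Kind.RNA,
        residues=target.residues[interval.start : interval.end],
    )
    antisense = reverse_complement(sub, Kind.DNA)
    pid = probe_id or f"{target.id}_probe_{interval.start}_{interval.end}"
    seq = NucleicSequence(id=pid, kind=Kind.DNA, residues=antisense.residues)
    return Probe(id=pid, sequence=seq, target_id=target.id, intended_interval=interval)


def design_five_prime_probe(target: NucleicSequence, length: int) -> Probe:
    """Antisense probe against the target's first ``length`` nucleotides.

    This is the cap-assay design: the probe-protected 5' fragment carries
    the cap (or triphosphate), so its gel position reads out cap status.
    """
    if target.kind is not Kind.RNA:
        raise ValueError("target must be RNA")
    if not (PROBE_MIN_LEN <= length <= min(PROBE_MAX_LEN, len(target))):
        raise ValueError(
            f"probe length {length} out of bounds for a {len(target)}-nt target"
        )
    return _make_probe(target, Interval(0, length), f"{target.id}_5p_{length}nt")


def design_region_probe(target: NucleicSequence, interval: Interval) -> Probe:
    """Antisense probe against an arbitrary target interval.

    Warns if the probe binds the target at more than one site (non-unique
    readout) and flags probes covering the target's 3' end as poly(A)/3'-end
    assay candidates.
    """
    if target.kind is not Kind.RNA:
        raise ValueError("target must be RNA")
    if interval.end > len(target):
        raise ValueError(f"interval {interval} outside target of length {len(target)}")
    probe = _make_probe(target, interval)
    sites = find_probe_bindings(target, probe.sequence)
    if len(sites) > 1:
        warnings.warn(
            f"probe {probe.id!r} binds {len(sites)} sites on {target.id!r}; "
            "the assay readout will not be unique",
            stacklevel=2,
        )
    if interval.end == len(target):
        warnings.warn(
            f"probe {probe.id!r} covers the target 3' end: candidate for a "
            "poly(A)/3'-end assay",
            stacklevel=2,
        )
    return probe


def evaluate_probe(
    target: NucleicSequence,
    probe: Probe | NucleicSequence,
    enzymes: list[EnzymeSpec],
    config: GelConfig | None = None,
    edge_rule: EdgeRule | str = EdgeRule.EDGE_PERMISSIVE,
    salt_mode: SaltMode | str = SaltMode.HIGH_SALT,
) -> ProbeReport:
    """Predict the assay outcome: binding sites, protected fragment length,
    detectable background, and whether the fragment sits in the gel's
    single-nucleotide resolution window.

    Under ``edge_permissive`` with a cleavable boundary base the protected
    fragment equals the probe length; under ``free_base_required`` it may run
    longer.  The applied rule is recorded in the report.
    """
    config = config or GelConfig()
    edge_rule = EdgeRule(edge_rule)
    seq = getattr(probe, "sequence", probe)
    if not isinstance(probe, Probe):
        probe = Probe(id=seq.id, sequence=seq, target_id=target.id)
    pmap = build_protection_map(target, [probe], salt_mode)
    n_sites = pmap.probe_reports[0].n_sites
    fragments = digest(target, pmap, enzymes, edge_rule)
    protected = [f for f in fragments if f.protected_overlap > 0]
    prot_len = len(protected[0]) if protected else None
    background = [
        f
        for f in detectable(fragments, config.min_detectable)
        if f.protected_overlap == 0
    ]
    lo, hi = config.resolution_window
    in_window = prot_len is not None and lo <= prot_len <= hi
    return ProbeReport(
        probe=probe,
        binding_sites=n_sites,
        protected_fragment_length=prot_len,
        offtarget_detectable_fragments=len(background),
        within_resolution_window=in_window,
        edge_rule=edge_rule,
    )
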