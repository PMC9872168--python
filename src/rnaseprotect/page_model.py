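"""Denaturing urea-PAGE lane prediction and capping-efficiency quantification.

Mobility is modeled ordinally through an *apparent length* in nt-equivalents:
a DNA oligo of length L defines the scale (apparent L); an RNA oligo of the
same length runs slower (apparent L + ``rna_offset``), and a cap 0 structure
adds a further ``cap0_offset``.  Relative mobility is a fixed monotone map of
apparent length, so only ordering and resolvability are meaningful — the gel
readout the assay relies on — never absolute migration distances.

Resolvability follows the gel's empirical behavior: single-nucleotide
resolution inside the 16-24 nt window, coarser (3 nt) outside it.  Species
whose apparent lengths differ by less than the applicable resolution
co-migrate and merge into one band whose intensity is the sum of the merged
molar abundances.  Species beyond ``max_resolved`` nt-equivalents survive
digestion but run as unresolved high-molecular-weight material (smears), not
sharp bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .digestion import (
    EdgeRule,
    EnzymeSpec,
    Fragment,
    SaltMode,
    build_protection_map,
    digest,
)
from .seqcore import FivePrime, Kind, NucleicSequence

__all__ = [
    "GelConfig",
    "GelBand",
    "Lane",
    "apparent_length",
    "predict_lane",
    "capping_efficiency",
    "AssayResult",
    "simulate_protection_assay",
    "lane_to_frame",
    "lane_to_tsv",
    "plot_lane",
]


@dataclass(frozen=True)
class GelConfig:
    """Tunables of the gel model.

    Offsets are in nt-equivalents on the DNA-length scale.  The default
    ``cap0_offset`` of 1.0 is the minimal value resolvable on a
    single-nucleotide gel — the true electrophoretic increment of a cap 0 is
    not established, so treat this as a calibration placeholder.
    """

    rna_offset: float = 1.0
    cap0_offset: float = 1.0
    resolution_window: tuple[int, int] = (16, 24)
    resolution_in_window: float = 1.0
    resolution_out_window: float = 3.0
    min_detectable: int = 8
    max_resolved: float = 80.0

    def __post_init__(self) -> None:
        if self.rna_offset < 0 or self.cap0_offset < 0:
            raise ValueError("offsets must be >= 0")
        lo, hi = self.resolution_window
        if not (0 < lo < hi):
            raise ValueError("resolution window bounds must be positive and ordered")


@dataclass(frozen=True)
class GelBand:
    """One resolved band: co-migrating species merged together."""

    species_ids: tuple[str, ...]
    kind: Kind
    nominal_length: int
    apparent_length: float
    relative_mobility: float
    intensity: float


@dataclass(frozen=True)
class _Species:
    id: str
    kind: Kind
    nominal_length: int
    apparent_length: float
    abundance: float
    capped: bool


@dataclass(frozen=True)
class Lane:
    """A predicted lane: sharp bands (fastest first) plus unresolved smear
    species that exceeded ``config.max_resolved``."""

    bands: tuple[GelBand, ...]
    unresolved: tuple[_Species, ...]
    config: GelConfig

    @property
    def total_intensity(self) -> float:
        return sum(b.intensity for b in self.bands) + sum(
            s.abundance for s in self.unresolved
        )

    def band_of(self, species_id: str) -> int | None:
        """Index of the band containing ``species_id`` (None if absent)."""
        for i, band in enumerate(self.bands):
            if species_id in band.species_ids:
                return i
        return None


def _mobility(apparent: float) -> float:
    # monotone, dimensionless, in (0, 1]; only ordering is meaningful
    return 1.0 / (1.0 + apparent / 100.0)


def apparent_length(
    kind: Kind | str,
    nominal_length: int,
    five_prime: FivePrime | str | None = None,
    config: GelConfig | None = None,
) -> float:
    """Apparent length in nt-equivalents on the DNA scale.

    DNA -> L; uncapped RNA -> L + rna_offset; cap 0 RNA -> L + rna_offset +
    cap0_offset.
    """
    config = config or GelConfig()
    kind = Kind(kind)
    if kind is Kind.DNA:
        return float(nominal_length)
    app = nominal_length + config.rna_offset
    if five_prime is not None and FivePrime(five_prime) is FivePrime.CAP0:
        app += config.cap0_offset
    return app


def _as_species(obj, abundance: float, config: GelConfig) -> _Species:
    if isinstance(obj, Fragment):
        kind = Kind.RNA
        nominal = len(obj)
        five = obj.five_prime
        sid = obj.species_id
        capped = obj.capped
    elif isinstance(obj, NucleicSequence):
        kind = obj.kind
        nominal = len(obj)
        five = obj.five_prime
        sid = obj.id
        capped = obj.five_prime is FivePrime.CAP0
    else:
        raise TypeError(f"cannot run {type(obj).__name__} on a gel")
    return _Species(
        id=sid,
        kind=kind,
        nominal_length=nominal,
        apparent_length=apparent_length(kind, nominal, five, config),
        abundance=float(abundance),
        capped=capped,
    )


def predict_lane(
    species: Sequence[tuple[object, float]],
    config: GelConfig | None = None,
) -> Lane:
    """Predict the lane for (sequence-or-fragment, molar abundance) pairs.

    Species shorter than ``min_detectable`` nt or with zero abundance are
    dropped; species beyond ``max_resolved`` nt-equivalents are reported as
    unresolved smear.  Adjacent species merge into one band when their
    apparent lengths differ by less than the applicable resolution —
    single-nucleotide if either member's nominal length lies in the
    resolution window, else the out-of-window resolution.  Bands come back
    sorted by decreasing mobility (shortest first).
    """
    config = config or GelConfig()
    pool: list[_Species] = []
    for obj, abundance in species:
        if abundance < 0:
            raise ValueError("abundances must be >= 0")
        sp = _as_species(obj, abundance, config)
        if sp.nominal_length < config.min_detectable or sp.abundance == 0:
            continue
        pool.append(sp)

    resolved = [s for s in pool if s.apparent_length <= config.max_resolved]
    unresolved = tuple(
        sorted(
            (s for s in pool if s.apparent_length > config.max_resolved),
            key=lambda s: s.apparent_length,
        )
    )

    resolved.sort(key=lambda s: (s.apparent_length, s.id))
    lo, hi = config.resolution_window

    def pair_resolution(a: _Species, b: _Species) -> float:
        if lo <= a.nominal_length <= hi or lo <= b.nominal_length <= hi:
            return config.resolution_in_window
        return config.resolution_out_window

    clusters: list[list[_Species]] = []
    for sp in resolved:
        if clusters and (
            sp.apparent_length - clusters[-1][-1].apparent_length
            < pair_resolution(clusters[-1][-1], sp)
        ):
            clusters[-1].append(sp)
        else:
            clusters.append([sp])

    bands = []
    for members in clusters:
        intensity = sum(m.abundance for m in members)
        if intensity > 0:
            app = sum(m.apparent_length * m.abundance for m in members) / intensity
        else:
            app = sum(m.apparent_length for m in members) / len(members)
        dominant = max(members, key=lambda m: (m.abundance, -m.apparent_length))
        bands.append(
            GelBand(
                species_ids=tuple(m.id for m in members),
                kind=dominant.kind,
                nominal_length=dominant.nominal_length,
                apparent_length=app,
                relative_mobility=_mobility(app),
                intensity=intensity,
            )
        )
    return Lane(bands=tuple(bands), unresolved=unresolved, config=config)


def capping_efficiency(
    lane: Lane,
    capped_band: int | None,
    uncapped_band: int | None,
) -> float:
    """Fraction capped = I(capped) / (I(capped) + I(uncapped)).

    Band arguments are lane indices; ``None`` means the band is absent
    (intensity 0), as happens at 0% or 100% capping.  Both intensities zero
    is undefined and raises.
    """

    def intensity(idx: int | None) -> float:
        if idx is None:
            return 0.0
        return lane.bands[idx].intensity

    cap, uncap = intensity(capped_band), intensity(uncapped_band)
    if cap < 0 or uncap < 0:
        raise ValueError("band intensities must be nonnegative")
    if cap + uncap == 0:
        raise ValueError("capping efficiency undefined: both bands have zero intensity")
    return cap / (cap + uncap)


@dataclass(frozen=True)
class AssayResult:
    """End-to-end protection-assay prediction for a pool of molecules."""

    fragments: tuple[tuple[Fragment, float], ...]
    lane: Lane
    capped_band: int | None
    uncapped_band: int | None

    @property
    def capping_efficiency(self) -> float | None:
        if self.capped_band is None and self.uncapped_band is None:
            return None
        return capping_efficiency(self.lane, self.capped_band, self.uncapped_band)


def simulate_protection_assay(
    pool: Sequence[tuple[NucleicSequence, float]],
    probe,
    enzymes: Sequence[EnzymeSpec],
    config: GelConfig | None = None,
    edge_rule: EdgeRule | str = EdgeRule.EDGE_PERMISSIVE,
    salt_mode: SaltMode | str = SaltMode.HIGH_SALT,
    probe_abundance: float | None = None,
) -> AssayResult:
    """Digest every pool member under the shared protection map and predict
    the lane, including the free-probe band.

    ``pool`` holds molecules of identical sequence that may differ in 5'
    chemistry (cap 0 versus triphosphate) and molar abundance — the
    capping-reaction readout.  The probe species is added to the lane at
    ``probe_abundance`` (default: total pool abundance, i.e. probe in
    equimolar excess).  The bands carrying the capped and uncapped
    probe-protected 5' fragments are located and returned so the capping
    efficiency can be read off the lane.
    """
    config = config or GelConfig()
    if not pool:
        raise ValueError("empty pool")
    probe_seq = getattr(probe, "sequence", probe)
    reference = pool[0][0]
    for member, _ in pool[1:]:
        if member.residues != reference.residues:
            raise ValueError("pool members must share one sequence")

    pmap = build_protection_map(reference, [probe], salt_mode)
    weighted: list[tuple[Fragment, float]] = []
    for member, abundance in pool:
        for frag in digest(member, pmap.for_target(member.id), enzymes, edge_rule):
            weighted.append((frag, abundance))

    species: list[tuple[object, float]] = list(weighted)
    total = sum(a for _, a in pool)
    species.append((probe_seq, total if probe_abundance is None else probe_abundance))
    lane = predict_lane(species, config)

    capped_band = uncapped_band = None
    for frag, _ in weighted:
        if frag.protected_overlap > 0 and frag.interval.start == 0:
            idx = lane.band_of(frag.species_id)
            if frag.capped:
                capped_band = idx
            else:
                uncapped_band = idx
    return AssayResult(
        fragments=tuple(weighted),
        lane=lane,
        capped_band=capped_band,
        uncapped_band=uncapped_band,
    )


def lane_to_frame(lane: Lane) -> pd.DataFrame:
    rows = [
        {
            "band": i + 1,
            "kind": b.kind.value,
            "nominal_length": b.nominal_length,
            "apparent_length": b.apparent_length,
            "relative_mobility": b.relative_mobility,
            "intensity": b.intensity,
            "members": ";".join(b.species_ids),
        }
        for i, b in enumerate(lane.bands)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "band",
            "kind",
            "nominal_length",
            "apparent_length",
            "relative_mobility",
            "intensity",
            "members",
        ],
    )


def lane_to_tsv(lane: Lane, path: str | Path) -> None:
    with open(path, "w") as handle:
        if lane.unresolved:
            smear = ";".join(s.id for s in lane.unresolved)
            handle.write(f"# unresolved_smear={smear}\n")
        handle.write(
            f"# cap0_offset={lane.config.cap0_offset} (calibration placeholder)\n"
        )
        lane_to_frame(lane).to_csv(handle, sep="\t", index=False)


def plot_lane(lane: Lane, ax=None):
    """Schematic lane sketch (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.8, 5))
    top = max((b.apparent_length for b in lane.bands), default=30.0) * 1.15
    max_i = max((b.intensity for b in lane.bands), default=1.0)
    for band in lane.bands:
        shade = 0.85 * band.intensity / max_i
        ax.axhline(band.apparent_length, xmin=0.15, xmax=0.85, lw=4, color=str(1 - shade))
        ax.annotate(
            f"{band.nominal_length} nt {band.kind.value}",
            (0.88, band.apparent_length),
            fontsize=7,
            va="center",
        )
    ax.set_ylim(top, 0)  # small species run farthest
    ax.set_xlim(0, 1.6)
    ax.set_xticks([])
    ax.set_ylabel("apparent length (nt-equivalents)")
    return ax
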