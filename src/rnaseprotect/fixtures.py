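"""Synthetic assay fixtures: targets, probes, and pools with known truth.

The generator emulates the structural features the protection assay relies
on, without reproducing any particular natural sequence: a known 5' end
complementary to a chosen probe, an unprotected body whose RNase-cleavable
sites are frequent enough that background digestion products stay below the
gel's detection threshold, an optional 3' poly(A) tail, and a pool split
between cap 0 and 5'-triphosphate molecules at a chosen capping fraction.

Background control is enforced by construction: every window of
``max_unprotected_run`` bases in the unprotected body contains a pyrimidine
(C or U), so complete digestion with RNase A alone — and a fortiori with the
RNase A + T1 mixture — leaves no unprotected fragment of that length or
more.  The last probe-covered base is forced to be a pyrimidine so the
protected fragment's 3' boundary is cleaved by RNase A (fragment length =
probe length under the edge-permissive convention).

All randomness is driven by the spec's seed; identical specs generate
byte-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .digestion import RNASE_A, RNASE_T1
from .page_model import AssayResult, GelConfig, simulate_protection_assay
from .probe_design import PROBE_MAX_LEN, PROBE_MIN_LEN, Probe, design_five_prime_probe
from .seqcore import FivePrime, Kind, NucleicSequence, find_probe_bindings

__all__ = ["FixtureSpec", "FixtureBundle", "generate_fixture"]

_BASES = np.array(list("ACGU"))
_PYRIMIDINES = np.array(list("CU"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic assay scenario.

    ``max_unprotected_run`` must stay below the gel's detection threshold
    (default 8 nt) for a clean two-band readout; 7 keeps one nucleotide of
    headroom.  ``cap_fraction`` splits the pool into cap 0 and triphosphate
    molecules.
    """

    target_length: int
    probe_length: int
    five_prime_match: bool = True
    cap_fraction: float = 0.0
    max_unprotected_run: int = 7
    polya_tail: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_unprotected_run < 1:
            raise ValueError("max_unprotected_run must be >= 1 (infeasible otherwise)")
        if not 0.0 <= self.cap_fraction <= 1.0:
            raise ValueError("cap_fraction must be within [0, 1]")
        if not (PROBE_MIN_LEN <= self.probe_length <= PROBE_MAX_LEN):
            raise ValueError(
                f"probe_length must lie in [{PROBE_MIN_LEN}, {PROBE_MAX_LEN}]"
            )
        if self.probe_length > self.target_length:
            raise ValueError("probe_length exceeds target_length")
        if self.polya_tail < 0:
            raise ValueError("polya_tail must be >= 0")
        body = self.target_length - self.polya_tail
        if self.five_prime_match and body < self.probe_length:
            raise ValueError(
                "target body (length minus poly(A) tail) shorter than the probe"
            )
        if body < 1:
            raise ValueError("poly(A) tail leaves no target body")


@dataclass(frozen=True)
class FixtureBundle:
    """A generated scenario: RNA pool with abundances, probe, and the
    pipeline's own summary of the expected readout."""

    spec: FixtureSpec
    target_id: str
    pool: tuple[tuple[NucleicSequence, float], ...]
    probe: Probe
    summary: dict


def _random_body(spec: FixtureSpec, rng: np.random.Generator) -> str:
    body_len = spec.target_length - spec.polya_tail
    out: list[str] = []
    run = 0  # consecutive non-pyrimidine bases in the unprotected body
    protected_until = spec.probe_length if spec.five_prime_match else 0
    for i in range(body_len):
        if spec.five_prime_match and i == spec.probe_length - 1:
            base = str(rng.choice(_PYRIMIDINES))  # cleavable probe boundary
        elif i < protected_until:
            base = str(rng.choice(_BASES))
        elif run >= spec.max_unprotected_run - 1:
            base = str(rng.choice(_PYRIMIDINES))
        else:
            base = str(rng.choice(_BASES))
        if i >= protected_until:
            run = 0 if base in ("C", "U") else run + 1
        out.append(base)
    return "".join(out)


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate the target pool, probe, and expected assay summary.

    The summary runs the package's own pipeline (RNase A + T1 mixture,
    default gel config) on the generated material and records the band
    count, protected fragment length, and — for mixed pools — the capping
    efficiency read from the lane.
    """
    rng = np.random.default_rng(spec.seed)
    target_id = f"synthetic_{spec.target_length}nt_seed{spec.seed}"
    residues = _random_body(spec, rng) + "A" * spec.polya_tail

    template = NucleicSequence(
        id=target_id,
        kind=Kind.RNA,
        residues=residues,
        five_prime=FivePrime.TRIPHOSPHATE,
    )

    if spec.five_prime_match:
        probe = design_five_prime_probe(template, spec.probe_length)
    else:
        probe = _nonbinding_probe(template, spec.probe_length, rng)

    pool: list[tuple[NucleicSequence, float]] = []
    if spec.cap_fraction < 1.0:
        pool.append(
            (
                NucleicSequence(
                    id=f"{target_id}|uncapped",
                    kind=Kind.RNA,
                    residues=residues,
                    five_prime=FivePrime.TRIPHOSPHATE,
                ),
                1.0 - spec.cap_fraction,
            )
        )
    if spec.cap_fraction > 0.0:
        pool.append(
            (
                NucleicSequence(
                    id=f"{target_id}|capped",
                    kind=Kind.RNA,
                    residues=residues,
                    five_prime=FivePrime.CAP0,
                ),
                spec.cap_fraction,
            )
        )

    result = simulate_protection_assay(
        pool, probe, [RNASE_A, RNASE_T1], GelConfig()
    )
    summary = _summarize(result, probe)
    return FixtureBundle(
        spec=spec,
        target_id=target_id,
        pool=tuple(pool),
        probe=probe,
        summary=summary,
    )


def _nonbinding_probe(
    target: NucleicSequence, length: int, rng: np.random.Generator
) -> Probe:
    for _ in range(100):
        residues = "".join(rng.choice(np.array(list("ACGT")), size=length))
        seq = NucleicSequence(
            id=f"{target.id}_noncomplementary_{length}nt",
            kind=Kind.DNA,
            residues=residues,
        )
        if not find_probe_bindings(target, seq):
            return Probe(
                id=seq.id, sequence=seq, target_id=target.id, intended_interval=None
            )
    raise RuntimeError("could not draw a non-binding probe (target too repetitive)")


def _summarize(result: AssayResult, probe: Probe) -> dict:
    protected = [
        (f, a) for f, a in result.fragments if f.protected_overlap > 0
    ]
    return {
        "n_bands": len(result.lane.bands),
        "n_unresolved": len(result.lane.unresolved),
        "probe_length": len(probe),
        "protected_fragment_length": len(protected[0][0]) if protected else None,
        "capping_efficiency": result.capping_efficiency,
    }
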