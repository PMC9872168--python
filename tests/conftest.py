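import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from rnaseprotect import (  # noqa: E402
    FivePrime,
    Interval,
    Kind,
    NucleicSequence,
    ProtectionMap,
)


def random_rna(rng: np.random.Generator, length: int, id: str = "rna") -> NucleicSequence:
    residues = "".join(rng.choice(list("ACGU"), size=length))
    return NucleicSequence(
        id=id, kind=Kind.RNA, residues=residues, five_prime=FivePrime.TRIPHOSPHATE
    )


def random_protection(
    rng: np.random.Generator, target: NucleicSequence, max_intervals: int = 3
) -> ProtectionMap:
    n = len(target)
    k = int(rng.integers(0, max_intervals + 1))
    points = sorted(rng.integers(0, n + 1, size=2 * k).tolist())
    intervals = []
    for a, b in zip(points[::2], points[1::2]):
        if b > a and (not intervals or a > intervals[-1].end):
            intervals.append(Interval(a, b))
    return ProtectionMap(target_id=target.id, intervals=tuple(intervals))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def make_rna():
    return random_rna


@pytest.fixture
def make_protection():
    return random_protection
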