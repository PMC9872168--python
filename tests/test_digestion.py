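"""RNase digestion under hybrid protection: examples, oracle, invariants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rnaseprotect import (
    RNASE_A,
    RNASE_T1,
    EdgeRule,
    EnzymeSpec,
    FivePrime,
    Interval,
    Kind,
    NucleicSequence,
    ProtectionMap,
    SaltMode,
    ThreePrime,
    build_protection_map,
    design_five_prime_probe,
    detectable,
    digest,
)


def oracle_digest(residues, protected_intervals, recognition, edge_rule):
    """Brute force: mark every cleavable bond independently, then split."""
    n = len(residues)
    protected = [False] * n
    for s, e in protected_intervals:
        for i in range(s, e):
            protected[i] = True
    cuts = []
    for i in range(n - 1):
        if residues[i] not in recognition:
            continue
        if edge_rule == "edge_permissive":
            ok = not protected[i + 1]
        else:
            ok = not protected[i] and not protected[i + 1]
        if ok:
            cuts.append(i)
    pieces, start = [], 0
    for c in cuts:
        pieces.append(residues[start : c + 1])
        start = c + 1
    pieces.append(residues[start:])
    return pieces


def _digest_pieces(residues, intervals=(), enzymes=(RNASE_A,), edge_rule=EdgeRule.EDGE_PERMISSIVE):
    target = NucleicSequence("t", Kind.RNA, residues)
    pmap = ProtectionMap("t", tuple(Interval(s, e) for s, e in intervals))
    return digest(target, pmap, list(enzymes), edge_rule)


class TestEnzymePresets:
    def test_specificities(self):
        assert RNASE_A.recognition == frozenset("CU")
        assert RNASE_T1.recognition == frozenset("G")

    def test_bad_recognition_rejected(self):
        with pytest.raises(ValueError):
            EnzymeSpec("bogus", frozenset("T"))


class TestDigestExamples:
    @pytest.mark.parametrize(
        "residues,enzymes,expected",
        [
            ("ACGAU", [RNASE_A], ["AC", "GAU"]),
            ("GGAUG", [RNASE_T1], ["G", "G", "AUG"]),
            ("AAAA", [RNASE_A, RNASE_T1], ["AAAA"]),
        ],
    )
    def test_unprotected(self, residues, enzymes, expected):
        assert [f.residues for f in _digest_pieces(residues, enzymes=enzymes)] == expected

    def test_protected_five_prime_block(self):
        # the protected fragment has exactly the probe length under
        # the edge-permissive convention
        frags = _digest_pieces(
            "ACGUACGUAC", [(0, 4)], (RNASE_A, RNASE_T1), EdgeRule.EDGE_PERMISSIVE
        )
        assert [f.residues for f in frags] == ["ACGU", "AC", "G", "U", "AC"]
        assert len(frags[0]) == 4
        assert frags[0].protected_overlap == 4

    def test_free_base_required_extends_protected_fragment(self):
        frags = _digest_pieces(
            "ACGUACGUAC", [(0, 4)], (RNASE_A, RNASE_T1), EdgeRule.FREE_BASE_REQUIRED
        )
        # the boundary bond U|A is not cleavable: U is protected
        assert frags[0].residues == "ACGUAC"

    def test_empty_enzyme_list_returns_parent(self):
        frags = _digest_pieces("ACGU", enzymes=())
        assert [f.residues for f in frags] == ["ACGU"]

    def test_wrong_target_id_rejected(self):
        target = NucleicSequence("t", Kind.RNA, "ACGU")
        with pytest.raises(ValueError):
            digest(target, ProtectionMap("other", ()), [RNASE_A])


class TestEndChemistry:
    def test_cut_products(self):
        frags = _digest_pieces("ACGAU", enzymes=(RNASE_A,))
        first, last = frags[0], frags[-1]
        assert first.five_prime is FivePrime.HYDROXYL  # parent default
        assert first.three_prime is ThreePrime.PHOSPHATE
        assert last.five_prime is FivePrime.HYDROXYL
        assert last.three_prime is ThreePrime.HYDROXYL

    def test_first_fragment_inherits_cap(self):
        target = NucleicSequence(
            "t", Kind.RNA, "AAACAAA", five_prime=FivePrime.CAP0
        )
        frags = digest(target, ProtectionMap("t", ()), [RNASE_A])
        assert frags[0].capped and frags[0].five_prime is FivePrime.CAP0
        assert not frags[1].capped

    def test_cyclic_product_selectable(self):
        rnase_a_cyclic = EnzymeSpec(
            "RNase A", frozenset("CU"), product_3prime=ThreePrime.CYCLIC_PHOSPHATE
        )
        frags = _digest_pieces("ACGAU", enzymes=(rnase_a_cyclic,))
        assert frags[0].three_prime is ThreePrime.CYCLIC_PHOSPHATE

    def test_mixture_products_follow_cutting_enzyme(self):
        t1_cyclic = EnzymeSpec(
            "RNase T1", frozenset("G"), product_3prime=ThreePrime.CYCLIC_PHOSPHATE
        )
        frags = _digest_pieces("ACGAU", enzymes=(RNASE_A, t1_cyclic))
        # "AC" cut by A (linear), "G" cut by T1 (cyclic)
        assert frags[0].three_prime is ThreePrime.PHOSPHATE
        assert frags[1].three_prime is ThreePrime.CYCLIC_PHOSPHATE


class TestProtectionMap:
    def test_single_probe_high_salt(self, make_rna, rng):
        target = make_rna(rng, 86)
        probe = design_five_prime_probe(target, 24)
        pmap = build_protection_map(target, [probe], SaltMode.HIGH_SALT)
        assert list(pmap.intervals) == [Interval(0, 24)]

    def test_low_salt_voids_protection(self, make_rna, rng):
        target = make_rna(rng, 86)
        probe = design_five_prime_probe(target, 24)
        pmap = build_protection_map(target, [probe], SaltMode.LOW_SALT)
        assert pmap.intervals == ()
        assert pmap.probe_reports[0].n_sites == 1  # binding still reported

    def test_overlapping_probes_merge(self, make_rna, rng):
        target = make_rna(rng, 60)
        p1 = design_five_prime_probe(target, 20)
        from rnaseprotect import design_region_probe

        p2 = design_region_probe(target, Interval(10, 30))
        pmap = build_protection_map(target, [p1, p2])
        assert list(pmap.intervals) == [Interval(0, 30)]

    def test_zero_binding_probe_reported_not_fatal(self, make_rna, rng):
        target = make_rna(rng, 50)
        stranger = NucleicSequence("p", Kind.DNA, "T" * 27)
        pmap = build_protection_map(target, [stranger])
        assert pmap.probe_reports[0].n_sites == 0
        assert pmap.intervals == ()


class TestDetectable:
    def test_threshold(self):
        frags = _digest_pieces("A" * 24 + "C" + "AAA" + "C" + "AA", enzymes=(RNASE_A,))
        lengths = sorted(len(f) for f in detectable(frags, 8))
        assert lengths == [25]

    def test_min_len_one_is_identity(self):
        frags = _digest_pieces("ACGAU")
        assert detectable(frags, 1) == frags

    def test_all_below_threshold(self):
        frags = _digest_pieces("ACACAC")
        assert detectable(frags, 8) == []


class TestDigestProperties:
    @given(
        st.integers(0, 2**32 - 1),
        st.sampled_from(["edge_permissive", "free_base_required"]),
        st.sampled_from([("CU",), ("G",), ("CU", "G")]),
    )
    def test_matches_bond_marking_oracle(self, seed, edge_rule, recogs):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 300))
        residues = "".join(rng.choice(list("ACGU"), size=n))
        k = int(rng.integers(0, 3))
        points = sorted(rng.integers(0, n + 1, size=2 * k).tolist())
        intervals = [
            (a, b)
            for a, b in zip(points[::2], points[1::2])
            if b > a
        ]
        merged = []
        for a, b in intervals:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(b, merged[-1][1]))
            else:
                merged.append((a, b))
        enzymes = [EnzymeSpec(f"e{r}", frozenset(r)) for r in recogs]
        got = [
            f.residues
            for f in _digest_pieces(residues, merged, enzymes, edge_rule)
        ]
        expected = oracle_digest(
            residues, merged, set("".join(recogs)), edge_rule
        )
        assert got == expected

    @given(st.integers(0, 2**32 - 1))
    def test_conservation_and_abutment(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 400))
        residues = "".join(rng.choice(list("ACGU"), size=n))
        frags = _digest_pieces(residues, enzymes=(RNASE_A, RNASE_T1))
        assert "".join(f.residues for f in frags) == residues
        pos = 0
        for f in frags:
            assert f.interval.start == pos
            pos = f.interval.end
        assert pos == n

    @given(st.integers(0, 2**32 - 1))
    def test_mixture_interiors_are_adenosine(self, seed):
        rng = np.random.default_rng(seed)
        residues = "".join(rng.choice(list("ACGU"), size=int(rng.integers(2, 200))))
        for f in _digest_pieces(residues, enzymes=(RNASE_A, RNASE_T1)):
            assert set(f.residues[:-1]) <= {"A"}

    @given(st.integers(0, 2**32 - 1))
    def test_adding_enzyme_never_reduces_fragments(self, seed):
        rng = np.random.default_rng(seed)
        residues = "".join(rng.choice(list("ACGU"), size=int(rng.integers(1, 200))))
        a_only = _digest_pieces(residues, enzymes=(RNASE_A,))
        mixture = _digest_pieces(residues, enzymes=(RNASE_A, RNASE_T1))
        assert len(mixture) >= len(a_only)

    def test_protected_interval_never_split(self, make_rna, make_protection, rng):
        for _ in range(50):
            target = make_rna(rng, int(rng.integers(10, 400)))
            pmap = make_protection(rng, target)
            frags = digest(target, pmap, [RNASE_A, RNASE_T1])
            for iv in pmap.intervals:
                containing = [
                    f
                    for f in frags
                    if f.interval.start <= iv.start and iv.end <= f.interval.end
                ]
                assert len(containing) == 1
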