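# Methods

## Model overview

The package simulates the DNA-probe RNase protection assay as four composed
models: hybridization (which target intervals a probe protects), digestion
(which phosphodiester bonds the RNases cut), electrophoresis (where the
surviving species run on a denaturing gel), and mass (what the fragments
weigh for an MS readout).  A rule engine for merging reaction-buffer
recipes and a deterministic fixture generator complete the toolkit.

All coordinates are 0-based, half-open.  Sequences are single strands with
explicit end chemistry; the 5' end distinguishes a primary IVT transcript
(triphosphate) from a cap 0 message, and digestion writes the products' end
chemistries explicitly because they shift computed masses.

## Hybridization and protection

Probe binding is **all-or-nothing**: a DNA probe occupies a target interval
iff it is the perfect, full-length reverse complement of that interval.
This mirrors the assay's observed logic — an imperfectly matched probe
yields no protected fragment at all — and deliberately omits mismatch
tolerance, duplex thermodynamics (Tm, dG) and secondary structure, which
are out of scope.  No minimum partial-match length exists below the full
probe; partial protection is not modeled.

Protection is salt-gated: in `high_salt` (bench condition ~700 mM NaCl)
DNA-RNA hybrids resist RNase A and the protection map is the merged union
of all binding sites; in `low_salt` the enzymes attack duplexes too, so the
map is empty regardless of binding.  Probes with zero or multiple sites are
reported, not fatal — a non-binding probe is the assay's negative control.

## Digestion

RNase A cleaves the bond 3' of pyrimidines (C, U); RNase T1 3' of G.  Both
leave 5'-hydroxyl and (after hydrolysis of the 2',3'-cyclic intermediate)
3'-phosphate products; the cyclic form is selectable per enzyme and only
affects masses.  Digestion is modeled as **complete** — every cleavable
bond is cut — because that is how assay lanes are read; no kinetics, no
partial digests, and no modeling of the salt condition beyond the binary
`salt_mode`.

Gel resolution (±1 nt) cannot decide whether cleavage happens exactly at
the hybrid boundary, so both conventions are implemented and surfaced in
output metadata:

- `edge_permissive` (default): the bond after base *i* is cut iff *i* is a
  recognition base and *i*+1 is unprotected.  The bond immediately 3' of a
  protected interval is cleavable when the boundary base is a recognition
  base, so the protected fragment has exactly the probe's length — the
  readout the bench assay reports (24-nt probe, 24-nt fragment).
- `free_base_required`: both bond neighbors must be unprotected; the
  protected fragment extends to the next cut and is >= the probe length.

Fragments below `min_detectable` (default 8 nt) are considered invisible
on the gel.  The bench description gives no number, only that small
fragments escape detection; 8 nt sits comfortably below the gel's 16-24 nt
optimum and is configurable.

## Gel model

Mobility is ordinal.  Each species gets an *apparent length* in
nt-equivalents on the DNA scale: DNA length L runs at L; RNA runs
`rna_offset` (default 1.0) slower; a cap 0 adds `cap0_offset` (default
1.0).  Relative mobility is the fixed monotone map `1/(1 + L_app/100)`;
only ordering and resolvability carry meaning, never absolute distances,
because the assay itself only reports ordering and shifts.

The true electrophoretic increment of a cap 0 is not established; the
default of 1.0 nt-equivalent is the smallest value resolvable on a
single-nucleotide gel and is flagged as a calibration placeholder in lane
output.

Resolvability: species merge into one band when their apparent lengths
differ by less than the applicable resolution — 1 nt when either member's
nominal length lies in the 16-24 nt window where the gel resolves single
nucleotides, 3 nt outside it.  The either-member rule is deliberate: 24-
and 26-nt RNA fragments (apparent 25 vs 27) are clearly resolved on the
bench even though 26 nt sits just past the window, while two species 0.5
nt-equivalents apart merge anywhere.  Merging uses apparent, not nominal,
length, so a 24-nt DNA and a 24-nt RNA resolve.

Species with apparent length above `max_resolved` (default 80
nt-equivalents) survive digestion but are reported as unresolved smear
rather than sharp bands — long undigested material (e.g. a surviving
poly(A) tail fragment) runs as the faint high-MW smear seen on real
oligo-resolving gels, not as a countable band.  Band intensity is
proportional to summed molar abundance; staining differences between DNA
and RNA are ignored.  Total lane intensity (bands + smear) conserves the
total detectable abundance.

Capping efficiency is `I_cap / (I_cap + I_uncap)` over the two protected
5'-fragment bands; a missing band contributes zero intensity (0% or 100%
capping), and both-zero is reported as an error.  On synthetic pools the
measured efficiency recovers the input cap fraction exactly whenever
digestion yields one protected fragment per molecule.

## Masses

Fragment masses are sums of chain-residue masses (nucleoside
5'-monophosphate minus water, from elemental formulas) plus water plus
end-chemistry adjustments relative to a 5'-monophosphate / 3'-OH strand:
5'-OH subtracts HPO3, 5'-triphosphate adds 2xHPO3, cap 0 adds 2xHPO3 plus
7-methylguanosine minus water (applied to the 5'-terminal fragment only),
3'-phosphate adds HPO3, and the 2',3'-cyclic form is the linear phosphate
minus one water.  Consequently, with linear-phosphate products, the sum of
fragment masses equals the parent mass plus one water per cut — a
conservation law the tests enforce on random digests.

## Probe-tiled mass mapping

A probe-free ("baseline") RNase mass map covers a position iff its
digestion fragment is detectable (default >= 3 nt; MS limits are
instrument-dependent and exposed in `MassMapConfig`) and its theoretical
mass is unique within tolerance (default 0.01 Da monoisotopic) among all
fragments of the digest.  A single uncut full-length fragment counts as
covered by default; set `max_fragment_length` to rule it undetectable.

Tiling runs one probe per digestion round (the bench format; a multiplex
mode co-incubating all probes exists but is off by default).  Greedy set
cover selects non-overlapping probe intervals: a candidate round is
admissible when its protected fragment is detectable and mass-unique in
that round's digest, rounds are scored by newly covered positions (all
detectable mass-unique fragments of the round count), ties break to the
leftmost, then shortest, interval, and selection stops when no round adds
coverage.  Coverage accumulates over probe rounds only; a target shorter
than the minimum probe length therefore has an empty design and zero
coverage.  Because every off-probe fragment of a round reproduces a
baseline fragment, tiled coverage dominates the baseline in practice (a
property verified on random targets).

The inner loop uses a vectorized digester that mirrors `digest()` exactly
(cut positions from the same bond rule, masses from cumulative sums); a
unit test pins the two to identical boundaries and masses.

## Buffer integration

Per reaction type, each component's occurrence frequency and median
concentration are computed over the recipes that *contain* it — absence is
absence, not an imputed zero — with the even-count median as the mean of
the central pair.  A component is *essential* iff its frequency is exactly
1.0.  Integration applies rule 1 (essential on either side: include at that
side's median), rule 2 (non-essential and one-sided: exclude), and rule 3
(present on both sides: the higher median, unless flagged `detrimental` or
`lowest_equivalent`, which both take the lower value with distinct
provenance tags — the flags encode experimental judgments that recipe
tables cannot supply).  Component names are canonicalized through a
shipped, user-extensible synonym table; unknown names pass through with a
warning.  Stocks multiply every concentration by N and append substrates
with their own provenance tag.

The bundled recipe table is **synthetic**: the supplementary survey behind
the published medians is not printed, so the fixture is constructed to
reproduce the published per-component medians (Tris-HCl 41.1, MgCl2 9.9,
DTT 7.4, spermidine 1.8, NTPs 2.0 mM over 11 IVT recipes) and the
published integrated 10x stock, including the rule-2 exclusions (KCl, NaCl,
Triton X-100, Tween-20).  It validates the rule engine, not the underlying
literature survey.

## Synthetic fixtures

`generate_fixture` builds seed-deterministic scenarios with the structural
features the assay assumes: a 5' region complementary to the designed
probe (or a verified non-binding probe for negative controls), an
unprotected body in which **every window of `max_unprotected_run` bases
(default 7) contains a pyrimidine**, an optional 3' poly(A) tail, and a
pool split between cap 0 and triphosphate molecules at the requested cap
fraction.  The pyrimidine constraint is intentionally stronger than
requiring any cleavable base: it guarantees sub-threshold background under
RNase A *alone* as well as under the A+T1 mixture.  The last probe-covered
base is forced to a pyrimidine so the protected fragment's 3' boundary is
cleavable by RNase A and the fragment length equals the probe length under
the edge-permissive convention.

What the fixtures do **not** emulate: real sequence composition biases,
secondary structure, incomplete transcription products, DNA template
contamination, partial digestion, or gel artifacts.  Passing tests
demonstrate the internal consistency of the assay logic on idealized
material, not the behavior of any particular biological sequence.

## Problem sizes and numerics

The test suite exercises the digestion oracle on 1,000 random instances up
to 2,000 nt, conservation laws on 300 random digests up to 1,500 nt, and
tiling-vs-baseline on 100 random 300-nt targets with 20-nt probes — sizes
chosen so the full suite completes in well under a minute while covering
the scales the assay targets (86-nt and 2,191-nt transcripts).  Mass
comparisons use absolute tolerances of 1e-4 Da or better; band merging
uses strict inequality against the applicable resolution, so a gap exactly
equal to the resolution resolves.  Degenerate inputs have defined
behavior: an empty enzyme list returns the intact parent, an empty species
list an empty lane, zero-abundance species are dropped, and a zero-binding
probe digests the target completely.

## Known limitations

- No mismatch or partial hybridization model; probe uniqueness is checked
  only against the given target, not a transcriptome.
- The gel model is ordinal; absolute migration distances and densitometry
  of real images are out of scope, as is smear modeling beyond the
  `max_resolved` cutoff.
- The cap 0 mobility increment is a placeholder pending calibration.
- Mass mapping ignores isotope distributions, adducts, and charge states;
  it compares neutral theoretical masses only.
- RNase H-based strategies and dsRNA-specific nucleases are not modeled.
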