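# Methods

This note documents the models, conventions and design choices behind
`mtplex`, and what the synthetic test battery does and does not establish
about real data.

## The assay model

Each of the 26 assays is a PCR primer pair (L and H strand, products
56–90 bp) plus a single-base-extension probe annealing immediately 5' of
the interrogated SNP. The probe carries a 5' poly-CT tail; its nominal
electrophoretic size is

    frag_nt = 2 · n_ct_repeats + (1 if an extra C) + probe length

and the extended ddNTP is read as a dye colour (A green, C yellow, G blue,
T red — a panel constant that can be overridden). Probes annealing to the
L strand ("reverse" orientation) incorporate the complement of the
template base. Two invariants carry the whole decoding scheme and are
validated on load:

1. all 26 nominal sizes are multiples of 4 in [32, 80] and reproduce the
   published size column from the tail/probe arithmetic, and
2. the (size, dye) → (site, allele) map over all assays × both alleles is
   injective (52 distinct bins).

Allele orientation is taken from the site labels (e.g. G12007A: ancestral
G, derived A), which are rCRS-relative; the printed detection-order column
is not relied on. Concentrations are stored verbatim and only used by the
balancing simulator.

## Typing scheme and call semantics

The phylogeny is the panel-restricted tree: each non-structural node owns
exactly one panel SNP; N, C and D are structural nodes without a panel
site, retained for ancestor queries but never emitted as calls (the
deepest callable M-side node without sub-haplogroup support is "M").
Because the rCRS sits inside macro-haplogroup N and all site labels put
the non-American state first, the root state is "ancestral at every site"
and an all-ancestral profile is `unassigned`.

Given per-site states (ancestral / derived / missing / conflict), the
call is computed by walking the derived-site chain:

- derived nodes must form a single root-to-leaf chain; two incomparable
  derived branches → `conflict`, listing the maximal offenders;
- an observed-ancestral site above a derived one is also a `conflict`
  (internally inconsistent profile, e.g. contamination);
- full derived path → `unambiguous`; derived defining site with >=1
  unobserved path site above it → `tentative`, rendered with a "?"
  suffix ("D1?");
- no derived site but something observed → `unassigned`; nothing
  observed → `failed`.

Per-site `conflict` states (both allele peaks above the floor) are treated
as uninformative for the chain walk but are always reported, and demote an
otherwise-unambiguous call to tentative — a deliberately conservative
choice, since a heteroplasmy-like signal anywhere undermines a clean
single-source interpretation. A site derived at a terminal branch whose
intermediate path site is merely unobserved (e.g. 16265 derived, 11365
missing) is likewise reported tentative rather than conflicting.

The caller is verified against an independent exhaustive node-scoring
oracle over all 4^6 profiles of a six-site subtree, and against the
idealised full-path profile of every node.

## Virtual PCR

Primer placement uses the standard 3'-anchored fidelity assumption: the
3'-terminal 10 nt must match exactly, up to 2 mismatches (configurable)
are tolerated in the 5' remainder, and N counts as a mismatch. Amplicons
are 1-based closed intervals from the L primer's 5' terminus to the H
primer's 5' terminus, which reproduces the published product lengths. A
primer pair with several consistent placements raises an ambiguity error
(distinct from not-found). Probe annealing inside the amplicon is exact;
the interrogated base is the one 3'-adjacent to the probe on its strand.
Polymorphism-driven primer dropout beyond mismatch counting is not
modelled, and primer names are never used for placement — only sequence
search is.

## Electropherogram simulation and decoding

Detection of each assay is Bernoulli with a logistic probability in
log10(copies/µL): p = eff / (1 + exp(−slope · (log10 c − log10 c50))).
The defaults c50 = 2,000 copies/µL and slope = 4 per decade are simulation
choices, set so that ~28,000 copies/µL gives >0.95 per-assay detection (a
near-complete profile at a 1:100 dilution of a typical buccal-swab
extract) while each further tenfold dilution loses most of the remaining
loci; they are exposed in `DropoutModel` and are not fitted to any
instrument trace. Peak heights are lognormal with mean 3000 rfu (the
balancing target) and a configurable CV; conflict states emit both allele
peaks at half height; per-dye mobility offsets default to 0 nt.

Decoding discards peaks at or below the 50-rfu floor (strict inequality),
requires same-dye bins to be disjoint under the size tolerance (default
±1.5 nt, the largest tolerance compatible with 4-nt spacing), keeps the
higher of two same-bin peaks with a warning, and reports unbinnable peaks
as off-panel. Raising the floor can only remove observations, never create
them.

Concentration balancing implements the inverse-proportional rule: the
percentage difference of each observed peak from the 3000-rfu target maps
to `conc · target/observed` (clamped to [floor, cap]); a zero-height assay
is doubled instead. Under a linear concentration→height response this
converges to within 5% of target in a single round and is iterated at most
5 times in the tests.

## Synthetic reference and study simulator

No external reference is bundled. The 26 printed primer/probe sequences
overlap each other within each amplicon, which pins the probe (and hence
the SNP) position inside a window of exactly the printed product length;
where the probe touches neither primer, any in-gap placement is equivalent
for the simulator and the leftmost is used, preferring placements that
keep the SNP base out of primer footprints. Windows are anchored so each
SNP lands at its rCRS coordinate in a 16,569-base scaffold; neighbouring
windows that genuinely overlap (the 8875/8913 pair) are merged with
consistency checking. In-window filler derives from per-assay generators,
so the assay windows are byte-identical across scaffold seeds; only
inter-window filler depends on the user seed and is re-drawn (bounded
retries) if it creates a spurious primer site. Construction is verified:
all 26 amplicons are found uniquely with printed lengths and the scaffold
types all-ancestral.

The study simulator draws, per individual, a haplogroup from a frequency
vector and two replicate copy numbers from a per-period lognormal
(log10 mean per period as a preservation proxy), then simulates two
independent electropherograms. Defaults mirror the packaged case study:
20/20/12 individuals across three periods; haplogroup frequencies close to
the observed consensus spectrum (B2 0.40, C1b 0.25, A2 0.15, B2b 0.10,
D1 0.05, M 0.05); log10 copy means 3.6/3.3/4.0 (Middle Horizon poorest,
Late Intermediate best) with SD 0.5. These reproduce the qualitative
period ordering of success rates; they are not fitted to the published
counts.

What the synthetic battery does **not** model: ancient-DNA cytosine
deamination damage, contaminant mixtures, PCR stutter/pull-up artifacts,
size-standard regression, or NUMT co-amplification. Passing round-trip
tests therefore demonstrates internal consistency of the encode/decode
chain and calling logic, not robustness to those real-world artifacts.

## Packaged study fixture

`data/replicate_calls.tsv` transcribes a published replicate comparison of
the SNP panel (`snp26`) against HVR-I sequencing (`hvr1`) on 52 ancient
Peruvian individuals. "Reliable" means: both replicate calls present,
neither "?"-suffixed, and the labels equal or ancestor/descendant; the
consensus is the shallower label. This single rule set applied to both
methods' columns reproduces all six published per-period counts (11/8/10
and 7/0/7) and the 29-sample total. The fixture's printed consensus column
occasionally integrates HVR-I information (e.g. one individual printed
"C1" where the panel-only consensus is "M"); it is stored verbatim for
reference but never used in computation. HVR-I labels such as "B4"/"C1"
are not panel-tree nodes; concordance therefore compares equal labels
before any tree lookup, and unequal labels must both be tree nodes.

For the paired method comparison the pairing unit is the individual;
unlisted individuals (the fixture lists only those with at least one
reliable result) failed both methods and enter as ties. The primary test
is an exact two-sided sign test on discordant pairs; a Wilcoxon
signed-rank on the paired 0/1 outcomes (ties dropped) is reported
alongside, as on binary outcomes the two are nearly equivalent.

## Problem sizes and determinism

All simulations in the test suite are seeded and sized for quick, exact
reproduction: 1,000 replicates per point on a six-point dilution grid for
the sensitivity checks, 4^6 profiles for oracle equivalence, 10 seeds per
haplogroup for end-to-end recovery, and 60–200 individuals per simulated
study. Every stochastic entry point takes an explicit seed and refuses to
run without one.
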