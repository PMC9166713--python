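# Methods

This note records the models, conventions and design decisions behind
`lectiscope`, in the order the pipeline runs them.

## Glycan structures and the condensed dialect

A glycan is a rooted tree: nodes are monosaccharide residues (optionally
decorated with substituents such as `6S` sulfation), the root is the
reducing end, and each edge carries an anomeric configuration (`a`, `b`, or
`?` for unknown) plus the child and parent linkage carbons. The text dialect
is condensed linear notation — `Galb1-3GlcNAcb1-2Mana1-3Man`,
`Mana1-3(Mana1-6)Manb1-4GlcNAc-Sp12` — in which the rightmost residue is the
root, a parenthesized branch attaches to the residue to its right, and a
trailing `-SpN` spacer is stripped. The residue table is fixed and
longest-match tokenized; unknown residue codes, malformed linkages and
unbalanced parentheses are parse errors (silently skipping tokens would
corrupt motif statistics downstream).

**Canonical form.** Children of a node are ordered by (parent carbon, child
residue code, anomeric, child carbon, serialized subtree); the first child
prints inline as the backbone and the rest print in parentheses. Two
structures are equal iff their canonical serializations are equal, which
makes round-tripping, deduplication and ranking tie-breaks deterministic.

## Array processing

Replicate RFUs are background-subtracted and may be negative; they are kept
as-is for aggregation. Aggregation drops exactly one maximum and one minimum
occurrence (not all tied extremes — six replicates always leave four) and
averages the rest, which absorbs one bad spot per tail. Normalization clips
negatives to zero and divides by the maximum aggregated value, so the top
glycan binder scores exactly 1; a profile with no positive value has no
anchor and is an error. Binders are called at normalized score ≥ 0.1 by
default. No binding criterion is standard for these screens, so the
fraction-of-top threshold is an explicit, configurable package choice, kept
conservative and consistent with the top-binder normalization.

## Motif mining

A binding motif is a connected sub-glycan. `contains_motif` tests injective
subtree embedding preserving residue codes, substituents, parent/child
relations, anomeric configuration and both linkage carbons; the motif root
may map anywhere (unanchored). One permissive rule: an edge whose anomeric
configuration is *unknown in the data* (`?`) matches any motif
configuration, because array structure tables are often under-specified; a
motif written with `?` conversely only matches data recorded as unknown.

`mine_motifs` enumerates every connected sub-glycan of the binders up to a
size cap, scores each as `binder_coverage − nonbinder_frequency` (exact
fractions computed by embedding tests), and sorts by score desc, size desc,
canonical text asc. A motif is suppressed when a strict super-motif scores
at least as well, so each score tier reports only maximal determinants —
without this rule every sub-chain of a perfect motif would tie with it. The
contrast score is deliberately transparent: it is trivially re-derivable by
an exhaustive oracle, which the test suite exploits.

## Alignment identity

Identity comes from a global Needleman–Wunsch/Gotoh alignment (BLOSUM62;
first gap residue −11, each further residue −1) and is defined as
matches / all alignment columns, terminal gap columns included. This is the
single identity definition used everywhere; it gives identity 1 exactly for
identical sequences and never exceeds `min(len)/max(len)` — a bound also
used to skip hopeless pairs cheaply. Alignment statistics are symmetric by
construction (the pair is canonically ordered before the DP) and traceback
ties prefer a residue pairing over a gap in the first sequence over a gap in
the second, so repeated runs are bit-identical. The DP kernel is compiled
with numba; the traceback is plain Python.

Two boundary semantics coexist deliberately: clustering admits members at
identity **≥** the threshold, while catalog/reference matching requires
identity **strictly >** the threshold. Matching additionally requires ≥ 80%
of query residues to be paired with a reference residue (default), so short
high-identity fragments do not count as gene-level matches; the coverage
floor is configurable because different studies treat fragmentary hits
differently.

## Clustering

Greedy centroid clustering processes sequences by (length desc, accession
asc); the first sequence founds a cluster, and each subsequent sequence
joins the best-identity centroid at or above the threshold (ties to the
earliest-created centroid) or founds a new one. This mirrors the standard
greedy centroid algorithm used for sequence deduplication, without its
k-mer/SIMD acceleration heuristics — faithfulness and determinism are the
goals at the scales this package targets, not throughput on millions of
sequences.

## Candidate filtering

A candidate lectin must have ≥ 1 CBM domain, no catalytic domain, a clean
description and (by default) unreviewed status. Rules are evaluated in the
fixed order *no_cbm, catalytic, keyword, reviewed* and the first failure is
reported, which makes rejection reasons stable and testable. Domain
categories come only from an explicit domain table; the package never
infers "catalytic" from an identifier string. Keyword screening is
case-insensitive whole-token matching over alphanumeric tokens of the
description, so the short keyword `Fim` does not fire inside `fimbriae`
(which has its own entry); matching can be switched to case-sensitive,
since the original curation convention is not recorded anywhere
authoritative. The packaged CBM list is a minimal default (IPR033803,
IPR024361); real analyses should pass the full curated set.

Architectures are N→C tuples of domain ids ordered by (start, end, id),
keeping repeated copies and ignoring spacing. Co-occurrence counts each
(CBM, secondary) pair once per record regardless of copy number; CBM–CBM
pairs are not counted, matching the convention that secondary domains are
the non-CBM partners.

## Presence, prevalence, rarefaction

A lectin is present in a sample iff any catalog gene matches it under the
strict matching rule. Each sample is treated as one person (visit structure
is out of scope). The most-prevalent set for a site is the top
`ceil(fraction × richness)` lectins by within-site sample count, ties
broken by accession. Overlap statistics derive from per-lectin site sets;
exact Venn region counts are emitted for up to six sites (2^k − 1 regions),
beyond which only the pairwise table is kept.

Rarefaction is sample-based (incidence): with N site samples and lectin *i*
in Nᵢ of them, the expected richness of a random n-sample subset is
S(n) = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)], evaluated with exact integer binomials
through rational arithmetic, so S(N) equals observed richness and S(1) the
mean per-sample richness to machine precision. An optional seeded
resampling mode estimates standard deviations; the expectation itself is
always analytic.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical shape* of the real inputs — a
protein universe where each decoy violates exactly one filter rule,
families with controlled divergence, per-site Bernoulli presence of planted
lectin genes among random background genes, and glycan libraries where all
binders embed one planted motif and non-binders are verified motif-free.
Defaults mirror the study conditions the pipeline is meant to handle: five
body sites, 90% identity thresholds, six replicates per array spot, a
planted `Galb1-3GlcNAcb1-2Mana1-3Man` motif, 12 + 12 array glycans.

Sequence divergence conventions: `within_divergence` is the expected
*pairwise* divergence between family members, so each member carries
exactly `round(L·d/2)` substitutions from the ancestor (drawn without
replacement, no indels). Exact substitution counts keep identity guarantees
deterministic — at 5% divergence every member pair sits at ≥ 95% identity,
safely above a 90% threshold — which is what makes perfect family recovery
a meaningful invariant rather than a coin flip. An i.i.d.-per-site reading
at the full rate would put member-to-centroid identity right at the
threshold and make recovery intrinsically unstable.

Because backgrounds are i.i.d. uniform residues and planted copies are
exact (or exactly-counted mutants), passing tests demonstrate the
*bookkeeping* of the pipeline — filtering, clustering, matching, counting,
and the analytic formulas — not robustness to real evolutionary divergence,
horizontal transfer, annotation noise, chimeric assemblies or array
cross-reactivity. Absolute counts from any real survey depend on database
versions and are not reproduced here.

## Numerical and determinism notes

- All RNG flows through one `numpy` generator per dataset with a documented
  draw order; identical (config, seed) is byte-identical output.
- DP scores are integer-valued floats, so traceback equality tests are
  exact; no epsilon comparisons are needed.
- Reports are JSON with sorted keys; TSV/CSV writers use fixed line
  terminators and `repr` floats, so end-to-end runs diff clean.
- Problem sizes in the tests and the acceptance script (hundreds of
  records, tens of samples, ≤ 8-node glycans for exhaustive oracles) were
  chosen so every exhaustive cross-check stays exact and the whole
  verification runs in seconds on one CPU.

## Known limitations

- The alignment kernel is O(L²) per pair with no banding or k-mer
  prefilter beyond the length-ratio bound; clustering is quadratic in the
  number of clusters. Fine for thousands of sequences, not millions.
- The glycan dialect covers the condensed notation subset used for array
  tables (single-character anomeric, single-digit carbons, `xS`/`xP`
  substituents); repeat units and multi-digit carbons are not parsed.
- Motif scoring is a set-level contrast, not a statistical enrichment test;
  with few binders the top motif should be read as descriptive, not as a
  significance claim.
- The binder threshold and the coverage floor are conventions, exposed as
  parameters; conclusions sensitive to them should be checked across a
  range.
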