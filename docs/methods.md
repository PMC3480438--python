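# Methods

This note documents the models, parameter choices and numerical decisions
behind `tagdge`, in the order the pipeline runs.

## Tag model and reference library

A tag is the 21-nt sequence `CATG` + 17 downstream bases. The reference
library enumerates **all** CATG+17 sites on both strands of every transcript
(`build_tag_library`), while the simulator emits only the **3′-most sense**
site per transcript: the library-prep chemistry captures the 3′ cDNA
fragment on oligo(dT) beads, so only the last NlaIII site survives MmeI
digestion. Keeping the full enumeration in the library lets mapping tests
exercise multi-site genes and antisense hits.

Ambiguity is defined at the gene level: a tag occurring at several positions
or on both strands of one gene still identifies that gene ("1 tag → 1
gene"); occurrences in two or more distinct genes — including a sense hit in
one gene and an antisense hit in another — make the tag ambiguous and
exclude it from quantification. This is the conservative reading; only
unambiguous tags drive expression values.

Candidate sites whose 21-nt window contains a non-ACGT letter are skipped
and counted in the build report.

### Lookup

Exact hits always win: a tag with any perfect match never receives
one-mismatch hits (the match taxonomy PM/1MM × sense/antisense is mutually
exclusive). One-mismatch search substitutes over the 17-nt variable region
only — 51 variants per tag — with the `CATG` anchor held fixed, because the
anchor is an enzymatic recognition site present by construction in both the
tag and the reference; letting it mismatch would admit tags that the enzyme
could not have produced. A consequence used by the tests: lookup is exactly
equivalent to an exhaustive anchored-Hamming-distance scan.

## QC filter

Order is fixed: (1) 3′-adapter trim, (2) empty/adapter-only removal, (3)
N removal, (4) singleton removal, (5) length-21 + CATG-prefix check.
Adapter trimming is exact suffix–prefix matching (minimum overlap 5, no
mismatches): the trim point is the leftmost position where the remainder of
the read matches a prefix of the adapter, allowing the adapter itself to be
truncated by the read end. The singleton filter operates on copy numbers
counted **after** steps 1–3; tags removed there are booked as singletons
even if they are also mis-sized, so the four discard categories partition
the discarded reads exactly and raw = clean + Σ discards always holds.

Copy-number histograms default to bins [2,5], [6,10], [11,20], [21,50],
[51,100], >100 (configurable), reporting both total-copy and distinct-tag
shares. The saturation curve subsamples clean tags without replacement on an
even 20-point depth grid using a single permutation, so it is monotone by
construction and deterministic under its seed; a gene counts as detected
when one tag mapping unambiguously to it has been drawn.

## Quantification

Per-gene expression accumulates the **copy numbers** of the gene's
unambiguous tags (distinct-tag counts are reported alongside but do not
drive TPM). TPM = count × 10⁶ / **total clean tags** of the library — the
denominator is deliberately not the mapped total, matching the "per million
clean tags" definition. Antisense unambiguous hits count toward expression;
a per-strand breakdown is kept so a sense-only vector can be derived.

## Audic–Claverie test

`p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1))` is evaluated in log
space via `gammaln`. The two-sided p-value is `min(1, 2·min(P(Y≤y|x),
P(Y≥y|x)))` — the doubled-smaller-tail convention, chosen because the
alternative (summing all outcomes with probability ≤ the observed one) is
less standard for this statistic; the construction is isolated in one
function so the convention can be swapped.

Numerics: the lower tail is a compensated (`math.fsum`) summation of
exponentiated log-pmf terms. The upper tail uses `1 − Σ_{k<y}` only while
well conditioned; because `gammaln` leaves ~1e-13 absolute error in the
complement, upper tails below 1e-2 are instead summed forward from `y`
directly — the term ratio tends to `(N2/N1)/(1+N2/N1) < 1`, so the series
converges geometrically and the sum is accurate relative to itself. The
same complement-vs-direct switch is used for the hypergeometric upper tail.
Both statistics agree with independent oracles (negative-binomial tails and
`hypergeom.sf`) to 10 significant digits in the tests.

The two-sided p is **not** exactly invariant under swapping `(x, N1)` with
`(y, N2)`: at a tail boundary one direction sums a single point mass where
the other sums a geometric tail, so the two p-values can differ by up to a
factor `1 + max(N1/N2, N2/N1)` (2 at equal sizes). The property suite
asserts this bound rather than exact symmetry.

DE thresholds: BH-FDR < 0.001 and |log₂(TPM2/TPM1)| ≥ 1, with TPM 0
replaced by 0.01 in the ratio only (the boundary is implemented as ≥ 1;
both it and the FDR cut are parameters). The BH family is the set of genes
with ≥ 1 unambiguous tag in either library; genes absent from both are
untestable and excluded. With one library per condition the test has no
replicate-level dispersion; p-values are exact under the equal-expression
null but biological variability is not modelled.

## Enrichment

`P(X ≥ m)` for X hypergeometric(N, M, n), with N = genes carrying ≥ 1
annotation in the given map (configurable override), q-values by BH across
the term family. Significance conventions: GO-style flags raw p < 0.05,
pathway-style flags q < 0.05 — both thresholds are exposed rather than
harmonised, since the two conventions coexist in practice. Term hierarchies
are not traversed; the annotation is taken as given.

## Synthetic-data generator

The generator emulates the statistical structure of a two-condition DGE
experiment. Defaults (the study conditions used by the acceptance script
and the recovery tests):

| parameter | default | rationale |
|---|---|---|
| n_genes | 1000 | enough genes for a meaningful BH family at desk scale |
| mean_length / sigma | 676 bp, lognormal σ=0.5, floor 100 | typical assembled-transcript length distribution |
| catg_fraction | 0.95 | a small minority of real transcripts lack a usable NlaIII site |
| depth | 5×10⁵ tags/library | desk-scale stand-in for multi-million-tag libraries |
| base_error_rate | 5×10⁻⁴/nt | ~1% of 21-nt tags carry an error, consistent with the observed singleton load |
| adapter_only / N-read / singleton-noise rates | 0.004 / 0.004 / 0.003 | tuned so clean/raw ≈ 98.4%, the proportion the QC stage should reproduce |
| DE truth | 50 genes at &#124;log₂FC&#124; = 3, baseline abundance ≥ 2×10⁻⁴ | planted effects sit on measurably expressed genes (mean TPM ≥ ~200) |

Abundances are lognormal (σ = 1) and normalised per condition; condition B
multiplies DE genes' abundance by 2^log2fc and renormalises (the
renormalisation perturbs non-DE genes' effective fold changes by a few
percent — negligible at 50/1000 DE genes). By default only transcripts with
a usable sense tag site receive abundance mass; if a truth table does give
mass to a siteless gene, the simulator reassigns it with a warning.

Reads are partitioned into biological / adapter-only / N-containing /
singleton-noise categories by a single multinomial draw, so the configured
depth is split exactly and every read carries a truth label. Singleton
noise tags are random distinct CATG+17-mers emitted exactly once, built to
exercise the copy-number filter. Quality strings are constant `I` (Q40):
tag QC in this pipeline is sequence-based, not quality-based. The adapter
is an arbitrary fixed 28-nt constant (configurable).

What the simulation does **not** model — and therefore what passing tests
do not establish about real data: PCR duplication bias, position- or
quality-dependent error profiles, incomplete reference transcriptomes (the
dominant source of real "unknown" tags), assembly chimeras, and biological
replicate variability. Recovery results (sensitivity ≥ 0.9, empirical FDR
≤ 0.05 at the default conditions) characterise the pipeline's statistical
machinery under its own model, not performance on any particular organism.

## Problem sizes

The test suite and acceptance script run the full pipeline at 1000 genes ×
5×10⁵ tags × 20 seeds (≈ 1 minute), type-I calibration on 20 equal-abundance
nulls of 1000 genes, and enrichment power/null studies of 100/200
replicates. These sizes give binomial standard errors comfortably inside
the asserted bounds while staying desk-scale.
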