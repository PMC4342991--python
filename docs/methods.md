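# Methods

## Motif scan

The scanner is a multi-pattern exact matcher over a precomputed
neighborhood: every ACGT word within Hamming distance `max_mismatches`
(default 1) of the consensus (default `GCAACAATGTTGC`) is placed in a hash
set, and each length-13 window of the genome is tested for membership.
The neighborhood size is Σ_{i≤d} C(k,i)·3^i; at k = 13, d = 1 that is 40
words (the consensus plus 39 single-base alternatives), so memory is
trivial and scan time is linear in genome length regardless of d.

Choices that matter:

- **Forward-strand scanning is the default.** The consensus is a
  pseudo-palindrome (one mismatch from its own reverse complement), so at
  d = 1 a forward-only scan still reports every exact minus-strand
  occurrence, as a 1-mismatch forward hit. A `scan_both_strands` mode is
  provided; a window matching on both strands then yields two hits.
- **Soft-masked (lowercase) sequence is uppercased before matching**; no
  masking rule is applied.
- **Non-ACGT characters disqualify a window** rather than acting as
  wildcards — the 3-alternatives-per-position arithmetic presumes a strict
  four-letter alphabet. `N` in the reverse-complement table exists only so
  ambiguous bases round-trip.
- **Overlapping and nested hits are all reported; nothing is merged.**
- Coordinates are 0-based half-open internally and in BED output;
  conversion to/from 1-based inclusive happens only at the GFF3 boundary.

## Gene assignment

A hit is *intragenic* for every gene whose interval it overlaps, and
otherwise associates with every gene whose closest end is within
`window_bp` (default 10 000 bp, boundary inclusive) of the hit. The window
anchors on the hit and gene *intervals* (closest-end gap), not on the TSS
or ORF start. Upstream/downstream labels follow the gene's strand (5′ side
= upstream); the hit's strand is ignored for labeling, and a hit exactly
adjacent to a gene (gap 0 without overlap) keeps its flanking label with
distance 0. All qualifying genes are reported, not only the nearest. The
default window of 10 kb is the sensible reading of the flanking distance
used in this analysis style; it is configurable for other readings.

## Differential expression

Raw probe intensities are floored at 1.0 and log2-transformed, then
quantile-normalized at probe level (normalize-then-summarize; the
alternative order is a judgment call with no stated convention in the
literature this emulates). Quantile normalization sorts each column, takes
the row-wise mean of the sorted columns as the reference distribution, and
reassigns by rank; ties within a column receive the mean of the reference
values at the tied ranks, which makes the transform idempotent and every
column's value multiset identical.

Probe-level values are summarized to one row per gene by the **median**
across the gene's probes (robust to a single aberrant probe among the 3–9
measurements per gene); mean is available.

Per gene, a two-sided two-sample **Student's pooled-variance t-test**
compares male vs female summarized values (Welch optional). The fold
change is `log2_fc = mean(male) − mean(female)`, i.e. log2(male/female).
When both groups have zero variance the test degenerates; the convention
is p = 1 for equal means and p = 0 otherwise. Raw p-values are adjusted by
**Bonferroni** (`min(1, p·m)`) by default — the conservative family-wise
reading — with Benjamini–Hochberg as the FDR alternative. A gene is a DET
when adjusted p < `alpha` (0.05); it is `male_strong`/`female_strong` when
additionally log2_fc exceeds ±`strong_lfc` (2.0), thresholds mirroring a
conventional volcano-plot classification. `-log10(p_adj)` of an exact
zero is rendered as the cap 320 in volcano tables.

Repeat hybridizations are included **as ordinary samples** by default (the
emulated design assessed six arrays per sex); `average_into_parent`
collapses each repeat into its parent column before testing, since the
original treatment of repeats is not documented.

## Synthetic data

All generators are pure functions of (config, seed); the single seed feeds
a named, CRC-keyed sub-stream per stage, so stages are independently
reproducible.

**Genome.** Background bases are i.i.d. with configurable GC content
(default 0.45, a typical AT-rich insect genome). Planted words are
constructed at exactly the requested Hamming distance from the consensus
and written at non-overlapping positions (minimum gap configurable;
spacing them widely also leaves room for a containing gene per site).
After planting, the background is *scrubbed*: every window within the
mismatch budget of the consensus on either strand that is not a planted
site has its non-protected bases re-sampled, iterating until none remain.
An accidental 13-mer match is a ~6 × 10⁻⁷ event per window, so this
converges almost immediately; its value is that the recorded truth is
provably exhaustive and scanner recall/precision are exact quantities.

**Annotation.** Non-overlapping stranded gene intervals (defaults
300–2000 bp) placed by rejection sampling; a sizing error is raised when
the request cannot fit. `contain_intervals` forces the first genes to
contain given intervals (used to make planted sites intragenic).

**Expression.** Raw-scale intensity is `2^(mu_g + a_p + b_g·x_j + e)`:
gene baseline `mu_g ~ N(8, 2)` (log2 units, a typical array intensity
range), probe offset `a_p ~ N(0, 0.25)` shared by a probe's three
technical replicates, male indicator `x_j`, and fresh noise
`e ~ N(0, 0.5)` per measurement. Each gene carries 1–3 probes, each
synthesized in triplicate (3–9 measurements per gene per sample). Each sex
has 4 unique samples and 2 repeat hybridizations; repeats share the
systematic signal and draw fresh noise, the closest defensible model of
re-hybridizing the same RNA (whether the original repeats reused labeled
cRNA is unknown; parents are assigned cyclically as metadata). Exactly
`round_half_up(n_genes · de_fraction)` genes carry an effect `b_g =
±effect_size` (default 2.5 log2 units), signs balanced with the extra one
male-up. Intensities are strictly positive by construction; no censoring
or spatial artifacts are simulated.

What the generator does **not** emulate: sequence composition realism
(repeats, isochores), probe thermodynamics and cross-hybridization, array
spatial effects, and intensity-dependent variance. Passing tests therefore
demonstrate the pipeline's correctness and calibration under its stated
model, not performance on any real array.

## Statistical behavior worth knowing

Quantile normalization under strong planted signal slightly compresses
extreme fold changes (planted |log2FC| of 2.5 is estimated around 2.3) and
can push a handful of null genes past Bonferroni significance through
rank-shift leakage — with small fold changes, so they do not enter the
strong classes. This is a real property of the emulated pipeline, visible
in the end-to-end counts, not a bug. Null calibration is verified
separately: across 200 no-effect studies the family-wise error of the
Bonferroni stage stays within the binomial bound of its nominal 5%.

## Integration

DET/motif-gene overlap is a plain set intersection with deterministic
(sorted) reporting. Over-representation uses the exact upper-tail
hypergeometric probability with BH adjustment across categories; the
default universe is the expression platform's gene set. This is labeled a
generic statistic — it does not replicate any annotation service's
EASE-style modified Fisher test, so externally published enrichment
p-values are out of reproduction scope.

## Problem sizes

The shipped end-to-end study uses four 500 kb scaffolds, 44 planted sites
(20 exact, 20 at one mismatch, 4 exact on the minus strand), 500 genes and
a 10 kb window — large enough that the motif-proximate set (~230 genes) is
a proper subset of the platform and the overlap statistic is non-trivial,
while a full run stays around a second. Calibration checks use 200
simulated null studies of 500 genes; scanner equivalence checks use
twenty 50 kb random sequences and twenty simulated genomes.
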