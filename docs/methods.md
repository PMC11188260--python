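# Methods

`nmdkit` annotates alternative-splicing events coupled to nonsense-mediated
decay (AS-NMD) in custom transcriptomes and prioritizes them with
splicing–expression statistics, conservation scoring and a kinetic model of
gene downregulation. This note describes the models, conventions and design
choices, and what the synthetic fixtures do and do not establish.

## Coordinates and the transcript model

All internal coordinates are 0-based half-open; GTF I/O converts to and
from the 1-based closed convention at the boundary, and exported event
tables print 1-based closed coordinates for consistency with GTF. A
transcript is a sorted, disjoint exon chain on one chromosome and strand
with an optional CDS contained in exonic space; the CDS convention
*includes* the termination codon (``stop_codon`` GTF features are merged
into the CDS on read; when an input annotates a CDS without stop-codon
rows, the annotated CDS 3' end is taken as the stop end). Transcripts with
undefined strand are rejected: donor/acceptor semantics and the NMD rule
are meaningless without one. Overlapping exons within one transcript —
occasionally produced by assemblers — are merged with a warning.

## Gene allocation

Novel transcripts that duplicate a reference isoform are removed by
intron-chain identity (ordered intron coordinates on the same strand;
terminal exon boundaries are ignored, matching the assembler "=" class).
Single-exon transcripts carry no chain and are removed only on exact exon
equality — the conservative analogue. Survivors are assigned to the
same-strand reference gene with the largest exonic-base overlap (antisense
overlap never assigns); ties break lexicographically on gene id, and
transcripts without any overlap found a new gene whose id is a stable hash
of the transcript span, so reruns agree.

## ORF construction and the 50-nt rule

Coding sequences for unannotated isoforms are built by projecting annotated
start codons of the same gene onto the isoform: all three bases of a
reference start must be exonic and read contiguously (possibly across a
shared junction); the 5'-most projectable start wins, and translation
proceeds in frame through the spliced sequence to the first stop codon.
There is no de-novo ORF search by default — invented ORFs on assembled
transcripts inflate false NMD calls — but a fallback (5'-most ATG, minimum
100 codons) is available behind a flag. Two reference starts cannot project
to the same transcript offset in different frames (the offset fixes the
frame), so no tie-break is needed there.

A transcript is NMD-sensitive when it has at least two exons and its stop
codon lies more than `threshold` (default 50, strict `>`) spliced
nucleotides upstream of the last exon–exon junction. The distance is
anchored at the base immediately after the stop codon by default; because
the anchoring edge is a convention rather than a biological fact, a
`stop_start` anchor is exposed as an option (it shifts the measured
distance by 3 nt). Verdicts are blind to any input biotype label.

## Event calculus

Isoform pairs of one gene are diffed into four patterns, defined in
transcription direction:

* **CE** — an intron of one isoform spans exactly one exon of the other
  with both flanking introns shared;
* **RI** — an intron of one isoform lies strictly inside a single exon of
  the other whose boundaries match the two flanking exons;
* **AD/AA** — two introns share one boundary while the exons on the shared
  side also share their outer boundary; which genomic side is shared,
  combined with the strand, decides donor vs acceptor. The event interval
  is the extension segment, anchored on the distal (event-defining) splice
  site.

Multi-exon skips, mutually exclusive exons and novel junctions at
transcript ends are reported as `complex` and skipped; alternative TSS/TES
differences without novel junctions produce no events. Inclusion of an
event co-occurring with an NMD-positive verdict across all informative
isoform pairs labels it NS (NMD-stimulating); the reverse labels NR;
disagreement across isoform backgrounds is an explicit `ambiguous`
category. By default only pairs differing by exactly one event contribute
to the label (confounded attribution is avoided); a permissive mode exists
for exploratory use. The catalog deduplicates by (type, coordinates,
strand) and pools supporting pairs.

## Statistics

PSI values are fractions throughout. The variance-stabilizing transform is
`VST_PSI = 2·arcsin(√PSI)/π`, which keeps the transformed scale in [0, 1]
with fixed points at 0, ½ and 1. The splicing–expression statistic is the
Pearson product-moment correlation of variance-stabilized expression with
`VST_PSI` for NR events and `1 − VST_PSI` for NS events, so a positive r
always reads "the NMD-protective pattern tracks expression"; events with
r > 0, p < 0.05 and BH FDR < 0.1 are flagged *facilitating*. FDR is
computed within event-type strata (NS-CE, NR-CE, other) by default, with a
global option. The minimum series length is 3 matched timepoints; n < 5 is
flagged low-power. p-values come from the two-sided t reference
distribution; the tests cross-check them against exhaustive permutation
enumeration at n = 5.

Responsiveness shortlisting keeps NS events with ΔPSI > 0.1 and
probability > 0.9, NR events with ΔPSI < −0.1 and probability > 0.9, plus
the near-constitutive retention rule (NS with mean PSI > 0.9, NR with mean
PSI < 0.1), all configurable; a stringent preset uses |ΔPSI| > 0.25 and
probability > 0.95. Kendall trends use tau-b with exact two-sided p-values
by enumeration for n ≤ 8 without ties and a tie-corrected normal
approximation otherwise (sidedness for tau is a package choice: two-sided);
monotone classification uses |τ| > 0.75 with p < 0.05. Enrichment uses the
one-sided (greater) Fisher exact test; a zero margin yields p = 1 with
undefined odds. Regulator-dependence (the PTBP1-style workflow) requires a
significant knockdown response — annotated from the highest-priority
significant contrast, single-KD before double-KD, then ESC before NPC — a
significant time-course correlation with regulator expression, and
opposite signs of r and knockdown ΔPSI.

Gene expression is accepted pre-transformed; the built-in substitute,
log2(1 + median-of-ratios-normalized counts), is a deliberately simple
approximation to a model-based variance-stabilizing transform and is
labelled as such.

## Conservation

Each event type scores a fixed intronic context: `padding` (default 100) nt
on both sides of a CE, the first and last `padding` nt of an RI, 2×padding
nt downstream of an AD's distal donor and 2×padding nt upstream of an AA's
distal acceptor, directions in transcription orientation. Whether the
proximal or distal splice site anchors AD/AA windows is a genuine
convention choice; the distal (event-defining) site is used. Windows are
truncated at chromosome ends or user-supplied intron bounds with a flag;
short retained introns are split without double counting. Track bases
without coverage are excluded from the mean and counted separately —
PhastCons gaps mark unalignable sequence, and imputing zeros would bias
comparisons — but a `missing_as_zero` mode exists for parity experiments.
bigWig input is supported via pyBigWig; a bedGraph text dialect serves
plain-text workflows and tests.

## Downregulation model

Productive mRNA abundance follows

    dR/dt = r_t(t)·r_n(t)·v_sr − k_dr·R(t),   k_dr = ln 2 / t_half,

with synthesis rate `v_sr` (molecules·cell⁻¹·h⁻¹), transcriptional
repression factor `r_t` and AS-NMD repression factor `r_n`, both
piecewise-constant in [0, 1]. NMD-sensitive isoforms are assumed
short-lived and excluded from R — there is no second compartment. Two
parameter presets ship: the transcriptome-median preset (v_sr = 1.76,
t_half = 7.08 h) and a gene-averaged preset (v_sr = 2.63, t_half = 5.11 h).
Default repression depths are r_t: 1 → 0.39 (estimated as the mean
late/early expression ratio) and r_n: 0.78 → 0.12 (from
r_n = 1 − PSI/100 of NMD-blocked inclusion measurements). Four scenarios
place the AS-NMD step relative to the transcriptional one (sole mechanism,
preceding, coincident, following), by default one day apart inside the
day 2–4 window; the exact breakpoints are user-settable since only the
±1-day offset between mechanisms is constrained.

The integrator is adaptive Runge–Kutta restarted at every schedule
breakpoint, so discontinuities never cross a solver step; the exact
piecewise-exponential solution
`R(t) = R* + (R(t_i) − R*)·e^{−k_dr (t−t_i)}` is implemented independently
and serves as the test oracle (agreement to 1e−6 relative error on random
schedules). The *dichotomy point* of a mutant/WT expression ratio series is
the timepoint immediately preceding the first exceedance of a threshold
(supplied, or the median of all pooled values) by the clone-averaged
series; a series that never exceeds, or exceeds already at the first point,
has none.

## Synthetic fixtures

The generators are pure functions of (plan, seed) and define the study
conditions for every test. Each toy gene is a five-exon locus (~2.2 kb,
GC 0.5 random background) whose productive isoform carries an annotated
CDS terminating in the last exon; the alternative isoform realizes one
planted event kind (NS-CE with a 37-nt poison exon, NR-CE whose skipping
frameshifts into a stop, NS-AD/NS-AA extensions, NS-RI, or a
frame-preserving neutral cassette). Coding sequence is assembled from
non-stop codons with stop codons written explicitly at in-frame positions,
and every gene is re-verified against the 50-nt rule with a ≥ 10-nt margin
before emission (re-randomized otherwise), so ground-truth labels hold by
construction rather than by chance.

Quantification tables emulate Whippet-style output: responsive events get a
ΔPSI of the planted magnitude (default 0.3) at probability ≈ 0.99 — the
probability column is a confidence stand-in, not a re-derivation of a
posterior — with observation noise applied on the VST scale (default
sd 0.02) and back-transformed. Expression series are constructed so the
in-sample Pearson correlation between the observed NMD-protective pattern
and expression equals the planted ρ exactly (orthogonalized-noise
construction). This choice makes "planted ρ" mean the realized, not the
population, correlation: recovery tests then check the statistic's
orientation and transform chain rather than sampling noise, and the
zero-noise ρ = 1 case yields r = 1 identically. Conservation tracks plant
value 0.9 over the flank windows of labelled events on a 0.1 background,
with optional coverage gaps.

What passing fixture tests do *not* show: the toy genes have idealized
geometry (uniform intron lengths, two isoforms per gene, no overlapping
genes, no splice-site sequence realism), PSI confidence values are not real
posteriors, and expression noise is Gaussian on the VST scale. Performance
on real assembled transcriptomes — fragmentary isoforms, dense loci,
biased quantification — is bounded separately by the reference-annotation
benchmark (`nmdkit.benchmark`), which requires the user to supply a GENCODE
GTF.

## Numerical choices and degenerate inputs

Zero-variance series yield an undefined r reported as non-significant with
a reason, never an exception; all-tied trend series report τ = 0, p = 1;
empty Fisher margins report p = 1 with undefined odds. VST endpoint
symmetry holds to ~1e−7 in double precision (the arcsine–square-root has
unbounded derivative at 0 and 1). Scale choices in the test-suite and
acceptance script — 500 two-isoform genes (1000 transcripts) for the
NMD-rule check, 24 genes for event-calculus round trips, 1000 replicates
per planted ρ, 100 random schedules for the integrator — are the package's
own verification sizes and run in seconds.

## Known limitations

uORF-triggered and long-3'UTR NMD are out of scope, as are EJC-deposition
models, selenocysteine/readthrough and non-ATG starts. The event calculus
does not decompose mutually exclusive exons or microexon special cases.
PSI estimation, transcript quantification and differential-expression
fitting are upstream of this package and consumed as tables. Abundance
filtering of assembled isoforms (e.g. minimum isoform fraction) is likewise
upstream and not replicated.
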