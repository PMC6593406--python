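# Methods

## Screening model

The screen asks, per target enzyme panel, whether raw reads from a
metagenome recruit to that enzyme at a coverage compatible with the gene
being present in the focal genome. Its two quantitative ingredients:

**FPKM with a panel-level reference length.** Reads are unassembled, so
there is no per-gene feature length; instead the nucleotide reference
length of a panel is `L = 3 × mean amino-acid length` of its members and
`FPKM = n_reads / (L/1000) / (total_reads/10⁶)`. `n_reads` counts distinct
reads whose *best* surviving hit lies in the panel (a read is never counted
twice). For the read-screening stage the denominator is the total number of
read records in the library — raw-read screening has no "mapped" universe;
for transcriptome features the denominator is reads mapped to the assembly,
and both denominators are explicit parameters. Paired mates are screened
and counted as independent records.

**Reference normalisation and the two-step absence rule.** Target FPKM is
divided by the median FPKM of the reference panels (each reference enzyme
is its own single-member panel, so the median is taken across enzymes;
even-length medians average the middle two). A ratio ≤ 1/50 (configurable)
calls the gene absent. Otherwise candidate reads are re-mapped to the
binned assembly: a majority mapping outside the focal bin attributes the
signal to co-occurring organisms and still supports absence from the focal
genome; a majority inside calls it present; with no assembly available the
result is ambiguous. A zero reference median is treated as an error — if
the expected-present enzymes are undetected the library cannot support any
absence claim.

## Built-in translated search

The engine emulates a blastx-style screen at desk scale: six-frame
translation (standard code; codons containing N → X; stops → `*`),
Smith–Waterman local alignment under BLOSUM62 with affine gap cost
`11 + k` for a gap of length k, via `Bio.Align.PairwiseAligner`. An exact
amino-acid k-mer prefilter (default k = 5) between translated frames and
panel members selects candidate pairs; this loses nothing at the default
reporting floor, which requires far more than five consecutive
near-identical residues.

*Score floor.* The default reporting floor is raw score 100 (≈ a 19–20
residue exact match, i.e. more than half of a 100-bp read aligned in one
frame). Under the Karlin–Altschul model with gapped BLOSUM62(11,1)
parameters (λ = 0.267, K = 0.041) the expected number of chance alignments
at this score is ≪ 1 per 10⁶ random 100-bp reads against a
kilobase-scale panel, so the screen stays specific, while any read
genuinely covering a panel protein by ≥ 60 bp clears the floor easily.
Because target and reference genes pass through the same floor, the
relative-coverage ratio is unaffected.

*E-values.* Reported E-values are a documented proxy:
`E = m·n·2^(−bits)`, `bits = (λS − ln K)/ln 2`, with search space `m·n` =
(query length / 3) × total panel residues. Exact E-values of external
aligners are version-dependent; the printed thresholds (E < 10⁻⁵, identity
> 30%, subject coverage > 70%, all strict) are applied to whichever hits —
built-in or parsed from external 12-column tabular output — enter
`filter_best_hits`. For the read screen the subject-coverage threshold
defaults to 0 (a 100-bp read covers only ~⅒ of a typical protein); the
70% threshold is used where whole proteins are compared, as in the
transporter census. Score ties break to the lexicographically smallest
subject id, making filtering order-independent.

## Bin attribution

Candidate reads are aligned to every contig on both strands with edlib
(infix mode: the whole read must align, so read coverage is 100% by
construction) and accepted at identity ≥ 0.97, taking the minimum-edit-
distance contig with ties to the smallest contig id. Unbinned contigs
count as outside the focal bin — they are positive evidence that the
signal is not in the focal genome — while unmapped reads carry no bin
evidence and are excluded from the attributed fraction's denominator
(`outside / (inside + outside)`).

## Transporter census

Protein-vs-transporter-database hits are filtered with the same strict
best-hit thresholds and restricted to a shortlist of uptake-related TC
families/subfamilies (user-supplied; a small built-in demo shortlist covers
ABC 3.A.1, TRAP-T 2.A.56, SSS 2.A.21, CNT 2.A.41, DAACS 2.A.23, NSS
2.A.22). Counts are tabulated per genome twice: all kept ORFs, and only
ORFs with predicted transmembrane segments. The built-in TM predictor is a
sliding-window Kyte–Doolittle hydropathy scan (window 19, mean > 1.6,
overlapping windows merged) — a deliberate, documented approximation of
HMM-based topology predictors that suffices to separate soluble subunits
(e.g. ABC ATPases) from membrane components; a precomputed TM table takes
precedence when supplied.

Genomes are ordinated by nonmetric MDS on Bray–Curtis dissimilarities
(`d = Σ|u−v| / Σ(u+v)`; a pair of all-zero rows is defined as distance 0
with a warning). NMDS minimises Kruskal stress-1 by SMACOF with monotone
regression (scikit-learn), best of `restarts` random starts (default 2000,
interpreted as restarts rather than iterations) drawn from a seeded
stream — deterministic given the seed, with stress non-increasing in the
number of restarts. Coordinates are centered; convergence tolerance is
1e-8 so that exactly embeddable configurations reach near-zero stress.

## Pan/core accumulation

Ortholog clusters are input (singletons tracked but never in the curves).
Core = clusters in every genome of a subset; pan = clusters in any.
Accumulation curves resample genome orders **with replacement** (default
200 draws); a genome drawn twice adds nothing, since core and pan over a
multiset equal those over its support. Uncertainty is reported as the
2.5/97.5 percentile envelope across draws; per-draw curves are exposed so
monotonicity (core non-increasing, pan non-decreasing) is checkable on
every draw.

## Synthetic communities and what they show

The generator emulates the screen's study design: a focal genome dominating
a single-host metagenome, low-abundance contaminants, reference genes
single-copy in the focal genome at genome coverage, and target genes
absent / focal / contaminant-only. Sequences are i.i.d. nucleotides at a
target GC; implants are back-translations of panel peptides with
uniform-random synonymous codons (100% peptide identity to the panel,
realistic <100% nucleotide identity between copies); reads start uniformly
along genomes chosen ∝ abundance × length, with i.i.d. substitution errors
(no indels — frame-preserving by design, since the engine's alignment is
indel-capable but the error model need not be) and equiprobable strands.

Default scenario conditions: three 50-kb genomes; abundances 80/10/10
(absence and presence scenarios) or 85/5/10 with the target in the 5%
contaminant; 100-bp single reads; error rate 0; 2×10⁵ reads for the
full-depth scenarios and 2×10⁴ (≈ 30× focal depth) for presence recovery.
Panels are uniform-random 300-aa peptides, all the same length so that
target and reference read recruitment have identical edge effects and the
expected relative coverage of a single-copy focal target is exactly 1.

What passing these scenarios does *not* show about real data: no GC- or
position-dependent coverage bias, no quality-score-correlated errors or
indels, no homologous gene families at intermediate identity (e.g.
RuBisCO-like proteins that recruit reads legitimately), perfectly binned
single-contig assemblies. The scenarios validate the *logic* — counting,
normalisation, thresholds, attribution — not the sensitivity of any
particular external aligner on diverged homologs.

## Numerical choices and degenerate inputs

- Median: order-statistic exact, even counts averaged (numpy).
- Percentiles: mid-rank percent rank, `100·(rank−1)/(n−1)` with average
  ranks for ties; max → 100, min → 0, all-tied → 50; needs ≥ 2 features.
- Bray–Curtis on two all-zero rows → 0 with a warning.
- Attribution with zero mapped candidates → fraction `None`, and the
  absence call falls back to coverage alone.
- Ambiguous residues (B, Z, J, U, O) in panels → X with a warning; `*` and
  gap characters stripped with a warning.
- Empty FASTA panels, duplicate sequence ids, panel sets without a
  reference panel: hard errors surfaced by `validate_panels`.

## Problem sizes in the test suite

The acceptance-style tests exercise the full stated conditions (2×10⁵
reads × 10 replicate communities for specificity and attribution). The
alignment engine is verified against an independent Gotoh dynamic program
exhaustively on all length-≤3 pairs over a 4-letter reduced alphabet and on
seeded random samples (3000 pairs of length ≤ 6; 500 BLOSUM62 pairs of
length ≤ 40), a coverage chosen to keep the oracle — deliberately written
as slow, explicit Python — within an ordinary test run.
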