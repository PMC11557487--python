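# Methods

## Study system

*srh1* is an EMS-induced, semi-dominant short-root-hair mutant of hexaploid
wheat. An F2 population of 266 plants segregated 62 short : 141
intermediate : 63 normal, fitting the 1:2:1 ratio of a single semi-dominant
locus (chi-square 0.97, df 2, p 0.62). The locus was mapped by bulked
segregant analysis of exome-captured BC1F3 bulks (63 mutant-phenotype, 55
wild-type-phenotype plants) to chromosome 3A, with a wider interval at
584–647 Mb and a peak interval at 595–617 Mb.

## Per-site statistics

At each biallelic SNP the bulk allele frequency is

    BAF = alternate-allele reads / total reads          (per bulk)

and the bulk frequency ratio is the signed difference

    BFR = BAF_mut − BAF_wt ∈ [−1, 1].

Sites are used only if both bulks are genotyped, the variant is a SNP (no
indels), and each bulk's depth lies in [5, 200]. BAF is undefined at zero
depth and the code raises rather than imputing.

## Window scan and interval calling

Windows of 27.5 Mb are placed at starts 0, 1.5 Mb, 3.0 Mb, … per
chromosome (jumping, overlapping ~18-fold), clipped at the chromosome end.
A 1-based position `pos` belongs to the 0-based half-open window
`(start, end]` iff `start < pos ≤ end`. A window's value is the mean BFR of
its members; windows with fewer than 5 variants are reported but not called.
Runs of consecutive called windows with value ≥ threshold are merged into
one interval per run; thresholds 0.35 (wider interval) and 0.5 (peak
interval). The peak position is the midpoint of the best window in the run,
best by (value, then lowest start coordinate).

All interval objects are 0-based half-open (BED convention); VCF positions
and the exon table are 1-based inclusive.

## Candidate cascade

Variants inside the peak interval pass, in order:

1. quality/depth: discard if QUAL ≤ 50 or combined (both-bulk) depth ≤ 20;
2. exome membership (1-based inclusive exon coordinates; a variant in two
   genes yields one row per gene);
3. expression in root tissue strictly > 0.5 (genes absent from the
   expression table count as unexpressed and are logged);
4. non-synonymous consequence (missense, stop gained, stop lost) with
   SIFT ≤ 0.05 — variants with no SIFT score are retained with a warning;
5. residue conservation ≥ 70% — variants with no conservation value are
   removed with a warning.

Survivors are classified by the EMS signature: exactly C>T and G>A are
canonical transitions; the other ten substitutions are atypical. Stages
whose required columns are absent (e.g. no exon table supplied) are skipped
and not recorded, so the same cascade runs on both fully annotated tables
and the minimal bundled candidate table.

## Protein consequences

For a 1-based CDS position `p`, the codon number is `ceil(p / 3)` and the
within-codon offset is `p − 3·(codon − 1)` (1, 2 or 3). Translation uses
the standard nuclear code. Consequence classes: synonymous, missense,
stop_gained (ref amino acid → `*`), stop_lost (`*` → amino acid). The
annotator validates frame (length divisible by 3), bounds, base alphabet,
and that the reference base matches the sequence.

## Conservation

For a column of a homolog alignment, conservation is the percentage of
non-focal rows whose residue matches the focal residue. Gapped rows are
excluded from the denominator by default (`count_gaps_as_mismatch=True`
counts them as mismatches instead). A column where all non-focal rows are
gapped has undefined conservation and raises.

## Differential expression

A gene is significant if FDR ≤ 0.01 and |log2FC| ≥ 1.5, both inclusive.
Direction (down iff log2FC < 0) and the direction counts use only the
magnitude rule, matching how the direction totals were tabulated. The fold
change for a log2 fold change `x` is `2^|x|` (2.83 at the 1.5 cutoff).
Colocalization labels each gene `in_peak`, `in_wider` or `outside` with
inclusive interval membership; genes without a genomic position are
`outside`.

## Transmission and read simulator

The generator's defaults are the study conditions and are used as-is in the
analysis scripts and tests.

- Genome: 5 chromosomes × 100 Mb (`GenomeModel.regular`).
- EMS variants: per-chromosome counts ~ Poisson(density × length), density
  3 per Mb; positions uniform without replacement; 98% of variants are
  canonical C>T / G>A, the rest uniform over the other substitutions.
- Cross: the BC1F1 is heterozygous at every mutant-derived site in coupling
  phase. Two rounds of selfing (F1 → F2 → F3) are simulated as two meioses;
  each gamete is a two-state Markov chain along the chromosome with
  switch probability r = Haldane(map_rate × distance), map rate 0.3 cM/Mb.
  At an unlinked locus the resulting F3 genotype law is
  P(0, 1, 2 mutant alleles) = (3/8, 1/4, 3/8).
- Bulks: under the semi-dominant model the mutant bulk takes plants
  homozygous mutant at the causal locus and the wild-type bulk plants
  homozygous wild type (63 and 55 plants). The causal site must be present
  in the variant table; `simulate_mapping_dataset` inserts a canonical C>T
  there if the Poisson draw missed it.
- Reads: per site and bulk, depth ~ Poisson(mean 40); alternate reads
  ~ Binomial(depth, f(1−e) + (1−f)e) with bulk allele frequency f and
  error rate e = 0.001. QUAL is a clipped Normal(200, 60) placeholder.

The fixture generators (`simulate_annotation_fixtures`, `simulate_deg_table`,
`make_cds_fixture`) produce annotation, expression, DEG and CDS test inputs
with planted truths; `make_cds_fixture` builds coding sequences from the 61
non-stop codons so arbitrary lengths are constructible, and its truth values
come from an independent translation oracle (Biopython).

## Numerical choices

- Chi-square goodness of fit, BH false-discovery control and random number
  generation use scipy/numpy; VCF parsing uses pysam (htslib); FASTA and
  translation oracles use Biopython.
- Window membership and BFR aggregation are vectorized; the scan raises on
  unsorted input instead of silently sorting.
- Floating-point comparisons in tests use tolerances
  (`pytest.approx`/`assert_allclose`), not equality.

## Validation

Beyond unit tests against hand-computed values and brute-force oracles
(explicit window membership, full-sequence translation, Monte-Carlo null
envelopes), the end-to-end check plants a causal locus under the study
conditions and requires the called peak interval to contain it in ≥ 95 of
100 replicates; the mean |BFR| at unlinked chromosomes must stay inside a
simulated null envelope that assumes worst-case (whole-chromosome)
correlation between markers.

## Limitations

- The simulator models a diploid cross; hexaploid wheat's homoeologous
  copies, capture-efficiency variation and mapping artifacts (homoeolog
  collapse, reference bias) are out of scope.
- The QUAL field is a placeholder distribution, not a calling-model score,
  so the quality filter exercises plumbing rather than realism.
- The recombination model is Haldane with a uniform 0.3 cM/Mb map; real
  wheat maps are strongly telomere-biased, which would narrow intervals
  near chromosome ends and widen them pericentromerically.
- Conservation and SIFT values in the bundled candidate table are taken as
  given; the package computes conservation only when an alignment is
  supplied.
- DEG colocalization uses gene start positions only; genes spanning an
  interval boundary are labeled by that single coordinate.
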