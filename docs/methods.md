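# Methods

## Model and procedure

`allelesplice` treats a heterozygous candidate splicing variant as a label
attached to one of the two parental alleles, and asks whether isoform
usage differs between alleles among long reads spanning the variant. The
unit of analysis is the *variant–site pair*: one splicing variant combined
with one allele-informative heterozygous SNV (or one phased block of
several SNVs). Reads are categorical observations in a two-way layout
(isoform × allele); the test is a per-isoform two-sided Fisher exact test
on the isoform-vs-rest 2×2 table, the pair statistic is the minimum
p-value over isoforms, and family-wise error across a variant list is
controlled by Bonferroni multiplication with the number of unique variants
that reached the test stage. This deliberately tests each isoform
marginally; no joint multinomial test is attempted, because the summary
quantity of interest is "some isoform differs" and the minimum-p summary
keeps per-isoform interpretability.

Assumptions worth making explicit:

- Input alignments are splice-aware and junction-accurate; junction-chain
  identity is taken at face value (exact matching by default). A
  configurable ±fuzz window exists for imperfectly corrected alignments.
- The base a read carries at an informative SNV identifies its allele up
  to base-calling error; a Phred-quality gate bounds that error (at
  quality threshold Q the mis-call probability per retained read is
  ≤ 10^(−Q/10), and only a third of mis-calls mimic the other allele —
  the rest are dropped as neither-ref-nor-alt).
- Reads are independent; PCR duplicates or fragment resampling (as in
  amplicon data) would overstate significance and are not modelled.

## Stages and their parameters

| Parameter | Default | Meaning |
|---|---|---|
| `delta_threshold` | 0.5 | minimum SpliceAI delta score (max of the four sub-scores) for a variant to enter; 0.2/0.8 trade recall against precision |
| `min_informative_reads` | 10 | spanning reads carrying a gated base required at a candidate SNV, regardless of allele identity |
| `min_base_quality` | 10 (15 amplicon) | Phred gate at the informative SNV; 10 ≙ 90% reliability |
| `min_isoform_support` | 4 | reads required to keep an isoform group after collapse |
| `min_intron` | 20 bp | shortest reference skip counted as an intron (separates introns from deletion artifacts) |
| `single_exon_overlap` | 0.8 | reciprocal-overlap threshold clustering junction-free reads |
| `alpha` | 0.05 | family-wise significance level on the corrected p |
| `s_max` | 16 | largest block phased by exhaustive MEC search |

The coverage gate counts reads with *any* present base at sufficient
quality; discarding bases that match neither allele happens afterwards,
inside the partition. The 10-read floor reflects that with ≥ 4 reads
needed per isoform group and two alleles each expressing at least one
isoform, fewer reads cannot yield a meaningful comparison.

## Phasing

When two or more informative sites pass the gate, reads covering several
of them are phased by minimum error correction: find the haplotype vector
h ∈ {0,1}^S (site s on haplotype 1 carries ref if h_s=0; haplotype 2 is
the complement) minimizing the total number of read calls that disagree
with the nearer haplotype. Missing calls cost nothing. With S ≤ `s_max`
the 2^(S−1) label-fixed phasings are enumerated, guaranteeing the optimum;
beyond that a deterministic multi-start heuristic is used: greedy
site-by-site extension in genomic order, plus one start per distinct
observed read row, each hill-climbed by single-site flips, best result
kept. Reads are then assigned to the haplotype nearer in Hamming distance
over their covered sites; equidistant reads stay unassigned rather than
inflating either allele. `mec_cost` sums the minimum distance over *all*
reads (the standard MEC objective), so tied reads contribute equally under
either labelling and cost is invariant to label swap.

## Exact test conventions

The two-sided p-value uses the point-probability method: the sum of
hypergeometric probabilities of all tables (at the observed margins) whose
probability does not exceed the observed table's. No mid-p or continuity
correction is applied. Isoforms with zero counts on both alleles are
uninformative and excluded; a pair with an empty allele is skipped with a
reason code rather than tested. The Bonferroni denominator counts unique
splicing variants, not pairs — several informative SNVs for one variant
are alternative views of the same hypothesis, not independent ones; a
pairs-level denominator is available behind `bonferroni_per_pair` for
sensitivity analysis.

## Simulator

The simulator emits exactly what the pipeline consumes, deterministically
under a seed: a random reference contig; two haplotype sequences differing
at the splicing variant and the informative SNVs (phase configurable);
per-allele reads drawn from configured isoform mixtures, with CIGARs built
directly from the true isoform (M across exons, N across introns;
intron-retention isoforms produce a contiguous M run, so their reads carry
bases at intronic variant positions); i.i.d. substitution errors at a
configured rate; and per-base Phred qualities from a clipped discretized
normal (mean 20, sd 5, clip [2, 40] — a plausible regime for recent
nanopore chemistries). Reads are emitted pre-aligned so the loop is closed
and needs no external aligner.

What it does *not* emulate: indel errors, homopolymer artifacts,
quality-correlated error placement (optional mode exists but is off by
default), truncated or chimeric reads (a geometric 5'-truncation option
exists, default off), multi-gene interference, or PCR duplication.
Passing tests therefore demonstrate correctness of the allele-separation,
collapse and testing machinery under substitution noise — not robustness
to every artifact of real nanopore libraries.

The McArdle-like preset encodes the motivating clinical situation: a
12-exon gene, an intronic A>C variant 3 bp upstream of an acceptor, and a
variant allele expressing exon skipping (22%), single-intron retention
(8%) and double retention (2%) against a 97%-canonical wild-type allele.
The mixture values are the preset's configured truth; recovered usage
fractions are compared against them, not against any external dataset.
The null twin (identical mixtures on both alleles) provides the matched
negative control used for type-I-error checks.

## Numerical and design choices

- **Coordinates**: VCF/GTF positions are 1-based at I/O; everything
  internal is 0-based half-open. Conversion happens only in readers and
  writers.
- **Multi-transcript SpliceAI records**: when several transcripts annotate
  one variant, the record with the maximal delta score is used, matching
  the delta score's "maximal probability" definition. Multi-allelic
  records are split into bi-allelic candidates first.
- **Self-informative sites**: only SNV splicing variants may partition
  reads at their own position; indels enter region derivation but never
  act as informative sites (base-at-position semantics are only
  well-defined for single bases).
- **Branch-point window**: the splice-region filter's exon (1–3 bp) and
  intron (3–8 bp) windows are fixed; the branch-point region is a
  configurable intronic window upstream of the acceptor (suggested 18–44
  bp) and is disabled by default, since published branch-point definitions
  vary between annotation tools and versions.
- **Chimera handling**: a read is chimeric when its primary record's SA
  tag places any split segment outside the target region; reads without
  stored base qualities are excluded from observation extraction with a
  counted warning.
- **Collapse determinism**: groups are keyed by exact chain identity and
  sorted by coordinates; novel labels are ordinals in that sort order;
  single-exon clustering operates on position-sorted spans — output is
  invariant to input read order and to worker count. Representative ends
  are member medians (annotation never adjusts them); FLAIR-style end
  refinement is intentionally not reproduced.
- **Parallelism**: one task per splicing variant; workers re-open file
  handles; results are merged by a stable sort on (variant, site), making
  the summary TSV byte-identical across worker counts.
- **Degenerate inputs**: an empty variant list yields an empty summary
  with header and an all-zero funnel; a gene absent from the GTF falls
  back to the SpliceAI-affected window with a logged warning; an allele
  with zero assigned reads, or a pair with no supported isoform group,
  is skipped with a reason code recorded in the run log.

## Problem sizes used in the checked examples

The statistical checks run on simulated data at 100 reads per allele and
5% substitution error: 100 seeds for effect recovery, 500 replicates for
null calibration, and ~2,000 partitioned read observations for the
mis-partition bound; the exact-test oracle comparison enumerates every
2×2 table with grand total ≤ 30. These sizes give binomial margins well
below the effect sizes being verified while keeping the default test run
fast.

## Known limitations

- Junction matching is exact by default; systematically shifted junctions
  (uncorrected alignments) fragment isoform groups and dilute power.
- The Bonferroni correction is conservative for variants with many
  correlated pairs; no FDR alternative is built in.
- Phasing is read-backed only: sites never bridged by common reads cannot
  be phased into one block (each still yields its own single-site pair).
- The minimum-p summary does not measure effect size; usage tables are
  emitted so users can judge magnitude separately.
- Real-data funnels depend on SNV density and coverage; variants without
  nearby informative SNVs are silently untestable, a selection effect the
  funnel counts make visible but cannot remove.
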