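# Methods

## Scope and model

`neoforge` implements the computational arm of a short-neoepitope vaccine
screen: from tumor-vs-normal somatic variant calls and tumor RNA-seq calls
to a ranked list of mutant 9-mer MHC-I binding candidates. It consumes
already-called VCFs; read alignment and the callers themselves (BWA/STAR,
Mutect2, FilterMutectCalls) are out of scope, as are peptide synthesis and
any immunological readouts.

The pipeline is a deterministic composition of set-filtering stages. For a
variant v with normalized key (chrom, pos, ref, alt):

    selected(v)  ⇐  pass(v) ∧ nonsyn(v) ∧ expressed(v) ∧ bind(v)

- `pass`: the somatic record carries no FILTER flags.
- `nonsyn`: some overlapping transcript yields a consequence in
  {missense, stop_gained, stop_lost, frameshift, inframe_indel}. Only
  missense variants proceed to tiling, since a k-mer window with a single
  substituted residue is defined only for single-residue changes;
  the other classes are annotated and reported.
- `expressed`: an RNA-seq record with the identical normalized key is PASS
  after site filtering and has INFO/DP ≥ 4 (inclusive). This is variant
  evidence, not mere site coverage: the screen's RNA workflow calls
  variants from RNA-seq, so a matching call is the natural notion of
  "detected".
- `bind`: some tiled mutant 9-mer has percentile rank ≤ 0.1 for at least
  one allele of the configured set.

## Normalization

Multiallelic records are split into one biallelic record per alternate
allele (site INFO copied, allele order preserved). Left-alignment uses the
standard trim/extend loop: shared trailing bases are trimmed, an emptied
allele is re-anchored by extending one reference base to the left, and
shared leading bases are trimmed while both alleles keep ≥ 1 base. The
result is parsimonious and position-minimal among all representations of
the same alternate haplotype, and idempotent; an indel pinned at the
contig start keeps its anchor with a shared trailing base, matching
`bcftools norm`. Correctness is tested against both an exhaustive
enumeration oracle and `bcftools norm` itself.

## Site filters

FS (Phred-scaled strand bias) and QD (quality by depth) use strict
inequalities as printed in the filter expressions: FS > 30.0 flags, QD <
2.0 flags, so records exactly at 30.0 / 2.0 PASS. The SNP-cluster rule
flags every SNV in a run of ≥ 3 consecutive SNVs (per chromosome, indels
ignored) whose first-to-last span is ≤ 35 bases — the sliding-run reading
of GATK's ClusteredSnps. A record missing FS or QD skips that rule with a
logged warning (GATK convention). Filters are applied to the RNA-seq call
set; flagged records are retained with flags for auditability and only
excluded as evidence at the support stage. The filter stage can also be
pointed at the somatic set (`filter_somatic`), off by default.

## Consequence engine

Transcript models are CDS-only (multi-exon, strand-aware, 1-based
inclusive GTF coordinates; UTRs unmodeled). Classification splices the
alternate allele into the CDS at the mapped offset (reverse-complemented
for minus-strand transcripts) and diffs the translations:

- equal-length substitution: no protein change → synonymous; one changed
  residue → missense / stop_gained / stop_lost; a substitution spanning two
  codons with two changed residues is reported with a compound label and
  excluded from tiling.
- length change: frameshift if the indel length is not a multiple of 3,
  otherwise inframe_indel.
- a variant overlapping the two intronic bases flanking an internal
  exon-exon junction, or straddling a CDS edge, is splice_region; deeper
  intronic variants within the gene span are non_coding.

Only the standard genetic code is supported. Missense and stop-gained
changes get compact labels `<ref_aa><position><alt_aa>` (stop written `*`),
e.g. `L4492R`. The engine is verified against an independent oracle that
mutates the whole chromosome, shifts the downstream CDS coordinates, and
re-translates (500+ random variants per run), and against a strand-mirror
construction.

## Peptide tiling and constructs

For a missense at protein position p, windows of length k = 9 place the
substituted residue at offsets 1..9; a window is emitted only if it lies
fully within the protein (no padding at termini — a truncated k-mer cannot
occupy the MHC groove as modeled). Each window pairs mutant and wild-type
sequences differing at exactly the mutated offset. Selected candidates are
emitted with an N-terminal tri-histidine tag (`HHH` + 9-mer) for
cobalt-porphyrin particle binding; the tag length is configurable.

## Binding predictor and selection

Each allele profile is a k × 20 log-odds matrix; a peptide's raw score is
the positional sum. Raw scores are converted to percentile ranks against
N = 100,000 background 9-mers drawn i.i.d. from natural amino-acid
frequencies (Robinson–Robinson) with a fixed per-allele calibration seed:

    rank = 100 · (n_greater + ½·n_equal + ½) / (N + 1)

The mid-rank tie convention keeps the rank strictly decreasing over
distinct scores and never exactly 0. Selection keeps candidates with best
(minimum) rank over the allele set ≤ 0.1, inclusive at the boundary; a
`require_all` mode demands rank ≤ cutoff for every allele, and a
`list-quantile` mode selects the top fraction of the candidate list
instead. The default allele set is the three BALB/c class-I molecules
H-2Kd, H-2Dd, H-2Ld.

The shipped profiles are synthetic, not trained: weights are standard
normal draws with the spread doubled at positions 2 and 9, reflecting the
dominant anchor positions of MHC-I 9-mer binding. They provide a
deterministic predictor with realistic rank behavior, not a model of the
real H-2d peptidome; for real predictions, parse NetMHC output through
`parse_netmhc_output`, which feeds the same selection stage.

## Synthetic study generator

The generator emulates the study design the pipeline assumes, at desk
scale: 2 chromosomes × 50 kb, 8 multi-exon genes (1–3 exons, alternating
strands, CDS of 120–300 codons starting ATG, ending a stop, no internal
stop; introns are GT..AG), background GC 0.45, and 50 somatic variants
split 26% synonymous / 54% missense / 6% stop-gained / 14% frameshift
indels — proportions typical of coding somatic SNV spectra. Variants are
placed ≥ 36 bases apart (so no accidental SNP cluster can form), except one
deliberate trio of SNVs spaced 15 bases apart to trip the cluster filter.
Each variant's class is verified at generation time by re-annotation
through the consequence engine; indels are emitted left-aligned. RNA depths
are drawn from 0–15 with forced values 3, 4 and 5; FS values include 30.0
and 35.0 and QD values 2.0 and 1.5, so every decision boundary is covered
from both sides. All randomness flows from one seed; identical config +
seed gives byte-identical files.

The strong-binder implant is engineered directly from the shipped
profiles: among all (position, codon, single-base change) combinations the
design picks the one maximizing the weight gap between the mutant and
wild-type residue, then fills the remaining eight residues greedily toward
a target score placed between the background's top band and a wild-type
ceiling. The resulting mutant 9-mer ranks ≈ 0.002 on its allele while the
wild-type window's best rank across all three alleles is > 9 — so the
recovery test discriminates sharply. The wild-type window is written into
gene 1's CDS at an interior position and the somatic SNV flips the one
designed base.

What the generator does **not** emulate: sequencing reads and their error
models, mapping artifacts, tumor purity/subclonality, copy number,
germline contamination, multi-transcript genes, UTRs, and real MHC binding
chemistry. Passing tests therefore demonstrate the correctness of the
pipeline's logic and bookkeeping on clean inputs, not calling or binding
accuracy on real tumors.

## Numerical and procedural choices

- Coordinates: 1-based inclusive at all I/O boundaries (VCF/GTF); 0-based
  offsets inside the coordinate maps.
- FS/QD are rounded to one decimal at generation so VCF float32
  round-trips are exact at the filter boundaries.
- Canonical transcript for tiling: first missense consequence by
  transcript_id (synthetic genes are single-transcript).
- A variant counts as non-synonymous if ANY overlapping transcript yields
  a non-synonymous consequence; all consequences are recorded.
- Candidate ordering: ascending best rank, ties broken lexicographically
  by peptide; the headline report keeps the best window per variant, the
  full table keeps all.
- Problem sizes in the default test suite (50-variant studies, 20-seed
  recovery sweep, 500-variant consequence oracle, 1,000-indel
  normalization oracle, N = 100,000 background peptides) keep a full run
  in seconds while leaving the boundary cases statistically forced rather
  than sampled.

## Known limitations

- The consequence engine handles one variant at a time; compound effects
  of nearby variants on the same haplotype are not modeled.
- Splice-region calls use a minimal 2-base flank rule, not a splicing
  model.
- The expression filter requires an exact normalized key match; RNA
  evidence at a different representation would be missed if inputs were
  not normalized by the same stage (the pipeline always normalizes both).
- The PSSM predictor's absolute ranks carry no information about real
  H-2d binding; only the rank-percentile mechanics are meaningful.
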