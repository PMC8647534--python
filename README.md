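# neoforge

Tumor neoepitope discovery from somatic variant calls, as a tested,
reusable Python pipeline.

When a tumor exome is sequenced against a matched normal, a few thousand
somatic mutations typically survive calling. Only a small fraction encode
short peptides that (a) change the protein, (b) are actually expressed by
the tumor, and (c) bind the host's MHC class I molecules strongly enough to
be presented to CD8+ T cells. `neoforge` implements that funnel for the
mouse (BALB/c, H-2<sup>d</sup> haplotype) setting used in syngeneic
renal-carcinoma vaccine studies:

1. **Normalization** — somatic and RNA-seq VCFs are split into biallelic
   records and indels are left-aligned, so both call sets share canonical
   variant keys.
2. **Site filtering** (RNA calls) — records with Fisher-strand bias
   FS > 30.0 or quality-by-depth QD < 2.0 are flagged, as is every SNV in a
   run of ≥ 3 SNVs spanning ≤ 35 bases (`SnpCluster`).
3. **Consequence calling** — each variant is classified per overlapping
   transcript (synonymous / missense / stop gained / frameshift / splice
   region / …) by splicing the alternate allele into the coding sequence
   and comparing translations under the standard genetic code.
4. **Expression support** — non-synonymous exome variants are kept only if
   the identical normalized variant was called in RNA-seq with read depth
   ≥ 4.
5. **Peptide tiling** — for each supported missense, the mutant residue is
   tiled through all nine positions of a 9-mer window (fewer near protein
   termini), each window paired with its wild-type counterpart.
6. **MHC-I rank selection** — every mutant 9-mer is scored against the
   three BALB/c class-I alleles (H-2K<sup>d</sup>, H-2D<sup>d</sup>,
   H-2L<sup>d</sup>) and converted to a percentile rank against a large
   random-peptide background (%Rank convention: smaller = stronger).
   Peptides with best rank ≤ 0.1 are selected and emitted as
   tri-histidine-tagged constructs (`HHH` + 9-mer) ready for
   cobalt-porphyrin liposome display.

The binding predictor is a deterministic position-weight-matrix baseline
with the same rank-percentile interface as NetMHC; output from an external
NetMHC-4.0 run can be parsed in its place (`parse_netmhc_output`), so the
selection stage is predictor agnostic.

Because real tumor/normal sequencing is not shipped with the package, a
first-class synthetic module generates a complete toy study — reference
genome, multi-exon genes on both strands, somatic and RNA VCFs whose
annotations straddle every filter boundary, and a ground-truth table
including one engineered missense whose mutant 9-mer is a top-percentile
binder while its wild-type window is not. The end-to-end test recovers that
implant from the candidate report.

## Worked example

```python
from neoforge import RunConfig, SyntheticConfig, run

result = run(RunConfig(outdir="demo_run", seed=7, synthetic=SyntheticConfig()))
print(result.funnel.counts)
print(result.headline[["peptide", "wild_type", "gene", "label",
                       "best_rank", "best_allele"]].to_string(index=False))
```

prints

```
{'total_variants': 50, 'pass': 50, 'non_synonymous': 37,
 'rna_supported': 26, 'tiled_windows': 162, 'selected_candidates': 2}
  peptide wild_type  gene label  best_rank best_allele
YAPPLGMGN YSPPLGMGN gene1  S63A   0.001500       H-2Kd
MITFLSDKR MITFLSDMR gene7  M56K   0.065499       H-2Dd
```

Of 50 implanted somatic variants, 37 are non-synonymous, 26 retain RNA-seq
support at depth ≥ 4 after site filtering, and 162 mutant 9-mers are tiled
from the supported missense variants. Two windows rank within the top 0.1
percentile for at least one allele: the engineered strong binder
(`YAPPLGMGN`, the S63A substitution in gene1, rank 0.0015 on
H-2K<sup>d</sup> — its wild-type window `YSPPLGMGN` ranks far outside the
band) plus one background window that clears the cutoff by chance. The
`demo_run/` directory holds every intermediate (normalized VCFs, annotation
and support TSVs, `windows.tsv`, the full `candidates.tsv`,
`candidates_best.tsv` with `HHH`-tagged constructs, `funnel.json`, and a
log with one line per dropped record).

The same stages are available on the shell via the `forge` CLI
(`forge simulate | normalize | filter | annotate | support | peptides |
rank | run`); running them individually reproduces the orchestrated run's
intermediate files byte for byte.

## Layout

- `src/neoforge/vcf_ops.py` — record model, multiallelic splitting, indel
  left-alignment, FS/QD/SnpCluster filters, VCF I/O
- `src/neoforge/consequence.py` — transcript models, CDS building,
  consequence classification, GTF/FASTA I/O
- `src/neoforge/expression.py` — RNA-seq support intersection
- `src/neoforge/peptides.py` — mutant window tiling, his-tag constructs
- `src/neoforge/mhc.py` — PSSM scoring, percentile ranks, candidate
  selection, NetMHC-4.0 table parsing
- `src/neoforge/synthetic.py` — the toy-study generator, including the
  engineered strong-binder implant
- `src/neoforge/pipeline.py` — orchestration, funnel report, run metadata
- `docs/methods.md` — model, parameters, design choices, limitations
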