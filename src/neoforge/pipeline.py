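"""End-to-end orchestration: simulate -> normalize -> filter -> annotate ->
support -> tile -> rank, with a stage-count funnel report.

The run is deterministic for a fixed config + seed. Every stage's output is
written to the run directory, dropped records are logged with the dropping
rule, and the funnel report gives the surviving count at each stage (all
variants -> PASS -> non-synonymous -> RNA-supported -> tiled windows ->
selected candidates), mirroring how a tumor-exome screen narrows thousands
of mutations down to a handful of vaccine candidates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .consequence import (
    NONSYNONYMOUS,
    annotate_all,
    load_genome,
    read_gtf,
    transcript_protein,
)
from .errors import ConfigError, NeoforgeError
from .expression import DEFAULT_MIN_DEPTH, intersect_with_rna
from .mhc import (
    DEFAULT_CUTOFF,
    get_profiles,
    rank_peptide,
    select_candidates,
)
from .peptides import DEFAULT_K, DEFAULT_TAG_LENGTH, his_tag, mutant_windows
from .synthetic import SyntheticConfig, simulate
from .vcf_ops import (
    DEFAULT_CLUSTER_COUNT,
    DEFAULT_CLUSTER_WINDOW,
    DEFAULT_FS_MAX,
    DEFAULT_QD_MIN,
    apply_site_filters,
    normalize_records,
    read_vcf,
    write_vcf,
)

log = logging.getLogger("neoforge")

DEFAULT_ALLELES = ("H-2Kd", "H-2Dd", "H-2Ld")


@dataclass
class RunConfig:
    """All run inputs and thresholds in one place.

    Exactly one of ``synthetic`` or the four input paths must be supplied.
    Threshold defaults are the screen's printed parameters.
    """

    outdir: str | Path = "neoforge_run"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    somatic_vcf: str | None = None
    rna_vcf: str | None = None
    fasta: str | None = None
    gtf: str | None = None
    fs_max: float = DEFAULT_FS_MAX
    qd_min: float = DEFAULT_QD_MIN
    cluster_count: int = DEFAULT_CLUSTER_COUNT
    cluster_window: int = DEFAULT_CLUSTER_WINDOW
    min_depth: int = DEFAULT_MIN_DEPTH
    k: int = DEFAULT_K
    tag_length: int = DEFAULT_TAG_LENGTH
    cutoff: float = DEFAULT_CUTOFF
    require_all: bool = False
    select_mode: str = "rank-cutoff"
    filter_somatic: bool = False
    alleles: tuple[str, ...] = DEFAULT_ALLELES

    def validate(self) -> None:
        paths = [self.somatic_vcf, self.rna_vcf, self.fasta, self.gtf]
        have_paths = all(p is not None for p in paths)
        if (self.synthetic is None) == (not have_paths):
            raise ConfigError(
                "supply exactly one of: a synthetic config, or all four input paths"
            )
        for name in ("fs_max", "qd_min", "cluster_count", "cluster_window",
                     "min_depth", "k", "cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.tag_length < 0:
            raise ConfigError("tag_length must be >= 0")
        if not self.alleles:
            raise ConfigError("allele set must be non-empty")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig.from_dict(raw["synthetic"])
        if "alleles" in raw:
            raw["alleles"] = tuple(raw["alleles"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class FunnelReport:
    """Stage-wise surviving counts plus per-stage drop tallies."""

    counts: dict = field(default_factory=dict)
    drop_reasons: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "drop_reasons": self.drop_reasons}, indent=2
        )


@dataclass
class PipelineResult:
    funnel: FunnelReport
    candidates: pd.DataFrame  # all tiled windows with ranks; 'selected' column
    headline: pd.DataFrame  # best selected window per variant
    supported: list
    paths: dict
    bundle: object | None = None
    truth: list | None = None


def _variant_key_str(v) -> str:
    return f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}"


def run(config: RunConfig) -> PipelineResult:
    """Execute the full funnel; writes all stage outputs under the run dir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "setup"
    try:
        bundle = truth = None
        if config.synthetic is not None:
            stage = "simulate"
            syn = replace(config.synthetic, seed=config.seed)
            sim = simulate(syn, outdir / "inputs")
            bundle, truth = sim["bundle"], sim["truth"]
            genome = bundle.chromosomes
            transcripts = bundle.transcripts
            somatic_in, rna_in = sim["somatic"], sim["rna"]
        else:
            stage = "load-inputs"
            genome = load_genome(config.fasta)
            transcripts = read_gtf(config.gtf)
            somatic_in = read_vcf(config.somatic_vcf)
            rna_in = read_vcf(config.rna_vcf)
        contigs = {name: len(seq) for name, seq in genome.items()}

        stage = "normalize"
        somatic = normalize_records(somatic_in, genome)
        rna = normalize_records(rna_in, genome)
        write_vcf(outdir / "somatic.normalized.vcf", somatic, contigs)

        stage = "site-filter"
        rna = apply_site_filters(
            rna, config.fs_max, config.qd_min,
            config.cluster_count, config.cluster_window,
        )
        if config.filter_somatic:
            somatic = apply_site_filters(
                somatic, config.fs_max, config.qd_min,
                config.cluster_count, config.cluster_window,
            )
        write_vcf(outdir / "rna.filtered.vcf", rna, contigs)

        stage = "annotate"
        annotate_all(somatic, transcripts, genome)
        ann_rows = [
            {
                "chromosome": v.chrom, "position": v.pos, "ref": v.ref, "alt": v.alt,
                "transcript_id": c.transcript_id, "classification": c.classification,
                "label": c.label,
            }
            for v in somatic
            for c in (v.consequences or [])
        ]
        pd.DataFrame(
            ann_rows,
            columns=["chromosome", "position", "ref", "alt", "transcript_id",
                     "classification", "label"],
        ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)

        stage = "support-intersect"
        supported = intersect_with_rna(somatic, rna, config.min_depth)
        sup_rows = [
            {
                "chromosome": s.variant.chrom, "position": s.variant.pos,
                "ref": s.variant.ref, "alt": s.variant.alt,
                "rna_depth": s.rna_depth,
                "classifications": ",".join(
                    c.classification for c in s.consequences
                ),
            }
            for s in supported
        ]
        pd.DataFrame(
            sup_rows,
            columns=["chromosome", "position", "ref", "alt", "rna_depth",
                     "classifications"],
        ).to_csv(outdir / "supported.tsv", sep="\t", index=False)

        stage = "tile"
        by_tid = {t.transcript_id: t for t in transcripts}
        windows = []
        window_meta = {}
        for s in supported:
            missense = sorted(
                (c for c in s.consequences if c.classification == "missense"),
                key=lambda c: c.transcript_id,
            )
            if not missense:
                log.info(
                    "no tiling for %s: non-synonymous but not a single-residue "
                    "substitution", _variant_key_str(s.variant),
                )
                continue
            c = missense[0]  # canonical transcript: first by transcript_id
            protein = transcript_protein(by_tid[c.transcript_id], genome)
            key = _variant_key_str(s.variant)
            window_meta[key] = {"gene": c.gene_id, "label": c.label}
            windows.extend(
                mutant_windows(
                    protein, c.protein_position, c.alt_aa, config.k,
                    source_variant=key, source_transcript=c.transcript_id,
                )
            )
        win_rows = [
            {
                "source_variant": w.source_variant,
                "transcript_id": w.source_transcript,
                "protein_position": w.protein_position,
                "offset": w.mutation_offset,
                "mutant": w.mutant_sequence,
                "wild_type": w.wild_type_sequence,
            }
            for w in windows
        ]
        pd.DataFrame(
            win_rows,
            columns=["source_variant", "transcript_id", "protein_position",
                     "offset", "mutant", "wild_type"],
        ).to_csv(outdir / "windows.tsv", sep="\t", index=False)

        stage = "rank"
        profiles = get_profiles(config.alleles)
        results = [
            rank_peptide(
                w.mutant_sequence, profiles,
                source_variant=w.source_variant, window=w,
            )
            for w in windows
        ]
        selected = select_candidates(
            results, config.cutoff, config.require_all, config.select_mode
        )
        selected_ids = {id(r) for r in selected}

        def _row(r):
            w = r.window
            meta = window_meta.get(r.source_variant, {})
            row = {
                "peptide": r.peptide,
                "wild_type": w.wild_type_sequence,
                "gene": meta.get("gene", "."),
                "label": meta.get("label", "."),
                "offset": w.mutation_offset,
                "source_variant": r.source_variant,
                "transcript_id": w.source_transcript,
            }
            for allele, (raw, rank) in r.per_allele.items():
                row[f"rank_{allele}"] = rank
            row["best_rank"] = r.best_rank
            row["best_allele"] = r.best_allele
            row["selected"] = int(id(r) in selected_ids)
            return row

        ordered = sorted(results, key=lambda r: (r.best_rank, r.peptide))
        candidates = pd.DataFrame([_row(r) for r in ordered])
        if candidates.empty:
            candidates = pd.DataFrame(
                columns=["peptide", "wild_type", "gene", "label", "offset",
                         "source_variant", "transcript_id", "best_rank",
                         "best_allele", "selected"]
            )
        candidates.to_csv(
            outdir / "candidates.tsv", sep="\t", index=False, float_format="%.6g"
        )

        # headline: best selected window per source variant, with constructs
        seen = set()
        head_rows = []
        fasta_entries = {}
        for r in selected:
            if r.source_variant in seen:
                continue
            seen.add(r.source_variant)
            row = _row(r)
            construct = his_tag(r.window, config.tag_length)
            row["construct"] = construct.sequence
            head_rows.append(row)
            meta = window_meta.get(r.source_variant, {})
            name = f"{meta.get('gene', 'gene')}_{meta.get('label', 'var')}_o{r.window.mutation_offset}"
            fasta_entries[name] = construct.sequence
        headline = pd.DataFrame(head_rows)
        headline.to_csv(
            outdir / "candidates_best.tsv", sep="\t", index=False, float_format="%.6g"
        )
        with open(outdir / "constructs.fa", "w") as fh:
            for name, seq in fasta_entries.items():
                fh.write(f">{name}\n{seq}\n")

        stage = "report"
        n_total = len(somatic)
        n_pass = sum(1 for v in somatic if v.is_pass)
        n_nonsyn = sum(
            1 for v in somatic
            if v.is_pass
            and any(c.classification in NONSYNONYMOUS for c in v.consequences)
        )
        funnel = FunnelReport(
            counts={
                "total_variants": n_total,
                "pass": n_pass,
                "non_synonymous": n_nonsyn,
                "rna_supported": len(supported),
                "tiled_windows": len(windows),
                "selected_candidates": len(selected),
            },
            drop_reasons={
                "somatic_non_pass": n_total - n_pass,
                "not_non_synonymous": n_pass - n_nonsyn,
                "no_or_weak_rna_support": n_nonsyn - len(supported),
                "rank_above_cutoff": len(windows) - len(selected),
            },
        )
        (outdir / "funnel.json").write_text(funnel.to_json())
        meta = {
            "neoforge_version": __version__,
            "seed": config.seed,
            "alleles": list(config.alleles),
            "thresholds": {
                "fs_max": config.fs_max,
                "qd_min": config.qd_min,
                "cluster_count": config.cluster_count,
                "cluster_window": config.cluster_window,
                "min_depth": config.min_depth,
                "k": config.k,
                "tag_length": config.tag_length,
                "cutoff": config.cutoff,
            },
            "select_mode": config.select_mode,
            "require_all": config.require_all,
        }
        (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
        paths = {
            "candidates": outdir / "candidates.tsv",
            "headline": outdir / "candidates_best.tsv",
            "constructs": outdir / "constructs.fa",
            "funnel": outdir / "funnel.json",
            "supported": outdir / "supported.tsv",
            "windows": outdir / "windows.tsv",
        }
        return PipelineResult(
            funnel=funnel,
            candidates=candidates,
            headline=headline,
            supported=supported,
            paths=paths,
            bundle=bundle,
            truth=truth,
        )
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        if isinstance(exc, NeoforgeError):
            raise type(exc)(f"[stage {stage}] {exc}") from exc
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
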