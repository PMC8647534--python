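"""Self-contained synthetic tumor/normal study generator.

Emulates the data a renal-carcinoma tumor/normal + RNA-seq experiment feeds
into the neoepitope funnel: a small diploid-agnostic reference with
multi-exon protein-coding genes on both strands, a somatic call set with
implanted SNVs and small indels realizing known consequence classes, an
RNA-seq call set with per-site depths, and a plain-TSV ground-truth table.

The generated annotations deliberately straddle every decision boundary the
pipeline uses (RNA depth 4, FS 30.0, QD 2.0, 3-SNVs-in-35-bases cluster),
and, when requested, exactly one missense is engineered so that its mutant
9-mer ranks in the top percentile band for one MHC-I allele of the built-in
predictor while its wild-type window does not.

All randomness flows from a single seed; identical config + seed yields
byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from . import mhc
from .consequence import (
    TranscriptModel,
    annotate,
    revcomp,
    write_fasta,
    write_gtf,
)
from .errors import ConfigError, PlacementError, RealizationError
from .vcf_ops import VariantRecord, left_align_and_trim, write_vcf

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
CODON_AA = {c: str(Seq(c).translate()) for c in CODONS}
AA_CODONS: dict[str, list[str]] = {}
for c, aa in CODON_AA.items():
    AA_CODONS.setdefault(aa, []).append(c)

#: minimum spacing (bases) between implanted variants, except the designed
#: SNV cluster; larger than the 35-base cluster window so no accidental
#: cluster can form
MIN_SPACING = 36

_CLASSES = ("synonymous", "missense", "stop_gained", "indel")


@dataclass
class SyntheticConfig:
    """Study-design knobs for the synthetic generator."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 50_000
    n_genes: int = 8
    exons_per_gene: tuple[int, int] = (1, 3)
    gc_fraction: float = 0.45
    n_somatic_variants: int = 50
    fraction_synonymous: float = 0.26
    fraction_missense: float = 0.54
    fraction_stop_gained: float = 0.06
    fraction_indel: float = 0.14
    rna_depth_range: tuple[int, int] = (0, 15)
    implant_strong_binder: bool = True

    def validate(self) -> None:
        total = (
            self.fraction_synonymous
            + self.fraction_missense
            + self.fraction_stop_gained
            + self.fraction_indel
        )
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class fractions sum to {total}, expected 1")
        for name in ("n_chromosomes", "chromosome_length", "n_genes", "n_somatic_variants"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 < self.gc_fraction < 1:
            raise ConfigError("gc_fraction must lie in (0, 1)")
        lo, hi = self.exons_per_gene
        if lo < 1 or hi < lo:
            raise ConfigError("exons_per_gene must be a range with 1 <= lo <= hi")
        if self.rna_depth_range[0] < 0 or self.rna_depth_range[1] < self.rna_depth_range[0]:
            raise ConfigError("rna_depth_range must be a non-negative range")
        if self.implant_strong_binder and self.fraction_missense * self.n_somatic_variants < 1:
            raise ConfigError("implant_strong_binder requires at least one missense slot")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticConfig":
        kwargs = dict(d)
        for key in ("exons_per_gene", "rna_depth_range"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class TruthVariant:
    """Ground truth for one implanted variant."""

    chromosome: str
    position: int
    ref: str
    alt: str
    intended_class: str
    rna_depth: int
    fs: float
    qd: float
    is_implanted_binder: bool
    transcript_id: str = "."
    label: str = "."
    in_cluster: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chromosome, self.position, self.ref, self.alt)


@dataclass
class EpitopeDesign:
    """A 9-mer engineered to discriminate mutant from wild type."""

    mut_window: str
    wt_window: str
    offset: int  # 1-based position of the substitution within the window
    mut_aa: str
    wt_aa: str
    mut_codon: str
    wt_codon: str
    site: int  # 0-based base index within the codon that the SNV flips
    allele_name: str


@dataclass
class ImplantSite:
    """Genomic realization of the designed epitope in the reference."""

    design: EpitopeDesign
    transcript_id: str
    gene_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    protein_position: int  # residue carrying the substitution
    window_start: int  # protein position of the window's first residue


@dataclass
class ReferenceBundle:
    """Genome sequences plus gene models (plus the implant site, if any)."""

    chromosomes: dict[str, str]
    transcripts: list[TranscriptModel]
    implant_site: ImplantSite | None = None

    @property
    def contigs(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}


def design_implant(
    profile: "mhc.AlleleProfile",
    all_profiles: Sequence["mhc.AlleleProfile"],
    cutoff: float = mhc.DEFAULT_CUTOFF,
) -> EpitopeDesign:
    """Engineer a (wild-type, mutant) 9-mer pair around a single SNV.

    The mutant must rank at or below ``cutoff`` for ``profile`` while the
    wild type stays clearly outside the selected band for every allele.
    The pair differs at one residue reachable by a one-base codon change,
    chosen to maximize the score gap; the remaining residues are filled
    greedily toward a target score between the background's top band and
    the wild-type ceiling. Deterministic given the profiles.
    """
    w = profile.position_weights
    k = profile.k
    best = None
    for p in range(k):
        for mut_codon in CODONS:
            m = CODON_AA[mut_codon]
            if m == "*":
                continue
            for site in range(3):
                for b in _BASES:
                    if b == mut_codon[site]:
                        continue
                    wt_codon = mut_codon[:site] + b + mut_codon[site + 1 :]
                    r = CODON_AA[wt_codon]
                    if r == "*" or r == m:
                        continue
                    gap = w[p, mhc.AA_INDEX[m]] - w[p, mhc.AA_INDEX[r]]
                    if best is None or gap > best[0]:
                        best = (gap, p, m, r, mut_codon, wt_codon, site)
    gap, p, m, r, mut_codon, wt_codon, site = best
    bg = profile.background_scores
    n = len(bg)
    lo = float(bg[-max(1, round(0.0005 * n))])  # mutant floor: rank ~0.05
    hi = float(bg[-max(1, round(0.02 * n))]) + gap  # wild-type ceiling: rank ~2
    if hi <= lo:
        raise RealizationError(
            "profile cannot discriminate a single-substitution epitope pair"
        )
    target = (lo + hi) / 2.0
    residues = [""] * k
    residues[p] = m
    remaining = target - w[p, mhc.AA_INDEX[m]]
    fill = [i for i in range(k) if i != p]
    for j, i in enumerate(fill):
        per_pos = remaining / (len(fill) - j)
        col = w[i]
        ri = int(np.argmin(np.abs(col - per_pos)))
        residues[i] = mhc.AA_ALPHABET[ri]
        remaining -= col[ri]
    mut_window = "".join(residues)
    wt_window = mut_window[:p] + r + mut_window[p + 1 :]
    mut_rank = mhc.percentile_rank(mhc.score(mut_window, profile), profile)
    if mut_rank > cutoff:
        raise RealizationError(f"designed mutant ranks {mut_rank:.3f} > {cutoff}")
    wt_best = min(
        mhc.percentile_rank(mhc.score(wt_window, q), q) for q in all_profiles
    )
    if wt_best <= 10 * cutoff:
        raise RealizationError(f"designed wild type ranks {wt_best:.3f}; too strong")
    return EpitopeDesign(
        mut_window=mut_window,
        wt_window=wt_window,
        offset=p + 1,
        mut_aa=m,
        wt_aa=r,
        mut_codon=mut_codon,
        wt_codon=wt_codon,
        site=site,
        allele_name=profile.allele_name,
    )


def _random_codon(rng: np.random.Generator, probs: np.ndarray) -> str:
    while True:
        codon = "".join(_BASES[i] for i in rng.choice(4, size=3, p=probs))
        if codon not in _STOPS:
            return codon


def generate_reference(config: SyntheticConfig) -> ReferenceBundle:
    """Build chromosomes and gene models; deterministic for a fixed seed.

    Every gene's CDS begins with ATG, ends with a stop codon, has length
    divisible by 3 and no internal stop; strands alternate so both are
    represented whenever there are at least two genes. When the config
    requests a strong-binder implant, the first gene's protein carries the
    designed wild-type epitope at an interior position.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    design = None
    if config.implant_strong_binder:
        profiles = mhc.get_profiles()
        design = design_implant(profiles[0], profiles)

    base_arr = np.array(list(_BASES))
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lists = {
        name: list(rng.choice(base_arr, size=config.chromosome_length, p=probs))
        for name in chrom_names
    }
    cursors = {name: 0 for name in chrom_names}
    transcripts: list[TranscriptModel] = []
    implant_meta = None

    ex_lo, ex_hi = config.exons_per_gene
    for j in range(config.n_genes):
        strand = "+" if j % 2 == 0 else "-"
        n_codons = int(rng.integers(120, 301))  # protein length in residues
        codons = ["ATG"] + [_random_codon(rng, probs) for _ in range(n_codons - 1)]
        pos_mut = window_start = None
        if j == 0 and design is not None:
            pos_mut = n_codons // 2
            window_start = pos_mut - (design.offset - 1)
            for idx, aa in enumerate(design.wt_window):
                aa_pos = window_start + idx
                if aa_pos == pos_mut:
                    codons[aa_pos - 1] = design.wt_codon
                else:
                    options = AA_CODONS[aa]
                    codons[aa_pos - 1] = options[int(rng.integers(len(options)))]
        codons.append(("TAA", "TAG", "TGA")[int(rng.integers(3))])
        cds = "".join(codons)

        n_exons = int(rng.integers(ex_lo, ex_hi + 1))
        extra = rng.multinomial(len(cds) - 9 * n_exons, [1 / n_exons] * n_exons)
        exon_lengths = [9 + int(e) for e in extra]
        exon_offsets = np.concatenate([[0], np.cumsum(exon_lengths)])[:-1]
        pieces = []
        intron_lengths = []
        for i, (off, ln) in enumerate(zip(exon_offsets, exon_lengths)):
            pieces.append(cds[off : off + ln])
            if i < n_exons - 1:
                ilen = int(rng.integers(50, 201))
                intron = "GT" + "".join(rng.choice(base_arr, size=ilen - 4, p=probs)) + "AG"
                pieces.append(intron)
                intron_lengths.append(ilen)
        pre_mrna = "".join(pieces)
        genomic_seq = pre_mrna if strand == "+" else revcomp(pre_mrna)

        chrom = chrom_names[j % config.n_chromosomes]
        gap = int(rng.integers(500, 1501))
        start = cursors[chrom] + gap + 1
        end = start + len(genomic_seq) - 1
        if end > config.chromosome_length:
            raise PlacementError(
                f"gene {j + 1} does not fit on {chrom} "
                f"(needs through base {end}, length {config.chromosome_length})"
            )
        cursors[chrom] = end
        chrom_lists[chrom][start - 1 : end] = list(genomic_seq)

        # exon starts within the pre-mRNA (transcript orientation)
        pre_starts = []
        off = 0
        for i, ln in enumerate(exon_lengths):
            pre_starts.append(off)
            off += ln
            if i < n_exons - 1:
                off += intron_lengths[i]
        segs = []
        lp = len(pre_mrna)
        for ps, ln in zip(pre_starts, exon_lengths):
            if strand == "+":
                segs.append((start + ps, start + ps + ln - 1))
            else:
                segs.append((start + lp - ps - ln, start + lp - ps - 1))
        t = TranscriptModel(f"tx{j + 1}", f"gene{j + 1}", chrom, strand, sorted(segs))
        transcripts.append(t)
        if pos_mut is not None:
            implant_meta = (t, pos_mut, window_start)

    chromosomes = {name: "".join(chrom_lists[name]) for name in chrom_names}
    bundle = ReferenceBundle(chromosomes, transcripts)

    if design is not None:
        t, pos_mut, window_start = implant_meta
        off = 3 * (pos_mut - 1) + design.site
        g = t.cds_to_genomic()[off]
        ref_base = chromosomes[t.chrom][g - 1]
        mut_base = design.mut_codon[design.site]
        wt_base = design.wt_codon[design.site]
        if t.strand == "-":
            mut_base, wt_base = revcomp(mut_base), revcomp(wt_base)
        assert ref_base == wt_base, "implant bookkeeping out of sync with genome"
        bundle.implant_site = ImplantSite(
            design=design,
            transcript_id=t.transcript_id,
            gene_id=t.gene_id,
            chrom=t.chrom,
            pos=g,
            ref=ref_base,
            alt=mut_base,
            protein_position=pos_mut,
            window_start=window_start,
        )
    return bundle


# ---------------------------------------------------------------------------
# variant implantation


def _class_counts(config: SyntheticConfig) -> dict[str, int]:
    """Largest-remainder allocation of the class fractions."""
    fracs = {
        "synonymous": config.fraction_synonymous,
        "missense": config.fraction_missense,
        "stop_gained": config.fraction_stop_gained,
        "indel": config.fraction_indel,
    }
    n = config.n_somatic_variants
    counts = {c: int(np.floor(f * n)) for c, f in fracs.items()}
    rem = n - sum(counts.values())
    order = sorted(_CLASSES, key=lambda c: fracs[c] * n - counts[c], reverse=True)
    for c in order[:rem]:
        counts[c] += 1
    return counts


class _Placer:
    """Places variants into CDS space with spacing and class realization."""

    def __init__(self, bundle: ReferenceBundle, rng: np.random.Generator):
        self.bundle = bundle
        self.rng = rng
        self.occupied: list[tuple[str, int, int]] = []

    def _clear(self, chrom: str, start: int, end: int) -> bool:
        for c, s, e in self.occupied:
            if c == chrom and start <= e + MIN_SPACING - 1 and end >= s - MIN_SPACING + 1:
                return False
        return True

    def reserve(self, rec: VariantRecord) -> None:
        self.occupied.append((rec.chrom, rec.pos, rec.end))

    def _consequence(self, rec: VariantRecord):
        cons = annotate(rec, self.bundle.transcripts, self.bundle.chromosomes)
        return cons[0] if cons else None

    def snv_at(self, g: int, t: TranscriptModel, intended: str):
        """First alternate base at genomic position g realizing ``intended``."""
        chrom_seq = self.bundle.chromosomes[t.chrom]
        ref = chrom_seq[g - 1]
        for b in _BASES:
            if b == ref:
                continue
            rec = VariantRecord(t.chrom, g, ref, [b])
            cons = self._consequence(rec)
            if cons is not None and cons.classification == intended:
                return rec, cons
        return None

    def _forbidden(self, t: TranscriptModel, aa_pos: int) -> bool:
        site = self.bundle.implant_site
        if site is None or t.transcript_id != site.transcript_id:
            return False
        return site.window_start - 1 <= aa_pos <= site.window_start + 9

    def place(self, intended: str, tries: int = 400):
        """Place one variant of the intended consequence class."""
        transcripts = self.bundle.transcripts
        for _ in range(tries):
            t = transcripts[int(self.rng.integers(len(transcripts)))]
            n_aa = t.cds_length // 3 - 1
            aa_pos = int(self.rng.integers(2, n_aa))
            if self._forbidden(t, aa_pos):
                continue
            site = int(self.rng.integers(3))
            cds_off = 3 * (aa_pos - 1) + site
            g = t.cds_to_genomic()[cds_off]
            chrom_seq = self.bundle.chromosomes[t.chrom]
            if intended == "indel":
                if g < 3:
                    continue
                if self.rng.integers(2):  # 1-base deletion with anchor
                    rec = VariantRecord(t.chrom, g - 1, chrom_seq[g - 2 : g], [chrom_seq[g - 2]])
                else:  # 1-base insertion after anchor
                    ins = _BASES[int(self.rng.integers(4))]
                    rec = VariantRecord(t.chrom, g, chrom_seq[g - 1], [chrom_seq[g - 1] + ins])
                rec = left_align_and_trim(rec, chrom_seq)
                cons = self._consequence(rec)
                if cons is None or cons.classification != "frameshift":
                    continue
                hit = (rec, cons)
            else:
                hit = self.snv_at(g, t, intended)
                if hit is None:
                    continue
            rec, cons = hit
            if not self._clear(rec.chrom, rec.pos, rec.end):
                continue
            self.reserve(rec)
            return rec, cons
        raise RealizationError(
            f"could not realize a {intended!r} variant in the available CDS space"
        )

    def place_cluster(self, intended: str = "missense", tries: int = 200):
        """Three SNVs of one class within a 35-base span in one exon."""
        for _ in range(tries):
            t = self.bundle.transcripts[int(self.rng.integers(len(self.bundle.transcripts)))]
            segs = [s for s in t.cds_segments if s[1] - s[0] + 1 >= 45]
            if not segs:
                continue
            s, e = segs[int(self.rng.integers(len(segs)))]
            g0 = int(self.rng.integers(s + 3, e - 33))
            positions = (g0, g0 + 15, g0 + 30)
            if not self._clear(t.chrom, positions[0], positions[-1]):
                continue
            aa_positions = set()
            n_aa = t.cds_length // 3 - 1
            ok = True
            hits = []
            for g in positions:
                aa = t.genomic_to_cds()[g] // 3 + 1
                if aa < 2 or aa >= n_aa or self._forbidden(t, aa) or aa in aa_positions:
                    ok = False
                    break
                aa_positions.add(aa)
                hit = self.snv_at(g, t, intended)
                if hit is None:
                    ok = False
                    break
                hits.append(hit)
            if not ok:
                continue
            for rec, _ in hits:
                self.reserve(rec)
            return hits
        raise RealizationError("could not place a 3-SNV cluster within 35 bases")


def implant_variants(
    bundle: ReferenceBundle, config: SyntheticConfig
) -> tuple[list[VariantRecord], list[VariantRecord], list[TruthVariant]]:
    """Implant somatic variants and derive the RNA call set and truth table.

    Returns (somatic records, RNA records, truth rows), each sorted by
    position. RNA records exist for every variant with nonzero depth and
    carry DP, FS and QD in INFO; FS/QD/depth assignments straddle every
    downstream filter boundary.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    counts = _class_counts(config)
    placer = _Placer(bundle, rng)

    entries = []  # (record, consequence-or-None, intended, implanted, in_cluster)

    if config.implant_strong_binder:
        if bundle.implant_site is None:
            raise ConfigError("config requests an implant but the bundle has none")
        if counts["missense"] < 1:
            raise ConfigError("no missense budget for the implanted binder")
        site = bundle.implant_site
        rec = VariantRecord(site.chrom, site.pos, site.ref, [site.alt])
        cons = annotate(rec, bundle.transcripts, bundle.chromosomes)[0]
        if cons.classification != "missense" or cons.protein_position != site.protein_position:
            raise RealizationError("implanted binder does not re-annotate as designed")
        placer.reserve(rec)
        entries.append((rec, cons, "missense", True, False))
        counts["missense"] -= 1

    if config.n_somatic_variants >= 10:
        cluster_class = next(
            (c for c in ("missense", "synonymous", "stop_gained") if counts[c] >= 3),
            None,
        )
        if cluster_class is not None:
            for rec, cons in placer.place_cluster(cluster_class):
                entries.append((rec, cons, cluster_class, False, True))
            counts[cluster_class] -= 3

    for cls in _CLASSES:
        for _ in range(counts[cls]):
            rec, cons = placer.place(cls)
            entries.append((rec, cons, cls, False, False))

    chrom_order = {name: i for i, name in enumerate(bundle.chromosomes)}
    entries.sort(key=lambda e: (chrom_order[e[0].chrom], e[0].pos))

    # default annotations, then deterministic boundary overrides
    lo_d, hi_d = config.rna_depth_range
    ann = []
    for rec, cons, intended, implanted, in_cluster in entries:
        depth = int(rng.integers(lo_d, hi_d + 1))
        fs = round(float(rng.uniform(0.0, 25.0)), 1)
        qd = round(float(rng.uniform(5.0, 30.0)), 1)
        ann.append([depth, fs, qd])
    safe_depth = max(6, lo_d + 1)
    for i, e in enumerate(entries):
        if e[3] or e[4]:  # implant or cluster member: survivable annotations
            ann[i][0] = max(ann[i][0], safe_depth)
            ann[i][1] = min(ann[i][1], 20.0)
            ann[i][2] = max(ann[i][2], 10.0)
    eligible = [i for i, e in enumerate(entries) if not e[3] and not e[4]]
    overrides = [
        ("depth", 3), ("depth", 4), ("depth", 5),
        ("fs", 35.0), ("fs", 30.0), ("qd", 1.5), ("qd", 2.0),
    ]
    for i, (kind, value) in zip(eligible, overrides):
        if kind == "depth":
            ann[i][0] = value
            ann[i][1], ann[i][2] = min(ann[i][1], 20.0), max(ann[i][2], 10.0)
        elif kind == "fs":
            ann[i][1] = value
            ann[i][0] = max(ann[i][0], safe_depth)
            ann[i][2] = max(ann[i][2], 10.0)
        else:
            ann[i][2] = value
            ann[i][0] = max(ann[i][0], safe_depth)
            ann[i][1] = min(ann[i][1], 20.0)

    somatic, rna, truth = [], [], []
    for (rec, cons, intended, implanted, in_cluster), (depth, fs, qd) in zip(entries, ann):
        realized = cons.classification
        somatic.append(replace(rec, info={"FS": fs, "QD": qd}))
        if depth > 0:
            rna.append(replace(rec, info={"DP": depth, "FS": fs, "QD": qd}))
        truth.append(
            TruthVariant(
                chromosome=rec.chrom,
                position=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                intended_class=realized,
                rna_depth=depth,
                fs=fs,
                qd=qd,
                is_implanted_binder=implanted,
                transcript_id=cons.transcript_id,
                label=cons.label,
                in_cluster=in_cluster,
            )
        )

    # internal realizability oracle: re-annotation reproduces every class
    for row, (rec, *_rest) in zip(truth, entries):
        redo = annotate(rec, bundle.transcripts, bundle.chromosomes)[0]
        assert redo.classification == row.intended_class
    return somatic, rna, truth


# ---------------------------------------------------------------------------
# file emission

TRUTH_COLUMNS = [
    "chromosome", "position", "ref", "alt", "intended_class", "rna_depth",
    "fs", "qd", "is_implanted_binder", "transcript_id", "label", "in_cluster",
]


def write_truth(path, truth: Sequence[TruthVariant]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truth:
            fh.write(
                "\t".join(
                    str(getattr(t, c)) if not isinstance(getattr(t, c), bool)
                    else ("1" if getattr(t, c) else "0")
                    for c in TRUTH_COLUMNS
                )
                + "\n"
            )


def read_truth(path) -> list[TruthVariant]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            d = dict(zip(header, line.rstrip("\n").split("\t")))
            out.append(
                TruthVariant(
                    chromosome=d["chromosome"],
                    position=int(d["position"]),
                    ref=d["ref"],
                    alt=d["alt"],
                    intended_class=d["intended_class"],
                    rna_depth=int(d["rna_depth"]),
                    fs=float(d["fs"]),
                    qd=float(d["qd"]),
                    is_implanted_binder=d["is_implanted_binder"] == "1",
                    transcript_id=d["transcript_id"],
                    label=d["label"],
                    in_cluster=d["in_cluster"] == "1",
                )
            )
    return out


def simulate(config: SyntheticConfig, outdir) -> dict:
    """Generate the full toy study and write it under ``outdir``.

    Emits reference.fa, genes.gtf, somatic.vcf, rna.vcf and truth.tsv;
    returns the bundle, record lists and file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_reference(config)
    somatic, rna, truth = implant_variants(bundle, config)
    paths = {
        "fasta": outdir / "reference.fa",
        "gtf": outdir / "genes.gtf",
        "somatic_vcf": outdir / "somatic.vcf",
        "rna_vcf": outdir / "rna.vcf",
        "truth": outdir / "truth.tsv",
    }
    write_fasta(paths["fasta"], bundle.chromosomes)
    write_gtf(paths["gtf"], bundle.transcripts)
    write_vcf(paths["somatic_vcf"], somatic, bundle.contigs)
    write_vcf(paths["rna_vcf"], rna, bundle.contigs)
    write_truth(paths["truth"], truth)
    return {
        "bundle": bundle,
        "somatic": somatic,
        "rna": rna,
        "truth": truth,
        "paths": paths,
    }
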