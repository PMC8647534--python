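"""Transcript-aware protein consequence calling.

Each normalized biallelic variant is classified against every overlapping
transcript by splicing the alternate allele into the coding sequence and
comparing the translations (standard genetic code). This is the in-repo
replacement for the VEP annotation step: it covers the consequence classes
the neoepitope funnel needs (synonymous, missense, stop gain/loss,
frameshift, in-frame indel, splice region, non-coding) rather than the full
VEP feature set.

Coordinates are 1-based inclusive in genomic space (GTF/VCF convention);
CDS offsets are 0-based in transcript orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import Seq

from .errors import CoordinateError, LabelError, NormalizationError
from .vcf_ops import VariantRecord

log = logging.getLogger("neoforge")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: classifications counted as non-synonymous for downstream filtering
NONSYNONYMOUS = frozenset(
    {"missense", "stop_gained", "stop_lost", "frameshift", "inframe_indel"}
)

#: intronic flank (bases) treated as splice region around internal junctions
SPLICE_FLANK = 2


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a nucleotide sequence; trailing partial codons are ignored."""
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


@dataclass
class TranscriptModel:
    """Strand-aware multi-exon CDS with genome<->CDS coordinate maps.

    ``cds_segments`` are 1-based inclusive genomic intervals in ascending
    genomic order; transcript order is ascending for '+' and descending
    for '-' strands.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_segments: list[tuple[int, int]]
    _g2c: dict | None = field(default=None, repr=False, compare=False)
    _c2g: list | None = field(default=None, repr=False, compare=False)
    _cds_seq: str | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        segs = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping CDS segments in {self.transcript_id}")
        self.cds_segments = segs

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_segments[0][0], self.cds_segments[-1][1]

    def _ordered_segments(self) -> list[tuple[int, int]]:
        return self.cds_segments if self.strand == "+" else self.cds_segments[::-1]

    def cds_to_genomic(self) -> list[int]:
        """Genomic position (1-based) of each CDS offset, 5'->3'."""
        if self._c2g is None:
            positions: list[int] = []
            for s, e in self._ordered_segments():
                rng = range(s, e + 1) if self.strand == "+" else range(e, s - 1, -1)
                positions.extend(rng)
            self._c2g = positions
        return self._c2g

    def genomic_to_cds(self) -> dict[int, int]:
        """CDS offset (0-based) of each genomic CDS base."""
        if self._g2c is None:
            self._g2c = {g: i for i, g in enumerate(self.cds_to_genomic())}
        return self._g2c


def build_cds(
    transcript: TranscriptModel, genome: Mapping[str, str]
) -> tuple[str, dict[int, int]]:
    """Extract the coding sequence and the genome->CDS coordinate map.

    Minus-strand transcripts yield the reverse complement of the
    concatenated genomic segments.
    """
    chrom_seq = genome[transcript.chrom]
    for s, e in transcript.cds_segments:
        if s < 1 or e > len(chrom_seq):
            raise CoordinateError(
                f"CDS segment {s}-{e} outside {transcript.chrom} "
                f"(length {len(chrom_seq)})"
            )
    if transcript._cds_seq is None:
        parts = [chrom_seq[s - 1 : e] for s, e in transcript.cds_segments]
        seq = "".join(parts).upper()
        if transcript.strand == "-":
            seq = revcomp(seq)
        transcript._cds_seq = seq
    return transcript._cds_seq, transcript.genomic_to_cds()


@dataclass
class ProteinConsequence:
    """Per-transcript classification of a variant's protein-level effect."""

    transcript_id: str
    classification: str
    protein_position: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    label: str = "."
    gene_id: str = "."


def hgvs_like_label(consequence: ProteinConsequence) -> str:
    """Compact change string, e.g. missense L4492R or stop gain W10*."""
    if consequence.classification not in ("missense", "stop_gained"):
        raise LabelError(
            f"no substitution label for class {consequence.classification!r}"
        )
    return f"{consequence.ref_aa}{consequence.protein_position}{consequence.alt_aa}"


def _near_internal_junction(variant: VariantRecord, t: TranscriptModel) -> bool:
    vs, ve = variant.pos, variant.end
    segs = t.cds_segments
    for i, (s, e) in enumerate(segs):
        if i > 0 and vs <= s - 1 and ve >= s - SPLICE_FLANK:  # acceptor flank
            return True
        if i < len(segs) - 1 and vs <= e + SPLICE_FLANK and ve >= e + 1:  # donor flank
            return True
    return False


def _diff_consequence(
    t: TranscriptModel, cds_ref: str, cds_alt: str, start_off: int
) -> ProteinConsequence:
    codon_idx = start_off // 3
    if len(cds_ref) != len(cds_alt):
        delta = len(cds_alt) - len(cds_ref)
        cls = "frameshift" if delta % 3 else "inframe_indel"
        p_ref = translate(cds_ref)
        p_alt = translate(cds_alt)
        first = next(
            (i for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b), codon_idx
        )
        first = min(first, len(p_ref) - 1)
        suffix = "fs" if cls == "frameshift" else ("del" if delta < 0 else "ins")
        return ProteinConsequence(
            t.transcript_id,
            cls,
            protein_position=first + 1,
            ref_aa=p_ref[first],
            label=f"{p_ref[first]}{first + 1}{suffix}",
            gene_id=t.gene_id,
        )
    p_ref = translate(cds_ref)
    p_alt = translate(cds_alt)
    diffs = [i for i, (a, b) in enumerate(zip(p_ref, p_alt)) if a != b]
    if not diffs:
        aa = p_ref[codon_idx]
        return ProteinConsequence(
            t.transcript_id,
            "synonymous",
            protein_position=codon_idx + 1,
            ref_aa=aa,
            alt_aa=aa,
            label=f"{aa}{codon_idx + 1}=",
            gene_id=t.gene_id,
        )
    if len(diffs) == 1:
        i = diffs[0]
        ra, aa = p_ref[i], p_alt[i]
        if aa == "*":
            cls = "stop_gained"
        elif ra == "*":
            cls = "stop_lost"
        else:
            cls = "missense"
        return ProteinConsequence(
            t.transcript_id,
            cls,
            protein_position=i + 1,
            ref_aa=ra,
            alt_aa=aa,
            label=f"{ra}{i + 1}{aa}",
            gene_id=t.gene_id,
        )
    # substitution spanning codons: compound change, excluded from tiling
    label = ";".join(f"{p_ref[i]}{i + 1}{p_alt[i]}" for i in diffs)
    return ProteinConsequence(
        t.transcript_id,
        "inframe_indel",
        protein_position=diffs[0] + 1,
        ref_aa=p_ref[diffs[0]],
        alt_aa=p_alt[diffs[0]],
        label=label,
        gene_id=t.gene_id,
    )


def _classify_one(
    variant: VariantRecord, t: TranscriptModel, genome: Mapping[str, str]
) -> ProteinConsequence:
    g2c = t.genomic_to_cds()
    span = range(variant.pos, variant.end + 1)
    inside = [p in g2c for p in span]
    if not all(inside):
        if any(inside) or _near_internal_junction(variant, t):
            cls = "splice_region"
        else:
            cls = "non_coding"
        return ProteinConsequence(t.transcript_id, cls, gene_id=t.gene_id)
    offsets = [g2c[p] for p in span]
    if max(offsets) - min(offsets) != len(offsets) - 1:
        # reference bases discontiguous in transcript space (spans a junction)
        return ProteinConsequence(t.transcript_id, "splice_region", gene_id=t.gene_id)
    cds_ref, _ = build_cds(t, genome)
    start_off = min(offsets)
    alt_t = variant.alt.upper() if t.strand == "+" else revcomp(variant.alt.upper())
    cds_alt = cds_ref[:start_off] + alt_t + cds_ref[start_off + len(variant.ref) :]
    return _diff_consequence(t, cds_ref, cds_alt, start_off)


def annotate(
    variant: VariantRecord,
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
) -> list[ProteinConsequence]:
    """One ProteinConsequence per transcript overlapping the variant.

    The variant must be normalized and biallelic; transcript overlap
    includes the 2-base intronic splice flanks.
    """
    if not variant.is_biallelic:
        raise NormalizationError("annotate requires a normalized biallelic record")
    out = []
    for t in transcripts:
        if t.chrom != variant.chrom:
            continue
        lo, hi = t.span
        if variant.end < lo - SPLICE_FLANK or variant.pos > hi + SPLICE_FLANK:
            continue
        out.append(_classify_one(variant, t, genome))
    return out


def annotate_all(
    variants: Iterable[VariantRecord],
    transcripts: Sequence[TranscriptModel],
    genome: Mapping[str, str],
) -> list[VariantRecord]:
    """Attach consequences to each record in place; returns the input list."""
    out = list(variants)
    for v in out:
        v.consequences = annotate(v, transcripts, genome)
    return out


def transcript_protein(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Translated protein, excluding the terminal stop if present."""
    prot = translate(build_cds(t, genome)[0])
    return prot[:-1] if prot.endswith("*") else prot


# ---------------------------------------------------------------------------
# GTF I/O

def read_gtf(path) -> list[TranscriptModel]:
    """Transcript models from GTF CDS features (UTRs and exons ignored)."""
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tid: dict[str, dict] = {}
    for cds in db.features_of_type("CDS"):
        tid = cds.attributes["transcript_id"][0]
        gid = cds.attributes.get("gene_id", ["."])[0]
        entry = by_tid.setdefault(
            tid, {"gene_id": gid, "chrom": cds.seqid, "strand": cds.strand, "segs": []}
        )
        entry["segs"].append((cds.start, cds.end))
    models = [
        TranscriptModel(tid, e["gene_id"], e["chrom"], e["strand"], sorted(e["segs"]))
        for tid, e in by_tid.items()
    ]
    models.sort(key=lambda t: t.transcript_id)
    return models


def write_gtf(path, transcripts: Sequence[TranscriptModel]) -> None:
    """Write gene/transcript/exon/CDS features with proper CDS frames."""
    lines = []
    for t in sorted(transcripts, key=lambda t: (t.chrom, t.span[0])):
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
        lo, hi = t.span
        lines.append((t.chrom, lo, f"{t.chrom}\tneoforge\tgene\t{lo}\t{hi}\t.\t{t.strand}\t.\t"
                      f'gene_id "{t.gene_id}";'))
        lines.append((t.chrom, lo, f"{t.chrom}\tneoforge\ttranscript\t{lo}\t{hi}\t.\t{t.strand}\t.\t{attrs}"))
        cum = 0
        frames = {}
        for s, e in t._ordered_segments():
            frames[(s, e)] = (3 - cum % 3) % 3
            cum += e - s + 1
        for s, e in t.cds_segments:
            lines.append((t.chrom, s, f"{t.chrom}\tneoforge\texon\t{s}\t{e}\t.\t{t.strand}\t.\t{attrs}"))
            lines.append((t.chrom, s, f"{t.chrom}\tneoforge\tCDS\t{s}\t{e}\t.\t{t.strand}\t{frames[(s, e)]}\t{attrs}"))
    with open(path, "w") as fh:
        for _, _, line in lines:
            fh.write(line + "\n")


def load_genome(path) -> dict[str, str]:
    """Load a FASTA reference into plain strings, keyed by contig name."""
    import pyfaidx

    with pyfaidx.Fasta(str(path), as_raw=True, rebuild=False) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
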