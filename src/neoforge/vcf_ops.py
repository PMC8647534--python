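"""Variant-record normalization and site filtering.

Somatic and RNA-seq call sets enter the pipeline as VCF v4.2 files. Before
any annotation, every record is brought to a canonical form: multiallelic
records are split into one biallelic record per alternate allele, and indels
are trimmed and shifted to the smallest coordinate that produces the same
alternate haplotype (left-alignment). Canonical keys make the later
exome/RNA intersection well defined.

Site filters mirror GATK VariantFiltration as applied to the RNA-seq calls:
records with Fisher-strand bias FS > 30.0 or quality-by-depth QD < 2.0 are
flagged, as is every SNV belonging to a run of >= 3 SNVs spanning <= 35
bases. Flagged records are retained with their flags (audit trail); they are
dropped only at the expression-support stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pysam

from .errors import (
    NormalizationError,
    OrderingError,
    ReferenceMismatchError,
)

log = logging.getLogger("neoforge")

#: default thresholds, matching GATK VariantFiltration usage on RNA calls
DEFAULT_FS_MAX = 30.0
DEFAULT_QD_MIN = 2.0
DEFAULT_CLUSTER_COUNT = 3
DEFAULT_CLUSTER_WINDOW = 35


@dataclass
class VariantRecord:
    """One VCF record with site-level annotations and filter flags.

    Positions are 1-based, VCF style. ``filter_flags`` empty means PASS.
    ``consequences`` is filled by the annotation stage.
    """

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    info: dict = field(default_factory=dict)
    filter_flags: set = field(default_factory=set)
    consequences: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("REF allele must be non-empty")
        for a in self.alts:
            if not a:
                raise ValueError("ALT alleles must be non-empty")
            if a == self.ref:
                raise ValueError(f"ALT equals REF ({a}) at {self.chrom}:{self.pos}")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def alt(self) -> str:
        if not self.is_biallelic:
            raise ValueError("record is multiallelic; split first")
        return self.alts[0]

    @property
    def is_snv(self) -> bool:
        return self.is_biallelic and len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_pass(self) -> bool:
        return not self.filter_flags

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized identity: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def end(self) -> int:
        """Last reference base covered, 1-based inclusive."""
        return self.pos + len(self.ref) - 1


def split_multiallelic(record: VariantRecord) -> list[VariantRecord]:
    """Split a record into one biallelic record per alternate allele.

    Site-level INFO is copied to each output; allele order is preserved.
    Biallelic input passes through (as a fresh copy).
    """
    out = []
    for alt in record.alts:
        out.append(
            VariantRecord(
                chrom=record.chrom,
                pos=record.pos,
                ref=record.ref,
                alts=[alt],
                info=dict(record.info),
                filter_flags=set(record.filter_flags),
            )
        )
    return out


def left_align_and_trim(record: VariantRecord, refseq: str) -> VariantRecord:
    """Return the canonical (parsimonious, left-most) representation.

    Shared trailing bases are trimmed; whenever an allele would become
    empty the record is extended one reference base to the left, which
    shifts indels through repeat tracts to their smallest equivalent
    coordinate. Finally shared leading bases are trimmed while both
    alleles keep at least one base. The operation is idempotent.

    ``refseq`` is the full sequence of the record's chromosome.
    """
    if not record.is_biallelic:
        raise NormalizationError("left-alignment requires a biallelic record")
    ref = record.ref.upper()
    alt = record.alt.upper()
    pos = record.pos
    if refseq[pos - 1 : pos - 1 + len(ref)].upper() != ref:
        raise ReferenceMismatchError(
            f"REF {record.ref} does not match reference at {record.chrom}:{pos}"
        )
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if (len(ref) == 1 or len(alt) == 1) and pos == 1:
                break  # at the contig start: keep the anchor's shared base
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                pos -= 1
                base = refseq[pos - 1].upper()
                ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(record, pos=pos, ref=ref, alts=[alt])


def normalize_records(
    records: Iterable[VariantRecord], genome: Mapping[str, str]
) -> list[VariantRecord]:
    """Split multiallelics, left-align each output, and sort by position."""
    out: list[VariantRecord] = []
    for rec in records:
        for bi in split_multiallelic(rec):
            out.append(left_align_and_trim(bi, genome[bi.chrom]))
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(r.chrom for r in out))}
    out.sort(key=lambda r: (chrom_order[r.chrom], r.pos, r.ref, r.alt))
    return out


def _check_sorted(records: Sequence[VariantRecord]) -> None:
    seen_done: set[str] = set()
    prev_chrom = None
    prev_pos = 0
    for r in records:
        if r.chrom != prev_chrom:
            if r.chrom in seen_done:
                raise OrderingError(f"chromosome {r.chrom} appears out of order")
            if prev_chrom is not None:
                seen_done.add(prev_chrom)
            prev_chrom, prev_pos = r.chrom, r.pos
        elif r.pos < prev_pos:
            raise OrderingError(
                f"record {r.chrom}:{r.pos} out of order after position {prev_pos}"
            )
        else:
            prev_pos = r.pos
    return None


def apply_site_filters(
    records: Sequence[VariantRecord],
    fs_max: float = DEFAULT_FS_MAX,
    qd_min: float = DEFAULT_QD_MIN,
    cluster_count: int = DEFAULT_CLUSTER_COUNT,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
) -> list[VariantRecord]:
    """Flag records failing the FS, QD and SNP-cluster site filters.

    Boundaries are strict, as printed in the filter expressions: FS exactly
    ``fs_max`` and QD exactly ``qd_min`` PASS. An SNV is flagged
    "SnpCluster" when it belongs to any run of ``cluster_count``
    consecutive SNVs (per chromosome, indels ignored) whose first-to-last
    span is <= ``cluster_window`` bases. Records missing FS or QD skip
    that rule (GATK convention) with a logged warning. Input must be
    sorted; non-flagged records are returned unmodified.
    """
    _check_sorted(records)
    out = [replace(r, filter_flags=set(r.filter_flags)) for r in records]
    for r in out:
        fs = r.info.get("FS")
        if fs is None:
            log.warning("no FS annotation at %s:%d; FS filter skipped", r.chrom, r.pos)
        elif float(fs) > fs_max:
            r.filter_flags.add("FS")
        qd = r.info.get("QD")
        if qd is None:
            log.warning("no QD annotation at %s:%d; QD filter skipped", r.chrom, r.pos)
        elif float(qd) < qd_min:
            r.filter_flags.add("QD")

    by_chrom: dict[str, list[VariantRecord]] = {}
    for r in out:
        if r.is_snv:
            by_chrom.setdefault(r.chrom, []).append(r)
    for snvs in by_chrom.values():
        for i in range(len(snvs) - cluster_count + 1):
            window = snvs[i : i + cluster_count]
            if window[-1].pos - window[0].pos <= cluster_window:
                for r in window:
                    r.filter_flags.add("SnpCluster")
    return out


# ---------------------------------------------------------------------------
# VCF I/O (pysam)

_INFO_DEFS = [
    ("FS", "1", "Float", "Phred-scaled p-value using Fisher's exact test for strand bias"),
    ("QD", "1", "Float", "Variant confidence normalized by depth"),
    ("DP", "1", "Integer", "Approximate read depth at the site"),
]

_FILTER_DEFS = [
    ("FS", "FS > 30.0"),
    ("QD", "QD < 2.0"),
    ("SnpCluster", "SNVs found in clusters"),
]


def build_vcf_header(contigs: Mapping[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    for ident, number, vtype, desc in _INFO_DEFS:
        header.add_meta(
            "INFO",
            items=[("ID", ident), ("Number", number), ("Type", vtype), ("Description", desc)],
        )
    for ident, desc in _FILTER_DEFS:
        header.add_meta("FILTER", items=[("ID", ident), ("Description", desc)])
    return header


def write_vcf(path, records: Iterable[VariantRecord], contigs: Mapping[str, int]) -> None:
    header = build_vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for r in records:
            rec = vf.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, *r.alts)
            )
            for k, v in r.info.items():
                rec.info[k] = v
            if r.filter_flags:
                for f in sorted(r.filter_flags):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            vf.write(rec)


def read_vcf(path) -> list[VariantRecord]:
    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = {}
            for k in rec.info:
                v = rec.info[k]
                if isinstance(v, tuple) and len(v) == 1:
                    v = v[0]
                info[k] = v
            flags = set(rec.filter.keys()) - {"PASS"}
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=list(rec.alts or ()),
                    info=info,
                    filter_flags=flags,
                )
            )
    return out


def read_contigs(path) -> dict[str, int]:
    """Contig names and lengths from a VCF header."""
    with pysam.VariantFile(str(path)) as vf:
        return {name: c.length for name, c in vf.header.contigs.items()}
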