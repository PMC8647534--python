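"""Independent reference implementations used to check the package.

These deliberately take different computational routes from the library:
exhaustive enumeration for indel normalization, genome-level mutation plus
coordinate shifting for consequences, and naive counting for percentile
ranks and SNP clusters.
"""

from __future__ import annotations

from Bio.Seq import Seq


def brute_force_normalize(pos: int, ref: str, alt: str, seq: str):
    """Minimum-position parsimonious representation via exhaustive search.

    Enumerates every (position, ref-length) pair that reproduces the same
    alternate haplotype, keeps the parsimonious ones (no shared trailing
    base unless pinned at the contig start, no trimmable leading base),
    and returns the smallest position.
    """
    mutated = seq[: pos - 1] + alt + seq[pos - 1 + len(ref) :]
    delta = len(alt) - len(ref)
    best = None
    for p in range(1, len(seq) + 1):
        if seq[: p - 1] != mutated[: p - 1]:
            break  # a differing prefix can never be reproduced
        for lr in range(1, len(seq) - p + 2):
            la = lr + delta
            if la < 1:
                continue
            r = seq[p - 1 : p - 1 + lr]
            a = mutated[p - 1 : p - 1 + la]
            if seq[: p - 1] + a + seq[p - 1 + lr :] != mutated:
                continue
            if r == a:
                continue
            if r[-1] == a[-1] and (len(r) > 1 or len(a) > 1):
                if not (p == 1 and (len(r) == 1 or len(a) == 1)):
                    continue
            if len(r) > 1 and len(a) > 1 and r[0] == a[0]:
                continue
            if best is None or p < best[0]:
                best = (p, r, a)
    return best


def _extract_cds(chrom_seq: str, segments, strand: str) -> str:
    seq = "".join(chrom_seq[s - 1 : e] for s, e in sorted(segments))
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def _translate(seq: str) -> str:
    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def oracle_consequence(variant, transcript, genome):
    """Classify by mutating the whole chromosome and re-extracting the CDS.

    The variant's reference bases must all lie in one CDS segment. Returns
    (classification, protein_position, ref_aa, alt_aa); the last three are
    None for indels.
    """
    s = genome[transcript.chrom]
    p, ref, alt = variant.pos, variant.ref, variant.alt
    delta = len(alt) - len(ref)
    mutated = s[: p - 1] + alt + s[p - 1 + len(ref) :]
    new_segments = []
    for s0, e0 in transcript.cds_segments:
        if e0 < p:
            new_segments.append((s0, e0))
        elif s0 <= p:
            new_segments.append((s0, e0 + delta))
        else:
            new_segments.append((s0 + delta, e0 + delta))
    cds_ref = _extract_cds(s, transcript.cds_segments, transcript.strand)
    cds_alt = _extract_cds(mutated, new_segments, transcript.strand)
    if delta % 3 != 0:
        return ("frameshift", None, None, None)
    if delta != 0:
        return ("inframe_indel", None, None, None)
    prot_ref = _translate(cds_ref)
    prot_alt = _translate(cds_alt)
    diffs = [i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b]
    if not diffs:
        # locate the affected codon for the synonymous position report
        changed = next(
            i for i, (a, b) in enumerate(zip(cds_ref, cds_alt)) if a != b
        )
        idx = changed // 3
        return ("synonymous", idx + 1, prot_ref[idx], prot_ref[idx])
    if len(diffs) == 1:
        i = diffs[0]
        ra, aa = prot_ref[i], prot_alt[i]
        if aa == "*":
            cls = "stop_gained"
        elif ra == "*":
            cls = "stop_lost"
        else:
            cls = "missense"
        return (cls, i + 1, ra, aa)
    return ("inframe_indel", diffs[0] + 1, prot_ref[diffs[0]], prot_alt[diffs[0]])


def brute_force_rank(raw: float, background) -> float:
    """Mid-rank percentile by naive counting."""
    n_gt = sum(1 for b in background if b > raw)
    n_eq = sum(1 for b in background if b == raw)
    return 100.0 * (n_gt + 0.5 * n_eq + 0.5) / (len(background) + 1)


def brute_force_cluster_flags(positions, count: int, window: int) -> set[int]:
    """Positions flagged by the SNP-cluster rule, by scanning every run."""
    ps = sorted(positions)
    flagged: set[int] = set()
    for i in range(len(ps)):
        for j in range(i + count - 1, len(ps)):
            if ps[j] - ps[i] <= window:
                flagged.update(ps[i : j + 1])
    return flagged


def mirror_construction(chrom_seq: str, transcript, variant):
    """Strand-mirrored genome, transcript and variant.

    Reverse-complements the chromosome, mirrors the CDS segments and flips
    the strand; protein-level consequences must be identical.
    """
    from neoforge.consequence import TranscriptModel, revcomp
    from neoforge.vcf_ops import VariantRecord

    length = len(chrom_seq)
    mirrored_seq = revcomp(chrom_seq)
    segs = [(length - e + 1, length - s + 1) for s, e in transcript.cds_segments]
    flipped = "-" if transcript.strand == "+" else "+"
    m_t = TranscriptModel(
        transcript.transcript_id, transcript.gene_id, transcript.chrom,
        flipped, sorted(segs),
    )
    var_end = variant.pos + len(variant.ref) - 1
    m_var = VariantRecord(
        variant.chrom,
        length - var_end + 1,
        revcomp(variant.ref),
        [revcomp(variant.alt)],
    )
    return mirrored_seq, m_t, m_var
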