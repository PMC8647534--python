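"""RNA-seq expression support for exome-derived somatic variants.

A somatic variant is carried forward only if it (a) is PASS, (b) has at
least one non-synonymous consequence, and (c) was independently called in
the RNA-seq data at the same normalized (chrom, pos, ref, alt) key with a
read depth of at least 4 — variant expression evidence, not mere site
coverage. Only PASS RNA records count as evidence, since site filtering of
the RNA calls precedes the intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .consequence import NONSYNONYMOUS, ProteinConsequence
from .errors import MissingAnnotationError
from .vcf_ops import VariantRecord

log = logging.getLogger("neoforge")

DEFAULT_MIN_DEPTH = 4


@dataclass
class SupportedVariant:
    """A non-synonymous somatic variant with RNA-seq expression evidence."""

    variant: VariantRecord
    rna_depth: int
    consequences: list[ProteinConsequence]


def intersect_with_rna(
    somatic: Sequence[VariantRecord],
    rna: Sequence[VariantRecord],
    min_depth: int = DEFAULT_MIN_DEPTH,
    require_pass_rna: bool = True,
) -> list[SupportedVariant]:
    """Retain PASS non-synonymous somatic variants seen in RNA at depth >= min.

    Matching is on the full normalized key; depth is read from the RNA
    record's INFO/DP (inclusive at ``min_depth``). Output preserves somatic
    input order.
    """
    rna_depth_by_key: dict[tuple, int] = {}
    for r in rna:
        if "DP" not in r.info:
            raise MissingAnnotationError(
                f"RNA record {r.chrom}:{r.pos} {r.ref}>{r.alts} has no DP annotation"
            )
        if require_pass_rna and not r.is_pass:
            log.info(
                "drop RNA evidence %s:%d %s>%s: flagged %s",
                r.chrom, r.pos, r.ref, r.alt, ",".join(sorted(r.filter_flags)),
            )
            continue
        rna_depth_by_key[r.key] = int(r.info["DP"])

    out: list[SupportedVariant] = []
    for v in somatic:
        if not v.is_pass:
            log.info("drop somatic %s:%d: non-PASS", v.chrom, v.pos)
            continue
        if not any(c.classification in NONSYNONYMOUS for c in v.consequences):
            log.info("drop somatic %s:%d: no non-synonymous consequence", v.chrom, v.pos)
            continue
        dp = rna_depth_by_key.get(v.key)
        if dp is None:
            log.info("drop somatic %s:%d: no RNA evidence", v.chrom, v.pos)
            continue
        if dp < min_depth:
            log.info("drop somatic %s:%d: RNA depth %d < %d", v.chrom, v.pos, dp, min_depth)
            continue
        out.append(SupportedVariant(v, dp, list(v.consequences)))
    return out
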