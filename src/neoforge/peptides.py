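"""Mutant k-mer enumeration and his-tagged construct assembly.

For every supported missense, the mutated residue is tiled through each of
the k positions of a k-mer window (offsets 1..k), yielding up to k candidate
peptides per variant; windows that would run past either protein terminus
are omitted. Each candidate carries its wild-type counterpart, which differs
at exactly the mutated position. Selected peptides gain an N-terminal
tri-histidine tag for particle formation (cobalt-porphyrin binding).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import AlphabetError, CoordinateError, NeoforgeError

DEFAULT_K = 9
DEFAULT_TAG_LENGTH = 3

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PeptideWindow:
    """One mutant k-mer and its wild-type counterpart.

    ``mutation_offset`` is the 1-based position of the substituted residue
    within the window; ``protein_position`` indexes the residue in the full
    protein.
    """

    mutant_sequence: str
    wild_type_sequence: str
    mutation_offset: int
    protein_position: int
    source_variant: str = ""
    source_transcript: str = ""

    def __post_init__(self) -> None:
        if len(self.mutant_sequence) != len(self.wild_type_sequence):
            raise ValueError("mutant and wild-type windows must have equal length")
        diffs = [
            i
            for i, (a, b) in enumerate(zip(self.mutant_sequence, self.wild_type_sequence))
            if a != b
        ]
        if diffs != [self.mutation_offset - 1]:
            raise ValueError(
                "windows must differ exactly at mutation_offset "
                f"(offset {self.mutation_offset}, diffs at {[d + 1 for d in diffs]})"
            )


@dataclass(frozen=True)
class Construct:
    """A vaccine-ready peptide: N-terminal his-tag + mutant window."""

    peptide: PeptideWindow
    tag_length: int
    sequence: str


def mutant_windows(
    protein_wt: str,
    position: int,
    alt_aa: str,
    k: int = DEFAULT_K,
    source_variant: str = "",
    source_transcript: str = "",
) -> list[PeptideWindow]:
    """Enumerate the k-mer windows containing the substituted residue.

    One window per offset o in 1..k whose span [position-o+1, position-o+k]
    lies fully within the protein; ordered by increasing offset. Interior
    positions yield exactly k windows; positions near a terminus fewer.
    """
    if not 1 <= position <= len(protein_wt):
        raise CoordinateError(
            f"position {position} outside protein of length {len(protein_wt)}"
        )
    if alt_aa not in STANDARD_AA:
        raise AlphabetError(f"non-standard substituting residue {alt_aa!r}")
    if protein_wt[position - 1] == alt_aa:
        raise NeoforgeError(
            f"residue at position {position} already {alt_aa}; not a substitution"
        )
    windows = []
    for offset in range(1, k + 1):
        start = position - offset + 1  # 1-based window start
        if start < 1 or start + k - 1 > len(protein_wt):
            continue
        wt = protein_wt[start - 1 : start - 1 + k]
        mut = wt[: offset - 1] + alt_aa + wt[offset:]
        windows.append(
            PeptideWindow(
                mutant_sequence=mut,
                wild_type_sequence=wt,
                mutation_offset=offset,
                protein_position=position,
                source_variant=source_variant,
                source_transcript=source_transcript,
            )
        )
    return windows


def his_tag(peptide: PeptideWindow, tag_length: int = DEFAULT_TAG_LENGTH) -> Construct:
    """Prepend ``tag_length`` histidines to the mutant window."""
    if not peptide.mutant_sequence:
        raise NeoforgeError("cannot tag an empty peptide")
    if tag_length < 0:
        raise ValueError("tag_length must be >= 0")
    return Construct(
        peptide=peptide,
        tag_length=tag_length,
        sequence="H" * tag_length + peptide.mutant_sequence,
    )
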