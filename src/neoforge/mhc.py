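"""MHC-I binding rank prediction and top-percentile candidate selection.

Candidate 9-mers are scored against each allele of the host's MHC class I
set (BALB/c: H-2Kd, H-2Dd, H-2Ld) and converted to percentile ranks against
a large background of random natural-frequency peptides: rank 0.1 means the
query scores in the top 0.1% of the background for that allele (smaller =
stronger, the %Rank convention of NetMHC-family predictors). Candidates
whose best rank across the allele set is at or below the cutoff (default
0.1) are selected.

The built-in predictor is a position-weight-matrix (PSSM) scorer with
fixed, deterministic background calibration — a desk-scale predictor with
the same rank-percentile interface as NetMHC. Output from an external
NetMHC-4.0 run can be parsed instead, so the selection stage is predictor
agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import AlphabetError, CalibrationError, CoverageError, FormatError

#: residue alphabet, alphabetical single-letter order; matrix column order
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: natural amino-acid background frequencies (Robinson & Robinson), in
#: AA_ALPHABET order, normalized to sum exactly to 1
_RAW_BG = np.array(
    [0.078, 0.019, 0.054, 0.063, 0.039, 0.074, 0.022, 0.051, 0.057, 0.091,
     0.022, 0.045, 0.052, 0.043, 0.051, 0.071, 0.058, 0.066, 0.013, 0.032]
)
BACKGROUND_FREQS = _RAW_BG / _RAW_BG.sum()

DEFAULT_K = 9
DEFAULT_CUTOFF = 0.1
DEFAULT_N_BACKGROUND = 100_000

#: per-allele seeds for the shipped synthetic profiles (fixed constants,
#: independent of any run seed, so profiles are identical across runs)
DEFAULT_ALLELE_SEEDS = {"H-2Kd": 20101, "H-2Dd": 20103, "H-2Ld": 20107}

#: extra spread at the canonical MHC-I anchor positions (2 and C-terminus)
ANCHOR_SCALE = 2.0


@dataclass
class AlleleProfile:
    """A per-allele PSSM plus its calibrated score background.

    ``position_weights`` is a k x 20 log-odds matrix in AA_ALPHABET column
    order; ``background_scores`` holds the sorted raw scores of the
    calibration peptides.
    """

    allele_name: str
    position_weights: np.ndarray
    calibration_seed: int
    background_scores: np.ndarray | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.position_weights.shape[0]

    @classmethod
    def synthetic(
        cls,
        allele_name: str,
        seed: int,
        k: int = DEFAULT_K,
        anchor_scale: float = ANCHOR_SCALE,
        n_background: int = DEFAULT_N_BACKGROUND,
    ) -> "AlleleProfile":
        """Deterministic synthetic profile with anchor-position emphasis."""
        rng = np.random.default_rng(seed)
        weights = rng.normal(0.0, 1.0, size=(k, 20))
        weights[1] *= anchor_scale
        weights[k - 1] *= anchor_scale
        profile = cls(allele_name, weights, calibration_seed=seed + 500_000)
        profile.calibrate(n_background)
        return profile

    def calibrate(self, n: int = DEFAULT_N_BACKGROUND) -> None:
        """Score ``n`` random background peptides and store the sorted scores."""
        rng = np.random.default_rng(self.calibration_seed)
        idx = rng.choice(20, size=(n, self.k), p=BACKGROUND_FREQS)
        scores = self.position_weights[np.arange(self.k), idx].sum(axis=1)
        self.background_scores = np.sort(scores)


def score(peptide: str, profile: AlleleProfile) -> float:
    """Positional sum of log-odds weights for a length-k peptide."""
    if len(peptide) != profile.k:
        raise AlphabetError(
            f"peptide length {len(peptide)} != profile k {profile.k}"
        )
    try:
        idx = [AA_INDEX[a] for a in peptide]
    except KeyError as exc:
        raise AlphabetError(f"non-standard residue {exc.args[0]!r} in {peptide}") from exc
    return float(profile.position_weights[np.arange(profile.k), idx].sum())


def percentile_rank(raw: float, profile: AlleleProfile) -> float:
    """Mid-rank percentile of a raw score against the calibrated background.

    rank = 100 * (n_greater + 0.5 * n_equal + 0.5) / (N + 1); strictly
    decreasing in the raw score over distinct values, never exactly 0.
    """
    bg = profile.background_scores
    if bg is None:
        raise CalibrationError(f"profile {profile.allele_name} is not calibrated")
    n = len(bg)
    n_le = int(np.searchsorted(bg, raw, side="right"))
    n_lt = int(np.searchsorted(bg, raw, side="left"))
    n_gt = n - n_le
    n_eq = n_le - n_lt
    return 100.0 * (n_gt + 0.5 * n_eq + 0.5) / (n + 1)


@lru_cache(maxsize=None)
def default_alleles() -> tuple[AlleleProfile, ...]:
    """The three calibrated BALB/c class-I profiles (H-2Kd, H-2Dd, H-2Ld)."""
    return tuple(
        AlleleProfile.synthetic(name, seed)
        for name, seed in DEFAULT_ALLELE_SEEDS.items()
    )


def get_profiles(names: Iterable[str] | None = None) -> list[AlleleProfile]:
    if names is None:
        return list(default_alleles())
    by_name = {p.allele_name: p for p in default_alleles()}
    out = []
    for name in names:
        if name in by_name:
            out.append(by_name[name])
        elif name in DEFAULT_ALLELE_SEEDS:
            out.append(AlleleProfile.synthetic(name, DEFAULT_ALLELE_SEEDS[name]))
        else:
            raise KeyError(f"no shipped profile for allele {name!r}")
    return out


@dataclass
class BindingResult:
    """Per-allele scores and ranks for one peptide, with the best aggregate."""

    peptide: str
    per_allele: dict[str, tuple[float, float]]  # allele -> (raw, rank)
    best_rank: float
    best_allele: str
    source_variant: str = ""
    window: object | None = None


def rank_peptide(peptide: str, profiles: Sequence[AlleleProfile], **meta) -> BindingResult:
    per_allele = {}
    for p in profiles:
        raw = score(peptide, p)
        per_allele[p.allele_name] = (raw, percentile_rank(raw, p))
    best_allele = min(per_allele, key=lambda a: per_allele[a][1])
    return BindingResult(
        peptide=peptide,
        per_allele=per_allele,
        best_rank=per_allele[best_allele][1],
        best_allele=best_allele,
        **meta,
    )


def rank_peptides(
    peptides: Iterable[str], profiles: Sequence[AlleleProfile]
) -> list[BindingResult]:
    return [rank_peptide(p, profiles) for p in peptides]


def select_candidates(
    results: Sequence[BindingResult],
    cutoff: float = DEFAULT_CUTOFF,
    require_all: bool = False,
    select_mode: str = "rank-cutoff",
) -> list[BindingResult]:
    """Top-percentile candidates, sorted by ascending best rank.

    Default: retain results with best_rank <= cutoff (inclusive), ties
    broken lexicographically by peptide. ``require_all`` demands
    rank <= cutoff for every allele. ``select_mode='list-quantile'``
    instead keeps the top cutoff% of the candidate list itself.
    """
    if results:
        allele_sets = {frozenset(r.per_allele) for r in results}
        if len(allele_sets) != 1:
            raise CoverageError("binding results cover inconsistent allele sets")
    ordered = sorted(results, key=lambda r: (r.best_rank, r.peptide))
    if select_mode == "list-quantile":
        n_keep = int(np.ceil(len(ordered) * cutoff / 100.0))
        return ordered[:n_keep]
    if select_mode != "rank-cutoff":
        raise ValueError(f"unknown select_mode {select_mode!r}")
    if require_all:
        return [
            r for r in ordered if max(rank for _, rank in r.per_allele.values()) <= cutoff
        ]
    return [r for r in ordered if r.best_rank <= cutoff]


# ---------------------------------------------------------------------------
# profile plain-text format

def write_profile(path, profile: AlleleProfile) -> None:
    """Plain-text matrix: header comments, then k rows x 20 columns."""
    with open(path, "w") as fh:
        fh.write(f"# allele: {profile.allele_name}\n")
        fh.write(f"# k: {profile.k}\n")
        fh.write(f"# alphabet: {AA_ALPHABET}\n")
        fh.write(f"# calibration_seed: {profile.calibration_seed}\n")
        for row in profile.position_weights:
            fh.write("\t".join(f"{w:.8g}" for w in row) + "\n")


def read_profile(path, n_background: int = DEFAULT_N_BACKGROUND) -> AlleleProfile:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                rows.append([float(x) for x in line.split()])
    weights = np.array(rows)
    if weights.ndim != 2 or weights.shape[1] != 20:
        raise FormatError("profile matrix must have 20 columns")
    profile = AlleleProfile(
        allele_name=meta.get("allele", "unknown"),
        position_weights=weights,
        calibration_seed=int(meta.get("calibration_seed", 0)),
    )
    profile.calibrate(n_background)
    return profile


# ---------------------------------------------------------------------------
# NetMHC-4.0 tabular interoperability

def parse_netmhc_output(text: str) -> dict[str, tuple[str, float]]:
    """Map peptide -> (allele, %Rank) from NetMHC-4.0 style tabular text.

    Comment lines (#), separator rules (----) and repeated headers are
    skipped; a peptide listed for several alleles keeps its best (lowest)
    rank. Raises FormatError if no %Rank column header is present.
    """
    header: list[str] | None = None
    rank_col = pep_col = allele_col = -1
    out: dict[str, tuple[str, float]] = {}
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith("#") or set(s) <= {"-"}:
            continue
        toks = s.split()
        if "%Rank" in toks:
            header = toks
            rank_col = toks.index("%Rank")
            pep_col = next(
                (i for i, t in enumerate(toks) if t.lower() == "peptide"), -1
            )
            allele_col = next(
                (i for i, t in enumerate(toks) if t.lower() in ("hla", "mhc", "allele")),
                -1,
            )
            if pep_col < 0:
                raise FormatError("NetMHC-4.0 dialect: no Peptide column in header")
            continue
        if header is None:
            continue  # preamble before the header
        if len(toks) <= rank_col:
            continue
        peptide = toks[pep_col]
        allele = toks[allele_col] if allele_col >= 0 else "."
        try:
            rank = float(toks[rank_col])
        except ValueError:
            continue
        if peptide not in out or rank < out[peptide][1]:
            out[peptide] = (allele, rank)
    if header is None:
        raise FormatError(
            "no %Rank column found; expected NetMHC-4.0 whitespace-delimited table"
        )
    return out


def write_netmhc_table(entries: Mapping[str, tuple[str, float]]) -> str:
    """Emit a minimal NetMHC-4.0 style table (round-trips through the parser)."""
    lines = [
        "# neoforge predictions, NetMHC-4.0 tabular dialect",
        "-" * 50,
        " pos HLA Peptide Score %Rank",
        "-" * 50,
    ]
    for i, (peptide, (allele, rank)) in enumerate(entries.items()):
        lines.append(f" {i} {allele} {peptide} 0.0 {rank:g}")
    lines.append("-" * 50)
    return "\n".join(lines) + "\n"
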