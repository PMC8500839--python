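"""Density-guided light-chain identification.

At intermediate cryo-EM resolution a subunit can be traced as a poly(Ala)
backbone whose side-chain densities are readable only as coarse size classes.
Each residue position is assigned one of four classes — large (W, Y, R, F, H),
middle (L, Q, N, I, M, K), small (P, V, S, T, C, E, D, A; the acidic residues
sit here because negatively charged side chains image weakly) and glycine —
plus a wildcard ``X`` for uninterpretable positions.  The class string is
matched against candidate sequences with regular-expression semantics, every
ungapped placement of a candidate is scored by counting positions whose
residue class contradicts the density (the penalty), and a candidate counts
as identified only if (1) it is a significant mass-spectrometry hit, (2) its
side chains match the density, and (3) no other homolog scores better.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "SizeClassMap",
    "DEFAULT_SIZE_CLASSES",
    "DensityPattern",
    "CandidateScore",
    "IdentificationStatus",
    "IdentificationResult",
    "classify_residues",
    "compile_pattern",
    "search_proteome",
    "penalty_score",
    "best_window_score",
    "rank_candidates",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
PATTERN_ALPHABET = "LMSGX"


@dataclass(frozen=True)
class SizeClassMap:
    """Residue → size-class table over the 20 standard amino acids."""

    classes: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = set(STANDARD_RESIDUES) - set(self.classes)
        if missing:
            raise ValueError(f"size-class map misses residues: {sorted(missing)}")
        bad = {c for c in self.classes.values() if c not in "LMSG"}
        if bad:
            raise ValueError(f"invalid class symbols: {sorted(bad)}")

    def residues_of(self, symbol: str) -> str:
        """All residues belonging to one class symbol (X = every residue)."""
        if symbol == "X":
            return STANDARD_RESIDUES
        return "".join(r for r in STANDARD_RESIDUES if self.classes[r] == symbol)


DEFAULT_SIZE_CLASSES = SizeClassMap(
    classes={
        **{r: "L" for r in "WYRFH"},
        **{r: "M" for r in "LQNIMK"},
        **{r: "S" for r in "PVSTCEDA"},
        "G": "G",
    }
)


@dataclass(frozen=True)
class DensityPattern:
    """String over {L, M, S, G, X}; X marks uninterpretable density."""

    symbols: str

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("pattern must be non-empty")
        bad = set(self.symbols) - set(PATTERN_ALPHABET)
        if bad:
            raise ValueError(f"pattern symbols outside {PATTERN_ALPHABET}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class CandidateScore:
    record_id: str
    offset: int
    penalty: int
    pattern_length: int
    ms_hit: bool = False


class IdentificationStatus(str, Enum):
    IDENTIFIED = "identified"
    AMBIGUOUS_TIE = "ambiguous_tie"
    NO_MS_HIT = "no_ms_hit"
    NO_MATCH = "no_match"


@dataclass(frozen=True)
class IdentificationResult:
    status: IdentificationStatus
    winner: Optional[CandidateScore]
    runner_up_penalty: Optional[int]


def classify_residues(sequence: str, size_map: SizeClassMap = DEFAULT_SIZE_CLASSES) -> str:
    """Substitute every residue by its size-class symbol."""
    out = []
    for i, r in enumerate(sequence.upper()):
        cls = size_map.classes.get(r)
        if cls is None:
            raise ValueError(f"non-standard residue {r!r} at position {i}")
        out.append(cls)
    return "".join(out)


def compile_pattern(
    pattern: DensityPattern, size_map: SizeClassMap = DEFAULT_SIZE_CLASSES
) -> re.Pattern:
    """Compile a density pattern into a regex over amino-acid strings.

    Each class symbol becomes the character class of its residues; X matches
    any standard residue.  The regex is wrapped in a lookahead so overlapping
    occurrences are all found.
    """
    parts = []
    for sym in pattern.symbols:
        residues = size_map.residues_of(sym)
        parts.append(residues if len(residues) == 1 else f"[{residues}]")
    return re.compile("(?=(" + "".join(parts) + "))")


def search_proteome(
    pattern: DensityPattern,
    proteome: Iterable[tuple[str, str]],
    size_map: SizeClassMap = DEFAULT_SIZE_CLASSES,
) -> list[tuple[str, int]]:
    """All zero-penalty occurrences of the pattern, overlaps included.

    ``proteome`` yields (record_id, sequence) pairs, e.g. from Bio.SeqIO.
    """
    rx = compile_pattern(pattern, size_map)
    hits = []
    for record_id, seq in proteome:
        for m in rx.finditer(str(seq).upper()):
            hits.append((record_id, m.start()))
    return hits


def penalty_score(
    candidate: str,
    offset: int,
    pattern: DensityPattern,
    size_map: SizeClassMap = DEFAULT_SIZE_CLASSES,
) -> int:
    """Count of positions whose residue class contradicts the density pattern.

    X positions are uninterpretable density and contribute nothing.
    """
    window = candidate.upper()[offset : offset + len(pattern)]
    if offset < 0 or len(window) < len(pattern):
        raise ValueError("window out of range for this candidate")
    classes = classify_residues(window, size_map)
    return sum(
        1 for sym, cls in zip(pattern.symbols, classes) if sym != "X" and cls != sym
    )


def best_window_score(
    record_id: str,
    candidate: str,
    pattern: DensityPattern,
    size_map: SizeClassMap = DEFAULT_SIZE_CLASSES,
    ms_hit: bool = False,
) -> Optional[CandidateScore]:
    """Minimal penalty over all ungapped placements (smallest offset on ties).

    Returns None when the candidate is shorter than the pattern.
    """
    n = len(candidate)
    plen = len(pattern)
    if n < plen:
        return None
    best_pen, best_off = None, 0
    for off in range(n - plen + 1):
        pen = penalty_score(candidate, off, pattern, size_map)
        if best_pen is None or pen < best_pen:
            best_pen, best_off = pen, off
            if pen == 0:
                break
    return CandidateScore(
        record_id=record_id,
        offset=best_off,
        penalty=int(best_pen),
        pattern_length=plen,
        ms_hit=ms_hit,
    )


def rank_candidates(
    scores: Sequence[CandidateScore], ms_hits: set[str]
) -> IdentificationResult:
    """Apply the three identification criteria to scored candidates.

    Identified only if the unique minimal-penalty candidate is a
    mass-spectrometry hit and strictly beats every other candidate; equal
    minimal penalties give an ambiguous tie, and a best candidate without MS
    support is reported as such.
    """
    scores = [s for s in scores if s is not None]
    if not scores:
        return IdentificationResult(IdentificationStatus.NO_MATCH, None, None)
    ordered = sorted(scores, key=lambda s: (s.penalty, s.record_id, s.offset))
    best = ordered[0]
    runner_up = ordered[1].penalty if len(ordered) > 1 else None
    best = CandidateScore(
        record_id=best.record_id,
        offset=best.offset,
        penalty=best.penalty,
        pattern_length=best.pattern_length,
        ms_hit=best.record_id in ms_hits,
    )
    if runner_up is not None and runner_up == best.penalty:
        return IdentificationResult(IdentificationStatus.AMBIGUOUS_TIE, best, runner_up)
    if not best.ms_hit:
        return IdentificationResult(IdentificationStatus.NO_MS_HIT, best, runner_up)
    return IdentificationResult(IdentificationStatus.IDENTIFIED, best, runner_up)
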