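"""Local alignment screen for probe cross-hybridization.

Probes (~60 nt) are aligned against genomic flanks or exon sequences with
Smith-Waterman scoring: match +10, mismatch 0, and an affine gap cost of
250 + 100 per gapped base (from the quoted flags: gap open -250, gap
extend -100). A probe "maps" when its best local score reaches 30% of the
maximum attainable (10 x probe length). Both the target and its reverse
complement are scanned by default, since a probe can hybridize either
strand; ``N`` never matches.

The dynamic programming engine is Bio.Align.PairwiseAligner; the affine
convention above maps to open_gap_score = -(250 + 100) for the first
gapped base and extend_gap_score = -100 thereafter.

Because mismatches cost nothing, an *unrestricted* local alignment
accumulates chance matches for free and any 60-nt probe reaches 30% of
the maximal score against essentially any target of comparable length —
random sequence included. The published screens behaved sensibly only
because the original read mapper evaluates alignments around exact
spaced-seed hits. The flank/exon screens here therefore anchor the DP on
shared exact k-mers (default k = 14): a probe maps only where it shares
a perfect 14-mer with the target (either strand) and the local alignment
around that anchor reaches the score threshold. ``smith_waterman``
itself stays a pure, unanchored DP.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

ALPHABET = "ACGTN"

MATCH = 10
MISMATCH = 0
GAP_OPEN = -250
GAP_EXTEND = -100
MIN_FRACTION = 0.30

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _clean(seq: str) -> str:
    s = seq.upper()
    return "".join(c if c in ALPHABET else "N" for c in s)


@lru_cache(maxsize=32)
def _aligner(match: int, mismatch: int, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    matrix = substitution_matrices.Array(ALPHABET, dims=2)
    for a in ALPHABET:
        for b in ALPHABET:
            matrix[a, b] = match if (a == b and a != "N") else mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # a length-L gap costs |gap_open| + L*|gap_extend|
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    score: int
    max_possible: int
    fraction: float
    mapped: bool


def smith_waterman(
    probe: str,
    target: str,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
    min_fraction: float = MIN_FRACTION,
    both_strands: bool = True,
) -> AlignmentResult:
    """Best local alignment of a probe against a target sequence.

    Scans the target and (by default) its reverse complement, keeping the
    larger score. Empty sequences score 0 and never map.
    """
    probe = _clean(probe)
    target = _clean(target)
    max_possible = match * len(probe)
    if not probe or not target:
        return AlignmentResult(0, max_possible, 0.0, False)
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    score = aligner.score(target, probe)
    if both_strands:
        score = max(score, aligner.score(reverse_complement(target), probe))
    score = int(round(score))
    fraction = score / max_possible if max_possible > 0 else 0.0
    return AlignmentResult(score, max_possible, fraction, fraction >= min_fraction)


SEED_LENGTH = 14


def _seed_positions(probe: str, target: str, k: int) -> list[int]:
    """Start positions in ``target`` sharing an exact k-mer with ``probe``."""
    if len(probe) < k or len(target) < k:
        return []
    kmers = {probe[i : i + k] for i in range(len(probe) - k + 1)}
    kmers = {m for m in kmers if "N" not in m}
    return [j for j in range(len(target) - k + 1) if target[j : j + k] in kmers]


def seeded_mapped(
    probe_seq: str,
    target_seq: str,
    seed_length: int = SEED_LENGTH,
    min_fraction: float = MIN_FRACTION,
    both_strands: bool = True,
    **scoring,
) -> bool:
    """Seed-anchored cross-hybridization decision.

    The probe maps when it shares an exact ``seed_length``-mer with the
    target (forward or reverse-complement strand) and the local alignment
    of the probe against a window around that seed reaches
    ``min_fraction`` of the maximal score.
    """
    probe = _clean(probe_seq)
    target = _clean(target_seq)
    if not probe or not target:
        return False
    pad = len(probe)
    for strand_seq in (target, reverse_complement(target)) if both_strands else (target,):
        for j in _seed_positions(probe, strand_seq, seed_length):
            window = strand_seq[max(j - pad, 0) : j + seed_length + pad]
            res = smith_waterman(
                probe, window, min_fraction=min_fraction, both_strands=False, **scoring
            )
            if res.mapped:
                return True
    return False


def probe_maps_to_flank(
    probe_seq: str,
    flank_seq: str,
    exclude: tuple[int, int] | None = None,
    seed_length: int = SEED_LENGTH,
    min_fraction: float = MIN_FRACTION,
    **scoring,
) -> bool:
    """Cross-hybridization screen of a probe against an eQTL flank sequence.

    ``exclude`` masks a 1-based inclusive interval of the flank (the
    probe's own annotated target, so a probe does not flag itself) by
    replacing it with N before alignment. Raises on a missing flank.
    """
    if flank_seq is None:
        raise ValueError("flank sequence is missing")
    flank = _clean(flank_seq)
    if exclude is not None:
        lo = max(exclude[0], 1)
        hi = min(exclude[1], len(flank))
        if lo <= hi:
            flank = flank[: lo - 1] + "N" * (hi - lo + 1) + flank[hi:]
    return seeded_mapped(
        probe_seq, flank, seed_length=seed_length, min_fraction=min_fraction, **scoring
    )
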