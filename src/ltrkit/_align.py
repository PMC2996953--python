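"""Shared pairwise-alignment helpers.

One DNA scheme and one protein scheme are used throughout the package so
detection, clustering and domain scoring stay mutually consistent:

* DNA, global: match +2, mismatch -3, gap open -5, gap extend -2
  (a gap of length L costs 5 + 2*(L-1)).
* Protein, local: BLOSUM62, gap open -11, gap extend -1.

Similarity/identity is always matches divided by alignment columns (gap
columns included), as a percentage.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "dna_global_aligner",
    "protein_local_aligner",
    "dna_similarity",
    "local_score",
    "local_score_and_identity",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=1)
def dna_global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -3.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -2.0
    return aligner


@lru_cache(maxsize=1)
def protein_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _alignment_identity(alignment) -> tuple[int, int]:
    """(matches, columns) of a Bio.Align.Alignment, counting gap columns."""
    counts = alignment.counts()  # gaps, identities, mismatches
    columns = alignment.length
    return counts.identities, columns


def dna_similarity(a: str, b: str) -> float:
    """Percent identity of the global alignment of two DNA strings,
    computed over all alignment columns (gaps included)."""
    if a == b:
        return 100.0
    alignment = dna_global_aligner().align(a, b)[0]
    matches, columns = _alignment_identity(alignment)
    return 100.0 * matches / columns


def local_score(peptide: str, reference: str) -> float:
    """Raw BLOSUM62 local-alignment score (fast path, no traceback)."""
    return float(protein_local_aligner().score(peptide, reference))


def local_score_and_identity(peptide: str, reference: str) -> tuple[float, float]:
    """Score and percent identity (over aligned columns) of the best local
    alignment of ``peptide`` against ``reference``."""
    alignment = protein_local_aligner().align(peptide, reference)[0]
    matches, columns = _alignment_identity(alignment)
    return float(alignment.score), 100.0 * matches / columns
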