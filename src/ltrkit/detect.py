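"""Candidate LTR-pair detection.

Direct-repeat mode finds the classic LTR pair at the two ends of an element;
inverted mode finds the proximal inverted repeats of DIRS-like elements (the
second copy is the reverse complement of the first).  Detection proceeds in
three stages:

1. exact seed matching (k = ``seed_length``) with the pair separation
   constrained to the configured element-length window,
2. chaining of collinear seeds into one anchor block per putative pair,
3. boundary refinement (ungapped extension under a windowed-identity rule,
   then snapping to the canonical TGT.../...ACA termini when present) and a
   global alignment of the two repeat copies.

Note that an inverted repeat of a TGT...ACA repeat unit again reads
TGT...ACA, so terminal-motif logic is shared between the two modes.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from collections import defaultdict, deque
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

from ._align import dna_similarity, revcomp
from .model import GenomeSequence, Interval, RepeatMode, ValidationError

logger = logging.getLogger(__name__)

Mode = Literal["direct", "inverted"]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class DetectionParams:
    """Tunable thresholds of the detector.

    Defaults target classic LTR retroelements; :meth:`dirs` returns the
    DIRS-mode variant (much shorter terminal repeats, narrower element-length
    window).  ``min_pair_similarity`` is a percent identity over alignment
    columns; flank-motif and TSD evidence are optional by default and can be
    made mandatory per run.
    """

    seed_length: int = 20
    min_ltr_len: int = 100
    max_ltr_len: int = 2000
    min_element_len: int = 3000
    max_element_len: int = 15000
    min_pair_similarity: float = 80.0
    require_flank_motif: bool = False
    require_tsd: bool = False
    tsd_len_range: tuple[int, int] = (4, 6)
    max_tsd_mismatch: int = 0
    # refinement knobs
    identity_window: int = 11
    identity_floor: float = 0.6
    motif_snap_window: int = 15
    # chaining knob: anchors within this diagonal drift are merged
    diag_tolerance: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.min_ltr_len < self.max_ltr_len):
            raise ValidationError("LTR length bounds must satisfy 0 < min < max")
        if not (0 < self.min_element_len < self.max_element_len):
            raise ValidationError("element length bounds must satisfy 0 < min < max")
        if not (0 < self.min_pair_similarity <= 100):
            raise ValidationError("min_pair_similarity must lie in (0, 100]")
        lo, hi = self.tsd_len_range
        if not (4 <= lo <= hi <= 6):
            raise ValidationError("tsd_len_range must lie within 4..6")

    @classmethod
    def dirs(cls, **overrides) -> "DetectionParams":
        base = dict(
            min_ltr_len=60,
            max_ltr_len=300,
            min_element_len=3500,
            max_element_len=6500,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_dict(cls, data: dict) -> "DetectionParams":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValidationError(f"unknown detection parameters: {sorted(bad)}")
        if "tsd_len_range" in data:
            data = dict(data)
            data["tsd_len_range"] = tuple(data["tsd_len_range"])
        return cls(**data)

    @property
    def separation_window(self) -> tuple[int, int]:
        """Allowed start-to-start seed separation for a genuine pair."""
        return (self.min_element_len - self.max_ltr_len, self.max_element_len)


@dataclass(frozen=True)
class AnchorBlock:
    """A chained run of exact seed matches: one putative LTR pair."""

    scaffold: str
    start1: int
    end1: int
    start2: int
    end2: int
    mode: RepeatMode
    n_seeds: int = 1


@dataclass(frozen=True)
class CandidatePair:
    """A refined, similarity-validated LTR pair (element body = outer bounds)."""

    scaffold: str
    ltr5: Interval
    ltr3: Interval
    similarity: float
    mode: RepeatMode
    flank_motif: Optional[str] = None
    tsd: Optional[str] = None

    @property
    def body(self) -> Interval:
        return Interval(self.scaffold, self.ltr5.start, self.ltr3.end)


def seed_hits(
    seq: str, params: DetectionParams, mode: Mode
) -> list[tuple[int, int]]:
    """All ordered exact seed matches (i, j), i < j, with separation j - i in
    the configured window.  In inverted mode the seed at j must equal the
    reverse complement of the seed at i.  Seeds containing N never match.
    """
    k = params.seed_length
    lo, hi = params.separation_window
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if "N" not in word:
            index[word].append(i)
    hits: list[tuple[int, int]] = []
    for word, positions in index.items():
        partner = revcomp(word) if mode == "inverted" else word
        targets = index.get(partner)
        if not targets:
            continue
        for i in positions:
            a = bisect_left(targets, i + lo)
            b = bisect_right(targets, i + hi)
            for j in targets[a:b]:
                if j > i:
                    hits.append((i, j))
    hits.sort()
    return hits


def chain_hits(
    hits: Sequence[tuple[int, int]],
    params: DetectionParams,
    mode: Mode,
    scaffold: str = "",
) -> list[AnchorBlock]:
    """Merge collinear seed hits into anchor blocks.

    Hits are collinear when their diagonals (j - i for direct repeats, i + j
    for inverted) drift by at most ``diag_tolerance`` and their i-coordinates
    are within ``max_ltr_len`` of each other.
    """
    if not hits:
        return []
    k = params.seed_length
    diag = (lambda h: h[0] + h[1]) if mode == "inverted" else (lambda h: h[1] - h[0])
    ordered = sorted(hits, key=lambda h: (diag(h), h[0]))
    blocks: list[AnchorBlock] = []
    cluster: list[tuple[int, int]] = []

    def flush() -> None:
        if not cluster:
            return
        i_lo = min(h[0] for h in cluster)
        i_hi = max(h[0] for h in cluster) + k
        j_lo = min(h[1] for h in cluster)
        j_hi = max(h[1] for h in cluster) + k
        blocks.append(
            AnchorBlock(
                scaffold=scaffold,
                start1=i_lo,
                end1=i_hi,
                start2=j_lo,
                end2=j_hi,
                mode=RepeatMode.INVERTED if mode == "inverted" else RepeatMode.DIRECT,
                n_seeds=len(cluster),
            )
        )
        cluster.clear()

    prev_diag: Optional[int] = None
    prev_i: Optional[int] = None
    for h in ordered:
        d, i = diag(h), h[0]
        if (
            prev_diag is not None
            and (d - prev_diag > params.diag_tolerance or (prev_i is not None and abs(i - prev_i) > params.max_ltr_len))
        ):
            flush()
        cluster.append(h)
        prev_diag, prev_i = d, i
    flush()
    blocks.sort(key=lambda b: (b.start1, b.start2))
    return blocks


def find_seed_pairs(
    genome: GenomeSequence, params: DetectionParams, mode: Mode = "direct"
) -> list[AnchorBlock]:
    """Stage 1 + 2: exact seed matching and chaining for one scaffold."""
    if len(genome) < params.min_element_len:
        return []
    hits = seed_hits(genome.residues, params, mode)
    return chain_hits(hits, params, mode, scaffold=genome.id)


def _extend(matches: Iterable[bool], window: int, floor: float, max_steps: int) -> int:
    """Number of positions to extend.

    Walks outward while the trailing ``window``-wide identity stays >=
    ``floor``, then trims back to the furthest matching position whose own
    trailing window still clears the floor (so isolated chance matches beyond
    the repeat edge are not kept).
    """
    ms: list[bool] = []
    for m in matches:
        if len(ms) >= max_steps:
            break
        ms.append(m)
        if len(ms) >= window and sum(ms[-window:]) / window < floor:
            break
    for t in range(len(ms), 0, -1):
        if not ms[t - 1]:
            continue
        w = min(window, t)
        if sum(ms[t - w : t]) / w >= floor:
            return t
    return 0


def _match_iter_direct(seq: str, p1: int, p2: int, direction: int):
    """Base-identity stream moving both copies in lockstep; N never matches."""
    n = len(seq)
    t = 1
    while True:
        a, b = p1 + direction * t, p2 + direction * t
        if not (0 <= a < n and 0 <= b < n):
            return
        x, y = seq[a], seq[b]
        yield x == y and x != "N"
        t += 1


def _match_iter_inverted(seq: str, p1: int, d1: int, p2: int, d2: int):
    """Identity stream for inverted repeats: copy-1 base vs complement of the
    mirrored copy-2 base."""
    n = len(seq)
    t = 1
    while True:
        a, b = p1 + d1 * t, p2 + d2 * t
        if not (0 <= a < n and 0 <= b < n):
            return
        x, y = seq[a], _COMPLEMENT[seq[b]]
        yield x == y and x != "N"
        t += 1


def _snap(seq: str, pos: int, motifs: Sequence[str], window: int, at_end: bool) -> int:
    """Snap a boundary to the nearest occurrence of the first findable motif
    within +/- window bp.  ``at_end`` boundaries match the motif ending at the
    boundary; start boundaries match the motif beginning at it."""
    n = len(seq)
    for motif in motifs:
        m = len(motif)
        for delta in sorted(range(-window, window + 1), key=lambda d: (abs(d), d)):
            p = pos + delta
            if at_end:
                if m <= p <= n and seq[p - m : p] == motif:
                    return p
            else:
                if 0 <= p <= n - m and seq[p : p + m] == motif:
                    return p
    return pos


def refine_pair(
    genome: GenomeSequence, block: AnchorBlock, params: DetectionParams
) -> Optional[CandidatePair]:
    """Stage 3: extend an anchor block to LTR boundaries, snap to terminal
    motifs, align the two copies and apply the length/similarity filters.

    Returns None (reject) when any bound fails; rejection is a value, not an
    error.
    """
    seq = genome.residues
    inverted = block.mode is RepeatMode.INVERTED
    s1, e1, s2, e2 = block.start1, block.end1, block.start2, block.end2
    win, floor = params.identity_window, params.identity_floor
    max_ext = params.max_ltr_len

    if inverted:
        # left of copy 1 pairs with right of copy 2, and vice versa
        left = _extend(_match_iter_inverted(seq, s1, -1, e2 - 1, +1), win, floor, max_ext)
        s1 -= left
        e2 += left
        right = _extend(_match_iter_inverted(seq, e1 - 1, +1, s2, -1), win, floor, max_ext)
        e1 += right
        s2 -= right
    else:
        left = _extend(_match_iter_direct(seq, s1, s2, -1), win, floor, max_ext)
        s1 -= left
        s2 -= left
        right = _extend(_match_iter_direct(seq, e1 - 1, e2 - 1, +1), win, floor, max_ext)
        e1 += right
        e2 += right

    # snap each copy's boundaries to the canonical termini when present
    w = params.motif_snap_window
    s1 = _snap(seq, s1, ("TGT", "TG"), w, at_end=False)
    e1 = _snap(seq, e1, ("ACA", "CA"), w, at_end=True)
    s2 = _snap(seq, s2, ("TGT", "TG"), w, at_end=False)
    e2 = _snap(seq, e2, ("ACA", "CA"), w, at_end=True)

    if not (s1 < e1 <= s2 < e2):
        return None
    len1, len2 = e1 - s1, e2 - s2
    span = e2 - s1
    if not (params.min_ltr_len <= len1 <= params.max_ltr_len):
        return None
    if not (params.min_ltr_len <= len2 <= params.max_ltr_len):
        return None
    if not (params.min_element_len <= span <= params.max_element_len):
        return None

    copy1 = seq[s1:e1]
    copy2 = seq[s2:e2]
    if inverted:
        copy2 = revcomp(copy2)
    similarity = dna_similarity(copy1, copy2)
    if similarity < params.min_pair_similarity:
        return None
    return CandidatePair(
        scaffold=genome.id,
        ltr5=Interval(genome.id, s1, e1),
        ltr3=Interval(genome.id, s2, e2),
        similarity=similarity,
        mode=block.mode,
    )


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def check_flank_and_tsd(
    genome: GenomeSequence, pair: CandidatePair, params: DetectionParams
) -> Optional[CandidatePair]:
    """Record the terminal di/tri-nucleotide motif and the target-site
    duplication of a retained pair.

    The TSD search prefers the longest window (6 down to 4 bp) immediately
    flanking the element with at most ``max_tsd_mismatch`` mismatches.  A pair
    is rejected only when a ``require_*`` flag is set and the corresponding
    feature is absent.  LTRs at a scaffold edge skip the affected check with a
    warning and mark the feature absent.
    """
    seq = genome.residues
    s, e = pair.ltr5.start, pair.ltr3.end

    if seq[s : s + 3] == "TGT" and seq[e - 3 : e] == "ACA":
        motif = "TGT/ACA"
    elif seq[s : s + 2] == "TG" and seq[e - 2 : e] == "CA":
        motif = "TG/CA"
    else:
        motif = "other"

    lo, hi = params.tsd_len_range
    tsd: Optional[str] = None
    edge = s - hi < 0 or e + hi > len(seq)
    if s - lo < 0 or e + lo > len(seq):
        logger.warning(
            "element at %s:[%d,%d) touches the scaffold edge; TSD check skipped",
            pair.scaffold, s, e,
        )
    else:
        for length in range(hi, lo - 1, -1):
            if s - length < 0 or e + length > len(seq):
                continue
            up = seq[s - length : s]
            down = seq[e : e + length]
            if "N" in up or "N" in down:
                continue
            if _hamming(up, down) <= params.max_tsd_mismatch:
                tsd = up
                break

    if params.require_flank_motif and motif == "other":
        return None
    if params.require_tsd and tsd is None:
        return None
    if edge and tsd is None:
        # edge elements cannot be fully checked; keep unless strict
        pass
    return replace(pair, flank_motif=motif, tsd=tsd)


def _resolve_overlaps(candidates: list[CandidatePair]) -> list[CandidatePair]:
    """Keep one candidate per locus: the higher-similarity pair wins, ties go
    to the longer element."""
    kept: list[CandidatePair] = []
    for cand in candidates:
        winner = True
        survivors = []
        for other in kept:
            if cand.body.overlaps(other.body):
                better = (cand.similarity, len(cand.body)) > (
                    other.similarity,
                    len(other.body),
                )
                if better:
                    continue  # drop `other`
                winner = False
                survivors.append(other)
            else:
                survivors.append(other)
        if winner:
            survivors.append(cand)
        kept = survivors
    return kept


def scan_genome(
    genomes: Iterable[GenomeSequence],
    params: DetectionParams | None = None,
    mode: Mode = "direct",
) -> list[CandidatePair]:
    """Run the full detection cascade over every scaffold.

    Output ordering is deterministic: (scaffold, 5' LTR start).
    """
    params = params or DetectionParams()
    out: list[CandidatePair] = []
    for genome in genomes:
        blocks = find_seed_pairs(genome, params, mode)
        refined: list[CandidatePair] = []
        for block in blocks:
            pair = refine_pair(genome, block, params)
            if pair is None:
                continue
            pair = check_flank_and_tsd(genome, pair, params)
            if pair is not None:
                refined.append(pair)
        refined.sort(key=lambda c: (c.ltr5.start, c.ltr3.end))
        # refinement of adjacent anchor blocks may converge on one locus
        deduped: dict[tuple[int, int, int, int], CandidatePair] = {}
        for cand in refined:
            key = (cand.ltr5.start, cand.ltr5.end, cand.ltr3.start, cand.ltr3.end)
            if key not in deduped or cand.similarity > deduped[key].similarity:
                deduped[key] = cand
        resolved = _resolve_overlaps(sorted(deduped.values(), key=lambda c: (c.ltr5.start, c.ltr3.end)))
        out.extend(sorted(resolved, key=lambda c: c.ltr5.start))
        logger.info(
            "scan %s (%s mode): %d anchor blocks -> %d candidates",
            genome.id, mode, len(blocks), len(resolved),
        )
    out.sort(key=lambda c: (c.scaffold, c.ltr5.start))
    return out
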