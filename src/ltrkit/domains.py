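"""Internal-region validation: ORF discovery and protein-domain homology.

An intact element must encode retroelement proteins.  ORFs are maximal
stop-to-stop runs in all six frames; their translations are scored against a
small reference peptide panel (RT, YR, ...) by Smith-Waterman local alignment
under BLOSUM62.  Direct-repeat elements require an RT hit; DIRS (inverted
repeat) elements require both RT and tyrosine recombinase (YR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike
from typing import Iterable, Optional, Union

from Bio.Seq import Seq

from ._align import local_score, local_score_and_identity, revcomp
from .detect import CandidatePair
from .model import (
    DomainHit,
    ElementAnnotation,
    FormatError,
    Group,
    Interval,
    RepeatMode,
    Strand,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathType = Union[str, PathLike]

DOMAIN_NAMES = ("GAG", "PR", "RT", "IN", "YR")
PANEL_GROUPS = ("BEL", "copia", "DIRS", "gypsy", "outgroup")

DEFAULT_MIN_ORF_LEN = 200  # residues
DEFAULT_MIN_DOMAIN_SCORE = 80.0  # raw BLOSUM62 units


@dataclass(frozen=True)
class PanelEntry:
    id: str
    domain: str
    group: str
    peptide: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAIN_NAMES:
            raise ValidationError(f"panel entry {self.id!r}: unknown domain {self.domain!r}")
        if self.group not in PANEL_GROUPS:
            raise ValidationError(f"panel entry {self.id!r}: unknown group {self.group!r}")
        bad = set(self.peptide) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValidationError(f"panel entry {self.id!r}: bad residues {sorted(bad)}")


@dataclass(frozen=True)
class ReferencePanel:
    """The reference peptide panel used for domain evidence and group calls."""

    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValidationError("panel ids must be unique")

    def by_id(self, entry_id: str) -> PanelEntry:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise KeyError(entry_id)

    def domain_entries(self, domain: str) -> list[PanelEntry]:
        return [e for e in self.entries if e.domain == domain]


def read_panel(path: PathType) -> ReferencePanel:
    """Read a panel FASTA whose headers follow ``>id|DOMAIN|GROUP``."""
    from Bio import SeqIO

    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split()[0].split("|")
        if len(parts) != 3:
            raise FormatError(f"{path}: panel header {rec.description!r} is not id|DOMAIN|GROUP")
        entries.append(PanelEntry(parts[0], parts[1], parts[2], str(rec.seq).upper()))
    if not entries:
        raise FormatError(f"{path}: empty panel")
    return ReferencePanel(tuple(entries))


def write_panel(panel: ReferencePanel, path: PathType) -> None:
    with open(path, "w") as fh:
        for e in panel.entries:
            fh.write(f">{e.id}|{e.domain}|{e.group}\n{e.peptide}\n")


@dataclass(frozen=True)
class OrfRecord:
    """A maximal stop-to-stop open reading frame with its translation.

    ``start``/``end`` are 0-based half-open coordinates on the forward strand
    of the scanned region; ``frame`` is +1..+3 / -1..-3.
    """

    start: int
    end: int
    frame: int
    peptide: str

    def __len__(self) -> int:
        return len(self.peptide)


def find_orfs(region: str, min_len: int = DEFAULT_MIN_ORF_LEN) -> list[OrfRecord]:
    """All maximal stop-to-stop ORFs of >= ``min_len`` residues in 6 frames.

    Stop-to-stop means runs of sense codons bounded by stops or the region
    ends; an initiator methionine is not required (retroelement pol is often
    expressed by frameshift/readthrough, so requiring ATG would discard real
    domains).  Order is deterministic: frame (+1,+2,+3,-1,-2,-3), then start.
    """
    region = region.upper()
    n = len(region)
    out: list[OrfRecord] = []
    for strand, seq in ((1, region), (-1, revcomp(region))):
        for off in range(3):
            frame = strand * (off + 1)
            usable = seq[off : off + 3 * ((n - off) // 3)]
            if len(usable) < 3:
                continue
            peptide = str(Seq(usable).translate())
            for segment, a, b in _split_on_stops(peptide):
                if len(segment) < min_len:
                    continue
                nt_a = off + 3 * a
                nt_b = off + 3 * b
                if strand == 1:
                    start, end = nt_a, nt_b
                else:
                    start, end = n - nt_b, n - nt_a
                out.append(OrfRecord(start=start, end=end, frame=frame, peptide=segment))
    out.sort(key=lambda o: (_frame_order(o.frame), o.start))
    return out


def _frame_order(frame: int) -> int:
    return {1: 0, 2: 1, 3: 2, -1: 3, -2: 4, -3: 5}[frame]


def _split_on_stops(peptide: str):
    """Yield (segment, codon_start, codon_end) for stop-free runs."""
    a = 0
    for i, aa in enumerate(peptide):
        if aa == "*":
            if i > a:
                yield peptide[a:i], a, i
            a = i + 1
    if len(peptide) > a:
        yield peptide[a:], a, len(peptide)


def score_domains(
    orfs: Iterable[OrfRecord],
    panel: ReferencePanel,
    min_score: float = DEFAULT_MIN_DOMAIN_SCORE,
    scaffold: str = "",
    region_offset: int = 0,
) -> list[DomainHit]:
    """Score every ORF against every panel entry; retain, per domain name,
    the best-scoring (ORF, reference) combination with score >= ``min_score``.

    ``region_offset`` shifts ORF coordinates into genome space when the region
    scanned was an element's internal region.  Peptides that are >50% X are
    skipped with a warning.
    """
    if not panel.entries:
        raise ValidationError("reference panel is empty")
    best: dict[str, tuple[float, OrfRecord, PanelEntry]] = {}
    for orf in orfs:
        if orf.peptide.count("X") > 0.5 * len(orf.peptide):
            logger.warning("ORF at %d-%d skipped: >50%% X", orf.start, orf.end)
            continue
        for entry in panel.entries:
            score = local_score(orf.peptide, entry.peptide)
            if score < min_score:
                continue
            prev = best.get(entry.domain)
            if prev is None or score > prev[0]:
                best[entry.domain] = (score, orf, entry)
    hits: list[DomainHit] = []
    for domain in DOMAIN_NAMES:
        if domain not in best:
            continue
        score, orf, entry = best[domain]
        _, identity = local_score_and_identity(orf.peptide, entry.peptide)
        hits.append(
            DomainHit(
                name=domain,
                orf=Interval(
                    scaffold,
                    region_offset + orf.start,
                    region_offset + orf.end,
                    Strand.PLUS if orf.frame > 0 else Strand.MINUS,
                ),
                frame=orf.frame,
                score=score,
                best_reference=entry.id,
                percent_identity=identity,
            )
        )
    return hits


def validate_element(
    pair: CandidatePair,
    hits: list[DomainHit],
    mode: str = "direct",
) -> Optional[ElementAnnotation]:
    """Promote a candidate pair to an intact element if its internal region
    carries the required domain evidence.

    Direct mode requires an RT hit (GAG/PR/IN recorded when present); DIRS
    mode requires both RT and YR.  Returns None on rejection, logging the
    missing requirement.
    """
    names = {h.name for h in hits}
    if not hits:
        logger.info("reject %s:[%d,%d): no domain evidence",
                    pair.scaffold, pair.ltr5.start, pair.ltr3.end)
        return None
    if "RT" not in names:
        logger.info("reject %s:[%d,%d): missing RT",
                    pair.scaffold, pair.ltr5.start, pair.ltr3.end)
        return None
    inverted = mode == "inverted" or pair.mode is RepeatMode.INVERTED
    if inverted and "YR" not in names:
        logger.info("reject %s:[%d,%d): DIRS candidate missing YR",
                    pair.scaffold, pair.ltr5.start, pair.ltr3.end)
        return None
    group = Group.DIRS if inverted else Group.UNCLASSIFIED
    return ElementAnnotation(
        id=None,
        group=group,
        family=None,
        ltr5=pair.ltr5,
        ltr3=pair.ltr3,
        body=pair.body,
        ltr_similarity=pair.similarity,
        flank_motif=pair.flank_motif or "absent",
        tsd=pair.tsd,
        domains=hits,
        repeat_mode=RepeatMode.INVERTED if inverted else RepeatMode.DIRECT,
    )


def element_internal_region(genome_residues: str, pair: CandidatePair) -> str:
    """The internal region between the two repeat copies."""
    return genome_residues[pair.ltr5.end : pair.ltr3.start]
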