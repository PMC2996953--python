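"""Overlap of elements with tiling-array transcriptionally active regions.

A TAR is a scaffold interval carrying a per-condition log2 intensity.  An
element is *transcribed* when it shares at least one base with at least one
TAR in any condition; per-condition overlapped totals are computed on the
union of the overlapping TARs (clipped to the element) so stacked TARs are
never double-counted.  Elements whose per-condition total exceeds the
long-TAR threshold (500 bp) are flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .model import ElementAnnotation, FormatError, Group, Interval, ValidationError

logger = logging.getLogger(__name__)

PathType = Union[str, PathLike]

DEFAULT_CONDITIONS = (
    "female",
    "male",
    "metal-control",
    "metal",
    "kairomone-control",
    "kairomone",
)

LONG_TAR_THRESHOLD = 500  # bp, per condition


@dataclass(frozen=True)
class TARInterval:
    interval: Interval
    condition: str
    intensity: float

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValidationError("log2 intensity must be >= 0")


def read_tar_bed(path: PathType) -> list[TARInterval]:
    """Read a BED6+2 TAR track: chrom start end name score strand condition
    intensity."""
    tars: list[TARInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise FormatError(f"{path}:{ln}: expected 8 BED columns, got {len(parts)}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if parts[5] in "+-" else "."
            tars.append(
                TARInterval(
                    interval=Interval(chrom, start, end),
                    condition=parts[6],
                    intensity=float(parts[7]),
                )
            )
    return tars


def write_tar_bed(tars: Iterable[TARInterval], path: PathType) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(tars, start=1):
            fh.write(
                f"{t.interval.scaffold}\t{t.interval.start}\t{t.interval.end}"
                f"\ttar_{i}\t0\t.\t{t.condition}\t{t.intensity:g}\n"
            )


@dataclass
class ExpressionRecord:
    element_id: str
    element_length: int
    overlap_bp: dict[str, int] = field(default_factory=dict)
    max_intensity: dict[str, float] = field(default_factory=dict)
    transcribed: bool = False
    long_tar: bool = False

    @property
    def total_tar_bp(self) -> int:
        """Largest per-condition overlapped total (the reported TAR length)."""
        return max(self.overlap_bp.values(), default=0)

    @property
    def coverage_percent(self) -> float:
        return 100.0 * self.total_tar_bp / self.element_length

    def conditions_expressed(self) -> list[str]:
        return [c for c, bp in self.overlap_bp.items() if bp > 0]


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    last_end = None
    for a, b in sorted(intervals):
        if last_end is None or a > last_end:
            total += b - a
            last_end = b
        elif b > last_end:
            total += b - last_end
            last_end = b
    return total


def overlap_elements(
    elements: Sequence[ElementAnnotation],
    tars: Sequence[TARInterval],
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    min_overlap_bp: int = 1,
    long_tar_threshold: int = LONG_TAR_THRESHOLD,
) -> list[ExpressionRecord]:
    """Intersect elements with a TAR track (half-open interval semantics).

    TARs on scaffolds absent from the element set are skipped with a warning;
    TARs in conditions outside ``conditions`` raise.
    """
    known_scaffolds = {el.body.scaffold for el in elements}
    by_scaffold: dict[str, list[TARInterval]] = {}
    for tar in tars:
        if tar.condition not in conditions:
            raise ValidationError(f"unknown condition {tar.condition!r}")
        if tar.interval.scaffold not in known_scaffolds:
            logger.warning("TAR on unknown scaffold %r skipped", tar.interval.scaffold)
            continue
        by_scaffold.setdefault(tar.interval.scaffold, []).append(tar)

    records: list[ExpressionRecord] = []
    for el in elements:
        rec = ExpressionRecord(
            element_id=el.id or f"{el.body.scaffold}:{el.body.start}",
            element_length=el.length,
        )
        local = by_scaffold.get(el.body.scaffold, [])
        for cond in conditions:
            pieces = []
            max_int = 0.0
            for tar in local:
                if tar.condition != cond:
                    continue
                ov = el.body.intersection_length(tar.interval)
                if ov >= 1:
                    pieces.append(
                        (
                            max(el.body.start, tar.interval.start),
                            min(el.body.end, tar.interval.end),
                        )
                    )
                    max_int = max(max_int, tar.intensity)
            bp = _union_length(pieces)
            rec.overlap_bp[cond] = bp
            rec.max_intensity[cond] = max_int if bp else 0.0
        rec.transcribed = any(bp >= min_overlap_bp for bp in rec.overlap_bp.values())
        rec.long_tar = any(bp > long_tar_threshold for bp in rec.overlap_bp.values())
        records.append(rec)
    return records


def _truncate2(x: float) -> float:
    return math.floor(x * 100) / 100.0


def transcribed_summary(
    records: Sequence[ExpressionRecord] | None = None,
    groups: Mapping[str, Group] | None = None,
    counts: Mapping | None = None,
    n_conditions: int = len(DEFAULT_CONDITIONS),
) -> pd.DataFrame:
    """Per-group transcribed counts with the copia:gypsy transcribed ratio.

    Either pass ``records`` plus a mapping element id -> group, or bare
    per-group transcribed ``counts``.  The ratio is truncated to 2 decimals.
    The table's ``attrs`` carry the total, the ratio, and (records path only)
    the number of elements expressed in exactly one / in all conditions.
    """
    one_condition = all_conditions = None
    if counts is None:
        if records is None or groups is None:
            raise ValidationError("pass records+groups or counts")
        tally: dict[Group, int] = {}
        for rec in records:
            if not rec.transcribed:
                continue
            group = groups[rec.element_id]
            group = Group(group) if not isinstance(group, Group) else group
            tally[group] = tally.get(group, 0) + 1
        counts = tally
        expressed = [rec for rec in records if rec.transcribed]
        one_condition = sum(1 for r in expressed if len(r.conditions_expressed()) == 1)
        all_conditions = sum(
            1 for r in expressed if len(r.conditions_expressed()) == n_conditions
        )

    clean = {Group(k) if not isinstance(k, Group) else k: int(v) for k, v in counts.items()}
    rows = [
        {"group": g.value, "n_transcribed": clean[g]}
        for g in (Group.BEL, Group.COPIA, Group.DIRS, Group.GYPSY)
        if g in clean
    ]
    df = pd.DataFrame(rows)
    df.attrs["total_transcribed"] = int(sum(clean.values()))
    if clean.get(Group.GYPSY):
        df.attrs["copia_gypsy_ratio"] = _truncate2(
            clean.get(Group.COPIA, 0) / clean[Group.GYPSY]
        )
    if one_condition is not None:
        df.attrs["expressed_in_one_condition"] = one_condition
        df.attrs["expressed_in_all_conditions"] = all_conditions
    return df


def expression_matrix(
    records: Sequence[ExpressionRecord],
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
) -> pd.DataFrame:
    """Dense elements x conditions matrix of max log2 intensity (0.0 where no
    overlap); rows sorted by element id, columns in configured order."""
    data = {
        rec.element_id: [rec.max_intensity.get(c, 0.0) for c in conditions]
        for rec in records
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(conditions))
    return df.sort_index()
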