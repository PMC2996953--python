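"""FASTA / GFF3 readers and writers, and element naming.

GFF3 output is 1-based inclusive (columns 4-5); everything upstream of this
module is 0-based half-open.
"""

from __future__ import annotations

import logging
from os import PathLike
from typing import Iterable, Union

from Bio import SeqIO

from .model import (
    ElementAnnotation,
    FormatError,
    GenomeSequence,
    LETTER_TO_GROUP,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathType = Union[str, PathLike]

_NORMALIZE = str.maketrans(
    {c: ("T" if c == "U" else c if c in "ACGTN" else "N")
     for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"}
)


def normalize_residues(raw: str) -> tuple[str, int]:
    """Uppercase, map U->T and any other ambiguity code to N.

    Returns the normalized string and the count of residues coerced to N.
    """
    up = raw.upper()
    out = up.translate(_NORMALIZE)
    coerced = sum(1 for a, b in zip(up, out) if a != b and b == "N")
    return out, coerced


def read_fasta(path: PathType) -> list[GenomeSequence]:
    """Read a multi-FASTA genome into normalized :class:`GenomeSequence` records.

    Raises :class:`FormatError` on an empty file or duplicate record ids.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    out: list[GenomeSequence] = []
    total_coerced = 0
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        residues, coerced = normalize_residues(str(rec.seq))
        total_coerced += coerced
        out.append(GenomeSequence(id=rec.id, residues=residues))
    if total_coerced:
        logger.info("read_fasta(%s): %d non-ACGTN residues mapped to N", path, total_coerced)
    return out


def write_fasta(seqs: Iterable[GenomeSequence], path: PathType, width: int = 60) -> None:
    """Write sequences with a fixed line width (byte-stable round trips)."""
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def name_element(
    genome_prefix: str,
    group_letter: str,
    family_number: int,
    scaffold: str,
    index_in_scaffold: int,
) -> str:
    """Canonical element name: ``<prefix>_<letter><family>_<scaffold>_<index>``.

    The group letter is B/C/D/G (BEL, copia, DIRS, gypsy); the index counts
    elements within a scaffold starting at 1.
    """
    if group_letter not in LETTER_TO_GROUP:
        raise ValidationError(
            f"unknown group letter {group_letter!r}; expected one of B, C, D, G"
        )
    if index_in_scaffold < 1:
        raise ValidationError("index_in_scaffold must be >= 1")
    return f"{genome_prefix}_{group_letter}{family_number}_{scaffold}_{index_in_scaffold}"


def _gff3_escape(value: str) -> str:
    return (
        value.replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
    )


def write_gff3(
    elements: Iterable[ElementAnnotation],
    path: PathType,
    scaffold_lengths: dict[str, int] | None = None,
    source: str = "ltrkit",
) -> None:
    """Write elements as GFF3: one LTR_retrotransposon parent with
    long_terminal_repeat and ORF (domain) children.

    ``scaffold_lengths``, when given, is used to validate coordinates and to
    emit ``##sequence-region`` pragmas.
    """
    lines = ["##gff-version 3"]
    if scaffold_lengths:
        for scaf, length in scaffold_lengths.items():
            lines.append(f"##sequence-region {scaf} 1 {length}")
    for el in elements:
        if el.id is None:
            raise ValidationError("cannot write an unnamed element; assign ids first")
        if scaffold_lengths is not None:
            limit = scaffold_lengths.get(el.body.scaffold)
            if limit is not None and el.body.end > limit:
                raise ValidationError(
                    f"element {el.id}: end {el.body.end} exceeds scaffold "
                    f"{el.body.scaffold} length {limit}"
                )
        attrs = (
            f"ID={_gff3_escape(el.id)};group={el.group.value};"
            f"family={_gff3_escape(el.family or 'NA')};"
            f"ltr_similarity={el.ltr_similarity:.1f};"
            f"flank_motif={_gff3_escape(el.flank_motif)};"
            f"tsd={_gff3_escape(el.tsd or 'absent')};"
            f"repeat_mode={el.repeat_mode.value}"
        )
        lines.append(
            "\t".join(
                [
                    el.body.scaffold,
                    source,
                    "LTR_retrotransposon",
                    str(el.body.start + 1),
                    str(el.body.end),
                    ".",
                    ".",
                    ".",
                    attrs,
                ]
            )
        )
        for tag, iv in (("five_prime", el.ltr5), ("three_prime", el.ltr3)):
            lines.append(
                "\t".join(
                    [
                        iv.scaffold,
                        source,
                        "long_terminal_repeat",
                        str(iv.start + 1),
                        str(iv.end),
                        ".",
                        ".",
                        ".",
                        f"ID={_gff3_escape(el.id)}_ltr_{tag};Parent={_gff3_escape(el.id)}",
                    ]
                )
            )
        for i, hit in enumerate(el.domains, start=1):
            strand = "+" if hit.frame > 0 else "-"
            lines.append(
                "\t".join(
                    [
                        hit.orf.scaffold,
                        source,
                        "ORF",
                        str(hit.orf.start + 1),
                        str(hit.orf.end),
                        f"{hit.score:.0f}",
                        strand,
                        ".",
                        f"ID={_gff3_escape(el.id)}_orf_{i};Parent={_gff3_escape(el.id)};"
                        f"domain={hit.name};reference={_gff3_escape(hit.best_reference)};"
                        f"percent_identity={hit.percent_identity:.1f}",
                    ]
                )
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
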