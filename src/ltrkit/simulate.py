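"""Synthetic genomes with planted retroelements, reference panels, TAR
tracks and truth manifests.

Every planted element follows the intact-element anatomy the detector looks
for: TSD + LTR + internal region (a single gag-pol-style ORF embedding a
panel-derived RT peptide, plus YR for DIRS) + LTR' + TSD, where LTR' is a
second, independently mutated copy of the repeat unit (reverse-complemented
for DIRS).  Element divergence d is realized as d/2 substitutions per LTR
copy (terminal motifs protected) and rate-d substitutions on the planted
domain peptides; the back-translation uses uniform synonymous codon choice.
All generators are fully deterministic under their seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from ._align import revcomp
from .domains import PanelEntry, ReferencePanel
from .model import GenomeSequence, LtrKitError, ValidationError
from .transcription import DEFAULT_CONDITIONS, TARInterval

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# per-group plant length ranges (bp): LTR and whole element
GROUP_LTR_RANGE = {
    "BEL": (193, 600),
    "copia": (172, 602),
    "DIRS": (88, 170),
    "gypsy": (134, 938),
}
GROUP_ELEMENT_RANGE = {
    "BEL": (3349, 12536),
    "copia": (4064, 8184),
    "DIRS": (4313, 5501),
    "gypsy": (4026, 12862),
}

_CODONS_BY_AA: dict[str, list[str]] = {}


def _codon_table() -> dict[str, list[str]]:
    global _CODONS_BY_AA
    if not _CODONS_BY_AA:
        table = unambiguous_dna_by_id[1]
        by_aa: dict[str, list[str]] = {}
        for codon, aa in table.forward_table.items():
            by_aa.setdefault(aa, []).append(codon)
        _CODONS_BY_AA = {aa: sorted(codons) for aa, codons in by_aa.items()}
    return _CODONS_BY_AA


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, len(AA20), size=length))


def _mutate_peptide(rng: np.random.Generator, peptide: str, rate: float) -> str:
    n = int(round(rate * len(peptide)))
    if n == 0:
        return peptide
    positions = rng.choice(len(peptide), size=min(n, len(peptide)), replace=False)
    chars = list(peptide)
    for p in positions:
        choices = [a for a in AA20 if a != chars[p]]
        chars[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def back_translate(rng: np.random.Generator, peptide: str) -> str:
    """Uniform synonymous codon choice (seeded)."""
    table = _codon_table()
    out = []
    for aa in peptide:
        codons = table.get(aa, table["L"])  # X falls back to an arbitrary codon set
        out.append(codons[int(rng.integers(0, len(codons)))])
    return "".join(out)


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    return "".join(bases[rng.choice(4, size=length, p=p)])


def _mutate_dna(
    rng: np.random.Generator,
    seq: str,
    rate: float,
    protect_ends: int = 0,
) -> str:
    """Substitute round(rate * len) positions, never touching the first/last
    ``protect_ends`` bases."""
    n = int(round(rate * len(seq)))
    lo, hi = protect_ends, len(seq) - protect_ends
    if n == 0 or hi <= lo:
        return seq
    positions = rng.choice(np.arange(lo, hi), size=min(n, hi - lo), replace=False)
    chars = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != chars[p]]
        chars[p] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def generate_panel(
    groups: Sequence[str] = ("BEL", "copia", "DIRS", "gypsy"),
    members_per_group: int = 2,
    seed: int = 0,
    include_outgroup: bool = False,
    ancestor_len_range: tuple[int, int] = (180, 280),
    within_divergence: float = 0.05,
    min_between_divergence: float = 0.40,
) -> ReferencePanel:
    """A reference peptide panel: one random RT ancestor per group with
    members at <= 10% divergence from it; random ancestors are ~95% divergent
    pairwise (regenerated in the unlikely case they are not), well beyond the
    40% between-group floor.  YR entries accompany the DIRS group."""
    if not groups:
        raise ValidationError("need at least one group")
    rng = np.random.default_rng(seed)
    ancestors: dict[str, str] = {}
    for group in groups:
        while True:
            length = int(rng.integers(ancestor_len_range[0], ancestor_len_range[1] + 1))
            pep = _random_peptide(rng, length)
            if all(_crude_identity(pep, other) <= 1 - min_between_divergence
                   for other in ancestors.values()):
                break
        ancestors[group] = pep
    entries: list[PanelEntry] = []
    for group in groups:
        for k in range(members_per_group):
            pep = _mutate_peptide(rng, ancestors[group], within_divergence)
            entries.append(PanelEntry(f"{group}_RT{k+1}", "RT", group, pep))
    if "DIRS" in groups:
        yr_ancestor = _random_peptide(rng, int(rng.integers(200, 301)))
        for k in range(members_per_group):
            pep = _mutate_peptide(rng, yr_ancestor, within_divergence)
            entries.append(PanelEntry(f"DIRS_YR{k+1}", "YR", "DIRS", pep))
    if include_outgroup:
        entries.append(
            PanelEntry("outgroup_RT1", "RT", "outgroup", _random_peptide(rng, 220))
        )
    return ReferencePanel(tuple(entries))


def _crude_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    return sum(1 for x, y in zip(a, b) if x == y) / n


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class PlantSpec:
    """What to plant: element counts per group and their properties.

    ``divergence`` may be a single rate or an inclusive (lo, hi) range
    sampled per element.  ``families`` optionally lists family sizes per
    group (summing to the group count); members of one family share an
    ancestral repeat unit, mutated per member at
    ``within_family_divergence``.  ``tsd_len`` of None plants no TSD;
    "random" draws 4-6 per element.
    """

    counts: dict = field(default_factory=lambda: {"BEL": 2, "copia": 3, "DIRS": 2, "gypsy": 3})
    divergence: float | tuple[float, float] = 0.02
    tsd_len: Optional[int | str] = "random"
    flank: str = "TGT/ACA"
    families: Optional[dict] = None
    within_family_divergence: float = 0.03
    min_gap: int = 300

    def __post_init__(self) -> None:
        lo, hi = self.divergence_range
        if not (0.0 <= lo <= hi <= 0.3):
            raise ValidationError("divergence must lie in [0, 0.3]")
        for g in self.counts:
            if g not in GROUP_LTR_RANGE:
                raise ValidationError(f"unknown group {g!r}")
        if self.families is not None:
            for g, sizes in self.families.items():
                if sum(sizes) != self.counts.get(g, 0):
                    raise ValidationError(f"family sizes for {g!r} do not sum to its count")
        if self.flank not in ("TGT/ACA", "TG/CA", "other"):
            raise ValidationError(f"unknown flank spec {self.flank!r}")

    @property
    def divergence_range(self) -> tuple[float, float]:
        if isinstance(self.divergence, (int, float)):
            return (float(self.divergence), float(self.divergence))
        return (float(self.divergence[0]), float(self.divergence[1]))


def _ltr_unit(rng: np.random.Generator, length: int, flank: str, gc: float) -> str:
    core = _random_dna(rng, length - 6, gc)
    if flank == "TGT/ACA":
        return "TGT" + core + "ACA"
    if flank == "TG/CA":
        # avoid the accidental tri-nucleotide motif
        mid = core
        if mid.startswith("T"):
            mid = "A" + mid[1:]
        if mid.endswith("A"):
            mid = mid[:-1] + "T"
        return "TG" + mid + "CA"
    # "other": make sure neither motif appears
    return "GG" + core + "TT"


def _filler_codons(rng: np.random.Generator, n: int) -> str:
    """Random sense (non-stop) codons."""
    stops = {"TAA", "TAG", "TGA"}
    out = []
    while len(out) < n:
        codon = _random_dna(rng, 3, 0.5)
        if codon not in stops:
            out.append(codon)
    return "".join(out)


def _build_internal(
    rng: np.random.Generator,
    length: int,
    rt_pep: str,
    yr_pep: Optional[str],
    gc: float,
) -> tuple[str, tuple[int, int], Optional[tuple[int, int]]]:
    """Internal region of the requested length carrying one long ORF.

    Returns (sequence, rt span, yr span) with spans relative to the internal
    region start.
    """
    gag_len, tail_len = 100, 30
    orf_pep_len = 1 + gag_len + len(rt_pep) + (len(yr_pep) if yr_pep else 0) + tail_len
    orf_nt = 3 * orf_pep_len + 3  # + stop
    if orf_nt + 6 > length:
        raise LtrKitError(
            f"internal region of {length} bp cannot host a {orf_nt} bp ORF"
        )
    pre_len = int(rng.integers(3, length - orf_nt - 2))
    post_len = length - orf_nt - pre_len
    gag = _filler_codons(rng, gag_len)
    rt_nt = back_translate(rng, rt_pep)
    yr_nt = back_translate(rng, yr_pep) if yr_pep else ""
    tail = _filler_codons(rng, tail_len)
    orf = "ATG" + gag + rt_nt + yr_nt + tail + "TAA"
    pre = _random_dna(rng, pre_len, gc)
    post = _random_dna(rng, post_len, gc)
    rt_start = pre_len + 3 + 3 * gag_len
    rt_span = (rt_start, rt_start + len(rt_nt))
    yr_span = None
    if yr_pep:
        yr_span = (rt_span[1], rt_span[1] + len(yr_nt))
    return pre + orf + post, rt_span, yr_span


def generate_genome(
    spec: PlantSpec,
    panel: ReferencePanel,
    background_length: int = 200_000,
    gc: float = 0.4,
    seed: int = 0,
    scaffold_id: str = "scaf1",
) -> tuple[list[GenomeSequence], dict]:
    """Plant elements on an i.i.d. background and return the genome plus a
    truth manifest (coordinates, groups, families, divergences, domains).

    Raises when the background cannot host all plants with ``min_gap``
    spacing.
    """
    rng = np.random.default_rng(seed)
    lo_div, hi_div = spec.divergence_range

    # per-group family layout
    plants: list[dict] = []
    for group, count in spec.counts.items():
        sizes = (spec.families or {}).get(group, [1] * count)
        fam_no = 0
        for size in sizes:
            fam_no += 1
            fam_label = f"{group}_fam{fam_no}"
            ltr_lo, ltr_hi = GROUP_LTR_RANGE[group]
            el_lo, el_hi = GROUP_ELEMENT_RANGE[group]
            ltr_len = int(rng.integers(ltr_lo, ltr_hi + 1))
            element_len = int(rng.integers(el_lo, el_hi + 1))
            unit = _ltr_unit(rng, ltr_len, spec.flank, gc)
            rt_entries = [e for e in panel.entries if e.domain == "RT" and e.group == group]
            if not rt_entries:
                raise ValidationError(f"panel has no RT entry for group {group!r}")
            rt_base = rt_entries[0].peptide
            yr_entries = [e for e in panel.entries if e.domain == "YR"]
            if group == "DIRS" and not yr_entries:
                raise ValidationError("panel has no YR entry for DIRS plants")
            yr_base = yr_entries[0].peptide if group == "DIRS" else None
            for _ in range(size):
                div = float(rng.uniform(lo_div, hi_div)) if hi_div > lo_div else lo_div
                member_unit = (
                    _mutate_dna(rng, unit, spec.within_family_divergence, protect_ends=3)
                    if size > 1
                    else unit
                )
                plants.append(
                    {
                        "group": group,
                        "family": fam_label,
                        "unit": member_unit,
                        "ltr_len": ltr_len,
                        "element_len": element_len,
                        "divergence": div,
                        "rt_base": rt_base,
                        "yr_base": yr_base,
                    }
                )
    order = rng.permutation(len(plants))
    plants = [plants[i] for i in order]

    # build element sequences
    built: list[dict] = []
    for plant in plants:
        div = plant["divergence"]
        unit = plant["unit"]
        ltr_a = _mutate_dna(rng, unit, div / 2, protect_ends=3)
        ltr_b = _mutate_dna(rng, unit, div / 2, protect_ends=3)
        inverted = plant["group"] == "DIRS"
        if inverted:
            ltr_b = revcomp(ltr_b)
        internal_len = plant["element_len"] - 2 * plant["ltr_len"]
        rt_pep = _mutate_peptide(rng, plant["rt_base"], div)
        yr_pep = (
            _mutate_peptide(rng, plant["yr_base"], div) if plant["yr_base"] else None
        )
        internal, rt_span, yr_span = _build_internal(rng, internal_len, rt_pep, yr_pep, gc)
        if spec.tsd_len is None:
            tsd = ""
        elif spec.tsd_len == "random":
            tsd = _random_dna(rng, int(rng.integers(4, 7)), gc)
        else:
            tsd = _random_dna(rng, int(spec.tsd_len), gc)
        built.append(
            {
                **plant,
                "sequence": ltr_a + internal + ltr_b,
                "tsd": tsd,
                "rt_span": rt_span,
                "yr_span": yr_span,
            }
        )

    total = sum(len(b["sequence"]) + 2 * len(b["tsd"]) for b in built)
    n = len(built)
    slack = background_length - total - (n + 1) * spec.min_gap
    if slack < 0:
        raise LtrKitError(
            f"background of {background_length} bp cannot host {n} plants "
            f"({total} bp + gaps); increase background_length"
        )
    if n:
        weights = rng.dirichlet(np.ones(n + 1))
        gaps = [spec.min_gap + int(w * slack) for w in weights]
    else:
        gaps = [background_length]

    parts: list[str] = []
    offset = 0
    manifest_elements: list[dict] = []
    for i, b in enumerate(built):
        gap = _random_dna(rng, gaps[i], gc)
        parts.append(gap)
        offset += len(gap)
        tsd = b["tsd"]
        parts.append(tsd)
        offset += len(tsd)
        start = offset
        seq = b["sequence"]
        parts.append(seq)
        ltr_len = b["ltr_len"]
        internal_start = start + ltr_len
        entry = {
            "id": f"plant_{i+1}",
            "group": b["group"],
            "family": b["family"],
            "scaffold": scaffold_id,
            "start": start,
            "end": start + len(seq),
            "ltr5": [start, start + ltr_len],
            "ltr3": [start + len(seq) - ltr_len, start + len(seq)],
            "divergence": b["divergence"],
            "tsd": tsd or None,
            "flank": spec.flank,
            "repeat_mode": "inverted" if b["group"] == "DIRS" else "direct",
            "rt_domain": [internal_start + b["rt_span"][0], internal_start + b["rt_span"][1]],
            "yr_domain": (
                [internal_start + b["yr_span"][0], internal_start + b["yr_span"][1]]
                if b["yr_span"]
                else None
            ),
        }
        offset += len(seq)
        parts.append(tsd)
        offset += len(tsd)
        manifest_elements.append(entry)
    tail = background_length - offset
    if tail > 0:
        parts.append(_random_dna(rng, tail, gc))
    residues = "".join(parts)
    genome = GenomeSequence(id=scaffold_id, residues=residues)
    manifest = {
        "seed": seed,
        "scaffolds": {scaffold_id: len(residues)},
        "elements": sorted(manifest_elements, key=lambda e: e["start"]),
        "tars": [],
    }
    logger.info("generated %d bp genome with %d planted elements", len(residues), n)
    return [genome], manifest


# ---------------------------------------------------------------------------
# TAR track
# ---------------------------------------------------------------------------

def generate_tar_track(
    manifest: dict,
    cover_fraction: float,
    conditions: Sequence[str] = DEFAULT_CONDITIONS,
    seed: int = 0,
    tar_length_range: tuple[int, int] = (200, 400),
    n_long: int = 0,
    long_length: int = 600,
    intensity_range: tuple[float, float] = (0.5, 4.82),
) -> list[TARInterval]:
    """TARs covering exactly round(cover_fraction * n_elements) planted
    elements (the first ``n_long`` of them get a > 500 bp TAR); the manifest
    is updated in place."""
    if not (0.0 <= cover_fraction <= 1.0):
        raise ValidationError("cover_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    elements = manifest["elements"]
    n_cover = int(round(cover_fraction * len(elements)))
    chosen = list(rng.choice(len(elements), size=n_cover, replace=False))
    tars: list[TARInterval] = []
    for rank, idx in enumerate(chosen):
        el = elements[idx]
        length = long_length if rank < n_long else int(
            rng.integers(tar_length_range[0], tar_length_range[1] + 1)
        )
        length = min(length, el["end"] - el["start"])
        start = int(rng.integers(el["start"], el["end"] - length + 1))
        condition = conditions[int(rng.integers(0, len(conditions)))]
        intensity = float(rng.uniform(*intensity_range))
        from .model import Interval

        tar = TARInterval(
            interval=Interval(el["scaffold"], start, start + length),
            condition=condition,
            intensity=round(intensity, 3),
        )
        tars.append(tar)
        manifest["tars"].append(
            {
                "element_id": el["id"],
                "scaffold": el["scaffold"],
                "start": start,
                "end": start + length,
                "condition": condition,
                "intensity": tar.intensity,
            }
        )
    return tars


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
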