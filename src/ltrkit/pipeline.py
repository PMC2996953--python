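"""End-to-end composition of the annotation stages.

``annotate_genome`` runs: seed/refine scan -> internal-region ORF + domain
validation -> group classification -> family clustering -> element naming,
and returns the named elements plus the family assignments.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable, Sequence

from .detect import DetectionParams, Mode, scan_genome
from .domains import (
    DEFAULT_MIN_DOMAIN_SCORE,
    DEFAULT_MIN_ORF_LEN,
    ReferencePanel,
    element_internal_region,
    find_orfs,
    score_domains,
    validate_element,
)
from .families import FamilyAssignment, assign_names, classify_group, cluster_families
from .model import ElementAnnotation, GenomeSequence

logger = logging.getLogger(__name__)


def validate_candidates(
    genomes: Sequence[GenomeSequence],
    candidates,
    panel: ReferencePanel,
    mode: Mode = "direct",
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
    min_domain_score: float = DEFAULT_MIN_DOMAIN_SCORE,
) -> list[ElementAnnotation]:
    """Domain-validate candidate pairs into (unnamed) element annotations."""
    by_id = {g.id: g for g in genomes}
    elements: list[ElementAnnotation] = []
    for pair in candidates:
        genome = by_id[pair.scaffold]
        region = element_internal_region(genome.residues, pair)
        if len(region) < 3 * min_orf_len:
            continue
        orfs = find_orfs(region, min_len=min_orf_len)
        hits = score_domains(
            orfs,
            panel,
            min_score=min_domain_score,
            scaffold=pair.scaffold,
            region_offset=pair.ltr5.end,
        )
        element = validate_element(pair, hits, mode=mode)
        if element is not None:
            ltr_seq = genome.residues[pair.ltr5.start : pair.ltr5.end]
            elements.append(replace(element, ltr_seq=ltr_seq))
    return elements


def annotate_genome(
    genomes: Sequence[GenomeSequence],
    panel: ReferencePanel,
    params: DetectionParams | None = None,
    mode: Mode = "direct",
    genome_prefix: str = "Syn",
    family_threshold: float = 80.0,
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
    min_domain_score: float = DEFAULT_MIN_DOMAIN_SCORE,
) -> tuple[list[ElementAnnotation], list[FamilyAssignment]]:
    """Full annotation of one mode (direct LTR groups, or DIRS in inverted
    mode); returns named elements and their families."""
    params = params or (DetectionParams.dirs() if mode == "inverted" else DetectionParams())
    candidates = scan_genome(genomes, params, mode)
    logger.info("%s scan: %d candidates", mode, len(candidates))
    elements = validate_candidates(
        genomes, candidates, panel, mode, min_orf_len, min_domain_score
    )
    logger.info("%d candidates validated as intact elements", len(elements))
    classified = []
    for el in elements:
        group = classify_group(el, panel)
        if group.value == "unclassified":
            logger.info("element at %s:%d left unclassified (no RT evidence)",
                        el.body.scaffold, el.body.start)
            continue
        if group.value == "DIRS" and el.repeat_mode.value == "direct":
            # homology says DIRS but the repeats are direct; structure wins
            logger.warning("direct-repeat element at %s:%d has DIRS RT best hit; skipped",
                           el.body.scaffold, el.body.start)
            continue
        classified.append(replace(el, group=group))
    families = cluster_families(classified, threshold=family_threshold)
    named = assign_names(classified, families, genome_prefix=genome_prefix)
    return named, families


def annotate_all(
    genomes: Sequence[GenomeSequence],
    panel: ReferencePanel,
    direct_params: DetectionParams | None = None,
    dirs_params: DetectionParams | None = None,
    genome_prefix: str = "Syn",
    family_threshold: float = 80.0,
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
    min_domain_score: float = DEFAULT_MIN_DOMAIN_SCORE,
):
    """Both detection modes in one pass, with joint family clustering and
    per-scaffold element numbering across all groups."""
    from .families import classify_group as _classify

    merged: list[ElementAnnotation] = []
    for mode, params in (
        ("direct", direct_params or DetectionParams()),
        ("inverted", dirs_params or DetectionParams.dirs()),
    ):
        candidates = scan_genome(genomes, params, mode)
        elements = validate_candidates(
            genomes, candidates, panel, mode, min_orf_len, min_domain_score
        )
        for el in elements:
            group = _classify(el, panel)
            if group.value == "unclassified":
                continue
            if group.value == "DIRS" and el.repeat_mode.value == "direct":
                continue
            merged.append(replace(el, group=group))
    merged.sort(key=lambda el: (el.body.scaffold, el.body.start))
    families = cluster_families(merged, threshold=family_threshold)
    named = assign_names(merged, families, genome_prefix=genome_prefix)
    return named, families
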