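"""Group classification and family clustering of intact elements.

Groups (gypsy, copia, BEL, DIRS) come from the best-scoring RT reference;
families are single-linkage clusters of elements whose 5' LTRs align at
> ``threshold`` percent identity (strict inequality), computed with the same
global DNA aligner the detector uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._align import dna_similarity
from .domains import ReferencePanel
from .io import name_element
from .model import ElementAnnotation, Group, RepeatMode, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_FAMILY_THRESHOLD = 80.0


def classify_group(element: ElementAnnotation, panel: ReferencePanel) -> Group:
    """Group of the best-scoring RT panel entry; structural DIRS evidence
    (inverted terminal repeats) overrides any homology call."""
    if element.repeat_mode is RepeatMode.INVERTED:
        return Group.DIRS
    rt = element.domain("RT")
    if rt is None:
        return Group.UNCLASSIFIED
    entry = panel.by_id(rt.best_reference)
    try:
        return Group(entry.group)
    except ValueError:
        return Group.UNCLASSIFIED


@dataclass
class FamilyAssignment:
    """One family: its id (e.g. G24), members (indices into the element list
    passed to :func:`cluster_families`) and the within-family LTR similarity
    matrix in member order."""

    family_id: str
    group: Group
    members: list[int]
    similarity: np.ndarray

    @property
    def size(self) -> int:
        return len(self.members)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_families(
    elements: list[ElementAnnotation],
    threshold: float = DEFAULT_FAMILY_THRESHOLD,
) -> list[FamilyAssignment]:
    """Single-linkage clustering of classified elements within each group.

    An element's representative sequence is its 5' LTR (``ltr_seq`` must be
    populated).  Two elements are linked when their LTR similarity is strictly
    greater than ``threshold``; families are the connected components.
    Family numbering is deterministic: per group, descending family size, then
    the genomically smallest member (scaffold, start).
    """
    for i, el in enumerate(elements):
        if el.ltr_seq is None:
            raise ValidationError(f"element #{i} has no cached 5' LTR sequence")
        if el.group is Group.UNCLASSIFIED:
            raise ValidationError(f"element #{i} is unclassified; classify before clustering")

    families: list[FamilyAssignment] = []
    for group in (Group.BEL, Group.COPIA, Group.DIRS, Group.GYPSY):
        idx = [i for i, el in enumerate(elements) if el.group is group]
        if not idx:
            continue
        n = len(idx)
        sim = np.full((n, n), 100.0)
        uf = _UnionFind(n)
        for a in range(n):
            for b in range(a + 1, n):
                s = dna_similarity(elements[idx[a]].ltr_seq, elements[idx[b]].ltr_seq)
                sim[a, b] = sim[b, a] = s
                if s > threshold:
                    uf.union(a, b)
        components: dict[int, list[int]] = {}
        for a in range(n):
            components.setdefault(uf.find(a), []).append(a)

        def genomic_key(local: list[int]) -> tuple:
            coords = [
                (elements[idx[a]].body.scaffold, elements[idx[a]].body.start)
                for a in local
            ]
            return min(coords)

        ordered = sorted(
            components.values(), key=lambda c: (-len(c), genomic_key(c))
        )
        for number, local in enumerate(ordered, start=1):
            local = sorted(
                local,
                key=lambda a: (elements[idx[a]].body.scaffold, elements[idx[a]].body.start),
            )
            sub = sim[np.ix_(local, local)]
            families.append(
                FamilyAssignment(
                    family_id=f"{group.letter}{number}",
                    group=group,
                    members=[idx[a] for a in local],
                    similarity=sub,
                )
            )
    return families


def assign_names(
    elements: list[ElementAnnotation],
    families: list[FamilyAssignment],
    genome_prefix: str = "Syn",
) -> list[ElementAnnotation]:
    """Name every element ``prefix_<letter><family>_<scaffold>_<index>``,
    where the index counts intact elements within a scaffold in genomic
    order (the second element of scaffold 147 gets index 2)."""
    order_in_scaffold: dict[int, int] = {}
    by_scaffold: dict[str, list[int]] = {}
    for i, el in enumerate(elements):
        by_scaffold.setdefault(el.body.scaffold, []).append(i)
    for scaffold, idxs in by_scaffold.items():
        for rank, i in enumerate(sorted(idxs, key=lambda i: elements[i].body.start), start=1):
            order_in_scaffold[i] = rank

    named = list(elements)
    for fam in families:
        number = int(fam.family_id[1:])
        for i in fam.members:
            el = elements[i]
            name = name_element(
                genome_prefix,
                fam.group.letter,
                number,
                el.body.scaffold,
                order_in_scaffold[i],
            )
            named[i] = el.with_identity(name, fam.family_id, fam.group)
    return named


def composition_summary(counts: dict) -> pd.DataFrame:
    """Per-group composition from bare element counts.

    Percentages are rounded to the nearest integer; the table carries the
    copia:gypsy element-count ratio (2 decimals) in ``df.attrs``.
    """
    clean = {Group(k) if not isinstance(k, Group) else k: int(v) for k, v in counts.items()}
    total = sum(clean.values())
    rows = []
    for group in (Group.BEL, Group.COPIA, Group.DIRS, Group.GYPSY):
        if group not in clean:
            continue
        n = clean[group]
        rows.append(
            {
                "group": group.value,
                "n_elements": n,
                "percent": int(round(100.0 * n / total)) if total else 0,
            }
        )
    df = pd.DataFrame(rows)
    if clean.get(Group.GYPSY):
        df.attrs["copia_gypsy_ratio"] = round(
            clean.get(Group.COPIA, 0) / clean[Group.GYPSY], 2
        )
    return df


def summarize_groups(
    elements: list[ElementAnnotation] | None = None,
    families: list[FamilyAssignment] | None = None,
    counts: dict | None = None,
) -> pd.DataFrame:
    """Composition table mirroring a per-group genome summary.

    Either pass clustered ``elements`` + ``families`` for the full table
    (element/family counts, LTR and element length statistics, percentages,
    copia:gypsy ratio) or bare per-group ``counts`` for the arithmetic-only
    form.
    """
    if counts is not None:
        return composition_summary(counts)
    if elements is None or families is None:
        return pd.DataFrame()
    if not elements:
        return pd.DataFrame()
    base = composition_summary(
        {
            g: sum(1 for el in elements if el.group is g)
            for g in (Group.BEL, Group.COPIA, Group.DIRS, Group.GYPSY)
            if any(el.group is g for el in elements)
        }
    )
    extra = []
    for group_name in base["group"]:
        group = Group(group_name)
        members = [el for el in elements if el.group is group]
        fams = [f for f in families if f.group is group]
        ltr_lens = [len(el.ltr5) for el in members] + [len(el.ltr3) for el in members]
        el_lens = [el.length for el in members]
        extra.append(
            {
                "n_families": len(fams),
                "ltr_len_mean": float(np.mean(ltr_lens)),
                "ltr_len_min": int(np.min(ltr_lens)),
                "ltr_len_max": int(np.max(ltr_lens)),
                "element_len_mean": float(np.mean(el_lens)),
                "element_len_min": int(np.min(el_lens)),
                "element_len_max": int(np.max(el_lens)),
            }
        )
    out = pd.concat([base, pd.DataFrame(extra)], axis=1)
    out.attrs.update(base.attrs)
    return out
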