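"""RT-based phylogenetics: progressive multiple alignment, Poisson-corrected
distances, Saitou-Nei neighbor joining and bootstrap supports.

Distances use pairwise deletion (a site counts for a pair only when both rows
hold residues) and the Poisson correction d = -ln(1 - p), which diverges as
p -> 1; p >= 0.95 is therefore clamped (with a warning).  All tie-breaks and
random resampling are deterministic, so trees are bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from ._align import local_score_and_identity
from .model import ValidationError

logger = logging.getLogger(__name__)

P_CLAMP = 0.95

_AA = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}

GAP_OPEN = 10.0
GAP_EXTEND = 0.5


@dataclass(frozen=True)
class MultipleAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValidationError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("alignment ids must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValidationError("alignment rows must have equal length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degap(self, taxon: str) -> str:
        return self.rows[self.ids.index(taxon)].replace("-", "")

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, row in zip(self.ids, self.rows):
                fh.write(f">{name}\n{row}\n")

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(tuple(ids), tuple(rows))


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("matrix shape must match taxon count")
        if not np.allclose(m, m.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ValidationError("distances must be finite and nonnegative")


@dataclass
class Node:
    name: Optional[str] = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with a trifurcating root."""

    root: Node

    def leaf_names(self) -> list[str]:
        return sorted(n.name for n in self.root.leaves())

    def bipartitions(self) -> set[frozenset]:
        """Canonical internal-edge splits: for each internal non-root node,
        the side of the split not containing the lexicographically smallest
        leaf."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        splits: set[frozenset] = set()

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            clade = frozenset().union(*(walk(c) for c in node.children))
            if node is not self.root and len(clade) > 1 and len(all_leaves - clade) > 1:
                side = clade if anchor not in clade else all_leaves - clade
                splits.add(side)
            return clade

        walk(self.root)
        return splits

    def to_newick(self, with_supports: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if with_supports and node.support is not None:
                label = f"{node.support:.0f}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------

def _blosum62_dense() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    dense = np.zeros((len(_AA), len(_AA)))
    for i, a in enumerate(_AA):
        for j, b in enumerate(_AA):
            dense[i, j] = mat[a, b]
    return dense


_S = None


def _profile(rows: Sequence[str]) -> np.ndarray:
    """Residue-count profile, shape (columns, 21); gaps contribute nothing."""
    n_cols = len(rows[0])
    prof = np.zeros((n_cols, len(_AA)))
    for row in rows:
        for j, aa in enumerate(row):
            if aa != "-":
                prof[j, _AA_INDEX.get(aa, _AA_INDEX["X"])] += 1
    return prof


def _merge_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Gotoh affine profile-profile alignment (BLOSUM62, open 10, extend 0.5);
    returns the two row groups with gap columns inserted."""
    global _S
    if _S is None:
        _S = _blosum62_dense()
    pa, pb = _profile(rows_a), _profile(rows_b)
    na, nb = len(rows_a), len(rows_b)
    score = (pa @ _S @ pb.T) / (na * nb)
    L1, L2 = score.shape
    NEG = -1e30
    M = np.full((L1 + 1, L2 + 1), NEG)
    Ix = np.full((L1 + 1, L2 + 1), NEG)  # gap in B (consume A)
    Iy = np.full((L1 + 1, L2 + 1), NEG)  # gap in A (consume B)
    M[0, 0] = 0.0
    for i in range(1, L1 + 1):
        Ix[i, 0] = -GAP_OPEN - GAP_EXTEND * (i - 1)
    for j in range(1, L2 + 1):
        Iy[0, j] = -GAP_OPEN - GAP_EXTEND * (j - 1)
    # tracebacks: 0=M,1=Ix,2=Iy
    tb_m = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)
    tb_x = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)
    tb_y = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)
    s = score  # local alias
    for i in range(1, L1 + 1):
        Mi1, Mi = M[i - 1], M[i]
        Ixi1, Ixi = Ix[i - 1], Ix[i]
        Iyi1, Iyi = Iy[i - 1], Iy[i]
        srow = s[i - 1]
        for j in range(1, L2 + 1):
            # match state
            best, arg = Mi1[j - 1], 0
            if Ixi1[j - 1] > best:
                best, arg = Ixi1[j - 1], 1
            if Iyi1[j - 1] > best:
                best, arg = Iyi1[j - 1], 2
            Mi[j] = best + srow[j - 1]
            tb_m[i, j] = arg
            # gap in B: consume column of A
            o, e = Mi1[j] - GAP_OPEN, Ixi1[j] - GAP_EXTEND
            if o >= e:
                Ixi[j], tb_x[i, j] = o, 0
            else:
                Ixi[j], tb_x[i, j] = e, 1
            # gap in A: consume column of B
            o, e = Mi[j - 1] - GAP_OPEN, Iyi[j - 1] - GAP_EXTEND
            if o >= e:
                Iyi[j], tb_y[i, j] = o, 0
            else:
                Iyi[j], tb_y[i, j] = e, 2

    ends = (M[L1, L2], Ix[L1, L2], Iy[L1, L2])
    state = int(np.argmax(ends))
    i, j = L1, L2
    path: list[int] = []
    while i > 0 or j > 0:
        path.append(state)
        if state == 0:
            nxt = tb_m[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            nxt = tb_x[i, j] if i > 1 or j > 0 else 1
            i -= 1
        else:
            nxt = tb_y[i, j] if j > 1 or i > 0 else 2
            j -= 1
        if i == 0 and j > 0:
            nxt = 2
        elif j == 0 and i > 0:
            nxt = 1
        state = nxt
    path.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for st in path:
        if st == 0:
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ia += 1
            ib += 1
        elif st == 1:
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            for k in range(len(rows_b)):
                out_b[k] += "-"
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
    return out_a, out_b


def align_progressive(peptides: Sequence[tuple[str, str]]) -> MultipleAlignment:
    """Progressive multiple alignment.

    Pairwise local-alignment identities give a distance matrix; an NJ guide
    tree fixes the merge order; profiles are merged with the affine Gotoh
    profile aligner.  Requires at least two sequences.
    """
    if len(peptides) < 2:
        raise ValidationError("progressive alignment needs >= 2 sequences")
    ids = [p[0] for p in peptides]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sequence ids")
    seqs = {p[0]: p[1].upper() for p in peptides}

    if len(peptides) == 2:
        a, b = ids
        ra, rb = _merge_profiles([seqs[a]], [seqs[b]])
        return MultipleAlignment((a, b), (ra[0], rb[0]))

    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, ident = local_score_and_identity(seqs[ids[i]], seqs[ids[j]])
            dm[i, j] = dm[j, i] = 1.0 - ident / 100.0
    guide = neighbor_joining(DistanceMatrix(tuple(ids), dm))

    def build(node: Node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.name], [seqs[node.name]]
        child_groups = [build(c) for c in node.children]
        names, rows = child_groups[0]
        for more_names, more_rows in child_groups[1:]:
            rows, more_rows = _merge_profiles(rows, more_rows)
            names = names + more_names
            rows = rows + more_rows
        return names, rows

    names, rows = build(guide.root)
    order = {name: k for k, name in enumerate(names)}
    ordered = sorted(ids, key=lambda x: order[x])
    # keep input order for output stability
    row_of = dict(zip(names, rows))
    return MultipleAlignment(tuple(ids), tuple(row_of[i] for i in ids))


# ---------------------------------------------------------------------------
# distances and NJ
# ---------------------------------------------------------------------------

def poisson_distance(alignment: MultipleAlignment) -> DistanceMatrix:
    """Poisson-corrected pairwise distances with pairwise gap deletion."""
    if alignment.n_rows < 2:
        raise ValidationError("need >= 2 rows")
    ids = alignment.ids
    arr = np.array([list(r) for r in alignment.rows])
    non_gap = arr != "-"
    n = len(ids)
    dm = np.zeros((n, n))
    d_cap = -math.log(1.0 - P_CLAMP)
    for i in range(n):
        for j in range(i + 1, n):
            shared = non_gap[i] & non_gap[j]
            sites = int(shared.sum())
            if sites == 0:
                raise ValidationError(
                    f"taxa {ids[i]!r} and {ids[j]!r} share no ungapped sites"
                )
            p = float((arr[i][shared] != arr[j][shared]).sum()) / sites
            if p >= P_CLAMP:
                logger.warning(
                    "p=%.3f for (%s, %s) clamped to %.2f", p, ids[i], ids[j], P_CLAMP
                )
                d = d_cap
            else:
                d = -math.log(1.0 - p)
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(ids, dm)


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    """Clamp a negative branch to zero, moving the deficit to its sibling."""
    if la < 0:
        lb = max(lb + la, 0.0)
        la = 0.0
    if lb < 0:
        la = max(la + lb, 0.0)
        lb = 0.0
    return la, lb


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the lexicographically smallest
    (cluster label, cluster label) pair, where a cluster's label is its
    smallest member taxon.  The result is an unrooted tree represented with a
    trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValidationError("neighbor joining needs >= 3 taxa")
    labels = list(dm.ids)
    nodes: dict[str, Node] = {t: Node(name=t) for t in labels}
    d = {
        (min(a, b), max(a, b)): float(dm.matrix[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }

    def dist(a: str, b: str) -> float:
        return 0.0 if a == b else d[(a, b) if a < b else (b, a)]

    active = sorted(labels)
    while len(active) > 3:
        m = len(active)
        r = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best_q = math.inf
        best_pair: Optional[tuple[str, str]] = None
        for ia in range(m):
            for ib in range(ia + 1, m):
                a, b = active[ia], active[ib]
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (a, b) < (best_pair or ("￿",) * 2)
                ):
                    best_q = q
                    best_pair = (a, b)
        a, b = best_pair
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb)
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length, child_b.length = la, lb
        parent_label = min(a, b)
        parent = Node(children=[child_a, child_b])
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (dist(a, c) + dist(b, c) - dab)
            key = (parent_label, c) if parent_label < c else (c, parent_label)
            d[key] = max(duc, 0.0)
        active = sorted(set(active) - {a, b} | {parent_label})
        nodes[parent_label] = parent

    # terminal three-point formulas
    a, b, c = active
    la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
    lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
    lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
    la, lb = _clamp_pair(la, lb)
    lc = max(lc, 0.0)
    na, nb, nc = nodes[a], nodes[b], nodes[c]
    na.length, nb.length, nc.length = la, lb, lc
    return PhyloTree(root=Node(children=[na, nb, nc]))


def bootstrap_support(
    alignment: MultipleAlignment,
    replicates: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """NJ tree on the full alignment with bootstrap supports on internal edges.

    Columns are resampled with replacement per replicate; an edge's support is
    the percentage of replicate trees containing its bipartition.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    if alignment.n_rows < 4:
        raise ValidationError("bootstrap needs >= 4 rows")
    tree = neighbor_joining(poisson_distance(alignment))
    target = tree.bipartitions()
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    n_cols = alignment.n_cols
    rows = np.array([list(r) for r in alignment.rows])
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = MultipleAlignment(
            alignment.ids, tuple("".join(row[cols]) for row in rows)
        )
        rep_tree = neighbor_joining(poisson_distance(resampled))
        for split in rep_tree.bipartitions():
            if split in counts:
                counts[split] += 1

    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)

    def annotate(node: Node) -> frozenset:
        if node.is_leaf:
            return frozenset([node.name])
        clade = frozenset().union(*(annotate(c) for c in node.children))
        if node is not tree.root and len(clade) > 1 and len(all_leaves - clade) > 1:
            side = clade if anchor not in clade else all_leaves - clade
            node.support = 100.0 * counts[side] / replicates
        return clade

    annotate(tree.root)
    return tree
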