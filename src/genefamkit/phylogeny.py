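"""Poisson-corrected distances, neighbor-joining, bootstrap, and clade assignment.

Distances between aligned protein sequences use the Poisson correction
d = -ln(1 - p), with p the proportion of differing sites over the columns
retained by the deletion rule (complete deletion drops every column with a
gap in any row; pairwise deletion drops columns with a gap in either member
of the pair).  Trees are built with the Saitou-Nei neighbor-joining
algorithm under the standard Q criterion, with deterministic lexicographic
tie-breaking so results are platform-independent.  Bootstrap support is the
percentage of column-resampled replicates whose NJ tree contains each
internal bipartition of the point-estimate tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .io_formats import ValidationError

SATURATION_CLAMP = 1.0 - 1e-6


@dataclass(frozen=True)
class MsaView:
    """An immutable view of a multiple sequence alignment ('-' = gap)."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValidationError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("duplicate ids in alignment")
        if len({len(r) for r in self.rows}) > 1:
            raise ValidationError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, rng: np.random.Generator) -> "MsaView":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        return MsaView(self.ids, tuple("".join(r[c] for c in cols) for r in self.rows))


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray  # symmetric, zero diagonal
    saturated_pairs: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("matrix shape does not match id count")
        if not np.allclose(m, m.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValidationError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(m)):
            raise ValidationError("non-finite distances")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.matrix[i, j])


class PhyloTree:
    """An unrooted tree with branch lengths and optional bootstrap supports.

    Thin wrapper over a :class:`dendropy.Tree`; construction from and export
    to Newick are stable round trips.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls(tree)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_ids(self) -> frozenset[str]:
        return frozenset(l.taxon.label for l in self._tree.leaf_node_iter())

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True,
                                    unquoted_underscores=True).strip()

    def splits(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each normalized to the side NOT
        containing the alphabetically first leaf."""
        all_leaves = self.leaf_ids
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()
        for node in self._tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if anchor in side:
                side = all_leaves - side
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(side)
        return out

    def midpoint_rooted(self) -> "PhyloTree":
        clone = self._tree.clone(depth=1)
        clone.reroot_at_midpoint(update_bipartitions=True)
        return PhyloTree(clone)

    def clade_leafset(self, ids: list[str]) -> frozenset[str]:
        """Leaves of the smallest clade containing all ``ids`` (on this rooting)."""
        missing = set(ids) - self.leaf_ids
        if missing:
            raise ValidationError(f"leaves missing from tree: {sorted(missing)}")
        mrca = self._tree.mrca(taxon_labels=list(ids))
        return frozenset(l.taxon.label for l in mrca.leaf_iter())


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def poisson_distance(msa: MsaView, deletion: str = "complete") -> DistanceMatrix:
    """Poisson-corrected pairwise distances d = -ln(1 - p).

    ``deletion`` is 'complete' (only columns gap-free in every row are
    compared, same column set for all pairs) or 'pairwise' (columns gap-free
    in the two rows of each pair).  p values at or above the saturation
    clamp are clamped and the pair flagged.
    """
    if deletion not in {"complete", "pairwise"}:
        raise ValueError(f"unknown deletion rule {deletion!r}")
    if len(msa.ids) < 2:
        raise ValidationError("need at least 2 sequences")
    n = len(msa.ids)
    rows = msa.rows
    if deletion == "complete":
        keep = [c for c in range(msa.n_columns)
                if all(r[c] != "-" for r in rows)]
        rows = tuple("".join(r[c] for c in keep) for r in rows)
    m = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            if deletion == "pairwise":
                cols = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            else:
                cols = list(zip(a, b))
            if not cols:
                raise ValidationError(
                    f"no comparable columns for pair ({msa.ids[i]}, {msa.ids[j]})")
            p = sum(1 for x, y in cols if x != y) / len(cols)
            if p >= SATURATION_CLAMP:
                p = SATURATION_CLAMP
                saturated.add((msa.ids[i], msa.ids[j]))
            m[i, j] = m[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(tuple(msa.ids), m, frozenset(saturated))


def pairwise_poisson_distance(records) -> DistanceMatrix:
    """Poisson-corrected distances from per-pair global alignments.

    For heterogeneous sets (e.g. candidates plus unrelated outgroups) a
    single multiple alignment can misalign the divergent members; aligning
    each pair on its own gives cleaner difference proportions.  Gapped
    columns of each pairwise alignment are ignored.
    """
    from .align import pairwise_align

    ids = tuple(r.id for r in records)
    n = len(ids)
    m = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb, _ = pairwise_align(records[i].sequence, records[j].sequence)
            cols = [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]
            if not cols:
                raise ValidationError(f"no comparable columns for ({ids[i]}, {ids[j]})")
            p = sum(1 for x, y in cols if x != y) / len(cols)
            if p >= SATURATION_CLAMP:
                p = SATURATION_CLAMP
                saturated.add((ids[i], ids[j]))
            m[i, j] = m[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(ids, m, frozenset(saturated))


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("label", "children", "key")

    def __init__(self, label: str | None, children=None, key: str = ""):
        self.label = label
        self.children: list[tuple[_Node, float]] = children or []
        self.key = key  # smallest descendant leaf id, for tie-breaking

    def newick(self) -> str:
        if not self.children:
            return self.label or ""
        parts = ",".join(f"{c.newick()}:{bl:.10g}" for c, bl in self.children)
        return f"({parts})"


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch of the same join (preserving their sum).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValidationError("need at least 3 leaves for an unrooted tree")
    nodes: list[_Node] = [_Node(i_, key=i_) for i_ in dm.ids]
    d = {(a, b): float(dm.matrix[i, j])
         for i, a in enumerate(dm.ids) for j, b in enumerate(dm.ids)}

    def dist(x: _Node, y: _Node) -> float:
        return d[(x.key, y.key)]

    while len(nodes) > 3:
        m = len(nodes)
        r = {x.key: sum(dist(x, y) for y in nodes if y is not x) for x in nodes}
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                x, y = nodes[i], nodes[j]
                q = (m - 2) * dist(x, y) - r[x.key] - r[y.key]
                tie = tuple(sorted((x.key, y.key)))
                if best is None or q < best[0] - 1e-12 or (
                        abs(q - best[0]) <= 1e-12 and tie < best[1]):
                    best = (q, tie, x, y)
        _, _, x, y = best
        dxy = dist(x, y)
        lx = 0.5 * dxy + (r[x.key] - r[y.key]) / (2 * (m - 2))
        ly = dxy - lx
        # clamp negatives, preserving lx + ly
        if lx < 0:
            ly += lx
            lx = 0.0
        if ly < 0:
            lx += ly
            ly = 0.0
        lx, ly = max(lx, 0.0), max(ly, 0.0)
        new = _Node(None, [(x, lx), (y, ly)], key=min(x.key, y.key))
        for z in nodes:
            if z is x or z is y:
                continue
            dz = 0.5 * (dist(x, z) + dist(y, z) - dxy)
            d[(new.key, z.key)] = d[(z.key, new.key)] = dz
        d[(new.key, new.key)] = 0.0
        nodes = [z for z in nodes if z is not x and z is not y] + [new]

    x, y, z = nodes
    dxy, dxz, dyz = dist(x, y), dist(x, z), dist(y, z)
    lx = max(0.5 * (dxy + dxz - dyz), 0.0)
    ly = max(0.5 * (dxy + dyz - dxz), 0.0)
    lz = max(0.5 * (dxz + dyz - dxy), 0.0)
    root = _Node(None, [(x, lx), (y, ly), (z, lz)], key=min(x.key, y.key, z.key))
    return PhyloTree.from_newick(root.newick() + ";")


def bootstrap_support(msa: MsaView, replicates: int = 1000, seed: int = 0,
                      deletion: str = "complete") -> tuple[PhyloTree, dict[frozenset[str], float]]:
    """Point-estimate NJ tree plus bootstrap support per internal split.

    Returns the point tree (with supports attached as internal node labels)
    and the split -> support-% mapping.  The point-estimate topology does
    not depend on the seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    point = nj_tree(poisson_distance(msa, deletion))
    point_splits = point.splits()
    counts = {s: 0 for s in point_splits}
    for _ in range(replicates):
        rep = msa.resample_columns(rng)
        try:
            rep_splits = nj_tree(poisson_distance(rep, deletion)).splits()
        except ValidationError:
            continue  # replicate lost all comparable columns for some pair
        for s in point_splits:
            if s in rep_splits:
                counts[s] += 1
    support = {s: 100.0 * c / replicates for s, c in counts.items()}

    all_leaves = point.leaf_ids
    anchor = min(all_leaves)
    for node in point.dendropy_tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if anchor in side:
            side = all_leaves - side
        if side in support:
            node.label = f"{support[side]:.0f}"
    return point, support


def assign_groups(tree: PhyloTree,
                  reference_groups: dict[str, list[str]]) -> dict[str, str]:
    """Assign each non-reference leaf to a reference group by nesting.

    The tree is midpoint-rooted; each non-reference leaf takes the majority
    group of the references in the smallest clade containing it and at
    least one reference.  A leaf whose smallest such clade is the whole
    tree is 'ungrouped'; an exact majority tie is 'ambiguous'.
    """
    ref_to_group: dict[str, str] = {}
    for group, ids in reference_groups.items():
        for rid in ids:
            ref_to_group[rid] = group
    missing = set(ref_to_group) - tree.leaf_ids
    if missing:
        raise ValidationError(f"reference leaves missing: {sorted(missing)}")
    rooted = tree.midpoint_rooted()
    dtree = rooted.dendropy_tree
    n_leaves = len(rooted.leaf_ids)
    out: dict[str, str] = {}
    for leaf in dtree.leaf_node_iter():
        label = leaf.taxon.label
        if label in ref_to_group:
            continue
        node = leaf.parent_node
        while node is not None:
            clade = [l.taxon.label for l in node.leaf_iter()]
            refs_in = [ref_to_group[l] for l in clade if l in ref_to_group]
            if refs_in:
                if len(clade) == n_leaves:
                    out[label] = "ungrouped"
                else:
                    best = sorted(set(refs_in),
                                  key=lambda g: (-refs_in.count(g), g))
                    if (len(best) > 1 and
                            refs_in.count(best[0]) == refs_in.count(best[1])):
                        out[label] = "ambiguous"
                    else:
                        out[label] = best[0]
                break
            node = node.parent_node
        else:
            out[label] = "ungrouped"
    return out
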