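"""Distance phylogeny with bootstrap supports and subclass assignment.

The in-scope estimator is neighbor joining (Saitou & Nei) on p- or
Poisson-corrected protein distances, after removing alignment columns with
insufficient site coverage.  Bootstrap supports (percent of column-resample
replicates reproducing each internal bipartition of the full-data tree) are
attached to the tree, edges below a collapse threshold can be contracted to
polytomies, and family subclasses are assigned to query genes that fall in
a sufficiently supported clade with reference genes of a single subclass.

A full maximum-likelihood tree search is deliberately not implemented here:
distance/NJ is the classical seed for such searches, and an externally
computed ML tree in Newick form (supports as internal node labels) can be
loaded with :meth:`SupportTree.from_newick` and used for assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode

__all__ = [
    "SupportTree",
    "SubclassAssignment",
    "filter_columns",
    "protein_distance",
    "nj_tree",
    "bootstrap_tree",
    "assign_subclasses",
]

Msa = Mapping[str, str]

_GAPS = set("-.")


def _check_aligned(msa: Msa) -> int:
    if not msa:
        raise ValueError("empty alignment")
    widths = {len(s) for s in msa.values()}
    if len(widths) != 1:
        raise ValueError("ragged alignment: rows differ in length")
    return widths.pop()


def filter_columns(msa: Msa, min_coverage: float = 0.95) -> dict[str, str]:
    """Keep columns whose fraction of non-gap residues is >= ``min_coverage``."""
    width = _check_aligned(msa)
    rows = list(msa.values())
    n = len(rows)
    keep = [
        j
        for j in range(width)
        if sum(r[j] not in _GAPS for r in rows) / n >= min_coverage
    ]
    if not keep:
        raise ValueError("column filter removed every alignment column")
    return {name: "".join(seq[j] for j in keep) for name, seq in msa.items()}


def protein_distance(msa: Msa, model: str = "poisson") -> DistanceMatrix:
    """Pairwise protein distances with pairwise deletion of gap sites.

    ``model="p"`` gives the raw mismatch proportion; ``model="poisson"``
    applies the Poisson correction ``d = -ln(1 - p)``.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    _check_aligned(msa)
    labels = list(msa.keys())
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    arr = np.array([list(msa[l]) for l in labels])
    gap = np.isin(arr, list(_GAPS))
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
            p = float((arr[i, ok] != arr[j, ok]).sum()) / total
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated distance between {labels[i]!r} and {labels[j]!r}"
                    )
                d = -math.log(1.0 - p)
            else:
                d = p
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids=labels)


class SupportTree:
    """An unrooted tree with bootstrap supports on internal edges.

    Internally the topology is held as a :class:`skbio.tree.TreeNode`
    rooted at an arbitrary trifurcation; each non-root internal node
    carries a ``support`` attribute (percent, or ``None`` when supports
    have not been computed).  ``supports`` keeps the pre-collapse support
    of every internal bipartition, so low-support edges remain reportable
    after the tree itself has been collapsed.
    """

    def __init__(self, tree: TreeNode):
        self.tree = tree
        #: pre-collapse support per bipartition (frozenset of tip names)
        self.supports: dict[frozenset, float] = {}

    # -- construction ------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "SupportTree":
        """Parse Newick with internal node labels read as supports."""
        tree = TreeNode.read([newick])
        st = cls(tree)
        for node in tree.non_tips():
            support = None
            if node.name is not None:
                try:
                    support = float(node.name)
                except ValueError:
                    support = None
            node.support = support
            if support is not None:
                st.supports[frozenset(t.name for t in node.tips())] = support
        return st

    def to_newick(self) -> str:
        """Newick string with supports as internal node labels."""
        import io

        clone = self.tree.copy()
        for node in clone.non_tips():
            support = getattr(node, "support", None)
            node.name = (
                None if support is None else f"{support:g}"
            )
            # keep skbio's writer from prefixing its own support field
            node.support = None
        buf = io.StringIO()
        clone.write(buf, format="newick")
        return buf.getvalue().strip()

    # -- queries -----------------------------------------------------
    @property
    def leaf_names(self) -> list[str]:
        return sorted(t.name for t in self.tree.tips())

    def internal_bipartitions(self) -> dict[frozenset, Optional[float]]:
        """Tip-set side of each internal edge -> support (None if unset)."""
        out: dict[frozenset, Optional[float]] = {}
        for node in self.tree.non_tips():
            if node is self.tree:
                continue
            side = frozenset(t.name for t in node.tips())
            out[side] = getattr(node, "support", None)
        return out

    def collapse(self, min_support: float) -> None:
        """Contract internal edges with support below ``min_support``.

        The collapsed edge's length is added to its children; pre-collapse
        supports remain available in :attr:`supports`.
        """
        changed = True
        while changed:
            changed = False
            for node in list(self.tree.non_tips()):
                if node is self.tree:
                    continue
                support = getattr(node, "support", None)
                if support is not None and support < min_support:
                    parent = node.parent
                    for child in list(node.children):
                        if node.length is not None and child.length is not None:
                            child.length += node.length
                        parent.append(child)
                    parent.remove(node)
                    changed = True
                    break


def nj_tree(d: DistanceMatrix) -> SupportTree:
    """Neighbor joining (Saitou & Nei) with deterministic tie-breaking.

    Equal Q-criterion minima are resolved toward the lexicographically
    smallest pair of subtree labels (the smallest tip name each subtree
    contains), so the topology is stable across platforms and input
    orderings.  Supports are left unset.
    """
    data = np.asarray(d.data, dtype=float)
    if not np.allclose(data, data.T):
        raise ValueError("distance matrix must be symmetric")
    labels = list(d.ids)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")

    nodes = [TreeNode(name=l) for l in labels]
    keys = list(labels)  # tie-break key: smallest tip label in subtree
    dist = data.copy()

    while len(nodes) > 3:
        n = len(nodes)
        r = dist.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * dist[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key)
                if best is None or cand < best[0:2]:
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        li = dist[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dist[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(li)
        child_j.length = float(lj)
        parent = TreeNode(children=[child_i, child_j])
        new_row = np.array(
            [
                (dist[i, k] + dist[j, k] - dist[i, j]) / 2.0
                for k in range(n)
                if k not in (i, j)
            ]
        )
        mask = [k for k in range(n) if k not in (i, j)]
        dist = dist[np.ix_(mask, mask)]
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row
        dist[:-1, -1] = new_row
        nodes = [nodes[k] for k in mask] + [parent]
        keys = [keys[k] for k in mask] + [min(keys[i], keys[j])]

    # resolve the final three subtrees around a central node
    (a, b, c) = nodes
    dab, dac, dbc = dist[0, 1], dist[0, 2], dist[1, 2]
    a.length = float((dab + dac - dbc) / 2.0)
    b.length = float((dab + dbc - dac) / 2.0)
    c.length = float((dac + dbc - dab) / 2.0)
    root = TreeNode(children=[a, b, c])
    for node in root.non_tips():
        node.support = None
    return SupportTree(root)


def _canonical(side: frozenset, all_tips: frozenset, anchor: str) -> frozenset:
    """Orient a bipartition side away from the anchor taxon."""
    return all_tips - side if anchor in side else side


def bootstrap_tree(
    msa: Msa,
    n_reps: int = 100,
    seed: Optional[int] = None,
    collapse_below: float = 30.0,
    model: str = "poisson",
) -> SupportTree:
    """NJ tree with bootstrap supports from column resampling.

    Supports are attached to the bipartitions of the full-data tree (the
    percentage of replicates whose NJ tree contains the same bipartition);
    edges supported below ``collapse_below`` percent are contracted.  All
    pre-collapse supports stay available in :attr:`SupportTree.supports`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    width = _check_aligned(msa)
    labels = list(msa.keys())
    full = nj_tree(protein_distance(msa, model=model))
    all_tips = frozenset(labels)
    anchor = min(labels)
    counts: dict[frozenset, int] = {
        _canonical(side, all_tips, anchor): 0
        for side in full.internal_bipartitions()
    }
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        rep_msa = {name: "".join(seq[j] for j in cols) for name, seq in msa.items()}
        rep_tree = nj_tree(protein_distance(rep_msa, model=model))
        rep_sides = {
            _canonical(s, all_tips, anchor)
            for s in rep_tree.internal_bipartitions()
        }
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    for node in full.tree.non_tips():
        if node is full.tree:
            continue
        side = _canonical(
            frozenset(t.name for t in node.tips()), all_tips, anchor
        )
        support = 100.0 * counts[side] / n_reps
        node.support = support
        full.supports[frozenset(t.name for t in node.tips())] = support
    if collapse_below > 0:
        full.collapse(collapse_below)
    return full


@dataclass(frozen=True)
class SubclassAssignment:
    """Subclass call for one query gene.

    ``status`` is "assigned" (clean clade at sufficient support),
    "motif_needed" (a clean clade exists but below the support threshold,
    so motif evidence must complement the phylogeny) or "unassigned"
    (every reference-containing clade around the query mixes subclasses).
    """

    gene: str
    subclass: Optional[str]
    support: Optional[float]
    evidence: str  # "phylogeny" or "phylogeny+motif-needed"
    status: str
    candidate_subclass: Optional[str] = None


def assign_subclasses(
    tree: SupportTree,
    reference: Mapping[str, str],
    min_support: float = 70.0,
) -> list[SubclassAssignment]:
    """Assign subclasses to query leaves from reference-gene clades.

    A query is assigned subclass *s* when it lies inside a clade with
    support >= ``min_support`` containing at least one reference gene of
    subclass *s* and none of any other subclass; the smallest such clade
    decides.  Only internal-edge bipartitions (either side) count as
    clades — the complement of a single leaf is maximally uninformative
    and is excluded.  Trees without computed supports are treated as
    fully supported (support 100 on every edge).
    """
    leaves = set(tree.leaf_names)
    missing = set(reference) - leaves
    if missing:
        raise ValueError(f"reference genes absent from tree: {sorted(missing)}")
    queries = sorted(leaves - set(reference))

    sides: list[tuple[frozenset, float]] = []
    for side, support in tree.internal_bipartitions().items():
        s = 100.0 if support is None else support
        sides.append((side, s))
        sides.append((frozenset(leaves) - side, s))

    out = []
    for q in queries:
        candidates = []  # (size, -support, subclass)
        for side, support in sides:
            if q not in side:
                continue
            refs = {reference[g] for g in side if g in reference}
            if len(refs) == 1:
                candidates.append((len(side), -support, refs.pop()))
        strong = [c for c in candidates if -c[1] >= min_support]
        if strong:
            size, neg_support, sub = min(strong)
            out.append(
                SubclassAssignment(q, sub, -neg_support, "phylogeny", "assigned")
            )
        elif candidates:
            size, neg_support, sub = min(candidates)
            out.append(
                SubclassAssignment(
                    q, None, -neg_support, "phylogeny+motif-needed",
                    "motif_needed", candidate_subclass=sub,
                )
            )
        else:
            out.append(
                SubclassAssignment(
                    q, None, None, "phylogeny+motif-needed", "unassigned"
                )
            )
    return out
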