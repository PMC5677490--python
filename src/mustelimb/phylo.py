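"""Dated trees and regime paintings.

A :class:`DatedTree` is a rooted, binary, ultrametric phylogeny with branch
lengths in millions of years (My).  Nodes are integer ids; the edge above a
non-root node is identified by that node's id.  Ages run backwards from the
present, so extant tips sit at age 0 and the root at age equal to the tree
height.

A :class:`RegimePainting` assigns a selective regime to every point of every
branch as an ordered (rootward to tipward) list of ``(regime, duration)``
segments per edge, plus the regime in force at the root.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "DatedTree",
    "RegimePainting",
    "NewickParseError",
    "TreeError",
    "parse_newick",
    "paint_from_node_states",
    "branch_lengths",
]

#: relative tolerance for the ultrametricity check (× tree height); published
#: dated trees carry rounded branch lengths, so an absolute check is too strict
ULTRAMETRIC_RTOL = 1e-6

#: edge length (My) inserted when an opt-in polytomy resolution is requested
RESOLUTION_EDGE_LENGTH = 1e-8


class TreeError(ValueError):
    """Structural problem with a tree (non-binary, non-ultrametric, ...)."""


class NewickParseError(ValueError):
    """Malformed Newick input."""


class DatedTree:
    """Immutable rooted binary ultrametric tree with branch lengths in My.

    Parameters
    ----------
    parent
        ``parent[i]`` is the parent node id of node ``i`` (-1 for the root).
    length
        ``length[i]`` is the length of the edge above node ``i`` in My
        (``nan`` for the root).
    labels
        Per-node labels; every tip must carry a unique label, internal labels
        are optional and ignored by all algorithms.
    """

    def __init__(
        self,
        parent: Sequence[int],
        length: Sequence[float],
        labels: Sequence[str | None],
        validate: bool = True,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"expected exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[int(self.parent[i])].append(i)
        self.tips = [i for i in range(n) if not self.children[i]]
        self.tip_labels = [self.labels[i] for i in self.tips]
        self._tip_index = {lab: k for k, lab in enumerate(self.tip_labels)}
        self._tip_node = {lab: i for i, lab in zip(self.tips, self.tip_labels)}
        self.preorder = self._preorder()
        self.postorder = self.preorder[::-1]
        self.depth = np.zeros(n)
        for v in self.preorder:
            if v != self.root:
                self.depth[v] = self.depth[self.parent[v]] + self.length[v]
        tip_depths = self.depth[self.tips]
        self.height = float(tip_depths.max()) if self.tips else 0.0
        self.ages = self.height - self.depth
        self._cache: dict[str, object] = {}
        if validate:
            self._validate()

    # -- construction -----------------------------------------------------

    def _preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(reversed(self.children[v]))
        if len(order) != self.parent.size:
            raise TreeError("tree is not connected (unreachable nodes)")
        return order

    def _validate(self) -> None:
        n = self.parent.size
        for i in range(n):
            if i == self.root:
                continue
            if not self.length[i] > 0:
                raise TreeError(f"edge above node {i} has non-positive length {self.length[i]}")
        for lab in self.tip_labels:
            if lab is None:
                raise TreeError("every tip must carry a label")
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise TreeError("tip labels are not unique")
        for v in range(n):
            k = len(self.children[v])
            if k not in (0, 2):
                raise TreeError(
                    f"node {v} has {k} children; tree must be binary "
                    "(resolve polytomies explicitly)"
                )
        if self.n_tips >= 2 and self.height > 0:
            spread = self.depth[self.tips].max() - self.depth[self.tips].min()
            if spread > ULTRAMETRIC_RTOL * self.height:
                raise TreeError(
                    f"tree is not ultrametric: root-to-tip spread {spread:g} "
                    f"exceeds {ULTRAMETRIC_RTOL:g} x height {self.height:g}"
                )

    # -- basic properties --------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def edges(self) -> list[int]:
        """Edge ids: every node except the root names the edge above it."""
        return [v for v in self.preorder if v != self.root]

    def tip_node(self, label: str) -> int:
        try:
            return self._tip_node[label]
        except KeyError:
            raise TreeError(f"no tip labelled {label!r}") from None

    def tip_index(self, label: str) -> int:
        """Index of a tip label in the canonical (preorder) tip ordering."""
        return self._tip_index[label]

    # -- cached matrices ---------------------------------------------------

    def lineage(self, tip: int) -> list[int]:
        """Edge ids on the root-to-tip path, rootward first."""
        path = []
        v = tip
        while v != self.root:
            path.append(v)
            v = int(self.parent[v])
        return path[::-1]

    def _ancestor_sets(self) -> list[set[int]]:
        key = "anc"
        if key not in self._cache:
            sets = []
            for t in self.tips:
                s = set()
                v = t
                while v != -1:
                    s.add(v)
                    v = int(self.parent[v]) if v != self.root else -1
                sets.append(s)
            self._cache[key] = sets
        return self._cache[key]  # type: ignore[return-value]

    def mrca(self, labels: Iterable[str]) -> int:
        """Most recent common ancestor node of a set of tip labels."""
        labs = list(labels)
        if not labs:
            raise TreeError("mrca of an empty set")
        common: set[int] | None = None
        for lab in labs:
            s = self._ancestor_sets()[self.tip_index(lab)]
            common = s if common is None else common & s
        assert common
        return max(common, key=lambda v: self.depth[v])

    def mrca_matrix(self) -> np.ndarray:
        """Tip × tip matrix of MRCA node ids in canonical tip order."""
        if "mrca" not in self._cache:
            nt = self.n_tips
            anc = self._ancestor_sets()
            m = np.empty((nt, nt), dtype=np.int64)
            for i in range(nt):
                m[i, i] = self.tips[i]
                for j in range(i + 1, nt):
                    common = anc[i] & anc[j]
                    v = max(common, key=lambda u: self.depth[u])
                    m[i, j] = m[j, i] = v
            self._cache["mrca"] = m
        return self._cache["mrca"]  # type: ignore[return-value]

    def shared_times(self) -> np.ndarray:
        """Tip × tip matrix of shared path durations from the root (My)."""
        if "shared" not in self._cache:
            self._cache["shared"] = self.depth[self.mrca_matrix()]
        return self._cache["shared"]  # type: ignore[return-value]

    def tip_distances(self) -> np.ndarray:
        """Tip × tip patristic distance matrix (My)."""
        if "dist" not in self._cache:
            d = self.depth[np.asarray(self.tips)]
            self._cache["dist"] = d[:, None] + d[None, :] - 2.0 * self.shared_times()
        return self._cache["dist"]  # type: ignore[return-value]

    def tip_descendants(self, edge: int) -> np.ndarray:
        """Boolean mask (canonical tip order) of tips below an edge."""
        key = ("desc", edge)
        if key not in self._cache:
            anc = self._ancestor_sets()
            self._cache[key] = np.array([edge in anc[i] for i in range(self.n_tips)])
        return self._cache[key]  # type: ignore[return-value]

    # -- editing (returns new trees) ---------------------------------------

    def graft(self, taxon: str, sister: str | Iterable[str], divergence_age: float) -> "DatedTree":
        """Attach an extant tip on the stem of ``sister`` at ``divergence_age``.

        ``sister`` is either a tip label or an iterable of tip labels naming a
        clade; the new tip is inserted on the edge above that tip/clade at the
        node of age ``divergence_age`` and receives a pendant edge of the same
        length, keeping the tree ultrametric.
        """
        if taxon in self._tip_index:
            raise TreeError(f"taxon {taxon!r} already present")
        if isinstance(sister, str):
            v = self.tip_node(sister)
        else:
            v = self.mrca(sister)
        if v == self.root:
            raise TreeError("cannot graft on the root (no stem edge)")
        p = int(self.parent[v])
        lo, hi = self.ages[v], self.ages[p]
        if not (lo < divergence_age < hi):
            raise TreeError(
                f"divergence age {divergence_age:g} outside the sister stem "
                f"interval ({lo:g}, {hi:g})"
            )
        n = self.n_nodes
        mid, tip = n, n + 1
        parent = np.concatenate([self.parent, [p, mid]])
        length = np.concatenate([self.length, [hi - divergence_age, divergence_age]])
        parent[v] = mid
        length[v] = divergence_age - lo
        labels = self.labels + [None, taxon]
        return DatedTree(parent, length, labels)

    def prune(self, taxon: str) -> "DatedTree":
        """Remove a tip and suppress the resulting degree-two node."""
        t = self.tip_node(taxon)
        if self.n_tips <= 2:
            raise TreeError("cannot prune below two tips")
        p = int(self.parent[t])
        sib = next(c for c in self.children[p] if c != t)
        keep = [v for v in range(self.n_nodes) if v not in (t, p)]
        remap = {v: i for i, v in enumerate(keep)}
        parent, length, labels = [], [], []
        g = int(self.parent[p]) if p != self.root else -1
        for v in keep:
            pv = int(self.parent[v])
            lv = float(self.length[v])
            if v == sib:
                if p == self.root:
                    pv, lv = -1, math.nan
                else:
                    pv = g
                    lv = lv + float(self.length[p])
            parent.append(remap[pv] if pv >= 0 else -1)
            length.append(lv)
            labels.append(self.labels[v])
        return DatedTree(parent, length, labels)

    # -- serialisation -----------------------------------------------------

    def to_newick(self, painting: "RegimePainting | None" = None) -> str:
        """Newick string; with a painting, edges carry ``[&regimes=...]`` comments."""

        def fmt(v: int) -> str:
            if self.children[v]:
                body = "(" + ",".join(fmt(c) for c in self.children[v]) + ")"
            else:
                body = self.labels[v] or ""
            if v == self.root:
                return body
            ann = ""
            if painting is not None:
                segs = painting.segments[v]
                ann = "[&regimes=" + "|".join(f"{r}:{d:.9g}" for r, d in segs) + "]"
            return f"{body}:{float(self.length[v]):.17g}{ann}"

        return fmt(self.root) + ";"

    def to_dict(self) -> dict:
        return {
            "parent": self.parent.tolist(),
            "length": [None if math.isnan(x) else x for x in self.length],
            "labels": self.labels,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DatedTree":
        length = [math.nan if x is None else x for x in d["length"]]
        return cls(d["parent"], length, list(d["labels"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "DatedTree":
        return cls.from_dict(json.loads(s))

    @classmethod
    def from_newick(cls, text: str, resolve_polytomies: bool = False) -> "DatedTree":
        return parse_newick(text, resolve_polytomies=resolve_polytomies)

    def __repr__(self) -> str:
        return f"<DatedTree {self.n_tips} tips, height {self.height:.4g} My>"


def parse_newick(text: str, resolve_polytomies: bool = False) -> DatedTree:
    """Parse a Newick string (branch lengths required) into a :class:`DatedTree`.

    Polytomies are rejected unless ``resolve_polytomies=True``, in which case
    they are broken into binary nodes by inserting edges of
    ``RESOLUTION_EDGE_LENGTH`` My (covered by the relative ultrametricity
    tolerance).
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        col = getattr(exc, "col_num", None)
        where = f" near character {col}" if col is not None else ""
        raise NewickParseError(f"malformed Newick{where}: {exc}") from exc

    if resolve_polytomies:
        dt.resolve_polytomies()
        for e in dt.preorder_edge_iter():
            if e.head_node is not dt.seed_node and (e.length is None or e.length == 0):
                # only edges created by resolution can be length-less here;
                # genuine missing lengths are caught below on original edges
                e.length = e.length if e.length else RESOLUTION_EDGE_LENGTH

    ids: dict = {}
    parent: list[int] = []
    length: list[float] = []
    labels: list[str | None] = []
    for node in dt.preorder_node_iter():
        ids[node] = len(parent)
        if node is dt.seed_node:
            parent.append(-1)
            length.append(math.nan)
        else:
            if node.edge.length is None:
                raise NewickParseError("missing branch length in Newick input")
            parent.append(ids[node.parent_node])
            length.append(float(node.edge.length))
        lab = node.taxon.label if node.taxon is not None else node.label
        labels.append(lab)
    return DatedTree(parent, length, labels)


def branch_lengths(tree: DatedTree) -> np.ndarray:
    """All edge lengths of the tree, sorted ascending (2n−2 for n tips)."""
    return np.sort(np.array([tree.length[e] for e in tree.edges]))


# ---------------------------------------------------------------------------
# regime paintings


@dataclass(frozen=True)
class RegimePainting:
    """Assignment of a regime to every point of every branch.

    ``segments[edge]`` is an ordered (rootward→tipward) tuple of
    ``(regime, duration)`` pairs whose durations sum to the edge length; the
    first segment continues the regime in force at the parent end.
    """

    root_regime: str
    segments: Mapping[int, tuple[tuple[str, float], ...]]

    @property
    def regimes(self) -> tuple[str, ...]:
        seen = {self.root_regime}
        for segs in self.segments.values():
            for r, _ in segs:
                seen.add(r)
        return tuple(sorted(seen))

    def regime_at_node(self, tree: DatedTree, node: int) -> str:
        """Regime in force at a node (tipward end of its edge)."""
        if node == tree.root:
            return self.root_regime
        return self.segments[node][-1][0]

    @classmethod
    def single_regime(cls, tree: DatedTree, label: str = "base") -> "RegimePainting":
        segs = {e: ((label, float(tree.length[e])),) for e in tree.edges}
        return cls(root_regime=label, segments=segs)

    def validate(self, tree: DatedTree, rtol: float = 1e-9) -> None:
        """Check segment conservation, adjacency and parent-end continuity."""
        for e in tree.edges:
            segs = self.segments.get(e)
            if not segs:
                raise TreeError(f"edge {e} has no painting segments")
            total = sum(d for _, d in segs)
            L = float(tree.length[e])
            if abs(total - L) > rtol * max(L, 1.0):
                raise TreeError(
                    f"segments on edge {e} sum to {total:g}, edge length {L:g}"
                )
            if any(d <= 0 for _, d in segs):
                raise TreeError(f"non-positive segment duration on edge {e}")
            for (r1, _), (r2, _) in zip(segs, segs[1:]):
                if r1 == r2:
                    raise TreeError(f"adjacent equal-regime segments on edge {e}")
            parent_end = self.regime_at_node(tree, int(tree.parent[e]))
            if segs[0][0] != parent_end:
                raise TreeError(
                    f"edge {e} starts in regime {segs[0][0]!r} but its parent "
                    f"ends in {parent_end!r}"
                )

    def lineage_segments(
        self, tree: DatedTree, tip_label: str
    ) -> list[tuple[str, float, float]]:
        """Root-to-tip regime intervals as ``(regime, t_start, t_end)``.

        Times are measured forwards from the root; intervals are half-open
        rootward-inclusive and partition ``[0, depth(tip)]``.
        """
        t = 0.0
        out: list[tuple[str, float, float]] = []
        for e in tree.lineage(tree.tip_node(tip_label)):
            for r, d in self.segments[e]:
                out.append((r, t, t + d))
                t += d
        # merge adjacent intervals in the same regime across edges
        merged: list[tuple[str, float, float]] = []
        for r, a, b in out:
            if merged and merged[-1][0] == r:
                merged[-1] = (r, merged[-1][1], b)
            else:
                merged.append((r, a, b))
        return merged


def paint_from_node_states(tree: DatedTree, node_states: Mapping[int, str]) -> RegimePainting:
    """Painting from per-node regime assignments.

    An edge whose endpoints share a regime gets a single segment in it;
    otherwise the edge splits at its midpoint (deterministic, symmetric
    convention — sampled mappings carry their own change points instead).
    """
    missing = [v for v in range(tree.n_nodes) if v not in node_states]
    if missing:
        raise TreeError(f"missing regime assignment for nodes {missing}")
    segs: dict[int, tuple[tuple[str, float], ...]] = {}
    for e in tree.edges:
        L = float(tree.length[e])
        pr = node_states[int(tree.parent[e])]
        cr = node_states[e]
        if pr == cr:
            segs[e] = ((cr, L),)
        else:
            segs[e] = ((pr, L / 2.0), (cr, L / 2.0))
    return RegimePainting(root_regime=node_states[tree.root], segments=segs)
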