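"""Rooted trees with branch lengths, node ages and annotations.

The pipeline's working tree is a small purpose-built structure rather than a
third-party tree object because grafting, rescaling and dating need two things
most tree libraries do not guarantee together: (i) node ages stored as primary
data (so that a calibrated node age survives arithmetic on branch lengths
bit-for-bit) and (ii) deepcopy-safe custom per-node annotations (support, HPD
interval, biogeographic area set, plus verbatim passthrough of unknown bracket
comments).  Newick text is *parsed* with DendroPy; serialisation is done here
so the bracket-comment dialect is fully under our control.

Conventions
-----------
* Trees are rooted.  Unrooted trees (e.g. raw neighbor-joining output) are
  represented with a trifurcating root.
* Ages are measured backwards from the present: extant tips sit at 0 Ma and a
  parent is always at least as old as its children.  In a dated tree the branch
  length equals the age difference between parent and child.
* Node annotations serialise as ``[&support=0.95,hpd={1.5,2.5},areas={A|B}]``
  placed after the node label and before the branch length.  Unknown keys are
  preserved verbatim on round-trip.
"""

from __future__ import annotations

import copy
import math
from typing import Callable, Iterable, Iterator, Optional, Sequence

import dendropy

__all__ = ["Node", "Chronogram", "TreeError"]

#: tolerance used for the dated-tree invariant checks
AGE_TOL = 1e-9


class TreeError(ValueError):
    """Structurally invalid tree or violated dating invariant."""


def _fmt(x: float) -> str:
    s = format(x, ".12g")
    return s


class Node:
    """A node of a rooted tree.

    ``length`` is the length of the branch leading to the parent (``None`` for
    the root).  ``age`` is optional; dated operations keep it in sync with the
    branch lengths.
    """

    __slots__ = (
        "label",
        "length",
        "age",
        "parent",
        "children",
        "support",
        "hpd_min",
        "hpd_max",
        "area_set",
        "extra",
    )

    def __init__(self, label: Optional[str] = None, length: Optional[float] = None):
        self.label = label
        self.length = length
        self.age: Optional[float] = None
        self.parent: Optional["Node"] = None
        self.children: list["Node"] = []
        self.support: Optional[float] = None
        self.hpd_min: Optional[float] = None
        self.hpd_max: Optional[float] = None
        self.area_set: Optional[frozenset[str]] = None
        self.extra: dict[str, str] = {}

    # -- structure ----------------------------------------------------------
    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return reversed(out)  # any reversal of preorder visits children first

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    # -- annotations --------------------------------------------------------
    def annotation_string(self) -> str:
        parts = []
        if self.support is not None:
            parts.append(f"support={_fmt(self.support)}")
        if self.hpd_min is not None and self.hpd_max is not None:
            parts.append(f"hpd={{{_fmt(self.hpd_min)},{_fmt(self.hpd_max)}}}")
        if self.area_set is not None:
            parts.append("areas={%s}" % "|".join(sorted(self.area_set)))
        for key in sorted(self.extra):
            parts.append(f"{key}={self.extra[key]}")
        return "[&%s]" % ",".join(parts) if parts else ""

    def parse_annotation(self, comment: str) -> None:
        """Parse an ``&key=value,...`` bracket comment body into this node."""
        body = comment.lstrip("&")
        for key, value in _split_annotation(body):
            if key == "support":
                self.support = float(value)
            elif key == "hpd":
                lo, hi = value.strip("{}").split(",")
                self.hpd_min = float(lo)
                self.hpd_max = float(hi)
            elif key == "areas":
                inner = value.strip("{}")
                self.area_set = frozenset(a for a in inner.split("|") if a)
            else:
                self.extra[key] = value

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} len={self.length} age={self.age}>"


def _split_annotation(body: str) -> list[tuple[str, str]]:
    """Split ``a=1,b={2,3}`` at top-level commas only."""
    items: list[tuple[str, str]] = []
    depth = 0
    token = []
    for ch in body + ",":
        if ch == "," and depth == 0:
            part = "".join(token).strip()
            if part:
                key, _, value = part.partition("=")
                items.append((key.strip(), value.strip()))
            token = []
            continue
        if ch in "{[(":
            depth += 1
        elif ch in "}])":
            depth -= 1
        token.append(ch)
    return items


class Chronogram:
    """A rooted tree, optionally dated (ultrametric, tips at 0 Ma)."""

    def __init__(self, root: Node):
        self.root = root

    # -- construction -------------------------------------------------------
    @classmethod
    def from_newick(
        cls,
        text: str,
        support_labels: bool = False,
        require_ultrametric: bool = False,
        allow_negative: bool = False,
        ultrametric_tol: float = 1e-6,
    ) -> "Chronogram":
        """Parse a Newick string.

        ``support_labels`` interprets internal node labels as support values
        (divided by 100 when > 1).  ``require_ultrametric`` validates equal
        root-to-tip depths and populates node ages.
        """
        try:
            dtree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
                extract_comment_metadata=False,
            )
        except Exception as exc:  # dendropy raises its own hierarchy
            raise TreeError(f"unparseable Newick: {exc}") from exc

        def convert(dnode) -> Node:
            if dnode.taxon is not None:
                label = dnode.taxon.label
            else:
                label = dnode.label
            node = Node(label=label, length=dnode.edge.length)
            for comment in dnode.comments:
                if comment.startswith("&"):
                    node.parse_annotation(comment)
                else:
                    node.extra.setdefault("comment", comment)
            if support_labels and dnode.child_nodes() and label not in (None, ""):
                try:
                    sup = float(label)
                except ValueError:
                    pass
                else:
                    node.support = sup / 100.0 if sup > 1.0 else sup
                    node.label = None
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        root = convert(dtree.seed_node)
        root.length = None
        tree = cls(root)
        if not allow_negative:
            for n in tree.nodes():
                if n.length is not None and n.length < 0:
                    raise TreeError(f"negative branch length on {n.label!r}")
        labels = tree.tip_labels()
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate tip labels")
        if require_ultrametric:
            if not tree.is_ultrametric(tol=ultrametric_tol):
                raise TreeError("tree is not ultrametric (unequal tip depths)")
            tree.compute_ages()
        return tree

    def copy(self) -> "Chronogram":
        return copy.deepcopy(self)

    # -- traversal ----------------------------------------------------------
    def nodes(self) -> Iterator[Node]:
        return self.root.preorder()

    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def tips(self) -> list[Node]:
        return self.root.leaves()

    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips()]

    def find(self, label: str) -> Node:
        for n in self.nodes():
            if n.label == label:
                return n
        raise KeyError(label)

    def n_tips(self) -> int:
        return len(self.tips())

    # -- tip sets and splits -------------------------------------------------
    def tipsets(self) -> dict[Node, frozenset[str]]:
        out: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                out[node] = frozenset([node.label])
            else:
                s: set[str] = set()
                for c in node.children:
                    s |= out[c]
                out[node] = frozenset(s)
        return out

    def mrca(self, labels: Iterable[str]) -> Node:
        want = frozenset(labels)
        have = frozenset(self.tip_labels())
        missing = want - have
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        tipsets = self.tipsets()
        best = self.root
        best_size = len(tipsets[self.root])
        for node, ts in tipsets.items():
            if want <= ts and len(ts) < best_size:
                best, best_size = node, len(ts)
        return best

    def clades(self, nontrivial_only: bool = True) -> set[frozenset[str]]:
        """Rooted clades (tip sets of internal nodes below the root)."""
        tipsets = self.tipsets()
        out = set()
        for node, ts in tipsets.items():
            if node is self.root:
                continue
            if nontrivial_only and len(ts) < 2:
                continue
            out.add(ts)
        return out

    def bipartitions(self, nontrivial_only: bool = True) -> set[frozenset[str]]:
        """Unrooted splits, canonicalised to the side without the smallest tip."""
        all_tips = frozenset(self.tip_labels())
        ref = min(all_tips)
        tipsets = self.tipsets()
        out = set()
        for node, ts in tipsets.items():
            if node is self.root:
                continue
            side = all_tips - ts if ref in ts else ts
            if not side or side == all_tips:
                continue
            if nontrivial_only and (len(side) < 2 or len(all_tips - side) < 2):
                continue
            out.add(side)
        return out

    def split_lengths(self, include_trivial: bool = True) -> dict[frozenset[str], float]:
        """Branch lengths indexed by unrooted split.

        The root's two child edges describe the same unrooted branch; their
        lengths are summed.
        """
        all_tips = frozenset(self.tip_labels())
        ref = min(all_tips)
        tipsets = self.tipsets()
        out: dict[frozenset[str], float] = {}
        for node, ts in tipsets.items():
            if node is self.root:
                continue
            side = all_tips - ts if ref in ts else ts
            if not side or side == all_tips:
                continue
            if not include_trivial and (len(side) < 2 or len(all_tips - side) < 2):
                continue
            length = node.length or 0.0
            out[side] = out.get(side, 0.0) + length
        return out

    # -- depths and ages -----------------------------------------------------
    def depths(self) -> dict[Node, float]:
        """Root-to-node path lengths."""
        out: dict[Node, float] = {self.root: 0.0}
        for node in self.nodes():
            if node is self.root:
                continue
            out[node] = out[node.parent] + (node.length or 0.0)
        return out

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.nodes() if n is not self.root)

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        depths = self.depths()
        tip_depths = [depths[t] for t in self.tips()]
        return max(tip_depths) - min(tip_depths) <= tol

    def compute_ages(self) -> None:
        """Populate node ages from branch lengths (tips at 0).

        Non-ultrametric inputs get ``age = max`` height above any descendant
        tip, which keeps parent >= child by construction.
        """
        for node in self.postorder():
            if node.is_leaf:
                node.age = 0.0
            else:
                node.age = max(c.age + (c.length or 0.0) for c in node.children)

    def set_lengths_from_ages(self) -> None:
        for node in self.nodes():
            if node is self.root:
                node.length = None
            else:
                node.length = node.parent.age - node.age

    def root_age(self) -> float:
        if self.root.age is None:
            self.compute_ages()
        return self.root.age

    def scale(self, factor: float) -> None:
        """Multiply branch lengths, ages and HPD bounds by ``factor``."""
        for node in self.nodes():
            if node.length is not None:
                node.length *= factor
            if node.age is not None:
                node.age *= factor
            if node.hpd_min is not None:
                node.hpd_min *= factor
            if node.hpd_max is not None:
                node.hpd_max *= factor

    def validate_dated(self, tol: float = AGE_TOL) -> None:
        """Enforce the dated-tree invariant: ultrametric, parent >= child age.

        Raises :class:`TreeError` on violation.  Called at module boundaries
        that consume or produce chronograms.
        """
        if self.root.age is None:
            self.compute_ages()
        depths = self.depths()
        root_age = self.root.age
        for node in self.nodes():
            if node.length is not None and node.length < -tol:
                raise TreeError(f"negative branch length at {node.label!r}")
            if node is not self.root:
                if node.parent.age < node.age - tol:
                    raise TreeError(
                        f"child older than parent near {node.label!r} "
                        f"({node.age} > {node.parent.age})"
                    )
            if node.is_leaf:
                if abs(depths[node] - root_age) > max(tol, 1e-9 * max(root_age, 1.0)):
                    raise TreeError(f"tip {node.label!r} not at age 0 (non-ultrametric)")
            if node.hpd_min is not None and node.hpd_max is not None and node.age is not None:
                if not (node.hpd_min - tol <= node.age <= node.hpd_max + tol):
                    raise TreeError(f"age outside HPD at {node.label!r}")

    # -- surgery -------------------------------------------------------------
    def suppress_unifurcations(self) -> None:
        changed = True
        while changed:
            changed = False
            for node in list(self.nodes()):
                if node.is_leaf or len(node.children) != 1:
                    continue
                child = node.children[0]
                if node is self.root:
                    child.parent = None
                    child.length = None
                    self.root = child
                else:
                    parent = node.parent
                    idx = parent.children.index(node)
                    child.length = (child.length or 0.0) + (node.length or 0.0)
                    child.parent = parent
                    parent.children[idx] = child
                changed = True

    def prune_tips(self, drop: Iterable[str]) -> None:
        dropset = set(drop)
        for tip in list(self.tips()):
            if tip.label in dropset:
                parent = tip.parent
                if parent is None:
                    raise TreeError("cannot prune the only node")
                parent.remove_child(tip)
        # remove now-empty internals
        for node in list(self.postorder()):
            if not node.is_leaf and not node.children and node.parent is not None:
                node.parent.remove_child(node)
        self.suppress_unifurcations()

    def extract_clade(self, node: Node) -> "Chronogram":
        sub = copy.deepcopy(node)
        sub.parent = None
        sub.length = None
        return Chronogram(sub)

    # -- rooting -------------------------------------------------------------
    def midpoint_root(self) -> "Chronogram":
        """Root on the midpoint of the longest tip-to-tip path."""
        # distances via double traversal on the unrooted graph
        adjacency: dict[Node, list[tuple[Node, float]]] = {}
        for node in self.nodes():
            adjacency.setdefault(node, [])
            for c in node.children:
                w = c.length or 0.0
                adjacency[node].append((c, w))
                adjacency.setdefault(c, []).append((node, w))

        def farthest(start: Node):
            dist = {start: 0.0}
            prev: dict[Node, Node] = {}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, w in adjacency[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        prev[v] = u
                        stack.append(v)
            tipdist = {n: d for n, d in dist.items() if n.is_leaf}
            end = max(tipdist, key=lambda n: (tipdist[n], n.label))
            return end, tipdist[end], prev

        tips = self.tips()
        if len(tips) < 2:
            return self.copy()
        a, _, _ = farthest(tips[0])
        b, diameter, prev = farthest(a)
        # walk back from b to a accumulating distance, find midpoint edge
        path = [b]
        while path[-1] is not a:
            path.append(prev[path[-1]])
        half = diameter / 2.0
        acc = 0.0
        edge_weight = {}
        for node in self.nodes():
            for c in node.children:
                edge_weight[(node, c)] = edge_weight[(c, node)] = c.length or 0.0
        for u, v in zip(path, path[1:]):
            w = edge_weight[(u, v)]
            if acc + w >= half - 1e-15:
                # midpoint lies on edge (u, v), at distance (half - acc) from u
                return self._reroot_on_edge(u, v, half - acc)
            acc += w
        return self.copy()

    def root_with_outgroup(self, labels: Sequence[str]) -> "Chronogram":
        tree = self.copy()
        tipsets = tree.tipsets()
        og = frozenset(labels)
        node = None
        for n, ts in tipsets.items():
            if ts == og and n is not tree.root:
                node = n
                break
        if node is None:
            raise TreeError(f"outgroup {sorted(og)} is not a clade/tip of the tree")
        length = node.length or 0.0
        return tree._reroot_on_edge(node.parent, node, length / 2.0)

    def _reroot_on_edge(self, u: Node, v: Node, dist_from_u: float) -> "Chronogram":
        """Return a copy rooted on the edge between adjacent nodes u and v."""
        tree = self.copy()
        # map nodes of self to copy by traversal order
        mapping = dict(zip(self.nodes(), tree.nodes()))
        u, v = mapping[u], mapping[v]
        if v.parent is not u:
            u, v = v, u
            dist_from_u = (v.length or 0.0) - dist_from_u
        if v.parent is not u:
            raise TreeError("nodes are not adjacent")
        w = v.length or 0.0
        dist_from_u = min(max(dist_from_u, 0.0), w)
        new_root = Node()
        # detach v
        u.remove_child(v)
        # reverse the path from u up to the old root; capture original lengths
        # first (each reversed edge takes the length of its former child side)
        path = []
        node = u
        while node is not None:
            path.append(node)
            node = node.parent
        orig_len = {id(n): n.length for n in path}
        for child, parent in zip(path, path[1:]):
            parent.children.remove(child)
        for child, parent in zip(path, path[1:]):
            child.add_child(parent)
            parent.length = orig_len[id(child)]
        u.length = dist_from_u
        v.length = w - dist_from_u
        new_root.add_child(u)
        new_root.add_child(v)
        out = Chronogram(new_root)
        out.suppress_unifurcations()
        return out

    # -- serialisation -------------------------------------------------------
    def newick(self, annotations: bool = True, support_as_label: bool = False) -> str:
        def render(node: Node) -> str:
            if node.is_leaf:
                body = node.label or ""
            else:
                inner = ",".join(render(c) for c in node.children)
                label = node.label or ""
                if support_as_label and node.support is not None:
                    label = _fmt(node.support)
                body = f"({inner}){label}"
            if annotations and not support_as_label:
                body += node.annotation_string()
            elif annotations:
                # keep hpd/areas even when support moved to the label
                saved = node.support
                node.support = None
                body += node.annotation_string()
                node.support = saved
            if node.length is not None:
                body += f":{_fmt(node.length)}"
            return body

        return render(self.root) + ";"

    def write(self, path, **kwargs) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick(**kwargs) + "\n")

    @classmethod
    def read(cls, path, **kwargs) -> "Chronogram":
        with open(path) as fh:
            return cls.from_newick(fh.read(), **kwargs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Chronogram {self.n_tips()} tips>"


def star_tree(labels: Sequence[str], length: float = 1.0) -> Chronogram:
    root = Node()
    for lab in sorted(labels):
        root.add_child(Node(label=lab, length=length))
    return Chronogram(root)
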