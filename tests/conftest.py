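"""Shared fixtures: tiny hand-built datasets and random tree generators."""

from __future__ import annotations

import numpy as np
import pytest

from phylograft.model import SequenceCluster, SequenceRecord, TaxaTable
from phylograft.trees import Chronogram, Node


def make_records(rows: dict[str, str], aligned: bool = True) -> list[SequenceRecord]:
    """rows: species_id -> residues; seq_id is '<species>_seq'."""
    return [
        SequenceRecord(f"{sp}_seq", sp, seq, is_aligned=aligned)
        for sp, seq in rows.items()
    ]


@pytest.fixture
def simple_taxa() -> TaxaTable:
    return TaxaTable(
        [
            ("A1", "A one", "A"),
            ("A2", "A two", "A"),
            ("B1", "B one", "B"),
            ("B2", "B two", "B"),
            ("C1", "C one", "C"),
            ("C2", "C two", "C"),
            ("D1", "D one", "D"),
            ("D2", "D two", "D"),
        ]
    )


def random_binary_tree(labels, rng, min_len=0.1, max_len=2.0) -> Chronogram:
    """Random rooted binary tree with positive branch lengths."""
    nodes = [Node(label=l, length=float(rng.uniform(min_len, max_len))) for l in labels]
    rng.shuffle(nodes)
    while len(nodes) > 2:
        a = nodes.pop(rng.integers(0, len(nodes)))
        b = nodes.pop(rng.integers(0, len(nodes)))
        parent = Node(length=float(rng.uniform(min_len, max_len)))
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    root = Node()
    for n in nodes:
        root.add_child(n)
    return Chronogram(root)


def random_ultrametric_tree(labels, rng, depth=10.0) -> Chronogram:
    """Random dated (ultrametric) tree by repeated cherry-joining."""
    nodes = [Node(label=l) for l in labels]
    for n in nodes:
        n.age = 0.0
    ages = sorted(rng.uniform(0.0, depth, size=len(labels) - 1))
    while len(nodes) > 1:
        a = nodes.pop(rng.integers(0, len(nodes)))
        b = nodes.pop(rng.integers(0, len(nodes)))
        parent = Node()
        parent.age = ages[len(ages) - len(nodes) - 1]
        parent.age = max(parent.age, a.age, b.age)
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    tree = Chronogram(nodes[0])
    tree.set_lengths_from_ages()
    return tree


def all_unrooted_topologies(labels):
    """Enumerate every unrooted binary topology on the labels (as Chronograms
    with unit branch lengths, arbitrarily rooted on the first tip's edge)."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")

    def edges_of(tree_root):
        out = []
        for node in tree_root.preorder():
            for child in node.children:
                out.append((node, child))
        return out

    import copy

    base = Node()
    for l in labels[:3]:
        base.add_child(Node(label=l, length=1.0))
    trees = [base]
    for label in labels[3:]:
        new_trees = []
        for t in trees:
            for i in range(len(edges_of(t))):
                t2 = copy.deepcopy(t)
                parent, child = edges_of(t2)[i]
                mid = Node(length=1.0)
                idx = parent.children.index(child)
                child.length = 1.0
                mid.add_child(child)
                mid.add_child(Node(label=label, length=1.0))
                mid.parent = parent
                parent.children[idx] = mid
                new_trees.append(t2)
        trees = new_trees
    return [Chronogram(t) for t in trees]
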