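"""Phylogenies whose branches carry lengths and rate-class labels.

Branch classes follow the multi-rate convention used by branch and
branch-site codon models: class 0 is the background; classes 1, 2, ...
mark focal branch sets (e.g. flightless and flying lineages, or the
foreground branch of a branch-site test). Classes are written/read as
PAML-style ``#k`` suffixes on Newick nodes, or assigned from a trait
file mapping leaves/clades to flight states.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

#: flight states and the branch class each maps to
STATE_TO_CLASS = {
    "background": 0,
    "flightless": 1,
    "flying": 2,
    "female_flightless": 3,
    "apterygote": 4,
}

_LABEL_RE = re.compile(r"^(.*?)\s*#(\d+)$")


@dataclass
class LabeledTree:
    """Rooted tree in flat arrays, ready for pruning.

    Node 0 is the root; nodes are stored so that every parent index is
    smaller than its children's (preorder). ``lengths[i]`` and
    ``classes[i]`` describe the branch above node ``i`` (unused for the
    root). Leaf nodes carry names in ``names``; internal nodes may too.
    """

    parent: np.ndarray
    lengths: np.ndarray
    classes: np.ndarray
    names: list[str | None]
    children: list[list[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.parent)
        if not self.children:
            self.children = [[] for _ in range(n)]
            for i in range(1, n):
                self.children[self.parent[i]].append(i)
        if np.any(self.lengths[1:] < 0):
            raise ValueError("negative branch length")

    # -- basic structure -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]

    def postorder(self) -> list[int]:
        return list(range(self.n_nodes - 1, -1, -1))

    def class_set(self) -> set[int]:
        return set(int(c) for c in self.classes[1:])

    # -- construction ----------------------------------------------------
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "LabeledTree":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        lengths = np.zeros(n)
        classes = np.zeros(n, dtype=np.int64)
        names: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is not None:
                    if nd.edge.length < 0:
                        raise ValueError("negative branch length")
                    lengths[i] = nd.edge.length
            raw = nd.taxon.label if nd.taxon is not None else nd.label
            if raw is not None:
                m = _LABEL_RE.match(raw)
                if m:
                    names[i] = m.group(1) or None
                    classes[i] = int(m.group(2))
                else:
                    names[i] = raw
        out = cls(parent=parent, lengths=lengths, classes=classes, names=names)
        out._normalise_classes()
        return out

    def _normalise_classes(self) -> None:
        """Remap class labels to be contiguous from 0 (0 stays background)."""
        present = sorted(self.class_set())
        if len(present) == 1 and 0 not in present:
            return  # single-class tree may keep its nonzero label
        if present != list(range(len(present))):
            remap = {c: i for i, c in enumerate(present)}
            self.classes = np.array(
                [remap.get(int(c), 0) for c in self.classes], dtype=np.int64
            )

    @classmethod
    def from_newick(cls, source: str | Path) -> "LabeledTree":
        """Parse Newick; ``#k`` suffixes on leaf or internal labels set classes."""
        text = Path(source).read_text() if _looks_like_path(source) else str(source)
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        return cls.from_dendropy(tree)

    def to_newick(self, with_classes: bool = True) -> str:
        def render(i: int) -> str:
            label = self.names[i] or ""
            cls_suffix = (
                f"#{int(self.classes[i])}"
                if with_classes and self.parent[i] >= 0 and self.classes[i] != 0
                else ""
            )
            if self.children[i]:
                inner = ",".join(render(c) for c in self.children[i])
                body = f"({inner}){label}{cls_suffix}"
            else:
                body = f"{label}{cls_suffix}"
            if self.parent[i] >= 0:
                body += f":{self.lengths[i]:.6g}"
            return body

        return render(0) + ";"

    # -- manipulation ----------------------------------------------------
    def copy(self) -> "LabeledTree":
        return LabeledTree(
            parent=self.parent.copy(),
            lengths=self.lengths.copy(),
            classes=self.classes.copy(),
            names=list(self.names),
        )

    def with_classes(self, classes: np.ndarray) -> "LabeledTree":
        out = self.copy()
        out.classes = np.asarray(classes, dtype=np.int64).copy()
        return out

    def merge_classes(self, merge: dict[int, int]) -> "LabeledTree":
        """Relabel branch classes (e.g. pool flightless+flying into one class)."""
        out = self.copy()
        out.classes = np.array([merge.get(int(c), int(c)) for c in self.classes])
        return out

    def subtree_nodes(self, node: int) -> list[int]:
        out = [node]
        stack = list(self.children[node])
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(self.children[i])
        return out

    def mrca(self, leaf_names: set[str]) -> int:
        """Most recent common ancestor of the named leaves."""
        want = set(leaf_names)
        found = {self.names[i] for i in self.leaves if self.names[i] in want}
        if found != want:
            raise ValueError(f"leaves not in tree: {sorted(want - found)}")
        # climb from one leaf, checking containment
        below: dict[int, set[str]] = {}
        for i in self.postorder():
            if not self.children[i]:
                below[i] = {self.names[i]} if self.names[i] in want else set()
            else:
                below[i] = set().union(*(below[c] for c in self.children[i]))
            if below[i] == want:
                return i
        raise ValueError("no common ancestor found")  # pragma: no cover

    def is_monophyletic(self, leaf_names: set[str]) -> bool:
        node = self.mrca(leaf_names)
        clade_leaves = {self.names[i] for i in self.subtree_nodes(node) if not self.children[i]}
        return clade_leaves == set(leaf_names)


def _looks_like_path(source: str | Path) -> bool:
    if isinstance(source, Path):
        return True
    s = str(source)
    return "(" not in s and (s.endswith(".nwk") or s.endswith(".tre") or Path(s).exists())


@dataclass
class TraitMap:
    """Flight-state annotations on leaves or monophyletic clades.

    Entries map an entry name to (set of leaf names, state); a single
    leaf is a one-member set. States are the keys of ``STATE_TO_CLASS``.
    """

    entries: list[tuple[frozenset, str]]

    @classmethod
    def read(cls, path: str | Path) -> "TraitMap":
        """Two-column TSV: comma-separated leaf names <TAB> state."""
        entries = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            leaves_field, state = line.split("\t")[:2]
            state = state.strip()
            if state not in STATE_TO_CLASS:
                raise ValueError(f"unknown flight state {state!r}")
            entries.append((frozenset(x.strip() for x in leaves_field.split(",")), state))
        return cls(entries=entries)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for leaves, state in self.entries:
                fh.write(",".join(sorted(leaves)) + "\t" + state + "\n")


def apply_traits(
    tree: LabeledTree, traits: TraitMap, include_stem: bool = True
) -> LabeledTree:
    """Assign branch classes from flight-state annotations.

    Each trait entry must name a monophyletic group of the tree; all
    branches inside the clade receive the state's class, and the clade's
    stem branch is included by default (the stem is where a trait shift
    such as flight loss is tested).
    """
    classes = np.zeros(tree.n_nodes, dtype=np.int64)
    for leaves, state in traits.entries:
        if not tree.is_monophyletic(set(leaves)):
            raise ValueError(f"trait clade {sorted(leaves)} is not monophyletic")
        node = tree.mrca(set(leaves))
        members = tree.subtree_nodes(node)
        if not include_stem:
            members = [i for i in members if i != node]
        for i in members:
            if tree.parent[i] >= 0:
                classes[i] = STATE_TO_CLASS[state]
    return tree.with_classes(classes)


def read_labeled_tree(
    path: str | Path,
    traits: TraitMap | str | Path | None = None,
    include_stem: bool = True,
) -> LabeledTree:
    """Read a Newick tree; branch classes come from ``#k`` suffixes or a trait file."""
    tree = LabeledTree.from_newick(Path(path))
    if traits is not None:
        if not isinstance(traits, TraitMap):
            traits = TraitMap.read(traits)
        tree = apply_traits(tree, traits, include_stem=include_stem)
    return tree
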