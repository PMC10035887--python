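"""Fixed species phylogeny handling.

The per-site rate analysis runs on a fixed, rooted species tree with
branch lengths in expected substitutions per site; the tree is an input,
never re-estimated.  :class:`PrimatePhylogeny` wraps a dendropy tree,
validates it, carries named clade subsets (``human``, ``great_apes``,
``apes``) used by the lineage-specific scans, and exports the flat arrays
the pruning-algorithm likelihood needs.

A packaged 18-taxon primate-like tree (synthetic: hand-built topology and
plausible branch lengths, not inferred from data) is available through
:func:`load_reference_tree`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import dendropy
import numpy as np

__all__ = ["PrimatePhylogeny", "TreeArrays", "load_reference_tree"]

_REFERENCE_TREE_RESOURCE = "primate18_synthetic.nwk"

_REFERENCE_CLADES = {
    "human": {"Homo_sapiens"},
    "great_apes": {
        "Homo_sapiens",
        "Pan_troglodytes",
        "Pan_paniscus",
        "Gorilla_gorilla",
        "Pongo_abelii",
    },
    "apes": {
        "Homo_sapiens",
        "Pan_troglodytes",
        "Pan_paniscus",
        "Gorilla_gorilla",
        "Pongo_abelii",
        "Nomascus_leucogenys",
    },
}


@dataclass
class TreeArrays:
    """Flat postorder representation of a rooted tree for likelihood code.

    Nodes are numbered 0..n_nodes-1 with leaves first (in ``leaf_names``
    order).  ``children[i]`` lists the child node ids of node ``i`` and
    ``blen[i]`` is the length of the branch above node ``i`` (0 for the
    root).  ``postorder`` lists internal node ids, children before
    parents, root last.
    """

    leaf_names: list[str]
    children: list[list[int]]
    blen: np.ndarray
    postorder: list[int]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    @property
    def root(self) -> int:
        return self.postorder[-1]


class PrimatePhylogeny:
    """A validated rooted species tree with branch lengths and named clades."""

    def __init__(self, tree: dendropy.Tree, clade_sets: dict[str, set[str]] | None = None):
        self._tree = tree
        self.taxon_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        self._validate()
        self.clade_sets: dict[str, set[str]] = {}
        for name, taxa in (clade_sets or {}).items():
            missing = set(taxa) - set(self.taxon_labels)
            if missing:
                raise ValueError(f"clade {name!r} contains unknown taxa: {sorted(missing)}")
            self.clade_sets[name] = set(taxa)

    def _validate(self) -> None:
        labels = self.taxon_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue
            if edge.length is None or edge.length <= 0:
                raise ValueError(
                    f"non-positive branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, clade_sets=None) -> "PrimatePhylogeny":
        """Parse a rooted Newick string (``#`` comment lines are skipped)."""
        payload = "\n".join(
            line for line in text.splitlines() if not line.lstrip().startswith("#")
        )
        try:
            tree = dendropy.Tree.get(
                data=payload,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises schema-specific errors
            raise ValueError(f"malformed Newick: {exc}") from exc
        return cls(tree, clade_sets)

    @classmethod
    def from_file(cls, path, clade_sets=None) -> "PrimatePhylogeny":
        with open(path) as handle:
            return cls.from_newick(handle.read(), clade_sets)

    # -- serialisation -------------------------------------------------

    def to_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )

    def write(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(self.to_newick())

    # -- queries -------------------------------------------------------

    def total_length(self) -> float:
        return sum(e.length for e in self._tree.edges() if e.length)

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf patristic distances, for topology/length comparisons."""
        pdm = self._tree.phylogenetic_distance_matrix()
        labels = sorted(self.taxon_labels)
        taxa = {t.label: t for t in self._tree.taxon_namespace}
        n = len(labels)
        mat = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    d = pdm.patristic_distance(taxa[a], taxa[b])
                    mat[i, j] = mat[j, i] = d
        return labels, mat

    def pruned_to(self, keep_taxa) -> "PrimatePhylogeny":
        """Restriction of the tree to a taxon subset, preserving path lengths."""
        keep = set(keep_taxa)
        missing = keep - set(self.taxon_labels)
        if missing:
            raise ValueError(f"taxa not in tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        clades = {
            name: taxa & keep for name, taxa in self.clade_sets.items() if taxa & keep
        }
        return PrimatePhylogeny(clone, clades)

    def to_arrays(self) -> TreeArrays:
        """Postorder arrays for the pruning likelihood (leaves numbered first)."""
        leaves = [n for n in self._tree.leaf_node_iter()]
        leaf_names = [n.taxon.label for n in leaves]
        ids: dict[int, int] = {id(n): i for i, n in enumerate(leaves)}
        internal = [n for n in self._tree.postorder_node_iter() if not n.is_leaf()]
        for k, node in enumerate(internal):
            ids[id(node)] = len(leaves) + k
        n_nodes = len(leaves) + len(internal)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        blen = np.zeros(n_nodes)
        for node in self._tree.postorder_node_iter():
            i = ids[id(node)]
            blen[i] = node.edge.length or 0.0
            children[i] = [ids[id(c)] for c in node.child_nodes()]
        postorder = [ids[id(n)] for n in internal]
        return TreeArrays(leaf_names, children, blen, postorder)

    def __len__(self) -> int:
        return len(self.taxon_labels)

    def __repr__(self):  # pragma: no cover
        return f"PrimatePhylogeny(n_taxa={len(self)}, clades={sorted(self.clade_sets)})"


def load_reference_tree(source: str = "primate18") -> PrimatePhylogeny:
    """Load the packaged synthetic 18-taxon primate-like tree.

    The tree carries clade sets ``human``, ``great_apes`` and ``apes`` for
    the lineage-specific scanners.
    """
    if source != "primate18":
        raise ValueError(f"unknown packaged tree {source!r}")
    text = (
        resources.files("ligevo").joinpath("data", _REFERENCE_TREE_RESOURCE).read_text()
    )
    return PrimatePhylogeny.from_newick(text, clade_sets=_REFERENCE_CLADES)
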