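"""Rooted species tree wrapper used by the f-branch decomposition.

Backed by :mod:`dendropy`; exposes the branch bookkeeping the f-branch
statistic needs (descendant leaf sets, sister clades, stable branch labels).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy


@dataclass(frozen=True)
class Branch:
    """A branch of the species tree, identified by its child clade."""

    label: str
    leaves: tuple[str, ...]  # descendant leaf labels, sorted
    sister_leaves: tuple[str, ...]
    is_leaf: bool


class SpeciesTree:
    """Rooted binary species tree with unique leaf labels."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise ValueError("duplicate leaf labels in tree")
        self._leaves = labels

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(data=newick, schema="newick")
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate leaf labels in newick: {exc}") from None
        return cls(tree)

    @property
    def leaf_labels(self) -> list[str]:
        return list(self._leaves)

    @property
    def n_leaves(self) -> int:
        return len(self._leaves)

    def newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    def branches(self, exclude_root_children_of_outgroup: str | None = None) -> list[Branch]:
        """All branches (terminal and internal) below the root.

        Branches whose clade contains the named outgroup are dropped, as are
        branches without a sister clade (the root itself).
        """
        out: list[Branch] = []
        counter = 0
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            leaves = tuple(sorted(l.taxon.label for l in node.leaf_iter()))
            outg = exclude_root_children_of_outgroup
            if outg is not None and outg in leaves:
                continue
            sisters: list[str] = []
            for sib in node.parent_node.child_nodes():
                if sib is not node:
                    sisters.extend(l.taxon.label for l in sib.leaf_iter())
            if outg is not None and outg in sisters:
                # sister clade is (or contains) the outgroup: no P1 proxy
                continue
            if len(leaves) == 1:
                label = leaves[0]
            else:
                counter += 1
                label = f"anc_{counter}({','.join(leaves)})"
            out.append(
                Branch(
                    label=label,
                    leaves=leaves,
                    sister_leaves=tuple(sorted(sisters)),
                    is_leaf=len(leaves) == 1,
                )
            )
        return out
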