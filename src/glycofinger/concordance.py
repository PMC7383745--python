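"""Agreement between glyco-group labels and a phylogenetic tree.

Trees are consumed, never inferred.  The qualitative claim that a barcode
phylogeny "goes hand in hand" with the fingerprint grouping is restated
as a monophyly statistic: for each group, the leaves carrying its label
are tested for monophyly against the (rooted) topology, ignoring
unlabeled leaves such as outgroups and database references; the overall
concordance is the fraction of groups that come out monophyletic.

Unrooted input is midpoint-rooted first.  Newick files with bootstrap
values as internal-node labels parse and the values are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

__all__ = [
    "LabeledTree",
    "load_tree",
    "read_label_map",
    "group_monophyly",
    "concordance",
    "simulate_labeled_tree",
]

MONOPHYLETIC = "monophyletic"
PARAPHYLETIC = "paraphyletic"
POLYPHYLETIC = "polyphyletic"


@dataclass
class LabeledTree:
    """A rooted tree plus a leaf -> glyco-group label map.

    Leaves absent from ``labels`` (outgroup, reference accessions) are
    ignored by the statistics.  At least two distinct groups must be
    labeled for concordance to be meaningful.
    """

    tree: dendropy.Tree
    labels: dict

    def __post_init__(self):
        leaf_names = {lf.taxon.label for lf in self.tree.leaf_node_iter()
                      if lf.taxon is not None}
        missing = set(self.labels) - leaf_names
        if missing:
            raise ValueError(f"labeled leaves not in tree: {sorted(missing)}")
        if len(set(self.labels.values())) < 2:
            raise ValueError("at least two distinct groups must be labeled")

    @property
    def groups(self) -> dict:
        """group -> set of leaf names carrying that label."""
        out: dict[str, set] = {}
        for leaf, group in self.labels.items():
            out.setdefault(group, set()).add(leaf)
        return out


def load_tree(source, schema: str = "newick") -> dendropy.Tree:
    """Read a tree; midpoint-root it if the input is unrooted.

    Missing edge lengths are treated as unit lengths for the midpoint
    convention.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        tree = dendropy.Tree.get(path=str(source), schema=schema,
                                 preserve_underscores=True)
    else:
        tree = dendropy.Tree.get(data=str(source), schema=schema,
                                 preserve_underscores=True)
    if not tree.is_rooted:
        for edge in tree.preorder_edge_iter():
            if edge.length is None and edge.head_node is not tree.seed_node:
                edge.length = 1.0

        def leafset(tr):
            return {lf.taxon.label for lf in tr.leaf_node_iter()
                    if lf.taxon is not None}

        rooted = tree.clone(depth=1)
        rooted.reroot_at_midpoint(update_bipartitions=True)
        # degenerate case (e.g. star tree): the midpoint can coincide with
        # a leaf node, which would silently drop that leaf; keep the
        # as-read basal node as root then
        if leafset(rooted) == leafset(tree):
            tree = rooted
        tree.is_rooted = True
    return tree


def read_label_map(source) -> dict:
    """Two-column TSV (leaf name, group); '#' comments and blanks skipped."""
    labels = {}
    with open(source) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"expected two columns in label map: {line!r}")
            labels[fields[0]] = fields[1]
    return labels


def _labeled_leafset_under(node, labeled: set) -> set:
    return {lf.taxon.label for lf in node.leaf_iter()
            if lf.taxon is not None} & labeled


def group_monophyly(t: LabeledTree) -> dict:
    """Monophyly status of every labeled group, ignoring unlabeled leaves.

    A group is monophyletic when the labeled leaves under its MRCA are
    exactly its own (single-leaf groups trivially so); otherwise it is
    paraphyletic if the complementary labeled set is itself monophyletic,
    and polyphyletic when neither holds.
    """
    taxa = {tx.label: tx for tx in t.tree.taxon_namespace}
    labeled = set(t.labels)

    def is_clade(leafset: set) -> bool:
        if len(leafset) <= 1:
            return True
        mrca = t.tree.mrca(taxa=[taxa[name] for name in leafset])
        return _labeled_leafset_under(mrca, labeled) == leafset

    out = {}
    for group, leaves in sorted(t.groups.items()):
        if is_clade(leaves):
            out[group] = MONOPHYLETIC
        elif is_clade(labeled - leaves):
            out[group] = PARAPHYLETIC
        else:
            out[group] = POLYPHYLETIC
    return out


def concordance(t: LabeledTree) -> float:
    """Fraction of labeled groups that are monophyletic on the tree."""
    status = group_monophyly(t)
    return sum(1 for s in status.values() if s == MONOPHYLETIC) / len(status)


def simulate_labeled_tree(n_groups: int = 4, leaves_per_group: int = 6,
                          noise_rate: float = 0.0,
                          rng: np.random.Generator | None = None,
                          seed: int | None = None) -> LabeledTree:
    """A group-block backbone with randomly attached noise leaves.

    The backbone is a caterpillar of monophyletic group blocks (perfect
    concordance at rate 0).  ``noise_rate`` controls how many extra
    leaves, each labeled with a random group, are grafted onto uniformly
    chosen edges; concordance decreases as the rate grows.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    group_names = [f"G{i + 1}" for i in range(n_groups)]
    blocks = []
    labels = {}
    for gi, group in enumerate(group_names):
        leaf_names = [f"{group}_t{j + 1}" for j in range(leaves_per_group)]
        for name in leaf_names:
            labels[name] = group
        block = leaf_names[0] + ":1"
        for name in leaf_names[1:]:
            block = f"({block},{name}:1):1"
        blocks.append(block)
    backbone = blocks[0]
    for block in blocks[1:]:
        backbone = f"({backbone},{block}):1"
    newick = backbone + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = True

    n_noise = int(round(noise_rate * n_groups * leaves_per_group))
    for k in range(n_noise):
        edges = [e for e in tree.preorder_edge_iter()
                 if e.tail_node is not None]
        edge = edges[int(rng.integers(len(edges)))]
        head, tail = edge.head_node, edge.tail_node
        split = dendropy.Node()
        split.edge.length = 0.5
        tail.remove_child(head)
        tail.add_child(split)
        head.edge.length = 0.5
        split.add_child(head)
        name = f"noise_{k + 1}"
        taxon = tree.taxon_namespace.require_taxon(label=name)
        leaf = dendropy.Node(taxon=taxon)
        leaf.edge.length = 1.0
        split.add_child(leaf)
        labels[name] = group_names[int(rng.integers(n_groups))]
    return LabeledTree(tree=tree, labels=labels)
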