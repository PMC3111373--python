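"""Topology comparison between recognized trees and ground truth.

Recognition without OCR yields placeholder leaf labels, so comparison maps
leaves positionally: the recognizer reports tips top-to-bottom, which is
exactly the rendering order of the truth's leaves. After that relabeling,
topology agreement is scored by the Robinson-Foulds (symmetric bipartition)
distance — 0 means identical topologies.
"""

from __future__ import annotations

import dendropy
from dendropy.calculate import treecompare

from .tree import Node, RecognizedTree


def rf_distance(newick_a: str, newick_b: str) -> int:
    """Robinson-Foulds distance between two rooted Newick strings."""
    ns = dendropy.TaxonNamespace()
    t_a = dendropy.Tree.get(
        data=newick_a, schema="newick", taxon_namespace=ns, rooting="force-rooted",
        preserve_underscores=True
    )
    t_b = dendropy.Tree.get(
        data=newick_b, schema="newick", taxon_namespace=ns, rooting="force-rooted",
        preserve_underscores=True
    )
    return int(treecompare.symmetric_difference(t_a, t_b))


def relabel_by_tip_order(recognized: RecognizedTree, labels: list[str]) -> None:
    """Assign ``labels`` to the recognized leaves in top-to-bottom order."""
    leaves = recognized.leaves()
    if len(leaves) != len(labels):
        raise ValueError(
            f"label count {len(labels)} != leaf count {len(leaves)}"
        )
    for leaf, label in zip(leaves, labels):
        leaf.label = label


def topology_match(truth_root: Node, recognized: RecognizedTree) -> bool:
    """RF-0 equivalence after positional relabeling, plus exact leaf count."""
    from .serialize import to_newick

    truth_labels = [leaf.label or "" for leaf in truth_root.leaves()]
    if recognized.n_leaves() != len(truth_labels):
        return False
    relabel_by_tip_order(recognized, truth_labels)
    truth_tree = RecognizedTree(root=truth_root)
    return (
        rf_distance(
            to_newick(truth_tree, include_lengths=False),
            to_newick(recognized, include_lengths=False),
        )
        == 0
    )
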