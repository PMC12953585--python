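"""Independent brute-force topology-weighting oracle built on dendropy.

Used only by tests: weights are recomputed by pruning the tree with
dendropy for every tip combination and matching the induced tree against
the catalog by Robinson-Foulds distance — no code shared with the
implementation under test.
"""

from __future__ import annotations

import itertools
import random

import dendropy
import numpy as np
from dendropy.calculate import treecompare


def random_binary_newick(tip_names: list[str], rng: random.Random) -> str:
    """Random binary tree over the given tips, with positive branch lengths."""
    nodes = [f"{name}:{rng.uniform(0.01, 1.0):.4f}" for name in tip_names]
    while len(nodes) > 1:
        i, j = sorted(rng.sample(range(len(nodes)), 2), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        nodes.append(f"({a},{b}):{rng.uniform(0.01, 1.0):.4f}")
    return nodes[0].rsplit(":", 1)[0] + ";"


def oracle_weights(newick: str, tip_groups: dict[str, str], catalog) -> np.ndarray:
    """Exhaustive weights over the catalog, via dendropy prune + RF match."""
    groups = list(catalog.groups)
    ns = dendropy.TaxonNamespace(groups)
    entry_trees = []
    for e in catalog.entries:
        t = dendropy.Tree.get(data=e.newick, schema="newick", taxon_namespace=ns)
        t.is_rooted = False
        t.encode_bipartitions()
        entry_trees.append(t)

    tips_by_group = {g: sorted(t for t, gg in tip_groups.items() if gg == g) for g in groups}
    weights = np.zeros(len(catalog.entries))
    n_combos = 0
    for combo in itertools.product(*(tips_by_group[g] for g in groups)):
        n_combos += 1
        big = dendropy.Tree.get(data=newick, schema="newick")
        big.retain_taxa_with_labels(list(combo))
        for leaf in big.leaf_node_iter():
            leaf.taxon.label = tip_groups[leaf.taxon.label]
        pruned = dendropy.Tree.get(
            data=big.as_string(schema="newick"), schema="newick", taxon_namespace=ns
        )
        pruned.is_rooted = False
        pruned.encode_bipartitions()
        matches = [
            i
            for i, et in enumerate(entry_trees)
            if treecompare.symmetric_difference(et, pruned) == 0
        ]
        assert matches, "induced topology matched no catalog entry"
        weights[matches] += 1.0 / len(matches)
    return weights / n_combos
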