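"""Independent oracles and random-tree generators for placement tests.

Deliberately implemented differently from the library: the distal test
walks each leaf's path to the root instead of iterating subtrees, and
the per-edge least-squares fit is a dense grid search.
"""

import numpy as np

from rtscout.phylo import Placement, RefTree

import dendropy


def random_reftree(rng, max_leaves=32, n_classes=3, min_leaves=4):
    """Random binary rooted tree with random branch lengths and a
    random leaf->class map."""
    n = int(rng.integers(min_leaves, max_leaves + 1))
    items = [f"L{i}" for i in range(n)]
    sub = {lab: lab for lab in items}
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a, b = items[j], items[i]  # pop higher index first
        items.pop(j)
        items.pop(i)
        la, lb = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
        merged = f"({sub[a]}:{la:.4f},{sub[b]}:{lb:.4f})"
        key = f"n{len(sub)}"
        sub[key] = merged
        items.append(key)
    newick = sub[items[0]] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    classes = [f"K{c}" for c in range(n_classes)]
    leaf_class = {f"L{i}": classes[int(rng.integers(0, n_classes))] for i in range(n)}
    return RefTree(tree=tree, leaf_class=leaf_class)


def random_placement(rng, ref):
    """A placement onto a uniformly random edge with random descending
    weights."""
    nodes = ref.postorder_nodes()
    edge_ids = [i for i, nd in enumerate(nodes) if nd.parent_node is not None]
    eid = int(rng.choice(edge_ids))
    w1 = float(rng.uniform(0.2, 1.0))
    w2 = float(rng.uniform(0.0, w1))
    return Placement(gene_id="q", edges=[(eid, w1), (eid, w2)], best_is_leaf_edge=nodes[eid].is_leaf())


def consensus_oracle(ref, placement, frac=0.90, lwr_gap=0.25):
    """Exhaustive re-derivation of the consensus-class rule: a leaf is
    distal to an edge iff the edge's child node lies on the leaf's
    path to the root."""
    if placement is None or not placement.edges:
        return None, None
    nodes = ref.postorder_nodes()
    child = nodes[placement.edges[0][0]]
    if child.is_leaf():
        cls = ref.leaf_class[child.taxon.label]
    else:
        counts = {}
        for leaf in ref.tree.leaf_node_iter():
            node, on_path = leaf, False
            while node is not None:
                if node is child:
                    on_path = True
                    break
                node = node.parent_node
            if on_path:
                c = ref.leaf_class[leaf.taxon.label]
                counts[c] = counts.get(c, 0) + 1
        total = sum(counts.values())
        top_cls, top_n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        cls = top_cls if top_n / total >= frac else None
    w1 = placement.edges[0][1]
    w2 = placement.edges[1][1] if len(placement.edges) > 1 else 0.0
    conf = 0.0 if (w1 - w2) < lwr_gap else w1
    return cls, conf


def grid_fit_edge(s_sign, c_off, d, edge_len, n_grid=160):
    """Brute-force least-squares attachment: dense grid over the
    attachment offset and pendant length."""
    xs = np.linspace(0.0, max(edge_len, 1e-12), n_grid)
    span = float(np.abs(d - c_off).max() + 1.0)
    ps = np.linspace(0.0, span, n_grid)
    best = np.inf
    for x in xs:
        pred0 = s_sign * x + c_off
        for p in ps:
            r = float(np.sum((p + pred0 - d) ** 2))
            if r < best:
                best = r
    return best
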