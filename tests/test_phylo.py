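"""Tree I/O, neighbor joining, query placement, and subtree consensus."""

import numpy as np
import pytest

import dendropy

from phylo_oracle import consensus_oracle, grid_fit_edge, random_placement, random_reftree
from rtscout.phylo import (
    Placement,
    RefTree,
    build_nj,
    consensus_class,
    make_reference_alignment,
    place_query,
    read_newick,
    write_newick,
    _fit_edge,
)
from rtscout.seqio import ProteinRecord


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def _patristic(newick):
    t = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    pdm = t.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in t.taxon_namespace}
    return lambda a, b: pdm.distance(taxa[a], taxa[b])


# ---------------------------------------------------------------------- I/O

def test_read_newick_basic(tmp_path):
    nwk = _write(tmp_path, "t.nwk", "((a:1,b:1):1,(c:1,d:1):1);")
    cmap = _write(tmp_path, "c.tsv", "a\tX\nb\tX\nc\tY\nd\tY\n")
    ref = read_newick(nwk, cmap)
    assert sorted(ref.leaf_class) == ["a", "b", "c", "d"]
    assert not ref.midpoint_rooted


def test_read_newick_missing_leaf_error(tmp_path):
    nwk = _write(tmp_path, "t.nwk", "((a:1,b:1):1,(c:1,d:1):1);")
    cmap = _write(tmp_path, "c.tsv", "a\tX\nb\tX\nc\tY\n")
    with pytest.raises(ValueError, match="d"):
        read_newick(nwk, cmap)


def test_read_newick_unrooted_midpoint_flag(tmp_path):
    nwk = _write(tmp_path, "t.nwk", "(a:1,b:1,(c:1,d:4):1);")
    cmap = _write(tmp_path, "c.tsv", "a\tX\nb\tX\nc\tY\nd\tY\n")
    ref = read_newick(nwk, cmap)
    assert ref.midpoint_rooted
    assert len(ref.tree.seed_node.child_nodes()) == 2


def test_newick_round_trip(tmp_path):
    nwk = _write(tmp_path, "t.nwk", "((a:1.25,b:0.5):0.125,(c:2,d:1):0.75);")
    cmap = _write(tmp_path, "c.tsv", "a\tX\nb\tX\nc\tY\nd\tY\n")
    ref = read_newick(nwk, cmap)
    out = tmp_path / "o.nwk"
    write_newick(ref, out)
    back = read_newick(out, cmap)
    d0, d1 = _patristic(nwk.read_text()), _patristic(out.read_text())
    for a in "abcd":
        for b in "abcd":
            assert d0(a, b) == pytest.approx(d1(a, b), abs=1e-6)


# ------------------------------------------------------------------- NJ

def test_nj_recovers_additive_tree():
    # tree ((a:2,b:3):1,(c:4,d:5)) -> additive distances
    labels = ["a", "b", "c", "d"]
    D = np.array(
        [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], dtype=float
    )
    nwk = build_nj(D, labels)
    dist = _patristic(nwk)
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            assert dist(x, y) == pytest.approx(D[i, j], abs=1e-9)


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
    nwk = build_nj(D, ["a", "b", "c"])
    dist = _patristic(nwk)
    assert dist("a", "b") == pytest.approx(2)
    assert dist("a", "c") == pytest.approx(3)
    assert dist("b", "c") == pytest.approx(4)


def test_nj_label_equivariance():
    rng = np.random.default_rng(3)
    # additive distances from a random tree via patristic matrix
    ref = random_reftree(rng, max_leaves=8, min_leaves=6)
    leaves = sorted(ref.leaf_class)
    pdm = ref.tree.phylogenetic_distance_matrix()
    taxa = {x.label: x for x in ref.tree.taxon_namespace}
    D = np.array([[pdm.distance(taxa[a], taxa[b]) for b in leaves] for a in leaves])
    perm = rng.permutation(len(leaves))
    d_orig = _patristic(build_nj(D, leaves))
    d_perm = _patristic(build_nj(D[np.ix_(perm, perm)], [leaves[i] for i in perm]))
    for a in leaves:
        for b in leaves:
            assert d_orig(a, b) == pytest.approx(d_perm(a, b), abs=1e-9)


def test_nj_input_validation():
    with pytest.raises(ValueError, match="symmetric"):
        build_nj(np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]), list("abc"))
    with pytest.raises(ValueError):
        build_nj(np.zeros((2, 2)), list("ab"))


# ------------------------------------------------------------- placement

def test_place_query_identical_leaf(bundle):
    nodes = bundle.ref_tree.postorder_nodes()
    for lab in list(bundle.ref_alignment.rows)[:3]:
        q = ProteinRecord(id="q", seq=bundle.ref_alignment.rows[lab])
        pl = place_query(bundle.ref_tree, bundle.ref_alignment, q)
        best = nodes[pl.edges[0][0]]
        assert pl.best_is_leaf_edge
        assert best.taxon.label == lab


def test_place_query_weights_sum_to_one(bundle):
    lab = next(iter(bundle.ref_alignment.rows))
    q = ProteinRecord(id="q", seq=bundle.ref_alignment.rows[lab])
    pl = place_query(bundle.ref_tree, bundle.ref_alignment, q, keep=10**6)
    total = sum(w for _, w in pl.edges)
    assert total == pytest.approx(1.0, abs=1e-9)
    ws = [w for _, w in pl.edges]
    assert ws == sorted(ws, reverse=True)


def test_place_query_short_overlap_returns_none(bundle):
    q = ProteinRecord(id="q", seq="X" * 50)
    assert place_query(bundle.ref_tree, bundle.ref_alignment, q) is None


def test_place_query_symmetric_tree_weight_classes(tmp_path):
    # query equidistant from all 4 leaves of a symmetric tree: weights
    # coincide within each edge symmetry class
    rng = np.random.default_rng(11)
    from rtscout.profiledb import AA

    base = "".join(rng.choice(list(AA), size=60))
    rows = {}
    for i, leaf in enumerate("abcd"):
        s = list(base)
        for pos in range(10 * i, 10 * i + 5):  # disjoint 5-site blocks
            s[pos] = "W" if s[pos] != "W" else "Y"
        rows[leaf] = "".join(s)
    nwk = _write(tmp_path, "t.nwk", "((a:1,b:1):1,(c:1,d:1):1);")
    cmap = _write(tmp_path, "c.tsv", "a\tX\nb\tX\nc\tY\nd\tY\n")
    ref = read_newick(nwk, cmap)
    ra = make_reference_alignment(rows)
    pl = place_query(ref, ra, ProteinRecord(id="q", seq=base), keep=10**6)
    nodes = ref.postorder_nodes()
    by_kind = {"leaf": [], "internal": []}
    for eid, w in pl.edges:
        by_kind["leaf" if nodes[eid].is_leaf() else "internal"].append(w)
    assert len(by_kind["leaf"]) == 4 and len(by_kind["internal"]) == 2
    assert np.ptp(by_kind["leaf"]) < 1e-9
    assert np.ptp(by_kind["internal"]) < 1e-9


def test_fit_edge_matches_grid_oracle():
    rng = np.random.default_rng(13)
    for _ in range(40):
        n = int(rng.integers(3, 12))
        s_sign = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        c_off = rng.uniform(0, 3, n)
        d = rng.uniform(0, 3, n)
        L = float(rng.uniform(0.0, 2.0))
        exact = _fit_edge(s_sign, c_off, d, L)
        grid = grid_fit_edge(s_sign, c_off, d, L)
        assert exact <= grid + 1e-9
        assert exact >= grid - 0.05  # grid resolution slack


def test_fit_edge_residual_scales_quadratically():
    rng = np.random.default_rng(17)
    s_sign = np.where(rng.random(6) < 0.5, 1.0, -1.0)
    c_off = rng.uniform(0, 2, 6)
    d = rng.uniform(0, 2, 6)
    base = _fit_edge(s_sign, c_off, d, 0.8)
    scaled = _fit_edge(s_sign, 3 * c_off, 3 * d, 3 * 0.8)
    assert scaled == pytest.approx(9 * base, rel=1e-9)


def test_mutant_queries_place_near_source_leaf(bundle):
    from rtscout.synthetic import _mutate

    rng = np.random.default_rng(19)
    nodes = bundle.ref_tree.postorder_nodes()
    labels = list(bundle.ref_alignment.rows)
    ok = 0
    trials = 20
    for _ in range(trials):
        lab = labels[int(rng.integers(0, len(labels)))]
        q = _mutate(rng, bundle.ref_alignment.rows[lab], 0.05)
        pl = place_query(bundle.ref_tree, bundle.ref_alignment, ProteinRecord(id="q", seq=q))
        best = nodes[pl.edges[0][0]]
        if best.is_leaf() and best.taxon.label == lab:
            ok += 1
        elif lab in {l.taxon.label for l in best.leaf_iter()}:
            ok += 1  # parent edge of the source leaf
    assert ok >= 0.95 * trials


# ------------------------------------------------------------- consensus

def _clade_tree(tmp_path, comp):
    """Binary tree with one clade of given class composition plus two
    outgroup leaves; returns (ref, postorder id of the clade's edge)."""
    leaves = [f"x{i}" for i in range(sum(comp.values()))]
    classes = [c for c, k in sorted(comp.items()) for _ in range(k)]
    sub = leaves[0]
    for leaf in leaves[1:]:
        sub = f"({sub}:0.5,{leaf}:0.5)"
    nwk = _write(tmp_path, "ct.nwk", f"(({sub}:1,o1:1):1,o2:1);")
    cmap_lines = [f"{l}\t{c}" for l, c in zip(leaves, classes)] + ["o1\tOut", "o2\tOut"]
    cmap = _write(tmp_path, "ct.tsv", "\n".join(cmap_lines) + "\n")
    ref = read_newick(nwk, cmap)
    nodes = ref.postorder_nodes()
    target = next(
        i
        for i, nd in enumerate(nodes)
        if not nd.is_leaf()
        and nd.parent_node is not None
        and {l.taxon.label for l in nd.leaf_iter()} == set(leaves)
    )
    return ref, target


def test_consensus_leaf_edge_uses_leaf_class(tmp_path):
    ref, _ = _clade_tree(tmp_path, {"GII": 3})
    nodes = ref.postorder_nodes()
    leaf_id = next(i for i, nd in enumerate(nodes) if nd.is_leaf() and nd.taxon.label == "x0")
    pl = Placement(gene_id="q", edges=[(leaf_id, 0.8), (leaf_id, 0.1)], best_is_leaf_edge=True)
    assert consensus_class(ref, pl) == ("GII", 0.8)


def test_consensus_ninety_percent_boundary_inclusive(tmp_path):
    ref, eid = _clade_tree(tmp_path, {"GII": 9, "DGRs": 1})
    pl = Placement(gene_id="q", edges=[(eid, 0.7), (eid, 0.1)], best_is_leaf_edge=False)
    cls, conf = consensus_class(ref, pl)
    assert (cls, conf) == ("GII", 0.7)


def test_consensus_below_ninety_percent_is_none(tmp_path):
    ref, eid = _clade_tree(tmp_path, {"GII": 8, "DGRs": 2})
    pl = Placement(gene_id="q", edges=[(eid, 0.7), (eid, 0.1)], best_is_leaf_edge=False)
    cls, _ = consensus_class(ref, pl)
    assert cls is None


def test_consensus_close_weights_zero_confidence(tmp_path):
    ref, eid = _clade_tree(tmp_path, {"GII": 10})
    pl = Placement(gene_id="q", edges=[(eid, 0.5), (eid, 0.3)], best_is_leaf_edge=False)
    cls, conf = consensus_class(ref, pl)
    assert (cls, conf) == ("GII", 0.0)  # class kept, confidence zeroed


def test_consensus_none_placement():
    assert consensus_class(None, None) == (None, None)


def test_consensus_matches_oracle_on_random_trees():
    rng = np.random.default_rng(23)
    for _ in range(80):
        ref = random_reftree(rng)
        pl = random_placement(rng, ref)
        assert consensus_class(ref, pl) == consensus_oracle(ref, pl)
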