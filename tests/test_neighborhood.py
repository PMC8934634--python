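"""Neighbor selection, locus annotation, and CRISPR-like reassignment."""

import numpy as np
import pytest

from rtscout.classify import ClassDecision
from rtscout.neighborhood import (
    Neighborhood,
    annotate_locus,
    intergenic_gap,
    reassign_crispr_like,
    select_neighbors,
)
from rtscout.search import DomainHit
from rtscout.seqio import GeneCall


def genes_from_gaps(left_gaps, rt_len, right_gaps, contig="c"):
    """Build a gene row from the RT outward: left_gaps/right_gaps list
    the intergenic gaps walking away from the RT."""
    glen = 300
    left, pos = [], 10_000
    for i, gap in enumerate(left_gaps):
        end = pos - gap
        left.append(GeneCall(contig, end - glen, end, "+", f"L{i+1}", "M" * 100))
        pos = end - glen
    rt = GeneCall(contig, 10_000, 10_000 + rt_len, "+", "RT", "M" * (rt_len // 3))
    right, pos = [], 10_000 + rt_len
    for i, gap in enumerate(right_gaps):
        start = pos + gap
        right.append(GeneCall(contig, start, start + glen, "+", f"R{i+1}", "M" * 100))
        pos = start + glen
    return rt, sorted(left + [rt] + right, key=lambda g: g.start)


def test_neighbor_selection_two_kb_cap():
    rt, genes = genes_from_gaps([100, 150], 900, [500, 2500])
    nb = select_neighbors(rt, genes)
    assert sorted(nb.neighbors) == [-2, -1, 1]
    assert nb.neighbors[-1].gene_id == "L1"
    assert nb.neighbors[1].gene_id == "R1"


def test_neighbor_selection_contig_edge():
    rt = GeneCall("c", 0, 900, "+", "RT", "M" * 300)
    rest = [
        GeneCall("c", 1000, 1300, "+", "R1", "M" * 100),
        GeneCall("c", 1400, 1700, "+", "R2", "M" * 100),
    ]
    nb = select_neighbors(rt, [rt] + rest)
    assert sorted(nb.neighbors) == [1, 2]


def test_neighbor_selection_stop_at_violation():
    # gaps 100, 3000, 50 walking left: only the first gene qualifies,
    # the 50-gap gene beyond the violation is not rescued
    rt, genes = genes_from_gaps([100, 3000, 50], 900, [])
    nb = select_neighbors(rt, genes)
    assert sorted(nb.neighbors) == [-1]


def test_neighbor_selection_overlap_clamps_to_zero_gap():
    rt = GeneCall("c", 1000, 1900, "+", "RT", "M" * 300)
    overlapping = GeneCall("c", 1800, 2400, "+", "R1", "M" * 200)
    assert intergenic_gap(rt, overlapping) == 0
    nb = select_neighbors(rt, [rt, overlapping])
    assert sorted(nb.neighbors) == [1]


def select_oracle(rt, genes, max_per_side=2, max_gap=2000):
    """Brute-force: rank genes by position, apply the cumulative
    stop-at-violation rule explicitly."""
    same = sorted([g for g in genes if g.contig_id == rt.contig_id], key=lambda g: g.start)
    i = next(k for k, g in enumerate(same) if g.gene_id == rt.gene_id)
    out = {}
    for sign in (-1, 1):
        prev = rt
        for rank in range(1, max_per_side + 1):
            j = i + sign * rank
            if not (0 <= j < len(same)):
                break
            g = same[j]
            gap = max(0, (g.start - prev.end) if sign > 0 else (prev.start - g.end))
            if gap > max_gap:
                break
            out[sign * rank] = g.gene_id
            prev = g
    return out


def test_neighbor_selection_matches_oracle_on_random_layouts():
    rng = np.random.default_rng(31)
    for _ in range(60):
        n_left = int(rng.integers(0, 4))
        n_right = int(rng.integers(0, 4))
        gaps_l = [int(rng.integers(0, 3500)) for _ in range(n_left)]
        gaps_r = [int(rng.integers(0, 3500)) for _ in range(n_right)]
        rt, genes = genes_from_gaps(gaps_l, 900, gaps_r)
        nb = select_neighbors(rt, genes)
        got = {pos: g.gene_id for pos, g in nb.neighbors.items()}
        assert got == select_oracle(rt, genes)


def test_neighbor_selection_ignores_other_contigs():
    rt, genes = genes_from_gaps([100], 900, [100])
    noise = [GeneCall("other", 9_900, 10_500, "+", "N1", "M" * 100)]
    a = select_neighbors(rt, genes)
    b = select_neighbors(rt, genes + noise)
    assert {p: g.gene_id for p, g in a.neighbors.items()} == {
        p: g.gene_id for p, g in b.neighbors.items()
    }


# --------------------------------------------------------------- annotation

def _hit(name, qs, qe, pid="RT"):
    return DomainHit(pid, name, None, 50.0, 1e-9, qs, qe, 0, qe - qs)


def test_fused_domain_from_disjoint_envelope(bundle):
    rt = GeneCall("c", 0, 900, "+", "RT", "M" * 300)
    nb = Neighborhood(rt_gene=rt)
    hits = [_hit("RVT_1", 10, 120), _hit("HEPN", 130, 200)]
    nb = annotate_locus(nb, bundle.broad_library, rt_domain_hits=hits, rt_envelope=(10, 120))
    assert nb.fused_domains == ["HEPN"]


def test_mostly_overlapping_envelope_not_fused(bundle):
    rt = GeneCall("c", 0, 900, "+", "RT", "M" * 300)
    nb = Neighborhood(rt_gene=rt)
    hits = [_hit("RVT_1", 10, 120), _hit("RT_G2_intron", 20, 110)]
    nb = annotate_locus(nb, bundle.broad_library, rt_domain_hits=hits, rt_envelope=(10, 120))
    assert nb.fused_domains == []


def test_planted_neighbor_domain_annotated(bundle, predictions):
    planted = {
        r.rt_gene_id: r.domain
        for r in bundle.truth
        if r.kind == "neighbor" and r.domain and r.in_range
    }
    by_id = {p.gene.gene_id: p for p in predictions}
    for rt_id, domain in planted.items():
        nb = by_id[rt_id].neighborhood
        names = {h.profile_name for hits in nb.neighbor_domains.values() for h in hits}
        assert domain in names


def test_neighbor_without_hits_still_listed(bundle):
    rt = GeneCall("c", 1000, 1900, "+", "RT", "M" * 300)
    plain = GeneCall("c", 2000, 2600, "+", "R1", "QQNE" * 40)
    nb = select_neighbors(rt, [rt, plain])
    nb = annotate_locus(nb, bundle.broad_library, rt_domain_hits=[], rt_envelope=None)
    assert nb.neighbor_domains["R1"] == []


# ------------------------------------------------------------- CRISPR-like

def _decision(cls, status="confident"):
    return ClassDecision(
        gene_id="RT", status=status, class_name=cls, top3=[(cls, 1e-20)], method="single_class"
    )


def _nb_with(domains):
    rt = GeneCall("c", 0, 900, "+", "RT", "M" * 300)
    nb = Neighborhood(rt_gene=rt)
    nb.neighbors = {1: GeneCall("c", 1000, 1300, "+", "N1", "M" * 100)}
    nb.neighbor_domains = {"N1": [_hit(d, 0, 50, pid="N1") for d in domains]}
    return nb


def test_crispr_with_cas_neighbor_kept():
    out = reassign_crispr_like(_decision("CRISPR"), _nb_with(["Cas1"]))
    assert out.class_name == "CRISPR"


def test_crispr_without_cas_downgraded():
    out = reassign_crispr_like(_decision("CRISPR"), _nb_with(["GxxExxY"]))
    assert out.class_name == "CRISPR-like"
    again = reassign_crispr_like(out, _nb_with(["GxxExxY"]))
    assert again == out  # idempotent


def test_non_crispr_classes_untouched():
    out = reassign_crispr_like(_decision("GII"), _nb_with([]))
    assert out.class_name == "GII"


def test_custom_cas_name_set():
    out = reassign_crispr_like(
        _decision("CRISPR"), _nb_with(["MyCasLike"]), cas_domain_names={"OtherCas"}
    )
    assert out.class_name == "CRISPR-like"
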