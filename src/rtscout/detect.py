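"""Two-stage RT candidate identification.

Stage 1 scans every predicted protein against the RT-class library;
any protein with a hit becomes a candidate. Because that library
contains only RT domains, weak spurious matches (classically,
DNA-binding proteins) slip through, so stage 2 re-scans candidates
against a broad domain library and keeps only those that carry at
least one RT-related domain there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .profiledb import ProfileLibrary
from .search import DomainHit, scan, scan_domains
from .seqio import GeneCall, ProteinRecord


@dataclass
class Candidate:
    """A gene whose protein matched the RT library, with its hits."""

    gene: GeneCall
    rt_hits: list[DomainHit]
    all_domain_hits: list[DomainHit] = field(default_factory=list)
    passed_refinement: bool = False


def stage1_candidates(
    genes: list[GeneCall],
    rt_library: ProfileLibrary,
    max_evalue: float = 1e-3,
) -> list[Candidate]:
    """Candidates = genes with >= 1 RT-library hit at E <= max_evalue."""
    proteins = [ProteinRecord(id=g.gene_id, seq=g.protein) for g in genes]
    hits = scan(proteins, rt_library, max_evalue=max_evalue)
    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.protein_id, []).append(h)
    out = []
    for g in genes:
        if g.gene_id in by_gene:
            gh = sorted(by_gene[g.gene_id], key=lambda h: (h.evalue, h.profile_name))
            out.append(Candidate(gene=g, rt_hits=gh))
    return out


def refine_candidates(
    candidates: list[Candidate],
    broad_library: ProfileLibrary,
    rt_related_names: set[str] | None = None,
    max_evalue: float = 1e-3,
) -> list[Candidate]:
    """Keep candidates whose broad-library hits include an RT-related
    domain; the rest are false positives (e.g. plain DNA-binding
    proteins) and are dropped.

    Each surviving candidate carries its full broad-library hit list
    (multi-envelope), later reused for fused-domain detection.
    """
    names = rt_related_names if rt_related_names is not None else broad_library.rt_related_names
    if not names:
        raise ValueError("rt_related_names is empty: refinement would reject everything")
    db = max(len(candidates), 1)
    out = []
    for cand in candidates:
        prot = ProteinRecord(id=cand.gene.gene_id, seq=cand.gene.protein)
        dom_hits = scan_domains(prot, broad_library, max_evalue=max_evalue, db_size=db)
        cand.all_domain_hits = dom_hits
        cand.passed_refinement = any(h.profile_name in names for h in dom_hits)
        if cand.passed_refinement:
            out.append(cand)
    return out


def default_rt_related(broad_library: ProfileLibrary) -> set[str]:
    """Broad-library profile names counted as RT related: anything
    matching RVT / RT_ / group_II_RT naming."""
    import re

    pat = re.compile(r"RVT|RT_|group_II_RT")
    return {p.name for p in broad_library if pat.search(p.name)}
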