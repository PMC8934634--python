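"""Genomic-neighborhood analysis of putative RT genes.

Up to two genes on each side of the RT are collected, walking outward
and stopping at the first intergenic gap above 2 kb. The RT protein
and its neighbors are annotated against the broad domain library;
domain envelopes on the RT protein that lie outside the RT-domain
envelope are reported as fused domains. A confident CRISPR call with
no cas gene anywhere in the locus is downgraded to CRISPR-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .classify import ClassDecision
from .profiledb import ProfileLibrary
from .search import DomainHit, scan_domains
from .seqio import GeneCall, ProteinRecord


@dataclass
class Neighborhood:
    """Selected flanking genes and locus domain annotation for one RT.

    ``neighbors`` maps relative position (-2, -1, +1, +2 in contig
    coordinates) to the neighbor GeneCall; all neighbors are on the
    RT's contig by construction.
    """

    rt_gene: GeneCall
    neighbors: dict[int, GeneCall] = field(default_factory=dict)
    neighbor_domains: dict[str, list[DomainHit]] = field(default_factory=dict)
    rt_domain_hits: list[DomainHit] = field(default_factory=list)
    rt_envelope: tuple[int, int] | None = None
    fused_domains: list[str] = field(default_factory=list)

    @property
    def rt_gene_id(self) -> str:
        return self.rt_gene.gene_id


def intergenic_gap(nearer: GeneCall, farther: GeneCall) -> int:
    """Gap in bp between two gene intervals, clamped to 0 on overlap."""
    if farther.start >= nearer.end:
        return farther.start - nearer.end
    if nearer.start >= farther.end:
        return nearer.start - farther.end
    return 0


def select_neighbors(
    rt_gene: GeneCall,
    genes_on_contig: list[GeneCall],
    max_per_side: int = 2,
    max_gap: int = 2000,
) -> Neighborhood:
    """Walk outward from the RT gene, adding up to ``max_per_side``
    genes per side while each successive intergenic gap is at most
    ``max_gap``; the walk stops at the first violation. Strand is
    ignored for selection."""
    same = sorted(
        (g for g in genes_on_contig if g.contig_id == rt_gene.contig_id),
        key=lambda g: (g.start, g.end, g.gene_id),
    )
    idx = next(i for i, g in enumerate(same) if g.gene_id == rt_gene.gene_id)
    nb = Neighborhood(rt_gene=rt_gene)
    for direction in (-1, +1):
        nearer = rt_gene
        for k in range(1, max_per_side + 1):
            j = idx + direction * k
            if j < 0 or j >= len(same):
                break
            cand = same[j]
            if intergenic_gap(nearer, cand) > max_gap:
                break
            nb.neighbors[direction * k] = cand
            nearer = cand
    return nb


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def annotate_locus(
    nb: Neighborhood,
    broad_library: ProfileLibrary,
    max_evalue: float = 1e-3,
    rt_domain_hits: list[DomainHit] | None = None,
    rt_envelope: tuple[int, int] | None = None,
) -> Neighborhood:
    """Annotate neighbor proteins (and the RT protein) against the
    broad library and derive fused domains.

    A broad-library envelope on the RT protein counts as fused when
    its overlap with the RT-domain envelope is under 50% of the
    shorter of the two envelopes. Pre-computed RT hits/envelope (from
    candidate refinement) are reused when given.
    """
    db = len(nb.neighbors) + 1
    for pos, gene in sorted(nb.neighbors.items()):
        prot = ProteinRecord(id=gene.gene_id, seq=gene.protein)
        nb.neighbor_domains[gene.gene_id] = scan_domains(
            prot, broad_library, max_evalue=max_evalue, db_size=db
        )
    if rt_domain_hits is None:
        prot = ProteinRecord(id=nb.rt_gene.gene_id, seq=nb.rt_gene.protein)
        rt_domain_hits = scan_domains(prot, broad_library, max_evalue=max_evalue, db_size=db)
    nb.rt_domain_hits = rt_domain_hits
    nb.rt_envelope = rt_envelope
    fused: list[str] = []
    if rt_envelope is not None:
        for h in rt_domain_hits:
            env = (h.q_start, h.q_end)
            shorter = min(env[1] - env[0], rt_envelope[1] - rt_envelope[0])
            if shorter <= 0:
                continue
            if _overlap(env, rt_envelope) < 0.5 * shorter:
                if h.profile_name not in fused:
                    fused.append(h.profile_name)
    nb.fused_domains = fused
    return nb


def locus_domain_names(nb: Neighborhood) -> set[str]:
    names = set(nb.fused_domains)
    for hits in nb.neighbor_domains.values():
        names.update(h.profile_name for h in hits)
    return names


def reassign_crispr_like(
    decision: ClassDecision,
    nb: Neighborhood | None,
    cas_domain_names: set[str] | None = None,
) -> ClassDecision:
    """Downgrade a confident CRISPR call to CRISPR-like when no cas
    domain (default: any domain named Cas*/cas*) occurs among the
    neighbors or fused domains. Idempotent; other classes unchanged."""
    if decision.status != "confident" or decision.class_name != "CRISPR":
        return decision
    names = locus_domain_names(nb) if nb is not None else set()
    if cas_domain_names is None:
        has_cas = any(n.lower().startswith("cas") for n in names)
    else:
        has_cas = bool(names & cas_domain_names)
    if has_cas:
        return decision
    return replace(decision, class_name="CRISPR-like")
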