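"""End-to-end prediction: genes in, classified RTs with annotated
neighborhoods out.

Steps: (1) scan all proteins against the RT-class library; (2) refine
candidates against the broad domain library; (3) decide the class
from hit E-values, falling back to phylogenetic placement for
ambiguous cases; (4) select and annotate the genomic neighborhood;
(5) downgrade cas-less CRISPR calls to CRISPR-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import ClassDecision, decide_by_hits, finalize
from .detect import Candidate, default_rt_related, refine_candidates, stage1_candidates
from .neighborhood import Neighborhood, annotate_locus, reassign_crispr_like, select_neighbors
from .phylo import Placement, RefTree, ReferenceAlignment, consensus_class, place_query
from .profiledb import ProfileLibrary
from .seqio import GeneCall, ProteinRecord


@dataclass
class PipelineConfig:
    """Tunable thresholds of the decision cascade (defaults are the
    published operating point)."""

    max_evalue: float = 1e-3
    evalue_ratio: float = 1e5
    consensus_frac: float = 0.90
    lwr_gap: float = 0.25
    max_neighbors_per_side: int = 2
    max_intergenic_gap: int = 2000
    cas_domain_names: set[str] | None = None  # None = any name starting Cas/cas


@dataclass
class RTPrediction:
    """Final call for one putative RT gene."""

    gene: GeneCall
    decision: ClassDecision
    neighborhood: Neighborhood | None = None
    placement: Placement | None = None
    candidate: Candidate | None = None


def run_pipeline(
    genes: list[GeneCall],
    rt_library: ProfileLibrary,
    broad_library: ProfileLibrary,
    ref_tree: RefTree | None = None,
    ref_alignment: ReferenceAlignment | None = None,
    config: PipelineConfig | None = None,
) -> list[RTPrediction]:
    cfg = config or PipelineConfig()
    rt_related = broad_library.rt_related_names or default_rt_related(broad_library)

    candidates = stage1_candidates(genes, rt_library, max_evalue=cfg.max_evalue)
    candidates = refine_candidates(
        candidates, broad_library, rt_related_names=rt_related, max_evalue=cfg.max_evalue
    )

    by_contig: dict[str, list[GeneCall]] = {}
    for g in genes:
        by_contig.setdefault(g.contig_id, []).append(g)

    preds: list[RTPrediction] = []
    for cand in candidates:
        decision = decide_by_hits(cand.rt_hits, ratio=cfg.evalue_ratio)
        placement = None
        if decision.status == "ambiguous":
            pl_class, pl_conf = None, None
            if ref_tree is not None and ref_alignment is not None:
                placement = place_query(
                    ref_tree, ref_alignment, ProteinRecord(id=cand.gene.gene_id, seq=cand.gene.protein)
                )
                pl_class, pl_conf = consensus_class(
                    ref_tree, placement, frac=cfg.consensus_frac, lwr_gap=cfg.lwr_gap
                )
            decision = finalize(decision, pl_class, pl_conf)

        nb = select_neighbors(
            cand.gene,
            by_contig[cand.gene.contig_id],
            max_per_side=cfg.max_neighbors_per_side,
            max_gap=cfg.max_intergenic_gap,
        )
        best_rt = cand.rt_hits[0]
        nb = annotate_locus(
            nb,
            broad_library,
            max_evalue=cfg.max_evalue,
            rt_domain_hits=cand.all_domain_hits,
            rt_envelope=(best_rt.q_start, best_rt.q_end),
        )
        decision = reassign_crispr_like(decision, nb, cfg.cas_domain_names)
        preds.append(
            RTPrediction(
                gene=cand.gene,
                decision=decision,
                neighborhood=nb,
                placement=placement,
                candidate=cand,
            )
        )
    return preds
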