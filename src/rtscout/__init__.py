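"""rtscout: reverse-transcriptase discovery and classification in
prokaryotic genome and metagenome assemblies.

Finds RT genes by a two-stage profile search, assigns each to an RT
class (group II intron, retron, DGR, CRISPR-associated, Abi, ...) via
an E-value decision cascade with a phylogenetic-placement fallback,
and characterizes each RT's genomic neighborhood (flanking-gene
domains, fused domains, co-occurrence and specificity statistics).
"""

from .classify import ClassDecision, decide_by_hits, finalize
from .detect import Candidate, refine_candidates, stage1_candidates
from .neighborhood import Neighborhood, annotate_locus, reassign_crispr_like, select_neighbors
from .phylo import Placement, RefTree, build_nj, consensus_class, place_query, read_newick
from .pipeline import PipelineConfig, RTPrediction, run_pipeline
from .profiledb import (
    ClassAlignment,
    ProfileLibrary,
    ProfileModel,
    build_profile,
    calibrate_evalue,
    dedup_exact,
    evalue,
    load_library,
    save_library,
)
from .search import DomainHit, align_score, scan, scan_domains
from .seqio import ContigSeq, GeneCall, ProteinRecord, call_orfs_naive, read_fasta, read_gff_genes, write_predictions
from .stats import CooccurrenceTable, build_cooccurrence, dedup90, frequency, specificity_score

__version__ = "0.1.0"

__all__ = [
    "ClassAlignment",
    "ClassDecision",
    "Candidate",
    "ContigSeq",
    "CooccurrenceTable",
    "DomainHit",
    "GeneCall",
    "Neighborhood",
    "PipelineConfig",
    "Placement",
    "ProfileLibrary",
    "ProfileModel",
    "ProteinRecord",
    "RTPrediction",
    "RefTree",
    "align_score",
    "annotate_locus",
    "build_cooccurrence",
    "build_nj",
    "build_profile",
    "calibrate_evalue",
    "call_orfs_naive",
    "consensus_class",
    "decide_by_hits",
    "dedup90",
    "dedup_exact",
    "evalue",
    "finalize",
    "frequency",
    "load_library",
    "place_query",
    "read_fasta",
    "read_gff_genes",
    "read_newick",
    "reassign_crispr_like",
    "refine_candidates",
    "run_pipeline",
    "save_library",
    "scan",
    "scan_domains",
    "select_neighbors",
    "specificity_score",
    "stage1_candidates",
    "write_predictions",
]
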