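"""Seeded synthetic data: class families, libraries, reference trees
and planted genomes with ground truth.

The generator emulates the structure the pipeline exploits in real
data: RT classes are protein families diverged far from each other
(between-class divergence ~0.55) but tight within (family divergence
~0.10), genomes carry RT genes surrounded by class-informative
neighbor genes (cas genes near CRISPR RTs, maturase near group II
introns, Avd near DGRs ...), and false-positive bait exists in the
form of a DNA-binding decoy protein sharing a short motif with one RT
family. Every generator is a pure function of (plan, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detect import default_rt_related
from .phylo import ReferenceAlignment, RefTree, build_nj, make_reference_alignment
from .profiledb import (
    AA,
    ClassAlignment,
    ProfileLibrary,
    build_profile,
    calibrate_evalue,
)
from .seqio import ContigSeq, GeneCall, translate

# alphabetically-first codon per residue (determinism over realism)
_CODONS: dict[str, str] = {}
for _b1 in "ACGT":
    for _b2 in "ACGT":
        for _b3 in "ACGT":
            _cod = _b1 + _b2 + _b3
            _aa = translate(_cod)
            if _aa != "*" and _aa not in _CODONS:
                _CODONS[_aa] = _cod


def reverse_translate(protein: str) -> str:
    return "".join(_CODONS[a] for a in protein)


@dataclass
class NeighborPlant:
    """A planted neighbor gene: offset in {-2,-1,+1,+2}, the broad
    domain its protein carries (None = plain background gene), and the
    intergenic gap (bp) between it and the next gene toward the RT."""

    offset: int
    domain: str | None
    gap: int


@dataclass
class RTPlant:
    contig: int
    slot: int
    class_name: str
    neighbors: list[NeighborPlant] = field(default_factory=list)


@dataclass
class DecoyPlant:
    """A DNA-binding decoy sharing a short motif with one RT class."""

    contig: int
    slot: int
    motif_class: str = "GII"
    motif_len: int = 25
    # degenerate similarity: strong enough for the sharp class profile,
    # too weak for the diffuse RT-related profile in the broad library
    motif_divergence: float = 0.40


@dataclass
class SimPlan:
    seed: int = 0
    class_names: tuple[str, ...] = ("GII", "Retrons", "DGRs", "CRISPR", "AbiA")
    family_size: int = 15
    family_divergence: float = 0.10
    between_class_divergence: float = 0.55
    n_contigs: int = 3
    genes_per_contig: int = 30
    rt_plants: list[RTPlant] = field(default_factory=list)
    decoys: list[DecoyPlant] = field(default_factory=list)
    broad_domains: tuple[str, ...] = (
        "Cas1",
        "Cas2",
        "GIIM",
        "Avd_like",
        "HTH_XRE",
        "GxxExxY",
        "ATPase",
    )

    def __post_init__(self):
        if not (0 <= self.family_divergence < self.between_class_divergence < 1):
            raise ValueError("need 0 <= family_divergence < between_class_divergence < 1")


def default_plan(seed: int = 0) -> SimPlan:
    """The standard study conditions: 5 classes x 15 members, 3 contigs
    x 30 genes, 10 planted RTs (one CRISPR with cas neighbors, one
    without), one DNA-binding decoy, and neighbor-gap layouts covering
    the in-range, out-of-range and stop-at-violation cases."""
    plants = [
        RTPlant(0, 4, "GII", [NeighborPlant(+1, "GIIM", 100)]),
        RTPlant(0, 12, "Retrons", [NeighborPlant(-1, "ATPase", 150)]),
        # stop-at-violation: -1 in range, -2 behind a >2 kb gap
        RTPlant(
            0,
            20,
            "DGRs",
            [NeighborPlant(-1, "Avd_like", 100), NeighborPlant(-2, None, 3000)],
        ),
        RTPlant(
            1,
            5,
            "CRISPR",
            [NeighborPlant(+1, "Cas1", 80), NeighborPlant(-1, "Cas2", 90)],
        ),
        # cas-less CRISPR: must be re-assigned CRISPR-like
        RTPlant(1, 14, "CRISPR", [NeighborPlant(-1, "GxxExxY", 100)]),
        # right neighbor beyond the 2 kb cap
        RTPlant(1, 22, "GII", [NeighborPlant(+1, None, 2500)]),
        RTPlant(2, 3, "AbiA", []),
        RTPlant(2, 10, "GII", [NeighborPlant(+2, "GIIM", 120)]),
        RTPlant(2, 17, "Retrons", [NeighborPlant(+1, "ATPase", 140)]),
        RTPlant(2, 25, "DGRs", [NeighborPlant(+1, "Avd_like", 110)]),
    ]
    decoys = [DecoyPlant(2, 20, motif_class="GII")]
    return SimPlan(seed=seed, rt_plants=plants, decoys=decoys)


def _rand_protein(rng, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


def _mutate(rng, seq: str, frac: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < frac:
            choices = [a for a in AA if a != out[i]]
            out[i] = choices[rng.integers(0, 19)]
    return "".join(out)


def p_distance(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if x != y) / len(a)


# ---------------------------------------------------------------------------
# families, tree, libraries

def gen_class_families(plan: SimPlan, max_tries: int = 1000):
    """Per-class alignments of i.i.d. mutants around rejection-sampled
    ancestors; all classes share one alignment frame (no indels), so
    the union of families is itself a master alignment.

    Returns (families: dict class -> ClassAlignment,
             ancestors: dict class -> str).
    """
    rng = np.random.default_rng([plan.seed, 0xFA01])
    length = int(rng.integers(200, 301))
    base = _rand_protein(rng, length)
    ancestors: dict[str, str] = {}
    for _ in range(max_tries):
        trial = {c: _mutate(rng, base, 0.45) for c in plan.class_names}
        ok = all(
            p_distance(trial[a], trial[b]) >= plan.between_class_divergence
            for i, a in enumerate(plan.class_names)
            for b in plan.class_names[i + 1 :]
        )
        if ok:
            ancestors = trial
            break
    else:
        raise RuntimeError(
            "could not draw class ancestors at the requested between-class "
            "divergence after 1000 tries; lower between_class_divergence"
        )
    families = {}
    for cls in plan.class_names:
        rows = [
            (f"{cls}__m{i:02d}", _mutate(rng, ancestors[cls], plan.family_divergence))
            for i in range(plan.family_size)
        ]
        families[cls] = ClassAlignment(class_name=cls, rows=rows)
    return families, ancestors


def gen_reference_tree(families: dict[str, ClassAlignment]):
    """Neighbor-joining tree over all family members (p-distances),
    plus the leaf -> class map.

    The tree is rooted on a class stem edge when the unrooted topology
    separates the classes (so every class is a rooted clade); midpoint
    rooting is the fallback. A root inside one class would make that
    class non-monophyletic in the rooted sense for no biological
    reason.
    """
    import dendropy

    rows = [(rid, seq) for aln in families.values() for rid, seq in aln.rows]
    labels = [rid for rid, _ in rows]
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = p_distance(rows[i][1], rows[j][1])
    newick = build_nj(D, labels)
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    class_sets = {cls: {rid for rid, _ in aln.rows} for cls, aln in families.items()}
    stem = None
    for node in tree.postorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below in class_sets.values():
            stem = node.edge
    if stem is not None:
        half = (stem.length or 0.0) / 2.0
        tree.reroot_at_edge(stem, length1=half, length2=half, update_bipartitions=True)
    elif len(tree.seed_node.child_nodes()) > 2:
        tree.reroot_at_midpoint(update_bipartitions=True)
    tree.suppress_unifurcations()
    tree.is_rooted = True
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.length < 0:
            edge.length = 0.0
    leaf_class = {rid: rid.split("__")[0] for rid, _ in rows}
    return RefTree(tree=tree, leaf_class=leaf_class, midpoint_rooted=True)


def gen_broad_alignments(plan: SimPlan, families: dict[str, ClassAlignment]):
    """Broad-library alignments: one family per named domain plus a
    generic RVT_1 family sampled across all RT classes (3 members
    each), which is what makes true RTs pass refinement."""
    rng = np.random.default_rng([plan.seed, 0xFA02])
    alns: dict[str, ClassAlignment] = {}
    for name in plan.broad_domains:
        length = int(rng.integers(120, 181))
        anc = _rand_protein(rng, length)
        rows = [(f"{name}__m{i}", _mutate(rng, anc, 0.10)) for i in range(8)]
        alns[name] = ClassAlignment(class_name=name, rows=rows)
    # one representative per class: a deliberately diffuse cross-class
    # core-domain model (full-length RTs still score far above its
    # null; short degenerate motifs do not)
    rvt_rows = [aln.rows[0] for aln in families.values()]
    alns["RVT_1"] = ClassAlignment(class_name="RVT_1", rows=rvt_rows)
    return alns


def build_libraries(plan: SimPlan, families, broad_alns, null_n: int = 200):
    """Build and calibrate the RT and broad profile libraries."""
    rt_profiles = []
    for i, (cls, aln) in enumerate(sorted(families.items())):
        prof = build_profile(aln)
        rt_profiles.append(calibrate_evalue(prof, null_n=null_n, seed=(plan.seed * 977 + i) % (2**31)))
    rt_lib = ProfileLibrary(profiles=rt_profiles, kind="rt")
    broad_profiles = []
    for i, (name, aln) in enumerate(sorted(broad_alns.items())):
        prof = build_profile(aln, name=name)
        prof.class_name = None
        broad_profiles.append(
            calibrate_evalue(prof, null_n=null_n, seed=(plan.seed * 977 + 100 + i) % (2**31))
        )
    broad_lib = ProfileLibrary(profiles=broad_profiles, kind="broad")
    broad_lib.rt_related_names = default_rt_related(broad_lib)
    return rt_lib, broad_lib


# ---------------------------------------------------------------------------
# genome

@dataclass
class TruthRow:
    gene_id: str
    contig_id: str
    kind: str  # rt | neighbor | decoy
    class_name: str | None = None
    domain: str | None = None
    rt_gene_id: str | None = None
    offset: int | None = None
    in_range: bool | None = None


def gen_genome(plan: SimPlan, families: dict[str, ClassAlignment], broad_alns):
    """Contigs + gene calls + planted-truth rows.

    Background genes are random proteins; planted RT genes carry a
    fresh family member (mutated ancestor) with short random flanks;
    planted neighbor genes carry a broad-domain consensus. Intergenic
    gaps default to 20-200 bp with plant-specified overrides.
    """
    rng = np.random.default_rng([plan.seed, 0xFA03])
    ancestors = {cls: aln.rows[0][1] for cls, aln in families.items()}
    domain_consensus = {name: aln.rows[0][1] for name, aln in broad_alns.items()}

    plants_by_pos: dict[tuple[int, int], RTPlant] = {}
    neighbor_by_pos: dict[tuple[int, int], tuple[RTPlant, NeighborPlant]] = {}
    gap_override: dict[tuple[int, int], int] = {}  # (contig, slot) -> gap before slot
    for plant in plan.rt_plants:
        plants_by_pos[(plant.contig, plant.slot)] = plant
        for nbp in plant.neighbors:
            slot = plant.slot + nbp.offset
            neighbor_by_pos[(plant.contig, slot)] = (plant, nbp)
            # gap sits on the boundary nearer the RT
            boundary = slot if nbp.offset > 0 else slot + 1
            gap_override[(plant.contig, boundary)] = nbp.gap
    decoys_by_pos = {(d.contig, d.slot): d for d in plan.decoys}

    contigs: list[ContigSeq] = []
    genes: list[GeneCall] = []
    truth: list[TruthRow] = []
    pending_links: list[tuple[TruthRow, tuple[int, int]]] = []
    for ci in range(plan.n_contigs):
        contig_id = f"contig{ci}"
        parts: list[str] = []
        cursor = 0
        for slot in range(plan.genes_per_contig):
            gap = gap_override.get((ci, slot), int(rng.integers(20, 201)))
            parts.append("".join(rng.choice(list("ACGT"), size=gap)))
            cursor += gap

            key = (ci, slot)
            strand = "+"
            row: TruthRow | None = None
            rt_pos: tuple[int, int] | None = None
            if key in plants_by_pos:
                plant = plants_by_pos[key]
                member = _mutate(rng, ancestors[plant.class_name], plan.family_divergence)
                protein = (
                    _rand_protein(rng, int(rng.integers(15, 30)))
                    + member
                    + _rand_protein(rng, int(rng.integers(15, 30)))
                )
                row = TruthRow(
                    gene_id="", contig_id=contig_id, kind="rt", class_name=plant.class_name
                )
            elif key in neighbor_by_pos:
                plant, nbp = neighbor_by_pos[key]
                if nbp.domain is None:
                    protein = _rand_protein(rng, int(rng.integers(120, 301)))
                else:
                    protein = (
                        _rand_protein(rng, 10)
                        + domain_consensus[nbp.domain]
                        + _rand_protein(rng, 10)
                    )
                row = TruthRow(
                    gene_id="",
                    contig_id=contig_id,
                    kind="neighbor",
                    domain=nbp.domain,
                    offset=nbp.offset,
                    in_range=nbp.gap <= 2000,
                )
                rt_pos = (plant.contig, plant.slot)
            elif key in decoys_by_pos:
                dec = decoys_by_pos[key]
                motif_src = ancestors[dec.motif_class]
                start = int(rng.integers(0, len(motif_src) - dec.motif_len))
                motif = _mutate(rng, motif_src[start : start + dec.motif_len], dec.motif_divergence)
                protein = (
                    domain_consensus["HTH_XRE"]
                    + motif
                    + _rand_protein(rng, 20)
                )
                row = TruthRow(gene_id="", contig_id=contig_id, kind="decoy")
            else:
                protein = _rand_protein(rng, int(rng.integers(120, 401)))
                strand = "+" if rng.random() < 0.5 else "-"

            nt = reverse_translate(protein)
            if strand == "-":
                from .seqio import reverse_complement

                nt = reverse_complement(nt)
            start, end = cursor, cursor + len(nt)
            gene_id = f"{contig_id}_{start + 1}_{end}_{strand}"
            genes.append(
                GeneCall(
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    gene_id=gene_id,
                    protein=protein,
                )
            )
            if row is not None:
                row.gene_id = gene_id
                if rt_pos is not None:
                    pending_links.append((row, rt_pos))
                truth.append(row)
            parts.append(nt)
            cursor = end
        parts.append("".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 150)))))
        contigs.append(ContigSeq(id=contig_id, seq="".join(parts)))

    # link neighbor truth rows to their RT gene ids
    gene_id_by_pos = {}
    gi = 0
    for ci in range(plan.n_contigs):
        for slot in range(plan.genes_per_contig):
            gene_id_by_pos[(ci, slot)] = genes[gi].gene_id
            gi += 1
    for row, pos in pending_links:
        row.rt_gene_id = gene_id_by_pos[pos]
    return contigs, genes, truth


@dataclass
class SimBundle:
    plan: SimPlan
    families: dict[str, ClassAlignment]
    ancestors: dict[str, str]
    rt_library: ProfileLibrary
    broad_library: ProfileLibrary
    ref_tree: RefTree
    ref_alignment: ReferenceAlignment
    contigs: list[ContigSeq]
    genes: list[GeneCall]
    truth: list[TruthRow]


def generate_all(plan: SimPlan | None = None, seed: int | None = None, null_n: int = 200) -> SimBundle:
    """One-call fixture: families, calibrated libraries, reference
    tree/alignment and a planted genome, all derived from the plan
    seed (optionally overridden by ``seed``)."""
    if plan is None:
        plan = default_plan(seed if seed is not None else 0)
    elif seed is not None:
        plan.seed = seed
    families, ancestors = gen_class_families(plan)
    ref_tree = gen_reference_tree(families)
    broad_alns = gen_broad_alignments(plan, families)
    rt_lib, broad_lib = build_libraries(plan, families, broad_alns, null_n=null_n)
    rows = {rid: seq for aln in families.values() for rid, seq in aln.rows}
    ref_alignment = make_reference_alignment(rows)
    contigs, genes, truth = gen_genome(plan, families, broad_alns)
    return SimBundle(
        plan=plan,
        families=families,
        ancestors=ancestors,
        rt_library=rt_lib,
        broad_library=broad_lib,
        ref_tree=ref_tree,
        ref_alignment=ref_alignment,
        contigs=contigs,
        genes=genes,
        truth=truth,
    )
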