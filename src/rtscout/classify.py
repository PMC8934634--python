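"""The class-assignment decision cascade.

A putative RT is assigned a class confidently when only one class of
RT profile hits it, or when the top hit is overwhelmingly better than
the runner-up (second E-value at least 1e5-fold higher). Otherwise the
top three classes are kept and the final call defers to phylogenetic
placement: a placement class that agrees with one of the top three is
accepted (with the placement's confidence); a disagreeing or absent
placement leaves the gene unresolved with all candidate classes
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .search import DomainHit

EVALUE_FLOOR = 1e-300


@dataclass
class ClassDecision:
    gene_id: str
    status: str  # confident | ambiguous
    class_name: str | None
    top3: list[tuple[str, float]]
    method: str  # single_class | evalue_ratio | placement | unresolved
    confidence: float | None = None
    placement_class: str | None = None


def decide_by_hits(rt_hits: list[DomainHit], ratio: float = 1e5) -> ClassDecision:
    """First-pass decision from RT-library hits alone.

    Hits are collapsed to the best E-value per class before ranking
    (otherwise one class could fill every top slot). E-values are
    floored at 1e-300 so the ratio test is defined; an exact tie
    between the two best classes is treated as ambiguous.
    """
    if not rt_hits:
        raise ValueError("decide_by_hits requires at least one hit")
    gene_id = rt_hits[0].protein_id
    best: dict[str, float] = {}
    for h in rt_hits:
        if h.class_name is None:
            raise ValueError(f"RT hit without class: {h.profile_name}")
        e = max(h.evalue, EVALUE_FLOOR)
        if h.class_name not in best or e < best[h.class_name]:
            best[h.class_name] = e
    ranked = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
    top3 = ranked[:3]
    if len(ranked) == 1:
        return ClassDecision(
            gene_id=gene_id,
            status="confident",
            class_name=ranked[0][0],
            top3=top3,
            method="single_class",
        )
    e1, e2 = ranked[0][1], ranked[1][1]
    if e1 < e2 and e2 >= ratio * e1:
        return ClassDecision(
            gene_id=gene_id,
            status="confident",
            class_name=ranked[0][0],
            top3=top3,
            method="evalue_ratio",
        )
    return ClassDecision(
        gene_id=gene_id,
        status="ambiguous",
        class_name=None,
        top3=top3,
        method="unresolved",
    )


def finalize(
    decision: ClassDecision,
    placement_class: str | None,
    placement_confidence: float | None,
) -> ClassDecision:
    """Resolve an ambiguous decision with a phylogenetic-placement
    class. Consistency means the placement class is among the top
    three profile-hit classes; anything else leaves the gene
    unresolved with every candidate class reported."""
    if decision.status != "ambiguous":
        raise ValueError("finalize is only defined for ambiguous decisions")
    if placement_class is not None and placement_class in {c for c, _ in decision.top3}:
        return replace(
            decision,
            status="confident",
            class_name=placement_class,
            method="placement",
            confidence=placement_confidence,
            placement_class=placement_class,
        )
    return replace(
        decision,
        status="ambiguous",
        class_name=None,
        method="unresolved",
        placement_class=placement_class,
    )
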