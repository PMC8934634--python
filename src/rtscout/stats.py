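"""Co-occurrence statistics over predicted RT loci.

Counts are taken over non-redundant RTs (90%-identity greedy
clustering): for each RT class, how many RTs carry a given domain in
their neighborhood or fused to the RT protein, at most once per RT.
The specificity score of a domain for a class is that class's count
over the domain's total count across all classes — 1 means the domain
occurs exclusively next to that RT class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from Bio import Align

from .neighborhood import locus_domain_names


@dataclass
class CooccurrenceTable:
    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    class_totals: dict[str, int] = field(default_factory=dict)

    def domains(self) -> set[str]:
        return {d for _, d in self.counts}

    def classes(self) -> set[str]:
        return set(self.class_totals)


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = 0.0
_aligner.extend_gap_score = 0.0


def identity(a: str, b: str) -> float:
    """Fraction of the shorter sequence matched in the best global
    alignment (match=1, mismatch/gap=0, i.e. maximal matched
    residues)."""
    if not a or not b:
        return 0.0
    matches = _aligner.score(a, b)
    return matches / min(len(a), len(b))


def dedup90(rt_proteins, threshold: float = 0.90):
    """Greedy identity clustering: longest-first, each sequence joins
    the first representative at >= ``threshold`` identity, else starts
    a new cluster. Returns the representatives in selection order."""
    ordered = sorted(
        enumerate(rt_proteins), key=lambda iv: (-len(iv[1].seq), iv[0])
    )
    reps = []
    for _, rec in ordered:
        for rep in reps:
            if identity(rec.seq, rep.seq) >= threshold:
                break
        else:
            reps.append(rec)
    return reps


def build_cooccurrence(predictions, level: str = "rt") -> CooccurrenceTable:
    """Count (class, domain) co-occurrences over finalized predictions.

    A domain counts once per RT even when several neighbors carry it.
    ``level='genome'`` counts genomes (via each prediction's
    ``genome_id``, defaulting to the contig) instead of RT instances.
    """
    if level not in ("rt", "genome"):
        raise ValueError(f"unknown counting level {level!r}")
    table = CooccurrenceTable()
    seen_units: dict[str, set] = {}
    seen_pairs: dict[tuple[str, str], set] = {}
    for p in predictions:
        cls = p.decision.class_name
        if cls is None or p.neighborhood is None:
            continue
        unit = (
            p.gene.gene_id
            if level == "rt"
            else getattr(p, "genome_id", None) or p.gene.contig_id
        )
        seen_units.setdefault(cls, set()).add(unit)
        for dom in locus_domain_names(p.neighborhood):
            seen_pairs.setdefault((cls, dom), set()).add(unit)
    table.class_totals = {c: len(u) for c, u in seen_units.items()}
    table.counts = {k: len(u) for k, u in seen_pairs.items()}
    return table


def frequency(table: CooccurrenceTable, class_name: str, domain: str) -> float:
    total = table.class_totals.get(class_name)
    if not total:
        raise ValueError(f"no RTs counted for class {class_name!r}")
    return table.counts.get((class_name, domain), 0) / total


def specificity_score(table: CooccurrenceTable, domain: str, class_name: str) -> float:
    """counts(class, domain) / sum_c counts(c, domain), in [0, 1]."""
    denom = sum(n for (c, d), n in table.counts.items() if d == domain)
    if denom == 0:
        raise ValueError(f"domain {domain!r} never observed in any neighborhood")
    return table.counts.get((class_name, domain), 0) / denom


def round2(x: float) -> float:
    """Half-up rounding to 2 decimals, as printed in reports."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def cooccurrence_frame(table: CooccurrenceTable) -> pd.DataFrame:
    """Tidy (class, domain, count, class_total, frequency, specificity)
    table, sorted for deterministic output."""
    rows = []
    for (cls, dom), n in sorted(table.counts.items()):
        rows.append(
            {
                "class_name": cls,
                "domain": dom,
                "count": n,
                "class_total": table.class_totals.get(cls, 0),
                "frequency": frequency(table, cls, dom),
                "specificity": specificity_score(table, dom, cls),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["class_name", "domain", "count", "class_total", "frequency", "specificity"],
    )
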