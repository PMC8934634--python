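"""Sequence and annotation I/O for the RT-finding pipeline.

Internal coordinates are 0-based half-open throughout; GFF3 input and
output use the standard 1-based inclusive convention. Translation uses
the standard genetic code with no special start-codon handling;
ambiguous nucleotides translate to ``X``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

_VALID_NT = set("ACGTN")
_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class ContigSeq:
    """A nucleotide contig (uppercase, alphabet {A,C,G,T,N})."""

    id: str
    seq: str


@dataclass
class ProteinRecord:
    """A protein sequence; non-canonical residues normalized to X."""

    id: str
    seq: str


@dataclass
class GeneCall:
    """A located coding gene on a contig.

    start/end are 0-based half-open base-pair coordinates on the
    forward strand of the contig; ``protein`` is the strand-aware
    translation (trailing stop removed if present).
    """

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    protein: str


def _clean_nt(seq: str) -> str:
    seq = seq.upper()
    return "".join(c if c in _VALID_NT else "N" for c in seq)


def _clean_aa(seq: str) -> str:
    seq = seq.upper()
    return "".join(c if c in _VALID_AA else "X" for c in seq)


def read_fasta(path, kind: str = "nucleotide"):
    """Read a FASTA file into ContigSeq or ProteinRecord objects.

    ``kind`` is "nucleotide" or "protein". The id is the header token
    before the first whitespace. Duplicate ids and empty files raise
    ``ValueError``.
    """
    if kind not in ("nucleotide", "protein"):
        raise ValueError(f"unknown kind: {kind!r}")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id: {rec.id!r} in {path}")
        seen.add(rec.id)
        raw = str(rec.seq)
        if len(raw) == 0:
            raise ValueError(f"empty sequence for id {rec.id!r} in {path}")
        seq = _clean_nt(raw) if kind == "nucleotide" else _clean_aa(raw)
        cls = ContigSeq if kind == "nucleotide" else ProteinRecord
        records.append(cls(id=rec.id, seq=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def read_contigs(path) -> list[ContigSeq]:
    return read_fasta(path, kind="nucleotide")


def read_proteins(path) -> list[ProteinRecord]:
    return read_fasta(path, kind="protein")


def translate(nt: str) -> str:
    """Plain translation of an in-frame nucleotide string (no start
    handling); trailing partial codon ignored, ambiguity -> X."""
    usable = len(nt) - len(nt) % 3
    aa = str(Seq(nt[:usable]).translate())
    return aa


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def _translate_gene(contig_seq: str, start: int, end: int, strand: str) -> str:
    sub = contig_seq[start:end]
    if strand == "-":
        sub = reverse_complement(sub)
    aa = translate(sub)
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        # internal stops kept as X so downstream scoring ignores them
        aa = aa.replace("*", "X")
    return _clean_aa(aa)


def read_gff_genes(path, contigs: list[ContigSeq]) -> list[GeneCall]:
    """Parse CDS features from a GFF3 file and derive proteins.

    Coordinates are converted from GFF3 1-based inclusive to internal
    0-based half-open. Features on unknown contigs or outside contig
    bounds raise ``ValueError``.
    """
    by_id = {c.id: c for c in contigs}
    genes: list[GeneCall] = []
    seen_ids: set[str] = set()
    n_auto = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, _src, ftype, start1, end1, _score, strand, _phase, attrs = parts
            if ftype not in ("CDS", "gene"):
                continue
            if seqid not in by_id:
                raise ValueError(f"{path}:{lineno}: unknown contig {seqid!r}")
            contig = by_id[seqid]
            start = int(start1) - 1
            end = int(end1)
            if not (0 <= start < end <= len(contig.seq)):
                raise ValueError(
                    f"{path}:{lineno}: feature {start1}..{end1} outside "
                    f"contig {seqid!r} (length {len(contig.seq)})"
                )
            if strand not in ("+", "-"):
                strand = "+"
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if gene_id is None:
                n_auto += 1
                gene_id = f"{seqid}_{start + 1}_{end}_{strand}"
            if gene_id in seen_ids:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen_ids.add(gene_id)
            genes.append(
                GeneCall(
                    contig_id=seqid,
                    start=start,
                    end=end,
                    strand=strand,
                    gene_id=gene_id,
                    protein=_translate_gene(contig.seq, start, end, strand),
                )
            )
    return genes


def call_orfs_naive(contigs: list[ContigSeq], min_aa: int = 60) -> list[GeneCall]:
    """Naive six-frame ORF caller (stand-in for a trained gene finder).

    Reports every maximal stop-to-stop open reading frame with at least
    ``min_aa`` residues, ordered by (contig, start). Output is flagged
    by gene ids ending in ``_orf`` so users can tell naive calls from
    supplied annotations.
    """
    calls: list[GeneCall] = []
    for contig in contigs:
        n = len(contig.seq)
        for strand in ("+", "-"):
            seq = contig.seq if strand == "+" else reverse_complement(contig.seq)
            for frame in range(3):
                aa = translate(seq[frame:])
                # maximal stop-free runs of codons
                pos = 0
                for chunk in aa.split("*"):
                    if len(chunk) >= min_aa:
                        c0, c1 = pos, pos + len(chunk)  # codon indices
                        s = frame + 3 * c0
                        e = frame + 3 * c1
                        if strand == "-":
                            s, e = n - e, n - s
                        calls.append(
                            GeneCall(
                                contig_id=contig.id,
                                start=s,
                                end=e,
                                strand=strand,
                                gene_id=f"{contig.id}_{s + 1}_{e}_{strand}_orf",
                                protein=chunk,
                            )
                        )
                    pos += len(chunk) + 1
    calls.sort(key=lambda g: (g.contig_id, g.start, g.end, g.strand))
    return calls


# ---------------------------------------------------------------------------
# prediction output

_TSV_COLS = [
    "gene_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "status",
    "class_name",
    "method",
    "confidence",
    "top3",
]


def write_predictions(preds, outdir) -> dict[str, str]:
    """Write predictions.tsv, predictions.gff3 and neighborhood.json.

    ``preds`` is a list of :class:`rtscout.pipeline.RTPrediction`.
    Returns the mapping of logical name -> written path. TSV and GFF3
    use 1-based inclusive coordinates.
    """
    os.makedirs(outdir, exist_ok=True)
    tsv_path = os.path.join(outdir, "predictions.tsv")
    gff_path = os.path.join(outdir, "predictions.gff3")
    json_path = os.path.join(outdir, "neighborhood.json")

    with open(tsv_path, "w", newline="") as fh:
        fh.write("\t".join(_TSV_COLS) + "\n")
        for p in preds:
            d = p.decision
            top3 = ",".join(f"{c}:{e:.3g}" for c, e in d.top3)
            conf = "" if d.confidence is None else f"{d.confidence:.4f}"
            row = [
                p.gene.gene_id,
                p.gene.contig_id,
                str(p.gene.start + 1),
                str(p.gene.end),
                p.gene.strand,
                d.status,
                d.class_name or "",
                d.method,
                conf,
                top3,
            ]
            fh.write("\t".join(row) + "\n")

    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in preds:
            d = p.decision
            attrs = [f"ID={p.gene.gene_id}"]
            if d.class_name:
                attrs.append(f"rt_class={d.class_name}")
            if d.confidence is not None:
                attrs.append(f"confidence={d.confidence:.4f}")
            attrs.append(f"method={d.method}")
            fh.write(
                "\t".join(
                    [
                        p.gene.contig_id,
                        "rtscout",
                        "CDS",
                        str(p.gene.start + 1),
                        str(p.gene.end),
                        ".",
                        p.gene.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )

    blob = {}
    for p in preds:
        nb = p.neighborhood
        if nb is None:
            blob[p.gene.gene_id] = None
            continue
        blob[p.gene.gene_id] = {
            "neighbors": [
                {
                    "gene_id": g.gene_id,
                    "position": pos,
                    "strand": g.strand,
                    "domains": [h.profile_name for h in nb.neighbor_domains.get(g.gene_id, [])],
                }
                for pos, g in sorted(nb.neighbors.items())
            ],
            "fused_domains": list(nb.fused_domains),
        }
    with open(json_path, "w") as fh:
        json.dump(blob, fh, indent=1, sort_keys=True)
        fh.write("\n")

    return {"tsv": tsv_path, "gff3": gff_path, "json": json_path}


def write_fasta(records, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_gff(genes: list[GeneCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "rtscout",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )
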