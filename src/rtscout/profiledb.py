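"""Class-specific profile models and the combined profile library.

Each RT class is summarized by a position-specific log-odds profile
built from a per-class multiple alignment (the in-repo analog of one
class HMM). Profiles carry their own extreme-value calibration: scores
of i.i.d. random sequences are fitted with a Gumbel distribution so
that raw bit scores convert to E-values, which is what every
downstream threshold (candidate detection, refinement, neighborhood
annotation) is expressed in.

Two libraries exist at run time: an RT library (every profile tagged
with an RT class; the combined "all RT classes" search target) and a
broad domain library used for refinement and neighborhood annotation.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}
BACKGROUND = 1.0 / 20.0
EULER_GAMMA = 0.5772156649015329


@dataclass
class ClassAlignment:
    """A per-class multiple alignment of RT core-domain sequences."""

    class_name: str
    rows: list[tuple[str, str]]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError(
                f"alignment for {self.class_name!r} needs >= 2 rows, got {len(self.rows)}"
            )
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"alignment rows for {self.class_name!r} differ in length")

    @property
    def ncols(self) -> int:
        return len(self.rows[0][1])


@dataclass
class ProfileModel:
    """Position-specific log-odds profile with affine gap penalties.

    ``match_scores`` has shape (ncols, 20), bit units, residue order
    :data:`AA`; unknown residues (X) score 0 everywhere. ``evd_mu`` and
    ``evd_lambda`` are the Gumbel location/scale fitted on a random
    null; they are None until :func:`calibrate_evalue` runs.
    """

    name: str
    class_name: str | None
    match_scores: np.ndarray
    gap_open: float = 10.0
    gap_extend: float = 1.0
    evd_mu: float | None = None
    evd_lambda: float | None = None
    null_n: int = 0
    # source-alignment column index of each match column (not serialized)
    match_columns: list[int] | None = None

    @property
    def ncols(self) -> int:
        return int(self.match_scores.shape[0])

    @property
    def calibrated(self) -> bool:
        return self.evd_mu is not None and self.evd_lambda is not None

    def consensus(self) -> str:
        return "".join(AA[j] for j in np.argmax(self.match_scores, axis=1))

    def max_score(self) -> float:
        return float(np.max(self.match_scores, axis=1).sum())


@dataclass
class ProfileLibrary:
    """A named set of calibrated profiles of one kind ('rt' or 'broad')."""

    profiles: list[ProfileModel]
    kind: str
    rt_related_names: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.kind not in ("rt", "broad"):
            raise ValueError(f"library kind must be 'rt' or 'broad', got {self.kind!r}")
        names = [p.name for p in self.profiles]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate profile names: {dup}")
        if self.kind == "rt":
            missing = [p.name for p in self.profiles if p.class_name is None]
            if missing:
                raise ValueError(f"rt-library profiles missing class_name: {missing}")

    def __iter__(self):
        return iter(self.profiles)

    def __len__(self):
        return len(self.profiles)

    def get(self, name: str) -> ProfileModel:
        for p in self.profiles:
            if p.name == name:
                return p
        raise KeyError(name)


def dedup_exact(records):
    """Drop exact duplicate sequences (case-insensitive), keeping the
    first occurrence of each; mirrors identity-1.0 clustering."""
    seen: set[str] = set()
    out = []
    for rec in records:
        key = rec.seq.upper()
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out


def build_profile(
    alignment: ClassAlignment,
    name: str | None = None,
    pseudocount: float = 1.0,
    max_gap_frac: float = 0.5,
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> ProfileModel:
    """Build a log-odds profile from a class alignment.

    Match columns are alignment columns whose gap fraction is at most
    ``max_gap_frac``. Per-column scores use Laplace-style pseudocounts
    against a uniform background:

        score(a) = log2( (n_a + pc * bg * 20) / (n_obs + pc * 20) / bg )

    with bg = 1/20. Fewer than 5 surviving columns is an error.
    """
    nrow = len(alignment.rows)
    ncols_in = alignment.ncols
    cols = []
    col_idx = []
    for c in range(ncols_in):
        col = [seq[c].upper() for _, seq in alignment.rows]
        gap_frac = sum(1 for x in col if x in "-.") / nrow
        if gap_frac <= max_gap_frac:
            cols.append(col)
            col_idx.append(c)
    if len(cols) < 5:
        raise ValueError(
            f"alignment too gappy/short: {len(cols)} match columns (< 5) "
            f"for {alignment.class_name!r}"
        )
    scores = np.zeros((len(cols), 20), dtype=float)
    for j, col in enumerate(cols):
        counts = np.zeros(20)
        for x in col:
            i = AA_INDEX.get(x)
            if i is not None:
                counts[i] += 1
        n_obs = counts.sum()
        probs = (counts + pseudocount * BACKGROUND * 20) / (n_obs + pseudocount * 20)
        scores[j] = np.log2(probs / BACKGROUND)
    return ProfileModel(
        name=name or alignment.class_name,
        class_name=alignment.class_name,
        match_scores=scores,
        gap_open=gap_open,
        gap_extend=gap_extend,
        match_columns=col_idx,
    )


def calibrate_evalue(
    profile: ProfileModel,
    null_n: int = 200,
    null_len: int = 350,
    seed: int = 0,
) -> ProfileModel:
    """Fit a Gumbel null distribution of local-alignment scores.

    Scores ``null_n`` i.i.d. uniform-residue random sequences of length
    ``null_len`` and fits Gumbel location/scale by the method of
    moments (lambda = pi / (sigma * sqrt(6)), mu = mean - gamma/lambda).
    Deterministic given ``seed``. Returns a calibrated copy.
    """
    from .search import score_batch  # deferred: search depends on this module

    # domain-separated stream: a calibration null must never replay a
    # sequence stream another component drew from the same user seed
    rng = np.random.default_rng([seed, 0xCA11])
    seqs = ["".join(rng.choice(list(AA), size=null_len)) for _ in range(null_n)]
    scores = score_batch(profile, seqs)
    sigma = float(np.std(scores))
    if sigma == 0.0:
        raise ValueError(f"degenerate null for profile {profile.name!r} (sigma = 0)")
    lam = math.pi / (sigma * math.sqrt(6.0))
    mu = float(np.mean(scores)) - EULER_GAMMA / lam
    return replace(profile, evd_mu=mu, evd_lambda=lam, null_n=null_n)


def evalue(profile: ProfileModel, score: float, db_size: int) -> float:
    """E-value of a bit score under the profile's Gumbel null:
    E = db_size * (1 - exp(-exp(-lambda * (score - mu))))."""
    if not profile.calibrated:
        raise ValueError(f"profile {profile.name!r} is not calibrated")
    x = -profile.evd_lambda * (score - profile.evd_mu)
    # p-value of the max-score null; guard overflow for very poor scores
    if x > 700:
        p = 1.0
    else:
        p = -math.expm1(-math.exp(x))
    return db_size * p


# ---------------------------------------------------------------------------
# plain-text library format: one file per profile

_HEADER_KEYS = ("name", "class", "ncols", "gap_open", "gap_extend", "evd_mu", "evd_lambda", "null_n")


def save_library(lib: ProfileLibrary, dirpath) -> None:
    """Write a library as one .profile text file per profile plus a
    LIBRARY file recording kind and RT-related names."""
    os.makedirs(dirpath, exist_ok=True)
    with open(os.path.join(dirpath, "LIBRARY"), "w") as fh:
        fh.write(f"kind\t{lib.kind}\n")
        fh.write("rt_related\t" + ",".join(sorted(lib.rt_related_names)) + "\n")
    for p in lib.profiles:
        with open(os.path.join(dirpath, f"{p.name}.profile"), "w") as fh:
            fh.write(f"name\t{p.name}\n")
            fh.write(f"class\t{p.class_name if p.class_name is not None else '-'}\n")
            fh.write(f"ncols\t{p.ncols}\n")
            fh.write(f"gap_open\t{p.gap_open:.6f}\n")
            fh.write(f"gap_extend\t{p.gap_extend:.6f}\n")
            fh.write(f"evd_mu\t{p.evd_mu:.6f}\n" if p.calibrated else "evd_mu\t-\n")
            fh.write(f"evd_lambda\t{p.evd_lambda:.6f}\n" if p.calibrated else "evd_lambda\t-\n")
            fh.write(f"null_n\t{p.null_n}\n")
            for row in p.match_scores:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


def _parse_err(path, lineno, msg):
    return ValueError(f"{path}:{lineno}: {msg}")


def load_library(dirpath, kind: str | None = None) -> ProfileLibrary:
    """Load a library directory written by :func:`save_library`."""
    meta_path = os.path.join(dirpath, "LIBRARY")
    lib_kind = kind or "rt"
    rt_related: set[str] = set()
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                key, _, val = line.rstrip("\n").partition("\t")
                if key == "kind":
                    lib_kind = val
                elif key == "rt_related":
                    rt_related = {v for v in val.split(",") if v}
                else:
                    raise _parse_err(meta_path, lineno, f"unknown key {key!r}")
    profiles = []
    for fname in sorted(os.listdir(dirpath)):
        if not fname.endswith(".profile"):
            continue
        path = os.path.join(dirpath, fname)
        with open(path) as fh:
            lines = fh.read().splitlines()
        header: dict[str, str] = {}
        for lineno, line in enumerate(lines[:8], 1):
            key, _, val = line.partition("\t")
            if key not in _HEADER_KEYS or not val:
                raise _parse_err(path, lineno, f"bad header line {line!r}")
            header[key] = val
        if set(header) != set(_HEADER_KEYS):
            raise _parse_err(path, 1, f"incomplete header: {sorted(header)}")
        try:
            ncols = int(header["ncols"])
        except ValueError:
            raise _parse_err(path, 3, f"bad ncols {header['ncols']!r}")
        body = lines[8:]
        if len(body) != ncols:
            raise _parse_err(path, 9, f"expected {ncols} score rows, found {len(body)}")
        scores = np.zeros((ncols, 20))
        for i, line in enumerate(body):
            vals = line.split("\t")
            if len(vals) != 20:
                raise _parse_err(path, 9 + i, f"expected 20 scores, found {len(vals)}")
            try:
                scores[i] = [float(v) for v in vals]
            except ValueError:
                raise _parse_err(path, 9 + i, "non-numeric score")
        profiles.append(
            ProfileModel(
                name=header["name"],
                class_name=None if header["class"] == "-" else header["class"],
                match_scores=scores,
                gap_open=float(header["gap_open"]),
                gap_extend=float(header["gap_extend"]),
                evd_mu=None if header["evd_mu"] == "-" else float(header["evd_mu"]),
                evd_lambda=None if header["evd_lambda"] == "-" else float(header["evd_lambda"]),
                null_n=int(header["null_n"]),
            )
        )
    return ProfileLibrary(profiles=profiles, kind=lib_kind, rt_related_names=rt_related)


def read_class_alignments(dirpath) -> list[ClassAlignment]:
    """Read per-class aligned FASTA files (filename stem = class name)."""
    from Bio import SeqIO

    alignments = []
    for fname in sorted(os.listdir(dirpath)):
        if not (fname.endswith(".fasta") or fname.endswith(".fa") or fname.endswith(".afa")):
            continue
        cls = os.path.splitext(fname)[0]
        rows = [
            (rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(os.path.join(dirpath, fname), "fasta")
        ]
        alignments.append(ClassAlignment(class_name=cls, rows=rows))
    return alignments
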