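"""Local alignment of proteins against profile models.

The scorer is a Smith-Waterman-style dynamic program over profile
columns with affine gap penalties (first gap residue/column costs
``gap_open`` bits, each further one ``gap_extend``). Scores are bits;
E-values come from each profile's Gumbel calibration. A batch scoring
path (vectorized across sequences) backs the scan and null-calibration
loops; the single-sequence path additionally recovers the alignment
envelope and the residue-to-column pairing used by phylogenetic
placement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiledb import AA_INDEX, ProfileLibrary, ProfileModel, evalue

NEG = -1e30
_TOL = 1e-9


@dataclass
class DomainHit:
    """A scored, localized profile match on a protein.

    q_start/q_end are the 0-based half-open residue envelope;
    p_start/p_end the matched profile-column envelope.
    """

    protein_id: str
    profile_name: str
    class_name: str | None
    score: float
    evalue: float
    q_start: int
    q_end: int
    p_start: int
    p_end: int


def _encode(seq: str) -> np.ndarray:
    """Residues -> indices 0..19; anything else (X etc.) -> 20."""
    return np.array([AA_INDEX.get(c, 20) for c in seq.upper()], dtype=np.intp)


def _ext_scores(profile: ProfileModel) -> np.ndarray:
    """(ncols, 21) score matrix; column 20 (unknown residue) scores 0."""
    m = profile.match_scores
    ext = np.zeros((m.shape[0], 21))
    ext[:, :20] = m
    return ext


def score_batch(profile: ProfileModel, seqs: list[str]) -> np.ndarray:
    """Best local alignment score of each sequence against the profile.

    Sequences of unequal length are padded with unknown residues, which
    score zero in every column and therefore cannot change the optimum.
    """
    if not seqs:
        return np.zeros(0)
    ext = _ext_scores(profile)
    m = ext.shape[0]
    nmax = max(len(s) for s in seqs)
    codes = np.full((len(seqs), nmax), 20, dtype=np.intp)
    for b, s in enumerate(seqs):
        codes[b, : len(s)] = _encode(s)
    go, ge = profile.gap_open, profile.gap_extend

    B = len(seqs)
    M = np.full((B, m), NEG)
    Ix = np.full((B, m), NEG)
    Iy = np.full((B, m), NEG)
    best = np.zeros(B)
    jext = np.arange(m) * ge
    for i in range(nmax):
        prev = np.maximum(0.0, np.maximum(M, np.maximum(Ix, Iy)))
        diag = np.empty((B, m))
        diag[:, 0] = 0.0
        diag[:, 1:] = prev[:, :-1]
        Ix = np.maximum(M - go, Ix - ge)
        M = ext[:, codes[:, i]].T + diag
        # Iy[j] = max_{k<j} M[k] - go - (j-1-k)*ge, via running max
        run = np.maximum.accumulate(M + jext, axis=1)
        Iy_new = np.full((B, m), NEG)
        if m > 1:
            Iy_new[:, 1:] = run[:, :-1] - go - jext[1:] + ge
        Iy = Iy_new
        np.maximum(best, M.max(axis=1), out=best)
    return best


def _dp_full(profile: ProfileModel, seq: str):
    """Full (n+1, m+1) DP matrices for one sequence (row 0/col 0 = NEG)."""
    ext = _ext_scores(profile)
    m = ext.shape[0]
    codes = _encode(seq)
    n = len(codes)
    go, ge = profile.gap_open, profile.gap_extend
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    jext = np.arange(m) * ge
    for i in range(1, n + 1):
        prev = np.maximum(0.0, np.maximum(M[i - 1], np.maximum(Ix[i - 1], Iy[i - 1])))
        M[i, 1:] = ext[:, codes[i - 1]] + prev[:-1]
        Ix[i, 1:] = np.maximum(M[i - 1, 1:] - go, Ix[i - 1, 1:] - ge)
        run = np.maximum.accumulate(M[i, 1:] + jext)
        if m > 1:
            Iy[i, 2:] = run[:-1] - go - jext[1:] + ge
    return M, Ix, Iy


def align_details(profile: ProfileModel, seq: str):
    """(score, envelope, pairs) of the best local alignment.

    ``pairs`` lists (residue_index, column_index) for aligned match
    states, both 0-based; ``envelope`` is (q_start, q_end, p_start,
    p_end) half-open, or None when the best alignment is empty
    (score 0).
    """
    if len(seq) == 0:
        return 0.0, None, []
    M, Ix, Iy = _dp_full(profile, seq)
    go, ge = profile.gap_open, profile.gap_extend
    best = float(M.max())
    if best <= 0.0:
        return 0.0, None, []
    i, j = np.unravel_index(int(np.argmax(M)), M.shape)
    pairs: list[tuple[int, int]] = []
    state = "M"
    while True:
        if state == "M":
            pairs.append((i - 1, j - 1))
            prev_val = max(0.0, M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            if prev_val <= _TOL:
                break
            if abs(M[i - 1, j - 1] - prev_val) < _TOL:
                state = "M"
            elif abs(Ix[i - 1, j - 1] - prev_val) < _TOL:
                state = "Ix"
            else:
                state = "Iy"
            i, j = i - 1, j - 1
        elif state == "Ix":
            if abs(M[i - 1, j] - go - Ix[i, j]) < _TOL:
                state = "M"
            else:
                state = "Ix"
            i = i - 1
        else:  # Iy
            if abs(M[i, j - 1] - go - Iy[i, j]) < _TOL:
                state = "M"
            else:
                state = "Iy"
            j = j - 1
    pairs.reverse()
    qs = [q for q, _ in pairs]
    ps = [p for _, p in pairs]
    env = (int(min(qs)), int(max(qs)) + 1, int(min(ps)), int(max(ps)) + 1)
    return best, env, pairs


def align_score(profile: ProfileModel, seq: str):
    """(score, envelope) of the best local alignment (see
    :func:`align_details`)."""
    score, env, _ = align_details(profile, seq)
    return score, env


def scan(
    proteins,
    library: ProfileLibrary,
    max_evalue: float = 1e-3,
    db_size: int | None = None,
) -> list[DomainHit]:
    """Scan proteins against every profile in a calibrated library.

    Reports all hits with E <= ``max_evalue``; the E-value database
    size defaults to the number of proteins scanned. Hits are sorted by
    (protein_id, evalue, profile_name) for deterministic output.
    """
    proteins = list(proteins)
    if not proteins:
        return []
    for p in library:
        if not p.calibrated:
            raise ValueError(f"profile {p.name!r} is not calibrated")
    n_db = db_size if db_size is not None else len(proteins)
    seqs = [pr.seq for pr in proteins]
    hits: list[DomainHit] = []
    for prof in library:
        scores = score_batch(prof, seqs)
        for idx in np.nonzero(scores > 0)[0]:
            e = evalue(prof, float(scores[idx]), n_db)
            if e <= max_evalue:
                s, env, _ = align_details(prof, seqs[idx])
                hits.append(
                    DomainHit(
                        protein_id=proteins[idx].id,
                        profile_name=prof.name,
                        class_name=prof.class_name,
                        score=s,
                        evalue=e,
                        q_start=env[0],
                        q_end=env[1],
                        p_start=env[2],
                        p_end=env[3],
                    )
                )
    hits.sort(key=lambda h: (h.protein_id, h.evalue, h.profile_name))
    return hits


def scan_domains(
    protein,
    library: ProfileLibrary,
    max_evalue: float = 1e-3,
    db_size: int = 1,
    max_envelopes: int = 4,
) -> list[DomainHit]:
    """Multi-envelope scan of one protein against a broad library.

    Per profile, the best envelope is reported, its residues masked to
    unknown, and the remainder re-scanned, up to ``max_envelopes``
    times while E stays under threshold — so two well-separated copies
    of a domain (or a domain fused to an RT) both surface.
    """
    hits: list[DomainHit] = []
    for prof in library:
        if not prof.calibrated:
            raise ValueError(f"profile {prof.name!r} is not calibrated")
        seq = protein.seq
        for _ in range(max_envelopes):
            score, env, _ = align_details(prof, seq)
            if env is None:
                break
            e = evalue(prof, score, db_size)
            if e > max_evalue:
                break
            hits.append(
                DomainHit(
                    protein_id=protein.id,
                    profile_name=prof.name,
                    class_name=prof.class_name,
                    score=score,
                    evalue=e,
                    q_start=env[0],
                    q_end=env[1],
                    p_start=env[2],
                    p_end=env[3],
                )
            )
            seq = seq[: env[0]] + "X" * (env[1] - env[0]) + seq[env[1] :]
    hits.sort(key=lambda h: (h.evalue, h.profile_name, h.q_start))
    return hits
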