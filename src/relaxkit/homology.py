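"""Desk-scale protein homology search: local alignment, E-values, deduplication.

This is a self-contained stand-in for a large-database iterated BLAST
workflow.  Optimal local alignments under BLOSUM62 with affine gaps
(open 11, extend 1: a gap of length g costs 11 + g) are computed through
Biopython's PairwiseAligner; significance uses the Karlin–Altschul formula
E = K·m·n·exp(−λS) with the standard gapped BLOSUM62/11/1 parameters
λ = 0.267 nats per score unit and K = 0.041, and the raw product of the
query length m and the summed database length n (no edge-effect
correction).  The point of the module is the thresholded hit lists that
feed neighborhood co-occurrence mining, not search sophistication; an
optional single-scheme PSSM iteration is provided but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin–Altschul parameters."""

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11      # cost of a gap of length g is gap_open + g*gap_extend
    gap_extend: int = 1
    lam: float = 0.267      # nats per score unit (gapped BLOSUM62/11/1)
    K: float = 0.041


@dataclass
class HomologHit:
    """One above-threshold local alignment between a query and a subject."""

    query_id: str
    subject_id: str
    score: float
    evalue: float
    query_span: tuple[int, int] | None = None    # 1-based inclusive
    subject_span: tuple[int, int] | None = None


@lru_cache(maxsize=8)
def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix_name)
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def _validate(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise InputError(f"empty {name}")
    bad = set(seq) - set(AA_ALPHABET)
    if bad:
        raise InputError(f"{name} contains unknown residue(s): {sorted(bad)}")


def smith_waterman(query: str, subject: str,
                   scheme: ScoringScheme = ScoringScheme(),
                   query_id: str = "query", subject_id: str = "subject",
                   with_spans: bool = True) -> HomologHit:
    """Optimal local alignment score (and spans) under affine gaps.

    Score is >= 0 by construction; a score of 0 means no positive-scoring
    local alignment exists and the spans are ``None``.
    """
    _validate(query, "query")
    _validate(subject, "subject")
    aligner = _aligner(scheme)
    score = float(aligner.score(query, subject))
    qspan = sspan = None
    if score > 0 and with_spans:
        aln = next(iter(aligner.align(query, subject)))
        qblocks, sblocks = aln.aligned
        qspan = (int(qblocks[0][0]) + 1, int(qblocks[-1][1]))
        sspan = (int(sblocks[0][0]) + 1, int(sblocks[-1][1]))
    return HomologHit(query_id, subject_id, max(score, 0.0), math.inf,
                      qspan, sspan)


def evalue(score: float, m: int, n: int,
           scheme: ScoringScheme = ScoringScheme()) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λS)."""
    if m <= 0 or n <= 0:
        raise InputError("sequence lengths must be positive")
    return scheme.K * m * n * math.exp(-scheme.lam * score)


def dedup_identical(seqs: dict[str, str]) -> tuple[dict[str, str], dict[str, str]]:
    """Collapse sequences with 100% identity; first-seen id is kept.

    Returns (kept id -> sequence, original id -> representative id).
    """
    kept: dict[str, str] = {}
    by_seq: dict[str, str] = {}
    mapping: dict[str, str] = {}
    for sid, seq in seqs.items():
        if seq in by_seq:
            mapping[sid] = by_seq[seq]
        else:
            by_seq[seq] = sid
            kept[sid] = seq
            mapping[sid] = sid
    return kept, mapping


def search(queries: dict[str, str], database: dict[str, str],
           threshold: float | dict[str, float],
           scheme: ScoringScheme = ScoringScheme(),
           iterate: bool = False, max_rounds: int = 10) -> list[HomologHit]:
    """Search each query against the database; keep hits with E <= threshold.

    ``threshold`` may be a single expectation cutoff or a per-query-id dict
    (families use different stringencies).  With ``iterate=True`` a simple
    PSSM refinement runs after round 1: position-specific scores are built
    from the ungapped columns of the round-1 alignments (pseudocount 1,
    log-odds in the same λ scale so the Karlin–Altschul formula still
    applies), the database is re-searched, and new hits are added until no
    new subjects appear or ``max_rounds`` is reached.
    """
    if not database:
        return []
    n_total = sum(len(s) for s in database.values())
    hits: list[HomologHit] = []
    for qid, qseq in queries.items():
        thr = threshold[qid] if isinstance(threshold, dict) else threshold
        qhits: dict[str, HomologHit] = {}
        for sid, sseq in database.items():
            hit = smith_waterman(qseq, sseq, scheme, qid, sid, with_spans=False)
            hit.evalue = evalue(hit.score, len(qseq), n_total, scheme)
            if hit.evalue <= thr:
                full = smith_waterman(qseq, sseq, scheme, qid, sid)
                full.evalue = hit.evalue
                qhits[sid] = full
        if iterate:
            for _ in range(max_rounds - 1):
                if not qhits:
                    break
                pssm = _build_pssm(qseq, [database[s] for s in qhits], scheme)
                new = 0
                for sid, sseq in database.items():
                    if sid in qhits:
                        continue
                    score, qspan, sspan = _pssm_local_align(pssm, sseq)
                    ev = evalue(score, len(qseq), n_total, scheme)
                    if ev <= thr:
                        qhits[sid] = HomologHit(qid, sid, score, ev, qspan, sspan)
                        new += 1
                if new == 0:
                    break
        hits.extend(qhits.values())
    return hits


def _build_pssm(query: str, subjects: list[str],
                scheme: ScoringScheme) -> np.ndarray:
    """Position-specific log-odds scores from ungapped alignment columns.

    Counts per query column come from the aligned (non-gap) subject residues
    of the optimal pairwise alignments, plus the query itself, with a
    pseudocount of 1 per residue type; the background is uniform.
    Scores are ln(f/bg)/λ so that λ·S stays in nats.
    """
    counts = np.ones((len(query), 20))
    for i, r in enumerate(query):
        counts[i, _AA_INDEX[r]] += 1
    aligner = _aligner(scheme)
    for sseq in subjects:
        if aligner.score(query, sseq) <= 0:
            continue
        aln = next(iter(aligner.align(query, sseq)))
        qblocks, sblocks = aln.aligned
        for (qs, qe), (ss, _se) in zip(qblocks, sblocks):
            for off in range(qe - qs):
                counts[qs + off, _AA_INDEX[sseq[ss + off]]] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return np.log(freqs / (1.0 / 20.0)) / ScoringScheme().lam


def _pssm_local_align(pssm: np.ndarray, subject: str,
                      scheme: ScoringScheme = ScoringScheme()
                      ) -> tuple[float, tuple[int, int], tuple[int, int]]:
    """Affine-gap local alignment of a PSSM against a sequence (Gotoh DP).

    Returns (score, query span, subject span), spans 1-based.  Python-speed;
    used only in the optional iteration rounds.
    """
    m, n = pssm.shape[0], len(subject)
    sub_idx = [_AA_INDEX[c] for c in subject]
    open_cost = scheme.gap_open + scheme.gap_extend
    ext_cost = scheme.gap_extend
    H = np.zeros((m + 1, n + 1))
    Ix = np.full((m + 1, n + 1), -np.inf)  # gap in subject
    Iy = np.full((m + 1, n + 1), -np.inf)  # gap in query
    best, best_pos = 0.0, (0, 0)
    for i in range(1, m + 1):
        row = pssm[i - 1]
        for j in range(1, n + 1):
            Ix[i, j] = max(H[i - 1, j] - open_cost, Ix[i - 1, j] - ext_cost)
            Iy[i, j] = max(H[i, j - 1] - open_cost, Iy[i, j - 1] - ext_cost)
            diag = H[i - 1, j - 1] + row[sub_idx[j - 1]]
            H[i, j] = max(0.0, diag, Ix[i, j], Iy[i, j])
            if H[i, j] > best:
                best, best_pos = H[i, j], (i, j)
    # traceback for spans only (diagonal preferred, then up, then left)
    i, j = best_pos
    qi, sj = i, j
    while i > 0 and j > 0 and H[i, j] > 0:
        qi, sj = i, j
        diag = H[i - 1, j - 1] + pssm[i - 1][sub_idx[j - 1]]
        if math.isclose(H[i, j], diag):
            i, j = i - 1, j - 1
        elif math.isclose(H[i, j], Ix[i, j]):
            i -= 1
        else:
            j -= 1
    return float(best), (qi, best_pos[0]), (sj, best_pos[1])
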