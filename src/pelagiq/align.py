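"""Local alignment and e-value engine.

This is the single alignment engine behind read screening, taxonomic
classification, fragment recruitment, and ANI. It provides exact
Smith–Waterman local alignment under affine gap penalties with
BLASTN-equivalent filtering semantics:

* identity is computed over all alignment columns, gap columns included
  (BLAST convention);
* e-values follow the Karlin–Altschul formula ``E = K * m * n * exp(-lambda*S)``
  with ``m`` the query length and ``n`` the total length of the searched
  database, using fixed, documented constants;
* both strands are searched and the better one is reported.

A gap of length ``k`` costs ``gap_open + k * gap_extend`` (the BLAST
convention: the opening penalty is charged on top of extension for the first
gap position).

Implementation: a numba-compiled score-only kernel locates the optimal score
and its end cell; the full alignment is then recovered by Biopython's
``PairwiseAligner`` — configured to the identical scoring convention — on a
subject window that provably contains the optimal alignment (an optimal local
alignment with positive score spans fewer than ``2 * len(query)`` subject
positions under these penalties). The kernel's score and the traceback score
are cross-checked on every call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from numba import njit

from .sequences import encode, revcomp

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "DEFAULT_SCHEME",
    "local_align",
    "evalue",
    "bit_score",
    "best_scores",
    "hits_to_outfmt6",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Scoring constants for the engine.

    match/mismatch/gap penalties are magnitudes (all non-negative except the
    match reward, which must be positive); ``lambda_`` and ``k_`` are the
    Karlin–Altschul statistical parameters used for e-values and bit scores.
    The defaults are megablast-like fixed constants chosen for reproducibility.
    """

    match: int = 1
    mismatch: int = 2
    gap_open: int = 2
    gap_extend: int = 1
    lambda_: float = 1.28
    k_: float = 0.46

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match reward must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")
        if self.lambda_ <= 0 or self.k_ <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")

    def substitution_matrix(self) -> np.ndarray:
        """5x5 int32 score matrix over A,C,G,T,N; N never matches anything."""
        sub = np.full((5, 5), -self.mismatch, dtype=np.int32)
        for i in range(4):
            sub[i, i] = self.match
        return sub


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class AlignmentHit:
    """One local alignment, the common currency of the whole pipeline.

    Coordinates are 0-based half-open on the forward strand of both
    sequences; ``strand`` is '+' or '-' for the query orientation.
    ``aln_length`` counts alignment columns including gap columns.
    """

    query_id: str
    subject_id: str
    identity_pct: float
    aln_length: int
    raw_score: int
    bit_score: float
    e_value: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "+"
    n_identical: int = 0
    n_mismatch: int = 0
    n_gap_opens: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct outside [0, 100]")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if self.aln_length < max(self.q_end - self.q_start, self.s_end - self.s_start):
            raise ValueError("aln_length shorter than an aligned span")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@njit(cache=True)
def _sw_end(prof, target, gap_open_ext, gap_ext):  # pragma: no cover - numba
    """Score-only affine Smith-Waterman.

    ``prof`` is the (5, m) query score profile; returns (best score, query
    end, target end), ends exclusive, of the first maximal cell in
    column-major scan order (leftmost subject end).
    """
    m = prof.shape[1]
    n = target.shape[0]
    H = np.zeros(m + 1, dtype=np.int32)
    E = np.zeros(m + 1, dtype=np.int32)
    best = 0
    best_i = 0
    best_j = 0
    for j in range(n):
        row = prof[target[j]]
        diag = 0
        F = 0
        for i in range(1, m + 1):
            e = E[i] - gap_ext
            o = H[i] - gap_open_ext
            if o > e:
                e = o
            if e < 0:
                e = 0
            E[i] = e
            f = F - gap_ext
            o = H[i - 1] - gap_open_ext
            if o > f:
                f = o
            F = f if f > 0 else 0
            h = diag + row[i - 1]
            if e > h:
                h = e
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[i]
            H[i] = h
            if h > best:
                best = h
                best_i = i
                best_j = j + 1
    return best, best_i, best_j


@njit(cache=True)
def _sw_end_multi(prof, cat, bounds, gap_open_ext, gap_ext):  # pragma: no cover
    """Run ``_sw_end`` against many concatenated targets.

    ``bounds`` holds ``len(targets)+1`` offsets into ``cat``. Returns three
    arrays (score, query end, target end) indexed by target.
    """
    k = bounds.shape[0] - 1
    m = prof.shape[1]
    scores = np.zeros(k, dtype=np.int32)
    q_ends = np.zeros(k, dtype=np.int32)
    t_ends = np.zeros(k, dtype=np.int32)
    H = np.zeros(m + 1, dtype=np.int32)
    E = np.zeros(m + 1, dtype=np.int32)
    for s in range(k):
        for i in range(m + 1):
            H[i] = 0
            E[i] = 0
        best = 0
        best_i = 0
        best_j = 0
        for j in range(bounds[s], bounds[s + 1]):
            row = prof[cat[j]]
            diag = 0
            F = 0
            for i in range(1, m + 1):
                e = E[i] - gap_ext
                o = H[i] - gap_open_ext
                if o > e:
                    e = o
                if e < 0:
                    e = 0
                E[i] = e
                f = F - gap_ext
                o = H[i - 1] - gap_open_ext
                if o > f:
                    f = o
                F = f if f > 0 else 0
                h = diag + row[i - 1]
                if e > h:
                    h = e
                if F > h:
                    h = F
                if h < 0:
                    h = 0
                diag = H[i]
                H[i] = h
                if h > best:
                    best = h
                    best_i = i
                    best_j = j - bounds[s] + 1
        scores[s] = best
        q_ends[s] = best_i
        t_ends[s] = best_j
    return scores, q_ends, t_ends


def _profile(query_codes: np.ndarray, scheme: ScoringScheme) -> np.ndarray:
    return np.ascontiguousarray(scheme.substitution_matrix()[:, query_codes])


_ALIGNER_CACHE: dict[ScoringScheme, Align.PairwiseAligner] = {}


def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    """Biopython aligner matching the kernel's scoring convention exactly."""
    al = _ALIGNER_CACHE.get(scheme)
    if al is None:
        mat = substitution_matrices.Array(alphabet="ACGTN", dims=2)
        sub = scheme.substitution_matrix()
        for i, a in enumerate("ACGTN"):
            for j, b in enumerate("ACGTN"):
                mat[a, b] = float(sub[i, j])
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = mat
        # Biopython charges open_gap_score on the first gap position, so the
        # BLAST-convention first-position cost is open+extend.
        al.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
        al.extend_gap_score = -scheme.gap_extend
        _ALIGNER_CACHE[scheme] = al
    return al


def evalue(hit_or_score, query_len: int, db_len: int,
           scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Karlin-Altschul expectation ``E = K * m * n * exp(-lambda * S)``.

    ``m`` is the query length, ``n`` the total nucleotides in the searched
    database, ``S`` the raw alignment score (an :class:`AlignmentHit` may be
    passed directly). Monotonically decreasing in S.
    """
    if query_len <= 0 or db_len <= 0:
        raise ValueError("query and database lengths must be positive")
    s = hit_or_score.raw_score if isinstance(hit_or_score, AlignmentHit) else hit_or_score
    return scheme.k_ * query_len * db_len * math.exp(-scheme.lambda_ * s)


def bit_score(raw_score: int, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Normalized score ``(lambda*S - ln K) / ln 2``."""
    return (scheme.lambda_ * raw_score - math.log(scheme.k_)) / math.log(2.0)


def _traceback(query: str, subject: str, t_end: int, kernel_score: int,
               scheme: ScoringScheme):
    """Recover the optimal alignment ending at ``t_end`` via a subject window.

    Returns (biopython alignment, window offset). The window
    ``[t_end - 2m - 8, t_end)`` always contains the optimal alignment: with a
    positive score, subject-side gap positions number fewer than
    ``m * match / gap_extend`` <= m (defaults), so the aligned subject span is
    < 2m. The traceback score must equal the kernel score.
    """
    m = len(query)
    margin = 2 * m * max(1, scheme.match) // max(1, scheme.gap_extend) + 8
    w0 = max(0, t_end - margin)
    aln = _aligner(scheme).align(query, subject[w0:t_end])[0]
    if int(aln.score) != kernel_score:
        raise RuntimeError(
            f"traceback score {aln.score} != kernel score {kernel_score}; "
            "scoring conventions diverged"
        )
    return aln, w0


def _hit_from_alignment(aln, w0: int, strand: str, query_len: int,
                        query_id: str, subject_id: str,
                        db_len: int, scheme: ScoringScheme) -> AlignmentHit:
    blocks_q, blocks_s = aln.aligned
    qs, qe = int(blocks_q[0][0]), int(blocks_q[-1][1])
    ss, se = int(blocks_s[0][0]) + w0, int(blocks_s[-1][1]) + w0
    if strand == "-":
        qs, qe = query_len - qe, query_len - qs
    counts = aln.counts()
    n_id = int(counts.identities)
    n_mm = int(counts.mismatches)
    n_gap = int(counts.gaps)
    n_cols = n_id + n_mm + n_gap
    gap_opens = sum(
        1
        for blocks in aln.aligned
        for a, b in zip(blocks[:-1], blocks[1:])
        if int(a[1]) != int(b[0])
    )
    raw = int(aln.score)
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        identity_pct=100.0 * n_id / n_cols,
        aln_length=n_cols,
        raw_score=raw,
        bit_score=bit_score(raw, scheme),
        e_value=evalue(raw, query_len, db_len, scheme),
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
        strand=strand,
        n_identical=n_id,
        n_mismatch=n_mm,
        n_gap_opens=gap_opens,
    )


def local_align(query: str, subject: str,
                scheme: ScoringScheme = DEFAULT_SCHEME,
                *, query_id: str = "query", subject_id: str = "subject",
                db_len: int | None = None,
                both_strands: bool = True) -> AlignmentHit | None:
    """Best-scoring Smith-Waterman local alignment, searching both strands.

    Returns ``None`` when no alignment with positive score exists. On a score
    tie between strands the forward strand wins. ``db_len`` (default:
    ``len(subject)``) sets the database size used for the e-value.
    """
    q_codes = encode(query)
    s_codes = encode(subject)
    if db_len is None:
        db_len = len(subject)
    prof_f = _profile(q_codes, scheme)
    goe = scheme.gap_open + scheme.gap_extend
    score_f, _, tend_f = _sw_end(prof_f, s_codes, goe, scheme.gap_extend)
    score_r, tend_r = -1, 0
    query_rc = None
    if both_strands:
        query_rc = revcomp(query)
        prof_r = _profile(encode(query_rc), scheme)
        score_r, _, tend_r = _sw_end(prof_r, s_codes, goe, scheme.gap_extend)
    if max(score_f, score_r) <= 0:
        return None
    if score_f >= score_r:
        aln, w0 = _traceback(query, subject, int(tend_f), int(score_f), scheme)
        return _hit_from_alignment(aln, w0, "+", len(query), query_id,
                                   subject_id, db_len, scheme)
    aln, w0 = _traceback(query_rc, subject, int(tend_r), int(score_r), scheme)
    return _hit_from_alignment(aln, w0, "-", len(query), query_id,
                               subject_id, db_len, scheme)


class SubjectIndex:
    """Pre-encoded, concatenated subject set for repeated kernel searches."""

    def __init__(self, subjects: Sequence[tuple[str, str]]):
        if not subjects:
            raise ValueError("empty subject set")
        self.ids = [sid for sid, _ in subjects]
        self.seqs = [seq for _, seq in subjects]
        codes = [encode(seq) for seq in self.seqs]
        self.cat = np.concatenate(codes)
        self.bounds = np.zeros(len(codes) + 1, dtype=np.int64)
        np.cumsum([len(c) for c in codes], out=self.bounds[1:])
        self.total_nt = int(self.bounds[-1])


def best_scores(query: str, index: SubjectIndex,
                scheme: ScoringScheme = DEFAULT_SCHEME,
                *, both_strands: bool = True):
    """Kernel scores of a query against every subject in the index.

    Returns ``(scores, t_ends, strands)`` arrays over subjects, where each
    entry reflects the better strand (forward wins ties).
    """
    goe = scheme.gap_open + scheme.gap_extend
    prof = _profile(encode(query), scheme)
    scores, _, t_ends = _sw_end_multi(prof, index.cat, index.bounds, goe,
                                      scheme.gap_extend)
    strands = np.full(len(index.ids), "+", dtype="U1")
    if both_strands:
        prof_r = _profile(encode(revcomp(query)), scheme)
        scores_r, _, t_ends_r = _sw_end_multi(prof_r, index.cat, index.bounds,
                                              goe, scheme.gap_extend)
        better = scores_r > scores
        scores = np.where(better, scores_r, scores)
        t_ends = np.where(better, t_ends_r, t_ends)
        strands = np.where(better, "-", "+")
    return scores, t_ends, strands


def align_to_subject(query: str, index: SubjectIndex, subject_idx: int,
                     strand: str, t_end: int, kernel_score: int,
                     scheme: ScoringScheme = DEFAULT_SCHEME,
                     *, query_id: str = "query",
                     db_len: int | None = None) -> AlignmentHit:
    """Full alignment of a query against one indexed subject (known winner)."""
    subject = index.seqs[subject_idx]
    oriented = query if strand == "+" else revcomp(query)
    aln, w0 = _traceback(oriented, subject, t_end, kernel_score, scheme)
    return _hit_from_alignment(aln, w0, strand, len(query), query_id,
                               index.ids[subject_idx],
                               db_len if db_len is not None else len(subject),
                               scheme)


def hits_to_outfmt6(hits: Sequence[AlignmentHit]):
    """Export hits as a BLAST outfmt-6-style table (1-based closed coords).

    Subject start/end are swapped on the minus strand, as BLAST does.
    """
    import pandas as pd

    rows = []
    for h in hits:
        sstart, send = h.s_start + 1, h.s_end
        if h.strand == "-":
            sstart, send = send, sstart
        rows.append((h.query_id, h.subject_id, round(h.identity_pct, 3),
                     h.aln_length, h.n_mismatch, h.n_gap_opens,
                     h.q_start + 1, h.q_end, sstart, send,
                     h.e_value, round(h.bit_score, 2)))
    return pd.DataFrame(rows, columns=[
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore"])
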