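"""Internal seed-and-extend local pairwise matcher.

One homology-search engine backs every stage that needs alignment (flank
assignment, pre-insertion discovery, iterative element search, REP
annotation, identity clustering): exact k-mer anchors against an indexed
subject set, extended by a banded local Smith–Waterman around each anchor
diagonal. Default scoring +1 match / −1 mismatch / −2 gap; both strands are
searched; hits are reported in descending score.

For gap-free optima that contain at least one exact k-mer, the best hit
matches a full Smith–Waterman by construction (the band is centred on the
anchor diagonal and the optimum never leaves it).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .seqio import SeqRecord, revcomp

__all__ = ["LocalHit", "SubjectIndex", "seed_extend_align"]


@dataclass
class LocalHit:
    """A local alignment between a query and one subject.

    Coordinates are 0-based half-open on the forward strand of both
    sequences; for ``strand == '-'`` the reverse complement of the query
    aligned, and query coordinates are mapped back via ``x -> L - x``.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    score: int
    identity: float
    n_columns: int = 0  # alignment columns incl. gaps

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise ValueError("bad query interval")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError("bad subject interval")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity outside [0,1]")


_CODE = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (N, ambiguity) -> 4 (never matches)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class SubjectIndex:
    """k-mer hash of a subject collection, built once and reused."""

    def __init__(self, subjects: list[SeqRecord], k: int):
        if k < 8:
            raise ValueError("k must be >= 8")
        if not subjects:
            raise ValueError("subjects must be non-empty")
        self.k = k
        self.subjects = subjects
        self._index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for si, rec in enumerate(subjects):
            s = rec.seq
            for pos in range(len(s) - k + 1):
                kmer = s[pos : pos + k]
                if "N" not in kmer and "-" not in kmer:
                    self._index[kmer].append((si, pos))

    def anchors(self, qseq: str):
        k = self.k
        for qpos in range(len(qseq) - k + 1):
            for si, spos in self._index.get(qseq[qpos : qpos + k], ()):
                yield si, spos - qpos, qpos


def _banded_sw(q: np.ndarray, s: np.ndarray, diag: int, band: int,
               match: int, mismatch: int, gap: int):
    """Banded local DP around ``diag`` (= s_pos - q_pos). Returns
    (score, q_start, q_end, s_start, s_end, matches, columns) or None."""
    m, n = len(q), len(s)
    w = 2 * band + 1
    NEG = -(10 ** 9)
    H_prev = np.full(w, 0, dtype=np.int64)
    # pointers: 0 stop, 1 diag, 2 up(del in subject/consume q), 3 left(consume s)
    ptr = np.zeros((m + 1, w), dtype=np.int8)
    best = (0, -1, -1)  # score, row, band-offset
    for i in range(1, m + 1):
        center = diag + (i - 1)  # subject col (0-based) paired with q[i-1] at offset band
        js = center - band + np.arange(w)  # 0-based subject positions
        valid = (js >= 0) & (js < n)
        if not valid.any():
            H_prev = np.where(valid, 0, NEG)
            continue
        sub = np.where(valid & (q[i - 1] == s[np.clip(js, 0, n - 1)]) & (q[i - 1] < 4),
                       match, mismatch)
        diag_sc = H_prev + sub            # same offset, previous row
        up_sc = np.full(w, NEG, dtype=np.int64)   # gap in subject: i-1 row, offset+1
        up_sc[:-1] = H_prev[1:] + gap
        cand = np.maximum(diag_sc, up_sc)
        best_sc = np.maximum(cand, 0)
        p = np.where(best_sc == 0, 0, np.where(diag_sc >= up_sc, 1, 2))
        # left (gap-in-query) moves propagate within the row; a prefix-max
        # scan on v[d] - gap*d is equivalent to sequential propagation
        if w > 1:
            u = best_sc - gap * np.arange(w)
            pm = np.maximum.accumulate(u[:-1])
            left_sc = gap * np.arange(1, w) + pm
            wins = left_sc > best_sc[1:]
            best_sc[1:] = np.where(wins, left_sc, best_sc[1:])
            p[1:][wins] = 3
        best_sc[~valid] = NEG
        p[~valid] = 0
        ptr[i] = p
        row_best = int(best_sc.max(initial=NEG))
        if row_best > best[0]:
            best = (row_best, i, int(best_sc.argmax()))
        H_prev = best_sc
    score, bi, bd = best
    if score <= 0:
        return None
    # traceback
    i, d = bi, bd
    matches = columns = 0
    q_end = bi
    s_end = diag + (bi - 1) - band + bd + 1
    while i > 0 and ptr[i, d] != 0:
        mv = ptr[i, d]
        j = diag + (i - 1) - band + d  # subject 0-based pos at this cell
        if mv == 1:
            columns += 1
            if q[i - 1] == s[j] and q[i - 1] < 4:
                matches += 1
            i -= 1
        elif mv == 2:
            columns += 1
            i -= 1
            d += 1
        else:  # 3: gap in query, consume subject
            columns += 1
            d -= 1
    q_start = i
    s_start = diag + (i - 1) - band + d + 1 if columns else s_end
    if columns == 0:
        return None
    return score, q_start, q_end, s_start, s_end, matches, columns


def _group_anchors(anchors, band):
    """Collapse anchors into one representative per (subject, diagonal band)."""
    groups: dict[tuple[int, int], tuple[int, int]] = {}
    for si, diag, qpos in anchors:
        key = (si, diag // max(band, 1))
        if key not in groups or qpos < groups[key][1]:
            groups[key] = (diag, qpos)
    return [(si_b[0], dq[0], dq[1]) for si_b, dq in groups.items()]


def seed_extend_align(
    query: SeqRecord,
    subjects: list[SeqRecord] | SubjectIndex,
    k: int = 11,
    min_score: int = 20,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    band: int = 8,
) -> list[LocalHit]:
    """Align ``query`` to all subjects on both strands; hits below
    ``min_score`` are dropped. A query shorter than ``k`` yields an empty
    result with a warning."""
    index = subjects if isinstance(subjects, SubjectIndex) else SubjectIndex(subjects, k)
    if len(query.seq) < index.k:
        warnings.warn(f"query {query.id!r} shorter than k={index.k}; no hits")
        return []
    enc_subj = [encode(r.seq) for r in index.subjects]
    Lq = len(query.seq)
    hits: list[LocalHit] = []
    for strand, qseq in (("+", query.seq), ("-", revcomp(query.seq))):
        q = encode(qseq)
        for si, diag, _qpos in _group_anchors(index.anchors(qseq), band):
            res = _banded_sw(q, enc_subj[si], diag, band, match, mismatch, gap)
            if res is None:
                continue
            score, q0, q1, s0, s1, matches, cols = res
            if score < min_score:
                continue
            if strand == "-":
                q0, q1 = Lq - q1, Lq - q0
            hits.append(
                LocalHit(query.id, index.subjects[si].id, q0, q1, s0, s1,
                         strand, score, matches / cols, cols)
            )
    return _dedupe(hits)


def _overlap(a0, a1, b0, b1) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _dedupe(hits: list[LocalHit]) -> list[LocalHit]:
    """Keep the best hit among near-duplicates (same subject+strand, mostly
    overlapping on both query and subject)."""
    hits = sorted(hits, key=lambda h: -h.score)
    kept: list[LocalHit] = []
    for h in hits:
        dup = False
        for g in kept:
            if g.subject_id != h.subject_id or g.strand != h.strand:
                continue
            qo = _overlap(g.q_start, g.q_end, h.q_start, h.q_end)
            so = _overlap(g.s_start, g.s_end, h.s_start, h.s_end)
            if (qo > 0.5 * (h.q_end - h.q_start)
                    and so > 0.5 * (h.s_end - h.s_start)):
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept
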