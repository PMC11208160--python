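"""IS-element boundary inference.

Boundaries come from comparative genomics: a post-insertion locus (element
plus ~1 kb flanks) is compared with candidate contigs; where both distal
flanks align contiguously to one candidate but the recombinase CDS region
does not, the candidate is a pre-insertion site and the inner edges of the
flank alignments are the element breakpoints. The 2-10-nt core is then the
longest repeat found near both predicted ends whose placement reconciles the
pre- and post-insertion junctions (the element carries exactly one copy, at
its 5' end, with the target's copy immediately downstream). An iterative
homology search then grows the element set to a fixed point: a hit becomes a
new element only when both element ends align and the junction core is
concordant with the query's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .align import LocalHit, SubjectIndex, seed_extend_align
from .seqio import SeqRecord, revcomp

__all__ = [
    "ISElement",
    "BoundaryEvidence",
    "find_pre_insertion_boundaries",
    "identify_core",
    "iterative_element_search",
]


@dataclass
class ISElement:
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    core: str | None = None
    cds_start: int | None = None
    cds_end: int | None = None
    provenance: str = "seed"
    iteration: int = 0
    seq: str | None = None          # element sequence on its own strand

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("element start must be < end")
        if self.core is not None and len(self.core) < 2:
            raise ValueError("core length must be >= 2")

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.contig_id, self.start, self.end)

    @property
    def le_interval(self) -> tuple[int, int] | None:
        """Left non-coding end (element-relative), if the CDS is known."""
        return (0, self.cds_start) if self.cds_start is not None else None

    @property
    def re_interval(self) -> tuple[int, int] | None:
        if self.cds_end is None:
            return None
        return (self.cds_end, self.end - self.start)


@dataclass
class BoundaryEvidence:
    locus_id: str
    pre_contig_id: str
    left_breakpoint: int            # locus coordinates, 0-based
    right_breakpoint: int
    flank_hit_left: LocalHit
    flank_hit_right: LocalHit
    cds_hit_absent: bool = True


def _best_hit(hits: list[LocalHit], subject_id: str,
              strand: str) -> LocalHit | None:
    cands = [h for h in hits if h.subject_id == subject_id and h.strand == strand]
    return max(cands, key=lambda h: h.score, default=None)


def find_pre_insertion_boundaries(
    locus: SeqRecord,
    candidates: list[SeqRecord],
    min_flank: int = 200,
    gap_tol: int = 20,
    flank: int = 1000,
    cds_interval: tuple[int, int] | None = None,
    min_cov: float = 0.9,
    k: int = 13,
) -> list[BoundaryEvidence]:
    """Candidates where both distal flanks of ``locus`` align contiguously
    (subject gap <= gap_tol) but the CDS region does not; breakpoints are the
    inner edges of the flank hits on the locus."""
    if len(locus.seq) <= 2 * min_flank:
        raise ValueError(f"locus shorter than 2*min_flank={2 * min_flank}")
    flank_len = min(flank, (len(locus.seq) - 1) // 2)
    if flank_len < flank:
        warnings.warn(f"locus {locus.id!r}: flanks shortened to {flank_len} nt")
    if not candidates:
        return []
    index = SubjectIndex(candidates, k)
    qL = SeqRecord("flankL", locus.seq[:flank_len])
    qR = SeqRecord("flankR", locus.seq[-flank_len:])
    if cds_interval is None:
        cds_interval = (flank_len + 100, len(locus.seq) - flank_len - 100)
    cs, ce = cds_interval
    cds_hits: list[LocalHit] = []
    if ce - cs >= k:
        cds_hits = seed_extend_align(SeqRecord("cds", locus.seq[cs:ce]), index,
                                     min_score=int(0.5 * min(200, ce - cs)))
    hitsL = seed_extend_align(qL, index, min_score=int(min_cov * flank_len * 0.5))
    hitsR = seed_extend_align(qR, index, min_score=int(min_cov * flank_len * 0.5))

    out: list[BoundaryEvidence] = []
    for cand in candidates:
        if any(h.subject_id == cand.id for h in cds_hits):
            continue
        for strand in ("+", "-"):
            hL = _best_hit(hitsL, cand.id, strand)
            hR = _best_hit(hitsR, cand.id, strand)
            if hL is None or hR is None:
                continue
            if (hL.q_end - hL.q_start) < min_cov * flank_len:
                continue
            if (hR.q_end - hR.q_start) < min_cov * flank_len:
                continue
            if strand == "+":
                gap = hR.s_start - hL.s_end
            else:
                gap = hL.s_start - hR.s_end
            if abs(gap) > gap_tol:
                continue
            left_bp = hL.q_end
            right_bp = len(locus.seq) - flank_len + hR.q_start
            out.append(BoundaryEvidence(locus.id, cand.id, left_bp, right_bp,
                                        hL, hR, cds_hit_absent=True))
    return out


def identify_core(locus: SeqRecord, left_bp: int, right_bp: int,
                  window: int = 30, max_core: int = 10
                  ) -> tuple[str | None, int, int]:
    """Longest exact repeat (2..max_core nt) near both predicted element ends
    whose placement reconciles the junctions.

    Returns (core, refined_start, refined_end): the element carries one core
    copy at refined_start and the downstream flank repeats it at refined_end.
    Ties break by repeat length (longest), then proximity to the
    breakpoints, then leftmost. (None, left_bp, right_bp) when no repeat of
    length >= 2 exists in the windows."""
    if window < max_core:
        raise ValueError("window must be >= max_core")
    s = locus.seq
    n = len(s)

    def longest_at(p: int, q: int) -> int:
        L = 0
        while (L < max_core and q + L < n and p + L < q
               and s[p + L] == s[q + L]):
            L += 1
        return L

    # Reconciliation: deleting [left_bp+d, right_bp+d) must reproduce the
    # pre-insertion joint, so only shifts d reachable through a contiguous
    # junction repeat qualify (s[left_bp:left_bp+d] == s[right_bp:right_bp+d]
    # for d>0, mirrored for d<0). The breakpoints themselves may be off by a
    # few bases, so each candidate shift is probed in (|d|, d) order.
    best: tuple[int, int, int, str] | None = None  # (-L, |d|, d, core)
    for d in sorted(range(-window, window + 1), key=lambda x: (abs(x), x)):
        p, q = left_bp + d, right_bp + d
        if p < 0 or q <= p or q >= n:
            continue
        if d > 0 and s[left_bp : left_bp + d] != s[right_bp : right_bp + d]:
            continue
        if d < 0 and s[p:left_bp] != s[q:right_bp]:
            continue
        L = longest_at(p, q)
        if L >= 2:
            cand = (-L, abs(d), d, s[p : p + L])
            if best is None or cand[:3] < best[:3]:
                best = cand
    if best is None:
        # loose fallback for noisy breakpoints: any same-shift repeat nearby
        for L in range(max_core, 1, -1):
            for d in sorted(range(-window, window + 1), key=lambda x: (abs(x), x)):
                p, q = left_bp + d, right_bp + d
                if p < 0 or q <= p or q + L > n:
                    continue
                if s[p : p + L] == s[q : q + L]:
                    return s[p : p + L], p, q
        return None, left_bp, right_bp
    _negL, _ad, d, core = best
    return core, left_bp + d, right_bp + d


def _q_coverage(hits: list[LocalHit], lo: int, hi: int) -> float:
    covered = 0
    pos = lo
    for h in sorted(hits, key=lambda h: h.q_start):
        a, b = max(h.q_start, pos), min(h.q_end, hi)
        if b > a:
            covered += b - a
            pos = b
    return covered / max(hi - lo, 1)


def iterative_element_search(
    seeds: list[ISElement],
    locus_db: list[SeqRecord],
    max_iter: int = 50,
    end_len: int = 100,
    end_cov: float = 0.9,
    end_identity: float = 0.8,
    k: int = 13,
) -> tuple[list[ISElement], pd.DataFrame, bool]:
    """Expand ``seeds`` against ``locus_db`` to convergence.

    Per iteration, every newly found element is aligned to all loci; a hit
    becomes a new element only if hits cover >= ``end_cov`` of each terminal
    ``end_len`` nt at >= ``end_identity`` identity and the junction core of
    the implied interval matches the query's core exactly (after strand
    normalization). The element set only grows; convergence is the fixed
    point. Returns (elements, per-iteration counts, converged flag)."""
    if not seeds:
        raise ValueError("seeds must be non-empty")
    contigs = {r.id: r for r in locus_db}
    index = SubjectIndex(locus_db, k)

    def elem_seq(e: ISElement) -> str:
        if e.seq is not None:
            return e.seq
        s = contigs[e.contig_id].seq[e.start : e.end]
        return revcomp(s) if e.strand == "-" else s

    elements: dict[tuple[str, int, int], ISElement] = {}
    for e in seeds:
        elements[e.key] = e
    frontier = list(seeds)
    counts = []
    converged = False
    for it in range(1, max_iter + 1):
        new: list[ISElement] = []
        for e in frontier:
            qseq = elem_seq(e)
            if e.core is None:
                continue
            Lq = len(qseq)
            query = SeqRecord(f"{e.contig_id}:{e.start}-{e.end}", qseq)
            hits = seed_extend_align(query, index, k=k,
                                     min_score=int(0.3 * Lq))
            by_subj: dict[tuple[str, str], list[LocalHit]] = {}
            for h in hits:
                by_subj.setdefault((h.subject_id, h.strand), []).append(h)
            for (sid, strand), shits in by_subj.items():
                ends = [h for h in shits if h.identity >= end_identity]
                if (_q_coverage(ends, 0, end_len) < end_cov
                        or _q_coverage(ends, Lq - end_len, Lq) < end_cov):
                    continue
                anchor = max(shits, key=lambda h: h.score)
                contig = contigs[sid]
                if strand == "+":
                    s0 = anchor.s_start - anchor.q_start
                    s1 = anchor.s_end + (Lq - anchor.q_end)
                else:
                    s0 = anchor.s_start - (Lq - anchor.q_end)
                    s1 = anchor.s_end + anchor.q_start
                if s0 < 0 or s1 > len(contig.seq):
                    continue
                sub = contig.seq[s0:s1]
                if strand == "-":
                    sub = revcomp(sub)
                core = e.core
                # core concordance: one copy at the element start, the
                # junction copy immediately downstream
                if not sub.startswith(core):
                    continue
                down = (contig.seq[s1 : s1 + len(core)] if strand == "+"
                        else revcomp(contig.seq[s0 - len(core) : s0]))
                if down != core:
                    continue
                cand = ISElement(sid, s0, s1, strand, core=core,
                                 provenance="iterative", iteration=it)
                if cand.key in elements or _near_duplicate(cand, elements):
                    continue
                elements[cand.key] = cand
                new.append(cand)
        counts.append(dict(iteration=it, n_new=len(new),
                           n_total=len(elements)))
        if not new:
            converged = True
            break
        frontier = new
    return list(elements.values()), pd.DataFrame(counts), converged


def _near_duplicate(cand: ISElement,
                    elements: dict[tuple[str, int, int], ISElement],
                    slop: int = 5) -> bool:
    for key in elements:
        cid, s, e = key
        if (cid == cand.contig_id and abs(s - cand.start) <= slop
                and abs(e - cand.end) <= slop):
            return True
    return False
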