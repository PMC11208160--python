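"""Per-guide consensus target motifs from natural insertion-site
collections, and their concordance with the guide-encoded expectation.

Sites are grouped by the exact (left guide, right guide) pair of their
bridge RNA after three filters: no gaps within either guide, a CT core
guide, and more than 20 associated sites per group. The group consensus is
the modal nucleotide at each of the 11 site positions, with ties written as
N. Concordance counts positional mismatches between the consensus and the
site the guides encode (N matches anything).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .align import SubjectIndex, seed_extend_align
from .geometry import GeometryError, TargetGeometry
from .seqio import AlignmentBlock, SeqRecord

__all__ = [
    "GuideGroup",
    "greedy_identity_cluster",
    "consensus_motifs_per_guide",
    "guide_motif_concordance",
    "count_matrix",
]


@dataclass
class GuideGroup:
    ltg: str
    rtg: str
    member_sites: list[str]
    consensus: str = ""
    mismatches: int | None = None
    mismatch_positions: list[int] = field(default_factory=list)  # 1-based
    geometry_flagged: bool = False

    @property
    def n_members(self) -> int:
        return len(self.member_sites)


def greedy_identity_cluster(seqs: list[SeqRecord], min_id: float = 0.8,
                            min_cov: float = 0.8, k: int = 8
                            ) -> list[tuple[SeqRecord, list[SeqRecord]]]:
    """Greedy centroid clustering, longest-first (ties lexicographic by
    sequence then id): a sequence joins the first centroid reached at
    >= min_id identity over >= min_cov mutual coverage, else founds a new
    cluster. Deterministic for a given input set."""
    if not seqs:
        return []
    ordered = sorted(seqs, key=lambda r: (-len(r.seq), r.seq, r.id))
    clusters: list[tuple[SeqRecord, list[SeqRecord]]] = []
    for rec in ordered:
        placed = False
        for centroid, members in clusters:
            if _matches(rec, centroid, min_id, min_cov, k):
                members.append(rec)
                placed = True
                break
        if not placed:
            clusters.append((rec, [rec]))
    return clusters


def _matches(rec: SeqRecord, centroid: SeqRecord, min_id: float,
             min_cov: float, k: int) -> bool:
    if len(rec.seq) < k or len(centroid.seq) < k:
        # too short to anchor; fall back to direct comparison
        if len(rec.seq) != len(centroid.seq):
            return False
        ident = sum(a == b for a, b in zip(rec.seq, centroid.seq)) / len(rec.seq)
        return ident >= min_id
    hits = seed_extend_align(rec, SubjectIndex([centroid], k), k=k,
                             min_score=max(5, int(0.3 * len(rec.seq))))
    for h in hits:
        q_cov = (h.q_end - h.q_start) / len(rec.seq)
        s_cov = (h.s_end - h.s_start) / len(centroid.seq)
        if h.identity >= min_id and q_cov >= min_cov and s_cov >= min_cov:
            return True
    return False


def consensus_motifs_per_guide(sites: AlignmentBlock, bridges: AlignmentBlock,
                               geometry: TargetGeometry | None = None,
                               guide_columns: tuple[tuple[int, int],
                                                    tuple[int, int]] | None = None,
                               min_members: int = 21) -> list[GuideGroup]:
    """Group paired (site, bridge RNA) rows by exact (LTG, RTG) and build
    modal consensus motifs.

    ``guide_columns`` gives the (start, end) alignment columns of the LTG
    and RTG within the bridge block; by default the guides are read from a
    paired TSV-like layout where the bridge row is exactly LTG+RTG.
    Rows are kept only if both guides are gap-free, the guides encode the
    geometry's core (CT by default), and sites are gap-free; groups below
    ``min_members`` members (default: more than 20) are discarded.
    """
    geometry = geometry or TargetGeometry()
    if sites.ids != bridges.ids:
        raise ValueError("site and bridge alignments must share row ids")
    if guide_columns is None:
        guide_columns = ((0, geometry.ltg_len),
                         (geometry.ltg_len, geometry.ltg_len + geometry.rtg_len))
    (l0, l1), (r0, r1) = guide_columns
    groups: dict[tuple[str, str], list[str]] = {}
    for srow, brow in zip(sites.rows, bridges.rows):
        ltg = brow.seq[l0:l1]
        rtg = brow.seq[r0:r1]
        site = srow.seq
        if "-" in ltg or "-" in rtg or "-" in site:
            continue
        if len(site) != geometry.site_length:
            continue
        if not geometry.check_guides(ltg, rtg):
            continue
        groups.setdefault((ltg, rtg), []).append(site)

    out: list[GuideGroup] = []
    for (ltg, rtg), members in sorted(groups.items()):
        if len(members) < min_members:
            continue
        cons = []
        for pos in range(geometry.site_length):
            counts = Counter(m[pos] for m in members)
            top = max(counts.values())
            winners = [b for b, n in counts.items() if n == top]
            cons.append(winners[0] if len(winners) == 1 else "N")
        out.append(GuideGroup(ltg=ltg, rtg=rtg, member_sites=members,
                              consensus="".join(cons)))
    return out


def guide_motif_concordance(group: GuideGroup,
                            geometry: TargetGeometry | None = None
                            ) -> GuideGroup:
    """Count positional mismatches between the group consensus and the
    guide-encoded expected site (N is a wildcard); 1-based mismatch
    positions are recorded. Groups whose guides disagree on the core
    overlap are flagged instead of scored."""
    geometry = geometry or TargetGeometry()
    try:
        expected = geometry.site_from_guides(group.ltg, group.rtg)
    except GeometryError:
        group.geometry_flagged = True
        return group
    mm = [i + 1 for i, (c, e) in enumerate(zip(group.consensus, expected))
          if c != "N" and e != "N" and c != e]
    group.mismatches = len(mm)
    group.mismatch_positions = mm
    return group


def count_matrix(group: GuideGroup) -> pd.DataFrame:
    """Position x nucleotide counts over group members (input for logo
    tools)."""
    n = len(group.consensus)
    mat = {b: [0] * n for b in "ACGT"}
    for m in group.member_sites:
        for i, b in enumerate(m):
            if b in mat:
                mat[b][i] += 1
    return pd.DataFrame(mat, index=[f"pos{i+1}" for i in range(n)])
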