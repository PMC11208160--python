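"""Donor-plasmid insertion-site calling from long reads.

Reads are scanned for the terminal 20-mers of the inserted donor (the 20 nt
immediately inside each recombination junction, excluding the 2-nt core),
allowing up to two mismatches; each hit splits the read into a donor-side
and a genome-side flank. Flanks are aligned to the genome and the plasmid
set and assigned to whichever scores strictly higher; genome-assigned flanks
yield the junction-adjacent coordinate, reported as the start of the
11-nt target site on the top strand. Junction coordinates within 5 bp merge
into one site (representative = modal coordinate, ties leftmost). Two
exclusion rules flag likely artifacts: (1) frequency < 1% AND Levenshtein
distance > 2 from both the 11-nt target and donor AND > 25% clipped
supporting reads; (2) frequency < 1% AND distance > 2 AND the same
coordinate present in a different sample at > 1% frequency with distance
< 3 there (index hopping). Off-target sites are binned by edit distance and
screened for shared k-mers against a per-sequence shuffle null.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np

from .align import SubjectIndex, encode, seed_extend_align
from .geometry import TargetGeometry
from .seqio import BedInterval, SeqRecord, revcomp

__all__ = [
    "JunctionRead",
    "InsertionSite",
    "REP_QUERIES",
    "donor_termini",
    "scan_donor_junctions",
    "assign_flank_origin",
    "merge_and_call_sites",
    "apply_site_filters",
    "classify_site",
    "levenshtein",
    "kmer_match_null",
    "annotate_rep_overlap",
    "downsample_reads",
    "sites_to_bed",
]

# Three known REP consensus sequences used to annotate the natural
# insertion target class of IS621 in E. coli.
REP_QUERIES = (
    "TGCCGGATGCGGCGTAAACGCCTTATCCGGCCTAC",
    "GCCTGATGCGCTACGCTTATCAGGCCTACG",
    "GCCTGATGCGACGCTGGCGCGTCTTATCAGGCCTACG",
)


@dataclass
class JunctionRead:
    read_id: str
    split_pos: int                      # terminus start on the (oriented) read
    donor_side: str                     # '5prime' (left junction) | '3prime'
    match_mismatches: int
    flank_genome_side: str              # sequence of the putative genome flank
    flank_donor_side: str
    orientation: str = "."              # genome strand of the insertion
    flank_left_origin: str = "unassigned"
    flank_right_origin: str = "unassigned"
    genome_contig: str | None = None
    genome_coord: int | None = None     # start of the 11-nt site, top strand
    clipped_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.match_mismatches > 2:
            raise ValueError("terminus match allows at most 2 mismatches")


@dataclass
class InsertionSite:
    contig: str
    coord: int
    strand: str
    read_count: int
    freq: float
    site_seq_11: str
    site_seq_14: str
    lev_target: int | None = None
    lev_donor: int | None = None
    category: str | None = None
    distance_bin: int | None = None
    core_is_CT: bool = False
    rep_overlap: bool = False
    clipped_fraction: float = 0.0       # fraction of clipped supporting reads
    filter_flags: set = field(default_factory=set)
    excluded: bool = False


def donor_termini(donor: SeqRecord, core_start: int,
                  core_len: int = 2, length: int = 20) -> tuple[str, str]:
    """(left, right) terminal ``length``-mers of the inserted donor,
    excluding the core: the donor opens at its core on insertion, so its 5'
    terminus is the 20 nt just 3' of the core and its 3' terminus the 20 nt
    just 5' of it."""
    p = donor.seq
    if len(p) < 2 * length + core_len:
        raise ValueError("donor too short for two terminal 20-mers")
    right = (p * 2)[core_start + core_len : core_start + core_len + length]
    left = (p * 2)[len(p) + core_start - length : len(p) + core_start]
    return left, right


def _hamming_hits(read_codes: np.ndarray, pattern: np.ndarray,
                  max_mm: int) -> list[tuple[int, int]]:
    L = len(pattern)
    if len(read_codes) < L:
        return []
    win = np.lib.stride_tricks.sliding_window_view(read_codes, L)
    mm = (win != pattern).sum(axis=1)
    return [(int(i), int(mm[i])) for i in np.nonzero(mm <= max_mm)[0]]


def scan_donor_junctions(reads: list[SeqRecord], donor: SeqRecord,
                         core_start: int, max_mm: int = 2,
                         terminus_len: int = 20) -> list[JunctionRead]:
    """Scan both strands of every read for the two donor termini (up to
    ``max_mm`` mismatches) and split at each hit. Reads without hits pass
    through unsplit (they produce no junction)."""
    left20, right20 = donor_termini(donor, core_start, length=terminus_len)
    pat = {"L": encode(left20), "R": encode(right20)}
    out: list[JunctionRead] = []
    for read in reads:
        seen: set[tuple[str, int]] = set()
        for oriented in (read.seq, revcomp(read.seq)):
            codes = encode(oriented)
            for which in ("R", "L"):
                for pos, mm in _hamming_hits(codes, pat[which], max_mm):
                    key = (oriented[max(0, pos - 5) : pos + terminus_len + 5], mm)
                    if key in seen:      # same junction seen on both strands
                        continue
                    seen.add(key)
                    before = oriented[:pos]
                    after = oriented[pos + terminus_len :]
                    if which == "R":    # left junction: genome | core | R20
                        out.append(JunctionRead(
                            read.id, pos, "5prime", mm,
                            flank_genome_side=before, flank_donor_side=after))
                    else:               # right junction: L20 | core | genome
                        out.append(JunctionRead(
                            read.id, pos, "3prime", mm,
                            flank_genome_side=after, flank_donor_side=before))
    return out


def assign_flank_origin(junctions: list[JunctionRead],
                        genome: list[SeqRecord],
                        plasmids: list[SeqRecord],
                        geometry: TargetGeometry | None = None,
                        k: int = 13, band: int = 16,
                        min_score: int = 25) -> list[JunctionRead]:
    """Assign each flank to genome or plasmid by best alignment score
    (strict inequality; ties and no-hits stay unassigned) and derive the
    junction-adjacent genome coordinate from the genome-side flank."""
    if not genome or not plasmids:
        raise ValueError("genome and plasmid references must be non-empty")
    geometry = geometry or TargetGeometry()
    gidx = SubjectIndex(genome, k)
    pidx = SubjectIndex(plasmids, k)
    glen = {r.id: len(r.seq) for r in genome}
    core_len = len(geometry.core)
    cs = geometry.core_start
    tail = geometry.site_length - geometry.core_start - core_len  # site right of core

    def best(flank: str, idx: SubjectIndex):
        if len(flank) < k:
            return None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hits = seed_extend_align(SeqRecord("f", flank), idx, k=k,
                                     min_score=min_score, band=band)
        return hits[0] if hits else None

    for j in junctions:
        gf = j.flank_genome_side
        df = j.flank_donor_side
        gh = best(gf, gidx)
        gp = best(gf, pidx)
        dh = best(df, gidx)
        dp = best(df, pidx)

        def origin(hg, hp):
            if hg is None and hp is None:
                return "unassigned"
            if hp is None or (hg is not None and hg.score > hp.score):
                return "genome"
            if hg is None or hp.score > hg.score:
                return "plasmid"
            return "unassigned"     # exact tie: conservative

        o_genome_side = origin(gh, gp)
        o_donor_side = origin(dh, dp)
        if j.donor_side == "5prime":
            j.flank_left_origin, j.flank_right_origin = o_genome_side, o_donor_side
        else:
            j.flank_left_origin, j.flank_right_origin = o_donor_side, o_genome_side

        if o_genome_side != "genome" or gh is None:
            continue
        L = len(gf)
        j.clipped_fraction = 1.0 - (gh.q_end - gh.q_start) / L
        j.genome_contig = gh.subject_id
        if j.donor_side == "5prime":
            # genome flank precedes the donor; its junction end carries the core
            if gh.strand == "+":
                core_end = gh.s_end + (L - gh.q_end)
                j.genome_coord = core_end - core_len - cs
                j.orientation = "+"
            else:
                boundary = gh.s_start - (L - gh.q_end)
                j.genome_coord = boundary - (geometry.site_length - cs - core_len)
                j.orientation = "-"
        else:
            # genome flank follows the donor; starts with the core
            if gh.strand == "+":
                core_begin = gh.s_start - gh.q_start
                j.genome_coord = core_begin - cs
                j.orientation = "+"
            else:
                boundary = gh.s_end + gh.q_start
                j.genome_coord = boundary + cs - geometry.site_length
                j.orientation = "-"
        if j.genome_coord is not None:
            gl = glen[j.genome_contig]
            if not 0 <= j.genome_coord <= gl - geometry.site_length:
                j.genome_coord = None
                j.genome_contig = None
    return junctions


def merge_and_call_sites(junctions: list[JunctionRead],
                         genome: list[SeqRecord],
                         merge_dist: int = 5,
                         geometry: TargetGeometry | None = None,
                         clip_read_thresh: float = 0.2
                         ) -> list[InsertionSite]:
    """Single-linkage merge of junction coordinates within ``merge_dist``
    per contig; one read contributes once per distinct (read, coordinate)."""
    geometry = geometry or TargetGeometry()
    gdict = {r.id: r.seq for r in genome}
    assigned: dict[tuple[str, int], list[JunctionRead]] = {}
    seen: set[tuple[str, str, int]] = set()
    for j in junctions:
        if j.genome_coord is None or j.genome_contig is None:
            continue
        key = (j.read_id, j.genome_contig, j.genome_coord)
        if key in seen:
            continue
        seen.add(key)
        assigned.setdefault((j.genome_contig, j.genome_coord), []).append(j)

    total = sum(len(v) for v in assigned.values())
    sites: list[InsertionSite] = []
    by_contig: dict[str, list[int]] = {}
    for (contig, coord) in assigned:
        by_contig.setdefault(contig, []).append(coord)
    for contig, coords in by_contig.items():
        coords = sorted(set(coords))
        cluster: list[int] = []
        clusters: list[list[int]] = []
        for c in coords:
            if cluster and c - cluster[-1] > merge_dist:
                clusters.append(cluster)
                cluster = []
            cluster.append(c)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            support = [j for c in cl for j in assigned[(contig, c)]]
            counts = Counter(j.genome_coord for j in support)
            top = max(counts.values())
            rep = min(c for c, n in counts.items() if n == top)
            gseq = gdict[contig]
            if rep + 14 > len(gseq):
                raise ValueError(f"site coordinate {rep} outside reference")
            seq11 = gseq[rep : rep + geometry.site_length]
            seq14 = gseq[rep : rep + 14]
            strand = Counter(j.orientation for j in support).most_common(1)[0][0]
            clipped = np.mean([j.clipped_fraction > clip_read_thresh
                               for j in support]) if support else 0.0
            sites.append(InsertionSite(
                contig=contig, coord=rep, strand=strand,
                read_count=len(support), freq=len(support) / total,
                site_seq_11=seq11, site_seq_14=seq14,
                core_is_CT=geometry.core_of(seq11) == "CT",
                clipped_fraction=float(clipped)))
    sites.sort(key=lambda s: -s.read_count)
    return sites


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def classify_site(site: InsertionSite, target_11: str, donor_11: str,
                  target_14: str | None = None, donor_14: str | None = None
                  ) -> InsertionSite:
    """Edit-distance bins against the intended target and the donor, and the
    site category used in specificity summaries."""
    site.lev_target = levenshtein(site.site_seq_11, target_11)
    site.lev_donor = levenshtein(site.site_seq_11, donor_11)
    site.distance_bin = min(site.lev_target, site.lev_donor)
    site.core_is_CT = site.site_seq_11[7:9] == "CT"
    if site.lev_target == 0:
        site.category = "on_target"
    elif site.lev_target < 3:
        site.category = "target_like"
    elif site.lev_donor < 3:
        site.category = "donor_like"
    else:
        site.category = "other"
    return site


def apply_site_filters(sites: list[InsertionSite],
                       per_sample_tables: dict[str, list[InsertionSite]]
                       | None = None,
                       clip_thresh: float = 0.25,
                       freq_thresh: float = 0.01,
                       lev_thresh: int = 2) -> list[InsertionSite]:
    """Flag (never drop) sites matching either exclusion rule; requires
    classify_site to have run. ``per_sample_tables`` maps other sample names
    to their classified site lists for the cross-sample rule."""
    for s in sites:
        if s.lev_target is None or s.lev_donor is None:
            raise ValueError("classify_site must run before filtering")
        far = s.lev_target > lev_thresh and s.lev_donor > lev_thresh
        if s.freq < freq_thresh and far and s.clipped_fraction > clip_thresh:
            s.filter_flags.add("low_quality")
        if per_sample_tables and s.freq < freq_thresh and far:
            for sample, others in per_sample_tables.items():
                for o in others:
                    if (o.contig == s.contig and o.coord == s.coord
                            and o.freq > freq_thresh
                            and o.lev_target is not None
                            and min(o.lev_target, o.lev_donor) < 3):
                        s.filter_flags.add(f"cross_sample:{sample}")
        s.excluded = bool(s.filter_flags)
    return sites


def _max_shared_kmer(seq: str, refs: tuple[str, ...]) -> int:
    ref_kmers = [set() for _ in range(len(seq) + 1)]
    for k in range(1, len(seq) + 1):
        for ref in refs:
            for i in range(len(ref) - k + 1):
                ref_kmers[k].add(ref[i : i + k])
    best = 0
    for k in range(len(seq), 0, -1):
        if any(seq[i : i + k] in ref_kmers[k] for i in range(len(seq) - k + 1)):
            best = k
            break
    return best


def kmer_match_null(offtargets_14: list[str], target_14: str, donor_14: str,
                    n_shuffle: int = 1000, seed: int = 0):
    """Observed max-shared-k-mer lengths of off-target 14-mers vs target and
    donor, against a null from per-sequence character shuffles.

    Returns (observed list, null means array, empirical p = fraction of
    shuffle means >= the observed mean)."""
    if n_shuffle < 100:
        warnings.warn("n_shuffle < 100 gives a coarse empirical p-value")
    for s in offtargets_14 + [target_14, donor_14]:
        if len(s) != 14:
            raise ValueError("all sequences must be 14 nt")
    refs = (target_14, donor_14)
    observed = [_max_shared_kmer(s, refs) for s in offtargets_14]
    obs_mean = float(np.mean(observed))
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_shuffle)
    arrs = [list(s) for s in offtargets_14]
    for it in range(n_shuffle):
        vals = []
        for a in arrs:
            rng.shuffle(a)
            vals.append(_max_shared_kmer("".join(a), refs))
        null_means[it] = np.mean(vals)
    p = float((null_means >= obs_mean).mean())
    return observed, null_means, p


def annotate_rep_overlap(sites: list[InsertionSite], genome: list[SeqRecord],
                         rep_queries: tuple[str, ...] = REP_QUERIES,
                         min_identity: float = 0.8, min_cov: float = 0.9,
                         pad: int = 5) -> list[InsertionSite]:
    """REP intervals = merged hits of the query sequences at >=80% identity
    over >=90% query coverage (both strands); a site overlaps when its
    coordinate falls within an interval +-5 nt."""
    idx = SubjectIndex(genome, k=8)
    intervals: dict[str, list[tuple[int, int]]] = {}
    for q in rep_queries:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hits = seed_extend_align(SeqRecord("rep", q), idx, k=8,
                                     min_score=int(len(q) * 0.5))
        for h in hits:
            if (h.identity >= min_identity
                    and (h.q_end - h.q_start) >= min_cov * len(q)):
                intervals.setdefault(h.subject_id, []).append((h.s_start, h.s_end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for contig, ivals in intervals.items():
        ivals.sort()
        out = [list(ivals[0])]
        for a, b in ivals[1:]:
            if a <= out[-1][1]:
                out[-1][1] = max(out[-1][1], b)
            else:
                out.append([a, b])
        merged[contig] = [(a, b) for a, b in out]
    for s in sites:
        s.rep_overlap = any(a - pad <= s.coord < b + pad
                            for a, b in merged.get(s.contig, []))
    return sites


def downsample_reads(reads: list[SeqRecord], target_depth: float,
                     genome_size: int, seed: int = 0) -> list[SeqRecord]:
    """Uniform random subset of reads achieving ``target_depth`` x coverage
    of ``genome_size``; if the target exceeds the available depth, all reads
    are returned with a warning."""
    total = sum(len(r.seq) for r in reads)
    want = target_depth * genome_size
    if want >= total:
        if want > total:
            warnings.warn("requested depth exceeds available; keeping all reads")
        return list(reads)
    n_keep = round(want / total * len(reads))
    rng = np.random.default_rng(seed)
    keep = sorted(rng.choice(len(reads), n_keep, replace=False).tolist())
    return [reads[i] for i in keep]


def sites_to_bed(sites: list[InsertionSite],
                 geometry: TargetGeometry | None = None) -> list[BedInterval]:
    geometry = geometry or TargetGeometry()
    return [BedInterval(s.contig, s.coord, s.coord + geometry.site_length,
                        f"site_{s.contig}_{s.coord}", s.read_count,
                        s.strand if s.strand in "+-" else ".")
            for s in sites]
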