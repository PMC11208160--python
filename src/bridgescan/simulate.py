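"""Synthetic data with planted ground truth for every pipeline stage.

Four generators emulate the statistical structure the analyses assume:

* orthologue families of bridge RNAs paired with 50-nt target/donor windows,
  with guide/partner co-mutation at a controlled coupling probability;
* a toy genome + donor plasmid + nanopore-like junction reads with planted
  insertion sites at known relative frequencies;
* pooled-screen count tables (control and recombinant, two replicates each)
  whose recombination efficiencies follow planted per-position mismatch
  penalties;
* post-/pre-insertion contig collections with planted element boundaries
  and cores, plus decoys, for the boundary search.

One global seed fans out into independent per-stage streams by stable
hashing of the stage name, so stages are reproducible and independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import TargetGeometry
from .seqio import AlignmentBlock, BedInterval, SeqRecord, revcomp

__all__ = [
    "stream",
    "FamilyTruth",
    "InsertionTruth",
    "ScreenTruth",
    "gen_orthologue_family",
    "gen_toy_genome_and_reads",
    "gen_screen_dataset",
    "gen_boundary_testset",
]

_BASES = "ACGT"


def stream(seed: int, name: str) -> np.random.Generator:
    """Independent, named random stream derived from one global seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[b] for b in rng.integers(0, 4, n))


def _codes(seq: str) -> np.ndarray:
    lut = np.full(128, 0, dtype=np.int8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), np.uint8)].astype(np.int64)


def _to_seq(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


# ---------------------------------------------------------------------------
# orthologue families


@dataclass
class FamilyTruth:
    """Planted geometry and evolution parameters of one orthologue family.

    ``coupling`` is the probability that a substitution at a guide position
    co-substitutes its DNA partner so the pairing survives; otherwise guide
    and partner mutate independently at ``sub_rate`` per position.
    """

    ltg: str
    rtg: str
    ldg: str
    rdg: str
    target_window: str
    donor_window: str
    coupling: float
    sub_rate: float
    n_orthologues: int
    seed: int
    geometry: TargetGeometry = field(default_factory=TargetGeometry)
    rna_length: int = 70
    # 0-based RNA starts of the four guide segments
    ltg_start: int = 5
    rtg_start: int = 20
    ldg_start: int = 34
    rdg_start: int = 50
    site_start: int = 17  # site start inside each 50-nt window

    def __post_init__(self) -> None:
        if not (0.0 <= self.coupling <= 1.0 and 0.0 <= self.sub_rate <= 1.0):
            raise ValueError("coupling and sub_rate must be in [0,1]")
        if self.n_orthologues < 10:
            raise ValueError("need n_orthologues >= 10")

    @classmethod
    def random(cls, seed: int, n_orthologues: int = 500, coupling: float = 0.9,
               sub_rate: float = 0.2,
               geometry: TargetGeometry | None = None) -> "FamilyTruth":
        geometry = geometry or TargetGeometry()
        rng = stream(seed, "family-truth")
        site_start = 17

        def window() -> str:
            w = list(_random_seq(rng, 50))
            cs = site_start + geometry.core_start
            w[cs : cs + len(geometry.core)] = geometry.core
            return "".join(w)

        tw, dw = window(), window()
        t_site = tw[site_start : site_start + geometry.site_length]
        d_site = dw[site_start : site_start + geometry.site_length]
        ltg, rtg = geometry.guides_from_site(t_site)
        ldg, rdg = geometry.guides_from_site(d_site)
        return cls(ltg=ltg, rtg=rtg, ldg=ldg, rdg=rdg, target_window=tw,
                   donor_window=dw, coupling=coupling, sub_rate=sub_rate,
                   n_orthologues=n_orthologues, seed=seed, geometry=geometry)

    def ancestral_rna(self, rng: np.random.Generator) -> str:
        rna = list(_random_seq(rng, self.rna_length))
        for start, guide in ((self.ltg_start, self.ltg),
                             (self.rtg_start, self.rtg),
                             (self.ldg_start, self.ldg),
                             (self.rdg_start, self.rdg)):
            rna[start : start + len(guide)] = guide
        return "".join(rna)

    def pairing_units(self, partner: str):
        """Co-mutation units for one partner ('target' or 'donor'): a list of
        (dna_pos, [(rna_pos, relation), ...]) where relation is 'eq' (guide
        equals top strand; bottom-strand pairing) or 'comp' (guide
        complements top strand; top-strand pairing). The 2-nt core positions
        carry two RNA partners (left-guide end and right-guide end)."""
        g = self.geometry
        if partner == "target":
            lstart, rstart = self.ltg_start, self.rtg_start
        elif partner == "donor":
            lstart, rstart = self.ldg_start, self.rdg_start
        else:
            raise ValueError(partner)
        units: dict[int, list[tuple[int, str]]] = {}
        for m in range(g.ltg_len):
            units.setdefault(self.site_start + m, []).append((lstart + m, "eq"))
        rt0 = self.site_start + g.core_start
        for m in range(g.rtg_len):
            dna = rt0 + g.rtg_len - 1 - m
            units.setdefault(dna, []).append((rstart + m, "comp"))
        return sorted(units.items())

    def planted_segments(self):
        """The four guide segments as (partner, rna interval, dna interval,
        strand) ground truth for detector scoring."""
        g = self.geometry
        rt0 = self.site_start + g.core_start
        out = []
        for partner, lstart, rstart in (("target", self.ltg_start, self.rtg_start),
                                        ("donor", self.ldg_start, self.rdg_start)):
            out.append((partner, (lstart, lstart + g.ltg_len),
                        (self.site_start, self.site_start + g.ltg_len), "bottom"))
            out.append((partner, (rstart, rstart + g.rtg_len),
                        (rt0, rt0 + g.rtg_len), "top"))
        return out


def gen_orthologue_family(truth: FamilyTruth):
    """Evolve ``n_orthologues`` rows from the planted ancestor.

    Returns (bridge block, target block, donor block) with shared row ids.
    Guide positions co-mutate with their DNA partners with probability
    ``coupling`` per unit (one joint substitution event at ``sub_rate``),
    otherwise every member of the unit mutates independently; all non-guide
    positions mutate independently at ``sub_rate``.
    """
    rng = stream(truth.seed, "family-rows")
    n = truth.n_orthologues
    anc_rna = _codes(truth.ancestral_rna(stream(truth.seed, "family-ancestor")))
    anc = {"target": _codes(truth.target_window), "donor": _codes(truth.donor_window)}

    rna = np.tile(anc_rna, (n, 1))
    windows = {p: np.tile(anc[p], (n, 1)) for p in ("target", "donor")}

    paired_rna: set[int] = set()
    units = {p: truth.pairing_units(p) for p in ("target", "donor")}
    for p in units:
        for _dna, partners in units[p]:
            paired_rna.update(i for i, _ in partners)
    paired_dna = {p: {d for d, _ in units[p]} for p in units}

    def mutate_free(mat: np.ndarray, cols) -> None:
        for c in cols:
            hit = rng.random(n) < truth.sub_rate
            shift = rng.integers(1, 4, n)
            mat[hit, c] = (mat[hit, c] + shift[hit]) % 4

    mutate_free(rna, [i for i in range(truth.rna_length) if i not in paired_rna])
    for p in ("target", "donor"):
        mutate_free(windows[p], [j for j in range(50) if j not in paired_dna[p]])

    for p in ("target", "donor"):
        win = windows[p]
        for dna_j, partners in units[p]:
            coupled = rng.random(n) < truth.coupling
            event = rng.random(n) < truth.sub_rate
            shift = rng.integers(1, 4, n)
            # coupled units: one joint substitution keeps the pairing intact
            joint = coupled & event
            new_dna = (win[joint, dna_j] + shift[joint]) % 4
            win[joint, dna_j] = new_dna
            for rna_i, rel in partners:
                rna[joint, rna_i] = new_dna if rel == "eq" else 3 - new_dna
            # uncoupled: every member drifts independently
            free = ~coupled
            idx = np.nonzero(free)[0]
            hit = rng.random(idx.size) < truth.sub_rate
            sh = rng.integers(1, 4, idx.size)
            win[idx[hit], dna_j] = (win[idx[hit], dna_j] + sh[hit]) % 4
            for rna_i, _rel in partners:
                hit = rng.random(idx.size) < truth.sub_rate
                sh = rng.integers(1, 4, idx.size)
                rna[idx[hit], rna_i] = (rna[idx[hit], rna_i] + sh[hit]) % 4

    ids = [f"orth{k:05d}" for k in range(n)]
    bridge = AlignmentBlock([SeqRecord(i, _to_seq(rna[k])) for k, i in enumerate(ids)])
    target = AlignmentBlock(
        [SeqRecord(i, _to_seq(windows["target"][k])) for k, i in enumerate(ids)])
    donor = AlignmentBlock(
        [SeqRecord(i, _to_seq(windows["donor"][k])) for k, i in enumerate(ids)])
    return bridge, target, donor


# ---------------------------------------------------------------------------
# toy genome + junction reads


@dataclass
class InsertionTruth:
    """Planted insertion experiment: genome, donor plasmid, sites.

    ``sites`` holds (genome coordinate of the 11-nt site start, relative
    frequency, planted site sequence). ``depth`` is the number of
    junction-spanning reads to draw; a further ``n_background`` reads carry
    genome sequence only. Error rates default to nanopore-like
    3% substitution / 2% insertion / 2% deletion.
    """

    genome: SeqRecord
    donor_plasmid: SeqRecord
    sites: list[tuple[int, float, str]]
    donor_core_start: int             # core start inside the plasmid
    error_rates: tuple[float, float, float] = (0.03, 0.02, 0.02)
    read_flank_range: tuple[int, int] = (150, 400)
    depth: int = 500
    n_background: int = 50
    seed: int = 0
    geometry: TargetGeometry = field(default_factory=TargetGeometry)

    def __post_init__(self) -> None:
        if self.sites:
            total = sum(f for _, f, _ in self.sites)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("site frequencies must sum to 1")
            coords = sorted(c for c, _, _ in self.sites)
            for a, b in zip(coords, coords[1:]):
                if b - a < self.geometry.site_length:
                    raise ValueError("planted sites overlap")
        if self.depth < 20:
            raise ValueError("depth must be >= 20 junction reads")

    @classmethod
    def random(cls, seed: int, genome_size: int = 100_000,
               plasmid_size: int = 3_000,
               site_freqs: tuple[float, ...] = (0.8, 0.2),
               depth: int = 500,
               error_rates: tuple[float, float, float] = (0.03, 0.02, 0.02),
               geometry: TargetGeometry | None = None) -> "InsertionTruth":
        geometry = geometry or TargetGeometry()
        rng = stream(seed, "insertion-truth")
        genome = list(_random_seq(rng, genome_size))
        margin = 2_000
        coords = sorted(
            rng.choice(
                np.arange(margin, genome_size - margin), len(site_freqs),
                replace=False).tolist())
        # intended target planted at the first (highest-frequency) site; the
        # others are 1-mismatch neighbours of it (off-target-like)
        intended = list(_random_seq(rng, geometry.site_length))
        cs = geometry.core_start
        intended[cs : cs + len(geometry.core)] = geometry.core
        intended = "".join(intended)
        sites = []
        order = np.argsort(site_freqs)[::-1]
        for rank, si in enumerate(order):
            seq = intended
            if rank > 0:
                pos = int(rng.integers(0, cs))  # mutate outside the core
                b = _BASES[(_codes(seq)[pos] + int(rng.integers(1, 4))) % 4]
                seq = seq[:pos] + b + seq[pos + 1 :]
            c = coords[si]
            genome[c : c + geometry.site_length] = seq
            sites.append((c, float(site_freqs[si]), seq))
        plasmid = list(_random_seq(rng, plasmid_size))
        dstart = plasmid_size // 2
        donor_site = list(_random_seq(rng, geometry.site_length))
        donor_site[cs : cs + len(geometry.core)] = geometry.core
        plasmid[dstart : dstart + geometry.site_length] = donor_site
        return cls(
            genome=SeqRecord("genome", "".join(genome)),
            donor_plasmid=SeqRecord("plasmid", "".join(plasmid)),
            sites=sorted(sites), donor_core_start=dstart + cs,
            error_rates=error_rates, depth=depth, seed=seed, geometry=geometry)

    @property
    def intended_target(self) -> str:
        if not self.sites:
            raise ValueError("no planted sites")
        return max(self.sites, key=lambda s: s[1])[2]

    @property
    def donor_site(self) -> str:
        g = self.geometry
        p = self.donor_plasmid.seq
        start = self.donor_core_start - g.core_start
        return p[start : start + g.site_length]


def _apply_errors(seq: str, rates, rng: np.random.Generator) -> str:
    ps, pi, pd = rates
    if ps == pi == pd == 0:
        return seq
    out = []
    for ch in seq:
        r = rng.random()
        if r < pd:
            continue
        if r < pd + ps:
            ch = _BASES[(_codes(ch)[0] + int(rng.integers(1, 4))) % 4]
        out.append(ch)
        if rng.random() < pi:
            out.append(_BASES[int(rng.integers(0, 4))])
    return "".join(out)


def gen_toy_genome_and_reads(truth: InsertionTruth):
    """Draw junction-spanning reads around the planted insertion loci.

    Returns (genome record, plasmid record, reads, truth BED intervals).
    Each junction read carries a donor terminus adjacent to the genome flank
    in the correct orientation; the truth BED records the planted 11-nt
    sites and their frequencies.
    """
    rng = stream(truth.seed, "insertion-reads")
    g = truth.genome.seq
    p = truth.donor_plasmid.seq
    dc = truth.donor_core_start
    core_len = len(truth.geometry.core)
    p_rot = p[dc + core_len :] + p[:dc]  # inserted plasmid, opened at the core
    reads: list[SeqRecord] = []
    lo, hi = truth.read_flank_range

    freqs = [f for _, f, _ in truth.sites]
    for ri in range(truth.depth if truth.sites else 0):
        si = int(rng.choice(len(truth.sites), p=freqs))
        coord, _, _ = truth.sites[si]
        K = coord + truth.geometry.core_start     # genome core start
        locus = g[: K + core_len] + p_rot + g[K:]
        left_j = K + core_len                     # start of donor in locus
        right_j = left_j + len(p_rot)             # back to genome
        side = "L" if rng.random() < 0.5 else "R"
        glen = int(rng.integers(lo, hi + 1))
        dlen = int(rng.integers(lo, hi + 1))
        if side == "L":
            raw = locus[max(0, left_j - glen) : left_j + dlen]
        else:
            raw = locus[right_j - dlen : right_j + glen]
        read = _apply_errors(raw, truth.error_rates, rng)
        if rng.random() < 0.5:
            read = revcomp(read)
        reads.append(SeqRecord(f"jread{ri:05d}", read))

    for bi in range(truth.n_background):
        glen = int(rng.integers(2 * lo, 2 * hi))
        start = int(rng.integers(0, len(g) - glen))
        read = _apply_errors(g[start : start + glen], truth.error_rates, rng)
        if rng.random() < 0.5:
            read = revcomp(read)
        reads.append(SeqRecord(f"bread{bi:05d}", read))

    bed = [BedInterval(truth.genome.id, c, c + truth.geometry.site_length,
                       f"site{i}", round(f * 1000), "+")
           for i, (c, f, _) in enumerate(truth.sites)]
    return truth.genome, truth.donor_plasmid, reads, bed


# ---------------------------------------------------------------------------
# pooled screens


@dataclass
class ScreenTruth:
    """Planted specificity screen: design plus an efficiency law.

    Efficiency of a (guide-encoded site, site) pair is a per-set scale times
    the product of planted per-position mismatch penalties over mismatched
    programmable positions, times optional nucleotide-preference multipliers;
    guide-core mismatches multiply by ``core_penalty``.
    """

    design: pd.DataFrame        # key, guide, site, category, set_id, efficiency
    penalties: dict[int, float]
    core_penalty: float
    control_sigma: float
    depth: int
    seed: int
    geometry: TargetGeometry = field(default_factory=TargetGeometry)

    def __post_init__(self) -> None:
        if self.design.empty:
            raise ValueError("design must be non-empty")
        if self.design["key"].duplicated().any():
            raise ValueError("duplicate keys in design")

    @classmethod
    def random(cls, seed: int, n_targets: int = 18, n_matched: int = 300,
               n_negative: int = 40, n_core_targets: int = 3,
               depth: int = 1_000_000, control_sigma: float = 0.5,
               core_penalty: float = 0.02,
               nt_preference: dict[tuple[int, str], float] | None = None,
               geometry: TargetGeometry | None = None) -> "ScreenTruth":
        geometry = geometry or TargetGeometry()
        rng = stream(seed, "screen-truth")
        cs, cl = geometry.core_start, len(geometry.core)
        slen = geometry.site_length
        prog = [i for i in range(slen) if not cs <= i < cs + cl]
        penalties = {p: float(np.exp(rng.uniform(np.log(0.03), np.log(0.5))))
                     for p in prog}
        nt_preference = dict(nt_preference or {})

        def rand_site() -> str:
            s = list(_random_seq(rng, slen))
            s[cs : cs + cl] = geometry.core
            return "".join(s)

        rows = []

        def eff_of(guide: str, site: str, scale: float) -> float:
            e = scale
            for pidx in prog:
                if guide[pidx] != site[pidx]:
                    e *= penalties[pidx]
                mult = nt_preference.get((pidx, site[pidx]))
                if mult:
                    e *= mult
            if guide[cs : cs + cl] != geometry.core:
                e *= core_penalty
            return e

        set_no = 0
        for _t in range(n_targets):
            base = rand_site()
            for pidx in prog:
                scale = float(np.exp(rng.normal(0.0, 0.5)))
                set_id = f"set{set_no:04d}"
                set_no += 1
                for gb in _BASES:
                    for tb in _BASES:
                        guide = base[:pidx] + gb + base[pidx + 1 :]
                        site = base[:pidx] + tb + base[pidx + 1 :]
                        rows.append(dict(
                            guide=guide, site=site, category="single_mm_4x4",
                            set_id=set_id, position=pidx,
                            efficiency=eff_of(guide, site, scale)))
        for m in range(n_matched):
            site = rand_site()
            scale = float(np.exp(rng.normal(0.0, 0.5)))
            rows.append(dict(guide=site, site=site, category="wt",
                             set_id=f"wt{m:04d}", position=-1,
                             efficiency=eff_of(site, site, scale)))
        for m in range(n_negative):
            site = rand_site()
            guide = "".join(
                _BASES[(_codes(c)[0] + int(rng.integers(1, 4))) % 4]
                if i in prog else c for i, c in enumerate(site))
            rows.append(dict(guide=guide, site=site, category="negative_ctrl",
                             set_id=f"neg{m:04d}", position=-1,
                             efficiency=eff_of(guide, site, 1.0)))
        for t in range(n_core_targets):
            site = rand_site()
            for ca in _BASES:
                for cb in _BASES:
                    guide = site[:cs] + ca + cb + site[cs + cl :]
                    rows.append(dict(
                        guide=guide, site=site, category="core_mm",
                        set_id=f"core{t:02d}", position=-1,
                        efficiency=eff_of(guide, site, 1.0)))

        design = pd.DataFrame(rows)
        design.insert(0, "key", _make_barcodes(len(design), 12, 3, rng))
        return cls(design=design, penalties=penalties,
                   core_penalty=core_penalty, control_sigma=control_sigma,
                   depth=depth, seed=seed, geometry=geometry)


def _make_barcodes(n: int, length: int, min_dist: int,
                   rng: np.random.Generator) -> list[str]:
    """Random barcodes with pairwise Hamming distance >= min_dist."""
    accepted = np.empty((0, length), dtype=np.int8)
    out: list[str] = []
    while len(out) < n:
        cand = rng.integers(0, 4, length).astype(np.int8)
        if accepted.size and int((accepted != cand).sum(axis=1).min()) < min_dist:
            continue
        accepted = np.vstack([accepted, cand])
        out.append(_to_seq(cand.astype(np.int64)))
    return out


def gen_screen_dataset(truth: ScreenTruth):
    """Control counts (overdispersed around uniform, log-normal weights) and
    recombinant counts (proportional to control abundance x planted
    efficiency), two replicates each, multinomial at ``depth`` reads.

    Returns (design, control, recombinant) DataFrames; count tables have
    columns key, r1, r2."""
    rng = stream(truth.seed, "screen-counts")
    K = len(truth.design)
    w = np.exp(rng.normal(0.0, truth.control_sigma, K))
    eff = truth.design["efficiency"].to_numpy()
    ctrl = {f"r{r+1}": rng.multinomial(truth.depth, w / w.sum())
            for r in range(2)}
    rw = w * eff
    rec = {f"r{r+1}": rng.multinomial(truth.depth, rw / rw.sum())
           for r in range(2)}
    keys = truth.design["key"]
    control = pd.DataFrame(dict(key=keys, **ctrl))
    recomb = pd.DataFrame(dict(key=keys, **rec))
    return truth.design.copy(), control, recomb


# ---------------------------------------------------------------------------
# boundary test set


def gen_boundary_testset(n_loci: int = 20, seed: int = 0,
                         element_len: int = 800, core: str = "CT",
                         flank: int = 1_000, n_pre: int | None = None,
                         n_decoys: int = 4, max_div: float = 0.06):
    """Post-insertion contigs (flank + element + core + flank), matching
    pre-insertion contigs (flanks joined across one core copy) and decoys.

    The element starts with one copy of ``core``; the flank immediately
    downstream starts with the core copy the target site contributed. Each
    locus carries a copy of a common ancestral element diverged by up to
    ``max_div`` substitutions/site (core and CDS-free terminal 20 nt kept
    exact so boundaries stay unambiguous). Returns (loci, pre_contigs,
    decoys, truth DataFrame).
    """
    if n_loci < 2:
        raise ValueError("need n_loci >= 2")
    rng = stream(seed, "boundary-testset")
    body = _random_seq(rng, element_len - len(core))
    ancestor = core + body
    cds = (100, min(700, element_len - 50))
    if n_pre is None:
        n_pre = n_loci

    def mutate(seq: str, rate: float, protect: set[int]) -> str:
        arr = _codes(seq)
        hit = rng.random(len(seq)) < rate
        for i in protect:
            hit[i] = False
        shift = rng.integers(1, 4, len(seq))
        arr[hit] = (arr[hit] + shift[hit]) % 4
        return _to_seq(arr)

    protect = set(range(len(core))) | set(range(len(ancestor) - 20, len(ancestor)))
    loci, pres, truth_rows = [], [], []
    for li in range(n_loci):
        div = 0.0 if li == 0 else float(rng.uniform(0.0, max_div))
        elem = ancestor if li == 0 else mutate(ancestor, div, protect)
        fl = _random_seq(rng, flank)
        fr = _random_seq(rng, flank - len(core))
        # keep the planted core the *maximal* junction repeat so boundaries
        # and core are unambiguous ground truth
        if fl[-1] == elem[-1]:
            fl = fl[:-1] + _BASES[(_codes(fl[-1])[0] + 1) % 4]
        if fr[0] == elem[len(core)]:
            fr = _BASES[(_codes(fr[0])[0] + 1) % 4] + fr[1:]
        post = fl + elem + core + fr
        loci.append(SeqRecord(f"locus{li:03d}", post))
        if li < n_pre:
            pres.append(SeqRecord(f"pre{li:03d}", fl + core + fr))
        truth_rows.append(dict(
            locus_id=f"locus{li:03d}", pre_id=f"pre{li:03d}" if li < n_pre else "",
            start=flank, end=flank + len(elem), core=core,
            cds_start=flank + cds[0], cds_end=flank + cds[1],
            divergence=div))

    decoys = []
    for di in range(n_decoys):
        if di % 2 == 0:
            # element-like copy with a discordant junction core
            elem = mutate(ancestor, 0.03, protect)
            bad_core = "GA" if core != "GA" else "TC"
            elem = bad_core + elem[len(core):]
            fl = _random_seq(rng, flank)
            fr = _random_seq(rng, flank - len(core))
            decoys.append(SeqRecord(f"decoy{di:03d}", fl + elem + bad_core + fr))
        else:
            decoys.append(SeqRecord(f"decoy{di:03d}",
                                    _random_seq(rng, flank * 2 + element_len)))
    return loci, pres, decoys, pd.DataFrame(truth_rows)
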