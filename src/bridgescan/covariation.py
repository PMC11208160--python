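"""Base-pairing concordance and signed covariation between a bridge-RNA
alignment and a paired DNA-window alignment.

The concordance score for RNA column *i* and DNA column *j* over the n rows
of a paired alignment is

    C_ij = absmax( sum_k CheckEqual(s_ki, t_kj),
                   sum_k CheckComplementary(s_ki, t_kj) ) / n

where CheckEqual is 1 for identical nucleotides (bottom-strand pairing,
positive sign), CheckComplementary is -1 for Watson-Crick complements
(top-strand pairing, negative sign) and rows with a gap or ambiguity at
either position are ignored and discounted from n. Observed scores are
z-scored against permutation nulls (row shuffles of the RNA alignment, or
column shuffles), separately min-max normalized per sign, and the sign of
the column-null z projects strandedness onto a covariation score (mutual
information with average-product correction by default, or an externally
computed matrix). Diagonal runs of strong signal localize the four guide
segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import AlignmentBlock, SeqRecord

__all__ = [
    "ConcordanceMatrix",
    "SignedCovariationMatrix",
    "GuideSegment",
    "project_to_reference",
    "concordance_matrix",
    "permutation_null_z",
    "signed_minmax",
    "covariation_matrix",
    "signed_covariation_map",
    "detect_guide_segments",
]

# A,C,G,T -> 0..3; gap/ambiguity -> 4 (carries no pairing information)
_CODE = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode_block(block: AlignmentBlock) -> np.ndarray:
    """(n_rows, width) int8 codes."""
    flat = "".join(r.seq for r in block.rows)
    arr = _CODE[np.frombuffer(flat.encode(), dtype=np.uint8)]
    return arr.reshape(len(block.rows), block.width)


def _onehot(codes: np.ndarray) -> np.ndarray:
    """(n, L, 4) float32; all-zero plane for gaps/ambiguity."""
    oh = np.zeros(codes.shape + (4,), dtype=np.float32)
    valid = codes < 4
    n_idx, l_idx = np.nonzero(valid)
    oh[n_idx, l_idx, codes[valid]] = 1.0
    return oh


def _pair_onehot(codes: np.ndarray, wobble: bool) -> np.ndarray:
    """One-hot of the bases that would PAIR each DNA base (Watson-Crick;
    optionally G:T wobble)."""
    oh = np.zeros(codes.shape + (4,), dtype=np.float32)
    valid = codes < 4
    n_idx, l_idx = np.nonzero(valid)
    comp = 3 - codes[valid]
    oh[n_idx, l_idx, comp] = 1.0
    if wobble:  # rG pairs dT, rU(=T) pairs dG
        t_mask = codes == 3
        oh[t_mask, 2] = 1.0
        g_mask = codes == 2
        oh[g_mask, 3] = 1.0
    return oh


@dataclass
class ConcordanceMatrix:
    """Per (RNA column i, DNA column j) concordance with permutation z."""

    C: np.ndarray                 # (Lb, Lt), NaN where n_eff == 0
    n_eff: np.ndarray             # rows counted after gap discount
    match_sum: np.ndarray
    comp_sum: np.ndarray          # negative by construction
    tie: np.ndarray               # absmax tie resolved to the match value
    z: np.ndarray | None = None
    null_mode: str | None = None
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None

    @property
    def shape(self):
        return self.C.shape


@dataclass
class SignedCovariationMatrix:
    signed: np.ndarray            # in [-1, 1]
    raw_covariation: np.ndarray
    sign_source: np.ndarray       # {+1, -1, 0}

    def to_tsv(self, path) -> None:
        """Heat-map table with the RNA on the x axis (columns)."""
        import pandas as pd

        Lb, Lt = self.signed.shape
        df = pd.DataFrame(
            self.signed.T,
            index=[f"dna_{j}" for j in range(Lt)],
            columns=[f"rna_{i}" for i in range(Lb)],
        )
        df.to_csv(path, sep="\t")


@dataclass(frozen=True)
class GuideSegment:
    """A maximal diagonal run of strong signed signal."""

    rna_start: int
    rna_end: int
    dna_start: int
    dna_end: int
    strand: str        # 'bottom' (+, diagonal) or 'top' (-, anti-diagonal)
    score: float       # mean |signed| over the run


def project_to_reference(block: AlignmentBlock, ref_id: str) -> AlignmentBlock:
    """Drop every column that is a gap in the reference row."""
    ref = block.row(ref_id)  # KeyError if absent
    keep = [i for i, c in enumerate(ref.seq) if c != "-"]
    if not keep:
        import warnings

        warnings.warn(f"reference row {ref_id!r} is all gaps; empty projection")
    rows = [SeqRecord(r.id, "".join(r.seq[i] for i in keep)) for r in block.rows]
    return AlignmentBlock(rows, reference_row_id=ref_id)


def _check_paired(bridge: AlignmentBlock, partner: AlignmentBlock) -> None:
    if bridge.ids != partner.ids:
        raise ValueError("bridge and partner alignments must share row ids "
                         "in the same order")
    if len(bridge.rows) < 10:
        raise ValueError("need at least 10 rows for covariation analysis")


def _sums(Boh, Toh, Tpair, Vb, Vt):
    """match / complement counts and n_eff via one (Lb,4n)x(4n,Lt) matmul each."""
    n = Boh.shape[0]
    Bf = Boh.transpose(1, 0, 2).reshape(Boh.shape[1], n * 4)
    Tf = Toh.transpose(1, 0, 2).reshape(Toh.shape[1], n * 4)
    Pf = Tpair.transpose(1, 0, 2).reshape(Tpair.shape[1], n * 4)
    match = Bf @ Tf.T
    paircnt = Bf @ Pf.T
    n_eff = Vb.T.astype(np.float32) @ Vt.astype(np.float32)
    return match, paircnt, n_eff


def _concordance_from_sums(match, paircnt, n_eff):
    comp = -paircnt
    take_match = match >= paircnt          # absmax; tie -> positive (match)
    tie = (match == paircnt) & (match > 0)
    num = np.where(take_match, match, comp)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(n_eff > 0, num / np.maximum(n_eff, 1), np.nan)
    C[n_eff == 0] = np.nan
    return C, match, comp, tie


def concordance_matrix(bridge: AlignmentBlock, partner: AlignmentBlock,
                       wobble: bool = False) -> ConcordanceMatrix:
    """Observed C for every (RNA column, DNA column) pair."""
    _check_paired(bridge, partner)
    bc = encode_block(bridge)
    tc = encode_block(partner)
    Boh = _onehot(bc)
    Toh = _onehot(tc)
    Tpair = _pair_onehot(tc, wobble)
    Vb, Vt = bc < 4, tc < 4
    match, paircnt, n_eff = _sums(Boh, Toh, Tpair, Vb, Vt)
    C, match, comp, tie = _concordance_from_sums(match, paircnt, n_eff)
    return ConcordanceMatrix(C=C, n_eff=n_eff, match_sum=match,
                             comp_sum=comp, tie=tie)


def permutation_null_z(bridge: AlignmentBlock, partner: AlignmentBlock,
                       mode: str = "columns", n_perm: int = 1000,
                       seed: int | None = 0,
                       wobble: bool = False) -> ConcordanceMatrix:
    """z-score the observed C against a permutation null.

    mode='rows' shuffles the rows of the RNA alignment (per-cell
    exchangeability null); mode='columns' shuffles its columns (the null
    whose sign the strand projection uses). Cells with null sd == 0 are
    masked (z = NaN).
    """
    if mode not in ("rows", "columns"):
        raise ValueError(f"invalid null mode {mode!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    _check_paired(bridge, partner)
    rng = np.random.default_rng(seed)
    obs = concordance_matrix(bridge, partner, wobble=wobble)

    if mode == "columns":
        Lb = obs.shape[0]
        perms = np.stack([rng.permutation(Lb) for _ in range(n_perm)])
        gathered = obs.C[perms, :]          # (n_perm, Lb, Lt)
        mean = np.nanmean(gathered, axis=0)
        sd = np.nanstd(gathered, axis=0)
    else:
        bc = encode_block(bridge)
        tc = encode_block(partner)
        Boh = _onehot(bc)
        Toh = _onehot(tc)
        Tpair = _pair_onehot(tc, wobble)
        Vb, Vt = bc < 4, tc < 4
        n = bc.shape[0]
        Tf = Toh.transpose(1, 0, 2).reshape(tc.shape[1], n * 4)
        Pf = Tpair.transpose(1, 0, 2).reshape(tc.shape[1], n * 4)
        Vt_f = Vt.astype(np.float32)
        s = np.zeros(obs.shape, dtype=np.float64)
        s2 = np.zeros(obs.shape, dtype=np.float64)
        gapless = bool(Vb.all() and Vt.all())
        if gapless:
            n_eff = np.full(obs.shape, float(n), dtype=np.float32)
        for _ in range(n_perm):
            p = rng.permutation(n)
            Bp = Boh[p].transpose(1, 0, 2).reshape(bc.shape[1], n * 4)
            match = Bp @ Tf.T
            paircnt = Bp @ Pf.T
            if not gapless:
                n_eff = Vb[p].T.astype(np.float32) @ Vt_f
            Cp, *_ = _concordance_from_sums(match, paircnt, n_eff)
            s += np.nan_to_num(Cp)
            s2 += np.nan_to_num(Cp) ** 2
        mean = s / n_perm
        sd = np.sqrt(np.maximum(s2 / n_perm - mean ** 2, 0.0))

    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs.C - mean) / sd
    z[~np.isfinite(z)] = np.nan
    z[sd == 0] = np.nan
    obs.z = z
    obs.null_mode = mode
    obs.null_mean = mean
    obs.null_sd = sd
    return obs


def signed_minmax(values: np.ndarray) -> np.ndarray:
    """Map positives to (0,1] and negatives to [-1,0) by dividing each sign
    class by its extreme; zeros stay zero, NaN stays NaN. Monotone,
    sign-preserving, idempotent on already-normalized input."""
    v = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("all values masked; nothing to normalize")
    out = np.array(v, copy=True)
    pos = finite & (v > 0)
    neg = finite & (v < 0)
    if pos.any():
        out[pos] = v[pos] / v[pos].max()
    if neg.any():
        out[neg] = v[neg] / abs(v[neg].min())
    return out


def mutual_information_apc(bridge: AlignmentBlock,
                           partner: AlignmentBlock) -> np.ndarray:
    """Column-pair MI (nats) with average-product correction, floored at 0.
    Gaps/ambiguity are excluded pairwise."""
    _check_paired(bridge, partner)
    bc = encode_block(bridge)
    tc = encode_block(partner)
    Boh = _onehot(bc)
    Toh = _onehot(tc)
    n = bc.shape[0]
    Lb, Lt = bc.shape[1], tc.shape[1]
    # joint counts J[a,b,i,j]
    J = np.empty((4, 4, Lb, Lt), dtype=np.float64)
    for a in range(4):
        Ba = np.ascontiguousarray(Boh[:, :, a].T)      # (Lb, n)
        for b in range(4):
            J[a, b] = Ba @ Toh[:, :, b]
    n_eff = J.sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        P = J / n_eff
        pa = P.sum(axis=1, keepdims=True)              # (4,1,Lb,Lt)
        pb = P.sum(axis=0, keepdims=True)
        terms = P * np.log(P / (pa * pb))
    mi = np.nansum(terms, axis=(0, 1))
    mi[n_eff == 0] = 0.0
    # average-product correction
    row_mean = mi.mean(axis=1, keepdims=True)
    col_mean = mi.mean(axis=0, keepdims=True)
    grand = mi.mean()
    apc = row_mean * col_mean / grand if grand > 0 else 0.0
    return np.maximum(mi - apc, 0.0)


def read_external_matrix(path, shape: tuple[int, int]) -> np.ndarray:
    """Whitespace-delimited numeric matrix (e.g. a contact-predictor dump),
    floored at 0; dimensions must match the paired alignments."""
    m = np.loadtxt(path, dtype=np.float64)
    m = np.atleast_2d(m)
    if m.shape != shape:
        raise ValueError(f"external matrix shape {m.shape} != alignments {shape}")
    return np.maximum(m, 0.0)


def covariation_matrix(bridge: AlignmentBlock, partner: AlignmentBlock,
                       method: str = "mi_apc",
                       external_path=None) -> np.ndarray:
    if method == "mi_apc":
        return mutual_information_apc(bridge, partner)
    if method == "external":
        _check_paired(bridge, partner)
        return read_external_matrix(external_path,
                                    (bridge.width, partner.width))
    raise ValueError(f"unknown covariation method {method!r}")


def signed_covariation_map(raw: np.ndarray,
                           concordance: ConcordanceMatrix
                           ) -> SignedCovariationMatrix:
    """Min-max normalized covariation multiplied by the sign of the
    (column-null) concordance z-score."""
    if concordance.z is None:
        raise ValueError("concordance matrix has no z-scores")
    if raw.shape != concordance.z.shape:
        raise ValueError(f"shape mismatch {raw.shape} vs {concordance.z.shape}")
    sign = np.sign(np.nan_to_num(concordance.z)).astype(np.int8)
    if np.nanmax(raw) > 0:
        norm = raw / np.nanmax(raw)        # raw >= 0 after flooring
    else:
        norm = np.zeros_like(raw)
    return SignedCovariationMatrix(signed=norm * sign, raw_covariation=raw,
                                   sign_source=sign)


def _runs(cells: list[tuple[int, int]], min_run: int):
    """Maximal runs of consecutive RNA positions among diagonal cells
    (already sharing one diagonal, sorted by rna index)."""
    out = []
    start = prev = None
    for i, j in cells:
        if prev is not None and i == prev[0] + 1:
            prev = (i, j)
        else:
            if start is not None and prev[0] - start[0] + 1 >= min_run:
                out.append((start, prev))
            start = prev = (i, j)
    if start is not None and prev[0] - start[0] + 1 >= min_run:
        out.append((start, prev))
    return out


def detect_guide_segments(signed: SignedCovariationMatrix | np.ndarray,
                          min_run: int = 4, threshold: float = 0.5,
                          structure: str | None = None) -> list[GuideSegment]:
    """Maximal diagonal (bottom strand, sign +) and anti-diagonal (top
    strand, sign -) runs of cells with |signed| >= threshold; overlapping
    runs of the same strand are merged. If a dot-bracket ``structure`` is
    supplied, only loop (unpaired, '.') RNA positions are considered."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    S = signed.signed if isinstance(signed, SignedCovariationMatrix) else signed
    Lb, Lt = S.shape
    loop_ok = np.ones(Lb, dtype=bool)
    if structure is not None:
        if len(structure) != Lb:
            raise ValueError("structure length disagrees with RNA width")
        loop_ok = np.array([c == "." for c in structure])
    with np.errstate(invalid="ignore"):
        pos_mask = (np.nan_to_num(S) >= threshold) & loop_ok[:, None]
        neg_mask = (np.nan_to_num(S) <= -threshold) & loop_ok[:, None]
    segments: list[GuideSegment] = []
    # bottom strand: diagonals i - j = d, ascending together
    for d in range(-(Lt - 1), Lb):
        cells = [(i, i - d) for i in range(max(0, d), min(Lb, Lt + d))
                 if pos_mask[i, i - d]]
        for (i0, j0), (i1, j1) in _runs(cells, min_run):
            score = float(np.mean([abs(S[i, i - d]) for i in range(i0, i1 + 1)]))
            segments.append(GuideSegment(i0, i1 + 1, j0, j1 + 1, "bottom", score))
    # top strand: anti-diagonals i + j = d; rna ascending, dna descending
    for d in range(Lb + Lt - 1):
        cells = [(i, d - i) for i in range(max(0, d - Lt + 1), min(Lb, d + 1))
                 if neg_mask[i, d - i]]
        for (i0, j0), (i1, j1) in _runs(cells, min_run):
            score = float(np.mean([abs(S[i, d - i]) for i in range(i0, i1 + 1)]))
            segments.append(GuideSegment(i0, i1 + 1, j1, j0 + 1, "top", score))
    return _merge_segments(segments)


def _merge_segments(segments: list[GuideSegment]) -> list[GuideSegment]:
    segments = sorted(segments, key=lambda s: (s.strand, s.rna_start, s.dna_start))
    merged: list[GuideSegment] = []
    for seg in segments:
        if merged:
            last = merged[-1]
            if (seg.strand == last.strand
                    and seg.rna_start < last.rna_end
                    and seg.dna_start < last.dna_end
                    and last.dna_start < seg.dna_end):
                merged[-1] = GuideSegment(
                    last.rna_start, max(last.rna_end, seg.rna_end),
                    min(last.dna_start, seg.dna_start),
                    max(last.dna_end, seg.dna_end),
                    seg.strand, max(last.score, seg.score))
                continue
        merged.append(seg)
    return merged
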