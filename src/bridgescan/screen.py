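"""Pooled specificity-screen quantification.

Barcode (or UMI) counts from control and recombination-selected conditions
are normalized to counts per million (CPM) within each replicate, averaged
across the two biological replicates, and corrected for library skew by a
per-key factor = expected CPM under uniformity (10^6 / K) divided by the
observed control CPM. Corrected recombinant CPM is the efficiency readout.

Mismatch tolerance summarizes 4x4 single-mismatch sets (all 16 guide x site
nucleotide combinations at one position): sets are ranked by their most
efficient member, the top quintile kept, each set converted to percent of
set-total CPM, and averaged per position. Nucleotide enrichment compares
the composition of the top quintile of mismatch-free pairs to the whole
set, as log2 ratios with a pseudocount.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import TargetGeometry

__all__ = [
    "LibraryDesign",
    "CountTable",
    "hamming",
    "assign_barcodes",
    "build_umi_map",
    "cpm_and_correction",
    "mismatch_tolerance",
    "top_quintile_enrichment",
    "core_iupac_summary",
    "IUPAC_CLASSES",
]

_BASES = "ACGT"

# IUPAC degeneracy classes used to summarize core-guide variants
IUPAC_CLASSES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "AG": "R", "CT": "Y", "CG": "S", "AT": "W", "GT": "K", "AC": "M",
    "CGT": "B", "AGT": "D", "ACT": "H", "ACG": "V", "ACGT": "N",
}


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass
class LibraryDesign:
    """The designed library: one row per oligo with its assignment key."""

    entries: pd.DataFrame            # key, guide, site, category [, set_id...]
    geometry: TargetGeometry = field(default_factory=TargetGeometry)
    min_key_dist: int = 3

    def __post_init__(self) -> None:
        need = {"key", "guide", "site", "category"}
        missing = need - set(self.entries.columns)
        if missing:
            raise ValueError(f"design lacks columns {sorted(missing)}")
        if self.entries["key"].duplicated().any():
            raise ValueError("duplicate keys in design")

    def validate_key_distances(self) -> None:
        """Pairwise Hamming >= 3 so single-mismatch assignment is unique."""
        keys = self.entries["key"].tolist()
        lut = np.zeros(128, dtype=np.int8)
        for i, b in enumerate(_BASES):
            lut[ord(b)] = i
        arr = np.stack([lut[np.frombuffer(k.encode(), np.uint8)] for k in keys])
        # blockwise pairwise distances to bound memory
        step = 512
        for i in range(0, len(keys), step):
            blk = arr[i : i + step]
            d = (blk[:, None, :] != arr[None, :, :]).sum(axis=2)
            for r in range(len(blk)):
                d[r, i + r] = 99
            if d.min() < self.min_key_dist:
                bad = np.unravel_index(d.argmin(), d.shape)
                raise ValueError(
                    f"keys {keys[i + bad[0]]!r} and {keys[bad[1]]!r} are within "
                    f"{d.min()} mismatches (need >= {self.min_key_dist})")


@dataclass
class CountTable:
    """Per-key counts, CPM and control-derived corrections."""

    table: pd.DataFrame    # key + per-sample columns + cpm/corrected columns
    dropped: list[str] = field(default_factory=list)

    def efficiency(self) -> pd.Series:
        """Replicate-averaged corrected recombinant CPM, indexed by key."""
        return self.table.set_index("key")["corrected_cpm"]


def assign_barcodes(observed: pd.DataFrame, design: LibraryDesign
                    ) -> pd.DataFrame:
    """Map observed barcode counts onto design keys, tolerating single
    mismatches; Hamming >= 2 barcodes land in the ``unassigned`` row.

    ``observed`` columns: barcode + one column per sample of raw counts.
    """
    design.validate_key_distances()
    keys = design.entries["key"].tolist()
    exact = {k: k for k in keys}
    length = len(keys[0])
    one_off: dict[str, str] = {}
    for k in keys:
        for pos, b in itertools.product(range(length), _BASES):
            if b != k[pos]:
                one_off[k[:pos] + b + k[pos + 1 :]] = k
    samples = [c for c in observed.columns if c != "barcode"]
    sums: dict[str, np.ndarray] = {k: np.zeros(len(samples)) for k in keys}
    sums["unassigned"] = np.zeros(len(samples))
    for row in observed.itertuples(index=False):
        bc = row.barcode
        key = exact.get(bc) or one_off.get(bc) or "unassigned"
        sums[key] += np.array([getattr(row, s) for s in samples], dtype=float)
    out = pd.DataFrame({"key": list(sums)})
    for i, s in enumerate(samples):
        out[s] = [sums[k][i] for k in sums]
    return out


def build_umi_map(reads: list[str], template: str,
                  umi_slice: slice, consensus: float = 0.9
                  ) -> tuple[dict[str, str], pd.DataFrame]:
    """Extract (UMI, variable-field) pairs from reads matching a template
    with N at the variable positions; a UMI maps to an oligo when >= 90% of
    its reads agree on the variable fields; conflicted UMIs are dropped.

    Returns (umi -> variable-field string, per-UMI log table)."""
    var_pos = [i for i, c in enumerate(template) if c == "N"
               and not (umi_slice.start <= i < umi_slice.stop)]
    votes: dict[str, dict[str, int]] = {}
    skipped = 0
    for r in reads:
        if len(r) != len(template):
            skipped += 1
            continue
        umi = r[umi_slice]
        fields = "".join(r[i] for i in var_pos)
        votes.setdefault(umi, {}).setdefault(fields, 0)
        votes[umi][fields] += 1
    mapping: dict[str, str] = {}
    log_rows = []
    for umi, d in votes.items():
        total = sum(d.values())
        fields, n = max(d.items(), key=lambda kv: kv[1])
        ok = n / total >= consensus
        if ok:
            mapping[umi] = fields
        log_rows.append(dict(umi=umi, n_reads=total, agreement=n / total,
                             status="mapped" if ok else "conflicted"))
    log = pd.DataFrame(log_rows)
    if skipped:
        log.attrs["skipped_reads"] = skipped
    return mapping, log


def cpm_and_correction(control: pd.DataFrame, recombinant: pd.DataFrame,
                       design: LibraryDesign | None = None) -> CountTable:
    """CPM per replicate, replicate-averaged; correction factor per key =
    (10^6 / K) / control CPM; corrected recombinant CPM = recombinant CPM x
    factor. Keys with zero control CPM are dropped and logged.

    Count tables: columns key, r1, r2 (same key universe in both)."""
    if control.empty or recombinant.empty:
        raise ValueError("count tables must be non-empty")
    if set(control["key"]) != set(recombinant["key"]):
        raise ValueError("control and recombinant key universes differ")
    reps = [c for c in control.columns if c != "key"]
    c = control.set_index("key").astype(float)
    r = recombinant.set_index("key").astype(float).loc[c.index]
    c_cpm = c / c.sum(axis=0) * 1e6
    r_cpm = r / r.sum(axis=0) * 1e6
    table = pd.DataFrame({
        "key": c.index,
        "control_cpm": c_cpm[reps].mean(axis=1).to_numpy(),
        "recomb_cpm": r_cpm[reps].mean(axis=1).to_numpy(),
    })
    zero = table["control_cpm"] == 0
    dropped = table.loc[zero, "key"].tolist()
    table = table[~zero].reset_index(drop=True)
    K = len(table)
    table["correction_factor"] = (1e6 / K) / table["control_cpm"]
    table["corrected_cpm"] = table["recomb_cpm"] * table["correction_factor"]
    if design is not None:
        table = table.merge(design.entries, on="key", how="left")
    return CountTable(table=table, dropped=dropped)


def _set_frame(counts: CountTable, design: LibraryDesign,
               category: str) -> pd.DataFrame:
    df = counts.table
    if not set(design.entries.columns) <= set(df.columns):
        df = df.merge(design.entries, on="key", how="inner")
    return df[df["category"] == category].copy()


def mismatch_tolerance(counts: CountTable, design: LibraryDesign,
                       order: str = "single", quintile: float = 0.2
                       ) -> dict[int, pd.DataFrame]:
    """Per-position 4x4 guide-x-site percent-of-set-CPM matrices, averaged
    over the top quintile of sets (ranked by their maximum-efficiency
    member, boundary ties included)."""
    if order not in ("single", "double"):
        raise ValueError(order)
    category = "single_mm_4x4" if order == "single" else "double_mm"
    df = _set_frame(counts, design, category)
    if df.empty:
        raise ValueError(f"design contains no {category} sets")
    cs = design.geometry.core_start
    cl = len(design.geometry.core)

    if "position" in df.columns:
        df["pos"] = df["position"].astype(int)
    else:
        # scanned position of a set = the position its members vary at
        from collections import Counter

        pos_of_set: dict[str, int] = {}
        for sid, grp in df.groupby("set_id"):
            diffs = Counter()
            for row in grp.itertuples(index=False):
                for i, (gb, sb) in enumerate(zip(row.guide, row.site)):
                    if gb != sb:
                        diffs[i] += 1
            pos_of_set[sid] = diffs.most_common(1)[0][0] if diffs else -1
        df["pos"] = df["set_id"].map(pos_of_set)
    set_max = df.groupby("set_id")["corrected_cpm"].max()
    set_tot = df.groupby("set_id")["corrected_cpm"].sum()
    nonzero = set_tot[set_tot > 0].index
    if len(nonzero) == 0:
        raise ValueError("all sets have zero total CPM")
    ranked = set_max.loc[nonzero].sort_values(ascending=False)
    n_keep = max(1, int(np.ceil(quintile * len(ranked))))
    cutoff = ranked.iloc[n_keep - 1]
    keep = set(ranked[ranked >= cutoff].index)   # boundary ties included
    df = df[df["set_id"].isin(keep)]

    out: dict[int, pd.DataFrame] = {}
    for pos, sub in df.groupby("pos"):
        if pos < 0 or cs <= pos < cs + cl:
            continue
        mats = []
        for _sid, grp in sub.groupby("set_id"):
            tot = grp["corrected_cpm"].sum()
            if tot == 0:
                continue
            m = np.zeros((4, 4))
            for row in grp.itertuples(index=False):
                gi = _BASES.index(row.guide[pos])
                si = _BASES.index(row.site[pos])
                m[gi, si] += row.corrected_cpm
            mats.append(m / tot * 100.0)
        if mats:
            out[int(pos)] = pd.DataFrame(np.mean(mats, axis=0),
                                         index=list(_BASES),
                                         columns=list(_BASES))
    return out


def top_quintile_enrichment(counts: CountTable, design: LibraryDesign,
                            quintile: float = 0.2,
                            matched_category: str = "wt") -> pd.DataFrame:
    """log2(nucleotide frequency in the top-quintile mismatch-free pairs /
    frequency in the whole mismatch-free set), per site position; zero
    frequencies floored with pseudocount 0.5/n."""
    df = _set_frame(counts, design, matched_category)
    df = df[df["guide"] == df["site"]]
    if len(df) < 50:
        raise ValueError("need >= 50 mismatch-free pairs for enrichment")
    df = df.sort_values("corrected_cpm", ascending=False)
    n_top = max(1, int(np.ceil(quintile * len(df))))
    top = df.head(n_top)
    slen = len(df["site"].iloc[0])

    def freqs(frame: pd.DataFrame) -> np.ndarray:
        f = np.zeros((slen, 4))
        for s in frame["site"]:
            for i, b in enumerate(s):
                f[i, _BASES.index(b)] += 1
        return f / len(frame)

    floor = 0.5 / n_top      # one shared floor so impossible cells stay at 0
    e = np.log2(np.maximum(freqs(top), floor) / np.maximum(freqs(df), floor))
    return pd.DataFrame(e, columns=list(_BASES),
                        index=[f"pos{i+1}" for i in range(slen)])


def core_iupac_summary(counts: CountTable, design: LibraryDesign
                       ) -> pd.DataFrame:
    """Corrected-CPM distribution of core-guide variants grouped by the
    IUPAC class of each core position (e.g. D = not C, V = not T)."""
    df = _set_frame(counts, design, "core_mm")
    if df.empty:
        raise ValueError("design contains no core_mm category")
    g = design.geometry
    cs, cl = g.core_start, len(g.core)
    df["guide_core"] = df["guide"].str[cs : cs + cl]

    def klass(core_guide: str) -> str:
        out = []
        for i, b in enumerate(core_guide):
            if b == g.core[i]:
                out.append(b)
            else:
                others = "".join(sorted(set(_BASES) - {g.core[i]}))
                out.append(IUPAC_CLASSES[others] if b in others else b)
        return "".join(out)

    rows = []
    for core_guide, grp in df.groupby("guide_core"):
        rows.append(dict(
            guide_core=core_guide,
            iupac_class=klass(core_guide),
            is_wt=core_guide == g.core,
            n=len(grp),
            median_corrected_cpm=float(grp["corrected_cpm"].median()),
            mean_corrected_cpm=float(grp["corrected_cpm"].mean())))
    return pd.DataFrame(rows).sort_values("median_corrected_cpm",
                                          ascending=False)
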