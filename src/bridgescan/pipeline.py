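"""Stage orchestration: validated run configs, deterministic outputs and a
reproducibility manifest.

Each run executes one stage with a flat parameter mapping (YAML document or
CLI flags); unknown keys are rejected by name, every parameter is echoed
into the manifest together with sha256 checksums of all outputs, and every
random choice in any stage flows from the single ``seed`` entry.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import TargetGeometry
from .seqio import (AlignmentBlock, read_sequences, write_alignment, write_bed,
                    write_sequences, write_tsv)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "STAGE_SCHEMAS"]


class ConfigError(ValueError):
    """Config violates the stage schema (exit code 1 territory)."""


STAGE_SCHEMAS: dict[str, set[str]] = {
    "simulate": {"kind", "n_orthologues", "coupling", "sub_rate", "depth",
                 "genome_size", "site_freqs", "error_rates", "n_loci",
                 "n_targets", "n_matched", "screen_depth"},
    "covary": {"bridge", "partner", "reference_id", "null", "n_perm",
               "method", "external_matrix", "min_run", "threshold",
               "structure", "wobble"},
    "boundaries": {"loci", "db", "max_iter", "flank", "gap_tol", "window",
                   "max_core"},
    "callsites": {"reads", "genome", "plasmid", "donor_core_start",
                  "target_11", "donor_11", "merge_dist", "max_mm",
                  "target_depth"},
    "screen": {"design", "control", "recomb", "order", "quintile"},
    "motif": {"pairs", "min_members"},
}

_COMMON_KEYS = {"stage", "seed", "out_dir"}


@dataclass
class RunConfig:
    stage: str
    out_dir: str
    seed: int = 0
    params: dict = dc_field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        mapping = dict(mapping)
        stage = mapping.get("stage")
        if stage not in STAGE_SCHEMAS:
            raise ConfigError(f"unknown or missing stage: {stage!r}")
        allowed = STAGE_SCHEMAS[stage] | _COMMON_KEYS
        unknown = set(mapping) - allowed
        if unknown:
            raise ConfigError(
                f"unknown config key(s) for stage {stage}: {sorted(unknown)}")
        if "out_dir" not in mapping:
            raise ConfigError("config requires out_dir")
        return cls(stage=stage, out_dir=str(mapping.pop("out_dir")),
                   seed=int(mapping.pop("seed", 0)),
                   params={k: v for k, v in mapping.items() if k != "stage"})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigError("config must be a YAML mapping")
        return cls.from_mapping(doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute one stage; outputs land under ``out_dir`` with a
    ``manifest.json``. Returns the manifest mapping. Missing inputs raise
    FileNotFoundError; schema violations raise ConfigError."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    runner = {
        "simulate": _run_simulate,
        "covary": _run_covary,
        "boundaries": _run_boundaries,
        "callsites": _run_callsites,
        "screen": _run_screen,
        "motif": _run_motif,
    }[config.stage]
    outputs = runner(config, out)
    manifest = {
        "stage": config.stage,
        "seed": config.seed,
        "parameters": config.params,
        "version": __version__,
        "outputs": {name: _sha256(out / name) for name in sorted(outputs)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return manifest


def _require(config: RunConfig, key: str):
    if key not in config.params:
        raise ConfigError(f"stage {config.stage} requires key {key!r}")
    return config.params[key]


def _run_simulate(config: RunConfig, out: Path) -> list[str]:
    from . import simulate as sim

    kind = _require(config, "kind")
    p = config.params
    if kind == "family":
        truth = sim.FamilyTruth.random(
            config.seed, n_orthologues=int(p.get("n_orthologues", 500)),
            coupling=float(p.get("coupling", 0.9)),
            sub_rate=float(p.get("sub_rate", 0.2)))
        bridge, target, donor = sim.gen_orthologue_family(truth)
        write_alignment(bridge, out / "bridge.afa")
        write_alignment(target, out / "targets.afa")
        write_alignment(donor, out / "donors.afa")
        truth_rows = [dict(partner=pt, rna_start=ri[0], rna_end=ri[1],
                           dna_start=di[0], dna_end=di[1], strand=st)
                      for pt, ri, di, st in truth.planted_segments()]
        write_tsv(pd.DataFrame(truth_rows), out / "truth_segments.tsv")
        return ["bridge.afa", "targets.afa", "donors.afa", "truth_segments.tsv"]
    if kind == "reads":
        truth = sim.InsertionTruth.random(
            config.seed, genome_size=int(p.get("genome_size", 100_000)),
            site_freqs=tuple(p.get("site_freqs", (0.8, 0.2))),
            depth=int(p.get("depth", 500)),
            error_rates=tuple(p.get("error_rates", (0.03, 0.02, 0.02))))
        genome, plasmid, reads, bed = sim.gen_toy_genome_and_reads(truth)
        write_sequences([genome], out / "genome.fa")
        write_sequences([plasmid], out / "plasmid.fa")
        write_sequences(reads, out / "reads.fastq", format="fastq")
        write_bed(bed, out / "truth_sites.bed")
        meta = dict(donor_core_start=truth.donor_core_start,
                    intended_target=truth.intended_target,
                    donor_site=truth.donor_site)
        (out / "truth_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
        return ["genome.fa", "plasmid.fa", "reads.fastq", "truth_sites.bed",
                "truth_meta.json"]
    if kind == "screen":
        truth = sim.ScreenTruth.random(
            config.seed, n_targets=int(p.get("n_targets", 18)),
            n_matched=int(p.get("n_matched", 300)),
            depth=int(p.get("screen_depth", 1_000_000)))
        design, control, recomb = sim.gen_screen_dataset(truth)
        write_tsv(design, out / "design.tsv")
        write_tsv(control, out / "control.tsv")
        write_tsv(recomb, out / "recomb.tsv")
        write_tsv(pd.DataFrame(
            dict(position=list(truth.penalties),
                 penalty=list(truth.penalties.values()))),
            out / "truth_penalties.tsv")
        return ["design.tsv", "control.tsv", "recomb.tsv", "truth_penalties.tsv"]
    if kind == "boundaries":
        loci, pres, decoys, truth = sim.gen_boundary_testset(
            n_loci=int(p.get("n_loci", 20)), seed=config.seed)
        write_sequences(loci, out / "loci.fa")
        write_sequences(pres + decoys, out / "contigs.fa")
        write_tsv(truth, out / "truth_elements.tsv")
        return ["loci.fa", "contigs.fa", "truth_elements.tsv"]
    raise ConfigError(f"unknown simulate kind {kind!r}")


def _matrix_tsv(m: np.ndarray, path: Path) -> None:
    pd.DataFrame(m).to_csv(path, sep="\t", float_format="%.6g")


def _run_covary(config: RunConfig, out: Path) -> list[str]:
    from . import covariation as cov

    p = config.params
    bridge = read_sequences(_require(config, "bridge"), "aligned-fasta")
    partner = read_sequences(_require(config, "partner"), "aligned-fasta")
    if p.get("reference_id"):
        bridge = cov.project_to_reference(bridge, p["reference_id"])
    conc = cov.permutation_null_z(
        bridge, partner, mode=p.get("null", "columns"),
        n_perm=int(p.get("n_perm", 1000)), seed=config.seed,
        wobble=bool(p.get("wobble", False)))
    raw = cov.covariation_matrix(bridge, partner,
                                 method=p.get("method", "mi_apc"),
                                 external_path=p.get("external_matrix"))
    signed = cov.signed_covariation_map(raw, conc)
    segs = cov.detect_guide_segments(
        signed, min_run=int(p.get("min_run", 4)),
        threshold=float(p.get("threshold", 0.5)),
        structure=p.get("structure"))
    _matrix_tsv(conc.C, out / "concordance.tsv")
    _matrix_tsv(conc.z, out / "z.tsv")
    signed.to_tsv(out / "signed.tsv")
    write_tsv(pd.DataFrame([s.__dict__ for s in segs]) if segs
              else pd.DataFrame(columns=["rna_start", "rna_end", "dna_start",
                                         "dna_end", "strand", "score"]),
              out / "segments.tsv")
    return ["concordance.tsv", "z.tsv", "signed.tsv", "segments.tsv"]


def _run_boundaries(config: RunConfig, out: Path) -> list[str]:
    from .boundaries import (find_pre_insertion_boundaries, identify_core,
                             iterative_element_search, ISElement)

    p = config.params
    loci = read_sequences(_require(config, "loci"), "fasta")
    db = read_sequences(_require(config, "db"), "fasta")
    seeds = []
    for locus in loci:
        for ev in find_pre_insertion_boundaries(
                locus, db, gap_tol=int(p.get("gap_tol", 20)),
                flank=int(p.get("flank", 1000))):
            core, s, e = identify_core(locus, ev.left_breakpoint,
                                       ev.right_breakpoint,
                                       window=int(p.get("window", 30)),
                                       max_core=int(p.get("max_core", 10)))
            if core is not None:
                seeds.append(ISElement(locus.id, s, e, core=core,
                                       provenance="pre_insertion"))
            break
    elements, iters, converged = iterative_element_search(
        seeds, loci + db, max_iter=int(p.get("max_iter", 50)))
    rows = [dict(contig=e.contig_id, start=e.start, end=e.end,
                 strand=e.strand, core=e.core, provenance=e.provenance,
                 iteration=e.iteration) for e in elements]
    write_tsv(pd.DataFrame(rows), out / "elements.tsv")
    write_tsv(iters, out / "iterations.tsv")
    (out / "converged.txt").write_text(f"{converged}\n")
    return ["elements.tsv", "iterations.tsv", "converged.txt"]


def _run_callsites(config: RunConfig, out: Path) -> list[str]:
    from . import insertion as ins

    p = config.params
    reads_path = Path(_require(config, "reads"))
    fmt = "fastq" if reads_path.suffix in (".fq", ".fastq") else "fasta"
    reads = read_sequences(reads_path, fmt)
    genome = read_sequences(_require(config, "genome"), "fasta")
    plasmid = read_sequences(_require(config, "plasmid"), "fasta")
    if p.get("target_depth"):
        gsize = sum(len(r.seq) for r in genome)
        reads = ins.downsample_reads(reads, float(p["target_depth"]), gsize,
                                     seed=config.seed)
    juncs = ins.scan_donor_junctions(reads, plasmid[0],
                                     int(_require(config, "donor_core_start")),
                                     max_mm=int(p.get("max_mm", 2)))
    juncs = ins.assign_flank_origin(juncs, genome, plasmid)
    sites = ins.merge_and_call_sites(juncs, genome,
                                     merge_dist=int(p.get("merge_dist", 5)))
    t11, d11 = p.get("target_11"), p.get("donor_11")
    if t11 and d11:
        for s in sites:
            ins.classify_site(s, t11, d11)
        ins.apply_site_filters(sites)
    write_bed(ins.sites_to_bed(sites), out / "sites.bed")
    rows = [dict(contig=s.contig, coord=s.coord, strand=s.strand,
                 read_count=s.read_count, freq=s.freq, site_11=s.site_seq_11,
                 site_14=s.site_seq_14, lev_target=s.lev_target,
                 lev_donor=s.lev_donor, category=s.category,
                 core_is_CT=s.core_is_CT, excluded=s.excluded,
                 flags=";".join(sorted(s.filter_flags))) for s in sites]
    write_tsv(pd.DataFrame(rows), out / "sites.tsv")
    jrows = [dict(read_id=j.read_id, donor_side=j.donor_side,
                  mismatches=j.match_mismatches, contig=j.genome_contig,
                  coord=j.genome_coord, orientation=j.orientation)
             for j in juncs]
    write_tsv(pd.DataFrame(jrows), out / "junctions.tsv")
    return ["sites.bed", "sites.tsv", "junctions.tsv"]


def _run_screen(config: RunConfig, out: Path) -> list[str]:
    from . import screen as scr

    p = config.params
    design = scr.LibraryDesign(pd.read_csv(_require(config, "design"), sep="\t"))
    control = pd.read_csv(_require(config, "control"), sep="\t")
    recomb = pd.read_csv(_require(config, "recomb"), sep="\t")
    counts = scr.cpm_and_correction(control, recomb, design)
    write_tsv(counts.table, out / "corrected.tsv")
    outputs = ["corrected.tsv"]
    tol = scr.mismatch_tolerance(counts, design,
                                 order=p.get("order", "single"),
                                 quintile=float(p.get("quintile", 0.2)))
    for pos, mat in tol.items():
        name = f"tolerance_pos{pos}.tsv"
        mat.to_csv(out / name, sep="\t")
        outputs.append(name)
    try:
        enr = scr.top_quintile_enrichment(counts, design)
        enr.to_csv(out / "enrichment.tsv", sep="\t")
        outputs.append("enrichment.tsv")
    except ValueError:
        pass
    try:
        core = scr.core_iupac_summary(counts, design)
        write_tsv(core, out / "core_classes.tsv")
        outputs.append("core_classes.tsv")
    except ValueError:
        pass
    return outputs


def _run_motif(config: RunConfig, out: Path) -> list[str]:
    from .motif import consensus_motifs_per_guide, guide_motif_concordance
    from .seqio import SeqRecord

    p = config.params
    pairs = pd.read_csv(_require(config, "pairs"), sep="\t")
    need = {"ltg", "rtg", "site"}
    if not need <= set(pairs.columns):
        raise ConfigError(f"pairs table requires columns {sorted(need)}")
    ids = [f"p{i}" for i in range(len(pairs))]
    sites = AlignmentBlock(
        [SeqRecord(i, s) for i, s in zip(ids, pairs["site"])])
    bridges = AlignmentBlock(
        [SeqRecord(i, l + r) for i, l, r in
         zip(ids, pairs["ltg"], pairs["rtg"])])
    groups = consensus_motifs_per_guide(
        sites, bridges, min_members=int(p.get("min_members", 21)))
    rows = []
    for g in groups:
        guide_motif_concordance(g)
        rows.append(dict(ltg=g.ltg, rtg=g.rtg, n_members=g.n_members,
                         consensus=g.consensus, mismatches=g.mismatches,
                         mismatch_positions=",".join(map(str, g.mismatch_positions)),
                         flagged=g.geometry_flagged))
    write_tsv(pd.DataFrame(rows) if rows else
              pd.DataFrame(columns=["ltg", "rtg", "n_members", "consensus",
                                    "mismatches", "mismatch_positions",
                                    "flagged"]),
              out / "groups.tsv")
    return ["groups.tsv"]
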