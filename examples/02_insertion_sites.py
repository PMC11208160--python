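"""Call donor insertion sites from simulated nanopore-like junction reads.

Two sites are planted at 80%/20% relative frequency in a 100-kb genome;
the caller scans reads for donor termini, assigns flank origins, merges
junctions within 5 bp and classifies each site against the intended target.
"""

from bridgescan import insertion as ins
from bridgescan.simulate import InsertionTruth, gen_toy_genome_and_reads

truth = InsertionTruth.random(seed=1, genome_size=100_000,
                              site_freqs=(0.8, 0.2), depth=500)
genome, plasmid, reads, _bed = gen_toy_genome_and_reads(truth)
print(f"{len(reads)} reads; intended target {truth.intended_target}")

junctions = ins.scan_donor_junctions(reads, plasmid, truth.donor_core_start)
junctions = ins.assign_flank_origin(junctions, [genome], [plasmid])
sites = ins.merge_and_call_sites(junctions, [genome])
for s in sites:
    ins.classify_site(s, truth.intended_target, truth.donor_site)
ins.apply_site_filters(sites)
ins.annotate_rep_overlap(sites, [genome])

print(f"{len(junctions)} junction reads -> {len(sites)} merged sites:")
for s in sites:
    print(f"  coord {s.coord}  reads {s.read_count:3d}  "
          f"freq {100 * s.freq:5.1f}%  {s.site_seq_11}  "
          f"lev(target)={s.lev_target}  {s.category}  "
          f"CT core={s.core_is_CT}  excluded={s.excluded}")
print("truth:", [(c, f) for c, f, _ in truth.sites])
print("freq = fraction of all assigned junction reads; lev = edit distance "
      "of the called 11-nt site to the intended target.")
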