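import numpy as np
import pytest

from bridgescan import insertion as ins
from bridgescan.seqio import SeqRecord, revcomp
from bridgescan.simulate import InsertionTruth, gen_toy_genome_and_reads

from conftest import levenshtein_dp, random_dna


@pytest.fixture(scope="module")
def clean_run():
    """Noise-free two-site experiment, fully called."""
    truth = InsertionTruth.random(1, genome_size=60_000, depth=120,
                                  error_rates=(0, 0, 0))
    genome, plasmid, reads, bed = gen_toy_genome_and_reads(truth)
    juncs = ins.scan_donor_junctions(reads, plasmid, truth.donor_core_start)
    juncs = ins.assign_flank_origin(juncs, [genome], [plasmid])
    sites = ins.merge_and_call_sites(juncs, [genome])
    for s in sites:
        ins.classify_site(s, truth.intended_target, truth.donor_site)
    return truth, genome, plasmid, reads, juncs, sites


def _mutate(s, positions):
    out = list(s)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestJunctionScan:
    def test_pure_genome_read_is_not_split(self, clean_run, rng):
        truth, genome, plasmid, *_ = clean_run
        read = SeqRecord("r", genome.seq[1000:1600])
        assert ins.scan_donor_junctions([read], plasmid,
                                        truth.donor_core_start) == []

    def test_mismatch_boundary_two_splits_three_does_not(self, clean_run):
        truth, genome, plasmid, *_ = clean_run
        left20, right20 = ins.donor_termini(plasmid, truth.donor_core_start)
        flank = genome.seq[500:800]
        for n_mm, expect in [(2, 1), (3, 0)]:
            read = SeqRecord("r", flank + _mutate(right20, range(n_mm))
                             + plasmid.seq[:200])
            found = ins.scan_donor_junctions([read], plasmid,
                                             truth.donor_core_start)
            assert len(found) == expect
            if expect:
                assert found[0].match_mismatches == n_mm
                assert found[0].split_pos == len(flank)

    def test_reverse_complement_read_found_once(self, clean_run):
        truth, genome, plasmid, *_ = clean_run
        left20, right20 = ins.donor_termini(plasmid, truth.donor_core_start)
        read = SeqRecord("r", revcomp(genome.seq[500:800] + right20
                                      + plasmid.seq[:200]))
        found = ins.scan_donor_junctions([read], plasmid,
                                         truth.donor_core_start)
        assert len(found) == 1 and found[0].donor_side == "5prime"

    def test_short_donor_rejected(self):
        with pytest.raises(ValueError):
            ins.donor_termini(SeqRecord("d", "ACGT" * 10), 20)


class TestFlankOrigin:
    def test_genome_flank_assigned_with_exact_coordinate(self, clean_run):
        truth, _, _, _, juncs, _ = clean_run
        truth_coords = {c for c, _, _ in truth.sites}
        assigned = [j for j in juncs if j.genome_coord is not None]
        assert len(assigned) >= 0.95 * len(juncs)
        assert {j.genome_coord for j in assigned} == truth_coords

    def test_plasmid_flank_assigned_plasmid(self, clean_run):
        truth, _, _, _, juncs, _ = clean_run
        for j in juncs[:20]:
            side = (j.flank_right_origin if j.donor_side == "5prime"
                    else j.flank_left_origin)
            assert side == "plasmid"

    def test_score_tie_stays_unassigned(self, rng):
        shared = random_dna(rng, 400)
        genome = [SeqRecord("g", shared + random_dna(rng, 400))]
        plasmid = [SeqRecord("p", shared + random_dna(rng, 400))]
        j = ins.JunctionRead("r", 0, "5prime", 0,
                             flank_genome_side=shared[:300],
                             flank_donor_side=random_dna(rng, 100))
        (out,) = ins.assign_flank_origin([j], genome, plasmid)
        assert out.flank_left_origin == "unassigned"
        assert out.genome_coord is None

    def test_empty_references_rejected(self):
        with pytest.raises(ValueError):
            ins.assign_flank_origin([], [], [SeqRecord("p", "ACGT" * 20)])


class TestMergeAndCall:
    def _junc(self, read_id, coord):
        return ins.JunctionRead(read_id, 0, "5prime", 0, "", "",
                                orientation="+", genome_contig="g",
                                genome_coord=coord)

    def test_nearby_coordinates_merge(self, genome_record):
        juncs = [self._junc(f"r{i}", c) for i, c in
                 enumerate([100, 103, 104])]
        sites = ins.merge_and_call_sites(juncs, [genome_record])
        assert len(sites) == 1 and sites[0].read_count == 3
        assert sites[0].coord == 100  # modal tie -> leftmost

    def test_gap_above_merge_dist_splits(self, genome_record):
        juncs = [self._junc(f"r{i}", c) for i, c in enumerate([100, 106])]
        sites = ins.merge_and_call_sites(juncs, [genome_record])
        assert sorted(s.coord for s in sites) == [100, 106]

    def test_modal_representative(self, genome_record):
        juncs = [self._junc(f"r{i}", c) for i, c in
                 enumerate([200, 202, 202, 203])]
        (site,) = ins.merge_and_call_sites(juncs, [genome_record])
        assert site.coord == 202

    def test_duplicate_read_coordinate_deduplicated(self, genome_record):
        juncs = [self._junc("same", 300), self._junc("same", 300)]
        (site,) = ins.merge_and_call_sites(juncs, [genome_record])
        assert site.read_count == 1

    def test_order_independence(self, genome_record, rng):
        coords = [100, 103, 104, 250, 251, 800]
        juncs = [self._junc(f"r{i}", c) for i, c in enumerate(coords)]
        a = ins.merge_and_call_sites(juncs, [genome_record])
        perm = [juncs[i] for i in rng.permutation(len(juncs))]
        b = ins.merge_and_call_sites(perm, [genome_record])
        assert [(s.coord, s.read_count) for s in a] == \
            [(s.coord, s.read_count) for s in b]

    def test_read_conservation_and_freq_sum(self, clean_run):
        *_, juncs, sites = clean_run
        n_assigned = len({(j.read_id, j.genome_coord) for j in juncs
                          if j.genome_coord is not None})
        assert sum(s.read_count for s in sites) == n_assigned
        assert sum(s.freq for s in sites) == pytest.approx(1.0)

    def test_calls_equal_truth_at_zero_noise(self, clean_run):
        truth, *_, sites = clean_run
        assert {s.coord for s in sites} == {c for c, _, _ in truth.sites}
        by_coord = {s.coord: s for s in sites}
        for coord, freq, seq in truth.sites:
            assert by_coord[coord].site_seq_11 == seq
            n = sum(s.read_count for s in sites)
            se = (freq * (1 - freq) / n) ** 0.5
            assert abs(by_coord[coord].freq - freq) < 4 * se + 1e-9


class TestClassifyAndFilters:
    def _site(self, **kw):
        base = dict(contig="g", coord=0, strand="+", read_count=1,
                    freq=0.5, site_seq_11="ATCAGGCCTAC",
                    site_seq_14="ATCAGGCCTACAAA")
        base.update(kw)
        return ins.InsertionSite(**base)

    def test_natural_vs_guide_encoded_target_single_mismatch_at_4(self):
        site = self._site(site_seq_11="ATCAGGCCTAC")
        ins.classify_site(site, "ATCGGGCCTAC", "GGGGGGGGGGG")
        assert site.lev_target == 1
        diff = [i + 1 for i, (a, b) in
                enumerate(zip("ATCAGGCCTAC", "ATCGGGCCTAC")) if a != b]
        assert diff == [4]
        assert site.category == "target_like"
        assert site.core_is_CT

    def test_identical_is_on_target(self):
        site = self._site()
        ins.classify_site(site, "ATCAGGCCTAC", "GGGGGGGGGGG")
        assert site.lev_target == 0 and site.category == "on_target"

    def test_levenshtein_agrees_with_dp_oracle(self, rng):
        for _ in range(1000):
            a = random_dna(rng, 11)
            b = random_dna(rng, 11)
            assert ins.levenshtein(a, b) == levenshtein_dp(a, b)

    def test_rule1_low_freq_far_clipped_excluded(self):
        site = self._site(freq=0.005, site_seq_11="GGGGGGGGGGG",
                          clipped_fraction=0.30)
        ins.classify_site(site, "ATCAGGCCTAC", "TTTTTTTTTTT")
        ins.apply_site_filters([site])
        assert site.excluded and "low_quality" in site.filter_flags

    def test_rule1_needs_all_three_conditions(self):
        # high frequency rescues an otherwise-bad site
        site = self._site(freq=0.02, site_seq_11="GGGGGGGGGGG",
                          clipped_fraction=0.30)
        ins.classify_site(site, "ATCAGGCCTAC", "TTTTTTTTTTT")
        ins.apply_site_filters([site])
        assert not site.excluded
        # low clipping rescues
        site2 = self._site(freq=0.005, site_seq_11="GGGGGGGGGGG",
                           clipped_fraction=0.10)
        ins.classify_site(site2, "ATCAGGCCTAC", "TTTTTTTTTTT")
        ins.apply_site_filters([site2])
        assert not site2.excluded

    def test_rule2_cross_sample_contamination(self):
        focal = self._site(coord=500, freq=0.002,
                           site_seq_11="GGGGGGGGGGG", clipped_fraction=0.10)
        ins.classify_site(focal, "ATCAGGCCTAC", "TTTTTTTTTTT")
        other = self._site(coord=500, freq=0.03, site_seq_11="ATCAGGCCTAT")
        ins.classify_site(other, "ATCAGGCCTAC", "TTTTTTTTTTT")
        ins.apply_site_filters([focal], {"sampleB": [other]})
        assert focal.excluded
        assert any(f.startswith("cross_sample") for f in focal.filter_flags)

    def test_filtered_sites_retained_in_output(self):
        site = self._site(freq=0.005, site_seq_11="GGGGGGGGGGG",
                          clipped_fraction=0.30)
        ins.classify_site(site, "ATCAGGCCTAC", "TTTTTTTTTTT")
        out = ins.apply_site_filters([site])
        assert out == [site]


class TestKmerNull:
    def test_offtarget_equal_to_target_is_14(self):
        t = "ATCAGGCCTACGGA"
        obs, null, p = ins.kmer_match_null([t], t, "G" * 14, n_shuffle=100,
                                           seed=0)
        assert obs == [14]

    def test_null_self_consistency_on_random_sequences(self, rng):
        offs = [random_dna(rng, 14) for _ in range(30)]
        obs, null, p = ins.kmer_match_null(offs, random_dna(rng, 14),
                                           random_dna(rng, 14),
                                           n_shuffle=200, seed=1)
        # random sequences are themselves draws from the shuffle null
        assert abs(np.mean(obs) - null.mean()) < 3 * null.std() + 0.3
        assert p > 0.01

    def test_planted_shared_8mer_detected(self, rng):
        donor = random_dna(rng, 14)
        offs = []
        for _ in range(50):
            s = random_dna(rng, 14)
            pos = int(rng.integers(0, 7))
            dpos = int(rng.integers(0, 7))
            offs.append(s[:pos] + donor[dpos : dpos + 8] + s[pos + 8 :])
        obs, null, p = ins.kmer_match_null(offs, random_dna(rng, 14), donor,
                                           n_shuffle=200, seed=2)
        assert np.median(obs) >= 8
        assert p < 0.05

    def test_length_checked_and_small_shuffle_warns(self):
        with pytest.raises(ValueError):
            ins.kmer_match_null(["ACGT"], "A" * 14, "C" * 14)
        with pytest.warns(UserWarning):
            ins.kmer_match_null(["A" * 14], "A" * 14, "C" * 14, n_shuffle=99)


class TestRepAnnotation:
    def test_planted_rep_copies_detected(self, rng):
        g = list(random_dna(rng, 20_000))
        rep = ins.REP_QUERIES[0]
        g[2000 : 2000 + len(rep)] = rep
        degraded = _mutate(rep, [5, 20])       # 2 substitutions: 0.94 id
        g[9000 : 9000 + len(rep)] = degraded
        genome = [SeqRecord("g", "".join(g))]
        sites = [ins.InsertionSite("g", c, "+", 1, 0.5, "A" * 11, "A" * 14)
                 for c in (2010, 9005, 15000)]
        ins.annotate_rep_overlap(sites, genome)
        assert [s.rep_overlap for s in sites] == [True, True, False]

    def test_rep_free_genome_all_false(self, rng):
        genome = [SeqRecord("g", random_dna(rng, 10_000))]
        sites = [ins.InsertionSite("g", 500, "+", 1, 1.0, "A" * 11, "A" * 14)]
        ins.annotate_rep_overlap(sites, genome)
        assert not sites[0].rep_overlap


class TestDownsample:
    def _reads(self, n, length, rng):
        return [SeqRecord(f"r{i}", random_dna(rng, length)) for i in range(n)]

    def test_arithmetic(self, rng):
        reads = self._reads(1000, 1000, rng)
        kept = ins.downsample_reads(reads, 5, 100_000, seed=1)
        assert len(kept) == 500

    def test_target_at_or_above_available_keeps_all(self, rng):
        reads = self._reads(10, 100, rng)
        with pytest.warns(UserWarning):
            kept = ins.downsample_reads(reads, 100, 10_000, seed=1)
        assert len(kept) == 10

    def test_deterministic_under_seed(self, rng):
        reads = self._reads(100, 200, rng)
        a = ins.downsample_reads(reads, 5, 2000, seed=7)
        b = ins.downsample_reads(reads, 5, 2000, seed=7)
        assert [r.id for r in a] == [r.id for r in b]
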