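"""Filtering and matching rules of the read-processing pipeline."""

import random
from collections import defaultdict

import numpy as np
import pytest

from flipkit import readproc, synthdata
from flipkit.readproc import (
    SiteDefinitions,
    VariantProfile,
    apply_read_threshold,
    build_profiles,
    call_discriminator_state,
    demultiplex,
    extract_rbs,
    filter_ambiguous,
    filter_cds_mutants,
    hamming,
    load_index_table,
    match_constant_region,
)


class TestAmbiguityFilter:
    @pytest.mark.parametrize(
        "read,keep",
        [
            ("ACGT" + "N" * 7 + "ACGT", False),   # more than six consecutive
            ("ACGT" + "N" * 6 + "ACGT", True),    # exactly six is permitted
            ("ACGTACGTACGT", True),
            ("N" * 6 + "A" + "N" * 6, True),      # runs broken by a base
        ],
    )
    def test_boundary(self, read, keep):
        assert filter_ambiguous(read) is keep


class TestConstantRegion:
    def test_exact_match_offset(self, sites):
        read = "TTTTT" + sites.constant_region + "AAAAA"
        assert match_constant_region(read, sites) == 5

    def test_three_mismatches_allowed(self, sites):
        mutated = "TAGCTCGCAA"  # 2 substitutions of GAGCTCGCAT
        mutated = "TAGCTCGGAA"  # 3 substitutions
        assert hamming(mutated, sites.constant_region) == 3
        read = "CCCC" + mutated + "CCCC"
        assert match_constant_region(read, sites) == 4

    def test_four_mismatches_rejected(self, sites):
        mutated = "TTGCTCGGAA"  # 4 substitutions
        assert hamming(mutated, sites.constant_region) == 4
        read = "CCCCC" + mutated + "CCCCC"
        # independent check: no 10-mer window of the read is within 3
        dists = [
            hamming(read[i:i + 10], sites.constant_region)
            for i in range(len(read) - 9)
        ]
        assert min(dists) == 4
        assert match_constant_region(read, sites) is None

    def test_leftmost_tie_break(self, sites):
        read = sites.constant_region + sites.constant_region
        assert match_constant_region(read, sites) == 0


class TestDemultiplex:
    def test_lookup_and_missing(self):
        table = {("AAAAAA", "CCCCCC"): "t0"}
        assert demultiplex(("AAAAAA", "CCCCCC"), table) == "t0"
        assert demultiplex(("GGGGGG", "CCCCCC"), table) is None

    def test_duplicate_pair_rejected(self, tmp_path):
        p = tmp_path / "idx.tsv"
        p.write_text(
            "sample\tindex1\tindex2\n"
            "t0\tAAAAAA\tCCCCCC\n"
            "t1\tAAAAAA\tCCCCCC\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_index_table(p)


class TestDiscriminatorState:
    def test_exact_attP_is_unflipped(self, sites):
        read = "AAAA" + sites.attP_site + "TTTT"
        assert call_discriminator_state(read, sites) == "unflipped"

    def test_attR_with_two_substitutions_is_flipped(self, sites):
        site = list(sites.attR_site)
        site[2] = "T" if site[2] != "T" else "A"
        site[9] = "T" if site[9] != "T" else "A"
        read = "AAAA" + "".join(site) + "TTTT"
        assert call_discriminator_state(read, sites) == "flipped"

    def test_att_sites_far_apart(self, sites):
        # direct per-position comparison: no read can match both sites
        assert hamming(sites.attP_site, sites.attR_site) == 13
        assert hamming(sites.attP_site, sites.attR_site) > \
            2 * sites.max_mismatches

    def test_state_call_symmetry(self, sites):
        """Swapping attP and attR definitions swaps the two labels."""
        swapped = SiteDefinitions(
            attP_site=sites.attR_site, attR_site=sites.attP_site
        )
        rng = random.Random(5)
        for site in (sites.attP_site, sites.attR_site):
            read = "".join(rng.choice("ACGT") for _ in range(10)) + site
            a = call_discriminator_state(read, sites)
            b = call_discriminator_state(read, swapped)
            assert {a, b} == {"unflipped", "flipped"}

    def test_close_site_definitions_rejected(self):
        with pytest.raises(ValueError, match="unambiguous"):
            SiteDefinitions(attP_site="A" * 17, attR_site="A" * 13 + "CCCC")


class TestRbsExtraction:
    def test_direct_slice(self):
        rbs = "AAGGAGGTTAACTTAAG"
        read = "TTT" + rbs + "ATGCCC"
        assert extract_rbs(read, 20) == rbs

    def test_truncated_read_rejected(self):
        with pytest.raises(ValueError, match="10 bases upstream"):
            extract_rbs("ACGTACGTAC" + "ATG", 10)


class TestVariantFilters:
    def _profile(self, frac, counts=((25, 5),)):
        return VariantProfile(
            "A" * 17, {f"t{i}": c for i, c in enumerate(counts)}, frac
        )

    def test_cds_filter_boundaries(self):
        profiles = [self._profile(0.081), self._profile(0.08),
                    self._profile(0.0)]
        kept = filter_cds_mutants(profiles)
        assert [p.cds_mismatch_fraction for p in kept] == [0.08, 0.0]

    def test_read_threshold(self):
        nine_good = self._profile(0.0, ((15, 5),) * 9)
        one_low = self._profile(0.0, ((15, 5),) * 8 + ((14, 5),))
        kept = apply_read_threshold([nine_good, one_low], 20)
        assert kept == [nine_good]
        assert sum(u + f for u, f in nine_good.counts.values()) == 180
        assert apply_read_threshold([nine_good, one_low], 0) == \
            [nine_good, one_low]


def _write_pairs(tmp_path, records):
    r1, r2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
    synthdata.write_fastq(records, r1, r2)
    return r1, r2


class TestBuildProfiles:
    def test_processing_preserves_generated_counts_exactly(
        self, small_experiment, sites
    ):
        """With no sequencing errors the pipeline is lossless: the
        per-variant, per-sample counts equal the generated reads."""
        exp = small_experiment
        gen = defaultdict(lambda: [0, 0])
        for rec in synthdata.simulate_reads(exp["variants"], exp["config"]):
            vi, t = rec.read_id.split(":")[1:3]
            flipped = sites.attR_site in rec.reverse_seq
            gen[(int(vi), f"t{t}")][flipped] += 1
        profiles, stats = build_profiles(
            exp["r1"], exp["r2"], exp["indexes"], min_reads=0
        )
        assert stats.conserved()
        by_rbs = {p.rbs_sequence: p for p in profiles}
        for vi, var in enumerate(exp["variants"]):
            prof = by_rbs[var.rbs_sequence]
            for label in exp["config"].sample_labels():
                u, f = gen[(vi, label)]
                assert prof.counts.get(label, (0, 0)) == (u, f)

    def test_shuffled_input_gives_identical_profiles(
        self, tmp_path, small_experiment
    ):
        exp = small_experiment
        records = list(
            synthdata.simulate_reads(exp["variants"], exp["config"])
        )
        random.Random(0).shuffle(records)
        r1, r2 = _write_pairs(tmp_path, records)
        shuffled, _ = build_profiles(r1, r2, exp["indexes"], min_reads=1)
        original, _ = build_profiles(
            exp["r1"], exp["r2"], exp["indexes"], min_reads=1
        )
        assert {p.rbs_sequence: p.counts for p in shuffled} == \
            {p.rbs_sequence: p.counts for p in original}

    def test_broken_constant_region_drops_everything(
        self, tmp_path, sites
    ):
        var = synthdata.GroundTruthVariant(
            "ACGTACGTACGTACGTA", (0.5, 1.0, -200.0, 1.0), 30.0
        )
        cfg = synthdata.SimConfig(
            n_variants=1, substitution_error_rate=0.0, seed=2,
            depth_lognormal_params=(np.log(30.0), 0.0),
        )
        records = []
        for rec in synthdata.simulate_reads([var], cfg):
            bad = rec.reverse_seq.replace(sites.constant_region, "TTTTTTTTTT")
            records.append(
                synthdata.ReadPairRecord(rec.read_id, rec.forward_seq, bad)
            )
        r1, r2 = _write_pairs(tmp_path, records)
        profiles, stats = build_profiles(
            r1, r2, cfg.index_table(), min_reads=1
        )
        assert profiles == []
        assert stats.no_constant_region == len(records)
        assert stats.conserved()

    def test_zero_flipped_gives_fraction_zero(self, tmp_path):
        var = synthdata.GroundTruthVariant(
            "ACGTACGTACGTACGTA", (0.0, 1.0, 300.0, 1.0), 40.0
        )
        cfg = synthdata.SimConfig(
            n_variants=1, sampling_times=(0,), substitution_error_rate=0.0,
            depth_lognormal_params=(np.log(40.0), 0.0), seed=4,
        )
        records = list(synthdata.simulate_reads([var], cfg))
        r1, r2 = _write_pairs(tmp_path, records)
        profiles, _ = build_profiles(r1, r2, cfg.index_table(), min_reads=1)
        assert len(profiles) == 1
        assert profiles[0].fraction_flipped("t0") == 0.0

    def test_corrupted_reads_are_filtered_and_counted(self, tmp_path):
        cfg = synthdata.SimConfig(
            n_variants=10, substitution_error_rate=0.0,
            corrupt_fraction=0.2, seed=8,
            depth_lognormal_params=(np.log(60.0), 0.0),
        )
        variants = synthdata.sample_library(cfg)
        r1, r2 = _write_pairs(
            tmp_path, synthdata.simulate_reads(variants, cfg)
        )
        _, stats = build_profiles(r1, r2, cfg.index_table(), min_reads=1)
        assert stats.ambiguous > 0           # injected long N runs
        assert stats.conserved()

    def test_slow_and_fast_paths_agree(self, tmp_path, small_experiment):
        """Mixed-length input falls back to the per-read path; its output
        must match the vectorized uniform-length path."""
        exp = small_experiment
        records = list(
            synthdata.simulate_reads(exp["variants"], exp["config"])
        )[:500]
        # appending one longer read pair forces the per-read path
        longer = synthdata.ReadPairRecord(
            "sim:extra", records[0].forward_seq + "A",
            records[0].reverse_seq + "A",
        )
        (tmp_path / "a").mkdir()
        (tmp_path / "b").mkdir()
        r1a, r2a = _write_pairs(tmp_path / "a", records)
        r1b, r2b = _write_pairs(tmp_path / "b", records + [longer])
        pa, _ = build_profiles(r1a, r2a, exp["indexes"], min_reads=1)
        pb, _ = build_profiles(r1b, r2b, exp["indexes"], min_reads=1)
        counts_a = {p.rbs_sequence: p.counts for p in pa}
        counts_b = {p.rbs_sequence: p.counts for p in pb}
        # the extra read adds at most one count to one variant
        total_a = sum(u + f for c in counts_a.values() for u, f in c.values())
        total_b = sum(u + f for c in counts_b.values() for u, f in c.values())
        assert total_b - total_a in (0, 1)
        assert set(counts_a) <= set(counts_b)
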