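"""Synthetic-data generator: planted structures, noise models, determinism."""

import edlib
import numpy as np
import pytest
from Bio.Seq import reverse_complement

from teloforge.label_io import digest
from teloforge.simulate import (
    ConfigurationError, EndEvent, NoiseParams, Placement, SimConfig,
    apply_end_event, default_config, emit_segdup_table, segdup_table_from_truth,
    simulate_contig_maps, simulate_long_reads, simulate_reference,
    simulate_terminal_read, simulate_trio,
)

NOISE_FREE = NoiseParams(0, 0, 0, 0, 0)


def small_config(**kw):
    kw.setdefault("n_chromosomes", 2)
    kw.setdefault("chrom_length", 120_000)
    kw.setdefault("placements", [])
    kw.setdefault("divergence_schedule", [])
    return SimConfig(**kw)


class TestSimulateReference:
    def test_no_placements_pure_random(self):
        genome, truth = simulate_reference(small_config(seed=5))
        assert set(genome) == {"chr1", "chr2"}
        assert all(len(s) == 120_000 for s in genome.values())
        assert truth.members == []

    def test_zero_divergence_copies_identical(self):
        cfg = small_config(
            placements=[
                Placement(0, "chr1", "q", 5_000),
                Placement(0, "chr2", "q", 5_000),
                Placement(0, "chr2", "p", 5_000),
            ],
            divergence_schedule=[0.0],
            seed=5,
        )
        genome, truth = simulate_reference(cfg)
        seqs = []
        for m in truth.members:
            s = genome[m.chrom][m.start:m.end]
            seqs.append(reverse_complement(s) if m.strand == "-" else s)
            # subtelomeric copies sit within their arm's terminal window
            if m.arm == "q":
                assert m.end > cfg.chrom_length - 20_000
            elif m.arm == "p":
                assert m.start < 20_000
        assert len(set(seqs)) == 1
        assert seqs[0] == truth.family_units[0]

    def test_divergence_matches_binomial_oracle(self):
        d = 0.01
        cfg = small_config(
            placements=[Placement(0, "chr1", "q", 5_000)],
            divergence_schedule=[d],
            seed=6,
        )
        genome, truth = simulate_reference(cfg)
        m = truth.members[0]
        copy = genome[m.chrom][m.start:m.end]
        unit = truth.family_units[0]
        mismatches = sum(a != b for a, b in zip(copy, unit))
        n = len(unit)
        sd = np.sqrt(n * d * (1 - d))
        assert abs(mismatches - n * d) <= 3 * sd

    def test_out_of_bounds_placement_rejected(self):
        cfg = small_config(placements=[Placement(0, "chr1", "q", 119_000)])
        with pytest.raises(ConfigurationError, match="bounds"):
            simulate_reference(cfg)

    def test_overlapping_placements_rejected(self):
        cfg = small_config(
            placements=[Placement(0, "chr1", "q", 5_000), Placement(0, "chr1", "q", 6_000)]
        )
        with pytest.raises(ConfigurationError, match="overlap"):
            simulate_reference(cfg)

    def test_seed_determinism(self):
        g1, t1 = simulate_reference(default_config(n_chromosomes=2, chrom_length=400_000, seed=9))
        g2, t2 = simulate_reference(default_config(n_chromosomes=2, chrom_length=400_000, seed=9))
        assert g1 == g2
        assert [vars(a) for a in t1.members] == [vars(b) for b in t2.members]


class TestApplyEndEvent:
    @pytest.fixture
    def reference(self):
        genome, _ = simulate_reference(small_config(seed=7))
        return genome

    def test_zero_length_deletion_is_identity(self, reference):
        e = EndEvent("terminal_deletion", ("chr1", "q"), 0)
        assert apply_end_event(reference["chr1"], e, reference) == reference["chr1"]

    def test_tandem_expansion_length_arithmetic(self, reference):
        e = EndEvent("tandem_expansion", ("chr1", "q"), 11_000, copies=4)
        out = apply_end_event(reference["chr1"], e, reference)
        assert len(out) == len(reference["chr1"]) + 3 * 11_000
        unit = reference["chr1"][-11_000:]
        assert out[-44_000:] == unit * 4

    def test_tandem_single_copy_is_identity(self, reference):
        e = EndEvent("tandem_expansion", ("chr1", "q"), 11_000, copies=1)
        assert apply_end_event(reference["chr1"], e, reference) == reference["chr1"]

    def test_extension_substring_oracle_q_from_p(self, reference):
        # q-arm extension copying a p-arm terminus: the new distal 20 kb is
        # the reverse complement of the donor's first 20 kb
        e = EndEvent(
            "extension_by_duplication", ("chr2", "q"), 20_000, donor=("chr1", "p")
        )
        out = apply_end_event(reference["chr2"], e, reference)
        assert out[:-20_000] == reference["chr2"]
        assert out[-20_000:] == reverse_complement(reference["chr1"][:20_000])

    def test_extension_on_p_arm_mirrors(self, reference):
        e = EndEvent(
            "extension_by_duplication", ("chr2", "p"), 15_000, donor=("chr1", "q")
        )
        out = apply_end_event(reference["chr2"], e, reference)
        assert out[15_000:] == reference["chr2"]
        assert out[:15_000] == reverse_complement(reference["chr1"][-15_000:])

    def test_deletion_removes_distal_bases(self, reference):
        e = EndEvent("terminal_deletion", ("chr1", "p"), 5_000)
        out = apply_end_event(reference["chr1"], e, reference)
        assert out == reference["chr1"][5_000:]

    def test_oversized_event_rejected(self, reference):
        e = EndEvent("terminal_deletion", ("chr1", "q"), 500_000)
        with pytest.raises(ConfigurationError):
            apply_end_event(reference["chr1"], e, reference)


class TestSimulateTrio:
    @pytest.fixture
    def reference(self):
        genome, _ = simulate_reference(small_config(seed=8))
        return genome

    def test_empty_events_child_identical_to_parents(self, reference):
        father, mother, child, truth = simulate_trio(reference, [], seed=1)
        pf, pm = truth.inheritance["c1"], truth.inheritance["c2"]
        assert child["c1"] == {**father, **mother}[pf]
        assert child["c2"] == {**father, **mother}[pm]

    def test_transmitted_extension_identical(self, reference):
        ev = EndEvent(
            "extension_by_duplication", ("chr2", "q"), 50_000,
            donor=("chr1", "p"), carrier="f1",
        )
        father, mother, child, truth = simulate_trio(reference, [ev], seed=1)
        assert len(father["f1"]["chr2"]) == 170_000
        if truth.inheritance["c1"] == "f1":
            assert child["c1"]["chr2"] == father["f1"]["chr2"]
        else:
            assert child["c1"]["chr2"] == reference["chr2"]

    def test_heterozygous_child_configuration(self, reference):
        """Extended allele from one side, reference from the other."""
        ev = EndEvent(
            "extension_by_duplication", ("chr2", "q"), 30_000,
            donor=("chr1", "p"), carrier="c1",
        )
        _, _, child, truth = simulate_trio(reference, [ev], seed=2)
        assert len(child["c1"]["chr2"]) == 150_000
        assert child["c2"]["chr2"] == reference["chr2"]
        assert truth.expected_status("c1", "chr2", "q", 25_000) == "extension"
        assert truth.expected_status("c2", "chr2", "q", 25_000) == "reference"

    def test_conflicting_events_rejected(self, reference):
        evs = [
            EndEvent("terminal_deletion", ("chr1", "q"), 1000, carrier="f1"),
            EndEvent("tandem_expansion", ("chr1", "q"), 500, copies=2, carrier="f1"),
        ]
        with pytest.raises(ConfigurationError, match="conflict"):
            simulate_trio(reference, evs, seed=1)


class TestContigMaps:
    def test_noise_free_equals_digestion(self):
        genome, _ = simulate_reference(small_config(seed=10))
        maps = simulate_contig_maps(genome, "GCTCTTC", NOISE_FREE, seed=1)
        for m in maps:
            assert m.labels.tolist() == digest(genome[m.meta["source"]], "GCTCTTC").tolist()
            assert m.length == len(genome[m.meta["source"]])

    def test_fn_rate_one_drops_everything(self):
        genome, _ = simulate_reference(small_config(seed=10))
        maps = simulate_contig_maps(
            genome, "GCTCTTC", NoiseParams(0, 0, 0, 1.0, 0), seed=1
        )
        assert all(m.n_labels == 0 for m in maps)

    def test_fn_retention_matches_binomial_oracle(self):
        cfg = small_config(n_chromosomes=1, chrom_length=2_000_000, seed=11)
        genome, _ = simulate_reference(cfg)
        n_true = digest(genome["chr1"], "GCTCTTC").size
        fn = 0.06
        maps = simulate_contig_maps(
            genome, "GCTCTTC", NoiseParams(0, 0, 0, fn, 0), seed=2
        )
        kept = maps[0].n_labels
        expect = n_true * (1 - fn)
        sd = np.sqrt(n_true * fn * (1 - fn))
        assert abs(kept - expect) <= 3 * sd

    def test_empty_genome_empty_list(self):
        assert simulate_contig_maps({}, "GCTCTTC", NOISE_FREE, seed=1) == []


class TestLongReads:
    @pytest.fixture
    def genome(self):
        genome, _ = simulate_reference(small_config(seed=12))
        return genome

    def test_error_free_reads_are_exact_substrings(self, genome):
        reads = simulate_long_reads(genome, 20, 10_000, 1_000, 0.0, seed=3)
        joined = {c: s for c, s in genome.items()}
        for r in reads:
            src = joined[r.chrom][r.start:r.end]
            assert r.sequence == (src if r.strand == "+" else reverse_complement(src))

    def test_error_rate_reflected_in_edit_distance(self, genome):
        e = 0.1
        reads = simulate_long_reads(genome, 10, 20_000, 5_000, e, seed=4)
        for r in reads:
            src = genome[r.chrom][r.start:r.end]
            if r.strand == "-":
                src = reverse_complement(src)
            dist = edlib.align(r.sequence, src)["editDistance"]
            n = len(src)
            sd = np.sqrt(n * e * (1 - e))
            assert abs(dist - n * e) <= 4 * sd

    def test_terminal_read_ends_at_chromosome_end(self, genome):
        r = simulate_terminal_read(genome, "chr1", "q", 30_000)
        assert r.sequence == genome["chr1"][-30_000:]
        assert r.end == len(genome["chr1"])
        rp = simulate_terminal_read(genome, "chr1", "p", 30_000)
        assert rp.sequence == reverse_complement(genome["chr1"][:30_000])


class TestSegdupTable:
    def test_empty_members(self):
        assert len(emit_segdup_table([])) == 0

    def test_pair_count_quadratic(self):
        cfg = default_config(n_chromosomes=5, chrom_length=5_000_000, seed=13)
        genome, truth = simulate_reference(cfg)
        fam0 = [m for m in truth.members if m.family == 0]
        assert len(fam0) == 16
        table = emit_segdup_table(truth.members)
        per_family = 16 * 15 // 2
        assert len(table) == 2 * per_family  # 120 records per 16-member family
        both = emit_segdup_table(truth.members, both_orders=True)
        assert len(both) == 4 * per_family

    def test_two_members_single_record_matches_truth(self):
        cfg = small_config(
            placements=[Placement(0, "chr1", "q", 5_000), Placement(0, "chr2", "q", 5_000)],
            divergence_schedule=[0.001],
            seed=14,
        )
        genome, truth = simulate_reference(cfg)
        table = emit_segdup_table(truth.members)
        assert len(table) == 1
        row = table.iloc[0]
        a, b = truth.members
        assert (row.chromA, row.startA, row.endA) == (a.chrom, a.start, a.end)
        assert (row.chromB, row.startB, row.endB) == (b.chrom, b.start, b.end)
        assert 0.9 < row.identity <= 1.0

    def test_measured_identity_close_to_schedule(self):
        cfg = small_config(
            placements=[Placement(0, "chr1", "q", 5_000), Placement(0, "chr2", "q", 5_000)],
            divergence_schedule=[0.004],
            seed=15,
        )
        genome, truth = simulate_reference(cfg)
        table = segdup_table_from_truth(truth, genome=genome)
        # two copies each mutated at 0.4%: expected identity ~ 1 - 0.008
        assert table.iloc[0].identity == pytest.approx(0.992, abs=0.004)
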