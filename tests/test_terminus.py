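"""Terminus anchoring, extension/missing calling, classification, trio logic."""

import numpy as np
import pytest

from teloforge.alignment import AlignmentParams, align
from teloforge.label_io import LabelMap, LabelStats, digest, merge_labels
from teloforge.simulate import (
    EndEvent, NoiseParams, Placement, SimConfig, apply_end_event,
    simulate_contig_maps, simulate_reference,
)
from teloforge.terminus import (
    anchor_terminus, call_terminus, classify_extension, compute_threshold,
    detect_diploid, terminal_window_map, trio_inheritance,
)

PARAMS = AlignmentParams(max_skip=6)


class TestComputeThreshold:
    def test_printed_spacing_gives_printed_threshold(self):
        model = compute_threshold(LabelStats(8.2, 8.3, 1000, 0))
        assert model.reported == 33.1

    def test_zero_variance(self):
        assert compute_threshold(LabelStats(10.0, 0.0, 10, 0)).threshold == 10.0

    def test_custom_k(self):
        assert compute_threshold(LabelStats(5.0, 2.0, 10, 0), k=2).threshold == 9.0

    def test_unrounded_internally(self):
        model = compute_threshold(LabelStats(8.21, 8.33, 10, 0))
        assert model.threshold == pytest.approx(8.21 + 3 * 8.33)
        assert model.reported == round(model.threshold, 1)


def _self_alignment(labels, length, ref_id="chr1", qid="contig"):
    ref = LabelMap(ref_id, length, np.asarray(labels, dtype=float))
    qry = LabelMap(qid, length, np.asarray(labels, dtype=float))
    (a,) = align(qry, ref, PARAMS)[:1]
    return a, qry, ref


class TestCallTerminus:
    def test_identity_gives_exact_zero_both_arms(self):
        labels = [5_000, 13_000, 22_000, 30_500, 41_000]
        a, qry, ref = _self_alignment(labels, 50_000.0)
        for arm in "pq":
            call = call_terminus(a, qry, ref, arm, threshold_bp=33_100)
            assert call.status == "reference"
            assert call.extension_len == 0.0
            assert call.missing_len == 0.0

    def test_distal_overhang_measured_exactly(self):
        # contig continues 50 kb past a reference whose last label it matches
        ref_labels = np.array([5_000.0, 13_000.0, 22_000.0, 30_500.0, 41_000.0])
        ref = LabelMap("chr1", 45_000.0, ref_labels)
        qry_labels = np.concatenate([ref_labels, [52_000.0, 63_000.0, 71_000.0]])
        qry = LabelMap("contig", 95_000.0, qry_labels)
        (a,) = align(qry, ref, PARAMS)[:1]
        call = call_terminus(a, qry, ref, "q", threshold_bp=33_100)
        # D_q = 95000 - 41000 = 54000, ref tail D_r = 4000 -> 50000 net
        assert call.status == "extension"
        assert call.extension_len == pytest.approx(50_000.0)
        assert call.missing_len == 0.0

    def test_missing_with_ngap_subtraction(self):
        # reference last 60 kb beyond the final matched label with a 30 kb
        # N-gap inside: missing is gap-corrected to 30 kb, below threshold
        ref = LabelMap(
            "chr1", 100_000.0, np.array([5_000.0, 20_000.0, 40_000.0])
        )
        qry = LabelMap("contig", 41_000.0, np.array([5_000.0, 20_000.0, 40_000.0]))
        (a,) = align(qry, ref, PARAMS)[:1]
        call = call_terminus(
            a, qry, ref, "q", threshold_bp=33_100, ngaps=[(60_000.0, 90_000.0)]
        )
        assert call.missing_len == pytest.approx(60_000 - 30_000 - 1_000)
        assert call.status == "reference"

    def test_terminal_deletion_measures_planted_length(self):
        ref_labels = np.array([5_000.0, 13_000.0, 22_000.0, 29_500.0, 41_000.0, 47_000.0])
        ref = LabelMap("chr1", 50_000.0, ref_labels)
        # haplotype lost its distal 20 kb: labels at 41k/47k gone
        qry = LabelMap("contig", 30_000.0, ref_labels[:4])
        (a,) = align(qry, ref, PARAMS)[:1]
        call = call_terminus(a, qry, ref, "q", threshold_bp=15_000)
        assert call.status == "missing"
        assert call.missing_len == pytest.approx(20_000.0, abs=1500)

    def test_divergent_both_sides_reports_both(self):
        # reference has distal labels the contig lacks AND the contig has a
        # distal labelled overhang: both sizes reported independently
        shared = np.array([5_000.0, 13_000.0, 22_000.0, 30_500.0])
        ref = LabelMap(
            "chr1", 120_000.0,
            np.concatenate([shared, [45_000.0, 60_000.0, 80_000.0, 100_000.0]]),
        )
        qry = LabelMap(
            "contig", 120_000.0,
            np.concatenate([shared, [38_000.0, 55_000.0, 76_000.0, 99_000.0]]),
        )
        params = AlignmentParams(max_skip=6, sd_fixed=200.0, min_labels=3)
        hits = align(qry, ref, params)
        best = hits[0]
        assert max(j for _, j in best.pairs) == 3  # only the shared block aligns
        call = call_terminus(best, qry, ref, "q", threshold_bp=33_100)
        assert call.status == "extension_and_missing"
        assert call.extension_len == pytest.approx(120_000 - 30_500)
        assert call.missing_len == pytest.approx(120_000 - 30_500)

    def test_threshold_monotonicity_in_k(self):
        """Raising k never converts a reference call into extension/missing."""
        labels = [5_000, 13_000, 22_000, 30_500, 41_000]
        a, qry, ref = _self_alignment(labels, 50_000.0)
        stats = LabelStats(8.2, 8.3, 100, 0)
        statuses = [
            call_terminus(
                a, qry, ref, "q", compute_threshold(stats, k).threshold_bp
            ).status
            for k in (1, 2, 3, 5, 10)
        ]
        assert statuses == ["reference"] * 5


class TestAnchorTerminus:
    def _aln(self, qid, ref, labels, score=None):
        qry = LabelMap(qid, float(labels[-1] + 2000), np.asarray(labels, dtype=float))
        hits = align(qry, ref, PARAMS)
        return qry, hits[0]

    def test_distality_dominates_score(self):
        ref = LabelMap(
            "chr1", 200_000.0,
            np.array([10_000.0, 30_000.0, 50_000.0, 80_000.0, 120_000.0,
                      145_000.0, 170_000.0, 190_000.0]),
        )
        # contig A matches a long proximal block, contig B a shorter block
        # reaching the most distal label
        qa, aa = self._aln("A", ref, [10_000, 30_000, 50_000, 80_000, 120_000])
        qb, ab = self._aln("B", ref, [120_000, 145_000, 170_000, 190_000])
        assert aa.score > ab.score
        best = anchor_terminus([aa, ab], "chr1", "q", ref, {"A": qa, "B": qb})
        assert best.query_id == "B"

    def test_score_breaks_distality_ties(self):
        ref = LabelMap(
            "chr1", 100_000.0,
            np.array([10_000.0, 30_000.0, 52_000.0, 75_000.0, 95_000.0]),
        )
        qa, aa = self._aln("A", ref, [10_000, 30_000, 52_000, 75_000, 95_000])
        qb, ab = self._aln("B", ref, [30_500, 52_000, 74_000, 95_500])
        assert aa.score > ab.score
        best = anchor_terminus([aa, ab], "chr1", "q", ref, {"A": qa, "B": qb})
        assert best.query_id == "A"

    def test_no_candidates_returns_none(self, rng):
        labels = np.sort(rng.uniform(2e6, 8e6, 20))
        ref = LabelMap("chr1", 1e7, labels)
        qa, aa = self._aln("A", ref, labels[:8].tolist())
        assert anchor_terminus([aa], "chr1", "q", ref, {"A": qa}) is None
        assert anchor_terminus([], "chr1", "q", ref) is None


class TestClassifyExtension:
    @pytest.fixture
    def planted(self):
        cfg = SimConfig(
            n_chromosomes=3, chrom_length=400_000,
            placements=[], divergence_schedule=[], seed=21,
        )
        genome, _ = simulate_reference(cfg)
        ev = EndEvent(
            "extension_by_duplication", ("chr2", "q"), 50_000, donor=("chr1", "p")
        )
        hap = dict(genome)
        hap["chr2"] = apply_end_event(genome["chr2"], ev, genome)
        refs = {
            n: LabelMap(n, float(len(s)), merge_labels(digest(s, cfg.enzyme_motif), 450))
            for n, s in genome.items()
        }
        contigs = simulate_contig_maps(
            {"c_chr2": hap["chr2"]}, cfg.enzyme_motif, NoiseParams(0, 0, 0, 0, 0), 1
        )
        cm = LabelMap("c_chr2", contigs[0].length, merge_labels(contigs[0].labels, 450))
        return refs, cm

    def test_planted_duplicative_extension_is_category_1_with_origin(self, planted):
        refs, cm = planted
        (a,) = align(cm, refs["chr2"], PARAMS)[:1]
        call = call_terminus(a, cm, refs["chr2"], "q", threshold_bp=33_100)
        assert call.status == "extension"
        call = classify_extension(call, cm, list(refs.values()), PARAMS)
        assert call.category == 1
        assert (call.origins[0].chrom, call.origins[0].arm) == ("chr1", "p")
        assert call.origins[0].span[0] < 5_000  # reaches the donor tip

    def test_novel_random_extension_is_category_2(self, rng):
        # labelled overhang with random spacings homologous to nothing
        ref = LabelMap("chr1", 100_000.0, np.array([10_000.0, 30_000.0, 52_000.0, 75_000.0, 95_000.0]))
        qry = LabelMap(
            "c", 180_000.0,
            np.array([10_000.0, 30_000.0, 52_000.0, 75_000.0, 95_000.0,
                      101_234.0, 132_600.0, 138_777.0, 171_001.0]),
        )
        (a,) = align(qry, ref, PARAMS)[:1]
        call = call_terminus(a, qry, ref, "q", threshold_bp=33_100)
        assert call.status == "extension"
        call = classify_extension(call, qry, [ref], PARAMS)
        assert call.category == 2

    def test_too_few_extension_labels_flagged(self):
        ref = LabelMap("chr1", 100_000.0, np.array([10_000.0, 30_000.0, 52_000.0, 75_000.0, 95_000.0]))
        qry = LabelMap(
            "c", 180_000.0,
            np.array([10_000.0, 30_000.0, 52_000.0, 75_000.0, 95_000.0, 140_000.0]),
        )
        (a,) = align(qry, ref, PARAMS)[:1]
        call = call_terminus(a, qry, ref, "q", threshold_bp=33_100)
        call = classify_extension(call, qry, [ref], PARAMS)
        assert call.category == 2
        assert "too_few_labels" in call.flags


class TestTrioAndDiploid:
    def _contig(self, cid, labels, length):
        return LabelMap(cid, float(length), np.asarray(labels, dtype=float))

    def test_identical_child_and_mother(self):
        labels = [5_000, 13_000, 22_000, 30_500, 41_000]
        child = self._contig("c", labels, 50_000)
        mother = self._contig("m", labels, 50_000)
        father = self._contig("f", [5_000, 13_000, 22_000, 30_500, 41_000, 60_000, 72_000, 81_000, 95_000], 100_000)
        tc = trio_inheritance((child, True), (father, True), (mother, True))
        assert tc.diff_mother == 0
        assert tc.parent_of_origin == "mother"

    def test_single_terminal_label_difference_within_tolerance(self):
        labels = [5_000.0, 13_000.0, 22_000.0, 30_500.0, 41_000.0]
        child = self._contig("c", labels, 50_000)
        father = self._contig("f", labels + [47_000.0], 50_000)  # one extra distal label
        mother = self._contig("m", [4_000.0, 11_000.0, 19_500.0, 33_000.0, 44_500.0, 47_000.0, 49_000.0], 50_000)
        tc = trio_inheritance((child, True), (father, True), (mother, True))
        assert tc.diff_father == 1
        assert tc.diff_mother > 1
        assert tc.parent_of_origin == "father"

    def test_neither_parent_within_tolerance(self):
        child = self._contig("c", [5_000.0, 13_000.0, 22_000.0, 30_500.0], 40_000)
        father = self._contig("f", [2_000.0, 9_500.0, 25_000.0, 36_000.0], 40_000)
        mother = self._contig("m", [1_000.0, 17_000.0, 28_000.0, 39_000.0], 40_000)
        tc = trio_inheritance((child, True), (father, True), (mother, True))
        assert tc.parent_of_origin == "neither"

    def test_missing_parent_flagged(self):
        child = self._contig("c", [5_000.0, 13_000.0, 22_000.0], 30_000)
        tc = trio_inheritance((child, True), None, None)
        assert tc.parent_of_origin == "neither"
        assert "missing_father" in tc.flags and "missing_mother" in tc.flags

    def test_diploid_two_alleles(self):
        base = [5_000.0, 13_000.0, 22_000.0, 30_500.0, 41_000.0]
        ref_type = self._contig("r", base, 50_000)
        extended = self._contig(
            "x", base + [52_000.0, 63_000.0, 71_000.0, 86_000.0], 95_000
        )
        near_identical = self._contig("r2", base + [47_000.0], 50_000)
        alleles = detect_diploid(
            [("r", ref_type, True), ("x", extended, True), ("r2", near_identical, True)]
        )
        assert sorted(map(sorted, alleles)) == [["r", "r2"], ["x"]]

    def test_single_contig_single_allele(self):
        m = self._contig("only", [5_000.0, 13_000.0, 22_000.0], 30_000)
        assert detect_diploid([("only", m, True)]) == [["only"]]

    def test_window_map_tip_first(self):
        m = self._contig("c", [5_000.0, 13_000.0, 41_000.0], 50_000)
        w = terminal_window_map(m, True, window=2)
        assert w.labels.tolist() == [9_000.0, 37_000.0]
        wp = terminal_window_map(m, False, window=2)
        assert wp.labels.tolist() == [5_000.0, 13_000.0]
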