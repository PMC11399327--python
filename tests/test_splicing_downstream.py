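import numpy as np
import pytest
from scipy import sparse

from ricat.annotation_model import TranscriptModel
from ricat.isoform_assignment import IsoformCountMatrix
from ricat.splicing_downstream import (
    Peak,
    annotate_peaks_to_promoters,
    classify_as_events,
    differential_isoforms,
    differential_peaks,
    isoform_switches,
    splice_site_dar_overlap,
    splice_site_windows,
)

from _oracles import brute_force_as_events, brute_force_nearest_gene


def tx(tid, exons, strand="+", gene="G"):
    return TranscriptModel(tid, gene, "chr1", strand, tuple(exons))


class TestClassifyASEvents:
    def test_identical_isoforms_no_events(self):
        a = tx("A", [(0, 100), (200, 300)])
        assert classify_as_events(a, a) == []

    def test_skipped_exon(self):
        a = tx("A", [(0, 100), (200, 300), (400, 500)])
        b = tx("B", [(0, 100), (400, 500)])
        events = classify_as_events(a, b)
        assert [e.event_type for e in events] == ["SE"]
        assert events[0].site == (200, 300)

    def test_retained_intron(self):
        a = tx("A", [(0, 500)])
        b = tx("B", [(0, 200), (300, 500)])
        events = classify_as_events(a, b)
        assert [e.event_type for e in events] == ["RI"]
        assert events[0].site == (200, 300)

    def test_mutually_exclusive_exons(self):
        a = tx("A", [(0, 100), (200, 250), (400, 500)])
        b = tx("B", [(0, 100), (300, 350), (400, 500)])
        events = classify_as_events(a, b)
        assert {e.event_type for e in events} == {"MXE"}
        assert events[0].site == (200, 350)

    def test_alternative_promoter_and_polya(self):
        a = tx("A", [(0, 100), (200, 300)])
        b = tx("B", [(20, 100), (200, 280)])
        types = {e.event_type for e in classify_as_events(a, b)}
        assert types == {"AP", "APA"}

    def test_a3ss_plus_strand(self):
        # shared donor 100, acceptors 200 vs 250
        a = tx("A", [(0, 100), (200, 300)])
        b = tx("B", [(0, 100), (250, 300)])
        events = classify_as_events(a, b)
        assert {e.event_type for e in events} == {"A3SS"}
        assert events[0].site == (200, 250)

    def test_a5ss_plus_strand(self):
        # shared acceptor 200, donors 100 vs 150 (TES equal, TSS equal)
        a = tx("A", [(0, 100), (200, 300)])
        b = tx("B", [(0, 150), (200, 300)])
        events = classify_as_events(a, b)
        assert {e.event_type for e in events} == {"A5SS"}

    def test_strand_aware_a3ss_a5ss_swap(self):
        # same junctions on the minus strand swap donor/acceptor roles
        a = tx("A", [(0, 100), (200, 300)], strand="-")
        b = tx("B", [(0, 100), (250, 300)], strand="-")
        types = {e.event_type for e in classify_as_events(a, b)}
        assert types == {"A5SS"}

    def test_different_genes_error(self):
        a = tx("A", [(0, 100)], gene="G1")
        b = tx("B", [(0, 100)], gene="G2")
        with pytest.raises(ValueError):
            classify_as_events(a, b)

    def test_symmetry(self):
        a = tx("A", [(0, 100), (200, 300), (400, 500)])
        b = tx("B", [(0, 100), (400, 500)])
        fwd = {e.event_type for e in classify_as_events(a, b)}
        rev = {e.event_type for e in classify_as_events(b, a)}
        assert fwd == rev

    def test_agrees_with_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        # random isoforms drawn from a shared 8-exon scaffold, with random
        # internal subsets, end choices, and occasional exon fusions (RI)
        scaffold = []
        pos = 0
        for _ in range(8):
            length = int(rng.integers(80, 200))
            scaffold.append((pos, pos + length))
            pos += length + int(rng.integers(100, 300))

        def random_isoform(tid):
            first = int(rng.integers(0, 2))
            last = 8 - 1 - int(rng.integers(0, 2))
            middle = [i for i in range(first + 1, last) if rng.random() < 0.7]
            chain = [scaffold[i] for i in [first] + middle + [last]]
            # random fusion of two adjacent exons -> retained intron
            if len(chain) > 2 and rng.random() < 0.3:
                i = int(rng.integers(0, len(chain) - 1))
                chain[i : i + 2] = [(chain[i][0], chain[i + 1][1])]
            return tx(tid, chain)

        n_checked = 0
        for _ in range(300):
            a, b = random_isoform("A"), random_isoform("B")
            got = {e.event_type for e in classify_as_events(a, b)}
            expected = brute_force_as_events(a, b)
            assert got == expected
            n_checked += 1
        assert n_checked == 300


def make_matrix(counts, ids=None, barcodes=None):
    counts = np.asarray(counts)
    ids = ids or [f"t{i}" for i in range(counts.shape[0])]
    barcodes = barcodes or [f"c{i}" for i in range(counts.shape[1])]
    sp = sparse.csr_matrix(counts)
    return IsoformCountMatrix(ids, barcodes, sp, sp, sparse.csr_matrix(sp.shape))


def two_group_labels(barcodes, n_a):
    return {b: ("A" if i < n_a else "B") for i, b in enumerate(barcodes)}


class TestDifferentialIsoforms:
    def test_null_permutation_nothing_significant(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(30, 60))
        m = make_matrix(counts)
        table = differential_isoforms(m, two_group_labels(m.barcodes, 30))
        assert table["significant"].sum() == 0

    def test_eightfold_shift_detected(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(10, size=(20, 100))
        counts[3, :50] = rng.poisson(80, size=50)  # 8-fold up in group A
        m = make_matrix(counts)
        table = differential_isoforms(m, two_group_labels(m.barcodes, 50))
        assert bool(table.loc[table.feature_id == "t3", "significant"].iloc[0])

    def test_significance_flag_matches_stated_thresholds(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(6, size=(25, 80))
        counts[0, :40] = rng.poisson(60, size=40)
        counts[1, :40] = rng.poisson(8, size=40)  # small shift, below log2FC cutoff
        m = make_matrix(counts)
        table = differential_isoforms(m, two_group_labels(m.barcodes, 40))
        recomputed = (table.log2_fold_change.abs() > 0.25) & (table.adjusted_p < 0.05)
        assert (table.significant == recomputed).all()
        assert table.adjusted_p.ge(table.p_value - 1e-12).all()

    def test_fewer_than_three_cells_errors(self):
        m = make_matrix(np.ones((4, 4)))
        with pytest.raises(ValueError):
            differential_isoforms(m, two_group_labels(m.barcodes, 2))

    def test_type_one_error_control_under_permutation(self):
        # homogeneous population, 100 random label permutations: the
        # fraction of (isoform, permutation) pairs flagged significant
        # stays below the nominal 0.05
        rng = np.random.default_rng(7)
        counts = rng.poisson(8, size=(20, 40))
        m = make_matrix(counts)
        n_sig = n_tot = 0
        for _ in range(100):
            perm = rng.permutation(40)
            labels = {m.barcodes[j]: ("A" if i < 20 else "B") for i, j in enumerate(perm)}
            table = differential_isoforms(m, labels)
            n_sig += int(table["significant"].sum())
            n_tot += len(table)
        assert n_sig / n_tot <= 0.05


class TestIsoformSwitches:
    def test_switch_flag(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(20, size=(2, 80))
        counts = np.vstack([base, rng.poisson(5, size=(2, 80))])
        counts[0, :40] = rng.poisson(60, size=40)  # isoform fraction shifts in group A
        m = make_matrix(counts)
        gene_of = {t: "G1" for t in m.transcript_ids}
        table = isoform_switches(m, two_group_labels(m.barcodes, 40), gene_of)
        assert (table.switch == ((table.dIF.abs() > 0.1) & (table.adjusted_p < 0.05))).all()
        assert table.switch.any()


class TestDifferentialPeaks:
    def _peaks(self, n):
        return [Peak("chr1", (1000 * i, 1000 * i + 500), f"p{i}") for i in range(n)]

    def test_null_nothing_significant(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5, size=(20, 40))
        peaks = self._peaks(20)
        bcs = [f"c{i}" for i in range(40)]
        table = differential_peaks(peaks, counts, bcs, two_group_labels(bcs, 20))
        assert table["significant"].sum() == 0

    def test_strong_shift_significant_with_peak_thresholds(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(10, size=(10, 80))
        counts[2, :40] = rng.poisson(50, size=40)
        peaks = self._peaks(10)
        bcs = [f"c{i}" for i in range(80)]
        table = differential_peaks(peaks, counts, bcs, two_group_labels(bcs, 40))
        assert bool(table.loc[table.feature_id == "p2", "significant"].iloc[0])
        recomputed = (table.log2_fold_change.abs() > 0.1) & (table.p_value < 0.0005)
        assert (table.significant == recomputed).all()


class TestAnnotatePeaks:
    def test_peak_in_promoter(self):
        t = tx("T", [(10000, 11000)])
        table = annotate_peaks_to_promoters([Peak("chr1", (9000, 9100), "p")], [t])
        assert table.iloc[0].region == "promoter"
        assert table.iloc[0].gene_id == "G"

    def test_distal_peak_distance(self):
        t = tx("T", [(10000, 11000)])
        table = annotate_peaks_to_promoters([Peak("chr1", (21000, 21200), "p")], [t])
        row = table.iloc[0]
        assert row.region == "distal"
        assert row.distance == 10000

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(6)
        transcripts = [
            tx(f"T{i}", [(s, s + 500)], gene=f"G{i}")
            for i, s in enumerate(sorted(rng.integers(0, 200_000, size=12) * 10))
        ]
        spans = {("chr1", t.gene_id): t.span for t in transcripts}
        peaks = [
            Peak("chr1", (int(p), int(p) + 300), f"p{i}")
            for i, p in enumerate(rng.integers(0, 2_100_000, size=80))
        ]
        table = annotate_peaks_to_promoters(peaks, transcripts)
        for _, row in table.iterrows():
            if row.region == "distal":
                gene, dist = brute_force_nearest_gene(
                    (row.start, row.end), "chr1", spans
                )
                assert abs(row.distance) == abs(dist)
                assert row.gene_id == gene


class TestSpliceSiteDarOverlap:
    def _events(self, n, gap=1000):
        from ricat.splicing_downstream import ASEvent

        return [
            ASEvent("G", "SE", (i * gap, i * gap + 100), ("A", "B"), "chr1")
            for i in range(n)
        ]

    def test_no_dars_zero(self):
        frac, flags = splice_site_dar_overlap(self._events(10), [])
        assert frac == 0.0 and not any(flags)

    def test_all_covered_one(self):
        events = self._events(10)
        dars = [Peak("chr1", e.site, "d") for e in events]
        frac, flags = splice_site_dar_overlap(events, dars)
        assert frac == 1.0 and all(flags)

    def test_constructed_743_of_10000(self):
        events = self._events(10000)
        dars = [Peak("chr1", events[i].site, f"d{i}") for i in range(743)]
        frac, _ = splice_site_dar_overlap(events, dars)
        assert frac == pytest.approx(0.0743)

    def test_monotone_in_window(self):
        rng = np.random.default_rng(8)
        events = self._events(200, gap=500)
        dars = [
            Peak("chr1", (int(p), int(p) + 50), f"d{i}")
            for i, p in enumerate(rng.integers(0, 100_000, size=40))
        ]
        fracs = [
            splice_site_dar_overlap(events, dars, window_bp=w)[0]
            for w in (0, 50, 100, 200, 400)
        ]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_events_errors(self):
        with pytest.raises(ValueError):
            splice_site_dar_overlap([], [])

    def test_windows_bed(self):
        events = self._events(3)
        rows = splice_site_windows(events, window_bp=100)
        assert rows[0] == ("chr1", 0, 200, "SE")  # clamped at 0
        assert rows[1] == ("chr1", 900, 1200, "SE")
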