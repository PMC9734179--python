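"""Target assignment, position classification, ranking, set comparison."""

import numpy as np
import pytest

from mbchip.models import GeneModel
from mbchip.regions import GenomicInterval
from mbchip.targets import (
    POSITION_LABELS,
    assign_targets,
    classify_position,
    compare_target_sets,
    rank_signal_report,
    round_half_up_percent,
    target_gene_ids,
)

from .test_reconcile import _one_signal, peaks_at
from mbchip.reconcile import reconcile_replicates
from .oracles import all_pairs_targets


def signal_at(anchor, contig="ctg1", q=5.0):
    from .conftest import make_peak

    a = [make_peak(contig=contig, start=max(0, anchor - 200), end=anchor + 200,
                   summit=anchor - max(0, anchor - 200), name="a", q=q)]
    b = [make_peak(contig=contig, start=max(0, anchor - 200), end=anchor + 200,
                   summit=anchor - max(0, anchor - 200), name="b", q=q - 0.5)]
    rec, _, _ = reconcile_replicates(a, b)
    return rec[0]


def bare_gene(gene_id, start, end, strand="+", contig="ctg1", exons=None, cds=()):
    span = GenomicInterval(contig, start, end, strand)
    return GeneModel(
        gene_id=gene_id,
        span=span,
        exons=tuple(exons) if exons else (GenomicInterval(contig, start, end, strand),),
        cds=tuple(cds),
    )


class TestClassifyPosition:
    def test_intron_between_exons(self, two_exon_plus_gene):
        sig = signal_at(2000)  # between exon 1 [1000,1500) and exon 2 [2500,3000)
        assert classify_position(sig, two_exon_plus_gene) == "Intron"

    def test_five_prime_utr_plus_strand(self, two_exon_plus_gene):
        # center in exon 1 before the CDS start at 1200
        sig = signal_at(1100)
        assert classify_position(sig, two_exon_plus_gene) == "5'UTR"

    def test_three_prime_utr_plus_strand(self, two_exon_plus_gene):
        sig = signal_at(2900)  # past CDS end 2800, inside exon 2
        assert classify_position(sig, two_exon_plus_gene) == "3'UTR"

    def test_exon_within_cds(self, two_exon_plus_gene):
        sig = signal_at(1300)
        assert classify_position(sig, two_exon_plus_gene) == "Exon"

    def test_upstream_minus_strand_is_higher_coordinate(self, two_exon_minus_gene):
        # 500 bp 5' of a minus-strand gene's TSS (span end 12,000)
        sig = signal_at(12_500)
        assert classify_position(sig, two_exon_minus_gene) == "Upstream"
        sig = signal_at(9_500)
        assert classify_position(sig, two_exon_minus_gene) == "Downstream"

    def test_utr_of_minus_strand_gene(self, two_exon_minus_gene):
        # exon bases above the CDS maximum (11,800) are the 5'UTR on '-'
        sig = signal_at(11_900)
        assert classify_position(sig, two_exon_minus_gene) == "5'UTR"
        sig = signal_at(10_100)  # below CDS minimum: 3'UTR on '-'
        assert classify_position(sig, two_exon_minus_gene) == "3'UTR"

    def test_strandless_gene_warns_and_defaults_plus(self):
        g = bare_gene("LOCX", 5000, 6000, strand=None)
        sig = signal_at(4000)
        with pytest.warns(UserWarning, match="LOCX"):
            assert classify_position(sig, g) == "Upstream"

    def test_exactly_one_label_per_pair(self, rng, two_exon_plus_gene):
        for _ in range(100):
            sig = signal_at(int(rng.integers(300, 4000)))
            label = classify_position(sig, two_exon_plus_gene)
            assert label in POSITION_LABELS


class TestAssignTargets:
    def test_intron_containment(self, two_exon_plus_gene):
        out = assign_targets([signal_at(2000)], [two_exon_plus_gene])
        assert len(out) == 1
        assert out[0].gene_id == "LOC000001"
        assert out[0].position_label == "Intron"
        assert out[0].signed_distance == 0

    def test_window_boundary_half_open(self):
        gene = bare_gene("LOCB", 50_000, 55_000)
        window = 10_000
        # signal whose interval starts at the last base within the window
        sig_in = signal_at(65_000 - 1 + 200)  # interval start = 64,999 = end + window - 1
        assert sig_in.representative.interval.start == 55_000 + window - 1
        assert target_gene_ids(assign_targets([sig_in], [gene], window)) == {"LOCB"}
        sig_out = signal_at(65_000 + 200)  # one base further: interval starts at end + window
        assert sig_out.representative.interval.start == 55_000 + window
        out = assign_targets([sig_out], [gene], window)
        assert out[0].gene_id is None

    def test_orphan_record_is_explicit(self):
        gene = bare_gene("LOCB", 500_000, 505_000)
        out = assign_targets([signal_at(1000)], [gene])
        assert len(out) == 1
        assert out[0].gene_id is None and out[0].position_label is None

    def test_multi_gene_signal_emits_every_gene(self):
        g1 = bare_gene("LOC1", 10_000, 12_000)
        g2 = bare_gene("LOC2", 14_000, 16_000, strand="+")
        out = assign_targets([signal_at(13_000)], [g1, g2])
        assert [a.gene_id for a in out] == ["LOC1", "LOC2"]
        # below a '+' gene is upstream of it; above the first '+' gene is downstream
        assert [a.position_label for a in out] == ["Downstream", "Upstream"]

    def test_minus_strand_orientation_flips_labels(self):
        g = bare_gene("LOC3", 14_000, 16_000, strand="-")
        below = assign_targets([signal_at(13_000)], [g])[0]
        above = assign_targets([signal_at(17_000)], [g])[0]
        assert below.position_label == "Downstream"  # past the 3' end
        assert above.position_label == "Upstream"  # TSS side (higher coordinate)

    def test_signed_distance_sign_convention(self):
        g = bare_gene("LOC1", 20_000, 25_000, strand="+")
        up = assign_targets([signal_at(19_000)], [g])[0]
        down = assign_targets([signal_at(26_000)], [g])[0]
        assert up.position_label == "Upstream" and up.signed_distance < 0
        assert down.position_label == "Downstream" and down.signed_distance > 0
        assert abs(up.signed_distance) <= 10_000 and down.signed_distance <= 10_000

    def test_random_instances_match_all_pairs_oracle(self, rng):
        genes = [
            bare_gene(
                f"LOC{i}",
                int(s),
                int(s) + int(rng.integers(1000, 6000)),
                strand="+" if rng.random() < 0.5 else "-",
                contig=f"ctg{1 + i % 2}",
            )
            for i, s in enumerate(rng.integers(5_000, 400_000, size=20))
        ]
        signals = [
            signal_at(int(a), contig=f"ctg{1 + int(rng.integers(2))}")
            for a in rng.integers(2_000, 420_000, size=50)
        ]
        out = assign_targets(signals, genes, window=10_000)
        got = {(signals.index(a.signal), a.gene_id) for a in out if a.gene_id}
        assert got == all_pairs_targets(signals, genes, 10_000)


class TestRankReport:
    def test_order_by_neg_log10_q(self):
        sigs = [signal_at(a, q=q) for a, q in [(1000, 17.7), (40_000, 35.7), (80_000, 23.3)]]
        assignments = assign_targets(sigs, [])
        report = rank_signal_report(assignments, top_n=20)
        assert report["neg_log10_q"].tolist() == [35.7, 23.3, 17.7]

    def test_single_signal_single_row(self):
        report = rank_signal_report(assign_targets([signal_at(1000)], []), top_n=20)
        assert len(report) == 1 and report.iloc[0]["gene_no"] == "1"

    def test_side_numbered_rows(self):
        g1 = bare_gene("LOC1", 10_000, 12_000)
        g2 = bare_gene("LOC2", 14_000, 16_000)
        report = rank_signal_report(assign_targets([signal_at(13_000)], [g1, g2]))
        assert report["gene_no"].tolist() == ["1-1", "1-2"]
        # signal-level stats shown once, on the first side-numbered row
        assert report.iloc[1]["neg_log10_q"] is None or np.isnan(report.iloc[1]["neg_log10_q"])

    def test_matches_independent_sort(self, rng):
        sigs = [
            signal_at(int(a), q=round(float(q), 2))
            for a, q in zip(
                rng.integers(1000, 10**6, size=100), rng.uniform(3, 40, size=100)
            )
        ]
        report = rank_signal_report(assign_targets(sigs, []), top_n=100)
        expected = sorted(
            (round(s.representative.neg_log10_q, 10) for s in sigs), reverse=True
        )
        assert report["neg_log10_q"].tolist() == pytest.approx(expected)

    def test_top_n_validation(self):
        with pytest.raises(ValueError):
            rank_signal_report([], top_n=0)


class TestTargetSetComparison:
    def test_printed_arithmetic(self):
        a = {f"a{i}" for i in range(300)}
        shared = {f"a{i}" for i in range(125)}
        b = shared | {f"b{i}" for i in range(138)}
        cmp_ = compare_target_sets(a, b)
        assert len(cmp_.set_b) == 263
        assert len(cmp_.common) == 125
        assert len(cmp_.b_specific) == 138
        assert cmp_.percent_b_specific == 52

    def test_disjoint_sets(self):
        cmp_ = compare_target_sets({"x", "y"}, {"u", "v", "w"})
        assert not cmp_.common
        assert cmp_.percent_a_specific == 100 and cmp_.percent_b_specific == 100

    def test_partition_invariant_random(self, rng):
        for _ in range(50):
            a = {int(x) for x in rng.integers(0, 200, size=rng.integers(1, 80))}
            b = {int(x) for x in rng.integers(0, 200, size=rng.integers(1, 80))}
            cmp_ = compare_target_sets(map(str, a), map(str, b))
            assert len(cmp_.a_specific) + len(cmp_.common) == len(cmp_.set_a)
            assert len(cmp_.b_specific) + len(cmp_.common) == len(cmp_.set_b)
            assert cmp_.common == {str(x) for x in a & b}

    def test_round_half_up(self):
        # exact binary fractions land on .5 and must round up, not to even
        assert round_half_up_percent(0.125) == 13
        assert round_half_up_percent(0.375) == 38
        assert round_half_up_percent(138 / 263) == 52
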