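"""Orientation and reading-frame classification of fusion records."""

import itertools

import pytest

from fusionframe.fusion_classify import (
    Frame,
    FusionCall,
    FusionFileError,
    Orientation,
    Productivity,
    classify_orientation,
    classify_productivity,
    frame_compatibility,
    interpretation_label,
    parse_fusion_records,
    retained_orientation,
    select_primary_call,
)
from fusionframe.gene_models import GeneModel
from fusionframe.synthetic_data import (
    SimulationConfig,
    _coding_offset_to_position,
    simulate_fusion_calls,
    write_fusion_tsv,
)

HEADER = (
    "#gene1\tgene2\tbreakpoint1\tbreakpoint2\tdirection1\tdirection2\t"
    "split_reads1\tsplit_reads2"
)


def _row(g1, g2, bp1, bp2, d1, d2, sr1=10, sr2=0):
    return f"{g1}\t{g2}\t{bp1}\t{bp2}\t{d1}\t{d2}\t{sr1}\t{sr2}"


class TestParsing:
    def test_parses_rows_with_breakpoints_and_reads(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            "\n".join(
                [
                    HEADER,
                    _row("MYB", "QKI", "chr6:110200", "chr6:530000", "downstream", "upstream", 40, 2),
                    _row("MYBL1", "MMP16", "chr8:719801", "chr8:1020000", "upstream", "upstream"),
                    _row("MMP16", "MYB", "chr8:1060200", "chr6:100200", "downstream", "downstream"),
                ]
            )
            + "\n"
        )
        calls = parse_fusion_records(p)
        assert len(calls) == 3
        assert calls[0].breakpoint1 == ("chr6", 110200)
        assert calls[0].split_reads == 42  # split_reads1 + split_reads2
        assert calls[0].retained_side1 == "left"  # downstream
        assert calls[1].retained_side1 == "right"  # upstream

    def test_intergenic_partner_preserved_as_locus(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            HEADER + "\n"
            + _row("MYB", ".", "chr6:150200", "chr6:800000", "downstream", "upstream")
            + "\n"
        )
        (call,) = parse_fusion_records(p)
        assert call.gene2 == "."
        assert call.breakpoint2 == ("chr6", 800000)

    def test_header_only_file_yields_empty_list(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(HEADER + "\n")
        assert parse_fusion_records(p) == []

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("#gene1\tgene2\tbreakpoint1\tbreakpoint2\tdirection1\n")
        with pytest.raises(FusionFileError, match="direction2"):
            parse_fusion_records(p)

    def test_bad_breakpoint_reports_row_number(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text(
            HEADER + "\n"
            + _row("MYB", "QKI", "nonsense", "chr6:1", "downstream", "upstream")
            + "\n"
        )
        with pytest.raises(FusionFileError, match="row 2"):
            parse_fusion_records(p)


class TestOrientation:
    @pytest.mark.parametrize(
        "strand,side,expected",
        [
            ("+", "left", "five_prime"),
            ("+", "right", "three_prime"),
            ("-", "left", "three_prime"),
            ("-", "right", "five_prime"),
        ],
    )
    def test_retained_side_strand_combinations(self, strand, side, expected):
        model = GeneModel("G", "chr1", strand, ((100, 200),), ((100, 200),))
        call = FusionCall("c", "G", ".", ("chr1", 150), ("chr9", 1), side, "left")
        assert retained_orientation(call, {"G": model})[0] == expected

    def test_case5_tail_to_tail(self, bundles, models):
        (call,) = bundles["5"].fusion_calls
        assert classify_orientation(call, models) is Orientation.TAIL_TO_TAIL

    def test_case6_tail_to_tail_with_partner_first(self, bundles, models):
        (call,) = bundles["6"].fusion_calls
        assert call.gene1 == "MMP16"
        assert classify_orientation(call, models) is Orientation.TAIL_TO_TAIL

    def test_case1_head_to_tail(self, bundles, models):
        (call,) = bundles["1"].fusion_calls
        assert classify_orientation(call, models) is Orientation.HEAD_TO_TAIL


class TestFrame:
    @staticmethod
    def _call_with_offsets(models, L, D):
        """Head-to-tail MYB::QKI call whose retained/discarded coding
        lengths are exactly L and D."""
        myb, qki = models["MYB"], models["QKI"]
        return FusionCall(
            "t",
            "MYB",
            "QKI",
            (myb.chromosome, _coding_offset_to_position(myb, L)),
            (qki.chromosome, _coding_offset_to_position(qki, D)),
            "left",
            "right",
        )

    def test_matched_coding_lengths_in_frame(self, models):
        call = self._call_with_offsets(models, 300, 300)
        assert frame_compatibility(call, models)[0] is Frame.IN_FRAME

    def test_one_base_shift_out_of_frame(self, models):
        call = self._call_with_offsets(models, 301, 300)
        assert frame_compatibility(call, models)[0] is Frame.OUT_OF_FRAME

    def test_residue_grid_three_of_nine_in_frame(self, models):
        """Exhaustive (L mod 3, D mod 3) grid: exactly the diagonal is
        in-frame."""
        verdicts = {}
        for lr, dr in itertools.product(range(3), repeat=2):
            call = self._call_with_offsets(models, 300 + lr, 300 + dr)
            verdicts[(lr, dr)] = frame_compatibility(call, models)[0]
        in_frame = [k for k, v in verdicts.items() if v is Frame.IN_FRAME]
        assert sorted(in_frame) == [(0, 0), (1, 1), (2, 2)]

    def test_utr_junction_flagged_not_out_of_frame(self, models):
        # 5' partner breakpoint upstream of its CDS start: frame undefined
        myb = models["MYB"]
        call = FusionCall(
            "t", "MYB", "QKI",
            (myb.chromosome, 10050),  # exon 1, 5'-UTR
            ("chr6", 530000),
            "left", "right",
        )
        frame, warn = frame_compatibility(call, models)
        assert frame is Frame.NOT_APPLICABLE
        assert any("UTR" in w for w in warn)


class TestProductivity:
    def test_case14_productive_in_frame(self, bundles, models):
        (call,) = bundles["14"].fusion_calls
        pc = classify_productivity(call, models)
        assert pc.productivity is Productivity.PRODUCTIVE_IN_FRAME
        assert pc.five_prime_partner == "MYBL1"

    @pytest.mark.parametrize("case_id", ["10", "11"])
    def test_mybl1_mmp16_out_of_frame(self, bundles, models, case_id):
        (call,) = bundles[case_id].fusion_calls
        pc = classify_productivity(call, models)
        assert pc.productivity is Productivity.NONPRODUCTIVE_OUT_OF_FRAME

    def test_case12_intergenic(self, bundles, models):
        (call,) = bundles["12"].fusion_calls
        pc = classify_productivity(call, models)
        assert pc.productivity is Productivity.NONPRODUCTIVE_INTERGENIC

    def test_caller_frame_discordance_warned(self, bundles, models):
        (call,) = bundles["10"].fusion_calls  # geometry says out-of-frame
        contradicted = FusionCall(
            call.case_id, call.gene1, call.gene2, call.breakpoint1,
            call.breakpoint2, call.retained_side1, call.retained_side2,
            call.split_reads, caller_frame_annotation="in-frame",
        )
        pc = classify_productivity(contradicted, models)
        assert pc.productivity is Productivity.NONPRODUCTIVE_OUT_OF_FRAME
        assert any("discordant" in w for w in pc.warnings)


class TestLabels:
    def test_case3_label_uses_cluster_alias(self, bundles, models):
        (call,) = bundles["3"].fusion_calls
        pc = classify_productivity(call, models)
        assert interpretation_label(pc, "MYB", call, models) == (
            "MYB in-frame fusion (to PCDHG)"
        )

    def test_case6_tail_to_tail_label(self, bundles, models):
        (call,) = bundles["6"].fusion_calls
        pc = classify_productivity(call, models)
        assert interpretation_label(pc, "MYB", call, models) == (
            "MYB truncation/non-productive fusion"
        )

    def test_goi_absent_from_call_raises(self, bundles, models):
        (call,) = bundles["1"].fusion_calls
        pc = classify_productivity(call, models)
        with pytest.raises(ValueError):
            interpretation_label(pc, "MYBL1", call, models)


class TestPrimarySelection:
    def test_most_split_reads_wins_ties_by_coordinate(self, models):
        mk = lambda sr, pos: FusionCall(
            "c", "MYB", "QKI", ("chr6", pos), ("chr6", 530000), "left", "right", sr
        )
        calls = [mk(10, 90200), mk(30, 110200), mk(30, 70200)]
        primary = select_primary_call(calls, "MYB")
        assert primary.breakpoint1 == ("chr6", 70200)
        assert select_primary_call(calls, "KHDRBS3") is None


class TestSimulationRoundTrip:
    def test_classifier_recovers_ground_truth_and_swap_symmetry(self, models):
        cfg = SimulationConfig(seed=202, n_random_fusions=300)
        calls, truth = simulate_fusion_calls(cfg, models)
        for call, expected in zip(calls, truth["truth"]):
            pc = classify_productivity(call, models)
            assert pc.productivity.value == expected
            swapped = classify_productivity(call.swapped(), models)
            assert swapped.productivity is pc.productivity
            assert swapped.orientation is pc.orientation

    def test_tsv_round_trip_preserves_classification(self, models, tmp_path):
        cfg = SimulationConfig(seed=17, n_random_fusions=40)
        calls, _ = simulate_fusion_calls(cfg, models)
        p = tmp_path / "sim.tsv"
        write_fusion_tsv(calls, p, models)
        reread = parse_fusion_records(p)
        assert len(reread) == len(calls)
        for a, b in zip(calls, reread):
            assert classify_productivity(a, models).productivity is (
                classify_productivity(b, models).productivity
            )
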