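"""Anchor location, position mapping, profile extraction, conservation."""

import numpy as np
import pytest

from mipkit.motifs import (
    AQP1_ARR_POSITIONS, AQP1_FROGER_POSITIONS, MotifProfile, ReferenceAnchor,
    anchor_from_reference, extract_profile, locate_npa_on_reference,
    map_reference_positions, read_anchor_tsv, summarize_conservation,
    write_anchor_tsv,
)
from mipkit.msa import MultipleAlignment, progressive_align
from mipkit.seqio import ProteinRecord


def rec(seq, rid="r"):
    return ProteinRecord(id=rid, sequence=seq)


class TestLocateNpa:
    def test_planted_boxes_found(self):
        seq = "G" * 40 + "NPA" + "G" * 60 + "NPA" + "G" * 40
        lb, le = locate_npa_on_reference(rec(seq))
        assert (lb, le) == (41, 104)

    def test_first_occurrence_per_half(self):
        seq = "G" * 10 + "NPA" + "G" * 10 + "NPA" + "G" * 40 + "NPA" + "G" * 20
        lb, le = locate_npa_on_reference(rec(seq))
        assert lb == 11 and le == 67

    def test_single_box_rejected(self):
        with pytest.raises(ValueError, match="manually"):
            locate_npa_on_reference(rec("G" * 30 + "NPA" + "G" * 30))

    def test_both_boxes_in_one_half_rejected(self):
        seq = "NPAGNPA" + "G" * 60
        with pytest.raises(ValueError):
            locate_npa_on_reference(rec(seq))


class TestAnchor:
    def test_positions_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            ReferenceAnchor("r", arr_positions=(58, 182, 197, 191),
                            npa_lb_start=10, npa_le_start=100)

    def test_default_positions_are_aqp1(self):
        a = ReferenceAnchor("r", npa_lb_start=76, npa_le_start=192)
        assert a.arr_positions == AQP1_ARR_POSITIONS == (58, 182, 191, 197)
        assert a.froger_positions == AQP1_FROGER_POSITIONS == (116, 196, 200, 212, 213)

    def test_tsv_round_trip(self, tmp_path, small_family):
        p = tmp_path / "anchor.tsv"
        write_anchor_tsv(small_family.anchor, p)
        assert read_anchor_tsv(p) == small_family.anchor


class TestMapPositions:
    def _anchor(self, ref_id="r"):
        return ReferenceAnchor(
            ref_id, arr_positions=(2, 4, 6, 8), froger_positions=(1, 3, 5, 7, 9),
            npa_lb_start=3, npa_le_start=7,
        )

    def test_gap_free_reference_identity_mapping(self):
        aln = MultipleAlignment(["r"], ["MKVLINAPWE"])
        cols = map_reference_positions(aln, self._anchor())
        assert cols["H2"] == 2 and cols["P5"] == 9

    def test_leading_gaps_offset_mapping(self):
        aln = MultipleAlignment(["r", "q"], ["-----MKVLINAPWE", "AMKVLMKVLINAPWE"])
        cols = map_reference_positions(aln, self._anchor())
        assert all(cols[s] == p + 5 for s, p in
                   [("H2", 2), ("H5", 4), ("LE1", 6), ("LE2", 8)])

    def test_random_gapped_rows_match_linear_scan(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACDEFGHIKL"), size=12))
            gapped = []
            for ch in seq:
                gapped.extend(["-"] * int(rng.integers(0, 3)) + [ch])
            row = "".join(gapped)
            aln = MultipleAlignment(["r"], [row])
            cols = map_reference_positions(aln, self._anchor())
            # linear-scan oracle: count residues left to right
            seen = 0
            expect = {}
            for c, ch in enumerate(row, start=1):
                if ch != "-":
                    seen += 1
                    expect[seen] = c
            for slot, pos in self._anchor().all_positions().items():
                assert cols[slot] == expect[pos]

    def test_position_beyond_reference_rejected(self):
        aln = MultipleAlignment(["r"], ["MKV"])
        with pytest.raises(ValueError, match="beyond"):
            map_reference_positions(aln, self._anchor())


class TestExtractProfile:
    def test_reference_reads_its_own_residues(self, small_family):
        fam = small_family
        prof = extract_profile(fam.alignment, fam.anchor, "AQP_REF")
        ref_seq = fam.anchor_record.sequence
        assert prof.arr == tuple(ref_seq[p - 1] for p in fam.anchor.arr_positions)
        assert prof.froger == tuple(
            ref_seq[p - 1] for p in fam.anchor.froger_positions
        )

    def test_gap_at_mapped_column_yields_dash(self):
        anchor = ReferenceAnchor(
            "r", arr_positions=(2, 4, 6, 8), froger_positions=(1, 3, 5, 7, 9),
            npa_lb_start=3, npa_le_start=7,
        )
        aln = MultipleAlignment(["r", "q"], ["MKVLINAPWE", "MK-LINAPWE"])
        prof = extract_profile(aln, anchor, "q")
        assert prof.froger[1] == "-"  # P2 maps to column 3, gapped in query

    def test_absent_query_rejected(self, small_family):
        with pytest.raises(ValueError, match="nope"):
            extract_profile(small_family.alignment, small_family.anchor, "nope")

    def test_planted_profiles_recovered_from_computed_alignment(self, small_family):
        fam = small_family
        aln = progressive_align(fam.all_records)
        for rid, want in fam.truth.profiles.items():
            got = extract_profile(aln, fam.anchor, rid)
            assert (got.npa_lb, got.npa_le, got.arr, got.froger) == \
                (want.npa_lb, want.npa_le, want.arr, want.froger), rid


class TestConservation:
    def _profiles(self):
        mk = lambda i, arr: MotifProfile(
            id=f"PIP_{i}", npa_lb="NPA", npa_le="NPA",
            arr=arr, froger=("Q", "S", "A", "F", "W"),
        )
        return [
            mk(1, ("F", "H", "T", "R")),
            mk(2, ("F", "H", "T", "R")),
            mk(3, ("F", "H", "C", "R")),  # planted deviant at LE1
        ]

    def test_identical_profiles_full_agreement(self):
        profs = self._profiles()[:2]
        df = summarize_conservation(profs, {p.id: "PIP" for p in profs})
        assert (df.agreement_pct == 100.0).all()

    def test_planted_deviant_reported(self):
        profs = self._profiles()
        df = summarize_conservation(profs, {p.id: "PIP" for p in profs})
        row = df[(df.subfamily == "PIP") & (df.slot == "LE1")].iloc[0]
        assert row.consensus == "T"
        assert row.agreement_pct == pytest.approx(100 * 2 / 3)
        assert row.deviants == "PIP_3"

    def test_no_assignments_rejected(self):
        with pytest.raises(ValueError):
            summarize_conservation(self._profiles(), {})

    def test_synthetic_family_consensus_matches_signatures(self, small_family):
        fam = small_family
        assignments = dict(
            zip(fam.truth.sequences.id, fam.truth.sequences.subfamily)
        )
        df = summarize_conservation(fam.truth.profiles.values(), assignments)
        pip_arr = df[(df.subfamily == "PIP") &
                     (df.slot.isin(["H2", "H5", "LE1", "LE2"]))]
        assert list(pip_arr.consensus) == ["F", "H", "T", "R"]
        assert (df.agreement_pct == 100.0).all()


def test_anchor_from_reference_locates_boxes(small_family):
    # the synthetic anchor sequence carries exact NPA boxes at the planted
    # layout positions (first-subfamily signature is NPA/NPA)
    fam = small_family
    a = anchor_from_reference(
        fam.anchor_record,
        arr_positions=fam.anchor.arr_positions,
        froger_positions=fam.anchor.froger_positions,
    )
    assert (a.npa_lb_start, a.npa_le_start) == \
        (fam.anchor.npa_lb_start, fam.anchor.npa_le_start)
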