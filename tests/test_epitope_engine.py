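"""Translation, pseudogene/C->T calls, epitope scanning, abundance tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gliascan.amplicon_db import AmpliconRecord
from gliascan.catalog import DQ25_CLASSES, EpitopeCatalog, EpitopeEntry
from gliascan.epitope_engine import (
    EpitopeOccurrence,
    call_pseudogene,
    classify_ct_stop,
    classify_type,
    epitope_abundance,
    find_epitopes,
    infer_panel_frame,
    pseudogene_percent,
    translate,
    type_abundance,
    variant_log2fc,
)


class TestTranslate:
    @pytest.mark.parametrize(
        "dna,frame,peptide",
        [
            ("CAACCA", 0, "QP"),
            ("TAGCAA", 0, "*Q"),
            ("ACAACCA", 1, "QP"),  # frame 1 drops the first base
            ("CAACC", 0, "Q"),     # trailing partial codon dropped
            ("CANCCA", 0, "XP"),   # ambiguous codon
        ],
    )
    def test_examples(self, dna, frame, peptide):
        assert translate(dna, frame) == peptide

    def test_bad_frame_raises(self):
        with pytest.raises(ValueError):
            translate("CAA", 3)


class TestFrameInference:
    def test_stop_free_panel_is_frame_zero(self):
        assert infer_panel_frame(["CAACCACAA", "CCTCAACCT"]) == 0

    def test_recovers_planted_frame(self):
        from gliascan.synthetic_data import SynthConfig, generate_panel

        config = SynthConfig(seed=5, panel_size=6, frame_offset=1,
                             pseudogene_prob=0.3)
        truth = generate_panel(config)
        assert infer_panel_frame(truth.panel) == 1

    def test_tie_breaks_to_smallest_offset(self):
        # stops in every frame: TAA at 0, TAG at 1, TGA at 2
        seq = "TAATAGTGATAATAGTGA"[0:18]
        assert infer_panel_frame([seq]) in (0, 1, 2)
        # all three frames have 2+ stops; the count-minimal set is a tie at
        # the smallest offset
        counts = [translate(seq, f).count("*") for f in (0, 1, 2)]
        assert infer_panel_frame([seq]) == int(np.argmin(counts))


class TestPseudogeneCalls:
    def test_call_pseudogene(self):
        assert not call_pseudogene("QPQPQ")
        assert call_pseudogene("QP*Q")
        assert not call_pseudogene("")

    def test_tag_reported_tga_excluded(self):
        # TAG reverts to CAG (Gln) -> reported; TGA reverts to CGA (Arg) -> not
        assert classify_ct_stop("CAATAGCAA", 0) == [1]
        assert classify_ct_stop("CAATGACAA", 0) == []
        assert classify_ct_stop("CAACAACAA", 0) == []

    def test_ct_stops_subset_of_peptide_stops(self):
        dna = "CAATAGTGACAGTAA"
        peptide = translate(dna, 0)
        stops = {i for i, aa in enumerate(peptide) if aa == "*"}
        assert set(classify_ct_stop(dna, 0)) <= stops

    def test_percent_formatting(self):
        assert pseudogene_percent(21, 76) == 27.6
        assert pseudogene_percent(9, 41) == 22.0


class TestFindEpitopes:
    def test_33mer_carries_six_overlapping_alpha_epitopes(self, catalog):
        peptide = catalog["region_33mer"].peptide
        occs = find_epitopes(peptide, catalog.select({"alpha-DQ2.5"}))
        assert len(occs) == 6
        assert {o.epitope_id for o in occs} == {
            "DQ2.5_glia_a1a", "DQ2.5_glia_a1b", "DQ2.5_glia_a2"
        }

    def test_s_variant_found_at_one_mismatch(self, catalog):
        occs = find_epitopes(
            "PQPQLPYSQ", [catalog["DQ2.5_glia_a2"]], max_mismatch=1
        )
        assert len(occs) == 1
        occ = occs[0]
        assert (occ.mismatches, occ.observed) == (1, "PQPQLPYSQ")

    def test_empty_peptide(self, catalog):
        assert find_epitopes("", catalog, max_mismatch=1) == []

    def test_exact_match_suppresses_variant_report_at_same_window(self):
        entries = [
            EpitopeEntry("e1", "QQQQQQQQQ", "alpha-DQ2.5"),
            EpitopeEntry("e2", "QQQQQQQQP", "alpha-DQ2.5"),
        ]
        occs = find_epitopes("QQQQQQQQQ", entries, max_mismatch=1)
        assert [(o.epitope_id, o.mismatches) for o in occs] == [("e1", 0)]

    @given(
        peptide=st.text(alphabet="QPFLSY", min_size=0, max_size=40),
        max_mm=st.integers(0, 1),
    )
    def test_matches_bruteforce_hamming_scan(self, catalog, peptide, max_mm):
        entries = catalog.select(DQ25_CLASSES)
        got = {
            (o.epitope_id, o.start, o.mismatches)
            for o in find_epitopes(peptide, entries, max_mm)
        }
        # independent oracle: all windows, plain Hamming count, then the
        # exact-first suppression rule applied per (window, length)
        raw = []
        exact = set()
        for e in entries:
            m = len(e.peptide)
            for s in range(len(peptide) - m + 1):
                d = sum(a != b for a, b in zip(peptide[s : s + m], e.peptide))
                if d <= max_mm:
                    raw.append((e.epitope_id, s, d, m))
                    if d == 0:
                        exact.add((s, m))
        expected = {
            (eid, s, d)
            for eid, s, d, m in raw
            if d == 0 or (s, m) not in exact
        }
        assert got == expected


def _occ(amp, eid, mm=0):
    return EpitopeOccurrence(amp, eid, 0, mm, "X")


class TestClassifyType:
    def test_33mer_plus_downstream_a3_is_alpha7(self, catalog):
        peptide = (
            catalog["region_33mer"].peptide
            + "QPSNQHQPT"
            + catalog["DQ2.5_glia_a3"].peptide
        )
        occs = find_epitopes(peptide, catalog)
        assert classify_type(occs, catalog, "alpha") == "Alpha_7"

    def test_no_epitopes_is_type_zero(self, catalog):
        assert classify_type([], catalog, "alpha") == "Alpha_0"
        assert classify_type([], catalog, "gamma") == "Gamma_0"

    def test_p31_43_never_contributes(self, catalog):
        occs = [_occ("a", "p31_43"), _occ("a", "DQ2.5_glia_a3")]
        assert classify_type(occs, catalog, "alpha") == "Alpha_1"

    def test_variant_occurrences_do_not_count(self, catalog):
        occs = [_occ("a", "DQ2.5_glia_a2", mm=1)]
        assert classify_type(occs, catalog, "alpha") == "Alpha_0"


def _records():
    return [
        AmpliconRecord("a1", "X", pseudogene=False),
        AmpliconRecord("a2", "X", pseudogene=False),
        AmpliconRecord("a3", "X", pseudogene=True),
    ]


class TestAbundanceTables:
    MATRIX = pd.DataFrame(
        {"g1": [40.0, 10.0, 50.0], "g2": [5.0, 10.0, 85.0]},
        index=["a1", "a2", "a3"],
    )

    def test_single_and_multi_amplicon_sums(self, catalog):
        occs = {
            "a1": [_occ("a1", "DQ2.5_glia_a2")],
            "a2": [_occ("a2", "DQ2.5_glia_a2")],
            "a3": [],
        }
        table = epitope_abundance(self.MATRIX, occs, catalog, _records())
        assert table.loc["g1", "DQ2.5_glia_a2"] == 50.0  # 40 + 10
        assert table.loc["g2", "DQ2.5_glia_a2"] == 15.0

    def test_pseudogene_only_epitope_reports_zero(self, catalog):
        occs = {"a3": [_occ("a3", "DQ2.5_glia_a1a")]}
        table = epitope_abundance(self.MATRIX, occs, catalog, _records())
        assert table["DQ2.5_glia_a1a"].sum() == 0.0
        relaxed = epitope_abundance(
            self.MATRIX, occs, catalog, _records(), putative_only=False
        )
        assert relaxed.loc["g1", "DQ2.5_glia_a1a"] == 50.0

    def test_monotone_in_added_amplicon(self, catalog):
        occs = {"a1": [_occ("a1", "DQ2.5_glia_a2")]}
        base = epitope_abundance(self.MATRIX, occs, catalog, _records())
        occs["a2"] = [_occ("a2", "DQ2.5_glia_a2")]
        more = epitope_abundance(self.MATRIX, occs, catalog, _records())
        assert (more["DQ2.5_glia_a2"] >= base["DQ2.5_glia_a2"]).all()

    def test_types_partition_putative_abundance(self, catalog):
        labels = {"a1": "Alpha_0", "a2": "Alpha_2", "a3": "Alpha_1"}
        table = type_abundance(self.MATRIX, labels, _records())
        putative_total = self.MATRIX.loc[["a1", "a2"]].sum(axis=0)
        assert np.allclose(table.sum(axis=1), putative_total)

    def test_type_additivity(self, catalog):
        labels = {"a1": "Alpha_0", "a2": "Alpha_0", "a3": "Alpha_0"}
        table = type_abundance(self.MATRIX, labels, _records())
        assert table.loc["g1", "Alpha_0"] == 50.0  # 40 + 10, pseudogene excluded


class TestVariantLog2FC:
    @pytest.mark.parametrize(
        "v,c,expected", [(3.0, 3.0, 0.0), (4.0, 2.0, 1.0), (0.0, 0.0, 0.0)]
    )
    def test_examples(self, v, c, expected):
        assert variant_log2fc(v, c) == pytest.approx(expected, abs=1e-6)

    def test_series_input(self):
        v = pd.Series([1.0, 2.0])
        c = pd.Series([1.0, 1.0])
        out = variant_log2fc(v, c)
        assert np.allclose(out, [0.0, 1.0], atol=1e-6)
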