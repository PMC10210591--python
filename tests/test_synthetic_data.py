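"""Generator: planted epitopes, pseudogenes, class masks, reads, determinism."""

import numpy as np
import pandas as pd
import pytest

from gliascan.catalog import EpitopeCatalog
from gliascan.epitope_engine import classify_ct_stop, translate
from gliascan.synthetic_data import (
    InfeasiblePlanError,
    SynthConfig,
    generate_panel,
    generate_profiles,
    simulate_reads,
)


def _brute_count(peptide: str, epitope: str) -> int:
    return sum(
        peptide[i : i + len(epitope)] == epitope
        for i in range(len(peptide) - len(epitope) + 1)
    )


class TestGeneratePanel:
    def test_planted_tandem_copies_found_by_bruteforce(self, catalog):
        # three overlapping alpha-2 copies on a ~210 bp amplicon
        config = SynthConfig(
            seed=3,
            epitope_plan=[[("DQ2.5_glia_a2", 3)]],
            secalin_fraction=0.0,
            pseudogene_prob=0.0,
            amplicon_length_range=(210, 213),
        )
        truth = generate_panel(config)
        peptide = translate(truth.panel[0].sequence, 0)
        assert _brute_count(peptide, catalog["DQ2.5_glia_a2"].peptide) == 3
        # truth records the scanner's own view, including the two incidental
        # alpha-1b copies created by the tandem overlap (as in the 33-mer)
        recorded = [
            o.epitope_id for o in truth.occurrences[truth.panel[0].id]
        ]
        assert recorded.count("DQ2.5_glia_a2") == 3

    def test_pseudogene_probability_extremes(self):
        none = generate_panel(SynthConfig(seed=4, panel_size=8, pseudogene_prob=0.0))
        assert not any(r.pseudogene for r in none.panel)
        every = generate_panel(SynthConfig(seed=4, panel_size=8, pseudogene_prob=1.0))
        for rec in every.panel:
            if rec.secalin:
                assert not rec.pseudogene
            else:
                assert rec.pseudogene
                # the planted stop is a C->T revertible glutamine codon
                assert classify_ct_stop(rec.sequence, rec.frame)

    def test_infeasible_plan_raises(self):
        config = SynthConfig(
            seed=5,
            epitope_plan=[[("region_33mer", 10)]],  # 330 residues > capacity
            secalin_fraction=0.0,
        )
        with pytest.raises(InfeasiblePlanError):
            generate_panel(config)

    def test_unknown_epitope_id_raises(self):
        config = SynthConfig(seed=5, epitope_plan=[[("nope", 1)]],
                             secalin_fraction=0.0)
        with pytest.raises(KeyError):
            generate_panel(config)

    def test_lengths_respect_range_and_frame(self):
        config = SynthConfig(seed=6, panel_size=6, frame_offset=2)
        truth = generate_panel(config)
        lo, hi = config.amplicon_length_range
        for rec in truth.panel:
            assert lo <= len(rec.sequence) <= hi
            assert (len(rec.sequence) - 2) % 3 == 0


class TestGenerateProfiles:
    def test_rows_are_simplex(self, small_dataset):
        _, truth, _ = small_dataset
        sums = truth.proportions.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_durum_and_tritordeum_exclude_secalin_and_d(self, small_dataset):
        _, truth, _ = small_dataset
        excluded = [r.id for r in truth.panel if r.secalin or r.subgenome == "D"]
        for genotype, cls in truth.genotype_classes.items():
            if cls in ("durum", "tritordeum"):
                assert (truth.proportions.loc[genotype, excluded] == 0).all()

    def test_secalin_only_in_translocation_carriers(self, small_dataset):
        _, truth, _ = small_dataset
        secalin = [r.id for r in truth.panel if r.secalin]
        assert secalin, "default plan should include secalin amplicons"
        for genotype, cls in truth.genotype_classes.items():
            if cls != "bread_wheat_translocation":
                assert (truth.proportions.loc[genotype, secalin] == 0).all()

    def test_high_concentration_limit_is_near_uniform(self):
        config = SynthConfig(seed=8, panel_size=6, secalin_fraction=0.0,
                             dirichlet_alpha=1e6,
                             n_genotypes_per_class={"bread_wheat": 1})
        truth = generate_profiles(generate_panel(config), config)
        row = truth.proportions.iloc[0]
        assert row.max() - row.min() < 1e-2

    def test_expected_tables_follow_engine_definitions(self, small_dataset):
        _, truth, _ = small_dataset
        # spot-check: one epitope column equals the summed proportions of the
        # putative amplicons carrying an exact occurrence
        epi = truth.expected_epitope_abundance
        eid = "DQ2.5_glia_a3"
        carriers = [
            amp_id
            for amp_id, occs in truth.occurrences.items()
            if any(o.epitope_id == eid and o.mismatches == 0 for o in occs)
        ]
        putative = {r.id for r in truth.panel if not r.pseudogene}
        carriers = [c for c in carriers if c in putative]
        expected = 100 * truth.proportions[carriers].sum(axis=1)
        assert np.allclose(epi[eid], expected.reindex(epi.index), atol=1e-9)


class TestSimulateReads:
    def test_deterministic_for_fixed_seed(self, tmp_path):
        config = SynthConfig(
            seed=9, panel_size=5, reads_per_sample=200, per_base_error=0.005,
            n_genotypes_per_class={"bread_wheat": 1},
        )
        out = []
        for run in ("a", "b"):
            truth = generate_profiles(generate_panel(config), config)
            simulate_reads(truth, config, tmp_path / run)
            out.append((tmp_path / run / "BWN_g01_rep1_R1.fastq").read_bytes())
            pd.testing.assert_frame_equal(
                truth.proportions, generate_profiles(
                    generate_panel(config), config
                ).proportions
            )
        assert out[0] == out[1]

    def test_zero_reads_gives_valid_empty_fastq(self, tmp_path):
        config = SynthConfig(
            seed=10, panel_size=4, reads_per_sample=0,
            n_genotypes_per_class={"durum": 1}, secalin_fraction=0.0,
        )
        truth = generate_profiles(generate_panel(config), config)
        sheet = simulate_reads(truth, config, tmp_path)
        for path in sheet["fastq_r1"]:
            assert open(path).read() == ""

    def test_error_positions_get_low_quality(self, tmp_path):
        config = SynthConfig(
            seed=11, panel_size=4, reads_per_sample=300, per_base_error=0.01,
            n_genotypes_per_class={"bread_wheat": 1}, secalin_fraction=0.0,
        )
        truth = generate_profiles(generate_panel(config), config)
        sheet = simulate_reads(truth, config, tmp_path)
        with open(sheet["fastq_r1"].iloc[0]) as fh:
            lines = fh.read().splitlines()
        quals = set("".join(lines[3::4]))
        assert quals <= {"D", "0"}  # Q35 for correct bases, Q15 at errors
        assert "0" in quals

    def test_realized_counts_match_written_reads(self, tmp_path):
        config = SynthConfig(
            seed=12, panel_size=4, reads_per_sample=500, per_base_error=0.0,
            n_genotypes_per_class={"bread_wheat": 1}, secalin_fraction=0.0,
        )
        truth = generate_profiles(generate_panel(config), config)
        sheet = simulate_reads(truth, config, tmp_path)
        for row in sheet.itertuples(index=False):
            n_reads = sum(1 for line in open(row.fastq_r1) if line.startswith("@"))
            assert n_reads == truth.realized_counts[row.sample_id].sum() == 500
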