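"""Synthetic data generators: determinism, planted effects, fixture arithmetic."""

import numpy as np
import pandas as pd
import pytest

from xtalk import io, simulate as sim
from xtalk.clustering import XTALK_CODES


class TestLargestRemainder:
    def test_sums_are_exact(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 10))
            fractions = rng.dirichlet(np.ones(k))
            total = int(rng.integers(1, 10_000))
            parts = sim.largest_remainder(total, fractions)
            assert parts.sum() == total
            assert (parts >= 0).all()

    def test_proportionality(self):
        np.testing.assert_array_equal(
            sim.largest_remainder(10, [0.5, 0.3, 0.2]), [5, 3, 2]
        )


class TestSimulateExpression:
    def test_seeded_determinism(self):
        a = sim.simulate_expression(200, seed=42)
        b = sim.simulate_expression(200, seed=42)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_zero_effect_means_equal_across_conditions(self):
        """Without planted effects, per-condition means differ only by noise."""
        explant, _, truth = sim.simulate_expression(
            2000, code_proportions={}, effect_size=0.0, seed=3
        )
        assert truth.empty
        cond_means = {
            c: explant.filter(regex=f"^{c}_").to_numpy().mean()
            for c in ("CTRL", "T3", "CORT", "T3CORT")
        }
        grand = np.mean(list(cond_means.values()))
        for c, m in cond_means.items():
            assert abs(m - grand) / grand < 0.05, (c, m, grand)

    def test_planted_unu_quadruples_t3_columns(self):
        """+2 log2 in T3 and T3+CORT means a 4x mean ratio vs CTRL."""
        explant, _, truth = sim.simulate_expression(
            100, code_proportions={"u_n_u": 1.0}, effect_size=2.0, seed=5
        )
        assert (truth.triad_code == "u_n_u").all()
        ctrl = explant.filter(regex="^CTRL_").to_numpy().mean()
        for cond in ("T3", "T3CORT"):
            ratio = explant.filter(regex=f"^{cond}_").to_numpy().mean() / ctrl
            assert 0.8 * 4 < ratio < 1.2 * 4
        cort_ratio = explant.filter(regex="^CORT_").to_numpy().mean() / ctrl
        assert 0.8 < cort_ratio < 1.2

    def test_truth_row_conservation(self):
        props = {"u_n_u": 0.4, "d_d_d": 0.35, "n_n_n": 0.25}
        _, _, truth = sim.simulate_expression(997, code_proportions=props, seed=1)
        expected = sim.largest_remainder(997, [0.4, 0.35, 0.25])
        assert len(truth) == expected[0] + expected[1]

    @pytest.mark.parametrize(
        "kwargs,match",
        [
            ({"n_genes": 0}, "n_genes"),
            ({"n_genes": 10, "code_proportions": {"z_z_z": 1.0}}, "unknown"),
            ({"n_genes": 10, "code_proportions": {"u_n_u": 0.8, "n_n_n": 0.3}}, "sum"),
            ({"n_genes": 10, "n_reps": 1}, "n_reps"),
        ],
    )
    def test_invalid_arguments_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            sim.simulate_expression(**kwargs)

    def test_nb_variance_exceeds_poisson(self):
        """Dispersion > 0 must inflate variance beyond the mean."""
        explant, _, _ = sim.simulate_expression(
            1, code_proportions={}, nb_dispersion=0.5, n_reps=3, seed=0,
            baseline_log_sd=0.0, baseline_log_mean=np.log(1000),
        )
        counts = explant.to_numpy().ravel().astype(float)
        assert counts.var() > counts.mean() * 2


class TestSimulateMethylome:
    def test_seeded_determinism(self):
        t = [sim.MethylationTruth("chr1", 100, 500, (-0.5, 0.0, -0.5))]
        a = sim.simulate_methylome(10_000, t, 5000, seed=9)
        b = sim.simulate_methylome(10_000, t, 5000, seed=9)
        for cond in a:
            np.testing.assert_array_equal(a[cond], b[cond])

    def test_read_counts_match_depth(self):
        reads = sim.simulate_methylome(10_000, [], 5000, seed=0)
        assert all(len(v) == 5000 for v in reads.values())

    def test_demethylation_thins_treatment_coverage(self):
        """effect -0.8 leaves the treated region at ~20% of CTRL coverage."""
        region = sim.MethylationTruth("chr1", 40_000, 42_000, (-0.8, 0.0, -0.8))
        reads = sim.simulate_methylome(100_000, [region], 200_000, fragment_len=50, seed=4)

        def mean_cov(intervals):
            from xtalk.dmr import coverage_track
            track = coverage_track(np.asarray(intervals), 100_000)
            return track[40_000:42_000].mean()

        ratio = mean_cov(reads["T3"]) / mean_cov(reads["CTRL"])
        assert abs(ratio - 0.2) < 0.15 * 0.2 + 0.02
        cort_ratio = mean_cov(reads["CORT"]) / mean_cov(reads["CTRL"])
        assert abs(cort_ratio - 1.0) < 0.15

    def test_overlapping_truth_rejected(self):
        t = [
            sim.MethylationTruth("chr1", 100, 500, (0.5, 0, 0.5)),
            sim.MethylationTruth("chr1", 400, 900, (0.5, 0, 0.5)),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            sim.simulate_methylome(10_000, t, 1000, seed=0)

    def test_out_of_genome_truth_rejected(self):
        t = [sim.MethylationTruth("chr1", 9000, 11_000, (0.5, 0, 0.5))]
        with pytest.raises(ValueError, match="outside"):
            sim.simulate_methylome(10_000, t, 1000, seed=0)

    def test_truth_code_derivation(self):
        t = sim.MethylationTruth("chr1", 0, 10, (-0.8, 0.0, 0.8))
        assert t.triad_code == "d_n_u"
        assert t.direction in ("demethylation", "re-methylation")


class TestSimulateGenome:
    def test_planted_motifs_written_verbatim(self, genome_fixture):
        seq = genome_fixture.sequences["chr1"]
        half, rc = "AGGTCA", "TGACCT"
        # DR4 at 120: two forward half-sites around a 4 bp spacer
        assert seq[120:126] == half and seq[130:136] == half
        # IR3 at 160: forward then reverse-complement
        assert seq[160:166] == half and seq[169:175] == rc
        # ER6 at 200: reverse-complement then forward
        assert seq[200:206] == rc and seq[212:218] == half

    def test_cpg_enrichment_within_expected_band(self, genome_fixture):
        """3-fold requested CG boost lands in [2, 4] measured on 100 kb."""
        from xtalk.annotation import dinucleotide_profile, extract_sequences

        dmr = dinucleotide_profile(
            extract_sequences(genome_fixture.sequences, genome_fixture.dmr_intervals)
        )
        exon = dinucleotide_profile(
            extract_sequences(
                genome_fixture.sequences,
                genome_fixture.exons[["seq_id", "start", "end"]],
            )
        )
        assert 2.0 <= dmr["CG"] / exon["CG"] <= 4.0

    def test_annotations_within_sequence(self, genome_fixture):
        L = len(genome_fixture.sequences["chr1"])
        for table in (genome_fixture.genes, genome_fixture.exons, genome_fixture.tes):
            assert (table.start >= 0).all() and (table.end <= L).all()
            assert (table.end > table.start).all()

    def test_bad_motif_spec_rejected(self):
        with pytest.raises(ValueError, match="spacer"):
            sim.simulate_genome(planted_motifs=[("chr1", 10, "DR", 9)], seed=0)
        with pytest.raises(ValueError, match="topology"):
            sim.simulate_genome(planted_motifs=[("chr1", 10, "XX", 3)], seed=0)

    def test_fasta_gff_bed_round_trip(self, genome_fixture, tmp_path):
        io.write_fasta(genome_fixture.sequences, tmp_path / "g.fa")
        assert io.read_fasta(tmp_path / "g.fa") == genome_fixture.sequences
        io.write_gff3(genome_fixture.genes, tmp_path / "g.gff3")
        back = io.read_gff3(tmp_path / "g.gff3")
        pd.testing.assert_frame_equal(
            back[["seq_id", "start", "end", "gene_id"]], genome_fixture.genes
        )
        io.write_bed(genome_fixture.tes, tmp_path / "t.bed")
        bed = io.read_bed(tmp_path / "t.bed")
        pd.testing.assert_frame_equal(
            bed.rename(columns={"family": "family"}),
            genome_fixture.tes[["seq_id", "start", "end", "family"]],
        )


class TestPaperCountsFixture:
    def test_row_totals(self, paper_tables):
        genes, dmrs = paper_tables
        assert len(genes) == 845
        assert len(dmrs) == 17_705

    def test_printed_dmr_code_counts(self, paper_tables):
        _, dmrs = paper_tables
        counts = dmrs.code.value_counts()
        for code, n in {
            "d_n_n": 2633, "u_n_n": 41, "n_d_n": 185, "n_u_n": 235,
            "d_n_u": 2064, "n_n_u": 378, "n_n_d": 94,
        }.items():
            assert counts[code] == n
        opposite = sum(counts.get(c, 0) for c in ("d_u_u", "d_d_u", "u_n_d", "u_u_d"))
        assert opposite == 1632

    def test_category_totals(self, paper_tables):
        genes, dmrs = paper_tables
        assert genes.category.value_counts().to_dict() == {
            "ADDITIVE": 376, "T3": 328, "XTALK": 103, "CORT": 38
        }
        assert dmrs.category.value_counts().to_dict() == {
            "XTALK": 11_576, "ADDITIVE": 3667, "T3": 1263, "CORT": 1199
        }

    def test_gene_overlap_count(self, paper_tables):
        _, dmrs = paper_tables
        assert (dmrs.nearest_gene_distance == 0).sum() == 4913

    def test_deterministic(self, paper_tables):
        again = sim.paper_counts_fixture()
        pd.testing.assert_frame_equal(paper_tables[0], again[0])
        pd.testing.assert_frame_equal(paper_tables[1], again[1])

    def test_all_xtalk_codes_are_xtalk(self, paper_tables):
        _, dmrs = paper_tables
        x = dmrs[dmrs.category == "XTALK"]
        assert set(x.code) <= set(XTALK_CODES)
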