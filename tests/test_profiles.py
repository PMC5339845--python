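"""Expression strata, metaprofiles, promoter summaries, rank correlations."""

import numpy as np
import pandas as pd
import pytest

import nomekit.simulate as sim
from nomekit.profiles import (
    exon_boundary_anchors,
    expression_correlations,
    expression_group,
    metaprofile,
    promoter_summary,
    promoter_table,
    read_bed12,
    read_gtf,
    tss_frame,
)

from conftest import make_calls


class TestExpressionGroups:
    @pytest.mark.parametrize(
        "rpkm,group",
        [
            (10.0, "intermediate"),  # (1, 10] boundary
            (10.01, "high"),
            (1.0, "low"),            # (0.1, 1] boundary
            (0.1, "silenced"),
            (0.0, "silenced"),
            (100.0, "high"),
            (0.5, "low"),
        ],
    )
    def test_boundary_literal_strata(self, rpkm, group):
        assert expression_group(rpkm) == group

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            expression_group(-0.1)


def uniform_calls(level_meth=3, level_unmeth=1, span=4000, spacing=10):
    rows = [("chr", p, "+", "GCH", level_meth, level_unmeth)
            for p in range(0, span, spacing)]
    return make_calls(rows)


class TestMetaprofile:
    def test_uniform_signal_gives_flat_profile(self):
        calls = uniform_calls()
        anchors = pd.DataFrame({"chrom": ["chr"], "pos": [2000], "strand": ["+"]})
        prof = metaprofile(calls, anchors, "GCH", flank=1000, bin_size=100)
        assert np.allclose(prof["level"].dropna(), 0.75)

    def test_minus_strand_profile_mirrors_plus(self):
        # asymmetric signal: methylated only downstream of the anchor
        rows = [("chr", p, "+", "GCH", (9 if p >= 2000 else 0), 1)
                for p in range(0, 4000, 10)]
        calls = make_calls(rows)
        plus = metaprofile(calls, pd.DataFrame({"chrom": ["chr"], "pos": [2000],
                                                "strand": ["+"]}),
                           "GCH", flank=1000, bin_size=100)
        minus = metaprofile(calls, pd.DataFrame({"chrom": ["chr"], "pos": [2000],
                                                 "strand": ["-"]}),
                            "GCH", flank=1000, bin_size=100)
        assert np.allclose(plus["level"].to_numpy(),
                           minus["level"].to_numpy()[::-1], equal_nan=True)

    def test_uncovered_bins_missing_not_zero(self):
        calls = make_calls([("chr", 2500, "+", "GCH", 5, 0)])
        prof = metaprofile(calls, pd.DataFrame({"chrom": ["chr"], "pos": [2000],
                                                "strand": ["+"]}),
                           "GCH", flank=1000, bin_size=100)
        assert prof["level"].notna().sum() == 1
        assert np.isnan(prof.loc[0, "level"])

    def test_open_promoters_peak_at_tss(self):
        cfg = sim.SimulationConfig(seed=21, genome_length=120_000, n_genes=20,
                                   n_nucleosomes=0, mean_depth=25.0)
        b = sim.simulate_study(cfg, [sim.SampleSpec("s", "fgc")])
        anchors = pd.DataFrame({"chrom": b.truth.genes["chrom"],
                                "pos": b.truth.genes["tss"],
                                "strand": b.truth.genes["strand"]})
        prof = metaprofile(b.samples["s"], anchors, "GCH", flank=1000, bin_size=50)
        peak_center = prof.loc[prof["level"].idxmax(), "bin_center"]
        assert abs(peak_center) <= 150  # planted NDR spans TSS +/- 150

    def test_wcg_dips_at_tss_with_hypomethylated_promoters(self):
        cfg = sim.SimulationConfig(seed=22, genome_length=120_000, n_genes=20,
                                   promoter_wcg_range=(0.02, 0.08), mean_depth=25.0)
        b = sim.simulate_study(cfg, [sim.SampleSpec("s", "soma")])
        anchors = pd.DataFrame({"chrom": b.truth.genes["chrom"],
                                "pos": b.truth.genes["tss"],
                                "strand": b.truth.genes["strand"]})
        prof = metaprofile(b.samples["s"], anchors, "WCG", flank=2000, bin_size=100)
        center = prof[np.abs(prof["bin_center"]) < 500]["level"].mean()
        edge = prof[np.abs(prof["bin_center"]) > 1500]["level"].mean()
        assert center < edge / 2

    def test_exon_preferential_protection(self):
        cfg = sim.SimulationConfig(seed=23, genome_length=200_000, n_genes=15,
                                   n_nucleosomes=0, gene_exons=3,
                                   exon_nucleosome_preference=True,
                                   baseline_open_prob=0.5, mean_depth=25.0)
        b = sim.simulate_study(cfg, [sim.SampleSpec("s", "fgc")])
        genes = b.truth.genes
        exon2 = [(g.chrom, *g.exons[1]) for g in genes.itertuples(index=False)]
        introns = []
        for g in genes.itertuples(index=False):
            spans = sorted([tuple(e) for e in g.exons])
            introns.append((g.chrom, spans[0][1], spans[1][0]))
        from nomekit.calls import regions_level
        exon_gch = regions_level(b.samples["s"], exon2, "GCH").level
        intron_gch = regions_level(b.samples["s"], introns, "GCH").level
        # protection = 1 - accessibility: higher inside exons
        assert (1 - exon_gch) > (1 - intron_gch)

    def test_flank_must_tile_bins(self):
        with pytest.raises(ValueError):
            metaprofile(uniform_calls(), pd.DataFrame({"chrom": ["chr"], "pos": [0],
                                                       "strand": ["+"]}),
                        "GCH", flank=1050, bin_size=100)


class TestPromoterSummary:
    def test_levels_from_both_contexts(self):
        calls = make_calls([
            ("chr", 950, "+", "GCH", 6, 2),
            ("chr", 1050, "+", "WCG", 1, 3),
        ])
        gch, wcg = promoter_summary({"chrom": "chr", "tss": 1000}, calls, flank=200)
        assert gch.level == pytest.approx(0.75)
        assert wcg.level == pytest.approx(0.25)

    def test_zero_coverage_promoter_undefined(self):
        calls = make_calls([("chr", 5000, "+", "GCH", 6, 2)])
        gch, wcg = promoter_summary({"chrom": "chr", "tss": 1000}, calls, flank=200)
        assert gch.level is None and wcg.level is None


class TestCorrelations:
    def test_rank_identical_gives_r1_one(self):
        expr = np.array([1.0, 2, 3, 4, 5])
        res = expression_correlations(expr, expr * 0.1, expr[::-1])
        assert res.r1 == pytest.approx(1.0)
        assert res.r2 == pytest.approx(-1.0)

    def test_hand_ranked_spearman(self):
        res = expression_correlations(
            np.array([1.0, 2, 3, 4, 5]),
            np.array([2.0, 1, 4, 3, 5]),
            np.array([1.0, 2, 3, 4, 5]),
        )
        assert res.r1 == pytest.approx(0.8)

    def test_nan_genes_dropped_pairwise(self):
        expr = np.array([1.0, 2, 3, 4, 5, 6])
        gch = np.array([1.0, 2, 3, 4, 5, np.nan])
        wcg = np.array([6.0, 5, 4, 3, 2, 1])
        res = expression_correlations(expr, gch, wcg)
        assert res.n1 == 5 and res.n2 == 6

    def test_too_few_genes_rejected(self):
        v = np.array([1.0, 2, 3])
        with pytest.raises(ValueError):
            expression_correlations(v, v, v)


class TestGeneModelReaders:
    def test_bed12_round_trip_via_simulator(self, tmp_path):
        cfg = sim.SimulationConfig(seed=4, genome_length=60_000, n_genes=6,
                                   gene_exons=3)
        _, truth = sim.simulate_genome(cfg)
        path = tmp_path / "genes.bed12"
        sim.write_gene_bed12(truth.genes, path)
        genes = read_bed12(path)
        assert len(genes) == 6
        assert set(genes["gene_id"]) == set(truth.genes["gene_id"])
        plus = truth.genes[truth.genes["strand"] == "+"]
        if len(plus):
            gid = plus.iloc[0]["gene_id"]
            assert genes.set_index("gene_id").loc[gid, "tss"] == plus.iloc[0]["exons"][0][0]

    def test_gtf_reader_minimal(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr\tsrc\texon\t501\t600\t.\t-\t.\tgene_id "g2";\n'
        )
        genes = read_gtf(gtf)
        g1 = genes.set_index("gene_id").loc["g1"]
        assert g1["tss"] == 100 and g1["tes"] == 400
        g2 = genes.set_index("gene_id").loc["g2"]
        assert g2["tss"] == 600 and g2["tes"] == 500

    def test_exon_boundary_anchors_strand_aware(self):
        genes = pd.DataFrame(
            [
                ("g1", "chr", "+", 0, 500, [[100, 200], [300, 400]]),
                ("g2", "chr", "-", 500, 0, [[100, 200]]),
            ],
            columns=["gene_id", "chrom", "strand", "tss", "tes", "exons"],
        )
        starts = exon_boundary_anchors(genes, "start")
        assert list(starts["pos"]) == [100, 300, 199]
        assert tss_frame(genes)["tss"].tolist() == [0, 500]
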