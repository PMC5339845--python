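"""Windowed chi-square segmentation: statistic, merging, classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, fisher_exact

import nomekit.simulate as sim
from nomekit.segmentation import (
    GenomeBackground,
    _merge_windows,
    call_ndrs,
    call_nucleosomes,
    classify_ndrs,
    compute_background,
    segments_to_bed,
    window_chi2_test,
    window_stats,
)

from conftest import make_calls


class TestBackground:
    def test_pooled_totals(self):
        calls = make_calls([
            ("chr", 10, "+", "GCH", 4, 1),
            ("chr", 20, "+", "GCH", 2, 3),
            ("chr", 30, "+", "GCH", 0, 5),
        ])
        bg = compute_background(calls, min_depth=3)
        assert (bg.total_meth, bg.total_unmeth) == (6, 9)
        assert bg.level == pytest.approx(0.4)

    def test_single_site(self):
        calls = make_calls([("chr", 10, "+", "GCH", 3, 1)])
        assert compute_background(calls, 3).level == pytest.approx(0.75)

    def test_no_qualifying_sites_rejected(self):
        calls = make_calls([("chr", 10, "+", "GCH", 1, 1)])
        with pytest.raises(ValueError):
            compute_background(calls, min_depth=3)


class TestChiSquare:
    def test_matches_contingency_oracle_on_small_tables(self):
        bg = GenomeBackground(500, 500)
        for wm in range(0, 21):
            for wu in range(0, 21 - wm):
                if wm + wu == 0:
                    continue
                p, _ = window_chi2_test(wm, wu, bg)
                table = [[wm, wu], [500, 500]]
                if wm == 0 or wu == 0:
                    continue  # zero-cell handling checked separately
                expected = chi2_contingency(table, correction=False)[1]
                assert p == pytest.approx(expected, rel=1e-9)

    def test_strong_open_enrichment(self):
        p, direction = window_chi2_test(60, 0, GenomeBackground(50_000, 50_000))
        assert direction == "open"
        assert -np.log10(p) > 5

    def test_strong_closed_enrichment(self):
        p, direction = window_chi2_test(0, 60, GenomeBackground(50_000, 50_000))
        assert direction == "closed"
        assert -np.log10(p) > 3

    def test_equal_proportion_gives_p_one(self):
        p, direction = window_chi2_test(5, 5, GenomeBackground(1000, 1000))
        assert p == 1.0 and direction == "none"

    def test_zero_depth_window_skipped(self):
        p, direction = window_chi2_test(0, 0, GenomeBackground(1000, 1000))
        assert p is None and direction == "none"

    def test_degenerate_background_column_gives_p_one(self):
        # all-methylated window against an all-methylated background: a
        # marginal is zero, the test is uninformative
        p, _ = window_chi2_test(10, 0, GenomeBackground(1000, 0))
        assert p == 1.0

    def test_p_ordering_agrees_with_exact_test(self):
        # clearly separated tables (2x in exact p) rank identically under
        # the asymptotic statistic; near-ties may legitimately reorder
        bg = GenomeBackground(700, 300)
        tables = [(1, 9), (5, 5), (9, 1), (12, 3), (2, 28), (25, 5)]
        chi_ps = [window_chi2_test(m, u, bg)[0] for m, u in tables]
        exact_ps = [fisher_exact([[m, u], [700, 300]])[1] for m, u in tables]
        for i in range(len(tables)):
            for j in range(len(tables)):
                if exact_ps[i] < exact_ps[j] / 2:
                    assert chi_ps[i] < chi_ps[j]


class TestMerging:
    def windows(self, spans, score=9.0):
        return pd.DataFrame(
            [("chr", s, e, score) for s, e in spans],
            columns=["chrom", "start", "end", "score"],
        )

    def test_overlapping_windows_merge(self):
        seg = _merge_windows(self.windows([(0, 100), (20, 120), (40, 140)]),
                             min_len=140, seg_type="NDR", merge_gap=0)
        assert len(seg) == 1
        assert (seg.loc[0, "start"], seg.loc[0, "end"], seg.loc[0, "n_windows"]) == (0, 140, 3)

    def test_short_merged_run_discarded(self):
        seg = _merge_windows(self.windows([(0, 100), (20, 120)]),
                             min_len=140, seg_type="NDR", merge_gap=0)
        assert len(seg) == 0

    def test_55bp_nucleosome_run_discarded(self):
        seg = _merge_windows(self.windows([(0, 55)]), min_len=60,
                             seg_type="nucleosome", merge_gap=0)
        assert len(seg) == 0

    def test_book_ended_windows_merge_but_gapped_do_not(self):
        seg = _merge_windows(self.windows([(0, 100), (100, 200), (301, 460)]),
                             min_len=140, seg_type="NDR", merge_gap=0)
        assert list(seg["start"]) == [0, 301]
        assert list(seg["end"]) == [200, 460]

    def test_score_is_max_over_merged_windows(self):
        win = self.windows([(0, 100), (20, 120), (40, 140)])
        win.loc[1, "score"] = 33.0
        seg = _merge_windows(win, 140, "NDR", 0)
        assert seg.loc[0, "score"] == 33.0


@pytest.fixture(scope="module")
def ndr_study():
    cfg = sim.SimulationConfig(seed=3, genome_length=200_000, n_genes=40,
                               n_nucleosomes=0, mean_depth=20.0)
    bundle = sim.simulate_study(cfg, [sim.SampleSpec("s", "fgc")])
    calls = bundle.samples["s"]
    return bundle, calls, compute_background(calls)


class TestCalling:
    def test_planted_ndrs_recovered_near_centers(self, ndr_study):
        bundle, calls, bg = ndr_study
        ndrs = call_ndrs(calls, bg)
        truth_centers = ((bundle.truth.ndrs["start"] + bundle.truth.ndrs["end"]) // 2).to_numpy()
        centers = ((ndrs["start"] + ndrs["end"]) // 2).to_numpy()
        hits = sum(np.abs(centers - c).min() <= 100 for c in truth_centers)
        assert hits >= 0.9 * len(truth_centers)

    def test_score_cut_monotone(self, ndr_study):
        _, calls, bg = ndr_study
        counts = [len(call_ndrs(calls, bg, score_cut=c)) for c in (3.0, 5.0, 10.0, 50.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_ndr_and_nucleosome_calls_never_overlap(self, ndr_study):
        _, calls, bg = ndr_study
        ndrs = call_ndrs(calls, bg)
        nucs = call_nucleosomes(calls, bg)
        for seg in nucs.itertuples(index=False):
            same = ndrs[ndrs["chrom"] == seg.chrom]
            assert not ((same["start"] < seg.end) & (same["end"] > seg.start)).any()

    def test_invert_directions_swaps_call_sets(self, ndr_study):
        _, calls, bg = ndr_study
        literal = call_ndrs(calls, bg, invert_directions=True)
        chemistry = call_nucleosomes(calls, bg, window=100, step=20,
                                     score_cut=5.0, min_len=140)
        assert literal[["chrom", "start", "end"]].equals(chemistry[["chrom", "start", "end"]])

    def test_deterministic_byte_identical_bed(self, ndr_study, tmp_path):
        _, calls, bg = ndr_study
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        segments_to_bed(call_ndrs(calls, bg), p1)
        segments_to_bed(call_ndrs(calls, bg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_uniform_genome_yields_no_calls(self):
        cfg = sim.SimulationConfig(seed=9, genome_length=150_000, n_genes=0,
                                   n_nucleosomes=0, mean_depth=20.0)
        bundle = sim.simulate_study(cfg, [sim.SampleSpec("s", "fgc")])
        calls = bundle.samples["s"]
        bg = compute_background(calls)
        assert len(call_ndrs(calls, bg)) == 0
        assert len(call_nucleosomes(calls, bg)) == 0

    def test_window_stats_schema(self, ndr_study):
        _, calls, bg = ndr_study
        win = window_stats(calls, bg)
        assert {"chrom", "start", "end", "p_value", "score", "direction"} <= set(win.columns)
        covered = win[win["n_sites"] > 0]
        assert ((covered["p_value"] > 0) & (covered["p_value"] <= 1)).all()


class TestProximity:
    TSS = pd.DataFrame({"gene_id": ["g1", "g2"], "chrom": ["chr", "chr"],
                        "tss": [10_000, 50_000]})

    def seg(self, center):
        return pd.DataFrame([("chr", center - 70, center + 70, "NDR", 9.0, 3)],
                            columns=["chrom", "start", "end", "seg_type", "score", "n_windows"])

    def test_1999_is_proximal(self):
        out = classify_ndrs(self.seg(11_999), self.TSS)
        assert out.loc[0, "proximity"] == "proximal"
        assert out.loc[0, "distance"] == 1999

    def test_2000_tie_is_distal(self):
        out = classify_ndrs(self.seg(12_000), self.TSS)
        assert out.loc[0, "proximity"] == "distal"

    def test_center_at_tss(self):
        out = classify_ndrs(self.seg(10_000), self.TSS)
        assert out.loc[0, "distance"] == 0
        assert out.loc[0, "nearest_tss"] == "g1"

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            classify_ndrs(self.seg(0), self.TSS.iloc[:0])
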