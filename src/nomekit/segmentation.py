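"""NDR and nucleosome calling by windowed chi-square enrichment.

The genome is tiled with sliding windows (100 bp / 20 bp step for NDRs,
40 bp / 20 bp for nucleosomes).  Within each window the read counts of every
GCH site at depth >= 3 are summed and a 2x2 chi-square test (no continuity
correction) compares the window's methylated/unmethylated totals against the
genome-wide GCH background.  Windows above the score cutoff (-log10 p > 5
for NDRs, > 3 for nucleosomes) in the right direction are merged when they
overlap or abut, and merged segments below the minimum length (140 bp for
NDRs, 60 bp for nucleosomes) are discarded.

Direction convention: M.CviPI methylates GpC in *accessible* chromatin, so
an NDR is a run of windows *enriched* for methylated GCH reads and a
positioned nucleosome is a run *depleted* of them.  ``invert_directions``
swaps the two for compatibility with pipelines using the opposite wording.

NDRs are classed proximal/distal by the distance from their center to the
nearest annotated TSS (distal iff >= 2 kb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .calls import DEFAULT_MIN_DEPTH, SampleCalls

__all__ = [
    "GenomeBackground",
    "compute_background",
    "window_chi2_test",
    "window_stats",
    "call_ndrs",
    "call_nucleosomes",
    "classify_ndrs",
    "segments_to_bed",
    "PROXIMAL_CUTOFF",
]

P_FLOOR = 1e-300          # avoids -log10 underflow at extreme enrichment
PROXIMAL_CUTOFF = 2000    # center-to-TSS distance; >= cutoff is distal

SEGMENT_COLUMNS = ["chrom", "start", "end", "seg_type", "score", "n_windows"]


@dataclass
class GenomeBackground:
    """Genome-wide pooled GCH read totals — the chi-square null."""

    total_meth: int
    total_unmeth: int

    @property
    def level(self) -> float:
        return self.total_meth / (self.total_meth + self.total_unmeth)


def compute_background(calls: SampleCalls, min_depth: int = DEFAULT_MIN_DEPTH) -> GenomeBackground:
    """Pool every qualifying GCH site of the sample into the null totals."""
    tm = tu = 0
    for chrom in calls.chroms:
        _, meth, unmeth = calls.arrays(chrom, "GCH", min_depth)
        tm += int(meth.sum())
        tu += int(unmeth.sum())
    if tm + tu == 0:
        raise ValueError("no GCH site passes the depth filter; cannot form a background")
    return GenomeBackground(tm, tu)


def _chi2_2x2(wm: np.ndarray, wu: np.ndarray, bm: float, bu: float) -> np.ndarray:
    """Vectorised 2x2 chi-square p-values, window counts vs background totals.

    p = 1 whenever a marginal is zero (an expected cell would be 0) or the
    statistic is 0; otherwise chi2 survival with 1 df, floored at P_FLOOR.
    """
    wm = wm.astype(np.float64)
    wu = wu.astype(np.float64)
    n = wm + wu + bm + bu
    r1 = wm + wu
    r2 = np.float64(bm + bu)
    c1 = wm + bm
    c2 = wu + bu
    denom = r1 * r2 * c1 * c2
    valid = denom > 0
    stat = np.zeros_like(wm)
    np.divide(n * (wm * bu - wu * bm) ** 2, denom, out=stat, where=valid)
    p = np.ones_like(stat)
    nz = valid & (stat > 0)
    p[nz] = np.maximum(chi2.sf(stat[nz], 1), P_FLOOR)
    return p


def window_chi2_test(window_meth: int, window_unmeth: int,
                     background: GenomeBackground) -> tuple[float | None, str]:
    """Chi-square enrichment of one window against the genome background.

    Returns (p_value, direction); direction is ``open`` when the window's
    GCH methylation exceeds the background proportion, ``closed`` below it,
    ``none`` at equality.  Zero window depth gives (None, "none") — the
    window is undetected, not significant.
    """
    depth = window_meth + window_unmeth
    if depth == 0:
        return None, "none"
    p = float(_chi2_2x2(np.array([window_meth]), np.array([window_unmeth]),
                        background.total_meth, background.total_unmeth)[0])
    wl = window_meth / depth
    if wl > background.level:
        direction = "open"
    elif wl < background.level:
        direction = "closed"
    else:
        direction = "none"
    return p, direction


def window_stats(calls: SampleCalls, background: GenomeBackground, *,
                 window: int = 100, step: int = 20,
                 min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Full per-window table: counts, n_sites, p-value, direction, score."""
    frames = []
    for chrom in calls.chroms:
        w = _chrom_windows(calls, chrom, background, window, step, min_depth)
        if w is not None:
            frames.append(w)
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "meth", "unmeth",
                                     "n_sites", "p_value", "score", "direction"])
    return pd.concat(frames, ignore_index=True)


def _chrom_windows(calls: SampleCalls, chrom: str, background: GenomeBackground,
                   window: int, step: int, min_depth: int) -> pd.DataFrame | None:
    pos, meth, unmeth = calls.arrays(chrom, "GCH", min_depth)
    if len(pos) == 0:
        return None
    starts = np.arange(0, pos[-1] + 1, step, dtype=np.int64)
    i0 = np.searchsorted(pos, starts)
    i1 = np.searchsorted(pos, starts + window)
    cm = np.concatenate(([0], np.cumsum(meth)))
    cu = np.concatenate(([0], np.cumsum(unmeth)))
    wm = cm[i1] - cm[i0]
    wu = cu[i1] - cu[i0]
    n_sites = i1 - i0
    depth = wm + wu
    covered = depth > 0
    p = np.ones(len(starts))
    p[covered] = _chi2_2x2(wm[covered], wu[covered],
                           background.total_meth, background.total_unmeth)
    level = np.divide(wm, depth, out=np.full(len(starts), np.nan), where=covered)
    direction = np.where(~covered | (level == background.level), "none",
                         np.where(level > background.level, "open", "closed"))
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + window,
            "meth": wm,
            "unmeth": wu,
            "n_sites": n_sites,
            "p_value": np.where(covered, p, np.nan),
            "score": np.where(covered, -np.log10(p), np.nan),
            "direction": direction,
        }
    )


def _merge_windows(win: pd.DataFrame, min_len: int, seg_type: str,
                   merge_gap: int) -> pd.DataFrame:
    """Merge overlapping/book-ended significant windows into segments."""
    rows = []
    for chrom, grp in win.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        scores = grp["score"].to_numpy()
        i = 0
        while i < len(starts):
            s, e, sc, n = starts[i], ends[i], scores[i], 1
            j = i + 1
            while j < len(starts) and starts[j] <= e + merge_gap:
                e = max(e, ends[j])
                sc = max(sc, scores[j])
                n += 1
                j += 1
            if e - s >= min_len:
                rows.append((chrom, int(s), int(e), seg_type, float(sc), int(n)))
            i = j
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def _call_segments(calls: SampleCalls, background: GenomeBackground, *,
                   window: int, step: int, min_depth: int, score_cut: float,
                   min_len: int, direction: str, seg_type: str,
                   merge_gap: int) -> pd.DataFrame:
    win = window_stats(calls, background, window=window, step=step, min_depth=min_depth)
    if not len(win):
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    sig = win[(win["direction"] == direction) & (win["score"] > score_cut)
              & (win["n_sites"] >= 1)]
    return _merge_windows(sig, min_len, seg_type, merge_gap)


def call_ndrs(calls: SampleCalls, background: GenomeBackground, *,
              window: int = 100, step: int = 20,
              min_depth: int = DEFAULT_MIN_DEPTH, score_cut: float = 5.0,
              min_len: int = 140, merge_gap: int = 0,
              invert_directions: bool = False) -> pd.DataFrame:
    """Call nucleosome-depleted regions (methylated-GCH-enriched windows)."""
    direction = "closed" if invert_directions else "open"
    return _call_segments(calls, background, window=window, step=step,
                          min_depth=min_depth, score_cut=score_cut,
                          min_len=min_len, direction=direction,
                          seg_type="NDR", merge_gap=merge_gap)


def call_nucleosomes(calls: SampleCalls, background: GenomeBackground, *,
                     window: int = 40, step: int = 20,
                     min_depth: int = DEFAULT_MIN_DEPTH, score_cut: float = 3.0,
                     min_len: int = 60, merge_gap: int = 0,
                     invert_directions: bool = False) -> pd.DataFrame:
    """Call positioned nucleosomes (methylated-GCH-depleted windows)."""
    direction = "open" if invert_directions else "closed"
    return _call_segments(calls, background, window=window, step=step,
                          min_depth=min_depth, score_cut=score_cut,
                          min_len=min_len, direction=direction,
                          seg_type="nucleosome", merge_gap=merge_gap)


def classify_ndrs(segments: pd.DataFrame, tss: pd.DataFrame,
                  proximal_cutoff: int = PROXIMAL_CUTOFF) -> pd.DataFrame:
    """Annotate NDR segments with nearest-TSS distance and proximity class.

    ``tss`` needs columns gene_id, chrom, tss.  Distance is measured from the
    segment center to the nearest TSS on the same chromosome; segments on
    chromosomes without any TSS get infinite distance (distal, no gene).
    Proximal iff distance < proximal_cutoff; a tie at the cutoff is distal
    ("at least 2 kb away").
    """
    if not len(tss):
        raise ValueError("TSS set is empty")
    out = segments.copy()
    centers = ((out["start"] + out["end"]) // 2).to_numpy(np.int64)
    nearest_gene = np.full(len(out), None, dtype=object)
    distance = np.full(len(out), np.inf)
    for chrom, grp in tss.groupby("chrom", sort=False):
        mask = (out["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        order = np.argsort(grp["tss"].to_numpy())
        tpos = grp["tss"].to_numpy(np.int64)[order]
        tgene = grp["gene_id"].to_numpy()[order]
        c = centers[mask]
        j = np.clip(np.searchsorted(tpos, c), 0, len(tpos) - 1)
        jlo = np.clip(j - 1, 0, len(tpos) - 1)
        pick = np.where(np.abs(tpos[j] - c) <= np.abs(tpos[jlo] - c), j, jlo)
        distance[mask] = np.abs(tpos[pick] - c)
        nearest_gene[mask] = tgene[pick]
    out["center"] = centers
    out["nearest_tss"] = nearest_gene
    out["distance"] = distance
    out["proximity"] = np.where(distance < proximal_cutoff, "proximal", "distal")
    return out


def segments_to_bed(segments: pd.DataFrame, path) -> None:
    """BED6: name = segment type, score = min(1000, round(10 * -log10 p))."""
    score = np.minimum(1000, np.round(10 * segments["score"].to_numpy(float))).astype(int)
    out = pd.DataFrame(
        {
            "chrom": segments["chrom"],
            "start": segments["start"],
            "end": segments["end"],
            "name": segments["seg_type"],
            "score": score,
            "strand": ".",
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
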