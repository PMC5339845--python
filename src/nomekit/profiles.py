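"""Metaprofiles, expression grouping, and accessibility-expression correlation.

Aggregates GCH (accessibility) or WCG (endogenous methylation) levels into
binned profiles around anchor coordinates (TSS, TES, NDR centers, exon
boundaries), stratifies genes by RPKM, summarises promoters (TSS +/- 1 kb by
default), and computes the two promoter-level Spearman correlations: r1 =
rho(expression, promoter accessibility) and r2 = rho(expression, promoter
endogenous methylation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .calls import DEFAULT_MIN_DEPTH, SampleCalls, region_level

__all__ = [
    "expression_group",
    "EXPRESSION_GROUPS",
    "metaprofile",
    "promoter_summary",
    "promoter_table",
    "expression_correlations",
    "CorrelationResult",
    "read_bed12",
    "read_gtf",
    "tss_frame",
    "exon_boundary_anchors",
    "sliding_gene_means",
]

#: ordered from silent to most active
EXPRESSION_GROUPS = ("silenced", "low", "intermediate", "high")

DEFAULT_PROMOTER_FLANK = 1000


def expression_group(rpkm: float) -> str:
    """RPKM strata: high > 10, intermediate (1, 10], low (0.1, 1], silenced <= 0.1."""
    if rpkm < 0:
        raise ValueError(f"expression must be non-negative, got {rpkm}")
    if rpkm > 10:
        return "high"
    if rpkm > 1:
        return "intermediate"
    if rpkm > 0.1:
        return "low"
    return "silenced"


def metaprofile(calls: SampleCalls, anchors: pd.DataFrame, context: str, *,
                flank: int = 2000, bin_size: int = 20, strand_aware: bool = True,
                min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Pooled per-bin level across anchors over [-flank, +flank).

    ``anchors`` needs columns chrom, pos and (if strand_aware) strand;
    minus-strand anchors are flipped so that positive offsets point
    downstream.  Bins without any covered site have level NaN (missing, not
    zero).  Returns bin_center, level, n_sites, meth, unmeth.
    """
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    if not len(anchors):
        raise ValueError("no anchors")
    n_bins = 2 * flank // bin_size
    meth = np.zeros(n_bins, dtype=np.int64)
    unmeth = np.zeros(n_bins, dtype=np.int64)
    n_sites = np.zeros(n_bins, dtype=np.int64)
    for chrom, grp in anchors.groupby("chrom", sort=False):
        pos, m, u = calls.arrays(chrom, context, min_depth)
        if len(pos) == 0:
            continue
        for row in grp.itertuples(index=False):
            a = int(row.pos)
            i0, i1 = np.searchsorted(pos, [a - flank, a + flank])
            if i0 == i1:
                continue
            offset = pos[i0:i1] - a
            if strand_aware and getattr(row, "strand", "+") == "-":
                offset = -offset - 1
            b = (offset + flank) // bin_size
            np.add.at(meth, b, m[i0:i1])
            np.add.at(unmeth, b, u[i0:i1])
            np.add.at(n_sites, b, 1)
    depth = meth + unmeth
    level = np.divide(meth, depth, out=np.full(n_bins, np.nan), where=depth > 0)
    centers = np.arange(n_bins) * bin_size - flank + bin_size // 2
    return pd.DataFrame({"bin_center": centers, "level": level,
                         "n_sites": n_sites, "meth": meth, "unmeth": unmeth})


def promoter_summary(gene, calls: SampleCalls, *,
                     flank: int = DEFAULT_PROMOTER_FLANK,
                     min_depth: int = DEFAULT_MIN_DEPTH):
    """(GCH, WCG) pooled levels over the promoter window TSS +/- flank.

    ``gene`` is any object with chrom and tss attributes (or a mapping).
    The window is clipped at the chromosome start.
    """
    if isinstance(gene, dict):
        chrom, tss = gene["chrom"], gene["tss"]
    else:
        chrom, tss = gene.chrom, gene.tss
    region = (chrom, max(0, int(tss) - flank), int(tss) + flank)
    gch = region_level(calls, region, "GCH", min_depth)
    wcg = region_level(calls, region, "WCG", min_depth)
    return gch, wcg


def promoter_table(genes: pd.DataFrame, calls: SampleCalls, *,
                   flank: int = DEFAULT_PROMOTER_FLANK,
                   min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """Per-gene promoter GCH/WCG levels (NaN where undefined)."""
    rows = []
    for g in genes.itertuples(index=False):
        gch, wcg = promoter_summary(g, calls, flank=flank, min_depth=min_depth)
        rows.append((g.gene_id,
                     np.nan if gch.level is None else gch.level,
                     np.nan if wcg.level is None else wcg.level,
                     gch.n_sites_used, wcg.n_sites_used))
    return pd.DataFrame(rows, columns=["gene_id", "gch_level", "wcg_level",
                                       "n_gch_sites", "n_wcg_sites"])


@dataclass
class CorrelationResult:
    r1: float   # Spearman(expression, promoter accessibility)
    p1: float
    r2: float   # Spearman(expression, promoter endogenous methylation)
    p2: float
    n1: int
    n2: int


def expression_correlations(expr: np.ndarray, gch: np.ndarray,
                            wcg: np.ndarray, min_n: int = 5) -> CorrelationResult:
    """The two promoter-level rank correlations, dropping NaN genes pairwise."""
    expr = np.asarray(expr, float)
    gch = np.asarray(gch, float)
    wcg = np.asarray(wcg, float)
    if not (len(expr) == len(gch) == len(wcg)):
        raise ValueError("vectors must be aligned per gene")
    m1 = np.isfinite(expr) & np.isfinite(gch)
    m2 = np.isfinite(expr) & np.isfinite(wcg)
    if m1.sum() < min_n or m2.sum() < min_n:
        raise ValueError(f"fewer than {min_n} genes with defined levels")
    r1, p1 = spearmanr(expr[m1], gch[m1])
    r2, p2 = spearmanr(expr[m2], wcg[m2])
    return CorrelationResult(float(r1), float(p1), float(r2), float(p2),
                             int(m1.sum()), int(m2.sum()))


def sliding_gene_means(expr: np.ndarray, level: np.ndarray,
                       window: int = 100, step: int = 1) -> pd.DataFrame:
    """Moving-average presentation: mean level in expression-rank windows."""
    order = np.argsort(expr, kind="mergesort")
    lv = np.asarray(level, float)[order]
    rows = []
    for s in range(0, max(1, len(lv) - window + 1), step):
        chunk = lv[s:s + window]
        rows.append((s + window / 2, float(np.nanmean(chunk))))
    return pd.DataFrame(rows, columns=["rank_center", "mean_level"])


# ---------------------------------------------------------------------------
# gene-model readers (BED12 and a GTF subset)

_BED12_COLS = ["chrom", "start", "end", "name", "score", "strand", "thick_start",
               "thick_end", "rgb", "block_count", "block_sizes", "block_starts"]


def read_bed12(path) -> pd.DataFrame:
    """BED12 gene models -> gene_id, chrom, strand, tss, tes, exon lists."""
    raw = pd.read_csv(path, sep="\t", header=None, names=_BED12_COLS, comment="#")
    rows = []
    for r in raw.itertuples(index=False):
        sizes = [int(x) for x in str(r.block_sizes).rstrip(",").split(",")]
        offs = [int(x) for x in str(r.block_starts).rstrip(",").split(",")]
        exons = [(r.start + o, r.start + o + s) for o, s in zip(offs, sizes)]
        tss, tes = (r.start, r.end) if r.strand == "+" else (r.end, r.start)
        rows.append((r.name, r.chrom, r.strand, tss, tes, exons))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes", "exons"])


def read_gtf(path) -> pd.DataFrame:
    """Minimal GTF subset reader: exon features grouped by gene_id."""
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] not in ("exon", "gene", "transcript"):
                continue
            attrs = dict(
                (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
                for kv in f[8].rstrip(";").split(";") if kv.strip()
            )
            gid = attrs.get("gene_id")
            if gid is None:
                continue
            rec = genes.setdefault(gid, {"chrom": f[0], "strand": f[6], "exons": []})
            if f[2] == "exon":
                rec["exons"].append((int(f[3]) - 1, int(f[4])))  # GTF is 1-based closed
    rows = []
    for gid, rec in genes.items():
        exons = sorted(set(rec["exons"]))
        if not exons:
            continue
        lo, hi = exons[0][0], exons[-1][1]
        tss, tes = (lo, hi) if rec["strand"] == "+" else (hi, lo)
        rows.append((gid, rec["chrom"], rec["strand"], tss, tes, exons))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes", "exons"])


def tss_frame(genes: pd.DataFrame) -> pd.DataFrame:
    """gene_id, chrom, tss — the TSS catalog used for proximity classing."""
    return genes[["gene_id", "chrom", "tss"]].copy()


def exon_boundary_anchors(genes: pd.DataFrame, kind: str = "start") -> pd.DataFrame:
    """Exon start (intron->exon) or end (exon->intron) anchors, strand-aware.

    For minus-strand genes the genomic roles are swapped so that positive
    profile offsets always point into the exon for ``start`` anchors.
    """
    rows = []
    for g in genes.itertuples(index=False):
        for (s, e) in g.exons:
            if g.strand == "+":
                pos = s if kind == "start" else e
            else:
                pos = e - 1 if kind == "start" else s - 1
            rows.append((g.chrom, pos, g.strand))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
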