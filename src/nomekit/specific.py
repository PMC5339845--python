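"""Cell-type-specific proximal NDRs and the cross-sample correlation structure.

A proximal NDR is called cell-type specific when its accessibility across
samples tracks the expression of its nearest gene (Spearman r > 0.6,
p < 0.1, asymptotic p, uncorrected) and it is assigned to the sample group
with the highest mean accessibility.  The module also emits the pairwise
sample distance matrix (1 - Spearman rho, pairwise-complete observations)
that hierarchical clustering or MDS consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .calls import DEFAULT_MIN_DEPTH, SampleCalls, region_level

__all__ = [
    "build_signal_matrix",
    "sample_distance_matrix",
    "call_specific_ndrs",
    "union_segments",
    "write_matrix",
    "read_matrix",
]

R_CUT = 0.6
P_CUT = 0.1


def ndr_id(chrom, start, end) -> str:
    return f"{chrom}:{start}-{end}"


def union_segments(segment_frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-sample segment calls into a union interval set."""
    allseg = pd.concat(segment_frames, ignore_index=True)
    rows = []
    for chrom, grp in allseg.sort_values(["chrom", "start"]).groupby("chrom", sort=False):
        cur_s = cur_e = None
        for r in grp.itertuples(index=False):
            if cur_s is None:
                cur_s, cur_e = r.start, r.end
            elif r.start <= cur_e:
                cur_e = max(cur_e, r.end)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = r.start, r.end
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out["seg_type"] = "NDR"
    return out


def build_signal_matrix(ndrs: pd.DataFrame, samples: dict[str, SampleCalls],
                        min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """NDR x sample matrix of pooled GCH levels; NaN where undefined."""
    if not len(ndrs):
        raise ValueError("empty NDR list")
    ids = [ndr_id(r.chrom, r.start, r.end) for r in ndrs.itertuples(index=False)]
    data = {}
    for sid, calls in samples.items():
        col = []
        for r in ndrs.itertuples(index=False):
            lv = region_level(calls, (r.chrom, r.start, r.end), "GCH", min_depth).level
            col.append(np.nan if lv is None else lv)
        data[sid] = col
    return pd.DataFrame(data, index=pd.Index(ids, name="ndr"))


def sample_distance_matrix(matrix: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """1 - pairwise-complete Spearman rho between sample columns.

    Pairs sharing fewer than ``min_shared`` rows get a missing distance.
    Diagonal is exactly 0.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    rho = matrix.corr(method="spearman", min_periods=min_shared)
    dist = 1.0 - rho
    np.fill_diagonal(dist.values, 0.0)
    return dist


def call_specific_ndrs(matrix: pd.DataFrame, expression: pd.DataFrame,
                       ndr_gene: dict[str, str], groups: dict[str, str], *,
                       r_cut: float = R_CUT, p_cut: float = P_CUT,
                       min_samples: int = 5,
                       wcg_matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Retain proximal NDRs whose accessibility tracks nearest-gene expression.

    ``matrix``: NDR x sample GCH levels; ``expression``: gene x sample RPKM;
    ``ndr_gene``: NDR id -> nearest gene id; ``groups``: sample -> group
    label.  An NDR is retained when Spearman(accessibility, expression)
    > r_cut with p < p_cut over >= min_samples paired samples, and assigned
    to the group with the highest mean accessibility.  The endogenous
    methylation-expression correlation is annotated when ``wcg_matrix`` is
    given (it never gates retention).
    """
    shared = [s for s in matrix.columns if s in expression.columns]
    rows = []
    for nid in matrix.index:
        gene = ndr_gene.get(nid)
        rec = {"ndr": nid, "gene": gene, "r_access_expr": np.nan,
               "p_access_expr": np.nan, "r_meth_expr": np.nan,
               "n_samples": 0, "assigned": "none"}
        if gene is not None and gene in expression.index:
            acc = matrix.loc[nid, shared].to_numpy(float)
            expr = expression.loc[gene, shared].to_numpy(float)
            ok = np.isfinite(acc) & np.isfinite(expr)
            rec["n_samples"] = int(ok.sum())
            if ok.sum() >= min_samples and len(set(acc[ok])) > 1 and len(set(expr[ok])) > 1:
                r, p = spearmanr(acc[ok], expr[ok])
                rec["r_access_expr"], rec["p_access_expr"] = float(r), float(p)
                if wcg_matrix is not None and nid in wcg_matrix.index:
                    w = wcg_matrix.loc[nid, shared].to_numpy(float)
                    okw = np.isfinite(w) & np.isfinite(expr)
                    if okw.sum() >= min_samples and len(set(w[okw])) > 1:
                        rec["r_meth_expr"] = float(spearmanr(w[okw], expr[okw])[0])
                if r > r_cut and p < p_cut:
                    means = {}
                    for g in sorted(set(groups.values())):
                        cols = [s for s in shared if groups.get(s) == g]
                        vals = matrix.loc[nid, cols].to_numpy(float)
                        if np.isfinite(vals).any():
                            means[g] = np.nanmean(vals)
                    if means:
                        rec["assigned"] = max(means, key=means.get)
        rows.append(rec)
    return pd.DataFrame(rows)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", na_rep="NA")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
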