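"""Accessibility and residual methylation over annotated genomic elements.

Summarises pooled GCH (accessibility) and WCG (endogenous methylation)
levels over element classes (CGI, promoters, exons, repeats, ...), reports
relative accessibility enrichment as log2(class GCH level / genome GCH
level), classifies promoters into HCP/ICP/LCP by CpG density around the
TSS, and groups repeat summaries by family/subfamily.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import DEFAULT_MIN_DEPTH, SampleCalls, genome_mean_level, regions_level

__all__ = [
    "ElementSummary",
    "element_summary",
    "element_table",
    "classify_promoter_cpg",
    "promoter_cpg_classes",
    "repeat_family_summary",
    "read_annotation_bed",
]

# Weber-style promoter CpG-density convention on TSS +/- 500 bp
CPG_OE_HIGH = 0.75
CPG_GC_HIGH = 0.55
CPG_OE_LOW = 0.48
PROMOTER_CPG_FLANK = 500


@dataclass
class ElementSummary:
    label: str
    gch_level: float | None
    wcg_level: float | None
    relative_enrichment: float | None  # log2(class GCH / genome GCH)
    n_gch_sites: int
    n_wcg_sites: int
    n_intervals: int


def element_summary(calls: SampleCalls, intervals: pd.DataFrame, label: str, *,
                    genome_gch_level: float | None = None,
                    min_depth: int = DEFAULT_MIN_DEPTH) -> ElementSummary:
    """Pooled GCH/WCG levels over every interval of one element class."""
    if not len(intervals):
        raise ValueError(f"element class {label!r} has no intervals")
    regions = list(intervals[["chrom", "start", "end"]].itertuples(index=False, name=None))
    gch = regions_level(calls, regions, "GCH", min_depth)
    wcg = regions_level(calls, regions, "WCG", min_depth)
    if genome_gch_level is None:
        genome_gch_level = genome_mean_level(calls, "GCH", min_depth).level
    enrich = None
    if gch.level is not None and genome_gch_level and gch.level > 0:
        enrich = float(np.log2(gch.level / genome_gch_level))
    return ElementSummary(label, gch.level, wcg.level, enrich,
                          gch.n_sites_used, wcg.n_sites_used, len(intervals))


def element_table(calls: SampleCalls, annotation: pd.DataFrame, *,
                  label_col: str = "label",
                  min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """One summary row per element class in ``annotation``."""
    genome_gch = genome_mean_level(calls, "GCH", min_depth).level
    rows = []
    for label, grp in annotation.groupby(label_col, sort=True):
        s = element_summary(calls, grp, str(label),
                            genome_gch_level=genome_gch, min_depth=min_depth)
        rows.append(vars(s))
    return pd.DataFrame(rows)


def classify_promoter_cpg(window_seq: str, *, oe_high: float = CPG_OE_HIGH,
                          gc_high: float = CPG_GC_HIGH,
                          oe_low: float = CPG_OE_LOW) -> str:
    """HCP/ICP/LCP from CpG observed/expected and GC fraction of a window.

    o/e = (#CpG * length) / (#C * #G); HCP iff o/e >= oe_high and GC >=
    gc_high; LCP iff o/e < oe_low; ICP otherwise.  Windows without any C or
    G are LCP (no CpG potential).
    """
    seq = window_seq.upper()
    n = len(seq)
    if n == 0:
        return "LCP"
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cg = seq.count("CG")
    if n_c * n_g == 0:
        return "LCP"
    oe = n_cg * n / (n_c * n_g)
    gc = (n_c + n_g) / n
    if oe >= oe_high and gc >= gc_high:
        return "HCP"
    if oe < oe_low:
        return "LCP"
    return "ICP"


def promoter_cpg_classes(genome: dict[str, str], genes: pd.DataFrame, *,
                         flank: int = PROMOTER_CPG_FLANK, **thresholds) -> pd.DataFrame:
    """Classify every gene's promoter (TSS +/- flank, clipped) into HCP/ICP/LCP."""
    rows = []
    for g in genes.itertuples(index=False):
        seq = genome[g.chrom]
        lo = max(0, int(g.tss) - flank)
        hi = min(len(seq), int(g.tss) + flank)
        rows.append((g.gene_id, classify_promoter_cpg(seq[lo:hi], **thresholds)))
    return pd.DataFrame(rows, columns=["gene_id", "cpg_class"])


def repeat_family_summary(calls: SampleCalls, repeats: pd.DataFrame, *,
                          min_depth: int = DEFAULT_MIN_DEPTH) -> pd.DataFrame:
    """One summary per repeat (family, subfamily); unlabeled -> 'unassigned'."""
    if not len(repeats):
        return pd.DataFrame(columns=["family", "subfamily", "gch_level", "wcg_level",
                                     "relative_enrichment", "n_gch_sites",
                                     "n_wcg_sites", "n_intervals"])
    rep = repeats.copy()
    for col in ("family", "subfamily"):
        if col not in rep.columns:
            rep[col] = "unassigned"
        rep[col] = rep[col].fillna("unassigned").replace("", "unassigned")
    genome_gch = genome_mean_level(calls, "GCH", min_depth).level
    rows = []
    for (fam, sub), grp in rep.groupby(["family", "subfamily"], sort=True):
        s = element_summary(calls, grp, f"{fam}/{sub}",
                            genome_gch_level=genome_gch, min_depth=min_depth)
        rows.append({"family": fam, "subfamily": sub, "gch_level": s.gch_level,
                     "wcg_level": s.wcg_level,
                     "relative_enrichment": s.relative_enrichment,
                     "n_gch_sites": s.n_gch_sites, "n_wcg_sites": s.n_wcg_sites,
                     "n_intervals": s.n_intervals})
    return pd.DataFrame(rows)


def read_annotation_bed(path) -> pd.DataFrame:
    """BED with a class label in the name column; optional col 7 = family.

    RepeatMasker-derived BED is accepted: name = subfamily, seventh column =
    family (or class/family string).  Returns chrom, start, end, label,
    [family, subfamily].
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = raw.shape[1]
    names = ["chrom", "start", "end", "label", "score", "strand", "family"][:ncol]
    raw.columns = names + [f"extra{i}" for i in range(ncol - len(names))]
    out = raw[["chrom", "start", "end", "label"]].copy()
    if "family" in raw.columns:
        out["family"] = raw["family"]
        out["subfamily"] = raw["label"]
    return out
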