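"""Per-cytosine bisulfite call tables and methylation-level summaries.

A sample is a table of strand-resolved cytosine observations (methylated /
unmethylated read counts) typed by NOMe context.  Regional summaries pool
read counts over qualifying sites (count-weighted), never average per-site
levels, matching the windowed statistics downstream.  Sites below the depth
filter (default 3 reads) are ignored.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import ANALYZABLE_CLASSES, CONTEXT_CLASSES, EXCLUDED_CLASSES, ContextIndex

__all__ = [
    "SampleCalls",
    "RegionMethylation",
    "read_cytosine_report",
    "write_cytosine_report",
    "site_level",
    "region_level",
    "regions_level",
    "genome_mean_level",
    "write_bedgraph",
    "split_chromosomes",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_DEPTH = 3

_CALL_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "unmeth"]


@dataclass
class RegionMethylation:
    """Pooled methylation over one region and context class."""

    chrom: str | None
    start: int | None
    end: int | None
    context: str
    pooled_meth: int
    pooled_unmeth: int
    n_sites_used: int

    @property
    def depth(self) -> int:
        return self.pooled_meth + self.pooled_unmeth

    @property
    def level(self) -> float | None:
        """meth/(meth+unmeth); ``None`` (undefined, not 0) without coverage."""
        if self.depth == 0:
            return None
        return self.pooled_meth / self.depth


@dataclass
class SampleCalls:
    """One sample's cytosine calls plus its design metadata.

    ``df`` holds chrom, pos (0-based), strand, context (WCG/GCH/OTHER),
    meth, unmeth — sorted by (chrom, pos).  GCG/CCG never appear here; they
    are removed on construction.
    """

    sample_id: str
    df: pd.DataFrame
    species: str = ""
    stage: str = ""
    cell_type: str = ""
    sex: str = ""
    replicate: str = ""
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        df = self.df
        if len(df):
            df = df[~df["context"].isin(EXCLUDED_CLASSES)]
            df = df.sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True)
        else:
            df = pd.DataFrame(columns=_CALL_COLUMNS)
        self.df = df

    @property
    def n_sites(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(pd.unique(self.df["chrom"])) if len(self.df) else []

    def arrays(self, chrom: str, context: str, min_depth: int = 1):
        """(pos, meth, unmeth) sorted by position for one chrom and context.

        Cached per (chrom, context); the depth filter is applied on top of
        the cached arrays.  Positions are unique within a chromosome (a base
        is either C or G), so both strands can be pooled positionally.
        """
        key = (chrom, context)
        if key not in self._cache:
            sub = self.df[(self.df["chrom"] == chrom) & (self.df["context"] == context)]
            self._cache[key] = (
                sub["pos"].to_numpy(np.int64),
                sub["meth"].to_numpy(np.int64),
                sub["unmeth"].to_numpy(np.int64),
            )
        pos, meth, unmeth = self._cache[key]
        if min_depth > 1:
            keep = (meth + unmeth) >= min_depth
            return pos[keep], meth[keep], unmeth[keep]
        return pos, meth, unmeth


def site_level(meth: int, unmeth: int) -> float | None:
    """Methylation level of one site; undefined (None) at zero depth."""
    depth = meth + unmeth
    if depth == 0:
        return None
    return meth / depth


def _pool(calls: SampleCalls, chrom: str, start: int | None, end: int | None,
          context: str, min_depth: int) -> tuple[int, int, int]:
    pos, meth, unmeth = calls.arrays(chrom, context, min_depth)
    if start is not None:
        i0, i1 = np.searchsorted(pos, [start, end])
        meth, unmeth = meth[i0:i1], unmeth[i0:i1]
    return int(meth.sum()), int(unmeth.sum()), int(len(meth))


def region_level(calls: SampleCalls, region: tuple[str, int, int], context: str,
                 min_depth: int = DEFAULT_MIN_DEPTH) -> RegionMethylation:
    """Count-pooled methylation level over one half-open region."""
    chrom, start, end = region
    if start > end:
        raise ValueError(f"malformed region {region}")
    m, u, n = _pool(calls, chrom, start, end, context, min_depth)
    return RegionMethylation(chrom, start, end, context, m, u, n)


def regions_level(calls: SampleCalls, regions: Sequence[tuple[str, int, int]],
                  context: str, min_depth: int = DEFAULT_MIN_DEPTH) -> RegionMethylation:
    """Pooled level over a collection of regions (treated as one footprint)."""
    tm = tu = tn = 0
    for chrom, start, end in regions:
        m, u, n = _pool(calls, chrom, start, end, context, min_depth)
        tm, tu, tn = tm + m, tu + u, tn + n
    return RegionMethylation(None, None, None, context, tm, tu, tn)


def genome_mean_level(calls: SampleCalls, context: str,
                      min_depth: int = DEFAULT_MIN_DEPTH,
                      exclude_chroms: Sequence[str] = ()) -> RegionMethylation:
    """Pooled level over every covered site of a context class."""
    tm = tu = tn = 0
    for chrom in calls.chroms:
        if chrom in exclude_chroms:
            continue
        m, u, n = _pool(calls, chrom, None, None, context, min_depth)
        tm, tu, tn = tm + m, tu + u, tn + n
    return RegionMethylation(None, None, None, context, tm, tu, tn)


def _detect_format(path: str | os.PathLike) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                fields = line.rstrip("\n").split("\t")
                if len(fields) >= 4 and fields[2] in "+-":
                    return "report"
                if len(fields) == 6:
                    return "coverage"
                raise ValueError(f"{path}: unrecognised call-table layout ({len(fields)} columns)")
    return "empty"


def read_cytosine_report(path: str | os.PathLike, index: ContextIndex,
                         sample_id: str | None = None, **metadata) -> SampleCalls:
    """Read a cytosine call table and type every row from the context index.

    Two tab-separated dialects are auto-detected:

    * cytosine report: chrom, 1-based pos, strand, meth count, unmeth count,
      [context string, ...] — the context column, if present, is ignored in
      favour of re-classification from the reference;
    * coverage: chrom, 1-based start, end, level%, meth count, unmeth count
      (strand recovered from the index).

    Rows at GCG/CCG positions are dropped (excluded contexts); rows whose
    position is absent from the index are dropped with a logged count.
    Duplicate rows for one site are summed with a warning.
    """
    sample_id = sample_id or os.path.splitext(os.path.basename(str(path)))[0]
    fmt = _detect_format(path)
    if fmt == "empty":
        return SampleCalls(sample_id, pd.DataFrame(columns=_CALL_COLUMNS), **metadata)

    try:
        if fmt == "report":
            raw = pd.read_csv(
                path, sep="\t", header=None, comment="#",
                usecols=[0, 1, 2, 3, 4],
                names=["chrom", "pos1", "strand", "meth", "unmeth"],
                dtype={"chrom": str, "pos1": np.int64, "strand": str,
                       "meth": np.int64, "unmeth": np.int64},
            )
        else:
            raw = pd.read_csv(
                path, sep="\t", header=None, comment="#",
                names=["chrom", "pos1", "end", "pct", "meth", "unmeth"],
                dtype={"chrom": str, "pos1": np.int64, "end": np.int64,
                       "pct": float, "meth": np.int64, "unmeth": np.int64},
            )
            raw["strand"] = ""
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: malformed row — {_locate_bad_line(path)}") from exc

    if fmt == "report" and not raw["strand"].isin(["+", "-"]).all():
        bad = raw.index[~raw["strand"].isin(["+", "-"])][0] + 1
        raise ValueError(f"{path}: malformed strand at line {bad}")

    raw["pos"] = raw["pos1"] - 1
    frames, n_unindexed = [], 0
    for chrom, grp in raw.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(np.int64)
        if fmt == "report":
            for strand in "+-":
                sel = grp["strand"].to_numpy() == strand
                codes = index.lookup_many(chrom, pos[sel], strand)
                frames.append(_typed_frame(grp[sel], codes, strand))
                n_unindexed += int((codes < 0).sum())
        else:
            codes_p = index.lookup_many(chrom, pos, "+")
            codes_m = index.lookup_many(chrom, pos, "-")
            strand = np.where(codes_p >= 0, "+", "-")
            codes = np.where(codes_p >= 0, codes_p, codes_m)
            grp = grp.assign(strand=strand)
            frames.append(_typed_frame(grp, codes.astype(np.int8), None))
            n_unindexed += int((codes < 0).sum())

    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=_CALL_COLUMNS)
    if n_unindexed:
        log.warning("%s: dropped %d rows not present in the context index", path, n_unindexed)

    dup = df.duplicated(subset=["chrom", "pos", "strand"], keep=False)
    if dup.any():
        log.warning("%s: summing %d duplicate site rows (merged lanes?)", path, int(dup.sum()))
        df = (df.groupby(["chrom", "pos", "strand", "context"], as_index=False, sort=False)
                [["meth", "unmeth"]].sum())
    return SampleCalls(sample_id, df[_CALL_COLUMNS], **metadata)


def _typed_frame(grp: pd.DataFrame, codes: np.ndarray, strand: str | None) -> pd.DataFrame:
    names = np.array(CONTEXT_CLASSES + ("NA",))
    keep = codes >= 0
    out = pd.DataFrame(
        {
            "chrom": grp["chrom"].to_numpy()[keep],
            "pos": grp["pos"].to_numpy(np.int64)[keep],
            "strand": (grp["strand"].to_numpy()[keep] if strand is None else strand),
            "context": names[codes[keep]],
            "meth": grp["meth"].to_numpy(np.int64)[keep],
            "unmeth": grp["unmeth"].to_numpy(np.int64)[keep],
        }
    )
    return out


def _locate_bad_line(path) -> str:
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if not line.strip() or line.startswith("#"):
                continue
            try:
                int(fields[1]); int(fields[-1]); int(fields[-2])
            except (ValueError, IndexError):
                return f"line {i}"
    return "line unknown"


def write_cytosine_report(calls: SampleCalls, path: str | os.PathLike) -> None:
    """Write the report dialect: chrom, 1-based pos, strand, meth, unmeth, context."""
    df = calls.df
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos1": df["pos"] + 1,
            "strand": df["strand"],
            "meth": df["meth"],
            "unmeth": df["unmeth"],
            "context": df["context"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(calls: SampleCalls, path: str | os.PathLike, context: str,
                   min_depth: int = DEFAULT_MIN_DEPTH) -> None:
    """bedGraph of per-site levels for one context class (depth-filtered)."""
    df = calls.df
    depth = df["meth"] + df["unmeth"]
    sub = df[(df["context"] == context) & (depth >= min_depth)]
    level = sub["meth"] / (sub["meth"] + sub["unmeth"])
    out = pd.DataFrame(
        {
            "chrom": sub["chrom"],
            "start": sub["pos"],
            "end": sub["pos"] + 1,
            "level": level.round(6),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def split_chromosomes(calls: SampleCalls, chroms: Sequence[str]) -> tuple[SampleCalls, SampleCalls]:
    """Partition a sample into (on ``chroms``, rest) — e.g. λ spike-in vs genome."""
    mask = calls.df["chrom"].isin(chroms)
    meta = dict(species=calls.species, stage=calls.stage, cell_type=calls.cell_type,
                sex=calls.sex, replicate=calls.replicate)
    inside = SampleCalls(calls.sample_id, calls.df[mask].reset_index(drop=True), **meta)
    outside = SampleCalls(calls.sample_id, calls.df[~mask].reset_index(drop=True), **meta)
    return inside, outside
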