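"""Cytosine context classification for NOMe-seq.

NOMe-seq reads out two signals from one bisulfite library: endogenous CpG
methylation at WCG sites (ACG/TCG) and M.CviPI-deposited GpC methylation at
GCH sites (GCA/GCT/GCC), which marks accessible chromatin.  GCG sites are
ambiguous (either enzyme could have methylated them) and CCG sites absorb
slight enzyme off-target activity, so both are excluded from all downstream
statistics.

Contexts are strand-asymmetric: a GpC on the plus strand is not a GpC on the
minus strand, so sites are classified per strand, reading the trinucleotide
5'->3' on the strand that carries the cytosine, and are never collapsed into
dyads.  Minus-strand sites are reported at the plus-strand coordinate of the
G whose complement they are.  Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXT_CLASSES",
    "EXCLUDED_CLASSES",
    "ANALYZABLE_CLASSES",
    "classify_cytosine_context",
    "ContextIndex",
    "build_context_index",
    "read_fasta",
    "write_fasta",
]

CONTEXT_CLASSES = ("WCG", "GCH", "GCG", "CCG", "OTHER")
#: classes dropped from every methylation statistic
EXCLUDED_CLASSES = frozenset({"GCG", "CCG"})
ANALYZABLE_CLASSES = ("WCG", "GCH", "OTHER")

_CODE = {name: i for i, name in enumerate(CONTEXT_CLASSES)}
_NAMES = np.array(CONTEXT_CLASSES)

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")

# complement lookup for uint8 base codes; everything unexpected maps to N
_COMP = np.full(256, _N, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _COMP[_x] = _y


def classify_cytosine_context(preceding_base: str, base: str, following_base: str) -> str:
    """Classify one cytosine from its strand-local trinucleotide.

    Bases are read 5'->3' on the strand carrying the cytosine.  Returns one
    of ``WCG``, ``GCH``, ``GCG``, ``CCG`` or ``OTHER``; any N flank is
    unclassifiable and yields ``OTHER``.
    """
    if base != "C":
        raise ValueError(f"center base must be C, got {base!r}")
    for b in (preceding_base, following_base):
        if b not in "ACGTN":
            raise ValueError(f"flanking base must be one of A,C,G,T,N, got {b!r}")
    if preceding_base == "G":
        if following_base == "G":
            return "GCG"
        if following_base in "ATC":
            return "GCH"
        return "OTHER"
    if following_base == "G":
        if preceding_base in "AT":
            return "WCG"
        if preceding_base == "C":
            return "CCG"
    return "OTHER"


def _classify_codes(prev: np.ndarray, nxt: np.ndarray) -> np.ndarray:
    """Vectorised trinucleotide classification (uint8 base arrays -> int8 codes)."""
    out = np.full(prev.shape, _CODE["OTHER"], dtype=np.int8)
    prev_g = prev == _G
    nxt_g = nxt == _G
    nxt_h = (nxt == _A) | (nxt == _T) | (nxt == _C)
    out[prev_g & nxt_h] = _CODE["GCH"]
    out[prev_g & nxt_g] = _CODE["GCG"]
    prev_w = (prev == _A) | (prev == _T)
    out[prev_w & nxt_g] = _CODE["WCG"]
    out[(prev == _C) & nxt_g] = _CODE["CCG"]
    return out


class ContextIndex:
    """Per-chromosome, per-strand sorted cytosine positions with context codes.

    ``data`` maps chrom -> strand ('+'/'-') -> (positions int64, codes int8),
    positions strictly increasing.
    """

    def __init__(self, data: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]]):
        self._data = data

    @classmethod
    def from_genome(cls, genome: Mapping[str, str]) -> "ContextIndex":
        data: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for chrom, seq in genome.items():
            a = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
            padded = np.concatenate(([_N], a, [_N]))
            # plus strand: C at i, trinucleotide seq[i-1:i+2]
            c_pos = np.flatnonzero(a == _C)
            plus_codes = _classify_codes(padded[c_pos], padded[c_pos + 2])
            # minus strand: C opposite a plus-strand G; read 5'->3' on minus,
            # the flanks are the complements of the plus bases at i+1 and i-1
            g_pos = np.flatnonzero(a == _G)
            minus_codes = _classify_codes(_COMP[padded[g_pos + 2]], _COMP[padded[g_pos]])
            data[chrom] = {
                "+": (c_pos.astype(np.int64), plus_codes),
                "-": (g_pos.astype(np.int64), minus_codes),
            }
        return cls(data)

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def strand_arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        return self._data[chrom][strand]

    def sites(self, chrom: str | None = None, context: str | None = None) -> pd.DataFrame:
        """All indexed sites as a frame (chrom, pos, strand, context)."""
        frames = []
        for c in [chrom] if chrom else self.chroms:
            for strand in "+-":
                pos, codes = self._data[c][strand]
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": c,
                            "pos": pos,
                            "strand": strand,
                            "context": _NAMES[codes],
                        }
                    )
                )
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["chrom", "pos", "strand", "context"]
        )
        if context is not None:
            df = df[df["context"] == context].reset_index(drop=True)
        return df.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)

    def lookup_many(self, chrom: str, pos: np.ndarray, strand: str) -> np.ndarray:
        """Context codes at ``pos`` on ``strand``; -1 where the site is absent."""
        out = np.full(len(pos), -1, dtype=np.int8)
        if chrom not in self._data:
            return out
        idx_pos, codes = self._data[chrom][strand]
        if len(idx_pos) == 0:
            return out
        j = np.searchsorted(idx_pos, pos)
        ok = (j < len(idx_pos)) & (idx_pos[np.minimum(j, len(idx_pos) - 1)] == pos)
        out[ok] = codes[j[ok]]
        return out

    def lookup(self, chrom: str, pos: int, strand: str) -> str | None:
        code = self.lookup_many(chrom, np.array([pos], dtype=np.int64), strand)[0]
        return None if code < 0 else str(_NAMES[code])

    def counts(self) -> pd.Series:
        """Number of indexed sites per context class."""
        totals = np.zeros(len(CONTEXT_CLASSES), dtype=np.int64)
        for per_chrom in self._data.values():
            for _, codes in per_chrom.values():
                totals += np.bincount(codes, minlength=len(CONTEXT_CLASSES))
        return pd.Series(totals, index=list(CONTEXT_CLASSES), name="n_sites")

    def to_bed(self, path: str | os.PathLike, classes: Iterable[str] | None = None) -> None:
        """BED6 of context sites: chrom, start, end, class, '.', strand."""
        keep = set(classes) if classes is not None else set(CONTEXT_CLASSES)
        df = self.sites()
        df = df[df["context"].isin(keep)]
        out = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["pos"],
                "end": df["pos"] + 1,
                "name": df["context"],
                "score": ".",
                "strand": df["strand"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)


def build_context_index(genome: Mapping[str, str]) -> ContextIndex:
    """Classify every cytosine on both strands of ``genome`` and index it."""
    if not genome:
        raise ValueError("genome is empty")
    return ContextIndex.from_genome(genome)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA into an in-memory {name: upper-case sequence} dict."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, as_raw=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(genome: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
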