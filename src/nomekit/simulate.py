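"""Synthetic NOMe-seq study generator with a machine-readable truth set.

Generates a random reference genome, plants a chromatin architecture on it
(promoter NDRs overlapping TSSs, phased nucleosome arrays downstream of
TSSs, labelled repeat/element compartments, optional exon-preferential
protection), then draws per-cytosine read counts that emulate the NOMe
chemistry:

* GCH site: P(read methylated) = open_prob * efficiency, i.e. the enzyme
  only reaches accessible GpCs and methylates a fraction ``efficiency`` of
  them;
* WCG site: P = endogenous methylation level of the site's compartment;
* any unmethylated cytosine still reads methylated with probability
  ``conversion_failure`` (incomplete bisulfite conversion), so the read
  probability is p + (1-p) * conversion_failure throughout.

Depth is negative-binomial around ``mean_depth``.  An unmethylated λ phage
"chromosome" is generated the same way (GCH P = efficiency, others = 0) for
spike-in QC.  Expression is coupled to promoter state: log10 RPKM =
a + b * open_prob + c * promoter WCG + noise with b > 0, c < 0.

Every random draw flows from ``SimulationConfig.seed`` through fixed
``SeedSequence`` spawn keys, so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .calls import SampleCalls
from .genome import ContextIndex, build_context_index

__all__ = [
    "ElementSpec",
    "SampleSpec",
    "SimulationConfig",
    "TruthSet",
    "StudyBundle",
    "simulate_genome",
    "simulate_sample",
    "simulate_lambda",
    "lambda_reference",
    "simulate_expression",
    "simulate_study",
    "default_repeat_specs",
    "write_gene_bed12",
    "LAMBDA_CHROM",
]

LAMBDA_CHROM = "lambda"

_KEY_GENOME, _KEY_LAMBDA, _KEY_EXPR, _KEY_SAMPLE = 0, 1, 2, 3

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class ElementSpec:
    """One labelled element/repeat compartment to paint on the genome."""

    label: str
    family: str
    n: int
    length: int
    open_prob: float
    wcg_level: float


def default_repeat_specs() -> list[ElementSpec]:
    """Repeat compartments emulating germline accessibility/methylation order.

    SVA specifically open; within LINEs the younger L1 is closed and keeps
    more residual methylation than the older L2; likewise Alu (young) vs MIR
    (old) within SINEs.
    """
    return [
        ElementSpec("SVA", "SVA", 30, 800, 0.70, 0.20),
        ElementSpec("L1", "LINE", 40, 900, 0.08, 0.35),
        ElementSpec("L2", "LINE", 40, 900, 0.30, 0.12),
        ElementSpec("Alu", "SINE", 60, 300, 0.10, 0.30),
        ElementSpec("MIR", "SINE", 60, 260, 0.25, 0.12),
        ElementSpec("LTR", "LTR", 40, 500, 0.12, 0.25),
    ]


@dataclass
class SampleSpec:
    sample_id: str
    cell_type: str = "fgc"
    group: str | None = None


@dataclass
class SimulationConfig:
    """All generator knobs; probabilities in [0,1], lengths in bp.

    ``wcg_levels`` carries the endogenous-methylation regimes per cell type
    (somatic niche high, germ cells reset low, early heart/epiblast high).
    """

    seed: int = 1
    chrom_name: str = "chr1"
    genome_length: int = 1_000_000
    gc_fraction: float = 0.42
    # gene / promoter-NDR architecture
    n_genes: int = 200
    ndr_length: int = 300
    ndr_open_prob: float = 0.85
    baseline_open_prob: float = 0.15
    promoter_open_range: tuple[float, float] | None = None
    n_distal_ndrs: int = 0
    # phased nucleosome arrays downstream of the TSS
    n_nucleosomes: int = 3
    nucleosome_len: int = 147
    linker_len: int = 53
    protection: float = 0.9
    linker_open_prob: float = 0.85
    # optional exon structure (disabled unless gene_exons > 0)
    gene_exons: int = 0
    exon_len: int = 150
    intron_len: int = 350
    exon_nucleosome_preference: bool = False
    # chemistry
    efficiency: float = 0.93
    conversion_failure: float = 0.013
    # endogenous methylation regimes per cell type
    wcg_levels: dict = field(default_factory=lambda: {
        "fgc": 0.067, "soma": 0.647, "heart": 0.729, "epiblast": 0.777,
    })
    promoter_wcg_range: tuple[float, float] | None = None
    promoter_flank: int = 1000
    # coverage model
    mean_depth: float = 20.0
    depth_dispersion: float = 5.0
    # λ spike-in
    lambda_length: int = 48_502
    lambda_gc: float = 0.5
    lambda_spike_fraction: float = 0.05
    lambda_depth: float | None = None
    # group-specific promoter NDRs
    groups: tuple[str, ...] | None = None
    group_low_open: float = 0.15
    # expression coupling (log10-RPKM scale)
    expr_intercept: float = -1.5
    expr_access_coef: float = 4.0
    expr_meth_coef: float = -2.0
    expr_noise_sd: float = 0.3
    # painted element compartments
    element_specs: list[ElementSpec] = field(default_factory=list)

    def __post_init__(self):
        for name in ("ndr_open_prob", "baseline_open_prob", "protection",
                     "linker_open_prob", "efficiency", "conversion_failure",
                     "group_low_open", "gc_fraction", "lambda_gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")

    def rng(self, *key: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=tuple(key)))

    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("element_specs"):
            d["element_specs"] = [ElementSpec(**e) for e in d["element_specs"]]
        for name in ("promoter_open_range", "promoter_wcg_range", "groups"):
            if d.get(name) is not None:
                d[name] = tuple(d[name])
        return cls(**d)


@dataclass
class TruthSet:
    """Planted architecture + generating parameters — the recovery oracle."""

    genes: pd.DataFrame        # gene_id chrom strand tss tes exons ndr_start ndr_end open_prob promoter_wcg group
    ndrs: pd.DataFrame         # chrom start end kind gene_id open_prob
    nucleosomes: pd.DataFrame  # chrom start end gene_id
    elements: pd.DataFrame     # chrom start end label family open_prob wcg_level
    params: dict

    def to_json(self, path) -> None:
        payload = {
            "genes": self.genes.to_dict(orient="list"),
            "ndrs": self.ndrs.to_dict(orient="list"),
            "nucleosomes": self.nucleosomes.to_dict(orient="list"),
            "elements": self.elements.to_dict(orient="list"),
            "params": self.params,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        def frame(key, cols):
            d = payload[key]
            return pd.DataFrame(d) if d else pd.DataFrame(columns=cols)
        return cls(
            genes=frame("genes", _GENE_COLS),
            ndrs=frame("ndrs", _NDR_COLS),
            nucleosomes=frame("nucleosomes", _NUC_COLS),
            elements=frame("elements", _ELT_COLS),
            params=payload["params"],
        )


_GENE_COLS = ["gene_id", "chrom", "strand", "tss", "tes", "exons",
              "ndr_start", "ndr_end", "open_prob", "promoter_wcg", "group"]
_NDR_COLS = ["chrom", "start", "end", "kind", "gene_id", "open_prob"]
_NUC_COLS = ["chrom", "start", "end", "gene_id"]
_ELT_COLS = ["chrom", "start", "end", "label", "family", "open_prob", "wcg_level"]


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def _gene_architecture(cfg: SimulationConfig, rng: np.random.Generator):
    """Place genes on fixed slots; returns (genes, ndrs, nucleosomes, occupied)."""
    genes, ndrs, nucs, occupied = [], [], [], []
    if cfg.n_genes == 0:
        return genes, ndrs, nucs, occupied
    slot = cfg.genome_length // cfg.n_genes
    body = (cfg.gene_exons * cfg.exon_len
            + max(0, cfg.gene_exons - 1) * cfg.intron_len) if cfg.gene_exons else 0
    array_span = cfg.n_nucleosomes * cfg.nucleosome_len + max(0, cfg.n_nucleosomes - 1) * cfg.linker_len
    half = cfg.ndr_length // 2
    reach = max(cfg.promoter_flank, half + array_span, half + body)
    if slot < 2 * reach + 200:
        raise ValueError(
            f"infeasible placement: {cfg.n_genes} genes need slots of "
            f"{2 * reach + 200} bp but only {slot} bp are available"
        )
    strands = rng.choice(np.array(["+", "-"]), size=cfg.n_genes)
    if cfg.promoter_open_range is not None:
        lo, hi = cfg.promoter_open_range
        opens = rng.uniform(lo, hi, size=cfg.n_genes)
    else:
        opens = np.full(cfg.n_genes, cfg.ndr_open_prob)
    if cfg.promoter_wcg_range is not None:
        lo, hi = cfg.promoter_wcg_range
        pwcg = rng.uniform(lo, hi, size=cfg.n_genes)
    else:
        pwcg = np.full(cfg.n_genes, np.nan)
    for i in range(cfg.n_genes):
        gid = f"gene{i:05d}"
        strand = str(strands[i])
        sign = 1 if strand == "+" else -1
        tss = i * slot + slot // 2
        group = cfg.groups[i % len(cfg.groups)] if cfg.groups else ""
        ndr_s, ndr_e = tss - half, tss - half + cfg.ndr_length
        ndrs.append((cfg.chrom_name, ndr_s, ndr_e, "promoter", gid, float(opens[i])))
        lo_ext, hi_ext = ndr_s, ndr_e
        edge = ndr_e if strand == "+" else ndr_s
        for k in range(cfg.n_nucleosomes):
            off = k * (cfg.nucleosome_len + cfg.linker_len)
            s = edge + sign * off if strand == "+" else edge - off - cfg.nucleosome_len
            nucs.append((cfg.chrom_name, int(s), int(s + cfg.nucleosome_len), gid))
            lo_ext = min(lo_ext, s)
            hi_ext = max(hi_ext, s + cfg.nucleosome_len)
        exons = []
        if cfg.gene_exons:
            for k in range(cfg.gene_exons):
                off = k * (cfg.exon_len + cfg.intron_len)
                if strand == "+":
                    s = tss + off
                else:
                    s = tss - off - cfg.exon_len
                exons.append([int(s), int(s + cfg.exon_len)])
                lo_ext = min(lo_ext, s)
                hi_ext = max(hi_ext, s + cfg.exon_len)
        tes = tss + sign * body if body else tss + sign * cfg.ndr_length
        genes.append((gid, cfg.chrom_name, strand, int(tss), int(tes), exons,
                      int(ndr_s), int(ndr_e), float(opens[i]),
                      float(pwcg[i]) if np.isfinite(pwcg[i]) else None, group))
        lo_occ = min(lo_ext, tss - cfg.promoter_flank)
        hi_occ = max(hi_ext, tss + cfg.promoter_flank)
        occupied.append((max(0, lo_occ), min(cfg.genome_length, hi_occ)))
    return genes, ndrs, nucs, occupied


def _place_in_gaps(items: list[int], occupied: list[tuple[int, int]],
                   genome_length: int, rng: np.random.Generator,
                   pad: int = 50) -> list[tuple[int, int]]:
    """Greedy placement of interval lengths into the unoccupied gaps."""
    occ = sorted(occupied)
    gaps, cur = [], 0
    for s, e in occ:
        if s > cur:
            gaps.append([cur, s])
        cur = max(cur, e)
    if cur < genome_length:
        gaps.append([cur, genome_length])
    order = rng.permutation(len(items))
    placed: list[tuple[int, int] | None] = [None] * len(items)
    for idx in order:
        length = items[idx]
        for gap in gaps:
            if gap[1] - gap[0] >= length + 2 * pad:
                s = gap[0] + pad
                placed[idx] = (s, s + length)
                gap[0] = s + length + pad
                break
        if placed[idx] is None:
            raise ValueError("infeasible placement: not enough free genome for elements")
    return placed  # type: ignore[return-value]


def simulate_genome(cfg: SimulationConfig):
    """Generate the reference, gene models, annotations and truth set.

    Returns (genome dict, TruthSet).
    """
    rng = cfg.rng(_KEY_GENOME)
    seq = _random_sequence(rng, cfg.genome_length, cfg.gc_fraction)
    genome = {cfg.chrom_name: seq}
    genes, ndrs, nucs, occupied = _gene_architecture(cfg, rng)
    # distal NDRs and element compartments share the free space
    lengths = [cfg.ndr_length] * cfg.n_distal_ndrs
    elt_rows = []
    for spec in cfg.element_specs:
        lengths.extend([spec.length] * spec.n)
        elt_rows.extend([spec] * spec.n)
    placed = _place_in_gaps(lengths, occupied, cfg.genome_length, rng) if lengths else []
    for j in range(cfg.n_distal_ndrs):
        s, e = placed[j]
        ndrs.append((cfg.chrom_name, s, e, "distal", None, cfg.ndr_open_prob))
    elements = []
    for j, spec in enumerate(elt_rows):
        s, e = placed[cfg.n_distal_ndrs + j]
        elements.append((cfg.chrom_name, s, e, spec.label, spec.family,
                         spec.open_prob, spec.wcg_level))
    truth = TruthSet(
        genes=pd.DataFrame(genes, columns=_GENE_COLS),
        ndrs=pd.DataFrame(ndrs, columns=_NDR_COLS),
        nucleosomes=pd.DataFrame(nucs, columns=_NUC_COLS),
        elements=pd.DataFrame(elements, columns=_ELT_COLS),
        params={
            "seed": cfg.seed,
            "efficiency": cfg.efficiency,
            "conversion_failure": cfg.conversion_failure,
            "wcg_levels": dict(cfg.wcg_levels),
            "baseline_open_prob": cfg.baseline_open_prob,
            "protection": cfg.protection,
            "lambda_spike_fraction": cfg.lambda_spike_fraction,
            "expr_access_coef": cfg.expr_access_coef,
            "expr_meth_coef": cfg.expr_meth_coef,
        },
    )
    return genome, truth


def _paint_maps(cfg: SimulationConfig, truth: TruthSet, cell_type: str,
                group: str | None) -> tuple[np.ndarray, np.ndarray]:
    """Per-base open-probability and WCG-level maps for one sample."""
    if cell_type not in cfg.wcg_levels:
        raise KeyError(f"no WCG regime for cell type {cell_type!r} in wcg_levels")
    open_arr = np.full(cfg.genome_length, cfg.baseline_open_prob)
    wcg_arr = np.full(cfg.genome_length, cfg.wcg_levels[cell_type])
    for e in truth.elements.itertuples(index=False):
        open_arr[e.start:e.end] = e.open_prob
        wcg_arr[e.start:e.end] = e.wcg_level
    gene_group = dict(zip(truth.genes["gene_id"], truth.genes["group"]))
    for g in truth.genes.itertuples(index=False):
        if g.promoter_wcg is not None and np.isfinite(g.promoter_wcg):
            lo = max(0, g.tss - cfg.promoter_flank)
            wcg_arr[lo:g.tss + cfg.promoter_flank] = g.promoter_wcg
    for r in truth.ndrs.itertuples(index=False):
        p = r.open_prob
        if cfg.groups and r.kind == "promoter":
            if gene_group.get(r.gene_id, "") != (group or ""):
                p = cfg.group_low_open
        open_arr[r.start:r.end] = p
    for nuc in truth.nucleosomes.itertuples(index=False):
        open_arr[nuc.start:nuc.end] = 1.0 - cfg.protection
    # linkers between consecutive nucleosomes of one gene
    by_gene: dict[str, list] = {}
    for nuc in truth.nucleosomes.itertuples(index=False):
        by_gene.setdefault(nuc.gene_id, []).append((nuc.start, nuc.end))
    for spans in by_gene.values():
        spans.sort()
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            open_arr[e1:s2] = cfg.linker_open_prob
    if cfg.exon_nucleosome_preference:
        for g in truth.genes.itertuples(index=False):
            for k, (s, e) in enumerate(g.exons):
                if k == 0:
                    continue  # first exon sits in the promoter NDR
                open_arr[s:e] = 1.0 - cfg.protection
    return open_arr, wcg_arr


def _draw_counts(pos: np.ndarray, codes: np.ndarray, strand: str, chrom: str,
                 p_true: np.ndarray, cfg: SimulationConfig,
                 rng: np.random.Generator, mean_depth: float) -> pd.DataFrame:
    p_read = p_true + (1.0 - p_true) * cfg.conversion_failure
    disp = cfg.depth_dispersion
    depth = rng.negative_binomial(disp, disp / (disp + mean_depth), size=len(pos))
    meth = rng.binomial(depth, p_read)
    keep = depth > 0
    names = np.array(["WCG", "GCH", "GCG", "CCG", "OTHER"])
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos[keep],
            "strand": strand,
            "context": names[codes[keep]],
            "meth": meth[keep],
            "unmeth": (depth - meth)[keep],
        }
    )


def simulate_sample(genome: dict[str, str], index: ContextIndex, truth: TruthSet,
                    cfg: SimulationConfig, sample_id: str, *,
                    cell_type: str = "fgc", group: str | None = None) -> SampleCalls:
    """Draw one sample's per-site counts from the planted architecture.

    GCH read probability is open_prob*efficiency (conversion-adjusted); WCG
    follows the compartment's endogenous level; OTHER cytosines only report
    conversion failure.  GCG/CCG sites are not emitted (excluded upstream).
    """
    rng = cfg.rng(_KEY_SAMPLE, zlib.crc32(sample_id.encode()))
    open_arr, wcg_arr = _paint_maps(cfg, truth, cell_type, group)
    frames = []
    for chrom in genome:
        for strand in "+-":
            pos, codes = index.strand_arrays(chrom, strand)
            keep = (codes == 0) | (codes == 1) | (codes == 4)  # WCG, GCH, OTHER
            pos, codes = pos[keep], codes[keep]
            p_true = np.zeros(len(pos))
            gch = codes == 1
            wcg = codes == 0
            p_true[gch] = open_arr[pos[gch]] * cfg.efficiency
            p_true[wcg] = wcg_arr[pos[wcg]]
            frames.append(_draw_counts(pos, codes, strand, chrom, p_true,
                                       cfg, rng, cfg.mean_depth))
    df = pd.concat(frames, ignore_index=True)
    return SampleCalls(sample_id, df, species="synthetic", cell_type=cell_type,
                       replicate=group or "")


def lambda_reference(cfg: SimulationConfig) -> dict[str, str]:
    """The study's λ spike-in reference (one fixed sequence per config seed)."""
    if cfg.lambda_length <= 0:
        raise ValueError("lambda_length must be positive")
    rng = cfg.rng(_KEY_LAMBDA)
    return {LAMBDA_CHROM: _random_sequence(rng, cfg.lambda_length, cfg.lambda_gc)}


def simulate_lambda(cfg: SimulationConfig, sample_id: str = "lambda") -> SampleCalls:
    """Unmethylated λ spike-in: GCH reads efficiency, non-GCH reads conversion."""
    seq = lambda_reference(cfg)[LAMBDA_CHROM]
    rng = cfg.rng(_KEY_LAMBDA, zlib.crc32(sample_id.encode()))
    index = build_context_index({LAMBDA_CHROM: seq})
    depth = cfg.lambda_depth if cfg.lambda_depth is not None else cfg.mean_depth
    frames = []
    for strand in "+-":
        pos, codes = index.strand_arrays(LAMBDA_CHROM, strand)
        keep = (codes == 0) | (codes == 1) | (codes == 4)
        pos, codes = pos[keep], codes[keep]
        p_true = np.where(codes == 1, cfg.efficiency, 0.0)
        frames.append(_draw_counts(pos, codes, strand, LAMBDA_CHROM, p_true,
                                   cfg, rng, depth))
    df = pd.concat(frames, ignore_index=True)
    return SampleCalls(sample_id, df, species="lambda")


def _sample_gene_state(cfg: SimulationConfig, truth: TruthSet,
                       cell_type: str, group: str | None):
    """Per-gene (open_prob, promoter wcg) as seen by one sample."""
    opens, wcgs = [], []
    for g in truth.genes.itertuples(index=False):
        p = g.open_prob
        if cfg.groups and g.group != (group or ""):
            p = cfg.group_low_open
        opens.append(p)
        if g.promoter_wcg is not None and np.isfinite(g.promoter_wcg):
            wcgs.append(g.promoter_wcg)
        else:
            wcgs.append(cfg.wcg_levels[cell_type])
    return np.array(opens), np.array(wcgs)


def simulate_expression(truth: TruthSet, cfg: SimulationConfig,
                        samples: list[SampleSpec]) -> pd.DataFrame:
    """RPKM table (gene x sample) coupled to promoter openness and methylation."""
    if not len(truth.genes):
        return pd.DataFrame()
    rng = cfg.rng(_KEY_EXPR)
    data = {}
    for spec in samples:
        opens, wcgs = _sample_gene_state(cfg, truth, spec.cell_type, spec.group)
        log10 = (cfg.expr_intercept
                 + cfg.expr_access_coef * opens
                 + cfg.expr_meth_coef * wcgs
                 + rng.normal(0.0, cfg.expr_noise_sd, size=len(opens)))
        data[spec.sample_id] = np.power(10.0, log10)
    return pd.DataFrame(data, index=pd.Index(truth.genes["gene_id"], name="gene_id"))


@dataclass
class StudyBundle:
    """Everything one simulated study produces, ready for the pipeline."""

    config: SimulationConfig
    genome: dict[str, str]
    index: ContextIndex
    truth: TruthSet
    samples: dict[str, SampleCalls]
    lambda_calls: dict[str, SampleCalls]
    expression: pd.DataFrame
    sample_specs: list[SampleSpec]


def simulate_study(cfg: SimulationConfig,
                   samples: list[SampleSpec] | None = None) -> StudyBundle:
    """Generate genome + truth, then calls, λ spike-ins and expression."""
    if samples is None:
        samples = [SampleSpec("fgc_rep1", "fgc"), SampleSpec("soma_rep1", "soma")]
    genome, truth = simulate_genome(cfg)
    index = build_context_index(genome)
    calls = {
        s.sample_id: simulate_sample(genome, index, truth, cfg, s.sample_id,
                                     cell_type=s.cell_type, group=s.group)
        for s in samples
    }
    lam = {s.sample_id: simulate_lambda(cfg, f"{s.sample_id}.lambda") for s in samples}
    expr = simulate_expression(truth, cfg, samples)
    return StudyBundle(cfg, genome, index, truth, calls, lam, expr, list(samples))


def write_gene_bed12(genes: pd.DataFrame, path) -> None:
    """Emit truth gene models as BED12 (single block when exon-less)."""
    rows = []
    for g in genes.itertuples(index=False):
        exons = g.exons if isinstance(g.exons, list) and g.exons else None
        if exons:
            spans = sorted((int(s), int(e)) for s, e in exons)
        else:
            lo, hi = sorted((int(g.tss), int(g.tes)))
            spans = [(lo, max(hi, lo + 1))]
        start, end = spans[0][0], spans[-1][1]
        sizes = ",".join(str(e - s) for s, e in spans) + ","
        offs = ",".join(str(s - start) for s, e in spans) + ","
        rows.append((g.chrom, start, end, g.gene_id, 0, g.strand,
                     start, end, "0", len(spans), sizes, offs))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# preset study conditions

def ndr_recovery_config(seed: int = 1) -> SimulationConfig:
    """200 planted 300-bp NDRs on 1 Mb, open 0.85 inside / 0.15 outside."""
    return SimulationConfig(seed=seed, genome_length=1_000_000, n_genes=200,
                            ndr_length=300, ndr_open_prob=0.85,
                            baseline_open_prob=0.15, n_nucleosomes=0,
                            efficiency=0.93, conversion_failure=0.013,
                            mean_depth=20.0)


def nucleosome_recovery_config(seed: int = 1) -> SimulationConfig:
    """Phased 147/53 arrays at protection 0.9 on a half-open background."""
    return SimulationConfig(seed=seed, genome_length=500_000, n_genes=100,
                            baseline_open_prob=0.5, linker_open_prob=0.5,
                            n_nucleosomes=3, protection=0.9, mean_depth=20.0)


def expression_coupling_config(seed: int = 1) -> SimulationConfig:
    """2,000 genes with graded promoter openness and methylation coupling."""
    return SimulationConfig(seed=seed, genome_length=5_000_000, n_genes=2000,
                            promoter_open_range=(0.05, 0.9),
                            promoter_wcg_range=(0.05, 0.95),
                            expr_noise_sd=0.3, mean_depth=20.0)


def specific_ndr_config(seed: int = 1) -> SimulationConfig:
    """Three groups of group-specific promoter NDRs with coupled expression."""
    return SimulationConfig(seed=seed, genome_length=400_000, n_genes=60,
                            groups=("heart", "fgc", "soma"),
                            ndr_open_prob=0.85, group_low_open=0.15,
                            n_nucleosomes=0, mean_depth=20.0)


def repeat_element_config(seed: int = 1) -> SimulationConfig:
    """Painted repeat compartments (SVA open, L1 closed/methylated vs L2)."""
    return SimulationConfig(seed=seed, genome_length=600_000, n_genes=20,
                            element_specs=default_repeat_specs(),
                            mean_depth=20.0)


def default_specific_samples() -> list[SampleSpec]:
    return [SampleSpec(f"{g}_rep{r}", cell_type=("fgc" if g == "fgc" else
                                                 "soma" if g == "soma" else "heart"),
                       group=g)
            for g in ("heart", "fgc", "soma") for r in (1, 2, 3)]
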