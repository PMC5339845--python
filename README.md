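# nomekit

Downstream analysis for **NOMe-seq** (nucleosome occupancy and methylome
sequencing). NOMe-seq treats nuclei with the M.CviPI GpC methyltransferase,
which methylates GpC cytosines only where chromatin is accessible, then reads
the genome by bisulfite sequencing. One library therefore carries two signals
at once:

* **GCH** sites (GCA/GCT/GCC): methylation level = chromatin accessibility;
* **WCG** sites (ACG/TCG): methylation level = endogenous CpG methylation.

GCG and CCG cytosines are excluded — the former is ambiguous between the two
signals, the latter absorbs slight enzyme off-target activity.

The package is aimed at studies of strongly reprogramming systems such as
fetal germ cells, where the endogenous methylome is nearly erased while
somatic niche cells stay highly methylated, and where promoter accessibility,
nucleosome phasing and repeat-element chromatin states are the quantities of
interest. It provides:

* context classification and indexing of a reference genome (strand-aware;
  GpC on one strand is not GpC on the other, so sites are never collapsed);
* readers for bismark-style cytosine reports / coverage tables, with pooled
  (count-weighted) methylation levels over arbitrary regions;
* λ spike-in QC: M.CviPI efficiency from λ GCH sites, bisulfite conversion
  rate from λ non-GCH cytosines, and the retention rule (efficiency ≥ 90%,
  conversion > 98%);
* **NDR and nucleosome calling**: 100 bp / 20 bp-step (NDR) and 40 bp /
  20 bp-step (nucleosome) sliding windows; per window, GCH read counts at
  depth ≥ 3 are summed and tested against the genome-wide GCH background
  with a 2×2 χ² (1 df, no continuity correction). Windows with
  −log10 p > 5 (NDR) or > 3 (nucleosome) in the right direction are merged;
  merged segments must span ≥ 140 bp (NDR) or ≥ 60 bp (nucleosome). NDR
  centers < 2 kb from a TSS are proximal, otherwise distal;
* metaprofiles around TSS/TES/exon-boundary anchors, RPKM strata
  (10 / 1 / 0.1 cutoffs), and the promoter-level Spearman correlations
  r1 = ρ(expression, promoter GCH) and r2 = ρ(expression, promoter WCG);
* cell-type-specific proximal NDRs (accessibility–expression ρ > 0.6,
  p < 0.1 across samples; assignment by highest group-mean accessibility)
  and the 1 − ρ pairwise-complete sample distance matrix;
* element/repeat summaries with relative enrichment
  log2(class GCH level / genome GCH level) and HCP/ICP/LCP promoter classes
  from CpG observed/expected and GC content;
* a **synthetic-data generator** that plants NDRs, phased nucleosome
  arrays, repeat compartments, cell-type methylation regimes, a λ spike-in
  and expression coupled to promoter state, with a serialisable truth set —
  so the whole pipeline is testable without any sequencing download.

## Worked example

```python
import nomekit.simulate as sim
from nomekit.segmentation import compute_background, call_ndrs, classify_ndrs
from nomekit.profiles import tss_frame
from nomekit.qc import qc_report

cfg = sim.SimulationConfig(seed=11, genome_length=200_000, n_genes=30,
                           n_nucleosomes=0)
bundle = sim.simulate_study(cfg, [sim.SampleSpec("fgc_rep1", "fgc")])
calls = bundle.samples["fgc_rep1"]

rep = qc_report(bundle.lambda_calls["fgc_rep1"])
print(f"QC: M.CviPI efficiency {rep.mcvipi_efficiency:.3f}, "
      f"conversion {rep.conversion_rate:.3f}, pass={rep.passed}")

bg = compute_background(calls)
print(f"genome GCH background level: {bg.level:.3f}")

ndrs = call_ndrs(calls, bg)
classified = classify_ndrs(ndrs, tss_frame(bundle.truth.genes))
print(f"{len(ndrs)} NDRs called; "
      f"{(classified['proximity'] == 'proximal').sum()} proximal")
print(classified[["chrom", "start", "end", "score", "distance", "proximity"]].head(3))
```

prints

```
QC: M.CviPI efficiency 0.931, conversion 0.987, pass=True
genome GCH background level: 0.181
30 NDRs called; 30 proximal
  chrom  start    end       score  distance proximity
0  chr1   3120   3560   77.152729       7.0  proximal
1  chr1   9800  10220   90.946583      11.0  proximal
2  chr1  16460  16880  111.286007       5.0  proximal
```

The λ spike-in recovers the generating enzyme efficiency (0.93) and
conversion rate (0.987), the GCH background reflects the mostly closed
genome (baseline openness 0.15 × efficiency, plus the open promoters), and
all 30 planted promoter NDRs are recovered, each centered a few bp from its
TSS with −log10 p well beyond the cutoff of 5.

The same stages are available from a shell:

```bash
nomekit simulate --seed 1 -o study/
nomekit qc study/fgc_rep1.lambda.tsv -g study/lambda.fa -o qc.tsv
nomekit call-ndr study/fgc_rep1.calls.tsv -g study/genome.fa -o ndr.bed
nomekit run-all --seed 1 -o run/        # full pipeline + manifest
```

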