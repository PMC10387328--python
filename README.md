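# ecdnatk

Toolkit for detecting extrachromosomal circular DNA (ecDNA) in single-cell
long-read sequencing data, with companion modules for long-read copy-number
calling, structural-variant integration with matched RNA reads, a fully
seeded simulator, and evaluation utilities.

The core idea: when a long read traverses the origin of a circular molecule,
its split alignments land on the reference in *reversed genomic order* —
the fragment later in the read starts at or upstream of the previous
fragment's start. The detector refines split-alignment chains, classifies
each adjacent fragment pair as a circular or linear junction, clusters
breakpoints across reads and cells, walks the resulting breakpoint graph for
cycles, filters repeat- and SV-confounded candidates, deduplicates junction
reads, and reports consensus circles with per-cell quantification.

## Quick start (library)

A seeded plasmid spike-in experiment — 16 circular species at copy numbers
1–100 mixed into 12 cells — detected end to end:

```python
from ecdnatk import simulate as sim
from ecdnatk.pipeline import detect_ecdna
from ecdnatk import evaluate as ev

res, copy_table, plasmids = sim.spike_in_experiment(seed=7, emit_sequences=False)
consensus = detect_ecdna(res.chains)
print("circles detected:", len(consensus))
c = consensus[0]
print("first:", c.id, c.cyclization_site, "pooled support", c.total_support)

table = ev.plasmid_detection_table(consensus, [p.label for p in plasmids],
                                   sorted(res.chains))
per_cell, avg = ev.plasmid_regression(table, copy_table)
print("avg per-cell R^2 = %.3f" % avg)
```

Output:

```
circles detected: 16
first: ecDNA_0001 ('plasmid_01', 0, 3300) pooled support 8
avg per-cell R^2 = 0.974
```

All 16 species are recovered, including the single-copy one, and detected
junction-read counts regress against true copy numbers with R² ≈ 0.97.

## Quick start (CLI)

```
$ ecdnatk --help
Usage: ecdnatk [OPTIONS] COMMAND [ARGS]...

  Single-cell long-read ecDNA / CNV / SV toolkit.

Commands:
  cnv       Bin-based CNV calling with GC correction and CBS segmentation.
  demo      Full synthetic round trip: simulate, detect, cnv, svrna, evaluate.
  detect    Run the ecDNA caller and write the result tables.
  evaluate  Compare detector output against simulator truth circles.
  simulate  Generate a synthetic dataset (FASTA, BED, SAM, FASTQ, truth tables).
  svrna     Filter/merge SVs and test whether each DEL/INS is transcribed.
```

The fastest way to see everything working together:

```bash
ecdnatk demo --seed 0 --out demo_out
cat demo_out/report.json
```

which runs simulate → detect → evaluate → cnv → svrna on a synthetic
genome and prints (deterministically for a given seed):

```json
{
  "cnv_gain_calls": 1,
  "detection": {
    "mean_site_error_bp": 0.0,
    "n_predicted": 19,
    "n_truth": 19,
    "precision": 1.0,
    "sensitivity": 1.0
  },
  "n_ecdna_detected": 19,
  "plasmid_avg_r2": 0.9914,
  "rna_truth_junction_reads": 60,
  "seed": 0,
  "sv_transcribed": {
    "DEL_chr1_104000_105000": true,
    "INS_chr2_105000": true
  }
}
```

Typical real-data style invocation (one SAM/BAM per cell, or pooled files
with cell-suffixed read names):

```bash
ecdnatk detect --bam cell1.bam --bam cell2.bam \
    --repeats repeats.bed --sv merged.vcf --gtf genes.gtf \
    --min-support 3 --out results/
ecdnatk cnv --bam cell1.bam --genome ref.fa --gaps gaps.bed \
    --bin-size 500000 --out cnv_out/
ecdnatk svrna --sv cell1.vcf --sv cell2.vcf --genome ref.fa \
    --rna cell1_rna.fastq --rna cell2_rna.fastq --out sv_out/
```

`detect` also accepts `--config config.yaml` exposing every pipeline
parameter (clustering tolerance, repeat-flank width, minimum support,
dedup window, …); command-line flags override the file.

## Package layout

| Module | Contents |
| --- | --- |
| `ecdnatk.model` | Frozen dataclasses for alignments, junctions, clusters, circles, SVs |
| `ecdnatk.io` | SAM/FASTA/FASTQ/BED/VCF/GTF readers and table writers |
| `ecdnatk.finder` | Chain refinement, junction calling, breakpoint clustering, cycle search, filters, consensus merge |
| `ecdnatk.cnv` | Genome binning, read counting, LOWESS GC correction, CBS segmentation, gain/loss calls |
| `ecdnatk.sv` | SV filtering/merging, variant reference construction, transcription validation against RNA reads |
| `ecdnatk.simulate` | Seeded genome/plasmid/read simulators (DNA and RNA) with error model and truth tables |
| `ecdnatk.evaluate` | Detection tables, copy-number regression, detection reports, expression contrasts |
| `ecdnatk.pipeline` | `detect_ecdna` — the end-to-end caller |
| `ecdnatk.cli` | `ecdnatk` command-line entry point |

See [docs/methods.md](docs/methods.md) for the algorithms, default
parameters, and design decisions.

## Tests

```bash
python -m pytest
```

The suite contains unit tests per module, hypothesis property tests,
CLI round trips, and `tests/test_acceptance.py`, which checks the headline
claims: full recovery of the 16-plasmid spike-in, per-cell copy-number
R² ≥ 0.8, binning arithmetic, equivalence of the cycle search against an
independent brute-force oracle on 200 random instances, boundary semantics
of every threshold, CNV recovery over 50 replicates, and transcribed-SV
validation.

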