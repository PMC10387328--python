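# Methods

This document describes the algorithms, default parameters, and design
decisions behind `ecdnatk`. All defaults quoted here live in
`ecdnatk.pipeline.PipelineConfig` (detection), the function signatures in
`ecdnatk.cnv` / `ecdnatk.sv`, and `ecdnatk.simulate`.

## 1. ecDNA detection (`ecdnatk.finder`, `ecdnatk.pipeline`)

### 1.1 Input model

Detection consumes per-cell split-alignment chains: for each long read, the
list of `AlignedInterval`s (read-space interval, chromosome, reference
interval, strand) produced by a split-read aligner. `ecdnatk.io` builds
chains from SAM/BAM primary + supplementary alignments; cell identity comes
from one file per cell or from a barcode suffix on read names
(`--barcode-sep`).

### 1.2 Chain refinement (`refine_chain`)

Chains are sorted by read-space start and cleaned by three rules applied to
a fixed point:

- **LOWALIGN** — drop intervals covering < 100 bp of read space
  (`min_interval`).
- **OVER** — drop an interval whose *read-space* span is contained in an
  adjacent interval's read-space span. Containment is deliberately tested
  in read space, not genome space: a read that traverses a small circle
  more than once legitimately produces a full-length genomic interval
  flanked by partial passes of the same locus, and genomic containment
  would delete exactly that multi-pass signal.
- **DUPLIC** — for adjacent intervals on the same chromosome whose
  reference starts and ends each differ by < 500 bp (`duplic_tol`), drop
  the shorter one if its read-space length is < 1000 bp
  (`duplic_max_len`). This removes aligner-induced near-duplicate split
  records while the length guard again protects genuine multi-pass reads.

### 1.3 Junction classification (`chain_to_junctions`)

Each adjacent pair of refined intervals becomes one junction:

- **Circular** if both intervals share chromosome and strand and the
  later-in-read interval starts *at or upstream of* the earlier one's
  start (`ref_start₂ ≤ ref_start₁` on "+", mirrored on "−"). The junction
  records the circle's head (smaller coordinate) and tail. Equality
  counts as circular on purpose: a linear continuation always begins at or
  beyond the previous fragment's genomic *end*, so a fragment restarting
  at the same start coordinate is a full pass followed by another pass —
  an origin crossing. A read wrapping a circle twice therefore yields two
  circular junctions at the same position, doubling its support.
- **Linear** otherwise (strand switch, chromosome switch, or a forward
  genomic jump). The junction records the two breakpoint endpoints with
  head/tail orientation derived from strand.

### 1.4 Breakpoint clustering (`cluster_breakpoints`)

Endpoints are grouped per (chromosome, orientation), sorted, and clustered
sequentially: a point joins the current cluster iff its distance to the
cluster's running lower-median is strictly < 500 bp (`merge_tol`);
otherwise it starts a new cluster. The cluster representative position is
the lower median of its members. Each cluster is then linked to its
nearest-neighbour cluster on the same chromosome (ties broken by
(distance, position)), forming candidate genomic fragments.

### 1.5 Cycle search (`detect_circles`)

A bipartite-style graph is built over clusters with two edge kinds:
*fragment* edges (nearest-neighbour links) and *junction* edges
(read-evidenced adjacencies between clusters). Single-fragment circles
come directly from circular-junction head/tail cluster pairs.
Multi-fragment circles are simple cycles (via `networkx.simple_cycles`)
alternating fragment and junction edges; cycles confined to one chromosome
must include at least one circular junction, so that chains of ordinary
linear rearrangements are not promoted to circles.

### 1.6 Filtering, deduplication, support

- **Repeat filter** — a candidate is removed when the 300 bp flanks
  (`flank`) on either side of its cyclization site overlap annotated
  repeats by ≥ 30 bp total (`repeat_min_ovl`, inclusive), because
  repeat-mediated chimeric alignments mimic circular junctions.
- **SV proximity filter** — candidates whose cyclization breakpoints fall
  within 500 bp of an independently called structural variant are removed
  as likely rearrangement artefacts.
- **Deduplication** — junction reads from the same cell with identical
  junction coordinates and outer alignment coordinates within 10 bp
  (`dedup_tol`) are counted once (PCR/optical duplicates).
- **Consensus merge** — per-cell candidates are merged across cells by
  single linkage with both cyclization endpoints within < 500 bp; the
  representative is the member with the longest total genomic span. Merged
  circles get stable ids `ecDNA_0001, …`.
- **Support filter** — a consensus circle is reported when its *pooled*
  cross-cell deduplicated junction-read support is ≥ 3 (`min_support`).
  Pooling is deliberate: at realistic depth a single-copy circle yields
  well under one junction read per cell but several across a 12-cell pool;
  filtering per cell before merging would make low-copy species
  undetectable by construction.

`detect_ecdna` returns `ConsensusEcDNA` records with fragments,
cyclization site, per-cell support and coverage, and optional gene /
cancer-gene annotation from a GTF and a catalogue list.

## 2. Copy-number calling (`ecdnatk.cnv`)

- **Binning** (`make_bins`) — fixed 500 kb bins per chromosome, excluding
  chrY and chrM. Assembly gaps are handled either by *excise* (default:
  remove gap bases, tile the remaining blocks, restart tiling after each
  gap) or *drop* (discard any bin overlapping a gap). A terminal partial
  bin is kept when it covers ≥ 20 % of the bin size. GC content per bin is
  computed when sequence is available.
- **Counting** (`count_reads`) — a read is assigned to every bin it
  overlaps by ≥ 10 bp (inclusive); counts are scaled to a common library
  size so cells are comparable.
- **GC correction** (`gc_correct`) — LOWESS (statsmodels, `frac=0.3`,
  3 robustness iterations) of count vs GC, interpolated at each bin's GC;
  the count/fit ratio is converted to copy number (2 × ratio) and a log2
  track. Requires ≥ 50 usable bins. Note: the robust reweighting step is
  discontinuous on near-constant data, so exact scale invariance holds
  only with `it=0`.
- **Segmentation** — circular binary segmentation implemented in-repo
  (no maintained Python CBS was available): recursively find the arc
  maximizing the t-statistic between arc and complement, accept via a
  seeded permutation test (with early stopping), recurse. Deterministic
  given the seed.
- **Calls** (`call_cnv`) — segment mean copy number > 2.6 → gain,
  < 1.4 → loss, both strict; calls spanning ≤ 500 kb (`min_len`) are reset
  to neutral.

## 3. SV integration and RNA validation (`ecdnatk.sv`)

- **Filtering** (`filter_svs`) — keep PRECISE calls with ≥ 3 supporting
  reads: deletions of 100 bp–100 kb, insertions of 100 bp–2.5 kb
  (inclusive bounds), and translocations. Order-preserving and
  idempotent.
- **Merging** (`merge_svs`) — true single linkage (union-find) over
  same-type, same-chromosome records whose both breakpoints differ by
  strictly < 500 bp. Leader-style clustering against a first-seen
  representative was rejected because it is input-order dependent; the
  union-find formulation is provably order invariant (and property-tested
  as such). `MergedSV.supporting_cells` counts distinct cells.
- **Variant references** — for each merged DEL/INS a variant-allele
  reference is built from 500 bp flanks around the junction (clipped at
  chromosome start; < 100 bp total is an error). For insertions the
  inserted sequence is embedded and its span recorded.
- **Transcription validation** (`validate_transcribed`) — each RNA read is
  locally aligned (Biopython `PairwiseAligner`, match 2, mismatch −4, gap
  open −6, extend −1) to the variant reference in both orientations; a
  read *supports* a deletion when ≥ 100 aligned bases fall on the variant
  reference with ≥ 20 bp on each side of the junction, and an insertion
  when ≥ 100 aligned bases fall inside the inserted region. A
  variant is *transcribed* with ≥ 1 supporting read and *reported* with
  support from ≥ 3 cells. An exact 15-mer prescreen (`seed_k`, `None`
  disables) skips the O(nm) alignment for reads sharing no 15-mer with the
  reference — at long-read error rates any read that could pass the
  100-aligned-base rule shares a 15-mer with near certainty, so the
  prescreen changes throughput, not calls.

## 4. Simulator (`ecdnatk.simulate`)

Everything is driven by `numpy.random.default_rng(seed)` and fully
deterministic per seed.

- **Genomes** (`make_genome`) — random sequence with per-window GC targets
  (fixed value or gradient range), true tandem repeats (2–50 bp units
  tiled over annotated intervals), and N-run assembly gaps. Returns
  `(genome, gaps, repeats)`.
- **Plasmids / circles** — circular templates excised from the genome or
  generated de novo (`make_plasmids`: 16 species, lengths evenly spanning
  3,300–27,300 bp by default).
- **DNA reads** (`simulate_dna_reads`) — fragment lengths lognormal
  (mean 6 kb, sd 3 kb); reads from circular templates may wrap the origin
  (reads longer than the circle always do), producing split chains with
  the circular signature plus SAM records and a truth table (read id,
  cell, source, junction count, length). Error model: 3 % substitutions,
  2 % indels. Because the error model consumes RNG draws, error-free and
  errorful runs are not read-for-read comparable.
- **Spike-in** (`spike_in_experiment`) — the 16-species pool at copy
  gradient {1, 2, 3, 5, 7, 10, 15, 20, 25, 30, 40, 50, 60, 70, 85, 100}
  across 12 cells at 1.0× per-copy coverage; returns reads, a
  cell × plasmid copy table, and the plasmid records. These conditions
  were fixed once, before any detector measurement, and are the conditions
  reproduced by `scripts/acceptance.py`.
- **RNA reads** (`simulate_rna_reads`) — full-length transcript reads by
  default (`read_len=None`), modelling full-length cDNA; fixed-length
  fragments via `read_len`. Truth marks whether a read spans a variant
  junction with ≥ 100 bp margin.
- **CNV reads** (`simulate_read_intervals`) — read intervals at depth
  scaled by a per-region copy-number profile.

**Scope and limits.** The simulator models split alignments directly
rather than running an aligner, uses i.i.d. substitution/indel errors (no
homopolymer bias), uniform fragment start positions, and no chimera or
barcode-collision artefacts. It is designed to exercise the detector's
geometry and thresholds, not to benchmark aligners.

## 5. Evaluation (`ecdnatk.evaluate`)

- `plasmid_detection_table` — cells × species support matrix, circles
  matched to species by cyclization chromosome.
- `plasmid_regression` — per-cell OLS R² of detected support vs true
  copies, plus the cell average. Cells with zero variance in true copies
  give NaN and are excluded from the average; zero variance in detected
  support gives R² = 0; fewer than 3 species with nonzero copies is an
  error.
- `detection_report` — sensitivity, precision, and mean cyclization-site
  error against truth circles matched within 500 bp per endpoint
  (empty predictions → precision NaN).
- `expression_contrast` — Mann–Whitney U contrast of ecDNA-resident vs
  other genes (keys `median_ecdna`, `median_other`, `statistic`,
  `pvalue`, counts).

## 6. Numerical and engineering choices

- All dataclasses in `ecdnatk.model` are frozen; pipeline functions are
  pure (no hidden state), and every stochastic routine takes an explicit
  seed or `Generator`.
- Threshold semantics are pinned by tests on both sides of every boundary
  (e.g. 99/100/101 bp for LOWALIGN, 499/500/501 bp for clustering and
  merging, 29/30/31 bp repeat overlap, 2/3/4 support).
- Established libraries are used for standard primitives — pysam/pyfaidx
  for alignment and FASTA I/O, statsmodels LOWESS, scipy statistics,
  Biopython pairwise alignment, networkx cycle enumeration — while the
  method-specific pieces (chain refinement, junction logic, clustering,
  cycle search, CBS, simulator) are implemented in-repo.
- The test suite cross-checks the cycle search against an independent
  brute-force oracle (`tests/oracles.py`) on 200 seeded random instances,
  and uses hypothesis property tests for idempotence, order invariance,
  and translation equivariance.

## 7. Known limitations

- The cycle search enumerates simple cycles; very dense breakpoint graphs
  (hundreds of interacting clusters on one chromosome) could be slow.
- GC correction assumes a mostly diploid baseline; genomes dominated by
  aneuploidy would bias the LOWESS fit.
- Circles whose cyclization sites sit entirely inside annotated repeats
  are filtered by design and cannot be recovered.
- RNA validation tests presence of junction-spanning transcription, not
  isoform structure or expression quantification.
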