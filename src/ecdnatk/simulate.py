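"""Synthetic-data generation for the whole toolkit.

The generator emulates transposase-fragmented single-cell long-read
genome sequencing: fragments are drawn lognormally around a 6-kb mean
from linear chromosomes, from genomic circles and from spiked-in circular
plasmids, with configurable substitution and indel error.  Circular
templates are sampled with a start position uniform on the circle, so a
fragment crosses the cyclization joint with probability
min(1, fragment/circle length).  Every read is emitted together with its
exact truth alignment (a junction-crossing read appears as two or more
split segments), so the downstream callers are testable without an
external aligner; FASTQ and truth SAM writers are provided for
integration against a real aligner.

Determinism: all randomness flows through one ``numpy.random.Generator``
seeded per call; identical seeds give identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .model import AlignedInterval, CircleSpec, FragmentChain, PlasmidSpec

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _fwd, _rev in zip(b"ACGTN", b"TGCAN"):
    _COMP[_fwd] = _rev
del _fwd, _rev

DEFAULT_FRAG_MEAN = 6000
DEFAULT_FRAG_SD = 3000
DEFAULT_ERR_SUB = 0.03
DEFAULT_ERR_INDEL = 0.02
MIN_FRAG = 200

# spike-in study conditions: 16 plasmid species evenly spanning
# 3.3-27.3 kb at a 1-100 copy gradient, 12 cells per pool
DEFAULT_GRADIENT = (1, 2, 3, 5, 7, 10, 15, 20, 25, 30, 40, 50, 60, 70, 85, 100)
PLASMID_LEN_RANGE = (3300, 27300)


def _seq_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _arr_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode()


def revcomp(seq: str) -> str:
    return _arr_to_seq(_COMP[_seq_to_arr(seq)][::-1])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)]


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def make_genome(
    n_chrom: int = 1,
    lengths: int | list[int] = 1_000_000,
    gc_target: float | tuple[float, float] = 0.45,
    n_repeats: int = 0,
    n_gaps: int = 0,
    gap_len: int = 20_000,
    gc_window: int = 100_000,
    seed: int = 0,
    chrom_names: list[str] | None = None,
) -> tuple[dict[str, str], dict[str, list[tuple[int, int]]], dict[str, list[tuple[int, int]]]]:
    """Random genome with annotated tandem repeats and N-gaps.

    ``gc_target`` may be a single fraction or a (lo, hi) range, in which
    case each ``gc_window`` stretch draws its own GC content — this gives
    the GC gradient the copy-number correction needs to be exercised
    against.  Tandem repeats (unit 2-50 bp, total 100-2000 bp) and N-gaps
    are injected and returned as 0-based half-open interval tracks.
    """
    rng = np.random.default_rng(seed)
    if isinstance(lengths, int):
        lengths = [lengths] * n_chrom
    names = chrom_names or [f"chr{i + 1}" for i in range(len(lengths))]
    genome: dict[str, str] = {}
    repeats: dict[str, list[tuple[int, int]]] = {}
    gaps: dict[str, list[tuple[int, int]]] = {}
    for name, length in zip(names, lengths):
        if isinstance(gc_target, tuple):
            chunks = []
            for off in range(0, length, gc_window):
                w = min(gc_window, length - off)
                gcw = rng.uniform(*gc_target)
                chunks.append(_random_seq(rng, w, gcw))
            arr = np.concatenate(chunks)
        else:
            arr = _random_seq(rng, length, gc_target)
        repeats[name] = []
        for _ in range(n_repeats):
            unit = int(rng.integers(2, 51))
            total = int(rng.integers(100, 2001))
            pos = int(rng.integers(0, max(1, length - total)))
            unit_seq = _random_seq(rng, unit, 0.5)
            tiled = np.tile(unit_seq, total // unit + 1)[:total]
            arr[pos : pos + total] = tiled
            repeats[name].append((pos, pos + total))
        gaps[name] = []
        for _ in range(n_gaps):
            pos = int(rng.integers(0, max(1, length - gap_len)))
            arr[pos : pos + gap_len] = ord("N")
            gaps[name].append((pos, pos + gap_len))
        repeats[name].sort()
        gaps[name].sort()
        genome[name] = _arr_to_seq(arr)
    return genome, gaps, repeats


def make_plasmids(
    n: int = 16,
    length_range: tuple[int, int] = PLASMID_LEN_RANGE,
    gradient: tuple[int, ...] = DEFAULT_GRADIENT,
    seed: int = 0,
) -> list[PlasmidSpec]:
    """``n`` unique circular plasmids with lengths evenly spanning the
    range, copy numbers assigned along the gradient."""
    rng = np.random.default_rng(seed)
    lengths = np.linspace(length_range[0], length_range[1], n).astype(int)
    if len(gradient) < n:
        raise ValueError("gradient shorter than plasmid count")
    return [
        PlasmidSpec(
            label=f"plasmid_{i + 1:02d}",
            sequence=_arr_to_seq(_random_seq(rng, int(L), 0.5)),
            copies=int(gradient[i]),
        )
        for i, L in enumerate(lengths)
    ]


# ---------------------------------------------------------------------------
# error model
# ---------------------------------------------------------------------------

def _mutate(
    arr: np.ndarray, err_sub: float, err_indel: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Apply substitutions and single-base indels to a template segment.

    Returns the query array and a pysam-style CIGAR (ops 0=M, 1=I, 2=D)
    describing how the query aligns back to the template.
    """
    n = len(arr)
    if err_sub <= 0 and err_indel <= 0:
        return arr.copy(), [(0, n)]
    p_del = p_ins = err_indel / 2.0
    keep = rng.random(n) >= p_del
    ins = rng.random(n) < p_ins
    out = arr.copy()
    if err_sub > 0:
        sub_mask = keep & (rng.random(n) < err_sub)
        idx = np.where(sub_mask)[0]
        if len(idx):
            # replace with one of the three other bases
            cur = np.searchsorted(_BASES, out[idx])
            out[idx] = _BASES[(cur + rng.integers(1, 4, size=len(idx))) % 4]
    counts = keep.astype(np.int64) + ins.astype(np.int64)
    offsets = np.cumsum(counts) - counts
    total = int(counts.sum())
    q = np.empty(total, dtype=np.uint8)
    m_idx = np.where(keep)[0]
    q[offsets[m_idx]] = out[m_idx]
    i_idx = np.where(ins)[0]
    if len(i_idx):
        q[offsets[i_idx] + keep[i_idx]] = _BASES[rng.integers(0, 4, size=len(i_idx))]
    # per-template-position op codes -> run-length encoded CIGAR
    ops = np.full(2 * n, -1, dtype=np.int8)
    ops[0::2] = np.where(keep, 0, 2)  # M or D
    ops[1::2] = np.where(ins, 1, -1)  # I or nothing
    ops = ops[ops >= 0]
    if len(ops) == 0:
        return q, []
    change = np.flatnonzero(np.diff(ops)) + 1
    bounds = np.concatenate([[0], change, [len(ops)]])
    cigar = [(int(ops[a]), int(b - a)) for a, b in zip(bounds[:-1], bounds[1:])]
    return q, cigar


# ---------------------------------------------------------------------------
# templates and reads
# ---------------------------------------------------------------------------

@dataclass
class _Template:
    """A linear or circular walkable source sequence mapped to references."""

    label: str
    segments: list[tuple[str, int, int]]  # (ref, start, end), + orientation
    circular: bool

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e in self.segments)

    def walk(self, start: int, length: int) -> tuple[list[tuple[str, int, int]], int]:
        """Reference pieces covered by a fragment starting at ``start``
        (template coordinates); returns the pieces in read order and the
        number of origin crossings (= cyclization-junction passes)."""
        pieces: list[tuple[str, int, int]] = []
        crossings = 0
        pos = start % self.length
        remaining = length
        first = True
        while remaining > 0:
            if not first and pos == 0 and self.circular:
                crossings += 1
            off = 0
            for ref, s, e in self.segments:
                seg_len = e - s
                if pos < off + seg_len:
                    take = min(remaining, off + seg_len - pos)
                    a = s + (pos - off)
                    pieces.append((ref, a, a + take))
                    pos += take
                    remaining -= take
                    break
                off += seg_len
            if pos >= self.length:
                if not self.circular:
                    break
                pos = 0
            first = False
        return pieces, crossings


@dataclass
class SimulatedReads:
    """In-memory result of a simulation run for one or more cells."""

    chains: dict[str, list[FragmentChain]]  # cell -> truth chains
    references: dict[str, str]  # reference name -> sequence (genome + plasmids)
    sequences: dict[str, str] = field(default_factory=dict)  # read -> bases
    truth: pd.DataFrame | None = None  # per-read origin table
    sam_records: dict[str, list[dict]] = field(default_factory=dict)

    def junction_reads(self, label: str, cell: str | None = None) -> pd.DataFrame:
        df = self.truth
        sel = (df["source"] == label) & (df["n_junctions"] > 0)
        if cell is not None:
            sel &= df["cell"] == cell
        return df[sel]

    def write_sam(self, cell: str, path) -> None:
        header = {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": len(s)} for n, s in self.references.items()],
        }
        ref_ids = {n: i for i, n in enumerate(self.references)}
        with pysam.AlignmentFile(str(path), "wh", header=header) as out:
            for rec in self.sam_records.get(cell, []):
                a = pysam.AlignedSegment()
                a.query_name = rec["name"]
                a.flag = rec["flag"]
                a.reference_id = ref_ids[rec["ref"]]
                a.reference_start = rec["pos"]
                a.mapping_quality = 60
                a.cigartuples = rec["cigar"]
                if rec.get("seq") is not None:
                    a.query_sequence = rec["seq"]
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(rec["seq"]))
                out.write(a)

    def write_fastq(self, cell: str, path) -> None:
        with open(path, "w") as fh:
            for ch in self.chains[cell]:
                seq = self.sequences.get(ch.read_id)
                if seq is None:
                    continue
                fh.write(f"@{ch.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def _frag_lengths(n: int, mean: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    lens = rng.lognormal(mu, math.sqrt(sigma2), size=n)
    return np.maximum(lens.astype(int), MIN_FRAG)


def simulate_dna_reads(
    genome: dict[str, str],
    cells: list[str],
    circles: list[CircleSpec] | None = None,
    plasmids: list[PlasmidSpec] | None = None,
    depth: float = 0.1,
    copy_coverage: float | None = None,
    frag_mean: float = DEFAULT_FRAG_MEAN,
    frag_sd: float = DEFAULT_FRAG_SD,
    err_sub: float = DEFAULT_ERR_SUB,
    err_indel: float = DEFAULT_ERR_INDEL,
    seed: int = 0,
    emit_sequences: bool = True,
) -> SimulatedReads:
    """Simulate per-cell long DNA reads with exact truth alignments.

    ``depth`` is the per-cell depth over the diploid linear genome;
    circular templates are sampled at ``copy_coverage`` per copy
    (default ``depth / 2``, i.e. the same per-copy coverage as one
    chromosome homolog, which makes circle copy numbers directly
    comparable with the diploid baseline).  Reads are oriented + or -
    with equal probability; truth chains express read coordinates on the
    original read orientation.
    """
    circles = circles or []
    plasmids = plasmids or []
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not genome and not plasmids and not circles:
        raise ValueError("empty template set")
    rng = np.random.default_rng(seed)
    per_copy = depth / 2.0 if copy_coverage is None else copy_coverage

    references = dict(genome)
    for p in plasmids:
        references[p.label] = p.sequence
    ref_arrs = {n: _seq_to_arr(s) for n, s in references.items()} if emit_sequences else {}

    chains: dict[str, list[FragmentChain]] = {c: [] for c in cells}
    sequences: dict[str, str] = {}
    sam_records: dict[str, list[dict]] = {c: [] for c in cells}
    truth_rows = []
    counter = 0

    templates: list[tuple[_Template, float, str]] = []  # (template, coverage, source)
    for chrom, seq in genome.items():
        templates.append((_Template(chrom, [(chrom, 0, len(seq))], circular=False), depth, chrom))
    for c in circles:
        segs = [(chrom, s, e) for chrom, s, e, _ in c.fragments]
        templates.append((_Template(c.label, segs, circular=True), per_copy, c.label))
    for p in plasmids:
        templates.append(
            (_Template(p.label, [(p.label, 0, p.length)], circular=True), per_copy, p.label)
        )

    for cell in cells:
        for tmpl, cov, source in templates:
            copies = 1
            spec = next((c for c in circles if c.label == source), None)
            if spec is not None:
                copies = spec.copies_per_cell.get(cell, 0)
            pspec = next((p for p in plasmids if p.label == source), None)
            if pspec is not None:
                copies = pspec.copies
            eff_cov = cov * (copies if (spec or pspec) else 1)
            if eff_cov <= 0:
                continue
            n_frag = int(rng.poisson(eff_cov * tmpl.length / frag_mean))
            if n_frag == 0:
                continue
            starts = rng.integers(0, tmpl.length, size=n_frag)
            lens = _frag_lengths(n_frag, frag_mean, frag_sd, rng)
            if tmpl.circular:
                lens = np.minimum(lens, 2 * tmpl.length)  # at most two full passes
            for st, ln in zip(starts, lens):
                counter += 1
                name = f"{cell}:read{counter:07d}"
                # linear fragments are clipped at the chromosome end by walk()
                pieces, crossings = tmpl.walk(int(st), int(ln))
                minus = bool(rng.integers(0, 2))
                _emit_read(
                    name, cell, pieces, minus, ref_arrs, err_sub, err_indel, rng,
                    chains, sequences, sam_records, emit_sequences,
                )
                truth_rows.append(
                    {"read_id": name, "cell": cell, "source": source,
                     "n_junctions": crossings, "length": int(sum(e - s for _, s, e in pieces))}
                )

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "cell", "source", "n_junctions", "length"]
    )
    return SimulatedReads(
        chains=chains, references=references, sequences=sequences,
        truth=truth, sam_records=sam_records,
    )


def _emit_read(
    name, cell, pieces, minus, ref_arrs, err_sub, err_indel, rng,
    chains, sequences, sam_records, emit_sequences,
):
    """Materialize one read: per-piece error injection, truth chain on the
    original read orientation, and SAM records (primary = longest piece)."""
    seg_info = []  # (ref, rs, re, refstart, refend, cigar)
    qparts = []
    qpos = 0
    for ref, s, e in pieces:
        if emit_sequences:
            q, cigar = _mutate(ref_arrs[ref][s:e], err_sub, err_indel, rng)
        else:
            q, cigar = np.empty(e - s, dtype=np.uint8), [(0, e - s)]
        qlen = len(q)
        seg_info.append((ref, qpos, qpos + qlen, s, e, cigar))
        if emit_sequences:
            qparts.append(q)
        qpos += qlen
    total = qpos
    plus_seq = None
    if emit_sequences:
        full = np.concatenate(qparts) if qparts else np.empty(0, dtype=np.uint8)
        plus_seq = _arr_to_seq(full)
        # the physical read; SAM stores the + orientation (revcomp of a
        # minus-strand read), FASTQ stores the physical sequence
        sequences[name] = revcomp(plus_seq) if minus else plus_seq

    ivals = []
    longest = max(range(len(seg_info)), key=lambda i: seg_info[i][2] - seg_info[i][1])
    for i, (ref, rs, re_, gs, ge, cigar) in enumerate(seg_info):
        if minus:
            a_rs, a_re = total - re_, total - rs
            strand = "-"
        else:
            a_rs, a_re = rs, re_
            strand = "+"
        ivals.append(
            AlignedInterval(
                read_id=name, cell_id=cell, read_start=a_rs, read_end=a_re,
                chrom=ref, ref_start=gs, ref_end=ge, strand=strand,
                mapq=60, is_supplementary=(i != longest),
            )
        )
        flag = (16 if minus else 0) | (0 if i == longest else 2048)
        sam_cigar = []
        if rs > 0:
            sam_cigar.append((4, rs))
        sam_cigar.extend(cigar)
        if total - re_ > 0:
            sam_cigar.append((4, total - re_))
        sam_records[cell].append(
            {
                "name": name, "flag": flag, "ref": ref, "pos": gs,
                "cigar": sam_cigar,
                "seq": plus_seq,
            }
        )
    chains[cell].append(FragmentChain(read_id=name, cell_id=cell, intervals=ivals))


# ---------------------------------------------------------------------------
# spike-in experiment
# ---------------------------------------------------------------------------

def spike_in_experiment(
    n_plasmids: int = 16,
    gradient: tuple[int, ...] = DEFAULT_GRADIENT,
    n_cells: int = 12,
    coverage_per_copy: float = 1.0,
    background_genome: dict[str, str] | None = None,
    background_depth: float = 0.3,
    frag_mean: float = DEFAULT_FRAG_MEAN,
    frag_sd: float = DEFAULT_FRAG_SD,
    err_sub: float = DEFAULT_ERR_SUB,
    err_indel: float = DEFAULT_ERR_INDEL,
    seed: int = 0,
    emit_sequences: bool = True,
) -> tuple[SimulatedReads, pd.DataFrame, list[PlasmidSpec]]:
    """The plasmid spike-in validation experiment: ``n_plasmids`` unique
    circular species at gradient copy numbers added to every cell's
    reaction.  Returns the simulated reads, the truth copy table
    (cell x plasmid with copies and length) and the plasmid specs.
    """
    rng = np.random.default_rng(seed)
    plasmids = make_plasmids(n_plasmids, gradient=gradient, seed=int(rng.integers(2**31)))
    cells = [f"cell{i + 1:02d}" for i in range(n_cells)]
    sim = simulate_dna_reads(
        genome=background_genome or {},
        cells=cells,
        plasmids=plasmids,
        depth=background_depth if background_genome else 1.0,
        copy_coverage=coverage_per_copy,
        frag_mean=frag_mean,
        frag_sd=frag_sd,
        err_sub=err_sub,
        err_indel=err_indel,
        seed=int(rng.integers(2**31)),
        emit_sequences=emit_sequences,
    )
    truth = pd.DataFrame(
        [
            {"cell": cell, "plasmid": p.label, "copies": p.copies, "length": p.length}
            for cell in cells
            for p in plasmids
        ]
    )
    return sim, truth, plasmids


# ---------------------------------------------------------------------------
# RNA reads
# ---------------------------------------------------------------------------

def simulate_rna_reads(
    genes,
    genome: dict[str, str],
    variants=None,
    expression: dict[str, int] | None = None,
    cells: list[str] | None = None,
    read_len: int | None = None,
    err_sub: float = 0.0,
    seed: int = 0,
    junction_margin: int = 100,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Transcript reads from gene spans, with the variant allele applied.

    ``variants`` maps gene_name -> SVRecord (DEL or INS inside the gene);
    the gene's transcript then carries the deletion splice or the inserted
    sequence.  ``expression`` gives reads per gene per cell.  The default
    ``read_len=None`` emits full-length transcript reads (the full-length
    cDNA long-read model); an integer samples fixed-length fragments
    instead.  Returns ``(read_id, cell_id, sequence)`` tuples and a truth
    table marking which reads span a variant junction with at least
    ``junction_margin`` bases on each side.
    """
    rng = np.random.default_rng(seed)
    variants = variants or {}
    expression = expression or {}
    cells = cells or ["cell01"]
    reads: list[tuple[str, str, str]] = []
    rows = []
    counter = 0
    for g in genes:
        n_reads = expression.get(g.gene_name, 0)
        if n_reads <= 0:
            continue
        seq = genome[g.chrom][g.start : g.end]
        sv = variants.get(g.gene_name)
        junction = None
        if sv is not None and sv.sv_type == "DEL":
            a, b = sv.pos1 - g.start, sv.pos2 - g.start
            seq = seq[:a] + seq[b:]
            junction = (a, a)
        elif sv is not None and sv.sv_type == "INS":
            a = sv.pos1 - g.start
            seq = seq[:a] + sv.inserted_seq + seq[a:]
            junction = (a, a + len(sv.inserted_seq))
        if read_len is not None and len(seq) < read_len:
            continue
        for cell in cells:
            for _ in range(n_reads):
                counter += 1
                if read_len is None:
                    start, end = 0, len(seq)
                else:
                    start = int(rng.integers(0, len(seq) - read_len + 1))
                    end = start + read_len
                rseq = seq[start:end]
                if err_sub > 0:
                    arr = _seq_to_arr(rseq).copy()
                    mask = rng.random(len(arr)) < err_sub
                    idx = np.where(mask)[0]
                    cur = np.searchsorted(_BASES, arr[idx])
                    arr[idx] = _BASES[(cur + rng.integers(1, 4, size=len(idx))) % 4]
                    rseq = _arr_to_seq(arr)
                name = f"{cell}:rna{counter:06d}"
                spans = (
                    junction is not None
                    and start <= junction[0] - junction_margin
                    and end >= junction[1] + junction_margin
                )
                reads.append((name, cell, rseq))
                rows.append(
                    {"read_id": name, "cell": cell, "gene": g.gene_name,
                     "spans_junction": bool(spans)}
                )
    truth = pd.DataFrame(rows, columns=["read_id", "cell", "gene", "spans_junction"])
    return reads, truth


# ---------------------------------------------------------------------------
# count-level fragment placement (CNV test bed)
# ---------------------------------------------------------------------------

def simulate_read_intervals(
    chrom_lengths: dict[str, int],
    cn_regions: list[tuple[str, int, int, float]] | None = None,
    depth: float = 0.3,
    frag_mean: float = DEFAULT_FRAG_MEAN,
    frag_sd: float = DEFAULT_FRAG_SD,
    cell: str = "cell01",
    seed: int = 0,
) -> list[FragmentChain]:
    """Fast coordinate-only fragment placement with a piecewise copy-number
    profile (baseline copy number 2; ``cn_regions`` override it locally).
    Each fragment becomes a single-interval chain; used to exercise the
    CNV caller where read sequences are irrelevant.
    """
    rng = np.random.default_rng(seed)
    cn_regions = cn_regions or []
    chains = []
    counter = 0
    for chrom, length in chrom_lengths.items():
        bounds = {0, length}
        for c, s, e, _ in cn_regions:
            if c == chrom:
                bounds.update((max(0, s), min(length, e)))
        edges = sorted(bounds)
        for s, e in zip(edges, edges[1:]):
            cn = 2.0
            for c, rs, re_, rcn in cn_regions:
                if c == chrom and rs <= s and e <= re_:
                    cn = rcn
            lam = depth * (cn / 2.0) * (e - s) / frag_mean
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            starts = rng.integers(s, e, size=n)
            lens = _frag_lengths(n, frag_mean, frag_sd, rng)
            for st, ln in zip(starts, lens):
                counter += 1
                end = min(int(st) + int(ln), length)
                if end - int(st) < MIN_FRAG:
                    continue
                name = f"{cell}:frag{counter:07d}"
                chains.append(
                    FragmentChain(
                        read_id=name,
                        cell_id=cell,
                        intervals=[
                            AlignedInterval(
                                read_id=name, cell_id=cell,
                                read_start=0, read_end=end - int(st),
                                chrom=chrom, ref_start=int(st), ref_end=end,
                                strand="+",
                            )
                        ],
                    )
                )
    return chains
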