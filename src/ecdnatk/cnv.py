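"""Bin-based copy-number calling from long reads.

The genome is tiled into consecutive fixed-size bins (default 500 kb)
after excising assembly N-gaps; every primary or supplementary aligned
segment with at least 10 bp of overlap increments a bin's count.  Counts
are depth-normalized, corrected for GC bias with a LOWESS fit of count
versus bin GC fraction, expressed as copy number on a diploid baseline,
segmented with circular binary segmentation (CBS) on the log2 ratio
track, and called as gain (> 2.6), loss (< 1.4) or neutral; only calls
longer than 500 kb are retained.
"""
from __future__ import annotations

import numpy as np
from intervaltree import IntervalTree
from statsmodels.nonparametric.smoothers_lowess import lowess

from .model import CNVBin, CNVSegment, FragmentChain, overlap_len

DEFAULT_EXCLUDE = ("chrY", "chrM")


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGTacgt")
    if acgt == 0:
        return 0.0
    gc = sum(seq.count(b) for b in "GCgc")
    return gc / acgt


def make_bins(
    genome: dict[str, str] | dict[str, int],
    gaps: dict[str, list[tuple[int, int]]] | None = None,
    bin_size: int = 500_000,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
    min_tail_frac: float = 0.2,
    gap_mode: str = "excise",
) -> list[CNVBin]:
    """Tile each chromosome into consecutive bins of ``bin_size``.

    ``genome`` maps chromosome to sequence (GC is computed) or to length
    (GC left at 0).  With ``gap_mode='excise'`` (default) N-gap intervals
    are removed before tiling, so bins never span a gap; with
    ``gap_mode='drop'`` the chromosome is tiled first and bins overlapping
    a gap are discarded.  A terminal partial bin is kept when it is at
    least ``min_tail_frac`` of ``bin_size``.
    """
    gaps = gaps or {}
    bins: list[CNVBin] = []
    for chrom in genome:
        if chrom in exclude:
            continue
        entry = genome[chrom]
        seq = entry if isinstance(entry, str) else None
        length = len(entry) if seq is not None else int(entry)
        gap_list = sorted(gaps.get(chrom, []))

        def add_bin(s: int, e: int) -> None:
            gc = _gc_fraction(seq[s:e]) if seq is not None else 0.0
            bins.append(CNVBin(chrom=chrom, start=s, end=e, gc_fraction=gc))

        if gap_mode == "excise":
            blocks, prev = [], 0
            for gs, ge in gap_list:
                if gs > prev:
                    blocks.append((prev, min(gs, length)))
                prev = max(prev, ge)
            if prev < length:
                blocks.append((prev, length))
            for bs, be in blocks:
                pos = bs
                while pos + bin_size <= be:
                    add_bin(pos, pos + bin_size)
                    pos += bin_size
                if be - pos >= min_tail_frac * bin_size:
                    add_bin(pos, be)
        elif gap_mode == "drop":
            pos = 0
            while pos < length:
                end = min(pos + bin_size, length)
                if end - pos >= (bin_size if end - pos == bin_size else min_tail_frac * bin_size):
                    if not any(overlap_len(pos, end, gs, ge) for gs, ge in gap_list):
                        add_bin(pos, end)
                pos += bin_size
        else:
            raise ValueError(f"unknown gap_mode {gap_mode!r}")
    return bins


def make_bins_from_index(faidx, **kwargs) -> list[CNVBin]:
    """Convenience wrapper taking a pyfaidx.Fasta: bins carry sequence GC."""
    genome = {name: str(faidx[name][:].seq) for name in faidx.keys()}
    return make_bins(genome, **kwargs)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

def count_reads(
    chains: list[FragmentChain],
    bins: list[CNVBin],
    min_overlap: int = 10,
    library_size: float | None = None,
) -> list[CNVBin]:
    """Count aligned segments per bin (>= ``min_overlap`` bp of overlap;
    a segment spanning several bins increments each of them), then scale
    so counts sum to ``library_size`` (default: number of bins, i.e. a
    mean normalized count of 1).
    """
    trees: dict[str, IntervalTree] = {}
    for i, b in enumerate(bins):
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, i)
    counts = np.zeros(len(bins))
    for ch in chains:
        for iv in ch:
            tree = trees.get(iv.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(iv.ref_start, iv.ref_end):
                if overlap_len(iv.ref_start, iv.ref_end, hit.begin, hit.end) >= min_overlap:
                    counts[hit.data] += 1
    total = counts.sum()
    target = library_size if library_size is not None else float(len(bins))
    scale = target / total if total > 0 else 0.0
    for b, c in zip(bins, counts * scale):
        b.raw_count = float(c)
    return bins


# ---------------------------------------------------------------------------
# GC correction
# ---------------------------------------------------------------------------

def gc_correct(
    bins: list[CNVBin],
    frac: float = 0.3,
    it: int = 3,
    baseline_ploidy: float = 2.0,
) -> np.ndarray:
    """LOWESS-correct counts against GC and convert to copy number.

    Fits normalized count as a smooth function of bin GC fraction, divides
    each bin's count by its fitted value and scales the ratio by the
    diploid baseline.  Returns the log2 ratio track used for segmentation;
    ``copy_number`` is set on each bin.
    """
    counts = np.array([b.raw_count for b in bins], dtype=float)
    gc = np.array([b.gc_fraction for b in bins], dtype=float)
    if np.count_nonzero(counts) == 0:
        raise ValueError("no coverage: all bin counts are zero")
    if len(bins) < 50:
        raise ValueError("need at least 50 bins for a stable GC fit")
    fitted_pairs = lowess(counts, gc, frac=frac, it=it, return_sorted=True)
    # map fitted values back through interpolation (handles tied GC values)
    xs, ys = fitted_pairs[:, 0], fitted_pairs[:, 1]
    fitted = np.interp(gc, xs, ys)
    fallback = counts[counts > 0].mean()
    fitted = np.where(fitted > 1e-12, fitted, fallback)
    ratio = counts / fitted
    for b, r in zip(bins, ratio):
        b.copy_number = baseline_ploidy * float(r)
    eps = 1e-6
    return np.log2(np.maximum(ratio, eps))


# ---------------------------------------------------------------------------
# segmentation (circular binary segmentation)
# ---------------------------------------------------------------------------

def smooth_outliers(x: np.ndarray, window: int = 5, n_mad: float = 3.0) -> np.ndarray:
    """Shrink single-point outliers toward their neighbourhood median
    (window of ``window`` bins, clipped at ``n_mad`` median absolute
    deviations of the neighbourhood)."""
    x = np.asarray(x, dtype=float)
    out = x.copy()
    half = window // 2
    n = len(x)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        nb = np.delete(x[lo:hi], i - lo)
        if len(nb) < 2:
            continue
        med = np.median(nb)
        mad = np.median(np.abs(nb - med))
        if abs(x[i] - med) > n_mad * max(mad, 1e-9):
            out[i] = med
    return out


def _max_arc_stat(x: np.ndarray, min_width: int = 1) -> tuple[float, int, int]:
    """Max over arcs [i, j) of the two-sample t-like statistic comparing
    the arc mean with the complement mean."""
    n = len(x)
    s = np.concatenate([[0.0], np.cumsum(x)])
    total = s[-1]
    sd = x.std()
    if sd < 1e-12 or n < 2 * min_width:
        return 0.0, 0, n
    best, bi, bj = 0.0, 0, n
    for i in range(n):
        lens = np.arange(1, n - i + 1)
        arc = s[i + 1 : n + 1] - s[i]
        k = lens
        m = n - k
        valid = (k >= min_width) & (m >= min_width)
        if not valid.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(arc / k - (total - arc) / m) / (sd * np.sqrt(1.0 / k + 1.0 / m))
        t = np.where(valid, t, 0.0)
        j = int(np.argmax(t))
        if t[j] > best:
            best, bi, bj = float(t[j]), i, i + j + 1
    return best, bi, bj


def _cbs_pvalue(
    x: np.ndarray,
    observed: float,
    nperm: int,
    rng: np.random.Generator,
    alpha: float,
    min_width: int,
) -> float:
    # sequential early stop: once enough permutations beat the observed
    # statistic the p-value cannot fall back below alpha
    limit = alpha * (nperm + 1)
    hits = 0
    y = x.copy()
    for done in range(nperm):
        rng.shuffle(y)
        t, _, _ = _max_arc_stat(y, min_width=min_width)
        if t >= observed:
            hits += 1
            if hits >= limit:
                return (hits + 1) / (done + 2)
    return (hits + 1) / (nperm + 1)


def _cbs_recurse(x, offset, alpha, nperm, rng, breaks, min_width=2):
    n = len(x)
    if n < 2 * min_width:
        return
    t, i, j = _max_arc_stat(x, min_width=min_width)
    if t == 0.0:
        return
    p = _cbs_pvalue(x, t, nperm, rng, alpha, min_width)
    if p > alpha:
        return
    cuts = sorted({c for c in (i, j) if 0 < c < n})
    if not cuts:
        return
    for c in cuts:
        breaks.add(offset + c)
    bounds = [0, *cuts, n]
    for a, b in zip(bounds, bounds[1:]):
        _cbs_recurse(x[a:b], offset + a, alpha, nperm, rng, breaks, min_width)


def segment(
    bins: list[CNVBin],
    log2_track: np.ndarray,
    alpha: float = 0.01,
    nperm: int = 1000,
    seed: int = 0,
    smooth: bool = True,
) -> list[CNVSegment]:
    """CBS change-point detection per chromosome on the log2 ratio track.

    Single-point outliers are smoothed first; change-points are accepted
    at permutation p-value <= ``alpha`` (``nperm`` permutations, seeded).
    Segment means are means of the member bins' copy numbers.
    """
    rng = np.random.default_rng(seed)
    segments: list[CNVSegment] = []
    chrom_order = list(dict.fromkeys(b.chrom for b in bins))
    for chrom in chrom_order:
        idx = [i for i, b in enumerate(bins) if b.chrom == chrom]
        x = np.asarray(log2_track, dtype=float)[idx]
        if smooth:
            x = smooth_outliers(x)
        breaks: set[int] = set()
        _cbs_recurse(x, 0, alpha, nperm, rng, breaks)
        bounds = [0, *sorted(breaks), len(idx)]
        for a, b in zip(bounds, bounds[1:]):
            members = [bins[i] for i in idx[a:b]]
            segments.append(
                CNVSegment(
                    chrom=chrom,
                    start=members[0].start,
                    end=members[-1].end,
                    mean_copy_number=float(np.mean([m.copy_number for m in members])),
                )
            )
    return segments


def call_cnv(
    segments: list[CNVSegment],
    gain_thr: float = 2.6,
    loss_thr: float = 1.4,
    min_len: int = 500_000,
) -> list[CNVSegment]:
    """Label segments: gain when mean copy number > ``gain_thr``, loss
    when < ``loss_thr``; gain/loss calls not longer than ``min_len`` are
    reset to neutral."""
    for s in segments:
        if s.mean_copy_number > gain_thr:
            s.call = "gain"
        elif s.mean_copy_number < loss_thr:
            s.call = "loss"
        else:
            s.call = "neutral"
        if s.call != "neutral" and s.length <= min_len:
            s.call = "neutral"
    return segments


def run_cnv(
    chains: list[FragmentChain],
    genome: dict[str, str],
    gaps=None,
    bin_size: int = 500_000,
    gain_thr: float = 2.6,
    loss_thr: float = 1.4,
    min_len: int = 500_000,
    seed: int = 0,
    alpha: float = 0.01,
    nperm: int = 1000,
    lowess_frac: float = 0.3,
) -> tuple[list[CNVBin], list[CNVSegment]]:
    """Binning -> counting -> GC correction -> CBS -> gain/loss calls."""
    bins = make_bins(genome, gaps=gaps, bin_size=bin_size)
    count_reads(chains, bins)
    track = gc_correct(bins, frac=lowess_frac)
    segs = segment(bins, track, alpha=alpha, nperm=nperm, seed=seed)
    call_cnv(segs, gain_thr=gain_thr, loss_thr=loss_thr, min_len=min_len)
    return bins, segs
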