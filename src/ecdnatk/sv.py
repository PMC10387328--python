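"""Structural-variant filtering, cross-cell merging and transcript validation.

SV calls (Sniffles dialect) are reduced to the three classes amenable to
pairwise transcriptome analysis — deletions, insertions, translocations —
filtered on length, PRECISE quality and read support, and merged across
cells when both breakpoints agree within 500 bp (strict inequalities).
For each merged deletion or insertion a small variant reference is built
from the genome and unmapped RNA reads are locally realigned against it
to test whether the variant allele is transcribed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .model import MergedSV, SVRecord

DEL_RANGE = (100, 100_000)
INS_RANGE = (100, 2_500)


# ---------------------------------------------------------------------------
# filtering and merging
# ---------------------------------------------------------------------------

def filter_svs(
    records: list[SVRecord],
    min_support: int = 3,
    del_range: tuple[int, int] = DEL_RANGE,
    ins_range: tuple[int, int] = INS_RANGE,
) -> list[SVRecord]:
    """Keep PRECISE DEL/INS/TRA calls with >= ``min_support`` reads;
    deletions within [100 bp, 100 kb] and insertions within [100 bp, 2.5 kb].
    Idempotent and order-preserving."""
    kept = []
    for r in records:
        if r.sv_type not in ("DEL", "INS", "TRA"):
            continue
        if r.quality_flag != "PRECISE":
            continue
        if r.n_support_reads < min_support:
            continue
        if r.sv_type == "DEL" and not del_range[0] <= r.length <= del_range[1]:
            continue
        if r.sv_type == "INS" and not ins_range[0] <= r.length <= ins_range[1]:
            continue
        kept.append(r)
    return kept


def _same_event(a: SVRecord, b: SVRecord, tol: int) -> bool:
    """The published merge rule with strict bounds:
    (iA - tol) < iB < (iA + tol) and (jA - tol) < jB < (jA + tol)."""
    return (
        a.sv_type == b.sv_type
        and a.chrom1 == b.chrom1
        and a.chrom2 == b.chrom2
        and abs(a.pos1 - b.pos1) < tol
        and abs(a.pos2 - b.pos2) < tol
    )


def merge_svs(records: list[SVRecord], tol: int = 500) -> list[MergedSV]:
    """Single-linkage clustering of same-type, same-chromosome records
    under the strict +/- ``tol`` breakpoint rule.  Output order and
    membership are invariant to input order; the representative is the
    first member in (chrom, pos) order."""
    order = sorted(
        range(len(records)),
        key=lambda i: (
            records[i].sv_type,
            records[i].chrom1,
            records[i].chrom2,
            records[i].pos1,
            records[i].pos2,
            records[i].cell_id,
        ),
    )
    recs = [records[i] for i in order]
    parent = list(range(len(recs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            if _same_event(recs[i], recs[j], tol):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[SVRecord]] = {}
    for i in range(len(recs)):
        groups.setdefault(find(i), []).append(recs[i])
    merged = [MergedSV(members=m, representative=m[0]) for _, m in sorted(groups.items())]
    return merged


# ---------------------------------------------------------------------------
# variant-reference construction
# ---------------------------------------------------------------------------

@dataclass
class VariantReference:
    """A local reference around one merged SV, used for RNA realignment.

    For a deletion the sequence splices the two flanks and
    ``junction_offset`` marks the splice point.  For an insertion the
    inserted sequence(s) sit between the flanks and ``inserted_region``
    is their half-open interval on the reference.
    """

    sv: MergedSV
    name: str
    sequence: str
    junction_offset: int | None = None
    inserted_region: tuple[int, int] | None = None
    supporting_reads: list[str] = field(default_factory=list)
    supporting_cells: set[str] = field(default_factory=set)


def _chrom_seq(genome, chrom: str) -> str:
    seq = genome[chrom]
    return seq if isinstance(seq, str) else str(seq[:].seq)


def build_deletion_reference(
    sv: MergedSV, genome: dict[str, str], flank: int = 500, name: str | None = None
) -> VariantReference:
    """Splice ``flank`` bases upstream of the first breakpoint to ``flank``
    bases downstream of the second; the junction offset is the length of
    the (possibly clipped) upstream flank."""
    rep = sv.representative
    seq = _chrom_seq(genome, rep.chrom1)
    up_start = max(0, rep.pos1 - flank)
    upstream = seq[up_start : rep.pos1]
    downstream = seq[rep.pos2 : rep.pos2 + flank]
    ref = upstream + downstream
    if len(ref) < 100:
        raise ValueError("variant reference shorter than 100 bp")
    return VariantReference(
        sv=sv,
        name=name or f"DEL_{rep.chrom1}_{rep.pos1}_{rep.pos2}",
        sequence=ref,
        junction_offset=len(upstream),
    )


def build_insertion_reference(
    sv: MergedSV, genome: dict[str, str], flank: int = 500, name: str | None = None
) -> VariantReference:
    """Insert the member insertion sequences (concatenated in member
    order) between the two flanks of the insertion site."""
    rep = sv.representative
    inserted = "".join(m.inserted_seq for m in sv.members if m.inserted_seq)
    if not inserted:
        raise ValueError("insertion record without inserted sequence")
    seq = _chrom_seq(genome, rep.chrom1)
    up_start = max(0, rep.pos1 - flank)
    upstream = seq[up_start : rep.pos1]
    downstream = seq[rep.pos1 : rep.pos1 + flank]
    ref = upstream + inserted + downstream
    if len(ref) < 100:
        raise ValueError("variant reference shorter than 100 bp")
    off = len(upstream)
    return VariantReference(
        sv=sv,
        name=name or f"INS_{rep.chrom1}_{rep.pos1}",
        sequence=ref,
        inserted_region=(off, off + len(inserted)),
    )


def build_variant_references(
    merged: list[MergedSV], genome: dict[str, str], flank: int = 500
) -> list[VariantReference]:
    """Variant references for all mergeable DEL/INS events (TRA events are
    reported but never transcript-tested)."""
    refs = []
    for sv in merged:
        if sv.sv_type == "DEL":
            refs.append(build_deletion_reference(sv, genome, flank))
        elif sv.sv_type == "INS":
            refs.append(build_insertion_reference(sv, genome, flank))
    return refs


# ---------------------------------------------------------------------------
# RNA read realignment
# ---------------------------------------------------------------------------

def _make_aligner(match=2, mismatch=-4, gap_open=-6, gap_extend=-1) -> Align.PairwiseAligner:
    return Align.PairwiseAligner(
        mode="local",
        match_score=match,
        mismatch_score=mismatch,
        open_gap_score=gap_open,
        extend_gap_score=gap_extend,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def _target_blocks(alignment) -> list[tuple[int, int]]:
    return [(int(s), int(e)) for s, e in alignment.aligned[0]]


def _supports(ref: VariantReference, blocks, min_mapped: int, min_side: int) -> bool:
    if ref.inserted_region is not None:
        lo, hi = ref.inserted_region
        inside = sum(max(0, min(e, hi) - max(s, lo)) for s, e in blocks)
        return inside >= min_mapped
    off = ref.junction_offset
    left = sum(max(0, min(e, off) - s) for s, e in blocks)
    right = sum(max(0, e - max(s, off)) for s, e in blocks)
    return left >= min_side and right >= min_side and left + right >= min_mapped


def validate_transcribed(
    rna_reads: list[tuple[str, str, str]],
    variant_refs: list[VariantReference],
    min_mapped: int = 100,
    min_side: int = 20,
    min_cells_del: int = 3,
    min_cells_ins: int = 3,
    scores: tuple[int, int, int, int] = (2, -4, -6, -1),
    seed_k: int | None = 15,
) -> dict[str, dict]:
    """Locally realign RNA reads ``(read_id, cell_id, sequence)`` (both
    orientations) to every variant reference.

    An insertion is supported by a read whose alignment covers at least
    ``min_mapped`` bases inside the inserted region; a deletion by a read
    crossing the splice junction with >= ``min_side`` aligned bases on each
    side and >= ``min_mapped`` in total.  An SV is transcribed when at
    least one read supports it; the ``reported`` flag additionally asks
    for the minimum number of distinct supporting cells.

    ``seed_k`` enables an exact k-mer prescreen: the dynamic-programming
    aligner only runs when read and reference share at least one k-mer
    (either orientation).  A read that can satisfy the >= ``min_mapped``
    aligned-base rule at long-read error rates shares such a seed with
    near certainty, while unrelated transcripts are skipped cheaply.
    Pass ``seed_k=None`` to align every pair unconditionally.
    """
    for ref in variant_refs:
        if len(ref.sequence) < 100:
            raise ValueError(f"variant reference {ref.name} shorter than 100 bp")
    aligner = _make_aligner(*scores)
    for ref in variant_refs:
        ref.supporting_reads = []
        ref.supporting_cells = set()
    ref_kmers = None
    if seed_k is not None:
        ref_kmers = [
            {ref.sequence[i : i + seed_k] for i in range(len(ref.sequence) - seed_k + 1)}
            for ref in variant_refs
        ]
    for read_id, cell_id, seq in rna_reads:
        read_kmers = None
        if seed_k is not None:
            read_kmers = {seq[i : i + seed_k] for i in range(len(seq) - seed_k + 1)}
            read_kmers |= {
                _revcomp(seq)[i : i + seed_k] for i in range(len(seq) - seed_k + 1)
            }
        for ref_idx, ref in enumerate(variant_refs):
            if read_kmers is not None and read_kmers.isdisjoint(ref_kmers[ref_idx]):
                continue
            hit = False
            for query in (seq, _revcomp(seq)):
                alns = aligner.align(ref.sequence, query)
                if len(alns) == 0:
                    continue
                if _supports(ref, _target_blocks(alns[0]), min_mapped, min_side):
                    hit = True
                    break
            if hit:
                ref.supporting_reads.append(read_id)
                ref.supporting_cells.add(cell_id)
    out = {}
    for ref in variant_refs:
        min_cells = min_cells_del if ref.junction_offset is not None else min_cells_ins
        out[ref.name] = {
            "sv_type": ref.sv.sv_type,
            "transcribed": len(ref.supporting_reads) >= 1,
            "n_supporting_reads": len(ref.supporting_reads),
            "n_supporting_cells": len(ref.supporting_cells),
            "reported": len(ref.supporting_cells) >= min_cells,
        }
    return out
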