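"""Domain types shared across the toolkit.

Coordinate convention: every in-memory interval is 0-based half-open,
both in read space and in genome space.  Conversion to 1-based inclusive
happens only at format boundaries (GTF/VCF in, report TSV out); BED and
BEDPE stay 0-based.  Read-space coordinates are always expressed on the
original read orientation (i.e. after undoing the reverse-complement a
minus-strand SAM record applies).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable


@dataclass(frozen=True)
class AlignedInterval:
    """One mapped segment of one read.

    ``read_start``/``read_end`` locate the segment on the original read;
    ``ref_start``/``ref_end`` locate it on the reference.  ``strand`` is the
    mapping orientation of this segment.
    """

    read_id: str
    cell_id: str
    read_start: int
    read_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str  # '+' or '-'
    mapq: int = 60
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        if self.read_end <= self.read_start:
            raise ValueError(f"empty read interval on {self.read_id}")
        if self.ref_end <= self.ref_start:
            raise ValueError(f"empty reference interval on {self.read_id}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def read_length(self) -> int:
        return self.read_end - self.read_start

    @property
    def ref_length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class FragmentChain:
    """All kept alignment segments of one read, ordered along the read."""

    read_id: str
    cell_id: str
    intervals: list[AlignedInterval]

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv.read_start)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


@dataclass(frozen=True)
class Junction:
    """An oriented adjacency between two consecutive mapped segments.

    Endpoints are canonically ordered so that (chrom_a, pos_a) <=
    (chrom_b, pos_b).  ``orient_*`` records which side of the genomic
    fragment abuts the break: ``tail`` = the ref_end side, ``head`` = the
    ref_start side.  ``kind`` is ``circular`` when the two segments lie on
    the same chromosome and strand with the downstream-in-read segment
    mapping upstream in the genome (the split-read signature of a
    circularization junction), otherwise ``linear``.
    """

    chrom_a: str
    pos_a: int
    orient_a: str  # 'head' | 'tail'
    chrom_b: str
    pos_b: int
    orient_b: str
    read_id: str
    cell_id: str
    kind: str  # 'circular' | 'linear'


@dataclass(frozen=True)
class SupportRead:
    """Evidence record used for PCR-duplicate-aware support counting.

    ``outer_start``/``outer_end`` are the genomic coordinates of the two
    molecule ends (the read-start side of the first segment and the
    read-end side of the last segment): PCR duplicates of one molecule
    share these up to a few bases, while independent molecules do not.
    """

    read_id: str
    cell_id: str
    head_pos: int
    tail_pos: int
    outer_start: int
    outer_end: int


@dataclass
class CircleCandidate:
    """A putative circular element from one cell's breakpoint graph."""

    fragments: list[tuple[str, int, int, str]]  # (chrom, start, end, strand)
    cyclization_site: tuple[str, int, int]  # (chrom, head_pos, tail_pos)
    support_reads: list[SupportRead]
    cell_id: str = ""

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    @property
    def total_span(self) -> int:
        return sum(e - s for _, s, e, _ in self.fragments)


@dataclass
class ConsensusEcDNA:
    """A cross-cell merged ecDNA with per-cell quantification."""

    id: str
    fragments: list[tuple[str, int, int, str]]
    cyclization_site: tuple[str, int, int]
    per_cell_support: dict[str, int] = field(default_factory=dict)
    per_cell_coverage: dict[str, float] = field(default_factory=dict)
    support_reads: list[SupportRead] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    cancer_genes: list[str] = field(default_factory=list)

    @property
    def ecdna_type(self) -> int:
        """Number of genomic fragments composing the circle."""
        return len(self.fragments)

    @property
    def total_support(self) -> int:
        return sum(self.per_cell_support.values())

    @property
    def circle_length(self) -> int:
        return sum(e - s for _, s, e, _ in self.fragments)


@dataclass(frozen=True)
class SVRecord:
    """A structural variant call (Sniffles dialect).

    ``pos1``/``pos2`` are the two breakpoints (iA and jA); for DEL/INS both
    lie on ``chrom1``.  ``quality_flag`` is PRECISE or IMPRECISE.
    """

    sv_type: str  # DEL INS DUP INV INVDUP TRA
    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    length: int
    quality_flag: str
    n_support_reads: int
    cell_id: str = ""
    inserted_seq: str = ""

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("SV length must be >= 0")
        if self.sv_type in ("DEL", "INS") and self.chrom1 != self.chrom2:
            raise ValueError(f"{self.sv_type} must be intra-chromosomal")


@dataclass
class MergedSV:
    """Cross-cell merged SV event."""

    members: list[SVRecord]
    representative: SVRecord

    @property
    def sv_type(self) -> str:
        return self.representative.sv_type

    @property
    def supporting_cells(self) -> int:
        return len({m.cell_id for m in self.members})


@dataclass
class CNVBin:
    """A genomic bin with raw count, GC fraction and corrected copy number."""

    chrom: str
    start: int
    end: int
    raw_count: float = 0.0
    gc_fraction: float = 0.0
    copy_number: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction outside [0,1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CNVSegment:
    chrom: str
    start: int
    end: int
    mean_copy_number: float
    call: str = "neutral"  # gain | loss | neutral

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A gene span with name and strand (internal 0-based half-open)."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class CircleSpec:
    """Simulation blueprint for a genomic circle."""

    label: str
    fragments: list[tuple[str, int, int, str]]
    copies_per_cell: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, s, e, _ in self.fragments:
            if e - s < 1000:
                raise ValueError("circle fragments must be >= 1 kb")
        for c in self.copies_per_cell.values():
            if c < 0:
                raise ValueError("copies must be >= 0")

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e, _ in self.fragments)


@dataclass
class PlasmidSpec:
    """Simulation blueprint for a spiked-in circular plasmid.

    The plasmid reference is its sequence linearized at the cyclization
    site, so junction-crossing reads map as split alignments joining the
    reference end back to its start.
    """

    label: str
    sequence: str
    copies: int

    def __post_init__(self) -> None:
        if not 3300 <= len(self.sequence) <= 27300:
            raise ValueError("plasmid length outside [3300, 27300] bp")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def cyclization_site(self) -> int:
        # midpoint of the (fully unique) sequence on the original circle;
        # on the linear reference the junction joins position length -> 0.
        return self.length // 2


_CONFIG_FIELDS = dict(
    min_interval=100,
    duplic_tol=500,
    duplic_max_len=1000,
    cluster_tol=500,
    repeat_flank=300,
    repeat_min_ovl=30,
    sv_dist=500,
    min_support=3,
    dedup_tol=10,
    merge_tol=500,
    gene_min_ovl=30,
    bin_size=500_000,
    bin_min_overlap=10,
    gain_thr=2.6,
    loss_thr=1.4,
    cnv_min_len=500_000,
    lowess_frac=0.3,
    cbs_alpha=0.01,
    cbs_nperm=1000,
    sv_merge_tol=500,
    sv_min_support=3,
    rna_min_mapped=100,
    rna_min_side=20,
    min_cells_del=3,
    min_cells_ins=3,
    seed=0,
)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their defaults."""

    min_interval: int = 100
    duplic_tol: int = 500
    duplic_max_len: int = 1000
    cluster_tol: int = 500
    repeat_flank: int = 300
    repeat_min_ovl: int = 30
    sv_dist: int = 500
    min_support: int = 3
    dedup_tol: int = 10
    merge_tol: int = 500
    gene_min_ovl: int = 30
    bin_size: int = 500_000
    bin_min_overlap: int = 10
    gain_thr: float = 2.6
    loss_thr: float = 1.4
    cnv_min_len: int = 500_000
    lowess_frac: float = 0.3
    cbs_alpha: float = 0.01
    cbs_nperm: int = 1000
    sv_merge_tol: int = 500
    sv_min_support: int = 3
    rna_min_mapped: int = 100
    rna_min_side: int = 20
    min_cells_del: int = 3
    min_cells_ins: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in _CONFIG_FIELDS:
            v = getattr(self, name)
            if name != "seed" and v <= 0:
                raise ValueError(f"config field {name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in _CONFIG_FIELDS}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Length of the overlap of two half-open intervals (0 if disjoint)."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def group_by_cell(chains: Iterable[FragmentChain]) -> dict[str, list[FragmentChain]]:
    out: dict[str, list[FragmentChain]] = {}
    for c in chains:
        out.setdefault(c.cell_id, []).append(c)
    return out
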