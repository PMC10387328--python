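"""Circle detection from split long-read alignments.

The caller proceeds in stages: per-read fragment-chain refinement,
conversion of adjacent segments into breakpoints, breakpoint clustering,
breakpoint-graph cycle detection, candidate filtering against tandem
repeats and SV breakpoints, cross-cell consensus merging, duplicate-aware
support quantification and gene annotation.

A circularization junction is the split-read signature in which the
downstream-in-read segment maps *upstream* in the genome on the same
chromosome and strand: sequencing through the joint of a circular
molecule produces exactly this reversal of genomic order along the read.
Circular junctions are canonicalized to the + strand (a circle read on
either strand is evidence for the same junction).
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass, field

import networkx as nx

from .model import (
    AlignedInterval,
    CircleCandidate,
    ConsensusEcDNA,
    FragmentChain,
    GeneModel,
    Junction,
    SupportRead,
    overlap_len,
)

MAX_CYCLE_FRAGMENTS = 10


# ---------------------------------------------------------------------------
# chain refinement
# ---------------------------------------------------------------------------

def refine_chain(
    chain: FragmentChain,
    min_interval: int = 100,
    duplic_tol: int = 500,
    duplic_max_len: int = 1000,
) -> FragmentChain:
    """Clean a fragment chain before junction extraction.

    Three rules, re-applied until a fixed point:

    1. drop segments shorter than ``min_interval`` bases in read space
       (low-quality split alignments);
    2. merge a segment whose read interval is completely contained in an
       adjacent segment's read interval into that neighbour (redundant
       split alignments of the same read bases).  Containment is judged
       in read space, not genomic space: a read that traverses a small
       circle more than once legitimately maps the same genomic interval
       at different read offsets, and that multi-pass evidence must
       survive refinement;
    3. of two adjacent segments whose genomic start and end each differ
       by less than ``duplic_tol``, keep only the longer one — but only
       when the removed copy is shorter than ``duplic_max_len`` in read
       space.  Longer near-identical repeats are genuine multi-pass
       evidence of a small circle and are retained.
    """
    ivals = list(chain.intervals)
    changed = True
    while changed:
        changed = False
        # rule 1: short intervals
        kept = [iv for iv in ivals if iv.read_length >= min_interval]
        if len(kept) != len(ivals):
            ivals, changed = kept, True
            continue
        # rule 2: contained in an adjacent interval
        for i, iv in enumerate(ivals):
            for j in (i - 1, i + 1):
                if not 0 <= j < len(ivals):
                    continue
                nb = ivals[j]
                if nb.read_start <= iv.read_start and iv.read_end <= nb.read_end:
                    ivals = [v for k, v in enumerate(ivals) if k != i]
                    changed = True
                    break
            if changed:
                break
        if changed:
            continue
        # rule 3: near-duplicate adjacent pair
        for i in range(len(ivals) - 1):
            a, b = ivals[i], ivals[i + 1]
            if (
                a.chrom == b.chrom
                and abs(a.ref_start - b.ref_start) < duplic_tol
                and abs(a.ref_end - b.ref_end) < duplic_tol
            ):
                drop = a if a.read_length <= b.read_length else b
                if drop.read_length < duplic_max_len:
                    ivals = [v for v in ivals if v is not drop]
                    changed = True
                    break
    return FragmentChain(read_id=chain.read_id, cell_id=chain.cell_id, intervals=ivals)


# ---------------------------------------------------------------------------
# junctions
# ---------------------------------------------------------------------------

def _is_circular_pair(a: AlignedInterval, b: AlignedInterval) -> bool:
    """True when read-adjacent segments reverse genomic order (circle signature).

    Equal starts count as circular: a linear continuation always begins at
    or beyond the previous fragment's genomic end, so a fragment restarting
    at the same coordinate (a full pass followed by another pass of the
    same circle) is wrap evidence, not colinearity.
    """
    if a.chrom != b.chrom or a.strand != b.strand:
        return False
    if a.strand == "+":
        return b.ref_start <= a.ref_start
    return b.ref_start >= a.ref_start


def chain_to_junctions(chain: FragmentChain) -> list[Junction]:
    """One junction per adjacent segment pair of a refined chain.

    Circular junctions are emitted canonically on the + strand: head at
    the genomically upstream coordinate, tail at the downstream one.
    """
    out: list[Junction] = []
    for a, b in zip(chain.intervals, chain.intervals[1:]):
        if _is_circular_pair(a, b):
            if a.strand == "+":
                head, tail = b.ref_start, a.ref_end
            else:
                head, tail = a.ref_start, b.ref_end
            out.append(
                Junction(
                    chrom_a=a.chrom, pos_a=head, orient_a="head",
                    chrom_b=a.chrom, pos_b=tail, orient_b="tail",
                    read_id=chain.read_id, cell_id=chain.cell_id, kind="circular",
                )
            )
            continue
        # endpoint abutting the break on each side
        pa = a.ref_end if a.strand == "+" else a.ref_start
        oa = "tail" if a.strand == "+" else "head"
        pb = b.ref_start if b.strand == "+" else b.ref_end
        ob = "head" if b.strand == "+" else "tail"
        ea = (a.chrom, pa, oa)
        eb = (b.chrom, pb, ob)
        if (eb[0], eb[1]) < (ea[0], ea[1]):
            ea, eb = eb, ea
        out.append(
            Junction(
                chrom_a=ea[0], pos_a=ea[1], orient_a=ea[2],
                chrom_b=eb[0], pos_b=eb[1], orient_b=eb[2],
                read_id=chain.read_id, cell_id=chain.cell_id, kind="linear",
            )
        )
    return out


# ---------------------------------------------------------------------------
# breakpoint clustering
# ---------------------------------------------------------------------------

@dataclass
class BreakpointCluster:
    """A group of nearby junction endpoints of the same kind."""

    id: int
    chrom: str
    orientation: str  # 'head' | 'tail'
    positions: list[int] = field(default_factory=list)
    members: list[tuple[int, str]] = field(default_factory=list)  # (junction idx, side)
    link: int | None = None  # nearest-neighbour cluster on the same chromosome

    @property
    def position(self) -> int:
        """Representative = lower median of member positions."""
        return int(statistics.median_low(self.positions))

    @property
    def span(self) -> int:
        return max(self.positions) - min(self.positions)


def cluster_breakpoints(junctions: list[Junction], tol: int = 500) -> list[BreakpointCluster]:
    """Group junction endpoints on the same chromosome and orientation
    whose distance to the cluster representative is strictly below ``tol``,
    then link each cluster to its nearest neighbour on the same chromosome
    (ties broken toward the smaller coordinate).
    """
    endpoints: list[tuple[str, str, int, int, str]] = []
    for idx, j in enumerate(junctions):
        endpoints.append((j.chrom_a, j.orient_a, j.pos_a, idx, "a"))
        endpoints.append((j.chrom_b, j.orient_b, j.pos_b, idx, "b"))
    endpoints.sort(key=lambda e: (e[0], e[1], e[2], e[3]))

    clusters: list[BreakpointCluster] = []
    cur: BreakpointCluster | None = None
    for chrom, orient, pos, idx, side in endpoints:
        if (
            cur is None
            or cur.chrom != chrom
            or cur.orientation != orient
            or abs(pos - cur.position) >= tol
        ):
            cur = BreakpointCluster(id=len(clusters), chrom=chrom, orientation=orient)
            clusters.append(cur)
        cur.positions.append(pos)
        cur.members.append((idx, side))

    for c in clusters:
        best = None
        for other in clusters:
            if other.id == c.id or other.chrom != c.chrom:
                continue
            d = abs(other.position - c.position)
            key = (d, other.position)
            if best is None or key < best[0]:
                best = (key, other.id)
        c.link = best[1] if best else None
    return clusters


# ---------------------------------------------------------------------------
# circle detection
# ---------------------------------------------------------------------------

def _support_read(j: Junction, chains_by_read: dict[str, FragmentChain] | None,
                  head: int, tail: int) -> SupportRead:
    outer_start, outer_end = j.pos_a, j.pos_b
    if chains_by_read and j.read_id in chains_by_read:
        ch = chains_by_read[j.read_id]
        first, last = ch.intervals[0], ch.intervals[-1]
        outer_start = first.ref_start if first.strand == "+" else first.ref_end
        outer_end = last.ref_end if last.strand == "+" else last.ref_start
    return SupportRead(
        read_id=j.read_id, cell_id=j.cell_id,
        head_pos=head, tail_pos=tail,
        outer_start=outer_start, outer_end=outer_end,
    )


def detect_circles(
    clusters: list[BreakpointCluster],
    junctions: list[Junction],
    chains: list[FragmentChain] | None = None,
) -> list[CircleCandidate]:
    """Extract circle candidates from the breakpoint graph.

    Graph nodes are breakpoint clusters; junction edges are read-evidenced
    adjacencies and fragment edges are the genomic segments between a
    cluster and its nearest linked neighbour.  A circular junction whose
    endpoints bound one genomic interval yields a single-fragment
    (self-cyclization) candidate; longer alternating junction/fragment
    cycles (up to :data:`MAX_CYCLE_FRAGMENTS` fragments) yield
    multi-fragment candidates.
    """
    chains_by_read = {c.read_id: c for c in chains} if chains else None
    cluster_of: dict[tuple[int, str], BreakpointCluster] = {}
    for c in clusters:
        for m in c.members:
            cluster_of[m] = c

    candidates: list[CircleCandidate] = []

    # single-fragment self-cyclizations
    by_pair: dict[tuple[int, int], list[Junction]] = {}
    for idx, j in enumerate(junctions):
        if j.kind != "circular":
            continue
        ch = cluster_of[(idx, "a")]
        ct = cluster_of[(idx, "b")]
        by_pair.setdefault((ch.id, ct.id), []).append(j)
    cl = {c.id: c for c in clusters}
    for (hid, tid), js in sorted(by_pair.items()):
        head, tail = cl[hid].position, cl[tid].position
        if tail <= head:
            continue
        chrom = cl[hid].chrom
        candidates.append(
            CircleCandidate(
                fragments=[(chrom, head, tail, "+")],
                cyclization_site=(chrom, head, tail),
                support_reads=[_support_read(j, chains_by_read, head, tail) for j in js],
                cell_id=js[0].cell_id,
            )
        )

    # multi-fragment cycles on the breakpoint graph
    g = nx.Graph()
    junc_edges: dict[frozenset, list[Junction]] = {}
    for idx, j in enumerate(junctions):
        a, b = cluster_of[(idx, "a")].id, cluster_of[(idx, "b")].id
        if a == b:
            continue
        junc_edges.setdefault(frozenset((a, b)), []).append(j)
    for key in junc_edges:
        a, b = tuple(key)
        g.add_edge(a, b)
        g.edges[a, b].setdefault("types", set()).add("junction")
    for c in clusters:
        if c.link is not None and cl[c.link].chrom == c.chrom:
            g.add_edge(c.id, c.link)
            g.edges[c.id, c.link].setdefault("types", set()).add("fragment")

    seen_pairs = set(by_pair)
    for cycle in nx.simple_cycles(g, length_bound=2 * MAX_CYCLE_FRAGMENTS):
        if len(cycle) < 4 or len(cycle) % 2:
            continue
        edges = [(cycle[i], cycle[(i + 1) % len(cycle)]) for i in range(len(cycle))]
        for phase in (0, 1):
            want = ["junction" if (i + phase) % 2 == 0 else "fragment" for i in range(len(edges))]
            if all(w in g.edges[e]["types"] for e, w in zip(edges, want)):
                frag_edges = [e for e, w in zip(edges, want) if w == "fragment"]
                jn_edges = [e for e, w in zip(edges, want) if w == "junction"]
                reads = []
                for a, b in jn_edges:
                    reads.extend(junc_edges.get(frozenset((a, b)), []))
                if not reads:
                    continue
                chroms = {cl[n].chrom for n in cycle}
                if len(chroms) == 1 and not any(j.kind == "circular" for j in reads):
                    continue  # same-chromosome cycle needs direct circular evidence
                fragments = sorted(
                    (
                        cl[a].chrom,
                        min(cl[a].position, cl[b].position),
                        max(cl[a].position, cl[b].position),
                        "+",
                    )
                    for a, b in frag_edges
                )
                first, last = fragments[0], fragments[-1]
                site = (first[0], first[1], first[2])
                key = tuple(fragments)
                if key in seen_pairs:
                    break
                seen_pairs.add(key)
                candidates.append(
                    CircleCandidate(
                        fragments=fragments,
                        cyclization_site=site,
                        support_reads=[
                            _support_read(j, chains_by_read, site[1], site[2]) for j in reads
                        ],
                        cell_id=reads[0].cell_id,
                    )
                )
                break
    return candidates


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_repeats(
    candidates: list[CircleCandidate],
    repeats: dict[str, list[tuple[int, int]]],
    flank: int = 300,
    min_ovl: int = 30,
    inclusive: bool = True,
) -> list[CircleCandidate]:
    """Drop candidates whose cyclization-site flanks overlap a simple
    tandem repeat by at least ``min_ovl`` bases (strictly more when
    ``inclusive`` is False).

    The two flanks are the ``flank`` bases inside the circle on each side
    of the junction: [head, head+flank) and [tail-flank, tail).
    """
    kept = []
    for cand in candidates:
        chrom, head, tail = cand.cyclization_site
        flanks = [(head, head + flank), (tail - flank, tail)]
        bad = False
        for rs, re_ in repeats.get(chrom, []):
            ov = sum(overlap_len(rs, re_, fs, fe) for fs, fe in flanks)
            if (ov >= min_ovl) if inclusive else (ov > min_ovl):
                bad = True
                break
        if not bad:
            kept.append(cand)
    return kept


def filter_sv_proximity(candidates, svs, dist: int = 500) -> list[CircleCandidate]:
    """Drop candidates whose cyclization site lies within ``dist`` bp of
    any SV breakpoint on the same chromosome (the unfiltered SV set: SVs
    and tandem duplications generate chimeric reads that mimic circles).
    """
    bp: dict[str, list[int]] = {}
    for sv in svs:
        bp.setdefault(sv.chrom1, []).append(sv.pos1)
        bp.setdefault(sv.chrom2, []).append(sv.pos2)
    kept = []
    for cand in candidates:
        chrom, head, tail = cand.cyclization_site
        positions = bp.get(chrom, [])
        if any(abs(p - head) <= dist or abs(p - tail) <= dist for p in positions):
            continue
        kept.append(cand)
    return kept


def dedup_support(reads: list[SupportRead], tol: int = 10) -> list[SupportRead]:
    """Collapse PCR duplicates: within one cell, reads with identical
    junction coordinates whose molecule-end coordinates each lie within
    ``tol`` bases are counted once.
    """
    kept: list[SupportRead] = []
    for r in sorted(reads, key=lambda r: (r.cell_id, r.head_pos, r.tail_pos,
                                          r.outer_start, r.outer_end, r.read_id)):
        dup = any(
            k.cell_id == r.cell_id
            and k.head_pos == r.head_pos
            and k.tail_pos == r.tail_pos
            and abs(k.outer_start - r.outer_start) <= tol
            and abs(k.outer_end - r.outer_end) <= tol
            for k in kept
        )
        if not dup:
            kept.append(r)
    return kept


def filter_support(candidates, min_support: int = 3, dedup_tol: int = 10):
    """Keep candidates with at least ``min_support`` deduplicated reads.

    Works on per-cell candidates and on cross-cell consensus entries alike
    (support is pooled over whatever cells the reads came from).
    """
    kept = []
    for cand in candidates:
        if len(dedup_support(cand.support_reads, tol=dedup_tol)) >= min_support:
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# consensus merging and quantification
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_consensus(candidates: list[CircleCandidate], tol: int = 500) -> list[ConsensusEcDNA]:
    """Merge per-cell candidates whose cyclization sites agree within
    ``tol`` on both ends (single linkage).  The consensus geometry is
    taken from the member with the longest total fragment span; member
    support is pooled.
    """
    n = len(candidates)
    uf = _UnionFind(n)
    for i in range(n):
        ci = candidates[i].cyclization_site
        for j in range(i + 1, n):
            cj = candidates[j].cyclization_site
            if ci[0] == cj[0] and abs(ci[1] - cj[1]) < tol and abs(ci[2] - cj[2]) < tol:
                uf.union(i, j)
    groups: dict[int, list[CircleCandidate]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(candidates[i])

    merged = []
    for members in groups.values():
        rep = max(members, key=lambda c: (c.total_span, -c.cyclization_site[1]))
        reads = [r for m in members for r in m.support_reads]
        merged.append(
            ConsensusEcDNA(
                id="",
                fragments=list(rep.fragments),
                cyclization_site=rep.cyclization_site,
                support_reads=reads,
            )
        )
    merged.sort(key=lambda c: (c.cyclization_site[0], c.cyclization_site[1], c.cyclization_site[2]))
    for k, c in enumerate(merged, 1):
        c.id = f"ecDNA_{k:04d}"
    return merged


def quantify(
    consensus: list[ConsensusEcDNA],
    chains: list[FragmentChain],
    dedup_tol: int = 10,
) -> list[ConsensusEcDNA]:
    """Fill per-cell deduplicated spanning-read counts and fractional read
    coverage of each circle.  Idempotent.
    """
    chains_by_read = {c.read_id: c for c in chains}
    for ec in consensus:
        dedup = dedup_support(ec.support_reads, tol=dedup_tol)
        cells = sorted({r.cell_id for r in ec.support_reads})
        ec.per_cell_support = {
            cell: sum(1 for r in dedup if r.cell_id == cell) for cell in cells
        }
        total = ec.circle_length
        ec.per_cell_coverage = {}
        for cell in cells:
            covered = 0
            for chrom, fs, fe, _ in ec.fragments:
                segs = []
                for r in ec.support_reads:
                    if r.cell_id != cell or r.read_id not in chains_by_read:
                        continue
                    for iv in chains_by_read[r.read_id]:
                        if iv.chrom == chrom:
                            s = max(iv.ref_start, fs)
                            e = min(iv.ref_end, fe)
                            if e > s:
                                segs.append((s, e))
                segs.sort()
                cur_s = cur_e = None
                for s, e in segs:
                    if cur_e is None or s > cur_e:
                        if cur_e is not None:
                            covered += cur_e - cur_s
                        cur_s, cur_e = s, e
                    else:
                        cur_e = max(cur_e, e)
                if cur_e is not None:
                    covered += cur_e - cur_s
            ec.per_cell_coverage[cell] = covered / total if total else 0.0
    return consensus


def annotate_genes(
    consensus: list[ConsensusEcDNA],
    genes: list[GeneModel],
    min_ovl: int = 30,
    cancer_catalogue: list[str] | None = None,
) -> list[ConsensusEcDNA]:
    """Attach genes overlapping any circle fragment by >= ``min_ovl`` bases;
    genes found in the catalogue are additionally flagged as cancer genes."""
    catalogue = set(cancer_catalogue or [])
    for ec in consensus:
        hit = []
        for g in genes:
            ov = sum(
                overlap_len(g.start, g.end, fs, fe)
                for chrom, fs, fe, _ in ec.fragments
                if chrom == g.chrom
            )
            if ov >= min_ovl:
                hit.append(g.gene_name)
        ec.genes = sorted(set(hit))
        ec.cancer_genes = sorted(set(hit) & catalogue)
    return consensus


def compare_sets(
    set_a: list[ConsensusEcDNA],
    set_b: list[ConsensusEcDNA],
    frac: float = 0.1,
) -> dict[str, list]:
    """Reciprocal-overlap comparison of two ecDNA sets (strand-agnostic).

    Two entries match when their cyclization-site intervals overlap by at
    least ``frac`` of each interval's length.
    """
    def interval(e):
        c, h, t = e.cyclization_site
        return c, h, t

    shared, matched_b = [], set()
    for a in set_a:
        ca, sa, ea = interval(a)
        for bi, b in enumerate(set_b):
            cb, sb, eb = interval(b)
            if ca != cb:
                continue
            ov = overlap_len(sa, ea, sb, eb)
            if ov >= frac * (ea - sa) and ov >= frac * (eb - sb):
                shared.append((a, b))
                matched_b.add(bi)
    a_shared = {id(a) for a, _ in shared}
    return {
        "shared": shared,
        "a_only": [a for a in set_a if id(a) not in a_shared],
        "b_only": [b for bi, b in enumerate(set_b) if bi not in matched_b],
    }


def mtdna_copy_number(
    chains: list[FragmentChain],
    chrom_lengths: dict[str, int],
    mt_chrom: str = "chrM",
    sex_chroms: tuple[str, ...] = ("chrX", "chrY"),
) -> float:
    """Mitochondrial copies per cell: 2 x (mean chrM depth / mean autosomal
    depth), the diploid autosomal background serving as the 2-copy anchor."""
    if mt_chrom not in chrom_lengths:
        raise ValueError(f"{mt_chrom} absent from genome")
    bases = {chrom: 0 for chrom in chrom_lengths}
    for ch in chains:
        for iv in ch:
            if iv.chrom in bases:
                bases[iv.chrom] += iv.ref_length
    mt_depth = bases[mt_chrom] / chrom_lengths[mt_chrom]
    auto = [c for c in chrom_lengths if c != mt_chrom and c not in sex_chroms]
    auto_bases = sum(bases[c] for c in auto)
    auto_len = sum(chrom_lengths[c] for c in auto)
    if auto_bases == 0:
        raise ValueError("no autosomal coverage")
    return 2.0 * mt_depth / (auto_bases / auto_len)
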