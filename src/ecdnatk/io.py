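"""Readers and writers for the external formats the pipeline touches.

SAM/BAM parsing goes through pysam; VCF through pysam.VariantFile.  BED
input is 0-based half-open and stays so internally; GTF and VCF are
1-based and are shifted to the internal 0-based half-open convention on
the way in.  Report TSVs print genomic coordinates 1-based inclusive;
BED/BEDPE outputs stay 0-based half-open.
"""
from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterator

import pandas as pd
import pysam

from .model import (
    AlignedInterval,
    ConsensusEcDNA,
    CNVSegment,
    FragmentChain,
    GeneModel,
    SVRecord,
)

_CLIP_OPS = {4, 5}  # soft, hard


def _read_span(aln: pysam.AlignedSegment) -> tuple[int, int, int]:
    """(read_start, read_end, read_length) on the original read orientation."""
    cig = aln.cigartuples
    if not cig:
        raise ValueError(f"alignment without CIGAR: {aln.query_name}")
    lead = cig[0][1] if cig[0][0] in _CLIP_OPS else 0
    tail = cig[-1][1] if len(cig) > 1 and cig[-1][0] in _CLIP_OPS else 0
    aligned = sum(n for op, n in cig if op in (0, 1, 7, 8))  # M, I, =, X
    total = lead + aligned + tail
    if aln.is_reverse:
        return tail, tail + aligned, total
    return lead, lead + aligned, total


def iter_alignments(
    path: str | Path,
    cell_id: str | None = None,
    barcode_sep: str | None = None,
    min_mapq: int = 0,
) -> Iterator[FragmentChain]:
    """Yield one :class:`FragmentChain` per read from a SAM/BAM file.

    Secondary alignments are excluded; primary and supplementary records
    are kept and ordered by their position on the original read.  Cell
    identity comes either from ``cell_id`` (one file per cell, the default
    mode) or, when ``barcode_sep`` is given, from the read-name prefix
    before that separator.

    No MAPQ filter is applied by default; ``min_mapq`` makes one available.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"alignment file not found: {path}")
    by_read: dict[str, list[AlignedInterval]] = {}
    try:
        mode = "rb" if path.suffix == ".bam" else "r"
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
            for aln in fh.fetch(until_eof=True):
                if aln.is_unmapped or aln.is_secondary:
                    continue
                if aln.mapping_quality < min_mapq:
                    continue
                rs, re_, _ = _read_span(aln)
                name = aln.query_name
                if barcode_sep is not None:
                    cell = name.split(barcode_sep, 1)[0]
                else:
                    cell = cell_id if cell_id is not None else path.stem
                by_read.setdefault(name, []).append(
                    AlignedInterval(
                        read_id=name,
                        cell_id=cell,
                        read_start=rs,
                        read_end=re_,
                        chrom=aln.reference_name,
                        ref_start=aln.reference_start,
                        ref_end=aln.reference_end,
                        strand="-" if aln.is_reverse else "+",
                        mapq=aln.mapping_quality,
                        is_supplementary=aln.is_supplementary,
                    )
                )
    except (OSError, ValueError) as exc:
        raise RuntimeError(f"unreadable alignment file {path}: {exc}") from exc
    for name in sorted(by_read):
        ivals = by_read[name]
        yield FragmentChain(read_id=name, cell_id=ivals[0].cell_id, intervals=ivals)


def read_alignments(path, cell_id=None, barcode_sep=None, min_mapq=0) -> list[FragmentChain]:
    return list(iter_alignments(path, cell_id, barcode_sep, min_mapq))


def load_tandem_repeats(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Load a BED repeat track (UCSC simpleRepeat dialect; columns past 3 ignored).

    Returns chrom -> sorted list of 0-based half-open intervals.  An empty
    file is a valid, empty track.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                parts = line.split()
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line") from exc
            out.setdefault(chrom, []).append((start, end))
    for chrom in out:
        out[chrom].sort()
    return out


def load_sv_vcf(path: str | Path, cell_id: str = "") -> list[SVRecord]:
    """Load SV calls from a Sniffles-dialect VCF.

    Uses INFO keys SVTYPE, SVLEN, END, CHR2, RE and the PRECISE/IMPRECISE
    flags.  POS (1-based) becomes a 0-based breakpoint; for DEL the second
    breakpoint is INFO/END, for TRA it is CHR2:END, for INS both
    breakpoints coincide.
    """
    def info_get(info, key, default=None):
        # pysam raises rather than returning the default when the key is
        # not declared in the VCF header
        try:
            val = info.get(key, default)
        except (KeyError, ValueError):
            return default
        return default if val is None else val

    records: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            svtype = info_get(info, "SVTYPE")
            if svtype is None:
                continue
            svtype = str(svtype)
            pos1 = rec.pos - 1
            chrom2 = str(info_get(info, "CHR2", rec.chrom))
            end = info_get(info, "END", rec.stop)
            pos2 = int(end) - 1 if svtype != "INS" else pos1
            svlen = info_get(info, "SVLEN", 0)
            if isinstance(svlen, tuple):
                svlen = svlen[0]
            length = abs(int(svlen)) if svlen else (abs(pos2 - pos1) if svtype != "TRA" else 0)
            try:
                precise = "PRECISE" if "PRECISE" in info else "IMPRECISE"
            except (KeyError, ValueError):
                precise = "IMPRECISE"
            support = int(info_get(info, "RE", 0))
            inserted = ""
            if svtype == "INS" and rec.alts and re.fullmatch("[ACGTNacgtn]+", rec.alts[0] or ""):
                inserted = rec.alts[0].upper()
                if not length:
                    length = len(inserted)
            records.append(
                SVRecord(
                    sv_type=svtype,
                    chrom1=rec.chrom,
                    pos1=pos1,
                    chrom2=chrom2 if svtype == "TRA" else rec.chrom,
                    pos2=pos2,
                    length=length,
                    quality_flag=precise,
                    n_support_reads=support,
                    cell_id=cell_id,
                    inserted_seq=inserted,
                )
            )
    return records


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def load_gene_models(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Load gene spans from a GTF file (1-based inclusive -> 0-based half-open).

    Reads lines whose feature column matches ``feature`` and extracts the
    gene_id / gene_name attributes (gene_name falls back to gene_id).
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{lineno}: malformed GTF line")
            if parts[2] != feature:
                continue
            try:
                start = int(parts[3]) - 1
                end = int(parts[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad GTF coordinates") from exc
            attrs = dict(_GTF_ATTR.findall(parts[8]))
            gid = attrs.get("gene_id", f"gene_{lineno}")
            genes.append(
                GeneModel(
                    gene_id=gid,
                    gene_name=attrs.get("gene_name", gid),
                    chrom=parts[0],
                    start=start,
                    end=end,
                    strand=parts[6] if parts[6] in "+-" else "+",
                )
            )
    return genes


ECDNA_COLUMNS = [
    "id",
    "chrom",
    "head_pos",
    "tail_pos",
    "ecdna_type",
    "fragments",
    "total_support",
    "n_cells",
    "genes",
    "cancer_genes",
]


def _fragments_to_str(fragments) -> str:
    # 1-based inclusive in the report, e.g. chr1:101-200:+
    return ";".join(f"{c}:{s + 1}-{e}:{st}" for c, s, e, st in fragments)


def _fragments_from_str(s: str):
    out = []
    for tok in str(s).split(";"):
        chrom, span, strand = tok.rsplit(":", 2)
        a, b = span.split("-")
        out.append((chrom, int(a) - 1, int(b), strand))
    return out


def write_outputs(consensus: list[ConsensusEcDNA], out_dir: str | Path) -> dict[str, Path]:
    """Write the ecDNA table (TSV, 1-based inclusive), junction BEDPE,
    per-cell support matrix (TSV) and a JSON report; returns written paths.

    Rows are ordered deterministically by (chrom, head_pos, id).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise RuntimeError(f"cannot create output directory {out_dir}: {exc}") from exc
    order = sorted(consensus, key=lambda c: (c.cyclization_site[0], c.cyclization_site[1], c.id))
    rows = []
    for c in order:
        chrom, head, tail = c.cyclization_site
        rows.append(
            {
                "id": c.id,
                "chrom": chrom,
                "head_pos": head + 1,
                "tail_pos": tail,
                "ecdna_type": c.ecdna_type,
                "fragments": _fragments_to_str(c.fragments),
                "total_support": c.total_support,
                "n_cells": sum(1 for v in c.per_cell_support.values() if v > 0),
                "genes": ",".join(c.genes),
                "cancer_genes": ",".join(c.cancer_genes),
            }
        )
    table = pd.DataFrame(rows, columns=ECDNA_COLUMNS)
    paths = {"table": out_dir / "ecdna.tsv", "bedpe": out_dir / "junctions.bedpe",
             "matrix": out_dir / "support_matrix.tsv", "report": out_dir / "report.json"}
    table.to_csv(paths["table"], sep="\t", index=False)

    with open(paths["bedpe"], "w") as fh:
        for c in order:
            chrom, head, tail = c.cyclization_site
            fh.write(f"{chrom}\t{head}\t{head + 1}\t{chrom}\t{tail - 1}\t{tail}\t{c.id}\t{c.total_support}\n")

    cells = sorted({cell for c in consensus for cell in c.per_cell_support})
    mat_rows = []
    for c in order:
        mat_rows.append({"id": c.id, **{cell: c.per_cell_support.get(cell, 0) for cell in cells}})
    pd.DataFrame(mat_rows, columns=["id", *cells]).to_csv(paths["matrix"], sep="\t", index=False)

    report = {
        "n_ecdna": len(order),
        "n_cells": len(cells),
        "type_counts": {str(t): sum(1 for c in order if c.ecdna_type == t)
                        for t in sorted({c.ecdna_type for c in order})},
    }
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return paths


def read_ecdna_table(path: str | Path) -> list[ConsensusEcDNA]:
    """Read back an ecDNA table written by :func:`write_outputs`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        out.append(
            ConsensusEcDNA(
                id=row["id"],
                fragments=_fragments_from_str(row["fragments"]),
                cyclization_site=(row["chrom"], int(row["head_pos"]) - 1, int(row["tail_pos"])),
                genes=[g for g in str(row["genes"]).split(",") if g],
                cancer_genes=[g for g in str(row["cancer_genes"]).split(",") if g],
            )
        )
    return out


def write_segments_bed(segments: list[CNVSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sorted(segments, key=lambda s: (s.chrom, s.start)):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.call}\t{s.mean_copy_number:.4f}\n")


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs
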