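"""End-to-end circle-calling orchestration with per-filter accounting."""
from __future__ import annotations

from typing import Callable

from . import finder
from .model import (
    ConsensusEcDNA,
    FragmentChain,
    GeneModel,
    PipelineConfig,
    SVRecord,
)


def detect_ecdna(
    chains_by_cell: dict[str, list[FragmentChain]],
    repeats: dict[str, list[tuple[int, int]]] | None = None,
    svs: list[SVRecord] | None = None,
    genes: list[GeneModel] | None = None,
    cancer_catalogue: list[str] | None = None,
    config: PipelineConfig | None = None,
    log: Callable[[dict], None] | None = None,
) -> list[ConsensusEcDNA]:
    """Run the full caller: per-cell refinement, junction extraction,
    breakpoint clustering, cycle detection, repeat/SV filtering, cross-cell
    consensus, pooled support filtering, quantification and annotation.

    The minimum-support filter is applied to the pooled (cross-cell merged)
    deduplicated support, so low-copy circles seen in several cells with
    one or two reads each are still recoverable.
    """
    cfg = config or PipelineConfig()
    repeats = repeats or {}
    svs = svs or []

    def _log(stage: str, n_in: int, n_out: int, **extra) -> None:
        if log is not None:
            log({"stage": stage, "in": n_in, "out": n_out, **extra})

    per_cell_candidates = []
    all_chains: list[FragmentChain] = []
    for cell in sorted(chains_by_cell):
        chains = [
            finder.refine_chain(
                c, cfg.min_interval, cfg.duplic_tol, cfg.duplic_max_len
            )
            for c in chains_by_cell[cell]
        ]
        chains = [c for c in chains if len(c) > 0]
        all_chains.extend(chains)
        junctions = [j for c in chains for j in finder.chain_to_junctions(c)]
        clusters = finder.cluster_breakpoints(junctions, tol=cfg.cluster_tol)
        cands = finder.detect_circles(clusters, junctions, chains=chains)
        _log("detect_circles", len(junctions), len(cands), cell=cell)

        n0 = len(cands)
        cands = finder.filter_repeats(
            cands, repeats, flank=cfg.repeat_flank, min_ovl=cfg.repeat_min_ovl
        )
        _log("filter_repeats", n0, len(cands), cell=cell)
        n0 = len(cands)
        cands = finder.filter_sv_proximity(cands, svs, dist=cfg.sv_dist)
        _log("filter_sv_proximity", n0, len(cands), cell=cell)
        per_cell_candidates.extend(cands)

    consensus = finder.merge_consensus(per_cell_candidates, tol=cfg.merge_tol)
    _log("merge_consensus", len(per_cell_candidates), len(consensus))

    n0 = len(consensus)
    consensus = finder.filter_support(
        consensus, min_support=cfg.min_support, dedup_tol=cfg.dedup_tol
    )
    # re-number after filtering so ids stay dense and deterministic
    for k, c in enumerate(consensus, 1):
        c.id = f"ecDNA_{k:04d}"
    _log("filter_support", n0, len(consensus))

    consensus = finder.quantify(consensus, all_chains, dedup_tol=cfg.dedup_tol)
    if genes:
        consensus = finder.annotate_genes(
            consensus, genes, min_ovl=cfg.gene_min_ovl, cancer_catalogue=cancer_catalogue
        )
    return consensus
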