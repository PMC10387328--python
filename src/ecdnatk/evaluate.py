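"""Scoring of pipeline output against simulation truth.

Includes the spike-in quantification analysis: per-cell ordinary
least-squares regression of detected junction-read counts on true
absolute plasmid copy numbers, summarized by the average R² across cells.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .finder import compare_sets
from .model import ConsensusEcDNA


def plasmid_detection_table(
    consensus: list[ConsensusEcDNA], plasmid_labels: list[str], cells: list[str]
) -> pd.DataFrame:
    """Per-cell deduplicated junction-read counts for each plasmid
    reference (cells x plasmids; absent detections count 0).  A plasmid is
    matched by the reference its cyclization site lies on; when several
    consensus entries fall on one reference their support is summed."""
    table = pd.DataFrame(0, index=list(cells), columns=list(plasmid_labels), dtype=int)
    for ec in consensus:
        chrom = ec.cyclization_site[0]
        if chrom not in table.columns:
            continue
        for cell, n in ec.per_cell_support.items():
            if cell in table.index:
                table.loc[cell, chrom] += n
    return table


def plasmid_regression(
    detected: pd.DataFrame, truth: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Per-cell OLS of detected counts on true copies and the average R².

    ``detected`` is the cells x plasmids count table; ``truth`` has
    columns cell/plasmid/copies.  R² = 1 - SS_res/SS_tot with a fitted
    intercept (equivalently the squared Pearson correlation).  A cell
    whose truth copies have zero variance has no defined R² and is
    reported missing; missing cells are excluded from the average.
    """
    r2 = {}
    for cell in detected.index:
        t = truth[truth["cell"] == cell].set_index("plasmid")["copies"]
        t = t.reindex(detected.columns)
        nonzero = t[t > 0]
        if len(nonzero) < 3:
            raise ValueError(f"cell {cell}: need >= 3 plasmids with nonzero copies")
        x = t.to_numpy(dtype=float)
        y = detected.loc[cell].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            r2[cell] = np.nan
            continue
        if np.ptp(y) == 0:
            # constant detected counts: the regression explains nothing
            r2[cell] = 0.0
            continue
        res = stats.linregress(x, y)
        r2[cell] = float(res.rvalue**2)
    series = pd.Series(r2, name="r_squared")
    return series, float(series.dropna().mean())


def detection_report(
    consensus: list[ConsensusEcDNA],
    truth_circles: list[ConsensusEcDNA],
    frac: float = 0.1,
    site_tol: int = 500,
) -> dict:
    """Sensitivity / precision / cyclization-site error of the caller.

    A truth circle counts as detected when some consensus entry matches
    it by reciprocal overlap (>= ``frac`` both ways) or has both
    cyclization-site ends within ``site_tol`` bp.
    """
    def site_match(a: ConsensusEcDNA, b: ConsensusEcDNA) -> bool:
        ca, ha, ta = a.cyclization_site
        cb, hb, tb = b.cyclization_site
        return ca == cb and abs(ha - hb) <= site_tol and abs(ta - tb) <= site_tol

    overlap = compare_sets(truth_circles, consensus, frac=frac)
    matched_truth = {id(a) for a, _ in overlap["shared"]}
    matched_pred = {id(b) for _, b in overlap["shared"]}
    site_errors = []
    for t in truth_circles:
        best = None
        for p in consensus:
            if site_match(t, p):
                matched_truth.add(id(t))
                matched_pred.add(id(p))
                err = abs(t.cyclization_site[1] - p.cyclization_site[1]) + abs(
                    t.cyclization_site[2] - p.cyclization_site[2]
                )
                best = err if best is None else min(best, err)
        if best is not None:
            site_errors.append(best / 2.0)
    n_truth = len(truth_circles)
    n_pred = len(consensus)
    tp = sum(1 for t in truth_circles if id(t) in matched_truth)
    pp = sum(1 for p in consensus if id(p) in matched_pred)
    return {
        "sensitivity": tp / n_truth if n_truth else float("nan"),
        "precision": pp / n_pred if n_pred else float("nan"),
        "mean_site_error_bp": float(np.mean(site_errors)) if site_errors else float("nan"),
        "n_truth": n_truth,
        "n_predicted": n_pred,
    }


def expression_contrast(
    expression: pd.DataFrame, ecdna_genes: list[str]
) -> dict:
    """Descriptive contrast of ecDNA-gene versus other-gene expression.

    ``expression`` is genes x cells.  Reports per-group median expression
    (over all gene/cell values) and a two-sided Wilcoxon rank-sum test of
    per-gene mean expression between the groups.
    """
    in_set = expression.index.isin(set(ecdna_genes))
    if in_set.sum() == 0 or (~in_set).sum() == 0:
        raise ValueError("both gene groups must be nonempty")
    ec = expression.loc[in_set]
    other = expression.loc[~in_set]
    stat = stats.ranksums(ec.mean(axis=1), other.mean(axis=1))
    return {
        "median_ecdna": float(np.median(ec.to_numpy())),
        "median_other": float(np.median(other.to_numpy())),
        "statistic": float(stat.statistic),
        "pvalue": float(stat.pvalue),
        "n_ecdna_genes": int(in_set.sum()),
        "n_other_genes": int((~in_set).sum()),
    }
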