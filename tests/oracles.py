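"""Independent brute-force re-implementations used as test oracles.

Everything here is written from the published rules, deliberately with
different algorithms and data layouts than the package (exhaustive scans
instead of graphs, explicit median recomputation instead of incremental
clustering) so that agreement is meaningful.
"""
from __future__ import annotations

import statistics


# ---------------------------------------------------------------------------
# refine rules, applied literally and exhaustively
# ---------------------------------------------------------------------------

def bf_refine(intervals, min_interval=100, duplic_tol=500, duplic_max_len=1000):
    """intervals: list of dicts with read_start/read_end/chrom/ref_start/
    ref_end/strand.  Returns the refined list (same dialect)."""
    ivs = sorted((dict(v) for v in intervals), key=lambda v: v["read_start"])
    while True:
        # LOWALIGN
        kept = [v for v in ivs if v["read_end"] - v["read_start"] >= min_interval]
        if len(kept) != len(ivs):
            ivs = kept
            continue
        # OVER: read-space containment in an adjacent interval
        removed = None
        for i, v in enumerate(ivs):
            for j in (i - 1, i + 1):
                if 0 <= j < len(ivs):
                    nb = ivs[j]
                    if (
                        nb["read_start"] <= v["read_start"]
                        and v["read_end"] <= nb["read_end"]
                    ):
                        removed = i
                        break
            if removed is not None:
                break
        if removed is not None:
            ivs = [v for k, v in enumerate(ivs) if k != removed]
            continue
        # DUPLIC: near-identical adjacent genomic intervals
        removed = None
        for i in range(len(ivs) - 1):
            a, b = ivs[i], ivs[i + 1]
            if (
                a["chrom"] == b["chrom"]
                and abs(a["ref_start"] - b["ref_start"]) < duplic_tol
                and abs(a["ref_end"] - b["ref_end"]) < duplic_tol
            ):
                la = a["read_end"] - a["read_start"]
                lb = b["read_end"] - b["read_start"]
                drop, dlen = (i, la) if la <= lb else (i + 1, lb)
                if dlen < duplic_max_len:
                    removed = drop
                    break
        if removed is not None:
            ivs = [v for k, v in enumerate(ivs) if k != removed]
            continue
        return ivs


# ---------------------------------------------------------------------------
# circular adjacency / clustering / circle enumeration
# ---------------------------------------------------------------------------

def bf_adjacencies(chains):
    """Scan every adjacent segment pair of every chain.

    Returns (circular, linear): circular entries are
    (chrom, head, tail, read_id); linear entries are
    ((chrom, pos, orient), (chrom, pos, orient), read_id, 'linear')
    with canonically ordered endpoints.
    """
    circular, linear = [], []
    for ch in chains:
        ivs = sorted(ch.intervals, key=lambda v: v.read_start)
        for a, b in zip(ivs, ivs[1:]):
            same = a.chrom == b.chrom and a.strand == b.strand
            if same and (
                (a.strand == "+" and b.ref_start <= a.ref_start)
                or (a.strand == "-" and b.ref_start >= a.ref_start)
            ):
                if a.strand == "+":
                    head, tail = b.ref_start, a.ref_end
                else:
                    head, tail = a.ref_start, b.ref_end
                circular.append((a.chrom, head, tail, ch.read_id))
            else:
                ea = (
                    (a.chrom, a.ref_end, "tail")
                    if a.strand == "+"
                    else (a.chrom, a.ref_start, "head")
                )
                eb = (
                    (b.chrom, b.ref_start, "head")
                    if b.strand == "+"
                    else (b.chrom, b.ref_end, "tail")
                )
                if (eb[0], eb[1]) < (ea[0], ea[1]):
                    ea, eb = eb, ea
                linear.append((ea, eb, ch.read_id))
    return circular, linear


def bf_cluster(endpoints, tol=500):
    """endpoints: list of (chrom, orient, pos, tag).  Sequential grouping:
    a point starts a new cluster unless its distance to the current
    cluster's lower-median is strictly below ``tol``.  Returns a list of
    dicts {chrom, orient, positions, tags, position}."""
    clusters = []
    for chrom, orient, pos, tag in sorted(endpoints):
        placed = False
        if clusters:
            cur = clusters[-1]
            if (
                cur["chrom"] == chrom
                and cur["orient"] == orient
                and abs(pos - statistics.median_low(cur["positions"])) < tol
            ):
                cur["positions"].append(pos)
                cur["tags"].append(tag)
                placed = True
        if not placed:
            clusters.append(
                {"chrom": chrom, "orient": orient, "positions": [pos], "tags": [tag]}
            )
    for c in clusters:
        c["position"] = statistics.median_low(c["positions"])
    return clusters


def bf_circles(chains, tol=500):
    """Exhaustive circle enumeration from raw (refined) chains.

    Returns a set of fragment tuples; each fragment is
    (chrom, start, end) at cluster-representative resolution.
    Covers single-fragment self-cyclizations and two-fragment cycles
    (fragment edge = nearest-neighbour cluster link on one chromosome,
    junction edge = read-evidenced adjacency), the geometries the random
    instance generator emits.
    """
    circular, linear = bf_adjacencies(chains)
    endpoints = []
    for k, (chrom, head, tail, read_id) in enumerate(circular):
        endpoints.append((chrom, "head", head, ("c", k)))
        endpoints.append((chrom, "tail", tail, ("c", k)))
    for k, (ea, eb, read_id) in enumerate(linear):
        endpoints.append((ea[0], ea[2], ea[1], ("l", k, "a")))
        endpoints.append((eb[0], eb[2], eb[1], ("l", k, "b")))
    clusters = bf_cluster(endpoints, tol=tol)

    def cluster_of(tag):
        for idx, c in enumerate(clusters):
            if tag in c["tags"]:
                return idx
        raise AssertionError(f"unassigned endpoint {tag}")

    found = set()
    # single-fragment self-cyclizations
    for k, (chrom, head, tail, read_id) in enumerate(circular):
        # the head and tail endpoints of junction k share the tag ("c", k);
        # recover both clusters by scanning the membership lists
        hids = [i for i, c in enumerate(clusters) if ("c", k) in c["tags"]]
        pos = {(clusters[i]["orient"], clusters[i]["position"]) for i in hids}
        heads = [p for o, p in pos if o == "head"]
        tails = [p for o, p in pos if o == "tail"]
        for h in heads:
            for t in tails:
                if t > h:
                    found.add(((chrom, h, t),))

    # nearest-neighbour fragment links between clusters
    def linked(i, j):
        ci, cj = clusters[i], clusters[j]
        if ci["chrom"] != cj["chrom"] or i == j:
            return False

        def nearest(a):
            best = None
            for b, cb in enumerate(clusters):
                if b == a or cb["chrom"] != clusters[a]["chrom"]:
                    continue
                key = (abs(cb["position"] - clusters[a]["position"]), cb["position"])
                if best is None or key < best[0]:
                    best = (key, b)
            return best[1] if best else None

        return nearest(i) == j or nearest(j) == i

    # junction evidence between two clusters (any adjacency, either kind)
    evid = {}
    for k in range(len(circular)):
        ids = [i for i, c in enumerate(clusters) if ("c", k) in c["tags"]]
        if len(ids) == 2:
            evid.setdefault(frozenset(ids), []).append("circular")
    for k in range(len(linear)):
        a = cluster_of(("l", k, "a"))
        b = cluster_of(("l", k, "b"))
        if a != b:
            evid.setdefault(frozenset((a, b)), []).append("linear")

    n = len(clusters)
    for a in range(n):
        for b in range(n):
            if not linked(a, b):
                continue
            for c in range(n):
                if c in (a, b) or frozenset((b, c)) not in evid:
                    continue
                for d in range(n):
                    if d in (a, b, c):
                        continue
                    if not linked(c, d) or frozenset((d, a)) not in evid:
                        continue
                    kinds = evid[frozenset((b, c))] + evid[frozenset((d, a))]
                    chroms = {clusters[i]["chrom"] for i in (a, b, c, d)}
                    if len(chroms) == 1 and "circular" not in kinds:
                        continue
                    frags = tuple(
                        sorted(
                            (
                                (
                                    clusters[i]["chrom"],
                                    min(clusters[i]["position"], clusters[j]["position"]),
                                    max(clusters[i]["position"], clusters[j]["position"]),
                                )
                                for i, j in ((a, b), (c, d))
                            )
                        )
                    )
                    if frags[0] != frags[1]:
                        found.add(frags)
    return found


# ---------------------------------------------------------------------------
# closed-form OLS R-squared
# ---------------------------------------------------------------------------

def bf_r_squared(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if syy == 0:
        return 0.0
    return sxy * sxy / (sxx * syy)
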