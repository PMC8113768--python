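"""Candidate-region calling from per-marker pscores, cross-method
intersection, and gene-interval annotation.

A marker is significant when its pscore (-log10 two-sided p) reaches the
threshold (default 2.5).  Sliding windows anchored at position 0 of each
chromosome qualify when they contain at least ``min_sig`` significant
markers; overlapping qualifying windows are merged and each merged span is
trimmed to its outermost significant markers, so reported bounds are marker
positions.  Default geometries: 2-Mb windows stepping 20 kb with >= 3
significant markers for iHS; 1-Mb windows stepping 10 kb with >= 4 for Rsb
and XP-EHH.
"""

from __future__ import annotations

import logging
from itertools import combinations, product

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import CandidateRegion

log = logging.getLogger(__name__)

#: Significance threshold on -log10 p shared by all three statistics.
DEFAULT_THRESHOLD = 2.5

#: (window_bp, step_bp, min_sig) per statistic.
WINDOW_RULES = {
    "iHS": (2_000_000, 20_000, 3),
    "Rsb": (1_000_000, 10_000, 4),
    "XP-EHH": (1_000_000, 10_000, 4),
}


def call_regions(
    scores: pd.DataFrame,
    method: str,
    threshold: float = DEFAULT_THRESHOLD,
    window_bp: int | None = None,
    step_bp: int | None = None,
    min_sig: int | None = None,
) -> list[CandidateRegion]:
    """Call candidate regions from a score table (needs chrom/pos_bp/pscore).

    Window geometry defaults to the rule registered for ``method`` in
    :data:`WINDOW_RULES`.  Windows cover ``[k*step, k*step + window)`` in
    0-based coordinates, anchored at the chromosome start.  Markers are
    re-sorted by position so the result is order-invariant.
    """
    if window_bp is None or step_bp is None or min_sig is None:
        try:
            dflt = WINDOW_RULES[method]
        except KeyError:
            raise ValueError(f"no default window rule for method {method!r}") from None
        window_bp = window_bp if window_bp is not None else dflt[0]
        step_bp = step_bp if step_bp is not None else dflt[1]
        min_sig = min_sig if min_sig is not None else dflt[2]
    if step_bp > window_bp:
        raise ValueError("step_bp must not exceed window_bp")

    out: list[CandidateRegion] = []
    for chrom, sub in scores.groupby("chrom", sort=False):
        sub = sub.sort_values("pos_bp")
        pos = sub["pos_bp"].to_numpy()
        ps = sub["pscore"].to_numpy()
        ids = sub["marker_id"].to_numpy()
        sig = np.nan_to_num(ps, nan=-np.inf) >= threshold
        spos = pos[sig]
        if len(spos) < min_sig:
            continue
        # qualifying window starts: k*step <= p-1 < k*step + window for >= min_sig markers
        p0 = spos - 1  # 0-based marker coordinates
        max_k = int(p0.max() // step_bp)
        spans: list[tuple[int, int]] = []  # merged qualifying windows, 0-based half-open
        for k in range(0, max_k + 1):
            lo = k * step_bp
            hi = lo + window_bp
            n_in = int(np.count_nonzero((p0 >= lo) & (p0 < hi)))
            if n_in < min_sig:
                continue
            if spans and lo <= spans[-1][1]:
                spans[-1] = (spans[-1][0], max(spans[-1][1], hi))
            else:
                spans.append((lo, hi))
        for lo, hi in spans:
            inside = (p0 >= lo) & (p0 < hi)
            if not inside.any():
                continue
            start = int(spos[inside].min())
            end = int(spos[inside].max())
            in_region = sig & (pos >= start) & (pos <= end)
            out.append(
                CandidateRegion(
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    methods=frozenset({method}),
                    n_sig=int(in_region.sum()),
                    peak_pscore=float(ps[in_region].max()),
                    marker_ids=tuple(ids[in_region]),
                )
            )
    log.info("call_regions[%s]: %d regions", method, len(out))
    return out


def intersect_regions(
    per_method: dict[str, list[CandidateRegion]],
    union: bool = False,
) -> tuple[list[CandidateRegion], list[CandidateRegion]]:
    """Cross-method joint regions plus the single-method leftovers.

    For every combination of >= 2 methods and one region from each, a
    non-empty common overlap (>= 1 bp) yields a joint region whose interval
    is the intersection (or the union of the contributors when
    ``union=True``) and whose method set is the union of contributors.
    Joint regions strictly dominated by a higher-order overlap (method set a
    strict subset, interval containing the dominator's) are dropped, so a
    three-way overlap is reported once with all three methods.  The second
    return value lists every input region tagged with its single method.
    """
    if len(per_method) < 2:
        raise ValueError("need region lists from at least two methods")
    joint: list[CandidateRegion] = []
    methods = sorted(per_method)
    for r in range(2, len(methods) + 1):
        for combo in combinations(methods, r):
            for regs in product(*(per_method[m] for m in combo)):
                chroms = {x.chrom for x in regs}
                if len(chroms) != 1:
                    continue
                start = max(x.start for x in regs)
                end = min(x.end for x in regs)
                if start > end:
                    continue
                if union:
                    start = min(x.start for x in regs)
                    end = max(x.end for x in regs)
                mset = frozenset().union(*(x.methods for x in regs))
                n_sig = sum(x.n_sig for x in regs)
                peak = max(x.peak_pscore for x in regs)
                joint.append(CandidateRegion(regs[0].chrom, start, end, mset, n_sig, peak))
    # drop duplicates, then lower-order overlaps shadowed by a higher-order one
    uniq: dict[tuple, CandidateRegion] = {}
    for r in joint:
        uniq[(r.chrom, r.start, r.end, r.methods)] = r
    joint = list(uniq.values())
    kept = [
        a
        for a in joint
        if not any(
            a.methods < b.methods
            and a.chrom == b.chrom
            and a.start <= b.start
            and a.end >= b.end
            for b in joint
        )
    ]
    kept.sort(key=lambda r: (str(r.chrom), r.start, r.end, tuple(sorted(r.methods))))
    singles = [r for m in methods for r in per_method[m]]
    log.info("intersect_regions: %d joint regions from %d methods", len(kept), len(methods))
    return kept, singles


def annotate_regions(
    regions: list[CandidateRegion], genes: pd.DataFrame
) -> pd.DataFrame:
    """Overlap regions with gene intervals (>= 1 bp), preserving file order.

    ``genes`` uses on-disk BED convention (0-based half-open); regions are
    1-based inclusive.  Returns one row per region with a comma-joined gene
    list.
    """
    trees: dict[str, IntervalTree] = {}
    order: dict[str, int] = {name: i for i, name in enumerate(genes["name"])}
    for chrom, sub in genes.groupby("chrom", sort=False):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e), n) for s, e, n in zip(sub["start"], sub["end"], sub["name"])
        )
    rows = []
    for r in regions:
        tree = trees.get(str(r.chrom))
        hits = tree.overlap(r.start - 1, r.end) if tree is not None else set()
        names = sorted({iv.data for iv in hits}, key=lambda n: order[n])
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "methods": ",".join(sorted(r.methods)),
                "n_genes": len(names),
                "genes": ",".join(names),
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "methods", "n_genes", "genes"])
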