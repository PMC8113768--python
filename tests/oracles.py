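"""Independent brute-force oracles used across the test suite.

These deliberately avoid the package's incremental algorithms: EHH/EHHS are
recomputed by hashing full haplotype substrings at every extent; region
calling enumerates every sliding window explicitly; intersection and
annotation are quadratic scans.
"""

from collections import Counter

import numpy as np


def _substring_classes(alleles, rows, lo, hi):
    return Counter(tuple(alleles[h, lo : hi + 1]) for h in rows)


def _decay_side_oracle(alleles, pos, rows, f, idx_iter, cutoff, norm):
    """One side of a decay curve by substring hashing; returns (pos, values, truncated)."""
    n = len(rows)
    ps, vs = [int(pos[f])], [1.0]
    for t in idx_iter:
        lo, hi = min(f, t), max(f, t)
        classes = _substring_classes(alleles, rows, lo, hi)
        val = sum(c * (c - 1) for c in classes.values()) / (n * (n - 1)) / norm
        ps.append(int(pos[t]))
        vs.append(val)
        if val < cutoff:
            return ps, vs, False
    return ps, vs, True


def ehh_oracle(panel, f, code, cutoff=0.05):
    """Allele-specific EHH decay for a single-chromosome panel."""
    alleles = panel.alleles
    pos = panel.markers.pos_bp
    rows = np.flatnonzero(alleles[:, f] == code)
    m = alleles.shape[1]
    left = _decay_side_oracle(alleles, pos, rows, f, range(f - 1, -1, -1), cutoff, 1.0)
    right = _decay_side_oracle(alleles, pos, rows, f, range(f + 1, m), cutoff, 1.0)
    return left, right


def ehhs_oracle(panel, f, cutoff=0.05):
    """Pooled site-EHH decay, normalized to 1 at the focal marker."""
    alleles = panel.alleles
    pos = panel.markers.pos_bp
    rows = np.arange(alleles.shape[0])
    n = len(rows)
    classes = _substring_classes(alleles, rows, f, f)
    h_focal = sum(c * (c - 1) for c in classes.values()) / (n * (n - 1))
    m = alleles.shape[1]
    left = _decay_side_oracle(alleles, pos, rows, f, range(f - 1, -1, -1), cutoff, h_focal)
    right = _decay_side_oracle(alleles, pos, rows, f, range(f + 1, m), cutoff, h_focal)
    return left, right


def call_regions_oracle(chroms, positions, pscores, threshold, window_bp, step_bp, min_sig):
    """Region calling by explicit enumeration of every sliding window.

    Returns a list of (chrom, start, end, n_sig) tuples."""
    out = []
    for chrom in dict.fromkeys(chroms):  # preserve first-seen order
        mask = np.asarray(chroms) == chrom
        pos = np.asarray(positions)[mask]
        ps = np.asarray(pscores)[mask]
        order = np.argsort(pos)
        pos, ps = pos[order], ps[order]
        sig = np.nan_to_num(ps, nan=-np.inf) >= threshold
        spos = pos[sig]
        if len(spos) == 0:
            continue
        qualifying = []
        k = 0
        while k * step_bp <= spos.max() - 1:
            lo, hi = k * step_bp, k * step_bp + window_bp
            if sum(lo <= p - 1 < hi for p in spos) >= min_sig:
                qualifying.append((lo, hi))
            k += 1
        merged = []
        for lo, hi in qualifying:
            if merged and lo <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        for lo, hi in merged:
            inside = [p for p in spos if lo <= p - 1 < hi]
            if not inside:
                continue
            start, end = min(inside), max(inside)
            n_sig = sum(1 for p in spos if start <= p <= end)
            out.append((chrom, int(start), int(end), int(n_sig)))
    return out


def intersect_oracle(per_method):
    """All >= 2-method overlaps with dominance pruning, by exhaustive scan.

    ``per_method`` maps method -> list of (chrom, start, end).  Returns a set
    of (chrom, start, end, frozenset(methods))."""
    from itertools import combinations, product

    methods = sorted(per_method)
    cands = set()
    for r in range(2, len(methods) + 1):
        for combo in combinations(methods, r):
            for regs in product(*(per_method[m] for m in combo)):
                if len({c for c, _, _ in regs}) != 1:
                    continue
                start = max(s for _, s, _ in regs)
                end = min(e for _, _, e in regs)
                if start <= end:
                    cands.add((regs[0][0], start, end, frozenset(combo)))
    kept = set()
    for a in cands:
        dominated = any(
            a[3] < b[3] and a[0] == b[0] and a[1] <= b[1] and a[2] >= b[2]
            for b in cands
        )
        if not dominated:
            kept.add(a)
    return kept


def annotate_oracle(regions, genes):
    """region index -> gene names, by quadratic scan (BED half-open genes)."""
    out = {}
    for i, r in enumerate(regions):
        names = []
        for _, g in genes.iterrows():
            if g["chrom"] == r.chrom and g["start"] < r.end and g["end"] > r.start - 1:
                names.append(g["name"])
        out[i] = names
    return out
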