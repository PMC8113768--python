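"""Inner loop of the EHH partition refinement.

Walking a decay curve outward refines the haplotype identity partition one
marker at a time; this is the only performance-critical loop in the package.
A numba-compiled kernel is used when numba is importable, with a pure-NumPy
implementation of identical semantics as fallback — both return the same
values bit-for-bit (integer label bookkeeping, float division at the end).
"""

from __future__ import annotations

import numpy as np

__all__ = ["side_decay_kernel", "gametes_kernel"]


def _gametes_numpy(haps, gpar, start, cuts_flat, cuts_off, m):
    n_gam = gpar.size
    out = np.empty((n_gam, m), dtype=np.uint8)
    for g in range(n_gam):
        a = haps[2 * gpar[g] + start[g]]
        b = haps[2 * gpar[g] + 1 - start[g]]
        cuts = np.sort(cuts_flat[cuts_off[g] : cuts_off[g + 1]])
        if cuts.size == 0:
            out[g] = a
            continue
        phase = np.zeros(m, dtype=np.int64)
        np.add.at(phase, cuts[cuts < m], 1)
        phase = np.cumsum(phase) % 2
        out[g] = np.where(phase == 0, a, b)
    return out


def _side_decay_numpy(alleles, rows, labels0, cols, positions, focal_pos, stop_below, scale, max_gap):
    n = rows.size
    out_pos = np.empty(cols.size + 1, dtype=np.int64)
    out_val = np.empty(cols.size + 1, dtype=np.float64)
    out_pos[0] = focal_pos
    out_val[0] = 1.0
    k = 1
    labels = labels0
    prev = focal_pos
    for idx in range(cols.size):
        c = int(cols[idx])
        p = int(positions[idx])
        if max_gap > 0 and abs(p - prev) > max_gap:
            return out_pos[:k], out_val[:k], True
        codes = labels * 2 + alleles[rows, c]
        counts = np.bincount(codes)
        nz = np.flatnonzero(counts)
        remap = np.empty(counts.size, dtype=np.int64)
        remap[nz] = np.arange(nz.size)
        labels = remap[codes]
        h = float((counts * (counts - 1)).sum()) / scale
        out_pos[k] = p
        out_val[k] = h
        k += 1
        if h < stop_below:
            return out_pos[:k], out_val[:k], False
        prev = p
    return out_pos[:k], out_val[:k], True


try:
    from numba import njit

    @njit(cache=False)
    def _side_decay_nb(alleles, rows, labels0, cols, positions, focal_pos, stop_below, scale, max_gap):  # pragma: no cover - jitted
        n = rows.size
        out_pos = np.empty(cols.size + 1, dtype=np.int64)
        out_val = np.empty(cols.size + 1, dtype=np.float64)
        out_pos[0] = focal_pos
        out_val[0] = 1.0
        k = 1
        labels = labels0.copy()
        codes = np.empty(n, dtype=np.int64)
        prev = focal_pos
        truncated = True
        for idx in range(cols.size):
            c = cols[idx]
            p = positions[idx]
            if max_gap > 0 and abs(p - prev) > max_gap:
                return out_pos[:k], out_val[:k], True
            n_groups = 0
            for i in range(n):
                code = labels[i] * 2 + alleles[rows[i], c]
                codes[i] = code
                if code + 1 > n_groups:
                    n_groups = code + 1
            counts = np.zeros(n_groups, dtype=np.int64)
            for i in range(n):
                counts[codes[i]] += 1
            remap = np.empty(n_groups, dtype=np.int64)
            nxt = 0
            ssq = 0
            for g in range(n_groups):
                cg = counts[g]
                if cg > 0:
                    remap[g] = nxt
                    nxt += 1
                    ssq += cg * (cg - 1)
            for i in range(n):
                labels[i] = remap[codes[i]]
            h = ssq / scale
            out_pos[k] = p
            out_val[k] = h
            k += 1
            if h < stop_below:
                return out_pos[:k], out_val[:k], False
            prev = p
        return out_pos[:k], out_val[:k], truncated

    @njit(cache=False)
    def _gametes_nb(haps, gpar, start, cuts_flat, cuts_off, m):  # pragma: no cover - jitted
        n_gam = gpar.size
        out = np.empty((n_gam, m), dtype=np.uint8)
        for g in range(n_gam):
            a = haps[2 * gpar[g] + start[g]]
            b = haps[2 * gpar[g] + 1 - start[g]]
            lo = cuts_off[g]
            hi = cuts_off[g + 1]
            if hi == lo:
                out[g, :] = a
                continue
            cuts = np.sort(cuts_flat[lo:hi])
            cur = 0
            prev = 0
            for ci in range(cuts.size):
                cut = min(cuts[ci], m)
                if cur == 0:
                    for j in range(prev, cut):
                        out[g, j] = a[j]
                else:
                    for j in range(prev, cut):
                        out[g, j] = b[j]
                cur = 1 - cur
                prev = cut
            if cur == 0:
                for j in range(prev, m):
                    out[g, j] = a[j]
            else:
                for j in range(prev, m):
                    out[g, j] = b[j]
        return out

    def gametes_kernel(haps, gpar, start, cuts_flat, cuts_off, m):
        return _gametes_nb(
            haps,
            gpar.astype(np.int64),
            start.astype(np.int64),
            cuts_flat.astype(np.int64),
            cuts_off.astype(np.int64),
            np.int64(m),
        )

    def side_decay_kernel(alleles, rows, labels0, cols, positions, focal_pos, stop_below, scale, max_gap):
        return _side_decay_nb(
            alleles,
            rows.astype(np.int64),
            labels0.astype(np.int64),
            cols.astype(np.int64),
            positions.astype(np.int64),
            np.int64(focal_pos),
            float(stop_below),
            float(scale),
            np.int64(max_gap),
        )

except ImportError:  # pragma: no cover - numba is normally available

    def gametes_kernel(haps, gpar, start, cuts_flat, cuts_off, m):
        return _gametes_numpy(
            haps,
            gpar.astype(np.int64),
            start.astype(np.int64),
            cuts_flat.astype(np.int64),
            cuts_off.astype(np.int64),
            int(m),
        )

    def side_decay_kernel(alleles, rows, labels0, cols, positions, focal_pos, stop_below, scale, max_gap):
        return _side_decay_numpy(
            alleles,
            rows.astype(np.int64),
            labels0.astype(np.int64),
            cols.astype(np.int64),
            positions.astype(np.int64),
            int(focal_pos),
            float(stop_below),
            float(scale),
            int(max_gap),
        )
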