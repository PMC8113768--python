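"""Extended haplotype homozygosity statistics: EHH/EHHS decay, iHH/iES
integration, iHS, Rsb, XP-EHH and the normal-theory -log10 p transform.

EHH at extent t is the probability that two haplotypes drawn without
replacement from the carriers of a focal core allele are identical over every
marker from the core out to t; it equals sum_h C(n_h,2)/C(n_c,2) over the
identity classes h of the extended haplotypes.  EHHS pools all haplotypes
regardless of core allele and is normalized to 1 at the core.  Integrating a
decay curve over physical distance (trapezoids, clipped by linear
interpolation at the first crossing of the cutoff) gives iHH (allele-specific)
or iES (site-specific), in bp x EHH units.

iHS is ln(iHH_ancestral / iHH_derived) standardized within derived-allele
frequency bins; Rsb and XP-EHH are the ln-ratio of iES between a test and a
reference population, centered on the median (Rsb) or the mean (XP-EHH) and
scaled to unit standard deviation.  Standardized scores are mapped to
-log10 two-sided normal p-values; scores are treated as standard normal under
neutrality, so pscore >= 2.5 corresponds to |z| >= 2.95 roughly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._kernels import side_decay_kernel
from .types import HaplotypePanel, PolarizedPanel

log = logging.getLogger(__name__)

#: Default EHH cutoff below which a decay curve is considered ended.
DEFAULT_CUTOFF = 0.05

#: Sentinel returned by :func:`integrate_decay` for border-discarded markers.
DISCARDED = float("nan")


@dataclass
class DecayCurve:
    """An EHH or EHHS decay profile around one focal marker.

    Each side starts at the focal position with value 1 and extends
    marker-by-marker away from it; ``left_truncated``/``right_truncated``
    mark sides that reached the chromosome border (or a ``max_gap`` breach)
    before the curve fell below ``cutoff``.
    """

    focal_id: str
    chrom: str
    focal_pos: int
    left_pos: np.ndarray  # decreasing from focal_pos, includes focal
    left_ehh: np.ndarray
    right_pos: np.ndarray  # increasing from focal_pos, includes focal
    right_ehh: np.ndarray
    cutoff: float
    left_truncated: bool
    right_truncated: bool

    def __post_init__(self) -> None:
        for side in (self.left_ehh, self.right_ehh):
            if len(side) and not (side[0] == 1.0):
                raise ValueError("decay curve must start at 1 at the focal marker")

    @property
    def truncated(self) -> bool:
        return self.left_truncated or self.right_truncated


def _extend_partition(alleles: np.ndarray, rows: np.ndarray, labels: np.ndarray, col: int):
    """Refine haplotype identity classes by one marker column.

    Returns (new labels, sum over classes of n_h * (n_h - 1))."""
    codes = labels * 2 + alleles[rows, col]
    counts = np.bincount(codes)
    nz = np.flatnonzero(counts)
    remap = np.empty(counts.size, dtype=np.int64)
    remap[nz] = np.arange(nz.size)
    return remap[codes], int((counts * (counts - 1)).sum())


def _side_decay(
    alleles: np.ndarray,
    rows: np.ndarray,
    labels0: np.ndarray,
    cols: np.ndarray,
    positions: np.ndarray,
    focal_pos: int,
    stop_below: float,
    scale: float,
    max_gap: int | None,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Walk one side outward; returns (positions, values, truncated)."""
    pos, val, truncated = side_decay_kernel(
        alleles, rows, labels0, np.asarray(cols), np.asarray(positions),
        focal_pos, stop_below, scale, 0 if max_gap is None else max_gap,
    )
    return pos, val, bool(truncated)


def _chrom_block(panel: HaplotypePanel, focal: int):
    m = panel.markers
    chrom = m.chrom[focal]
    on = np.flatnonzero(m.chrom == chrom)
    return chrom, on


def _resolve_focal(panel: HaplotypePanel, focal) -> int:
    if isinstance(focal, (int, np.integer)):
        return int(focal)
    return panel.markers.index_of(focal)


def ehh_decay(
    p: PolarizedPanel | HaplotypePanel,
    focal,
    allele,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int | None = None,
) -> DecayCurve:
    """Allele-specific EHH decay around one focal marker.

    ``allele`` is ``"ancestral"``/``"derived"`` on a polarized panel (or the
    raw code 0/1).  The curve is computed over the haplotypes carrying that
    allele at the focal marker and each side stops at the first value below
    ``cutoff`` or at the chromosome border (truncation flag set).
    """
    panel = p.panel if isinstance(p, PolarizedPanel) else p
    f = _resolve_focal(panel, focal)
    code = {"ancestral": 0, "derived": 1, 0: 0, 1: 1}[allele]
    alleles = panel.alleles
    rows = np.flatnonzero(alleles[:, f] == code)
    if len(rows) < 2:
        raise ValueError(
            f"EHH needs >= 2 carriers of allele {allele!r} at marker "
            f"{panel.markers.marker_id[f]!r} (found {len(rows)})"
        )
    n = len(rows)
    scale = float(n * (n - 1))
    chrom, on = _chrom_block(panel, f)
    k = int(np.flatnonzero(on == f)[0])
    pos = panel.markers.pos_bp
    labels0 = np.zeros(n, dtype=np.int64)

    lcols = on[:k][::-1]
    rcols = on[k + 1 :]
    lp, lv, ltr = _side_decay(alleles, rows, labels0, lcols, pos[lcols], pos[f], cutoff, scale, max_gap)
    rp, rv, rtr = _side_decay(alleles, rows, labels0, rcols, pos[rcols], pos[f], cutoff, scale, max_gap)
    return DecayCurve(
        panel.markers.marker_id[f], chrom, int(pos[f]),
        np.array(lp), np.array(lv), np.array(rp), np.array(rv),
        cutoff, ltr, rtr,
    )


def ehhs_decay(
    h: HaplotypePanel | PolarizedPanel,
    focal,
    cutoff: float = DEFAULT_CUTOFF,
    max_gap: int | None = None,
) -> DecayCurve:
    """Site-EHH decay: pooled over all haplotypes, normalized to 1 at the core.

    The partition starts from the focal marker's allele classes and each side
    stops when the normalized curve falls below ``cutoff``.  A monomorphic
    focal marker yields a flat curve (it is excluded from cross-population
    scoring, where the contrast is uninformative).
    """
    panel = h.panel if isinstance(h, PolarizedPanel) else h
    f = _resolve_focal(panel, focal)
    alleles = panel.alleles
    n = alleles.shape[0]
    if n < 2:
        raise ValueError("EHHS needs at least two haplotypes")
    rows = np.arange(n)
    scale = float(n * (n - 1))
    labels0, ssq0 = _extend_partition(alleles, rows, np.zeros(n, dtype=np.int64), f)
    h_focal = ssq0 / scale
    chrom, on = _chrom_block(panel, f)
    k = int(np.flatnonzero(on == f)[0])
    pos = panel.markers.pos_bp
    # stop when h / h_focal < cutoff; values are reported normalized
    stop_below = cutoff * h_focal
    lcols = on[:k][::-1]
    rcols = on[k + 1 :]
    lp, lv, ltr = _side_decay(alleles, rows, labels0, lcols, pos[lcols], pos[f], stop_below, scale, max_gap)
    rp, rv, rtr = _side_decay(alleles, rows, labels0, rcols, pos[rcols], pos[f], stop_below, scale, max_gap)
    lv = np.array(lv) / h_focal
    rv = np.array(rv) / h_focal
    lv[0] = rv[0] = 1.0
    return DecayCurve(
        panel.markers.marker_id[f], chrom, int(pos[f]),
        np.array(lp), lv, np.array(rp), rv,
        cutoff, ltr, rtr,
    )


def _side_area(pos: np.ndarray, val: np.ndarray, cutoff: float, truncated: bool, keep: bool) -> float:
    """Trapezoidal area of one side, clipped at the first cutoff crossing."""
    if len(pos) < 2:
        return 0.0
    x = np.abs(pos.astype(float) - float(pos[0]))
    if truncated:
        if not keep:
            return DISCARDED
        return float(np.trapezoid(val, x))
    # last point is the first one strictly below the cutoff: interpolate
    x0, x1 = x[-2], x[-1]
    v0, v1 = val[-2], val[-1]
    xc = x0 if v0 <= cutoff else x0 + (x1 - x0) * (v0 - cutoff) / (v0 - v1)
    area = float(np.trapezoid(val[:-1], x[:-1]))
    area += 0.5 * (v0 + cutoff) * (xc - x0)
    return area


def integrate_decay(c: DecayCurve, border_policy: str = "discard") -> float:
    """Integrate a decay curve to iHH / iES (bp x EHH units).

    Each side is integrated with the trapezoid rule over physical distance,
    clipped by linear interpolation at the first crossing of the curve's
    cutoff; the two side areas are summed.  With ``border_policy="discard"``
    (default) a marker whose curve reaches a chromosome border before
    crossing the cutoff returns NaN; ``"keep"`` integrates the truncated side
    as observed.
    """
    if border_policy not in ("discard", "keep"):
        raise ValueError("border_policy must be 'discard' or 'keep'")
    keep = border_policy == "keep"
    if not keep and (c.left_truncated or c.right_truncated):
        return DISCARDED
    left = _side_area(c.left_pos, c.left_ehh, c.cutoff, c.left_truncated, keep)
    right = _side_area(c.right_pos, c.right_ehh, c.cutoff, c.right_truncated, keep)
    return left + right


def p_transform(score) -> np.ndarray | float:
    """Map a standardized score to -log10 of its two-sided normal p-value.

    pscore = -log10(1 - 2|Phi(z) - 0.5|) = -log10(2 * Phi(-|z|)), computed
    through the log survival function so extreme scores never underflow to an
    infinite value from naive subtraction.  NaN scores map to NaN.
    """
    z = np.asarray(score, dtype=float)
    with np.errstate(invalid="ignore"):
        logp = np.log(2.0) + norm.logsf(np.abs(z))
    out = -logp / np.log(10.0)
    if np.ndim(score) == 0:
        return float(out)
    return out


def _merge_bins(bin_ids: np.ndarray, n_bins: int, min_bin: int) -> np.ndarray:
    """Merge adjacent frequency bins left-to-right until each group >= min_bin.

    Returns a group id per marker.  The final group is merged backwards if it
    ends up under-filled."""
    counts = np.bincount(bin_ids, minlength=n_bins)
    group_of_bin = np.zeros(n_bins, dtype=int)
    g = 0
    acc = 0
    for b in range(n_bins):
        group_of_bin[b] = g
        acc += counts[b]
        if acc >= min_bin:
            g += 1
            acc = 0
    if acc > 0 and g > 0:  # trailing underfilled group: fold into the previous
        group_of_bin[group_of_bin == g] = g - 1
    return group_of_bin[bin_ids]


def ihs_scores(
    p: PolarizedPanel,
    cutoff: float = DEFAULT_CUTOFF,
    border_policy: str = "discard",
    bins: int = 20,
    min_bin: int = 10,
    max_gap: int | None = None,
) -> pd.DataFrame:
    """Per-marker iHS: ln(iHH_A / iHH_D) standardized within frequency bins.

    Markers are scored only where both alleles have >= 2 carriers and both
    integrals are positive and defined under the border policy; excluded
    markers stay in the table with a ``status`` explaining why.  Scored
    markers are binned by derived-allele frequency into ``bins`` equal-width
    bins, adjacent bins merged until each holds >= ``min_bin`` markers, and
    standardized to zero mean / unit sd within each bin; ``pscore`` is the
    -log10 two-sided normal p of the standardized score.
    """
    m = p.markers
    n_markers = m.n_markers
    ihh_a = np.full(n_markers, np.nan)
    ihh_d = np.full(n_markers, np.nan)
    status = np.full(n_markers, "ok", dtype=object)
    counts1 = p.alleles.sum(axis=0)
    n_hap = p.alleles.shape[0]
    for j in range(n_markers):
        if counts1[j] < 2 or n_hap - counts1[j] < 2:
            status[j] = "few_carriers"
            continue
        ca = ehh_decay(p, j, "ancestral", cutoff=cutoff, max_gap=max_gap)
        cd = ehh_decay(p, j, "derived", cutoff=cutoff, max_gap=max_gap)
        a = integrate_decay(ca, border_policy)
        d = integrate_decay(cd, border_policy)
        if np.isnan(a) or np.isnan(d):
            status[j] = "border"
            continue
        if a <= 0 or d <= 0:
            status[j] = "zero_ihh"
            continue
        ihh_a[j] = a
        ihh_d[j] = d

    raw = np.full(n_markers, np.nan)
    ok = status == "ok"
    raw[ok] = np.log(ihh_a[ok] / ihh_d[ok])
    if not ok.any():
        raise ValueError("no marker survived iHS scoring (all discarded)")

    p_d = np.asarray(p.derived_freq, dtype=float)
    bin_id = np.minimum((p_d * bins).astype(int), bins - 1)
    group = np.full(n_markers, -1)
    group[ok] = _merge_bins(bin_id[ok], bins, min_bin)
    z = np.full(n_markers, np.nan)
    for gid in np.unique(group[ok]):
        sel = ok & (group == gid)
        mu = raw[sel].mean()
        sd = raw[sel].std()
        z[sel] = (raw[sel] - mu) / sd if sd > 0 else 0.0
    pscore = p_transform(z)

    log.info("ihs_scores: %d markers in, %d scored", n_markers, int(ok.sum()))
    return pd.DataFrame(
        {
            "marker_id": m.marker_id,
            "chrom": m.chrom,
            "pos_bp": m.pos_bp,
            "p_d": p_d,
            "ihh_a": ihh_a,
            "ihh_d": ihh_d,
            "raw": raw,
            "bin": group,
            "z": z,
            "pscore": pscore,
            "status": status,
        }
    )


def _ies_per_marker(
    panel: HaplotypePanel, cutoff: float, border_policy: str, max_gap: int | None
) -> tuple[np.ndarray, np.ndarray]:
    m = panel.markers
    ies = np.full(m.n_markers, np.nan)
    status = np.full(m.n_markers, "ok", dtype=object)
    for j in range(m.n_markers):
        c = ehhs_decay(panel, j, cutoff=cutoff, max_gap=max_gap)
        v = integrate_decay(c, border_policy)
        if np.isnan(v):
            status[j] = "border"
        elif v <= 0:
            status[j] = "zero_ies"
        else:
            ies[j] = v
    return ies, status


def crosspop_scores(
    h1: HaplotypePanel,
    h2: HaplotypePanel,
    mode: str,
    cutoff: float = DEFAULT_CUTOFF,
    border_policy: str = "discard",
    max_gap: int | None = None,
) -> pd.DataFrame:
    """Rsb or XP-EHH between a test population (``h1``) and a reference.

    Per shared marker, iES is computed in each population; the ln-ratio
    ln(iES_pop1 / iES_pop2) is centered on its median (``mode="rsb"``) or
    mean (``mode="xpehh"``) and scaled to unit sd.  Positive standardized
    scores mean elongated haplotype homozygosity in the test population.
    Markers unscorable in either population are kept with a ``status``; the
    dropped count is logged.
    """
    if mode not in ("rsb", "xpehh"):
        raise ValueError("mode must be 'rsb' or 'xpehh'")
    return crosspop_scores_both(h1, h2, cutoff=cutoff, border_policy=border_policy, max_gap=max_gap)[mode]


def crosspop_scores_both(
    h1: HaplotypePanel,
    h2: HaplotypePanel,
    cutoff: float = DEFAULT_CUTOFF,
    border_policy: str = "discard",
    max_gap: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Rsb and XP-EHH from a single shared iES computation.

    The two statistics differ only in how the ln-ratio is centered, so the
    expensive per-marker iES integration is done once; returns
    ``{"rsb": ..., "xpehh": ...}``.
    """
    m1, m2 = h1.markers, h2.markers
    if not (
        np.array_equal(m1.marker_id, m2.marker_id)
        and np.array_equal(m1.pos_bp, m2.pos_bp)
        and np.array_equal(m1.chrom, m2.chrom)
    ):
        raise ValueError("the two panels must share one marker map")

    ies1, st1 = _ies_per_marker(h1, cutoff, border_policy, max_gap)
    ies2, st2 = _ies_per_marker(h2, cutoff, border_policy, max_gap)
    status = np.where(st1 == "ok", st2, st1)
    ok = status == "ok"
    raw = np.full(m1.n_markers, np.nan)
    raw[ok] = np.log(ies1[ok] / ies2[ok])
    if not ok.any():
        raise ValueError("no marker scorable in both populations")

    out: dict[str, pd.DataFrame] = {}
    for mode in ("rsb", "xpehh"):
        center = np.median(raw[ok]) if mode == "rsb" else raw[ok].mean()
        sd = raw[ok].std()
        z = np.full(m1.n_markers, np.nan)
        z[ok] = (raw[ok] - center) / sd if sd > 0 else 0.0
        pscore = p_transform(z)
        log.info(
            "crosspop_scores[%s]: %d markers in, %d scored (%d dropped)",
            mode, m1.n_markers, int(ok.sum()), int((~ok).sum()),
        )
        out[mode] = pd.DataFrame(
            {
                "marker_id": m1.marker_id,
                "chrom": m1.chrom,
                "pos_bp": m1.pos_bp,
                "ies_pop1": ies1,
                "ies_pop2": ies2,
                "raw": raw,
                "z": z,
                "pscore": pscore,
                "status": status,
            }
        )
    return out
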