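"""Quality control: marker/sample filters, PIHAT relatedness, LD pruning.

The filter chain is fixed as markers -> samples -> relatedness -> LD, and
every stage reports input/output counts so the data reduction is auditable.
Thresholds follow common SNP-array practice: markers with MAF <= 0.01 or
call rate <= 0.95 removed, samples with > 5% missing calls removed, one
member of any pair with PIHAT >= 0.15 removed, and greedy 50-SNP/5-step
r^2 > 0.5 LD pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class MarkerQCReport:
    """Per-marker MAF/call-rate statistics and keep/remove decisions."""

    table: pd.DataFrame  # marker_id, maf, call_rate, kept, reason

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    @property
    def n_removed(self) -> int:
        return int((~self.table["kept"]).sum())


@dataclass
class RelatednessMatrix:
    """Pairwise method-of-moments IBD estimates.

    ``pihat[i, j]`` = P(IBD=2) + 0.5 P(IBD=1) for the sample pair; undefined
    pairs (no jointly observed markers) are NaN and flagged.  Per-sample
    genotype missingness is carried along for the pruning tie-breaks.
    """

    sample_ids: list[str]
    pihat: np.ndarray
    ibs_counts: np.ndarray  # n x n x 3 (IBS0, IBS1, IBS2 marker counts)
    missing_rate: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        i, j = np.where(np.isnan(np.triu(self.pihat, 1)) & np.triu(np.ones_like(self.pihat, bool), 1))
        return [(self.sample_ids[a], self.sample_ids[b]) for a, b in zip(i, j)]


def filter_markers(
    g: GenotypeMatrix, maf_min: float = 0.01, call_rate_min: float = 0.95
) -> tuple[GenotypeMatrix, MarkerQCReport]:
    """Remove markers with MAF <= ``maf_min`` or call rate <= ``call_rate_min``.

    Both cutoffs are inclusive removals (a marker exactly at the threshold is
    removed).  MAF is computed over non-missing calls only.  The report lists
    the first-triggered reason, MAF before call rate.
    """
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must lie in [0, 0.5)")
    if not (0 < call_rate_min <= 1):
        raise ValueError("call_rate_min must lie in (0, 1]")
    if g.n_markers == 0 or g.n_samples == 0:
        raise ValueError("empty genotype matrix")

    maf = g.maf()
    cr = g.call_rate()
    low_maf = np.nan_to_num(maf, nan=0.0) <= maf_min
    low_cr = cr <= call_rate_min
    kept = ~(low_maf | low_cr)
    reason = np.where(low_maf, "maf", np.where(low_cr, "call_rate", ""))
    report = MarkerQCReport(
        pd.DataFrame(
            {
                "marker_id": g.markers.marker_id,
                "maf": maf,
                "call_rate": cr,
                "kept": kept,
                "reason": reason,
            }
        )
    )
    log.info("filter_markers: %d -> %d markers", g.n_markers, int(kept.sum()))
    return g.subset_markers(np.flatnonzero(kept)), report


def filter_samples(g: GenotypeMatrix, max_missing: float = 0.05) -> GenotypeMatrix:
    """Remove samples with strictly more than ``max_missing`` missing calls."""
    if not (0 <= max_missing < 1):
        raise ValueError("max_missing must lie in [0, 1)")
    rate = g.sample_missing_rate()
    keep = rate <= max_missing
    if not keep.any():
        raise ValueError("sample filter removed every sample")
    log.info("filter_samples: %d -> %d samples", g.n_samples, int(keep.sum()))
    return g.subset_samples(np.flatnonzero(keep))


def _ibs_state_expectations(p: np.ndarray) -> np.ndarray:
    """Per-marker P(IBS state | IBD state) under HWE with allele freq ``p``.

    Returns an array (markers, 3 IBS states, 3 IBD states)."""
    q = 1.0 - p
    e = np.zeros((len(p), 3, 3))
    e[:, 0, 0] = 2 * p**2 * q**2
    e[:, 1, 0] = 4 * p**3 * q + 4 * p * q**3
    e[:, 2, 0] = p**4 + 4 * p**2 * q**2 + q**4
    e[:, 1, 1] = 2 * p**2 * q + 2 * p * q**2
    e[:, 2, 1] = p**3 + q**3 + p * q
    e[:, 2, 2] = 1.0
    return e


def pihat_matrix(g: GenotypeMatrix) -> RelatednessMatrix:
    """Method-of-moments IBD sharing (PIHAT) for every sample pair.

    For each pair, observed IBS0/1/2 marker counts are compared with their
    expectations under the sample allele frequencies to solve for
    P(IBD=0,1,2); estimates are truncated to [0,1] and renormalized, and
    PIHAT = P(IBD=2) + 0.5 P(IBD=1).  Monomorphic markers are uninformative
    and skipped.  Intended to be run within one population at a time.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples to estimate relatedness")
    calls = g.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    alt = np.where(obs, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
    informative = np.isfinite(p) & (p > 0) & (p < 1)
    p = p[informative]
    calls = calls[:, informative]
    obs = obs[:, informative]
    e = _ibs_state_expectations(p)

    n = g.n_samples
    pihat = np.full((n, n), np.nan)
    np.fill_diagonal(pihat, 1.0)
    ibs_counts = np.zeros((n, n, 3), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            joint = obs[i] & obs[j]
            if not joint.any():
                continue  # undefined pair: PIHAT stays NaN
            diff = np.abs(calls[i, joint].astype(int) - calls[j, joint].astype(int))
            ibs = 2 - diff
            counts = np.bincount(ibs, minlength=3).astype(float)
            esum = e[joint].sum(axis=0)  # (3 IBS, 3 IBD)
            z0 = counts[0] / esum[0, 0] if esum[0, 0] > 0 else 0.0
            z1 = (counts[1] - z0 * esum[1, 0]) / esum[1, 1] if esum[1, 1] > 0 else 0.0
            z2 = (counts[2] - z0 * esum[2, 0] - z1 * esum[2, 1]) / esum[2, 2]
            z = np.clip(np.array([z0, z1, z2]), 0.0, 1.0)
            total = z.sum()
            z = z / total if total > 0 else np.array([1.0, 0.0, 0.0])
            ph = z[2] + 0.5 * z[1]
            pihat[i, j] = pihat[j, i] = ph
            ibs_counts[i, j] = ibs_counts[j, i] = counts.astype(np.int64)
    return RelatednessMatrix(list(g.sample_ids), pihat, ibs_counts, g.sample_missing_rate())


def prune_related(r: RelatednessMatrix, pihat_max: float = 0.15) -> list[str]:
    """Greedily remove one member of each pair with PIHAT >= ``pihat_max``.

    While any kept pair is at or above the cutoff, the member removed is the
    one with (in tie-break order) higher genotype missingness, higher mean
    PIHAT to the remaining samples, then the lexicographically later sample
    id — a fully deterministic rule.  Returns the kept sample ids in input
    order.
    """
    n = r.n_samples
    miss = r.missing_rate if len(r.missing_rate) == n else np.zeros(n)
    kept = list(range(n))
    pihat = np.nan_to_num(r.pihat, nan=0.0)

    while True:
        over = [
            (i, j)
            for ai, i in enumerate(kept)
            for j in kept[ai + 1 :]
            if pihat[i, j] >= pihat_max
        ]
        if not over:
            break

        def mean_pihat(i: int) -> float:
            others = [k for k in kept if k != i]
            return float(np.mean([pihat[i, k] for k in others])) if others else 0.0

        # candidates: every sample in an offending pair; remove the "worst" one
        cand = sorted({i for pair in over for i in pair})
        worst = max(
            cand,
            key=lambda i: (round(miss[i], 12), round(mean_pihat(i), 12), r.sample_ids[i]),
        )
        kept.remove(worst)
    return [r.sample_ids[i] for i in kept]


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of {0,1,2} dosages over jointly observed calls."""
    joint = (a != MISSING) & (b != MISSING)
    if joint.sum() < 2:
        return 0.0
    x = a[joint].astype(float)
    y = b[joint].astype(float)
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    rho = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(rho * rho)


def ld_prune(
    g: GenotypeMatrix,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.5,
) -> np.ndarray:
    """Greedy within-chromosome LD pruning; returns kept marker indices.

    Scans ``window``-marker windows advancing ``step`` markers; within a
    window, any kept pair with dosage r^2 > ``r2_max`` loses its lower-MAF
    member (tie: later position).  Passes repeat until stable, so the kept
    set is idempotent under re-pruning.  Markers on different chromosomes
    are never compared.
    """
    if step > window:
        raise ValueError("step must not exceed window")
    maf = np.nan_to_num(g.maf(), nan=0.0)
    kept = np.ones(g.n_markers, dtype=bool)
    chroms = g.markers.chrom

    complete = not (g.calls == MISSING).any()

    def window_r2(win: list[int]) -> np.ndarray | None:
        """r^2 matrix over the window's markers, or None to fall back per-pair."""
        if not complete:
            return None
        x = g.calls[:, win].astype(float)
        sd = x.std(axis=0)
        if (sd == 0).any():
            x = x.copy()
            x[:, sd == 0] = 0.0
            sd = np.where(sd == 0, 1.0, sd)
        xc = (x - x.mean(axis=0)) / sd
        return (xc.T @ xc / x.shape[0]) ** 2

    changed = True
    while changed:
        changed = False
        for c in pd.unique(chroms):
            idx = np.flatnonzero(chroms == c)
            start = 0
            while start < len(idx):
                win = [i for i in idx[start : start + window] if kept[i]]
                r2 = window_r2(win)
                for a in range(len(win)):
                    if not kept[win[a]]:
                        continue
                    for b in range(a + 1, len(win)):
                        i, j = win[a], win[b]
                        if not (kept[i] and kept[j]):
                            continue
                        val = r2[a, b] if r2 is not None else _dosage_r2(g.calls[:, i], g.calls[:, j])
                        if val > r2_max:
                            if maf[i] < maf[j]:
                                drop = i
                            elif maf[j] < maf[i]:
                                drop = j
                            else:  # tie: drop the later-position marker
                                drop = j
                            kept[drop] = False
                            changed = True
                start += step
    log.info("ld_prune: %d -> %d markers", g.n_markers, int(kept.sum()))
    return np.flatnonzero(kept)
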