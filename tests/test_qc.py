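"""QC filters, PIHAT relatedness estimation, LD pruning."""

import numpy as np
import pytest

from ehhscan import qc
from ehhscan.types import MISSING

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# marker / sample filters


def test_monomorphic_marker_removed():
    calls = np.ones((10, 3), dtype=np.int8)
    calls[:, 0] = 0  # monomorphic: maf = 0
    calls[:5, 1] = 0  # maf 0.5
    calls[:5, 2] = 2
    g, report = qc.filter_markers(make_genotypes(calls))
    assert g.n_markers == 2
    row = report.table.set_index("marker_id").loc["m0"]
    assert not row.kept and row.reason == "maf"


def test_low_call_rate_marker_removed():
    calls = np.tile(np.array([0, 2], dtype=np.int8), (10, 1)).T.copy()
    calls = np.column_stack([calls[:, [0]], calls]).astype(np.int8)
    calls = np.repeat(np.array([[0], [2]], dtype=np.int8), 5, axis=0)
    calls = np.hstack([calls, calls])
    calls[0, 1] = MISSING  # call rate 0.9 <= 0.95
    g, report = qc.filter_markers(make_genotypes(calls))
    assert list(g.markers.marker_id) == ["m0"]
    assert report.table.set_index("marker_id").loc["m1", "reason"] == "call_rate"


def test_marker_filter_matches_bruteforce_recount(rng):
    calls = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.08] = MISSING
    g = make_genotypes(calls)
    kept, _ = qc.filter_markers(g, 0.1, 0.9)
    expect = []
    for j in range(50):
        col = calls[:, j]
        obs = col[col != MISSING]
        p = obs.sum() / (2 * len(obs))
        maf = min(p, 1 - p)
        cr = len(obs) / 20
        if not (maf <= 0.1 or cr <= 0.9):
            expect.append(f"m{j}")
    assert list(kept.markers.marker_id) == expect


@pytest.mark.parametrize("n_missing,kept", [(6, False), (5, True)])
def test_sample_missingness_boundary(n_missing, kept):
    calls = np.tile(np.array([0, 1, 2, 1], dtype=np.int8), (3, 25))
    calls[0, :n_missing] = MISSING  # out of 100 markers
    g = qc.filter_samples(make_genotypes(calls), 0.05)
    assert ("s0" in g.sample_ids) is kept


# ---------------------------------------------------------------------------
# PIHAT


def _hwe_genotypes(rng, n_markers=2000):
    p = rng.uniform(0.1, 0.9, n_markers)
    def draw():
        return (rng.random(n_markers) < p).astype(np.int8) + (rng.random(n_markers) < p).astype(np.int8)
    return p, draw


def test_pihat_grades(rng):
    """Duplicate ~ 1, parent-offspring ~ 0.5, unrelated ~ 0."""
    p, draw = _hwe_genotypes(rng)
    a = draw()
    dup = a.copy()
    unrel = draw()
    # child: one allele from parent a, one from the population
    from_parent = np.where(rng.random(len(p)) < 0.5, (a > 0).astype(np.int8), (a > 1).astype(np.int8))
    child = from_parent + (rng.random(len(p)) < p).astype(np.int8)
    g = make_genotypes(np.vstack([a, dup, unrel, child]))
    rel = qc.pihat_matrix(g)
    ids = rel.sample_ids
    ph = {(ids[i], ids[j]): rel.pihat[i, j] for i in range(4) for j in range(4)}
    assert abs(ph[("s0", "s1")] - 1.0) < 0.02
    assert abs(ph[("s0", "s2")]) < 0.05
    assert abs(ph[("s0", "s3")] - 0.5) < 0.05
    assert np.allclose(rel.pihat, rel.pihat.T, equal_nan=True)


def test_pihat_monotone_in_relatedness_grade(rng):
    """unrelated < half sib < parent-offspring < duplicate, over replicates."""
    wins = 0
    reps = 20
    for _ in range(reps):
        p, draw = _hwe_genotypes(rng, 1200)
        a = draw()
        unrel = draw()
        par = np.where(rng.random(len(p)) < 0.5, (a > 0), (a > 1)).astype(np.int8) + (
            rng.random(len(p)) < p
        ).astype(np.int8)
        # half sib: share one parent's transmitted allele half the time
        shared = np.where(rng.random(len(p)) < 0.5, (a > 0), (a > 1)).astype(np.int8)
        half1 = shared + (rng.random(len(p)) < p).astype(np.int8)
        transmit2 = np.where(rng.random(len(p)) < 0.5, shared, (rng.random(len(p)) < p).astype(np.int8))
        half2 = transmit2 + (rng.random(len(p)) < p).astype(np.int8)
        g = make_genotypes(np.vstack([a, unrel, half1, half2, par, a.copy()]))
        rel = qc.pihat_matrix(g)
        vals = [rel.pihat[0, 1], rel.pihat[2, 3], rel.pihat[0, 4], rel.pihat[0, 5]]
        if vals[0] < vals[1] < vals[2] < vals[3]:
            wins += 1
    assert wins >= reps - 2


def test_pihat_undefined_pair_flagged():
    calls = np.array([[0, MISSING, 1, 2], [MISSING, 1, MISSING, MISSING], [0, 1, 2, 0]], dtype=np.int8)
    calls = np.hstack([calls] * 3)
    calls[1, :] = MISSING
    calls[1, 1] = 1
    calls[0, 1] = MISSING
    rel = qc.pihat_matrix(make_genotypes(calls))
    assert ("s0", "s1") in rel.undefined_pairs()


# ---------------------------------------------------------------------------
# relatedness pruning


def _rel(ids, pairs, miss=None):
    n = len(ids)
    ph = np.zeros((n, n))
    np.fill_diagonal(ph, 1.0)
    for (a, b), v in pairs.items():
        i, j = ids.index(a), ids.index(b)
        ph[i, j] = ph[j, i] = v
    return qc.RelatednessMatrix(ids, ph, np.zeros((n, n, 3), int), np.array(miss or [0.0] * n))


def test_prune_removes_higher_mean_pihat_member():
    rel = _rel(["A", "B", "C"], {("A", "B"): 0.2, ("B", "C"): 0.1})
    assert qc.prune_related(rel) == ["A", "C"]  # B has higher mean PIHAT


def test_prune_triangle_single_removal_suffices():
    rel = _rel(["A", "B", "C"], {("A", "B"): 0.2, ("B", "C"): 0.3, ("A", "C"): 0.05})
    assert qc.prune_related(rel) == ["A", "C"]


def test_prune_missingness_tiebreak_first():
    rel = _rel(["A", "B"], {("A", "B"): 0.2}, miss=[0.04, 0.01])
    assert qc.prune_related(rel) == ["B"]  # A removed: higher missingness


def test_prune_noop_below_threshold():
    rel = _rel(["A", "B", "C"], {("A", "B"): 0.14})
    assert qc.prune_related(rel) == ["A", "B", "C"]


# ---------------------------------------------------------------------------
# LD pruning


def test_identical_markers_one_removed(rng):
    col = rng.integers(0, 3, 30).astype(np.int8)
    other = rng.integers(0, 3, 30).astype(np.int8)
    g = make_genotypes(np.column_stack([col, col, other]))
    kept = qc.ld_prune(g)
    assert 0 in kept and 1 not in kept  # later-position duplicate dropped


def test_cross_chromosome_pairs_never_compared(rng):
    col = rng.integers(0, 3, 30).astype(np.int8)
    calls = np.column_stack([col, col])
    g = make_genotypes(calls)
    g.markers = __import__("conftest").make_map(2)
    chroms = g.markers.chrom.copy()
    chroms[1] = "2"
    from ehhscan.types import MarkerMap

    g.markers = MarkerMap(g.markers.marker_id, chroms, g.markers.pos_bp, g.markers.allele1, g.markers.allele2)
    assert len(qc.ld_prune(g)) == 2


def test_ld_prune_invariant_and_idempotent(rng):
    # correlated blocks: each block copies one column with noise
    base = rng.integers(0, 3, size=(40, 40)).astype(np.int8)
    cols = []
    for j in range(40):
        cols.append(base[:, j])
        noisy = base[:, j].copy()
        flip = rng.random(40) < 0.1
        noisy[flip] = rng.integers(0, 3, flip.sum())
        cols.append(noisy)
    g = make_genotypes(np.column_stack(cols)[:, :200] if len(cols) > 200 else np.column_stack(cols))
    kept = qc.ld_prune(g, window=50, step=5, r2_max=0.5)
    gk = g.subset_markers(kept)

    # oracle rescan: no evaluated within-window pair may exceed r2_max
    for start in range(0, gk.n_markers, 5):
        win = list(range(start, min(start + 50, gk.n_markers)))
        for a in range(len(win)):
            for b in range(a + 1, len(win)):
                r2 = qc._dosage_r2(gk.calls[:, win[a]], gk.calls[:, win[b]])
                assert r2 <= 0.5 + 1e-12

    # idempotence
    assert len(qc.ld_prune(gk, window=50, step=5, r2_max=0.5)) == gk.n_markers
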