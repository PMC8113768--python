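"""EHH/EHHS decay, integration, iHS/Rsb/XP-EHH scores, p transform."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from ehhscan import ehh
from ehhscan.polarize import polarize_panel
from ehhscan.types import PolarizedPanel

from conftest import make_panel, random_panel
from oracles import ehh_oracle, ehhs_oracle


# ---------------------------------------------------------------------------
# decay curves


def test_ehh_is_one_at_focal_and_direct_combinatorics():
    # 4 derived carriers split into classes {3,1} one marker to the right
    alleles = np.array(
        [
            [1, 0],
            [1, 0],
            [1, 0],
            [1, 1],
            [0, 0],
            [0, 1],
        ],
        dtype=np.uint8,
    )
    c = ehh.ehh_decay(make_panel(alleles), 0, 1)
    assert c.right_ehh[0] == 1.0
    assert c.right_ehh[1] == pytest.approx((3 * 2 + 0) / (4 * 3))  # = 0.5


def test_ehh_needs_two_carriers():
    alleles = np.array([[1, 0], [0, 0], [0, 1], [0, 1]], dtype=np.uint8)
    with pytest.raises(ValueError, match="carriers"):
        ehh.ehh_decay(make_panel(alleles), 0, 1)


def test_ehhs_identical_haplotypes_flat_and_truncated():
    alleles = np.tile(np.array([1, 0, 1, 1, 0], dtype=np.uint8), (6, 1))
    c = ehh.ehhs_decay(make_panel(alleles), 2)
    assert np.all(c.left_ehh == 1.0) and np.all(c.right_ehh == 1.0)
    assert c.left_truncated and c.right_truncated


def test_ehhs_starts_at_one_with_balanced_classes(rng):
    panel = random_panel(rng, n_hap=12, n_markers=9)
    panel.alleles[:, 4] = np.repeat([0, 1], 6)
    c = ehh.ehhs_decay(panel, 4)
    assert c.left_ehh[0] == 1.0 and c.right_ehh[0] == 1.0


@pytest.mark.parametrize("seed", range(6))
def test_decay_curves_match_bruteforce_oracle(seed):
    rng = np.random.default_rng(1000 + seed)
    panel = random_panel(rng, n_hap=30, n_markers=200)
    f = int(rng.integers(5, 195))
    code = int(panel.alleles[:, f].mean() >= 0.5)  # the common allele has >= 2 carriers
    c = ehh.ehh_decay(panel, f, code)
    (lp, lv, ltr), (rp, rv, rtr) = ehh_oracle(panel, f, code)
    assert list(c.left_pos) == lp and list(c.right_pos) == rp
    assert np.allclose(c.left_ehh, lv) and np.allclose(c.right_ehh, rv)
    assert (c.left_truncated, c.right_truncated) == (ltr, rtr)

    s = ehh.ehhs_decay(panel, f)
    (lp, lv, ltr), (rp, rv, rtr) = ehhs_oracle(panel, f)
    assert list(s.left_pos) == lp and list(s.right_pos) == rp
    assert np.allclose(s.left_ehh, lv) and np.allclose(s.right_ehh, rv)
    assert (s.left_truncated, s.right_truncated) == (ltr, rtr)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_decay_curve_invariants(seed):
    """EHH curves live in [0,1], start at 1 and never increase outward."""
    rng = np.random.default_rng(seed)
    panel = random_panel(rng, n_hap=16, n_markers=40)
    f = int(rng.integers(0, 40))
    code = int(panel.alleles[:, f].mean() >= 0.5)
    c = ehh.ehh_decay(panel, f, code)
    for side in (c.left_ehh, c.right_ehh):
        assert side[0] == 1.0
        assert np.all((side >= 0) & (side <= 1))
        assert np.all(np.diff(side) <= 1e-12)


# ---------------------------------------------------------------------------
# integration


def _curve_one_side(positions, values, cutoff=0.05, truncated=None):
    pos = np.asarray(positions)
    val = np.asarray(values, dtype=float)
    if truncated is None:
        truncated = val[-1] >= cutoff
    return ehh.DecayCurve(
        "m", "1", int(pos[0]),
        np.array([pos[0]]), np.array([1.0]),
        pos, val, cutoff,
        left_truncated=True, right_truncated=truncated,
    )


def test_integrate_interpolates_cutoff_crossing():
    # one side {0: 1, 10_000: 0}: crossing at 9_500, area = 0.5*(1+0.05)*9_500
    c = _curve_one_side([0, 10_000], [1.0, 0.0])
    assert ehh.integrate_decay(c, "keep") == pytest.approx(4987.5)


def test_integrate_discards_border_truncated():
    c = _curve_one_side([0, 10_000], [1.0, 0.5], truncated=True)
    assert np.isnan(ehh.integrate_decay(c, "discard"))


def test_integrate_keep_is_at_least_clipped_area():
    crossing = _curve_one_side([0, 10_000], [1.0, 0.0])
    kept = _curve_one_side([0, 10_000], [1.0, 0.5], truncated=True)
    assert ehh.integrate_decay(kept, "keep") >= ehh.integrate_decay(crossing, "keep")


# ---------------------------------------------------------------------------
# p transform


def test_p_transform_oracle_values():
    assert ehh.p_transform(0.0) == pytest.approx(0.0, abs=1e-12)
    # two-sided p = 0.05 at |z| = 1.959964
    assert ehh.p_transform(1.959964) == pytest.approx(1.30103, abs=1e-4)
    assert ehh.p_transform(-1.959964) == pytest.approx(1.30103, abs=1e-4)
    # invert: the 2.5 significance threshold corresponds to this z cutoff
    z_star = norm.isf(0.5 * 10**-2.5)
    assert z_star == pytest.approx(2.9515, abs=1e-3)
    assert ehh.p_transform(z_star) == pytest.approx(2.5, abs=1e-9)


def test_p_transform_extreme_scores_stay_finite():
    out = ehh.p_transform(np.array([-50.0, 50.0, 8.0]))
    assert np.all(np.isfinite(out))
    assert out[0] == out[1] > out[2] > 0


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.floats(0, 30), st.floats(0, 30))
def test_p_transform_monotone_in_magnitude(a, b):
    lo, hi = sorted((a, b))
    assert ehh.p_transform(hi) >= ehh.p_transform(lo) - 1e-12


# ---------------------------------------------------------------------------
# iHS


def test_ihs_mirror_symmetric_marker_has_zero_raw(rng):
    # derived carriers are an exact mirror (0<->1 flip) of ancestral carriers,
    # so iHH_A == iHH_D at the focal marker
    half = (rng.random((8, 61)) < 0.5).astype(np.uint8)
    alleles = np.vstack([half, 1 - half])
    panel = make_panel(alleles)
    f = 30
    pp = PolarizedPanel(panel, panel.alleles.mean(axis=0))
    ca = ehh.ehh_decay(pp, f, "ancestral")
    cd = ehh.ehh_decay(pp, f, "derived")
    a = ehh.integrate_decay(ca, "keep")
    d = ehh.integrate_decay(cd, "keep")
    assert a == pytest.approx(d, rel=1e-12)


def test_ihs_bin_moments_are_standard(rng):
    panel = random_panel(rng, n_hap=40, n_markers=400, spacing=2000)
    pp = PolarizedPanel(panel, panel.alleles.mean(axis=0))
    tab = ehh.ihs_scores(pp, border_policy="keep", bins=10, min_bin=15)
    ok = tab[tab.status == "ok"]
    for _, grp in ok.groupby("bin"):
        assert abs(grp.z.mean()) < 1e-8
        assert abs(grp.z.std(ddof=0) - 1) < 1e-8
    assert np.isfinite(ok.pscore).all()


# ---------------------------------------------------------------------------
# cross-population scores


def test_crosspop_identity_gives_zero_raw(rng):
    panel = random_panel(rng, n_hap=20, n_markers=80, spacing=3000)
    tab = ehh.crosspop_scores(panel, panel, "rsb", border_policy="keep")
    ok = tab[tab.status == "ok"]
    assert len(ok) > 0
    assert np.allclose(ok.raw, 0.0)


def test_crosspop_swap_negates_raw(rng):
    h1 = random_panel(rng, n_hap=20, n_markers=80, spacing=3000)
    h2 = make_panel(
        (np.random.default_rng(7).random((24, 80)) < 0.5).astype(np.uint8),
        markers=h1.markers,
    )
    fwd = ehh.crosspop_scores(h1, h2, "xpehh", border_policy="keep")
    rev = ehh.crosspop_scores(h2, h1, "xpehh", border_policy="keep")
    ok = fwd.status == "ok"
    assert (rev.status == "ok").equals(fwd.status == "ok")
    assert np.allclose(fwd.raw[ok], -rev.raw[ok].to_numpy())


def test_crosspop_standardization_moments(rng):
    h1 = random_panel(rng, n_hap=20, n_markers=120, spacing=2500)
    h2 = make_panel(
        (np.random.default_rng(8).random((20, 120)) < 0.5).astype(np.uint8),
        markers=h1.markers,
    )
    both = ehh.crosspop_scores_both(h1, h2, border_policy="keep")
    rsb_ok = both["rsb"][both["rsb"].status == "ok"]
    xp_ok = both["xpehh"][both["xpehh"].status == "ok"]
    assert abs(np.median(rsb_ok.z)) < 1e-8
    assert abs(rsb_ok.z.std(ddof=0) - 1) < 1e-8
    assert abs(xp_ok.z.mean()) < 1e-8
    assert abs(xp_ok.z.std(ddof=0) - 1) < 1e-8


def test_crosspop_requires_shared_map(rng):
    h1 = random_panel(rng, n_hap=10, n_markers=20)
    h2 = random_panel(rng, n_hap=10, n_markers=20)
    with pytest.raises(ValueError, match="share"):
        ehh.crosspop_scores(h1, h2, "rsb")
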