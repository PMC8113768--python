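"""IBS/difference distances, classical MDS, neighbor joining."""

import io

import dendropy
import numpy as np
import pytest

from ehhscan import structure as st
from ehhscan.types import MISSING

from conftest import make_genotypes


# ---------------------------------------------------------------------------
# distances


def test_ibs_distance_limits(rng):
    m = 15
    a = rng.integers(0, 3, m).astype(np.int8)
    opposite = (2 - a).astype(np.int8)
    g = make_genotypes(np.vstack([a, a.copy(), np.where(a == 1, 1, opposite)]))
    d = st.ibs_distance(g)
    assert d.values[0, 1] == 0.0  # identical samples
    # fully discordant hom-hom pairs give distance 1
    g2 = make_genotypes(np.vstack([np.zeros(m, np.int8), np.full(m, 2, np.int8)]))
    assert st.ibs_distance(g2).values[0, 1] == 1.0


def test_ibs_distance_matches_hand_enumeration(rng):
    calls = rng.integers(0, 3, size=(2, 20)).astype(np.int8)
    calls[0, 3] = MISSING
    d = st.ibs_distance(make_genotypes(calls)).values[0, 1]
    shared = tot = 0
    for j in range(20):
        if MISSING in (calls[0, j], calls[1, j]):
            continue
        shared += 2 - abs(int(calls[0, j]) - int(calls[1, j]))
        tot += 2
    assert d == pytest.approx(1 - shared / tot)


def test_diff_count_distance(rng):
    calls = rng.integers(0, 3, size=(2, 30)).astype(np.int8)
    calls[1, 5] = MISSING
    d = st.diff_count_distance(make_genotypes(calls)).values[0, 1]
    expect = sum(
        1
        for j in range(30)
        if MISSING not in (calls[0, j], calls[1, j]) and calls[0, j] != calls[1, j]
    )
    assert d == expect
    ident = make_genotypes(np.vstack([calls[0], calls[0]]))
    assert st.diff_count_distance(ident).values[0, 1] == 0


def test_disjoint_missingness_is_an_error():
    calls = np.array([[0, MISSING], [MISSING, 1]], dtype=np.int8)
    with pytest.raises(ValueError, match="jointly"):
        st.ibs_distance(make_genotypes(calls))


# ---------------------------------------------------------------------------
# classical MDS


def _dist_matrix(vals, ids=None):
    vals = np.asarray(vals, float)
    ids = ids or [f"s{i}" for i in range(len(vals))]
    return st.DistanceMatrix(ids, vals, "one_minus_ibs")


def test_mds_three_equidistant_points():
    d = _dist_matrix(np.ones((3, 3)) - np.eye(3))
    mds = st.classical_mds(d, k=2)
    emb = mds.coords
    pair = [np.linalg.norm(emb[i] - emb[j]) for i, j in [(0, 1), (0, 2), (1, 2)]]
    assert max(pair) - min(pair) < 1e-9


def test_mds_recovers_euclidean_configuration(rng):
    pts = rng.normal(size=(12, 2))
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    mds = st.classical_mds(_dist_matrix(D), k=2)
    emb = mds.coords
    De = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
    assert np.max(np.abs(De - D)) < 1e-6
    assert mds.eigenvalues[0] >= mds.eigenvalues[1] > 0


def test_mds_truncates_to_positive_eigenvalues():
    d = _dist_matrix(np.ones((3, 3)) - np.eye(3))
    mds = st.classical_mds(d, k=5)
    assert mds.coords.shape[1] == 2  # only 2 positive dimensions exist


def test_mds_sign_convention_reproducible(rng):
    pts = rng.normal(size=(8, 2))
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    a = st.classical_mds(_dist_matrix(D), k=2).coords
    b = st.classical_mds(_dist_matrix(D.copy()), k=2).coords
    assert np.array_equal(a, b)
    for dim in range(2):
        assert a[np.argmax(np.abs(a[:, dim])), dim] > 0


# ---------------------------------------------------------------------------
# neighbor joining


def _patristic(newick):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return lambda a, b: pdm.distance(taxa[a], taxa[b])


def test_nj_three_taxa_closed_form():
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
    tree = st.neighbor_joining(st.DistanceMatrix(["A", "B", "C"], D, "diff_count"))
    lengths = {child.name: bl for child, bl in tree.children}
    assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(2.0), "C": pytest.approx(3.0)}


def test_nj_recovers_four_taxon_tree():
    # unrooted tree: A-1-x, B-2-x, x-1-y, C-3-y, D-4-y
    ids = ["A", "B", "C", "D"]
    D = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
    )
    tree = st.neighbor_joining(st.DistanceMatrix(ids, D, "diff_count"))
    dist = _patristic(tree.to_newick())
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            assert dist(a, b) == pytest.approx(D[ids.index(a), ids.index(b)], abs=1e-9)


def _random_additive_tree(rng, n=6):
    """Random unrooted binary tree over n taxa; returns its distance matrix."""
    import itertools

    nodes = {i: [] for i in range(n)}  # node -> list of (neighbor, length)
    next_id = n
    active = list(range(n))
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        a, b = active[i], active[j]
        u = next_id
        next_id += 1
        nodes[u] = []
        for x in (a, b):
            w = float(rng.uniform(0.1, 3.0))
            nodes[u].append((x, w))
            nodes[x].append((u, w))
        active = [x for x in active if x not in (a, b)] + [u]
    w = float(rng.uniform(0.1, 3.0))
    a, b = active
    nodes[a].append((b, w))
    nodes[b].append((a, w))

    def path_len(s, t):
        seen = {s}
        stack = [(s, 0.0)]
        while stack:
            x, acc = stack.pop()
            if x == t:
                return acc
            for y, wl in nodes[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append((y, acc + wl))
        raise AssertionError

    D = np.zeros((n, n))
    for s, t in itertools.combinations(range(n), 2):
        D[s, t] = D[t, s] = path_len(s, t)
    return D


@pytest.mark.parametrize("seed", range(20))
def test_nj_consistent_on_additive_matrices(seed):
    """NJ recovers random additive 6-taxon trees exactly (patristic == input)."""
    rng = np.random.default_rng(3000 + seed)
    D = _random_additive_tree(rng, 6)
    ids = list("ABCDEF")
    tree = st.neighbor_joining(st.DistanceMatrix(ids, D, "diff_count"))
    dist = _patristic(tree.to_newick())
    for i in range(6):
        for j in range(i + 1, 6):
            assert dist(ids[i], ids[j]) == pytest.approx(D[i, j], abs=1e-9)


def test_nj_matches_skbio_on_additive_matrix():
    """Independent cross-check of the NJ topology against scikit-bio."""
    skbio_tree = pytest.importorskip("skbio.tree")
    from skbio import DistanceMatrix as SkDM

    rng = np.random.default_rng(77)
    D = _random_additive_tree(rng, 7)
    ids = list("ABCDEFG")
    ours = st.neighbor_joining(st.DistanceMatrix(ids, D, "diff_count"))
    ref = skbio_tree.nj(SkDM(D, ids))
    t1 = dendropy.Tree.get(data=ours.to_newick(), schema="newick")
    taxa = t1.taxon_namespace
    t2 = dendropy.Tree.get(data=str(ref), schema="newick", taxon_namespace=taxa)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


def test_nj_rejects_asymmetric_input():
    D = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], float)
    with pytest.raises(ValueError, match="symmetric"):
        st.neighbor_joining(st.DistanceMatrix(["a", "b", "c"], D, "diff_count"))


# ---------------------------------------------------------------------------
# two-population properties on simulated data


@pytest.fixture(scope="module")
def two_pop_genotypes():
    from ehhscan import simulate as sim

    cfg = sim.neutral_preset(
        42, n_markers=600, chrom_length_bp=3_000_000, n1=60, n2=60,
        n_founder_haps=240, g0=20, g1=30, n_sample1=20, n_sample2=20,
    )
    p1, p2, _ = sim.simulate_dataset(cfg)
    return sim.combined_genotypes(p1, p2)


def test_mds_dimension_one_separates_populations(two_pop_genotypes):
    g = two_pop_genotypes
    mds = st.classical_mds(st.ibs_distance(g), k=2)
    c1 = mds.coords[:, 0]
    a = c1[g.population_labels == "pop1"]
    b = c1[g.population_labels == "pop2"]
    assert max(a.max(), b.max()) == pytest.approx(c1.max())
    # zero overlap between the two populations along dimension 1
    assert a.min() > b.max() or b.min() > a.max()


def test_nj_two_populations_form_two_clades(two_pop_genotypes):
    g = two_pop_genotypes
    tree = st.neighbor_joining(st.diff_count_distance(g))
    t = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
    pop1 = {s for s, p in zip(g.sample_ids, g.population_labels) if p == "pop1"}
    t.encode_bipartitions()
    split_sets = [
        {tx.label for tx in bip.leafset_taxa(t.taxon_namespace)}
        for bip in t.bipartition_encoding
    ]
    all_labels = {lf.taxon.label for lf in t.leaf_node_iter()}
    assert pop1 in split_sets or (all_labels - pop1) in split_sets
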