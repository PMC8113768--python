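"""Population-structure diagnostics: IBS sharing with classical MDS, and a
neighbor-joining tree on pairwise genotype-difference counts.

These checks justify treating the two groups as distinct populations before
any cross-population haplotype contrast is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances between samples."""

    sample_ids: list[str]
    values: np.ndarray
    kind: str  # "one_minus_ibs" or "diff_count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")


@dataclass
class MDSCoordinates:
    """Principal-coordinate embedding: samples x dimensions, with eigenvalues."""

    sample_ids: list[str]
    coords: np.ndarray  # n x k
    eigenvalues: np.ndarray  # k, decreasing, all positive

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords, columns=[f"C{i + 1}" for i in range(self.coords.shape[1])]
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df


class TreeNode:
    """A node of an (unrooted) NJ tree; leaves carry sample names."""

    def __init__(self, name: str | None = None, children: list | None = None):
        self.name = name
        self.children: list[tuple[TreeNode, float]] = children or []

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out

    def to_newick(self) -> str:
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return self.name
        parts = [f"{c._newick_inner()}:{bl:.17g}" for c, bl in self.children]
        return "(" + ",".join(parts) + ")"


def _pair_masks(g: GenotypeMatrix):
    calls = g.calls
    obs = calls != MISSING
    return calls, obs


def ibs_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """1 - mean identity-by-state allele sharing for every sample pair.

    Per jointly observed marker a pair shares 2, 1 or 0 alleles
    (= 2 - |dosage difference|); the IBS proportion divides the total shared
    by twice the jointly observed marker count.
    """
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    calls, obs = _pair_masks(g)
    n = g.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = obs[i] & obs[j]
            m = int(joint.sum())
            if m == 0:
                raise ValueError(
                    f"samples {g.sample_ids[i]!r} and {g.sample_ids[j]!r} share no "
                    "jointly observed marker"
                )
            shared = (2 - np.abs(calls[i, joint].astype(int) - calls[j, joint].astype(int))).sum()
            d[i, j] = d[j, i] = 1.0 - shared / (2.0 * m)
    return DistanceMatrix(list(g.sample_ids), d, "one_minus_ibs")


def diff_count_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Number of jointly observed markers at which two samples' genotypes differ."""
    if g.n_samples < 2:
        raise ValueError("need at least two samples")
    calls, obs = _pair_masks(g)
    n = g.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            joint = obs[i] & obs[j]
            if not joint.any():
                raise ValueError(
                    f"samples {g.sample_ids[i]!r} and {g.sample_ids[j]!r} share no "
                    "jointly observed marker"
                )
            d[i, j] = d[j, i] = int((calls[i, joint] != calls[j, joint]).sum())
    return DistanceMatrix(list(g.sample_ids), d, "diff_count")


def classical_mds(d: DistanceMatrix, k: int = 2) -> MDSCoordinates:
    """Classical (metric) multidimensional scaling / principal coordinates.

    Double-centers -D^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their eigenvalues.  Dimensions with non-positive
    eigenvalues are dropped (with a warning if that truncates below ``k``).
    The sign of each dimension is fixed by making its largest-magnitude
    loading positive, so output is reproducible across platforms.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    D = d.values
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12 * max(vals.max(), 1.0)
    n_pos = int(pos.sum())
    if n_pos < k:
        log.warning("classical_mds: only %d positive eigenvalues, truncating from k=%d", n_pos, k)
    k_eff = min(k, n_pos)
    vals, vecs = vals[:k_eff], vecs[:, :k_eff]
    coords = vecs * np.sqrt(vals)
    for dim in range(k_eff):
        apex = np.argmax(np.abs(coords[:, dim]))
        if coords[apex, dim] < 0:
            coords[:, dim] *= -1
    return MDSCoordinates(list(d.sample_ids), coords, vals)


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with a deterministic tie-break.

    Agglomerates the pair minimizing the Q criterion (ties broken on the
    lowest (i, j) index pair in current matrix order).  Negative branch
    lengths are clamped to zero and the clamped deficit logged.  Returns an
    unrooted tree represented with a trifurcating root node.
    """
    n = d.values.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least three samples")
    D = d.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=s) for s in d.sample_ids]
    clamped = 0.0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) among minimizers: flat argmin on the upper triangle scan order
        iu = np.triu_indices(m, 1)
        qvals = Q[iu]
        best = int(np.flatnonzero(qvals == qvals.min())[0])
        i, j = int(iu[0][best]), int(iu[1][best])

        li = clamp(0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = clamp(D[i, j] - (0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))))
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])

        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[x] for x in keep] + [new]

    # final three nodes: three-point formulas around a trifurcation
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = clamp(0.5 * (d01 + d02 - d12))
    l1 = clamp(0.5 * (d01 + d12 - d02))
    l2 = clamp(0.5 * (d02 + d12 - d01))
    root = TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    if clamped > 0:
        log.info("neighbor_joining: clamped %.6g of negative branch length to zero", clamped)
    return root
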