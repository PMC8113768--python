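import numpy as np
import pytest

from ehhscan.types import GenotypeMatrix, HaplotypePanel, MarkerMap


def make_map(n, chrom="1", spacing=1000, start=1000):
    pos = start + spacing * np.arange(n)
    return MarkerMap(
        np.array([f"m{i}" for i in range(n)], dtype=object),
        np.array([chrom] * n, dtype=object),
        pos,
        np.array(["A"] * n, dtype=object),
        np.array(["G"] * n, dtype=object),
    )


def make_genotypes(calls, pops=None, chrom="1"):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    ids = [f"s{i}" for i in range(n)]
    pops = np.array(pops if pops is not None else ["p"] * n, dtype=object)
    return GenotypeMatrix(ids, pops, calls, make_map(m, chrom=chrom))


def make_panel(alleles, pops=None, markers=None):
    alleles = np.asarray(alleles, dtype=np.uint8)
    nh, m = alleles.shape
    assert nh % 2 == 0
    ids = [f"s{i}" for i in range(nh // 2)]
    pops = np.array(pops if pops is not None else ["p"] * (nh // 2), dtype=object)
    return HaplotypePanel(ids, pops, alleles, markers if markers is not None else make_map(m))


def random_panel(rng, n_hap=20, n_markers=50, spacing=None):
    """A random phased panel with irregular positions for oracle comparisons."""
    alleles = (rng.random((n_hap, n_markers)) < rng.uniform(0.1, 0.9, n_markers)).astype(np.uint8)
    if spacing is None:
        pos = np.sort(rng.choice(np.arange(1, n_markers * 5000), n_markers, replace=False))
    else:
        pos = 1 + spacing * np.arange(n_markers)
    mm = MarkerMap(
        np.array([f"m{i}" for i in range(n_markers)], dtype=object),
        np.array(["1"] * n_markers, dtype=object),
        pos,
        np.array(["A"] * n_markers, dtype=object),
        np.array(["G"] * n_markers, dtype=object),
    )
    return make_panel(alleles, markers=mm)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
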