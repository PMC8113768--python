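"""Forward-in-time synthetic data: two populations from a common founder
pool, SNP-array-like markers, and an optional selective sweep.

The generator emulates the data a two-breed haplotype scan consumes: a
founder pool with a configurable allele-frequency spectrum and
distance-decaying LD (template-mosaic haplotypes), Wright-Fisher diploid
generations with Poisson recombination and no new mutation (array-ascertained
standing variation), a split into two populations, optional positive
selection on a standing derived allele in population 1 (genotype fitness
1 : 1+s : 1+2s), outgroup species calls equal to the true ancestral allele
with configurable error and missingness, and a ground-truth record for
power/recovery tests.

All randomness flows from a single mandatory seed through named
``numpy.random.default_rng`` streams, so output is reproducible across
platforms.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as eio
from ._kernels import gametes_kernel
from .types import MISSING, GenotypeMatrix, HaplotypePanel, MarkerMap

_NUC = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """All knobs of the synthetic two-population scenario.

    Defaults are desk-scale study conditions: 5,000 markers on a 20-Mb
    chromosome (array-like density), diploid population sizes 800 (breed
    scale, with the recombination rate rescaled so N x r stays realistic),
    50 generations before and after the split, and a sweep preset with
    selection coefficient 0.05 driving a rare standing variant (initial
    frequency 0.05, a near-hard sweep) toward 0.8.  Scan panels sample 70
    and 160 individuals, mirroring the retained test/reference sample sizes
    of a two-breed array study.
    """

    seed: int
    n_markers: int = 5000
    chrom: str = "1"
    chrom_length_bp: int = 20_000_000
    n_founder_haps: int = 3200
    n_templates: int = 12
    founder_beta_a: float = 1.0
    founder_beta_b: float = 1.0
    f_min: float = 0.05
    f_max: float = 0.95
    template_switch_rate: float = 5e-6  # per bp; sets founder LD decay scale
    recomb_rate: float = 1e-7  # per bp per meiosis; rescaled so N * r stays realistic at desk-scale N
    n1: int = 800
    n2: int = 800
    g0: int = 50
    g1: int = 50
    sweep_enabled: bool = False
    s: float = 0.05
    sweep_p0: float = 0.05
    sweep_target_freq: float = 0.8
    sweep_max_extra: int = 150
    sweep_max_retries: int = 20
    n_sample1: int = 70
    n_sample2: int = 160
    outgroup_species: tuple = ("yak", "buffalo", "sheep")
    outgroup_error: float = 0.05
    outgroup_missing: float = 0.02
    mask_rate: float = 0.0  # genotype masking applied when writing PED

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory (no silent entropy)")
        for name in (
            "f_min", "f_max", "sweep_p0", "sweep_target_freq",
            "outgroup_error", "outgroup_missing", "mask_rate",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (self.f_min < self.f_max):
            raise ValueError("f_min must be < f_max")
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        for name in ("n1", "n2", "n_founder_haps", "n_templates"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")
        if self.n_founder_haps % 2:
            raise ValueError("n_founder_haps must be even")
        if self.n_markers < 2 or self.n_markers > self.chrom_length_bp:
            raise ValueError("infeasible marker count for chromosome length")
        if self.n_sample1 > self.n1 or self.n_sample2 > self.n2:
            raise ValueError("cannot sample more individuals than the population holds")

    def to_file(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                v = getattr(self, f.name)
                if isinstance(v, tuple):
                    v = ",".join(v)
                fh.write(f"{f.name}={v}\n")


def neutral_preset(seed: int, **overrides) -> SimConfig:
    """The neutral (s = 0) scenario used for null calibration."""
    return SimConfig(seed=seed, sweep_enabled=False, **overrides)


def sweep_preset(seed: int, **overrides) -> SimConfig:
    """The default sweep scenario: s = 0.05 from p0 = 0.05 toward 0.8 in pop1."""
    return SimConfig(seed=seed, sweep_enabled=True, **overrides)


@dataclass
class SimTruth:
    """Simulator ground truth for power and recovery tests."""

    seed: int
    focal_marker: str | None
    focal_index: int | None
    s: float
    traj_pop1: list[float] = field(default_factory=list)  # from the split, per generation
    traj_pop2: list[float] = field(default_factory=list)
    ancestral_alleles: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    markers: MarkerMap | None = None

    def to_json(self, path: str | os.PathLike) -> None:
        payload = {
            "seed": self.seed,
            "focal_marker": self.focal_marker,
            "focal_index": self.focal_index,
            "s": self.s,
            "traj_pop1": [float(x) for x in self.traj_pop1],
            "traj_pop2": [float(x) for x in self.traj_pop2],
            "ancestral_alleles": list(self.ancestral_alleles),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), stream])


def generate_founders(cfg: SimConfig) -> HaplotypePanel:
    """Build the founder haplotype pool with array-like MAF and decaying LD.

    Marker positions are uniform over the chromosome.  Per-marker derived
    frequencies are drawn from Beta(a, b) truncated to [f_min, f_max];
    haplotypes are mosaics over ``n_templates`` template haplotypes with a
    per-bp template-switch rate, which yields LD that decays monotonically
    with distance.  Markers whose realized frequency violates the bounds are
    redrawn (bounded retries, then an exact-count fallback).
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    m, nh, nt = cfg.n_markers, cfg.n_founder_haps, cfg.n_templates

    pos = np.sort(rng.choice(cfg.chrom_length_bp, size=m, replace=False)) + 1

    # truncated Beta derived-allele frequencies
    f = rng.beta(cfg.founder_beta_a, cfg.founder_beta_b, size=m)
    for _ in range(200):
        bad = (f < cfg.f_min) | (f > cfg.f_max)
        if not bad.any():
            break
        f[bad] = rng.beta(cfg.founder_beta_a, cfg.founder_beta_b, size=int(bad.sum()))
    else:
        raise ValueError("infeasible founder MAF bounds for the Beta law")

    templates = (rng.random((nt, m)) < f).astype(np.uint8)

    gaps = np.diff(pos, prepend=pos[0])
    switch_p = 1.0 - np.exp(-cfg.template_switch_rate * gaps)
    switch = rng.random((nh, m)) < switch_p
    switch[:, 0] = True
    fresh = rng.integers(0, nt, size=(nh, m))
    idx = np.where(switch, np.arange(m), 0)
    idx = np.maximum.accumulate(idx, axis=1)
    path = fresh[np.arange(nh)[:, None], idx]
    alleles = templates[path, np.arange(m)]

    # enforce realized-frequency bounds marker by marker
    freq = alleles.mean(axis=0)
    for j in np.flatnonzero((freq < cfg.f_min) | (freq > cfg.f_max)):
        ok = False
        for _ in range(30):
            templates[:, j] = rng.random(nt) < f[j]
            col = templates[path[:, j], j]
            fr = col.mean()
            if cfg.f_min <= fr <= cfg.f_max:
                alleles[:, j] = col
                ok = True
                break
        if not ok:  # exact-count fallback, loses LD at this marker only
            k = int(round(f[j] * nh))
            k = min(max(k, int(np.ceil(cfg.f_min * nh))), int(np.floor(cfg.f_max * nh)))
            col = np.zeros(nh, dtype=np.uint8)
            col[rng.choice(nh, size=k, replace=False)] = 1
            alleles[:, j] = col

    anc = rng.integers(0, 4, size=m)
    der = (anc + rng.integers(1, 4, size=m)) % 4
    markers = MarkerMap(
        np.array([f"snp{j + 1}" for j in range(m)], dtype=object),
        np.array([cfg.chrom] * m, dtype=object),
        pos,
        _NUC[anc],
        _NUC[der],
    )
    sample_ids = [f"F{i + 1:04d}" for i in range(nh // 2)]
    pops = np.array(["founder"] * (nh // 2), dtype=object)
    return HaplotypePanel(sample_ids, pops, alleles, markers)


def _wf_generation(
    haps: np.ndarray,
    n_children: int,
    pos: np.ndarray,
    recomb_rate: float,
    length_bp: int,
    rng: np.random.Generator,
    fitness: np.ndarray | None = None,
) -> np.ndarray:
    """One Wright-Fisher diploid generation with Poisson recombination."""
    n_parents = haps.shape[0] // 2
    if fitness is not None:
        w = fitness / fitness.sum()
        parents = rng.choice(n_parents, size=(n_children, 2), p=w)
    else:
        parents = rng.integers(0, n_parents, size=(n_children, 2))
    gpar = parents.ravel()  # gamete g comes from parent gpar[g]
    n_gam = 2 * n_children
    n_xo = rng.poisson(recomb_rate * length_bp, size=n_gam)
    start = rng.integers(0, 2, size=n_gam)
    bp_flat = rng.integers(1, length_bp, size=int(n_xo.sum()))
    cuts_flat = np.searchsorted(pos, bp_flat, side="right")
    cuts_off = np.concatenate([[0], np.cumsum(n_xo)])
    return gametes_kernel(haps, gpar, start, cuts_flat, cuts_off, haps.shape[1])


def evolve_two_pops(
    founders: HaplotypePanel, cfg: SimConfig
) -> tuple[HaplotypePanel, HaplotypePanel, SimTruth]:
    """Run the Wright-Fisher scenario: common pool, split, optional sweep.

    ``g0`` generations in a single population of size n1 + n2, then a split
    into sizes n1 and n2 and ``g1`` further generations.  With the sweep
    enabled, the segregating marker whose pop1 frequency is nearest
    ``sweep_p0`` at the split becomes the focal marker and its derived
    allele gets genotype fitness 1 : 1+s : 1+2s in pop1 only; after ``g1``
    generations both populations keep evolving (up to ``sweep_max_extra``
    extra generations) until the focal allele reaches the target frequency
    or fixes.  If the focal allele is lost, a new focal marker is drawn
    (bounded retries).  Returns panels of ``n_sample1``/``n_sample2``
    sampled individuals plus the ground truth.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    pos = founders.markers.pos_bp
    L = cfg.chrom_length_bp
    n0 = cfg.n1 + cfg.n2

    haps = founders.alleles
    if haps.shape[0] != 2 * n0:
        pick = rng.choice(haps.shape[0], size=2 * n0, replace=haps.shape[0] < 2 * n0)
        haps = haps[pick]
    for _ in range(cfg.g0):
        haps = _wf_generation(haps, n0, pos, cfg.recomb_rate, L, rng)

    split = haps.copy()
    pop1_0 = split[: 2 * cfg.n1]
    pop2_0 = split[2 * cfg.n1 :]

    def run_from_split(focal: int | None):
        p1, p2 = pop1_0.copy(), pop2_0.copy()
        traj1, traj2 = [], []
        if focal is not None:
            traj1.append(float(p1[:, focal].mean()))
            traj2.append(float(p2[:, focal].mean()))

        def step(with_selection: bool):
            nonlocal p1, p2
            fit = None
            if with_selection and focal is not None:
                geno = p1[0::2, focal].astype(int) + p1[1::2, focal].astype(int)
                fit = 1.0 + cfg.s * geno
            p1 = _wf_generation(p1, cfg.n1, pos, cfg.recomb_rate, L, rng, fitness=fit)
            p2 = _wf_generation(p2, cfg.n2, pos, cfg.recomb_rate, L, rng)
            if focal is not None:
                traj1.append(float(p1[:, focal].mean()))
                traj2.append(float(p2[:, focal].mean()))

        selection = cfg.sweep_enabled and focal is not None
        for _ in range(cfg.g1):
            step(selection)
            if selection and traj1[-1] == 0.0:
                return None, None, traj1, traj2  # lost
        extra = 0
        while (
            selection
            and 0.0 < traj1[-1] < 1.0
            and traj1[-1] < cfg.sweep_target_freq
            and extra < cfg.sweep_max_extra
        ):
            step(True)
            extra += 1
            if traj1[-1] == 0.0:
                return None, None, traj1, traj2
        return p1, p2, traj1, traj2

    focal = None
    traj1: list[float] = []
    traj2: list[float] = []
    if cfg.sweep_enabled:
        tried: set[int] = set()
        freq1 = pop1_0.mean(axis=0)
        # keep the focal away from chromosome ends so its decay curves are
        # observable on both sides
        central = (pos >= 0.25 * L) & (pos <= 0.75 * L)
        for _ in range(cfg.sweep_max_retries):
            cand = np.flatnonzero((freq1 > 0) & (freq1 < 1) & central)
            cand = np.array([c for c in cand if c not in tried])
            if len(cand) == 0:
                raise RuntimeError("no segregating marker left to sweep")
            focal = int(cand[np.argmin(np.abs(freq1[cand] - cfg.sweep_p0))])
            p1, p2, traj1, traj2 = run_from_split(focal)
            if p1 is not None:
                break
            tried.add(focal)
        else:
            raise RuntimeError(
                f"focal allele lost in {cfg.sweep_max_retries} consecutive attempts"
            )
    else:
        p1, p2, traj1, traj2 = run_from_split(None)

    def sample_panel(haps_pop: np.ndarray, n_pop: int, n_take: int, tag: str) -> HaplotypePanel:
        pick = np.sort(rng.choice(n_pop, size=n_take, replace=False))
        rows = np.ravel(np.column_stack([2 * pick, 2 * pick + 1]))
        ids = [f"{tag}_{i + 1:04d}" for i in pick]
        pops = np.array([tag] * n_take, dtype=object)
        return HaplotypePanel(ids, pops, haps_pop[rows], founders.markers)

    panel1 = sample_panel(p1, cfg.n1, cfg.n_sample1, "pop1")
    panel2 = sample_panel(p2, cfg.n2, cfg.n_sample2, "pop2")
    truth = SimTruth(
        seed=cfg.seed,
        focal_marker=founders.markers.marker_id[focal] if focal is not None else None,
        focal_index=focal,
        s=cfg.s if cfg.sweep_enabled else 0.0,
        traj_pop1=traj1,
        traj_pop2=traj2,
        ancestral_alleles=founders.markers.allele1.copy(),
        markers=founders.markers,
    )
    return panel1, panel2, truth


def simulate_dataset(cfg: SimConfig) -> tuple[HaplotypePanel, HaplotypePanel, SimTruth]:
    """Convenience: founders + evolution in one call."""
    return evolve_two_pops(generate_founders(cfg), cfg)


def emit_outgroups(truth: SimTruth, cfg: SimConfig) -> pd.DataFrame:
    """Outgroup-species allele calls derived from the true ancestral states.

    Each species' call equals the true ancestral allele, flipped to the
    derived allele with probability ``outgroup_error`` and set missing with
    probability ``outgroup_missing``, independently per species and marker.
    """
    if truth.markers is None:
        raise ValueError("truth carries no marker map")
    rng = _rng(cfg, 2)
    m = truth.markers
    data = {}
    for sp in cfg.outgroup_species:
        calls = np.array(truth.ancestral_alleles, dtype=object)
        flip = rng.random(m.n_markers) < cfg.outgroup_error
        calls[flip] = m.allele2[flip]
        miss = rng.random(m.n_markers) < cfg.outgroup_missing
        calls[miss] = np.nan
        data[sp] = calls
    return pd.DataFrame(data, index=pd.Index(m.marker_id, name="marker_id"))


def combined_genotypes(
    pop1: HaplotypePanel, pop2: HaplotypePanel, cfg: SimConfig | None = None
) -> GenotypeMatrix:
    """Diploid genotypes of both panels stacked, optionally masked to MISSING."""
    g1 = pop1.to_genotypes()
    g2 = pop2.to_genotypes()
    calls = np.vstack([g1.calls, g2.calls])
    g = GenotypeMatrix(
        list(g1.sample_ids) + list(g2.sample_ids),
        np.concatenate([g1.population_labels, g2.population_labels]),
        calls,
        pop1.markers,
    )
    if cfg is not None and cfg.mask_rate > 0:
        rng = _rng(cfg, 3)
        mask = rng.random(g.calls.shape) < cfg.mask_rate
        g.calls[mask] = MISSING
    return g


def write_dataset(
    pop1: HaplotypePanel,
    pop2: HaplotypePanel,
    truth: SimTruth,
    cfg: SimConfig,
    outdir: str | os.PathLike,
) -> dict[str, str]:
    """Write the full simulated file set; returns a name -> path map.

    Files: PED/MAP genotypes (with optional masking), the allele-coding
    table, a combined phased VCF, a sample -> population table, the outgroup
    TSV, the ground-truth JSON and a config echo.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "ped": os.path.join(outdir, "genotypes.ped"),
        "map": os.path.join(outdir, "genotypes.map"),
        "alleles": os.path.join(outdir, "alleles.tsv"),
        "vcf": os.path.join(outdir, "phased.vcf"),
        "samples": os.path.join(outdir, "samples.tsv"),
        "outgroups": os.path.join(outdir, "outgroups.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
        "config": os.path.join(outdir, "sim_config.txt"),
    }
    g = combined_genotypes(pop1, pop2, cfg)
    eio.write_ped_map(g, paths["ped"], paths["map"], allele_table=paths["alleles"])
    both = HaplotypePanel(
        list(pop1.sample_ids) + list(pop2.sample_ids),
        np.concatenate([pop1.population_labels, pop2.population_labels]),
        np.vstack([pop1.alleles, pop2.alleles]),
        pop1.markers,
    )
    eio.write_phased_vcf(both, paths["vcf"])
    pd.DataFrame(
        {"sample_id": both.sample_ids, "population": both.population_labels}
    ).to_csv(paths["samples"], sep="\t", index=False)
    eio.write_outgroup_table(emit_outgroups(truth, cfg), paths["outgroups"])
    truth.to_json(paths["truth"])
    cfg.to_file(paths["config"])
    return paths
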