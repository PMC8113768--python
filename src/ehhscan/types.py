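"""Core in-memory containers shared by every stage of the scan.

Coordinate convention: marker positions are 1-based inclusive base-pair
coordinates (linkage-map convention) everywhere in memory; BED output is
converted to 0-based half-open at the file boundary and nowhere else.

Genotype calls count copies of ``allele2`` (0, 1 or 2); missing calls use the
explicit :data:`MISSING` sentinel, never an in-band code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call.
MISSING: int = -1


class FormatError(ValueError):
    """A malformed on-disk record (bad allele code, ragged row, unphased GT...)."""


@dataclass(frozen=True)
class MarkerMap:
    """Marker coordinates and allele coding for one genotyping panel.

    Parameters
    ----------
    marker_id
        Unique marker names.
    chrom
        Chromosome label per marker (any string; no chromosome is excluded).
    pos_bp
        1-based physical position, strictly increasing within each chromosome.
    allele1, allele2
        The two observed alleles; genotype codes count copies of ``allele2``.
    """

    marker_id: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "marker_id", np.asarray(self.marker_id, dtype=object))
        object.__setattr__(self, "chrom", np.asarray(self.chrom, dtype=object))
        object.__setattr__(self, "pos_bp", np.asarray(self.pos_bp, dtype=np.int64))
        object.__setattr__(self, "allele1", np.asarray(self.allele1, dtype=object))
        object.__setattr__(self, "allele2", np.asarray(self.allele2, dtype=object))
        n = len(self.marker_id)
        for name in ("chrom", "pos_bp", "allele1", "allele2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"MarkerMap field {name!r} length mismatch")
        if len(set(self.marker_id)) != n:
            raise ValueError("marker ids are not unique")
        if np.any(self.pos_bp < 0):
            raise ValueError("negative marker position")
        if any(a == b for a, b in zip(self.allele1, self.allele2)):
            raise ValueError("allele1 == allele2 for some marker")
        # positions strictly increasing within each chromosome block
        for c in pd.unique(self.chrom):
            p = self.pos_bp[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"marker positions not strictly increasing on chromosome {c}; "
                    "refusing to sort silently"
                )

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        """Restrict to the given marker indices (order preserved)."""
        idx = np.asarray(idx)
        return MarkerMap(
            self.marker_id[idx],
            self.chrom[idx],
            self.pos_bp[idx],
            self.allele1[idx],
            self.allele2[idx],
        )

    def index_of(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.marker_id == marker_id)
        if len(hits) == 0:
            raise KeyError(marker_id)
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chrom": self.chrom,
                "pos_bp": self.pos_bp,
                "allele1": self.allele1,
                "allele2": self.allele2,
            }
        )


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls (samples x markers) tied to a :class:`MarkerMap`.

    ``calls[i, j]`` counts copies of ``markers.allele2[j]`` carried by sample
    ``i`` at marker ``j``; :data:`MISSING` marks a no-call.
    """

    sample_ids: list[str]
    population_labels: np.ndarray
    calls: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.population_labels = np.asarray(self.population_labels, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), self.markers.n_markers):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.markers.n_markers} markers"
            )
        if len(self.population_labels) != len(self.sample_ids):
            raise ValueError("population label per sample required")
        ok = (self.calls == MISSING) | ((self.calls >= 0) & (self.calls <= 2))
        if not ok.all():
            raise ValueError("genotype codes must be in {0,1,2} or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.markers.n_markers

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per marker, over non-missing calls only."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per marker."""
        return (self.calls != MISSING).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        """Fraction of missing calls per sample."""
        return (self.calls == MISSING).mean(axis=1)

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.sample_ids),
            self.population_labels.copy(),
            self.calls[:, np.asarray(idx)],
            self.markers.subset(idx),
        )

    def subset_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            self.population_labels[idx],
            self.calls[idx, :],
            self.markers,
        )


@dataclass
class HaplotypePanel:
    """Phased binary haplotypes (2 per sample) over a marker map.

    ``alleles[h, j]`` is 0 for ``allele1`` and 1 for ``allele2``; rows
    ``2*i`` and ``2*i + 1`` are the two haplotypes of sample ``i``.  No
    missing entries are allowed: EHH statistics assume fully phased,
    imputation-complete input.
    """

    sample_ids: list[str]
    population_labels: np.ndarray
    alleles: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.population_labels = np.asarray(self.population_labels, dtype=object)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        if self.alleles.shape != (2 * len(self.sample_ids), self.markers.n_markers):
            raise ValueError("alleles must be (2 * n_samples) x n_markers")
        if len(self.population_labels) != len(self.sample_ids):
            raise ValueError("population label per sample required")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype alleles must be binary (no missing)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def haplotype_ids(self) -> list[str]:
        return [f"{s}_{k}" for s in self.sample_ids for k in (1, 2)]

    def to_genotypes(self) -> GenotypeMatrix:
        """Collapse haplotype pairs into diploid allele2-dosage calls."""
        calls = self.alleles[0::2].astype(np.int8) + self.alleles[1::2].astype(np.int8)
        return GenotypeMatrix(list(self.sample_ids), self.population_labels.copy(), calls, self.markers)

    def subset_markers(self, idx: np.ndarray) -> "HaplotypePanel":
        return HaplotypePanel(
            list(self.sample_ids),
            self.population_labels.copy(),
            self.alleles[:, np.asarray(idx)],
            self.markers.subset(idx),
        )

    def subset_samples(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        hap_idx = np.ravel(np.column_stack([2 * idx, 2 * idx + 1]))
        return HaplotypePanel(
            [self.sample_ids[i] for i in idx],
            self.population_labels[idx],
            self.alleles[hap_idx, :],
            self.markers,
        )


@dataclass
class PolarizedPanel:
    """A haplotype panel recoded to 0 = ancestral / 1 = derived.

    Only markers with a resolved ancestral state are present.  ``derived_freq``
    is the derived-allele frequency recomputed on this panel, the binning
    variable for iHS standardization.  ``provenance`` records, per marker, the
    inferred ancestral allele and the outgroup votes behind it.
    """

    panel: HaplotypePanel
    derived_freq: np.ndarray
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.derived_freq = np.asarray(self.derived_freq, dtype=float)
        if len(self.derived_freq) != self.panel.markers.n_markers:
            raise ValueError("derived_freq length must match marker count")
        if np.any((self.derived_freq < 0) | (self.derived_freq > 1)):
            raise ValueError("derived-allele frequencies must lie in [0, 1]")

    @property
    def markers(self) -> MarkerMap:
        return self.panel.markers

    @property
    def alleles(self) -> np.ndarray:
        return self.panel.alleles


@dataclass(frozen=True)
class CandidateRegion:
    """A candidate selection region: an interval of significant markers.

    ``start``/``end`` are 1-based inclusive marker positions (the outermost
    significant markers).  ``methods`` names the statistics supporting the
    region; ``n_sig`` counts significant markers inside it.
    """

    chrom: str
    start: int
    end: int
    methods: frozenset = frozenset()
    n_sig: int = 0
    peak_pscore: float = float("nan")
    marker_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")
        object.__setattr__(self, "methods", frozenset(self.methods))
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))

    @property
    def span_bp(self) -> int:
        """Distance between the bounding positions, as region tables print it."""
        return self.end - self.start

    @property
    def span_mb(self) -> float:
        return self.span_bp / 1e6

    def overlaps(self, other: "CandidateRegion") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end

    def with_methods(self, methods) -> "CandidateRegion":
        return replace(self, methods=frozenset(methods))
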