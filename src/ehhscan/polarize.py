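"""Ancestral-allele polarization against outgroup species.

The ancestral state of each marker is taken as the majority allele across a
set of outgroup species (e.g., yak, buffalo, sheep for cattle arrays); one
allele call per species.  Markers whose ancestral state cannot be resolved
(tie, no usable votes, or only third-allele votes) are dropped rather than
guessed, and the resolved + unresolved counts always add back to the input
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import HaplotypePanel, MarkerMap, PolarizedPanel

log = logging.getLogger(__name__)


@dataclass
class AncestralCalls:
    """Outcome of outgroup-majority ancestral inference.

    ``calls`` maps marker_id -> ancestral allele for resolved markers;
    ``unresolved`` lists the rest; ``provenance`` records per-marker vote
    counts for each of the marker's two alleles and the usable vote total.
    """

    calls: dict[str, str]
    unresolved: list[str]
    provenance: pd.DataFrame

    @property
    def n_resolved(self) -> int:
        return len(self.calls)

    @property
    def n_unresolved(self) -> int:
        return len(self.unresolved)


def infer_ancestral(
    markers: MarkerMap, outgroups: pd.DataFrame, min_votes: int = 1
) -> AncestralCalls:
    """Infer each marker's ancestral allele by outgroup majority vote.

    ``outgroups`` is indexed by marker_id with one column per species, each
    entry a nucleotide or NaN.  Votes that match neither of the marker's two
    alleles are discarded (the table must be pre-harmonized to the map's
    allele coding).  A strict majority among at least ``min_votes`` usable
    votes resolves the marker; ties and vote-less markers are unresolved —
    a data outcome, not an error.
    """
    if outgroups.shape[1] < 1:
        raise ValueError("need at least one outgroup species column")
    calls: dict[str, str] = {}
    unresolved: list[str] = []
    rows = []
    for j in range(markers.n_markers):
        mid = markers.marker_id[j]
        a1, a2 = markers.allele1[j], markers.allele2[j]
        votes = []
        if mid in outgroups.index:
            votes = [v for v in outgroups.loc[mid] if isinstance(v, str)]
        v1 = sum(v == a1 for v in votes)
        v2 = sum(v == a2 for v in votes)
        usable = v1 + v2
        if usable >= min_votes and v1 != v2:
            anc = a1 if v1 > v2 else a2
            calls[mid] = anc
        else:
            anc = None
            unresolved.append(mid)
        rows.append((mid, v1, v2, usable, anc if anc else "."))
    provenance = pd.DataFrame(
        rows, columns=["marker_id", "votes_allele1", "votes_allele2", "usable_votes", "ancestral"]
    )
    log.info(
        "infer_ancestral: %d markers -> %d resolved + %d unresolved",
        markers.n_markers,
        len(calls),
        len(unresolved),
    )
    return AncestralCalls(calls, unresolved, provenance)


def polarize_panel(h: HaplotypePanel, ancestral: AncestralCalls | dict) -> PolarizedPanel:
    """Recode a haplotype panel to 0 = ancestral / 1 = derived.

    Markers are restricted to those with a resolved ancestral call; where the
    ancestral allele is ``allele2`` the binary codes are flipped (and the
    map's allele columns swapped so code 1 is always the derived allele).
    The derived-allele frequency is recomputed on the polarized panel.
    """
    calls = ancestral.calls if isinstance(ancestral, AncestralCalls) else dict(ancestral)
    m = h.markers
    keep = [j for j in range(m.n_markers) if m.marker_id[j] in calls]
    if not keep:
        raise ValueError("no markers with a resolved ancestral state in the panel")
    sub = h.subset_markers(np.array(keep))
    sm = sub.markers
    alleles = sub.alleles.copy()
    a1 = sm.allele1.copy()
    a2 = sm.allele2.copy()
    for j in range(sm.n_markers):
        anc = calls[sm.marker_id[j]]
        if anc == sm.allele1[j]:
            pass
        elif anc == sm.allele2[j]:
            alleles[:, j] = 1 - alleles[:, j]
            a1[j], a2[j] = sm.allele2[j], sm.allele1[j]
        else:
            raise ValueError(
                f"ancestral allele {anc!r} for marker {sm.marker_id[j]!r} matches "
                f"neither panel allele {sm.allele1[j]}/{sm.allele2[j]}"
            )
    new_map = MarkerMap(sm.marker_id, sm.chrom, sm.pos_bp, a1, a2)
    panel = HaplotypePanel(list(sub.sample_ids), sub.population_labels.copy(), alleles, new_map)
    p_d = panel.alleles.mean(axis=0)
    prov = (
        ancestral.provenance.set_index("marker_id").loc[new_map.marker_id].reset_index()
        if isinstance(ancestral, AncestralCalls) and len(ancestral.provenance)
        else pd.DataFrame()
    )
    return PolarizedPanel(panel, p_d, prov)
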