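"""Audit trail for marker/sample counts through the filter chain.

Every stage of the pipeline reduces a marker or sample set; recording
(input, removed, output) triples and checking ``input - removed == output``
at record time makes the whole data-reduction chain auditable on any
dataset, the way genotype-QC reports tabulate their arithmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

log = logging.getLogger(__name__)


class CountMismatchError(RuntimeError):
    """A stage's removed + retained counts do not add back to its input."""


@dataclass(frozen=True)
class StageCount:
    stage: str
    unit: str  # "markers" or "samples"
    n_in: int
    n_removed: int
    n_out: int


def reduce_count(n_in: int, n_removed: int) -> int:
    """Markers/samples left after removing ``n_removed`` of ``n_in``."""
    if n_removed < 0 or n_removed > n_in:
        raise ValueError(f"cannot remove {n_removed} of {n_in}")
    return n_in - n_removed


def combine_counts(*groups: int) -> int:
    """Total individuals across retained groups."""
    if any(g < 0 for g in groups):
        raise ValueError("negative group size")
    return sum(groups)


@dataclass
class CountLedger:
    """Ordered stage-count records with built-in arithmetic checks."""

    records: list[StageCount] = field(default_factory=list)

    def record(
        self,
        stage: str,
        unit: str,
        n_in: int,
        n_removed: int | None = None,
        n_out: int | None = None,
    ) -> int:
        """Record one stage; returns the retained count.

        Exactly one of ``n_removed``/``n_out`` may be omitted (it is
        derived); if both are given they must satisfy the subtraction
        identity.
        """
        if n_removed is None and n_out is None:
            raise ValueError("give n_removed or n_out")
        if n_removed is None:
            n_removed = n_in - n_out
        if n_out is None:
            n_out = reduce_count(n_in, n_removed)
        if n_in - n_removed != n_out:
            raise CountMismatchError(
                f"stage {stage!r}: {n_in} - {n_removed} != {n_out}"
            )
        self.records.append(StageCount(stage, unit, n_in, n_removed, n_out))
        log.info("%s: %d -> %d %s (%d removed)", stage, n_in, n_out, unit, n_removed)
        return n_out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def chained(self, unit: str) -> bool:
        """True if each stage's input equals the previous stage's output."""
        seq = [r for r in self.records if r.unit == unit]
        return all(a.n_out == b.n_in for a, b in zip(seq, seq[1:]))
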