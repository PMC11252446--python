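"""SWIM-seq confirmation of promoter yeast strains from alignment summaries.

A promoter strain is sequence-confirmed when at least 25% of its pMW3-vector
reads align to the expected promoter sequence.  Only pMW3 summaries gate the
decision; pMW2 rows may be stored but are ignored here.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable

import pandas as pd

from .model import AlignmentSummary


@dataclasses.dataclass(frozen=True)
class ConfirmationResult:
    strain_id: str
    aligned_fraction: float  # NaN when no reads were obtained
    confirmed: bool
    status: str  # confirmed / failed / unconfirmable


def confirm_strain(summary: AlignmentSummary, threshold: float = 0.25) -> ConfirmationResult:
    """Confirm one strain from its pMW3 alignment summary.

    The threshold is inclusive ("at least 25%").  Zero total reads yield an
    "unconfirmable" status, distinct from a failed confirmation.
    """
    if summary.vector != "pMW3":
        raise ValueError(
            f"{summary.strain_id}: confirmation is gated on pMW3 summaries, got {summary.vector}"
        )
    if summary.reads_total == 0:
        return ConfirmationResult(summary.strain_id, math.nan, False, "unconfirmable")
    fraction = summary.reads_matching_expected / summary.reads_total
    confirmed = fraction >= threshold
    return ConfirmationResult(
        summary.strain_id, fraction, confirmed, "confirmed" if confirmed else "failed"
    )


def confirm_strains(
    summaries: Iterable[AlignmentSummary], threshold: float = 0.25
) -> pd.DataFrame:
    """Confirm every pMW3 summary; returns a tidy result table."""
    rows = [
        dataclasses.asdict(confirm_strain(s, threshold))
        for s in summaries
        if s.vector == "pMW3"
    ]
    return pd.DataFrame(
        rows, columns=["strain_id", "aligned_fraction", "confirmed", "status"]
    )
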