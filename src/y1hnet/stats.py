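"""Family enrichment tests, pair-event preference tests, mutation frequency, FDR.

Family representation in the network (per TF or per interaction) is compared
against the screened TF array with a pooled two-proportion z-test; families
with expected counts below 5 fall back to Fisher's exact test, whose normal
approximation would otherwise be invalid.  TF-pair event preferences
(cooperative / antagonized / antagonist, per family) use Fisher's exact test
against all other families.  Mutation frequency follows the case-count
formula (mutated minus synonymous, over all cases).  Benjamini-Hochberg
step-up q-values are provided for user-requested batches.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

from .calling import PairwiseOutcome
from .model import MutationSummary, TFRecord
from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)

EVENT_TYPES = ("cooperative", "antagonized", "antagonist")


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    family: str
    count_in_foreground: int
    total_foreground: int
    count_in_background: int
    total_background: int
    p_value: float
    direction: str  # enriched / depleted / none

    def __post_init__(self) -> None:
        if not (
            0 <= self.count_in_foreground <= self.total_foreground
            and 0 <= self.count_in_background <= self.total_background
        ):
            raise ValueError("counts exceed totals")


def proportion_test(
    count_fg: int, total_fg: int, count_bg: int, total_bg: int
) -> float:
    """Two-sided comparison of two proportions.

    Pooled two-proportion z-test; falls back to Fisher's exact test whenever
    any expected cell count of the 2x2 table is below 5.
    """
    table = np.array(
        [[count_fg, total_fg - count_fg], [count_bg, total_bg - count_bg]],
        dtype=float,
    )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        return float(sps.fisher_exact(table.astype(int))[1])
    if count_fg / total_fg == count_bg / total_bg:
        return 1.0  # z-test returns nan on identical degenerate proportions
    _, p = proportions_ztest([count_fg, count_bg], [total_fg, total_bg])
    return float(p)


def family_proportion_test(
    network: RegulatoryNetwork,
    array: Iterable[TFRecord],
    unit: str = "tfs",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-family enrichment/depletion of the network against the TF array.

    ``unit`` selects the counting unit: "tfs" compares the fraction of TFs in
    each family, "interactions" the fraction of interactions involving each
    family.  Families absent from the array background are skipped with a
    warning.  Direction is set only at p < alpha.
    """
    if unit not in ("tfs", "interactions"):
        raise ValueError("unit must be 'tfs' or 'interactions'")
    array = list(array)
    bg_counts = Counter(rec.family for rec in array)
    total_bg = len(array)

    family_of = {rec.tf_id: rec.family for rec in array}
    family_of.update({tf: rec.family for tf, rec in network.tf_annotations.items()})
    if unit == "tfs":
        units = [family_of.get(tf, "other") for tf in network.tf_ids]
    else:
        units = [family_of.get(i.tf_id, "other") for i in network.interactions]
    fg_counts = Counter(units)
    total_fg = len(units)

    results = []
    for family in sorted(fg_counts | bg_counts):
        if family not in bg_counts:
            logger.warning("family %s absent from the array background; skipped", family)
            continue
        fg, bg = fg_counts.get(family, 0), bg_counts[family]
        p = proportion_test(fg, total_fg, bg, total_bg)
        direction = "none"
        if p < alpha:
            direction = "enriched" if fg / total_fg > bg / total_bg else "depleted"
        results.append(
            EnrichmentResult(family, fg, total_fg, bg, total_bg, p, direction)
        )
    return results


def pair_events(
    outcomes: Iterable[PairwiseOutcome],
    tf_families: Mapping[str, str],
) -> pd.DataFrame:
    """Expand pair verdicts into per-TF binding events with families.

    A cooperative outcome contributes one "cooperative" event per pair member;
    an antagonistic outcome contributes one "antagonized" event per antagonized
    TF and one "antagonist" event per partner TF.
    """
    rows = []
    for out in outcomes:
        if out.verdict == "cooperative":
            for tf in (out.tf1_id, out.tf2_id):
                rows.append((tf, "cooperative", out.promoter_id))
        elif out.verdict == "antagonistic":
            pair = (out.tf1_id, out.tf2_id)
            for tf in out.antagonized_tfs:
                rows.append((tf, "antagonized", out.promoter_id))
                for partner in pair:
                    if partner != tf:
                        rows.append((partner, "antagonist", out.promoter_id))
    df = pd.DataFrame(rows, columns=["tf_id", "event_type", "promoter_id"])
    df["family"] = df["tf_id"].map(lambda t: tf_families.get(t, "other"))
    return df


def pair_family_preference(
    outcomes: Iterable[PairwiseOutcome],
    tf_annotations: Mapping[str, TFRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-family event-type fractions with Fisher's exact tests.

    For each family and event type, the 2x2 table (family events of this type
    / family other events // other families' events of this type / their other
    events) is tested with Fisher's exact test.  Fractions sum to 1 within a
    family; families with no events are excluded.
    """
    families = {tf: rec.family for tf, rec in tf_annotations.items()}
    events = pair_events(outcomes, families)
    if events.empty:
        return pd.DataFrame(
            columns=["family", "event_type", "count", "family_total", "fraction", "p_value", "direction"]
        )
    counts = events.groupby(["family", "event_type"]).size()
    totals = events.groupby("family").size()
    grand_total = len(events)
    type_totals = events.groupby("event_type").size()

    rows = []
    for family in sorted(totals.index):
        fam_total = int(totals[family])
        for event_type in EVENT_TYPES:
            k = int(counts.get((family, event_type), 0))
            type_total = int(type_totals.get(event_type, 0))
            table = [
                [k, fam_total - k],
                [type_total - k, (grand_total - fam_total) - (type_total - k)],
            ]
            p = float(sps.fisher_exact(table)[1])
            direction = "none"
            if p < alpha and grand_total > fam_total:
                fam_frac = k / fam_total
                other_frac = (type_total - k) / (grand_total - fam_total)
                direction = "enriched" if fam_frac > other_frac else "depleted"
            rows.append(
                {
                    "family": family,
                    "event_type": event_type,
                    "count": k,
                    "family_total": fam_total,
                    "fraction": k / fam_total,
                    "p_value": p,
                    "direction": direction,
                }
            )
    return pd.DataFrame(rows)


def mutation_frequency(summary: MutationSummary) -> float:
    """Fraction of cancer cases with a non-synonymous mutation in the TF.

    (mutated cases - synonymous cases) / total cases; undefined (error) when
    no cases were assayed.
    """
    if summary.total_cases == 0:
        raise ValueError(f"{summary.tf_id}: mutation frequency undefined with 0 cases")
    return (summary.mutated_cases - summary.synonymous_cases) / summary.total_cases


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Monotone nondecreasing in sorted order, each q >= its p, capped at 1.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
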