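"""Interaction calling from quadruplicate colony readouts.

Two assays are called here.  In the single-TF screen (eY1H) an interaction is
positive when at least three of the four colonies display reporter activity,
where a colony is active if its ordinal level is nonzero and exceeds the
empty-control background consensus on the same bait.  In the TF-pair screen
(pY1H) the pair strain and both monomer strains are reduced to quad consensus
levels and compared: a cooperative interaction has moderate/strong pair signal
with no/weak monomers; an antagonistic interaction has moderate/strong signal
from at least one monomer with no/weak pair signal.

The ordinal scale is 0 none / 1 weak / 2 moderate / 3 strong; "no or only
weak" means level <= 1 and "moderate or strong" means level >= 2.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from collections import Counter
from collections.abc import Iterable, Mapping

from .config import MODERATE_LEVEL
from .model import QuadReadout

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ConsensusResult:
    """Modal colony level of a quad and whether it forms a consensus.

    A quad is ``uniform`` when its modal level occurs in at least 3 of the 4
    colonies; only then is ``consensus_level`` defined.  ``modal_level`` is
    always defined (on a 2-2 tie the higher level is recorded, conservatively,
    but the quad is not uniform).
    """

    modal_level: int
    n_agreeing: int
    uniform: bool

    @property
    def consensus_level(self) -> int | None:
        return self.modal_level if self.uniform else None


class CallStatus(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNSCORABLE = "unscorable"


@dataclasses.dataclass(frozen=True)
class PairwiseOutcome:
    """Verdict for one TF-pair x promoter test with its ranking indices."""

    tf1_id: str
    tf2_id: str
    promoter_id: str
    verdict: str
    antagonized_tfs: tuple[str, ...] = ()
    cooperativity_index: int = 0
    antagonism_index_1: int = 0
    antagonism_index_2: int = 0

    def __post_init__(self) -> None:
        if self.verdict == "antagonistic" and not self.antagonized_tfs:
            raise ValueError("antagonistic verdict requires antagonized TFs")
        if self.verdict != "antagonistic" and self.antagonized_tfs:
            raise ValueError("antagonized TFs only defined for antagonistic verdicts")


def score_quad(readout: QuadReadout) -> ConsensusResult:
    """Reduce a quad to its modal level; uniform iff >= 3 of 4 colonies agree."""
    counts = Counter(readout.colony_levels)
    n_agreeing = max(counts.values())
    # modal level; on ties (2-2) take the higher level but mark non-uniform
    modal = max(lev for lev, n in counts.items() if n == n_agreeing)
    return ConsensusResult(modal_level=modal, n_agreeing=n_agreeing, uniform=n_agreeing >= 3)


def _background_level(background: ConsensusResult | int | None) -> int:
    if background is None:
        return 0
    if isinstance(background, int):
        return background
    # fall back to the modal level when the control quad itself is noisy
    return background.modal_level


def call_ey1h(
    readout: QuadReadout,
    background: ConsensusResult | int | None = None,
) -> CallStatus:
    """Call one single-TF x promoter test.

    A colony displays reporter activity iff its level is >= 1 and strictly
    exceeds the empty-control background level on the same promoter, which
    makes calls on autoactive baits conservative.  Positive iff >= 3 of the 4
    colonies are active.  Failed mating gives an unscorable status, which is
    excluded from denominators rather than counted negative.
    """
    if not readout.mated_growth:
        return CallStatus.UNSCORABLE
    bg = _background_level(background)
    active = sum(1 for lev in readout.colony_levels if lev >= 1 and lev > bg)
    return CallStatus.POSITIVE if active >= 3 else CallStatus.NEGATIVE


def compute_pair_indices(
    pair_level: int, tf1_level: int, tf2_level: int
) -> tuple[int, int, int]:
    """Ranking indices comparing pair-strain signal with monomer signals.

    cooperativity = pair - max(monomers); antagonism_1 = tf1 - pair;
    antagonism_2 = tf2 - pair.  These order candidates for review and
    reporting only; verdicts never depend on them.
    """
    return (
        pair_level - max(tf1_level, tf2_level),
        tf1_level - pair_level,
        tf2_level - pair_level,
    )


def call_py1h(
    pair: QuadReadout,
    tf1: QuadReadout,
    tf2: QuadReadout,
    pair_control: ConsensusResult | int | None = None,
) -> PairwiseOutcome:
    """Call one TF-pair x promoter test from the pair and monomer quads.

    Unscorable when any of the three strains failed mating, when any quad
    lacks a >= 3/4 consensus, or when the empty-empty control itself shows
    moderate/strong signal (autoactive bait).  Otherwise, with L the consensus
    levels: cooperative iff L(pair) >= 2 and both monomers <= 1; antagonistic
    iff L(pair) <= 1 and at least one monomer >= 2 (those monomers are the
    antagonized TFs); independent iff pair and at least one monomer are both
    >= 2; none otherwise.
    """
    if not (pair.promoter_id == tf1.promoter_id == tf2.promoter_id):
        raise ValueError(
            "pair and monomer readouts must refer to one promoter, got "
            f"{pair.promoter_id!r}/{tf1.promoter_id!r}/{tf2.promoter_id!r}"
        )
    tf1_id, tf2_id = pair.tf_ids if pair.is_pair else (tf1.tf_key, tf2.tf_key)

    def unscorable() -> PairwiseOutcome:
        return PairwiseOutcome(tf1_id, tf2_id, pair.promoter_id, "unscorable")

    if not (pair.mated_growth and tf1.mated_growth and tf2.mated_growth):
        return unscorable()
    consensi = [score_quad(q) for q in (pair, tf1, tf2)]
    if not all(c.uniform for c in consensi):
        return unscorable()
    if _background_level(pair_control) >= MODERATE_LEVEL:
        return unscorable()

    lp, l1, l2 = (c.consensus_level for c in consensi)
    indices = compute_pair_indices(lp, l1, l2)
    if lp >= MODERATE_LEVEL and l1 < MODERATE_LEVEL and l2 < MODERATE_LEVEL:
        verdict, antagonized = "cooperative", ()
    elif lp < MODERATE_LEVEL and (l1 >= MODERATE_LEVEL or l2 >= MODERATE_LEVEL):
        verdict = "antagonistic"
        antagonized = tuple(
            tf for tf, lev in ((tf1_id, l1), (tf2_id, l2)) if lev >= MODERATE_LEVEL
        )
    elif lp >= MODERATE_LEVEL and max(l1, l2) >= MODERATE_LEVEL:
        verdict, antagonized = "independent", ()
    else:
        verdict, antagonized = "none", ()
    return PairwiseOutcome(
        tf1_id,
        tf2_id,
        pair.promoter_id,
        verdict,
        antagonized_tfs=antagonized,
        cooperativity_index=indices[0],
        antagonism_index_1=indices[1],
        antagonism_index_2=indices[2],
    )


def filter_autoactive(
    promoter_ids: Iterable[str],
    background: Mapping[str, ConsensusResult],
    max_level: int = MODERATE_LEVEL,
) -> list[str]:
    """Select baits eligible for the pair screen: low empty-control signal.

    Retains promoters whose empty-control level is strictly below
    ``max_level`` (default: below moderate).  Promoters without a control are
    excluded with a logged warning.
    """
    retained = []
    for pid in promoter_ids:
        control = background.get(pid)
        if control is None:
            logger.warning("promoter %s has no empty-control readout; excluded", pid)
            continue
        if _background_level(control) < max_level:
            retained.append(pid)
    return retained


def latest_day_readouts(readouts: Iterable[QuadReadout]) -> dict[tuple[str, str], QuadReadout]:
    """Keep one readout per (tf_key, promoter): the latest imaging day's.

    An interaction is counted once per strain x bait regardless of how many
    imaging days show signal.
    """
    best: dict[tuple[str, str], QuadReadout] = {}
    for r in readouts:
        key = (r.tf_key, r.promoter_id)
        if key not in best or r.imaging_day > best[key].imaging_day:
            best[key] = r
    return best


def call_ey1h_screen(
    readouts: Iterable[QuadReadout],
) -> dict[tuple[str, str], CallStatus]:
    """Call every single-TF readout against its bait's empty-control quad.

    Control readouts (empty ``tf_key``) supply the per-promoter background and
    are not themselves called.
    """
    latest = latest_day_readouts(readouts)
    background = {
        pid: score_quad(r) for (tf, pid), r in latest.items() if tf == ""
    }
    calls = {}
    for (tf, pid), readout in latest.items():
        if tf == "" or readout.is_pair:
            continue
        calls[(tf, pid)] = call_ey1h(readout, background.get(pid))
    return calls
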