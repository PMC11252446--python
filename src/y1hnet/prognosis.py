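"""Prognosis scoring, permutation null, and targetable-TF nomination.

A TF's prognosis score is (#poor-prognosis targets - #good-prognosis targets)
divided by its total number of gene-level targets, a value in [-1, 1].  The
null distribution is built by shuffling the gene -> prognosis-label assignment
(preserving the label multiset and every TF's degree) and rescoring; empirical
two-sided p-values use add-one smoothing so they are never zero.  Oncogene
nominations select activator/bifunctional TFs bound to an oncogene's promoter
whose score strictly exceeds a threshold (default 0.33): down-regulating such
a TF is expected to lower the oncogene without tilting the poor/good balance
unfavourably.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .model import GeneRecord, TFRecord
from .network import RegulatoryNetwork


@dataclasses.dataclass(frozen=True)
class PrognosisScore:
    tf_id: str
    n_targets: int
    n_poor: int
    n_good: int
    score: float


def _labels_for(network: RegulatoryNetwork, gene_annotations: Mapping[str, GeneRecord] | None):
    annotations = gene_annotations if gene_annotations is not None else network.gene_annotations
    return {g: rec.prognosis_label for g, rec in annotations.items()}


def prognosis_score(
    network: RegulatoryNetwork,
    tf_id: str,
    gene_annotations: Mapping[str, GeneRecord] | None = None,
    labeled_only: bool = False,
) -> PrognosisScore:
    """Score one TF over its gene-level targets.

    The denominator counts ALL targets; cancer-dependent and unlabeled genes
    dilute the score but do not shift its sign.  ``labeled_only`` switches to
    a poor+good denominator (off by default).  Unknown TF -> KeyError.
    """
    targets = network.gene_targets(tf_id)  # raises KeyError if absent
    labels = _labels_for(network, gene_annotations)
    n_poor = sum(1 for g in targets if labels.get(g) == "poor")
    n_good = sum(1 for g in targets if labels.get(g) == "good")
    denom = (n_poor + n_good) if labeled_only else len(targets)
    score = (n_poor - n_good) / denom if denom else 0.0
    return PrognosisScore(tf_id, len(targets), n_poor, n_good, score)


def score_all(
    network: RegulatoryNetwork,
    gene_annotations: Mapping[str, GeneRecord] | None = None,
    labeled_only: bool = False,
) -> pd.DataFrame:
    """Per-TF score table (tf_id, n_targets, n_poor, n_good, score)."""
    rows = [
        dataclasses.asdict(prognosis_score(network, tf, gene_annotations, labeled_only))
        for tf in network.tf_ids
    ]
    return pd.DataFrame(rows, columns=["tf_id", "n_targets", "n_poor", "n_good", "score"])


@dataclasses.dataclass
class NullEnsemble:
    """Per-TF permutation null of the prognosis score."""

    n_perm: int
    seed: int
    tf_ids: list[str]
    degrees: np.ndarray  # gene-level degree per TF
    observed: np.ndarray  # observed score per TF
    null_scores: np.ndarray  # shape (n_tfs, n_perm)
    p_values: np.ndarray  # two-sided empirical, add-one smoothed

    def pooled_by_degree(self) -> dict[int, np.ndarray]:
        """Null scores pooled over TFs sharing a gene-level degree."""
        pools: dict[int, list[np.ndarray]] = {}
        for i, d in enumerate(self.degrees):
            pools.setdefault(int(d), []).append(self.null_scores[i])
        return {d: np.concatenate(arrs) for d, arrs in sorted(pools.items())}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tf_id": self.tf_ids,
                "degree": self.degrees,
                "observed_score": self.observed,
                "null_mean": self.null_scores.mean(axis=1),
                "null_sd": self.null_scores.std(axis=1),
                "p_value": self.p_values,
            }
        )


def permutation_null(
    network: RegulatoryNetwork,
    n_perm: int = 1000,
    seed: int = 0,
    gene_annotations: Mapping[str, GeneRecord] | None = None,
) -> NullEnsemble:
    """Build the permutation null by shuffling gene prognosis labels.

    Each replicate permutes the gene -> label assignment over the annotated
    gene universe (the label multiset is preserved and network edges are
    untouched) and recomputes every TF's score.  Two-sided empirical p-values:
    p = (1 + #{|null| >= |observed|}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = _labels_for(network, gene_annotations)
    # universe: every annotated gene plus any network gene lacking annotation
    genes = sorted(set(labels) | {i.gene_id for i in network.interactions})
    gene_index = {g: i for i, g in enumerate(genes)}

    tf_ids = network.tf_ids
    membership = np.zeros((len(tf_ids), len(genes)), dtype=np.float64)
    for row, tf in enumerate(tf_ids):
        for g in network.gene_targets(tf):
            if g in gene_index:
                membership[row, gene_index[g]] = 1.0
    degrees = membership.sum(axis=1)

    label_codes = np.array(
        [{"poor": 1, "good": -1}.get(labels.get(g), 0) for g in genes], dtype=np.float64
    )
    # score numerator = membership @ (poor - good indicator); denominator = degree
    safe_deg = np.where(degrees > 0, degrees, 1.0)
    observed = (membership @ label_codes) / safe_deg

    rng = np.random.default_rng(seed)
    perms = np.empty((len(genes), n_perm), dtype=np.float64)
    for j in range(n_perm):
        perms[:, j] = label_codes[rng.permutation(len(genes))]
    null_scores = (membership @ perms) / safe_deg[:, None]

    exceed = (np.abs(null_scores) >= np.abs(observed)[:, None]).sum(axis=1)
    p_values = (1.0 + exceed) / (1.0 + n_perm)
    return NullEnsemble(
        n_perm=n_perm,
        seed=seed,
        tf_ids=tf_ids,
        degrees=degrees.astype(int),
        observed=observed,
        null_scores=null_scores,
        p_values=p_values,
    )


@dataclasses.dataclass(frozen=True)
class NominationResult:
    nominations: dict[str, tuple[str, ...]]  # oncogene gene_id -> nominated TFs
    n_oncogenes_tested: int
    n_oncogenes_with_nominee: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": gene, "tf_id": tf}
            for gene, tfs in sorted(self.nominations.items())
            for tf in tfs
        ]
        return pd.DataFrame(rows, columns=["gene_id", "tf_id"])


def nominate_targetable(
    network: RegulatoryNetwork,
    scores: Mapping[str, float] | pd.DataFrame | None = None,
    tf_annotations: Mapping[str, TFRecord] | None = None,
    score_threshold: float = 0.33,
) -> NominationResult:
    """Nominate TFs whose inhibition could reduce each oncogene's expression.

    For every oncogene in the network, selects its promoter-binding TFs that
    (1) are annotated activators or bifunctional and (2) have prognosis score
    strictly greater than ``score_threshold``.  Scores default to
    :func:`score_all` on the network's own annotations.
    """
    tf_ann = tf_annotations if tf_annotations is not None else network.tf_annotations
    if scores is None:
        scores = score_all(network)
    if isinstance(scores, pd.DataFrame):
        scores = dict(zip(scores["tf_id"], scores["score"]))

    oncogenes = sorted(
        {
            i.gene_id
            for i in network.interactions
            if network.gene_annotations.get(i.gene_id) is not None
            and network.gene_annotations[i.gene_id].role == "oncogene"
        }
    )
    nominations = {}
    for gene in oncogenes:
        nominees = tuple(
            sorted(
                tf
                for tf in network.tfs_binding_gene(gene)
                if tf in tf_ann
                and tf_ann[tf].effector_class in ("activator", "bifunctional")
                and scores.get(tf, 0.0) > score_threshold
            )
        )
        nominations[gene] = nominees
    return NominationResult(
        nominations=nominations,
        n_oncogenes_tested=len(oncogenes),
        n_oncogenes_with_nominee=sum(1 for tfs in nominations.values() if tfs),
    )
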