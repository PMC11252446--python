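"""Closed vocabularies, thresholds, and pipeline configuration.

All categorical vocabularies used across the package (TF families, effector
classes, prognosis labels, gene roles, assay names, pair verdicts) are declared
here so that annotation readers, the synthetic-world generator, and the
statistics modules share one source of truth.  Thresholds carry the screen's
operating points: the ordinal reporter scale, the "moderate" cut separating
no/weak from moderate/strong signal, the autoactivity cut for pY1H bait
selection, the hub degree, the nomination prognosis-score cut, and the SWIM-seq
alignment fraction required to confirm a promoter strain.
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

# --- closed vocabularies -----------------------------------------------------

TF_FAMILIES: tuple[str, ...] = (
    "ZF-C2H2",
    "NHR",
    "bHLH",
    "bZIP",
    "homeodomain",
    "AP-2",
    "EBF1",
    "grainyhead",
    "forkhead",
    "ETS",
    "other",
)

EFFECTOR_CLASSES: tuple[str, ...] = ("activator", "repressor", "bifunctional", "unknown")

PROGNOSIS_LABELS: tuple[str, ...] = ("poor", "good", "cancer_dependent", "unknown")

GENE_ROLES: tuple[str, ...] = ("oncogene", "tsg", "fusion", "other")

ASSAYS: tuple[str, ...] = ("eY1H", "pY1H_monomer", "pY1H_pair")

EVIDENCE_CLASSES: tuple[str, ...] = ("novel", "chip_only", "literature_only", "both")

PAIR_VERDICTS: tuple[str, ...] = (
    "cooperative",
    "antagonistic",
    "independent",
    "none",
    "unscorable",
)

#: Ordinal colony reporter scale: 0 none, 1 weak, 2 moderate, 3 strong.
LEVELS: tuple[int, ...] = (0, 1, 2, 3)

#: Levels counted as "moderate or strong" reporter activity.
MODERATE_LEVEL = 2


@dataclasses.dataclass
class PipelineConfig:
    """Tunable operating points of the pipeline.

    Defaults reproduce the screen's published rules: a 2 kb promoter window,
    activity above empty-control background in >= 3 of 4 colonies for an eY1H
    positive, baits with empty-control consensus < 2 eligible for pY1H, hubs at
    degree >= 10, nomination at prognosis score strictly > 0.33, SWIM-seq
    confirmation at >= 25% of pMW3 reads, 1,000 label permutations.
    """

    promoter_length: int = 2000
    strict_promoter_length: bool = False
    autoactivity_max_level: int = 2  # retain baits with control consensus < this
    hub_degree: int = 10
    nomination_score_threshold: float = 0.33
    swim_threshold: float = 0.25
    n_perm: int = 1000
    labeled_only_denominator: bool = False  # alternative prognosis-score denominator
    seed: int | None = None

    def validate(self) -> None:
        if not 0 < self.promoter_length:
            raise ValueError("promoter_length must be positive")
        if self.autoactivity_max_level not in LEVELS:
            raise ValueError("autoactivity_max_level must be an ordinal level 0-3")
        if self.hub_degree < 1:
            raise ValueError("hub_degree must be >= 1")
        if not -1.0 <= self.nomination_score_threshold <= 1.0:
            raise ValueError("nomination_score_threshold must be in [-1, 1]")
        if not 0.0 <= self.swim_threshold <= 1.0:
            raise ValueError("swim_threshold must be in [0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a TOML file.

    Unknown keys raise ``ValueError`` so that typos in config files fail loudly.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg
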