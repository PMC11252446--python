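"""Core domain records shared across the pipeline.

Coordinates are 0-based, half-open everywhere.  A promoter region covers the
2 kb immediately upstream of a transcription start site: on the + strand the
region ends at the TSS (``end == tss``), on the - strand it starts at the TSS
(``start == tss``).
"""

from __future__ import annotations

import dataclasses

from . import config


class ValidationError(ValueError):
    """A record violates a domain invariant."""


class FormatError(ValueError):
    """An input file does not match its declared grammar."""


@dataclasses.dataclass(frozen=True)
class TFRecord:
    tf_id: str
    symbol: str
    family: str = "other"
    effector_class: str = "unknown"
    in_ey1h_array: bool = True
    in_py1h_array: bool = False

    def __post_init__(self) -> None:
        if self.family not in config.TF_FAMILIES:
            raise ValidationError(f"unknown TF family {self.family!r} for {self.tf_id}")
        if self.effector_class not in config.EFFECTOR_CLASSES:
            raise ValidationError(
                f"unknown effector class {self.effector_class!r} for {self.tf_id}"
            )


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    symbol: str
    role: str = "other"
    prognosis_label: str = "unknown"

    def __post_init__(self) -> None:
        if self.role not in config.GENE_ROLES:
            raise ValidationError(f"unknown gene role {self.role!r} for {self.gene_id}")
        if self.prognosis_label not in config.PROGNOSIS_LABELS:
            raise ValidationError(
                f"unknown prognosis label {self.prognosis_label!r} for {self.gene_id}"
            )


@dataclasses.dataclass(frozen=True)
class PromoterRegion:
    promoter_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"{self.promoter_id}: negative start")
        if self.start >= self.end:
            raise ValidationError(f"{self.promoter_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.promoter_id}: strand must be + or -")
        expected_tss = self.end if self.strand == "+" else self.start
        if self.tss != expected_tss:
            raise ValidationError(
                f"{self.promoter_id}: tss {self.tss} inconsistent with strand "
                f"{self.strand} (expected {expected_tss})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_bed_fields(
        cls,
        chrom: str,
        start: int,
        end: int,
        name: str,
        strand: str,
    ) -> "PromoterRegion":
        """Build from BED6 fields; TSS inferred from strand.

        The BED name field is ``promoter_id`` or ``promoter_id|gene_id``; when
        no gene is given the promoter id doubles as the gene id.
        """
        if "|" in name:
            promoter_id, gene_id = name.split("|", 1)
        else:
            promoter_id, gene_id = name, name
        tss = end if strand == "+" else start
        return cls(promoter_id, gene_id, chrom, start, end, strand, tss)


@dataclasses.dataclass(frozen=True)
class QuadReadout:
    """Reporter levels of one strain x bait test in adjacent quadruplicate.

    ``tf_key`` is a single TF id, ``"tf1|tf2"`` for a TF-pair strain, or ``""``
    for the empty control.  Levels are ordinals 0 (none) to 3 (strong).
    """

    tf_key: str
    promoter_id: str
    colony_levels: tuple[int, int, int, int]
    mated_growth: bool = True
    imaging_day: int = 7

    def __post_init__(self) -> None:
        if len(self.colony_levels) != 4:
            raise ValidationError(
                f"{self.tf_key}x{self.promoter_id}: exactly four colony levels required"
            )
        for lev in self.colony_levels:
            if lev not in config.LEVELS:
                raise ValidationError(
                    f"{self.tf_key}x{self.promoter_id}: colony level {lev!r} outside 0-3"
                )

    @property
    def is_control(self) -> bool:
        return self.tf_key == ""

    @property
    def is_pair(self) -> bool:
        return "|" in self.tf_key

    @property
    def tf_ids(self) -> tuple[str, ...]:
        return tuple(self.tf_key.split("|")) if self.tf_key else ()


@dataclasses.dataclass(frozen=True)
class ChipPeak:
    chrom: str
    start: int
    end: int
    tf_symbol: str
    score: float = 0.0
    strand: str = "."
    signal_value: float = 0.0
    p_value: float = -1.0
    q_value: float = -1.0
    summit: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"peak {self.tf_symbol} {self.chrom}:{self.start}-{self.end}: start >= end"
            )

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclasses.dataclass(frozen=True)
class MutationSummary:
    tf_id: str
    total_cases: int
    mutated_cases: int
    synonymous_cases: int

    def __post_init__(self) -> None:
        if not 0 <= self.synonymous_cases <= self.mutated_cases <= self.total_cases:
            raise ValidationError(
                f"{self.tf_id}: need synonymous <= mutated <= total cases, got "
                f"{self.synonymous_cases}/{self.mutated_cases}/{self.total_cases}"
            )


@dataclasses.dataclass(frozen=True)
class AlignmentSummary:
    strain_id: str
    vector: str
    reads_total: int
    reads_matching_expected: int

    def __post_init__(self) -> None:
        if self.vector not in ("pMW2", "pMW3"):
            raise ValidationError(f"{self.strain_id}: vector must be pMW2 or pMW3")
        if not 0 <= self.reads_matching_expected <= self.reads_total:
            raise ValidationError(
                f"{self.strain_id}: matching reads exceed total reads"
            )
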