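"""Readers and writers for the pipeline's external text formats.

Formats: BED6 for promoter regions (name field ``promoter_id|gene_id``),
narrowPeak (BED6+4) for ChIP-seq peaks with the TF symbol in the name column,
and tab-separated tables with declared headers for colony readouts, TF/gene
annotations, literature flags, mutation summaries, SWIM-seq alignment
summaries, interaction calls, and TF-pair outcomes.  Every writer/reader pair
round-trips its record collection exactly.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

import pandas as pd

from .model import (
    AlignmentSummary,
    ChipPeak,
    FormatError,
    GeneRecord,
    MutationSummary,
    PromoterRegion,
    QuadReadout,
    TFRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

READOUT_COLUMNS = [
    "tf_key",
    "promoter_id",
    "colony_1",
    "colony_2",
    "colony_3",
    "colony_4",
    "mated_growth",
    "imaging_day",
]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    _require_columns(df, required, path)
    return df


# --- quadruplicate colony readouts ------------------------------------------


def parse_readout_table(path: str | Path) -> list[QuadReadout]:
    """Parse a tab-separated readout table into QuadReadout records.

    One row per strain x promoter with four ordinal colony-level columns.
    An empty ``tf_key`` denotes the empty-control strain.  Levels outside
    {0..3} raise :class:`ValidationError` naming the offending row.
    """
    df = _read_tsv(path, READOUT_COLUMNS)
    records = []
    level_cols = ["colony_1", "colony_2", "colony_3", "colony_4"]
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        levels = []
        for col in level_cols:
            token = getattr(row, col)
            try:
                value = int(token)
            except ValueError:
                raise ValidationError(
                    f"{path} line {i}: colony level {token!r} is not an integer"
                ) from None
            if value not in (0, 1, 2, 3):
                raise ValidationError(
                    f"{path} line {i}: colony level {value} outside 0-3"
                )
            levels.append(value)
        records.append(
            QuadReadout(
                tf_key=row.tf_key,
                promoter_id=row.promoter_id,
                colony_levels=tuple(levels),
                mated_growth=_parse_bool(row.mated_growth, path, i),
                imaging_day=int(row.imaging_day),
            )
        )
    return records


def write_readout_table(records: Iterable[QuadReadout], path: str | Path) -> None:
    rows = [
        {
            "tf_key": r.tf_key,
            "promoter_id": r.promoter_id,
            "colony_1": r.colony_levels[0],
            "colony_2": r.colony_levels[1],
            "colony_3": r.colony_levels[2],
            "colony_4": r.colony_levels[3],
            "mated_growth": str(r.mated_growth),
            "imaging_day": r.imaging_day,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=READOUT_COLUMNS).to_csv(path, sep="\t", index=False)


def _parse_bool(token: str, path: object, line: int) -> bool:
    if token in ("True", "true", "1"):
        return True
    if token in ("False", "false", "0"):
        return False
    raise ValidationError(f"{path} line {line}: boolean token {token!r} not recognized")


# --- promoter regions (BED6) -------------------------------------------------


def parse_promoter_bed(
    path: str | Path,
    expected_length: int = 2000,
    strict_length: bool = False,
) -> list[PromoterRegion]:
    """Parse a BED6 file of promoter regions.

    The TSS is inferred from the strand (end for +, start for -).  Regions
    whose length differs from ``expected_length`` warn by default and raise
    only under ``strict_length``.
    """
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"{path} line {lineno}: BED6 requires 6 columns (strand present)"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"{path} line {lineno}: malformed coordinates {start_s!r}/{end_s!r}"
                ) from None
            try:
                region = PromoterRegion.from_bed_fields(chrom, start, end, name, strand)
            except ValidationError as exc:
                raise ValidationError(f"{path} line {lineno}: {exc}") from None
            if region.length != expected_length:
                message = (
                    f"{path} line {lineno}: promoter {region.promoter_id} has length "
                    f"{region.length}, expected {expected_length}"
                )
                if strict_length:
                    raise ValidationError(message)
                logger.warning(message)
            regions.append(region)
    return regions


def write_promoter_bed(regions: Iterable[PromoterRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            name = r.promoter_id if r.promoter_id == r.gene_id else f"{r.promoter_id}|{r.gene_id}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


# --- ChIP-seq peaks (narrowPeak) ---------------------------------------------


def parse_narrowpeak(path: str | Path) -> list[ChipPeak]:
    """Parse a MACS2-style narrowPeak (BED6+4) file; TF symbol in the name column."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise FormatError(
                    f"{path} line {lineno}: narrowPeak requires 10 columns"
                )
            try:
                peak = ChipPeak(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    tf_symbol=fields[3],
                    score=float(fields[4]),
                    strand=fields[5],
                    signal_value=float(fields[6]),
                    p_value=float(fields[7]),
                    q_value=float(fields[8]),
                    summit=int(fields[9]),
                )
            except ValueError as exc:
                raise FormatError(f"{path} line {lineno}: {exc}") from None
            peaks.append(peak)
    return peaks


def write_narrowpeak(peaks: Iterable[ChipPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.tf_symbol}\t{p.score:g}\t{p.strand}"
                f"\t{p.signal_value:g}\t{p.p_value:g}\t{p.q_value:g}\t{p.summit}\n"
            )


# --- annotation tables -------------------------------------------------------

TF_COLUMNS = ["tf_id", "symbol", "family", "effector_class", "in_ey1h_array", "in_py1h_array"]
GENE_COLUMNS = ["gene_id", "symbol", "role", "prognosis_label"]


def parse_tf_table(path: str | Path) -> list[TFRecord]:
    df = _read_tsv(path, TF_COLUMNS)
    return [
        TFRecord(
            tf_id=row.tf_id,
            symbol=row.symbol,
            family=row.family,
            effector_class=row.effector_class,
            in_ey1h_array=_parse_bool(row.in_ey1h_array, path, i),
            in_py1h_array=_parse_bool(row.in_py1h_array, path, i),
        )
        for i, row in enumerate(df.itertuples(index=False), start=2)
    ]


def write_tf_table(records: Iterable[TFRecord], path: str | Path) -> None:
    rows = [
        {
            "tf_id": r.tf_id,
            "symbol": r.symbol,
            "family": r.family,
            "effector_class": r.effector_class,
            "in_ey1h_array": str(r.in_ey1h_array),
            "in_py1h_array": str(r.in_py1h_array),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=TF_COLUMNS).to_csv(path, sep="\t", index=False)


def parse_gene_table(path: str | Path) -> list[GeneRecord]:
    df = _read_tsv(path, GENE_COLUMNS)
    return [
        GeneRecord(
            gene_id=row.gene_id,
            symbol=row.symbol,
            role=row.role,
            prognosis_label=row.prognosis_label,
        )
        for row in df.itertuples(index=False)
    ]


def write_gene_table(records: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "symbol": r.symbol,
            "role": r.role,
            "prognosis_label": r.prognosis_label,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# --- mutation and alignment summaries ---------------------------------------

MUTATION_COLUMNS = ["tf_id", "total_cases", "mutated_cases", "synonymous_cases"]
ALIGNMENT_COLUMNS = ["strain_id", "vector", "reads_total", "reads_matching_expected"]


def parse_mutation_table(path: str | Path) -> list[MutationSummary]:
    df = _read_tsv(path, MUTATION_COLUMNS)
    return [
        MutationSummary(
            tf_id=row.tf_id,
            total_cases=int(row.total_cases),
            mutated_cases=int(row.mutated_cases),
            synonymous_cases=int(row.synonymous_cases),
        )
        for row in df.itertuples(index=False)
    ]


def write_mutation_table(records: Iterable[MutationSummary], path: str | Path) -> None:
    rows = [
        {
            "tf_id": r.tf_id,
            "total_cases": r.total_cases,
            "mutated_cases": r.mutated_cases,
            "synonymous_cases": r.synonymous_cases,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=MUTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def parse_alignment_table(path: str | Path) -> list[AlignmentSummary]:
    df = _read_tsv(path, ALIGNMENT_COLUMNS)
    return [
        AlignmentSummary(
            strain_id=row.strain_id,
            vector=row.vector,
            reads_total=int(row.reads_total),
            reads_matching_expected=int(row.reads_matching_expected),
        )
        for row in df.itertuples(index=False)
    ]


def write_alignment_table(records: Iterable[AlignmentSummary], path: str | Path) -> None:
    rows = [
        {
            "strain_id": r.strain_id,
            "vector": r.vector,
            "reads_total": r.reads_total,
            "reads_matching_expected": r.reads_matching_expected,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


# --- literature evidence flags ----------------------------------------------

LITERATURE_COLUMNS = ["tf_id", "gene_id"]


def parse_literature_flags(path: str | Path) -> set[tuple[str, str]]:
    """Curated literature evidence: one (tf_id, gene_id) pair per row."""
    df = _read_tsv(path, LITERATURE_COLUMNS)
    return {(row.tf_id, row.gene_id) for row in df.itertuples(index=False)}


def write_literature_flags(flags: Iterable[tuple[str, str]], path: str | Path) -> None:
    rows = [{"tf_id": t, "gene_id": g} for t, g in sorted(flags)]
    pd.DataFrame(rows, columns=LITERATURE_COLUMNS).to_csv(path, sep="\t", index=False)


# --- interaction calls and pair outcomes (supplementary-table dialects) ------

INTERACTION_COLUMNS = ["tf_id", "promoter_id", "gene_id", "assay", "evidence_class"]
PAIR_COLUMNS = [
    "tf1_id",
    "tf2_id",
    "promoter_id",
    "verdict",
    "antagonized_tfs",
    "cooperativity_index",
    "antagonism_index_1",
    "antagonism_index_2",
]


def parse_interaction_table(path: str | Path) -> pd.DataFrame:
    """Read a called-interactions table (one row per TF x promoter edge)."""
    return _read_tsv(path, INTERACTION_COLUMNS)


def write_interaction_table(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, INTERACTION_COLUMNS, path)
    df.loc[:, INTERACTION_COLUMNS].to_csv(path, sep="\t", index=False)


def parse_pair_table(path: str | Path) -> pd.DataFrame:
    """Read a TF-pair outcome table (one row per pair x promoter verdict)."""
    df = _read_tsv(path, PAIR_COLUMNS)
    for col in ("cooperativity_index", "antagonism_index_1", "antagonism_index_2"):
        df[col] = df[col].astype(int)
    return df


def write_pair_table(df: pd.DataFrame, path: str | Path) -> None:
    _require_columns(df, PAIR_COLUMNS, path)
    df.loc[:, PAIR_COLUMNS].to_csv(path, sep="\t", index=False)
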