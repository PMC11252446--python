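"""End-to-end orchestration of the screen-analysis stages.

Stages communicate through tab-separated files in a working directory, so
each stage is independently re-runnable: simulate -> call-ey1h -> call-py1h ->
build-network -> annotate-evidence -> prognosis -> permute -> nominate ->
enrich -> qc -> report.  Every stage's output is written before the next
stage starts, and the final report aggregates all summary counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import calling, io, network as net, prognosis as prog, qc as qc_mod, simulate, stats
from .config import PipelineConfig

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class ScreenDesign:
    """Tested-grid bookkeeping for the two screens.

    Single-TF tests are counted as TF x gene pairs (each gene's promoters are
    screened against the whole array); pair tests as TF-pair x promoter sets.
    """

    n_array_tfs: int
    n_genes: int
    n_promoters: int
    n_tf_pairs: int
    n_pair_promoters: int

    @property
    def n_ey1h_tests(self) -> int:
        return self.n_array_tfs * self.n_genes

    @property
    def n_py1h_tests(self) -> int:
        return self.n_tf_pairs * self.n_pair_promoters


def _positives_frame(calls: dict[tuple[str, str], calling.CallStatus], assay: str) -> pd.DataFrame:
    rows = [
        {"tf_id": tf, "promoter_id": pid, "assay": assay, "status": status.value}
        for (tf, pid), status in sorted(calls.items())
    ]
    return pd.DataFrame(rows, columns=["tf_id", "promoter_id", "assay", "status"])


def stage_call_ey1h(readout_path: Path, out_path: Path) -> pd.DataFrame:
    """Call the single-TF screen; writes one row per scorable test."""
    readouts = io.parse_readout_table(readout_path)
    calls = calling.call_ey1h_screen(readouts)
    frame = _positives_frame(calls, "eY1H")
    frame.to_csv(out_path, sep="\t", index=False)
    return frame


def stage_call_py1h(
    readout_path: Path,
    pairs_out: Path,
    monomers_out: Path,
    autoactivity_max_level: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call the TF-pair screen.

    Produces the pair-outcome table (one row per pair x promoter) and an
    eY1H-style call table for the monomer strains riding on the same plates.
    Baits whose empty-empty control is autoactive are dropped up front.
    """
    readouts = io.parse_readout_table(readout_path)
    latest = calling.latest_day_readouts(readouts)
    background = {pid: calling.score_quad(r) for (tf, pid), r in latest.items() if tf == ""}
    all_promoters = {pid for _, pid in latest}
    eligible = set(
        calling.filter_autoactive(sorted(all_promoters), background, autoactivity_max_level)
    )

    pair_keys = sorted(
        {(r.tf_key, r.promoter_id) for r in latest.values() if r.is_pair}
    )
    outcome_rows = []
    for pair_key, pid in pair_keys:
        if pid not in eligible:
            continue
        tf1_id, tf2_id = pair_key.split("|")
        pair_q = latest[(pair_key, pid)]
        tf1_q = latest.get((tf1_id, pid))
        tf2_q = latest.get((tf2_id, pid))
        if tf1_q is None or tf2_q is None:
            logger.warning("pair %s at %s lacks monomer readouts; skipped", pair_key, pid)
            continue
        out = calling.call_py1h(pair_q, tf1_q, tf2_q, background.get(pid))
        outcome_rows.append(
            {
                "tf1_id": out.tf1_id,
                "tf2_id": out.tf2_id,
                "promoter_id": out.promoter_id,
                "verdict": out.verdict,
                "antagonized_tfs": ",".join(out.antagonized_tfs),
                "cooperativity_index": out.cooperativity_index,
                "antagonism_index_1": out.antagonism_index_1,
                "antagonism_index_2": out.antagonism_index_2,
            }
        )
    pair_frame = pd.DataFrame(outcome_rows, columns=io.PAIR_COLUMNS)
    io.write_pair_table(pair_frame, pairs_out)

    monomer_calls = {}
    for (tf, pid), readout in latest.items():
        if tf == "" or readout.is_pair or pid not in eligible:
            continue
        monomer_calls[(tf, pid)] = calling.call_ey1h(readout, background.get(pid))
    monomer_frame = _positives_frame(monomer_calls, "pY1H_monomer")
    monomer_frame.to_csv(monomers_out, sep="\t", index=False)
    return pair_frame, monomer_frame


def _collect_positive_calls(
    ey1h_calls: pd.DataFrame | None,
    monomer_calls: pd.DataFrame | None,
    pair_outcomes: pd.DataFrame | None,
) -> list[tuple[str, str, str]]:
    calls: list[tuple[str, str, str]] = []
    for frame in (ey1h_calls, monomer_calls):
        if frame is None or frame.empty:
            continue
        pos = frame[frame["status"] == "positive"]
        calls.extend(zip(pos["tf_id"], pos["promoter_id"], pos["assay"]))
    if pair_outcomes is not None and not pair_outcomes.empty:
        coop = pair_outcomes[pair_outcomes["verdict"] == "cooperative"]
        calls.extend(
            (f"{t1}|{t2}", pid, "pY1H_pair")
            for t1, t2, pid in zip(coop["tf1_id"], coop["tf2_id"], coop["promoter_id"])
        )
    return calls


def stage_build_network(
    workdir: Path,
    promoters_bed: Path,
    tf_table: Path,
    gene_table: Path,
    out_path: Path,
) -> net.RegulatoryNetwork:
    """Assemble the deduplicated network from all positive calls on disk."""

    def maybe(name: str) -> pd.DataFrame | None:
        path = workdir / name
        return pd.read_csv(path, sep="\t", dtype=str) if path.exists() else None

    ey1h = maybe("ey1h_calls.tsv")
    monomers = maybe("py1h_monomer_calls.tsv")
    pairs_path = workdir / "pair_outcomes.tsv"
    pairs = io.parse_pair_table(pairs_path) if pairs_path.exists() else None

    promoters = {r.promoter_id: r for r in io.parse_promoter_bed(promoters_bed)}
    tf_ann = {r.tf_id: r for r in io.parse_tf_table(tf_table)}
    gene_ann = {r.gene_id: r for r in io.parse_gene_table(gene_table)}
    network = net.build_network(
        _collect_positive_calls(ey1h, monomers, pairs), promoters, tf_ann, gene_ann
    )
    io.write_interaction_table(network.to_frame(), out_path)
    return network


def stage_annotate_evidence(
    network: net.RegulatoryNetwork,
    peaks_path: Path | None,
    flags_path: Path | None,
    out_path: Path,
) -> dict[str, int]:
    peaks = io.parse_narrowpeak(peaks_path) if peaks_path and peaks_path.exists() else []
    flags = (
        io.parse_literature_flags(flags_path) if flags_path and flags_path.exists() else set()
    )
    counts = net.classify_evidence(network, peaks, flags)
    io.write_interaction_table(network.to_frame(), out_path)
    return counts


@dataclasses.dataclass
class RunReport:
    counts: dict

    def to_json(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.counts, fh, indent=2, sort_keys=True)


def run_pipeline(
    workdir: str | Path,
    config: PipelineConfig | None = None,
    world_params: simulate.WorldParams | None = None,
) -> RunReport:
    """Run every stage in order inside ``workdir``.

    When ``world_params`` is given, a synthetic world is generated first and
    its files become the pipeline inputs; otherwise the expected input files
    must already exist in ``workdir``.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    cfg = config or PipelineConfig()
    cfg.validate()

    if world_params is not None:
        simulate.emit_files(simulate.generate_world(world_params), workdir)

    ey1h_frame = stage_call_ey1h(workdir / "ey1h_readouts.tsv", workdir / "ey1h_calls.tsv")

    py1h_path = workdir / "py1h_readouts.tsv"
    if py1h_path.exists():
        pair_frame, _ = stage_call_py1h(
            py1h_path,
            workdir / "pair_outcomes.tsv",
            workdir / "py1h_monomer_calls.tsv",
            cfg.autoactivity_max_level,
        )
    else:
        pair_frame = pd.DataFrame(columns=io.PAIR_COLUMNS)

    network = stage_build_network(
        workdir,
        workdir / "promoters.bed",
        workdir / "tf_annotations.tsv",
        workdir / "gene_annotations.tsv",
        workdir / "interactions.tsv",
    )
    evidence_counts = stage_annotate_evidence(
        network,
        workdir / "peaks.narrowPeak",
        workdir / "literature_flags.tsv",
        workdir / "interactions.tsv",
    )

    scores = prog.score_all(network, labeled_only=cfg.labeled_only_denominator)
    scores.to_csv(workdir / "prognosis_scores.tsv", sep="\t", index=False)

    seed = cfg.seed if cfg.seed is not None else 0
    ensemble = prog.permutation_null(network, n_perm=cfg.n_perm, seed=seed)
    ensemble.to_frame().to_csv(workdir / "permutation_null.tsv", sep="\t", index=False)

    nominations = prog.nominate_targetable(
        network, scores, score_threshold=cfg.nomination_score_threshold
    )
    nominations.to_frame().to_csv(workdir / "nominations.tsv", sep="\t", index=False)

    tf_ann = list(network.tf_annotations.values())
    enrich_frames = []
    for unit in ("tfs", "interactions"):
        results = stats.family_proportion_test(network, tf_ann, unit=unit)
        frame = pd.DataFrame([dataclasses.asdict(r) for r in results])
        frame.insert(0, "unit", unit)
        enrich_frames.append(frame)
    pd.concat(enrich_frames, ignore_index=True).to_csv(
        workdir / "family_enrichment.tsv", sep="\t", index=False
    )

    pair_pref = stats.pair_family_preference(
        _pair_outcomes_from_frame(pair_frame), network.tf_annotations
    )
    pair_pref.to_csv(workdir / "pair_family_preference.tsv", sep="\t", index=False)

    alignments_path = workdir / "alignments.tsv"
    if alignments_path.exists():
        confirmations = qc_mod.confirm_strains(
            io.parse_alignment_table(alignments_path), cfg.swim_threshold
        )
    else:
        confirmations = pd.DataFrame(columns=["strain_id", "aligned_fraction", "confirmed", "status"])
    confirmations.to_csv(workdir / "strain_confirmations.tsv", sep="\t", index=False)

    dstats = net.degree_stats(network, hub_degree=cfg.hub_degree)
    verdict_counts = pair_frame["verdict"].value_counts().to_dict() if not pair_frame.empty else {}
    report = RunReport(
        counts={
            "n_interactions": network.n_interactions,
            "n_tfs": network.n_tfs,
            "n_genes": network.n_genes,
            "evidence_classes": evidence_counts,
            "n_novel_by_identity": network.n_interactions
            - evidence_counts["chip_only"]
            - evidence_counts["literature_only"]
            - evidence_counts["both"],
            "degree": {
                "n_tfs": dstats.n_tfs,
                "frac_degree_one": dstats.frac_degree_one,
                "frac_hub": dstats.frac_hub,
                "n_hubs": len(dstats.hubs),
                "max_degree": dstats.max_degree,
            },
            "n_cooperative": int(verdict_counts.get("cooperative", 0)),
            "n_antagonistic": int(verdict_counts.get("antagonistic", 0)),
            "n_oncogenes_tested": nominations.n_oncogenes_tested,
            "n_oncogenes_with_nominee": nominations.n_oncogenes_with_nominee,
            "n_strains_confirmed": int(confirmations["confirmed"].sum())
            if not confirmations.empty
            else 0,
            "n_perm": cfg.n_perm,
            "seed": seed,
        }
    )
    report.to_json(workdir / "report.json")
    return report


def _pair_outcomes_from_frame(frame: pd.DataFrame) -> list[calling.PairwiseOutcome]:
    outcomes = []
    for row in frame.itertuples(index=False):
        antagonized = tuple(t for t in str(row.antagonized_tfs).split(",") if t)
        outcomes.append(
            calling.PairwiseOutcome(
                tf1_id=row.tf1_id,
                tf2_id=row.tf2_id,
                promoter_id=row.promoter_id,
                verdict=row.verdict,
                antagonized_tfs=antagonized,
                cooperativity_index=int(row.cooperativity_index),
                antagonism_index_1=int(row.antagonism_index_1),
                antagonism_index_2=int(row.antagonism_index_2),
            )
        )
    return outcomes
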