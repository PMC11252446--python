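"""Synthetic screen worlds with known ground truth.

Generates complete, self-consistent inputs for every pipeline stage: a truth
bipartite TF-promoter network with power-law out-degrees, quadruplicate colony
readouts for the single-TF and TF-pair screens (with per-colony dropout and
false-activation noise so the >= 3/4 calling rule is actually exercised),
promoter regions, ChIP-seq peaks covering a fraction of true edges, literature
flags, mutation-case summaries, and SWIM-seq alignment summaries spanning the
confirmation boundary.  Every emitted file parses through :mod:`y1hnet.io`,
and at zero noise the calling + network stages reconstruct the truth exactly.

Also provides planted scenarios: a study-scale interaction/pair table set with
exact published-style counts (see :func:`make_planted_study`) and an
oncogene-nomination configuration with a known number of nominatable
oncogenes (:func:`make_planted_nomination`).
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .model import (
    AlignmentSummary,
    ChipPeak,
    GeneRecord,
    MutationSummary,
    PromoterRegion,
    QuadReadout,
    TFRecord,
)
from .network import RegulatoryNetwork, build_network

_PROMOTER_LENGTH = 2000
_PROMOTER_SPACING = 6000
_EDGE_LEVEL = 3  # reporter level of a true interaction's colonies
_AUTOACTIVE_LEVEL = 2  # empty-control level of an autoactive bait


def _check_probability_vector(name: str, probs: dict[str, float]) -> None:
    values = list(probs.values())
    if any(p < 0 or p > 1 for p in values):
        raise ValueError(f"{name}: probabilities must lie in [0, 1]")
    if abs(sum(values) - 1.0) > 1e-9:
        raise ValueError(f"{name}: probabilities must sum to 1, got {sum(values)}")


@dataclasses.dataclass
class WorldParams:
    """Generator settings; the defaults are the study conditions.

    300 TFs x 150 promoters (136 genes, ~10% with an alternative promoter) and
    50 TF pairs keep full-pipeline runs fast while preserving the structure of
    the real screens; 18% of baits are autoactive, mirroring the fraction of
    promoters excluded from the pair screen.  Colony noise is injected per
    colony: a true-edge colony drops out (no growth) with probability 0.1 and
    a non-edge colony shows spurious signal with probability 0.001.

    ``pair_relation_probabilities`` are conditional on the monomer truth:
    "cooperative" vs "none" apply where neither monomer binds (each pair of
    entries sums to 1), "antagonistic" vs "independent" where at least one
    monomer binds.
    """

    n_tfs: int = 300
    n_genes: int = 136
    alt_promoter_fraction: float = 0.1
    degree_exponent: float = -1.8
    max_degree: int = 54
    family_probabilities: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "ZF-C2H2": 0.25,
            "homeodomain": 0.16,
            "bHLH": 0.10,
            "bZIP": 0.10,
            "NHR": 0.08,
            "forkhead": 0.06,
            "ETS": 0.06,
            "AP-2": 0.03,
            "EBF1": 0.01,
            "grainyhead": 0.01,
            "other": 0.14,
        }
    )
    effector_probabilities: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "activator": 0.32,
            "repressor": 0.12,
            "bifunctional": 0.16,
            "unknown": 0.40,
        }
    )
    prognosis_probabilities: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "poor": 0.35,
            "good": 0.35,
            "cancer_dependent": 0.10,
            "unknown": 0.20,
        }
    )
    role_probabilities: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "oncogene": 0.40,
            "tsg": 0.40,
            "fusion": 0.10,
            "other": 0.10,
        }
    )
    colony_dropout_prob: float = 0.1
    colony_false_active_prob: float = 0.001
    pair_relation_probabilities: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "cooperative": 0.015,
            "none": 0.985,
            "antagonistic": 0.5,
            "independent": 0.5,
        }
    )
    n_tf_pairs: int = 50
    chip_coverage_prob: float = 0.45
    literature_flag_prob: float = 0.06
    autoactive_promoter_fraction: float = 0.18
    seed: int = 0

    def validate(self) -> None:
        if self.n_tfs < 1 or self.n_genes < 1:
            raise ValueError("n_tfs and n_genes must be positive")
        _check_probability_vector("family_probabilities", self.family_probabilities)
        _check_probability_vector("effector_probabilities", self.effector_probabilities)
        _check_probability_vector("prognosis_probabilities", self.prognosis_probabilities)
        _check_probability_vector("role_probabilities", self.role_probabilities)
        pr = self.pair_relation_probabilities
        for a, b in (("cooperative", "none"), ("antagonistic", "independent")):
            _check_probability_vector(
                f"pair_relation_probabilities[{a}/{b}]", {a: pr[a], b: pr[b]}
            )
        for name in (
            "alt_promoter_fraction",
            "colony_dropout_prob",
            "colony_false_active_prob",
            "chip_coverage_prob",
            "literature_flag_prob",
            "autoactive_promoter_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if 2 * self.n_tf_pairs > self.n_tfs:
            raise ValueError("need at least 2 TFs per pair in the array")


@dataclasses.dataclass
class SyntheticWorld:
    params: WorldParams
    tfs: list[TFRecord]
    genes: list[GeneRecord]
    promoters: dict[str, PromoterRegion]
    truth_edges: set[tuple[str, str]]  # (tf_id, promoter_id)
    truth_pair_relations: dict[tuple[str, str, str], str]  # (tf1, tf2, promoter) -> relation
    tf_pairs: list[tuple[str, str]]
    ey1h_readouts: list[QuadReadout]
    py1h_readouts: list[QuadReadout]
    peaks: list[ChipPeak]
    literature_flags: set[tuple[str, str]]
    mutation_summaries: list[MutationSummary]
    alignment_summaries: list[AlignmentSummary]
    autoactive_promoters: set[str]

    @property
    def truth_gene_edges(self) -> set[tuple[str, str]]:
        return {(tf, self.promoters[p].gene_id) for tf, p in self.truth_edges}


def _sample_powerlaw_degrees(
    rng: np.random.Generator, n: int, exponent: float, max_degree: int
) -> np.ndarray:
    degrees = np.arange(1, max_degree + 1, dtype=float)
    weights = degrees**exponent
    weights /= weights.sum()
    return rng.choice(np.arange(1, max_degree + 1), size=n, p=weights)


def _sample_categorical(
    rng: np.random.Generator, probs: dict[str, float], size: int
) -> list[str]:
    cats = list(probs)
    return list(rng.choice(cats, size=size, p=[probs[c] for c in cats]))


def _make_promoters(n_genes: int, alt_fraction: float) -> tuple[list[GeneRecord], dict[str, PromoterRegion]]:
    n_alt = int(round(n_genes * alt_fraction))
    promoters: dict[str, PromoterRegion] = {}
    gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    k = 0
    for gi, gene_id in enumerate(gene_ids):
        n_prom = 2 if gi < n_alt else 1
        for pi in range(n_prom):
            promoter_id = f"{gene_id}.P{pi + 1}"
            pos = 10_000 + k * _PROMOTER_SPACING
            strand = "+" if k % 2 == 0 else "-"
            start, end = pos, pos + _PROMOTER_LENGTH
            tss = end if strand == "+" else start
            promoters[promoter_id] = PromoterRegion(
                promoter_id, gene_id, "chr1", start, end, strand, tss
            )
            k += 1
    return gene_ids, promoters


def generate_world(params: WorldParams) -> SyntheticWorld:
    """Sample a complete synthetic screen world from the given parameters."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    gene_ids, promoters = _make_promoters(params.n_genes, params.alt_promoter_fraction)
    promoter_ids = list(promoters)
    n_prom = len(promoter_ids)

    # --- annotations ---------------------------------------------------------
    tf_ids = [f"TF{i + 1:04d}" for i in range(params.n_tfs)]
    families = _sample_categorical(rng, params.family_probabilities, params.n_tfs)
    effectors = _sample_categorical(rng, params.effector_probabilities, params.n_tfs)
    pair_members = set(
        rng.choice(params.n_tfs, size=2 * params.n_tf_pairs, replace=False).tolist()
    )
    tfs = [
        TFRecord(
            tf_id=tf_ids[i],
            symbol=f"Sym{tf_ids[i]}",
            family=families[i],
            effector_class=effectors[i],
            in_ey1h_array=True,
            in_py1h_array=i in pair_members,
        )
        for i in range(params.n_tfs)
    ]
    labels = _sample_categorical(rng, params.prognosis_probabilities, params.n_genes)
    roles = _sample_categorical(rng, params.role_probabilities, params.n_genes)
    genes = [
        GeneRecord(gene_id=g, symbol=f"Sym{g}", role=roles[i], prognosis_label=labels[i])
        for i, g in enumerate(gene_ids)
    ]

    # --- truth network (labels above are drawn independently of these edges) --
    max_degree = min(params.max_degree, n_prom)
    degrees = _sample_powerlaw_degrees(rng, params.n_tfs, params.degree_exponent, max_degree)
    edge_matrix = np.zeros((params.n_tfs, n_prom), dtype=bool)
    for i, d in enumerate(degrees):
        targets = rng.choice(n_prom, size=int(d), replace=False)
        edge_matrix[i, targets] = True
    truth_edges = {
        (tf_ids[i], promoter_ids[j]) for i, j in zip(*np.nonzero(edge_matrix))
    }

    # --- autoactive baits ----------------------------------------------------
    n_auto = int(round(params.autoactive_promoter_fraction * n_prom))
    auto_idx = set(rng.choice(n_prom, size=n_auto, replace=False).tolist())
    bg = np.array(
        [_AUTOACTIVE_LEVEL if j in auto_idx else 0 for j in range(n_prom)], dtype=int
    )
    autoactive_promoters = {promoter_ids[j] for j in auto_idx}

    # --- single-TF screen readouts -------------------------------------------
    shape = (params.n_tfs, n_prom, 4)
    base = np.where(edge_matrix[:, :, None], _EDGE_LEVEL, bg[None, :, None])
    drop = rng.random(shape) < params.colony_dropout_prob
    levels = np.where(drop, 0, base)
    false_mask = (rng.random(shape) < params.colony_false_active_prob) & ~edge_matrix[
        :, :, None
    ]
    fa_levels = rng.integers(1, 4, size=shape)
    levels = np.where(false_mask, np.maximum(levels, fa_levels), levels)

    ey1h_readouts = [
        QuadReadout("", pid, (int(b),) * 4) for pid, b in zip(promoter_ids, bg)
    ]
    for i in range(params.n_tfs):
        for j in range(n_prom):
            ey1h_readouts.append(
                QuadReadout(
                    tf_ids[i], promoter_ids[j], tuple(int(x) for x in levels[i, j])
                )
            )

    # --- TF-pair screen -------------------------------------------------------
    pair_list = sorted(pair_members)
    tf_pairs = [
        (tf_ids[pair_list[2 * k]], tf_ids[pair_list[2 * k + 1]])
        for k in range(params.n_tf_pairs)
    ]
    eligible = [j for j in range(n_prom) if bg[j] < _AUTOACTIVE_LEVEL]
    pr = params.pair_relation_probabilities

    def noisy_quad(level: int) -> tuple[int, int, int, int]:
        out = []
        for _ in range(4):
            lev = level
            if lev > 0 and rng.random() < params.colony_dropout_prob:
                lev = 0
            elif lev == 0 and rng.random() < params.colony_false_active_prob:
                lev = int(rng.integers(1, 4))
            out.append(lev)
        return tuple(out)

    py1h_readouts = [QuadReadout("", promoter_ids[j], (0, 0, 0, 0)) for j in eligible]
    truth_pair_relations: dict[tuple[str, str, str], str] = {}
    tf_index = {tf: i for i, tf in enumerate(tf_ids)}
    for tf1, tf2 in tf_pairs:
        for j in eligible:
            pid = promoter_ids[j]
            e1 = edge_matrix[tf_index[tf1], j]
            e2 = edge_matrix[tf_index[tf2], j]
            if e1 or e2:
                relation = (
                    "antagonistic" if rng.random() < pr["antagonistic"] else "independent"
                )
            else:
                relation = "cooperative" if rng.random() < pr["cooperative"] else "none"
            pair_level = _EDGE_LEVEL if relation in ("cooperative", "independent") else 0
            l1 = _EDGE_LEVEL if e1 else 0
            l2 = _EDGE_LEVEL if e2 else 0
            py1h_readouts.append(
                QuadReadout(f"{tf1}|{tf2}", pid, noisy_quad(pair_level))
            )
            py1h_readouts.append(QuadReadout(tf1, pid, noisy_quad(l1)))
            py1h_readouts.append(QuadReadout(tf2, pid, noisy_quad(l2)))
            if relation != "none":
                truth_pair_relations[(tf1, tf2, pid)] = relation

    # --- evidence layers ------------------------------------------------------
    symbol_of = {t.tf_id: t.symbol for t in tfs}
    peaks: list[ChipPeak] = []
    literature_flags: set[tuple[str, str]] = set()
    for tf_id, pid in sorted(truth_edges):
        region = promoters[pid]
        if rng.random() < params.chip_coverage_prob:
            center = int(rng.integers(region.start + 100, region.end - 100))
            peaks.append(
                ChipPeak(
                    chrom=region.chrom,
                    start=center - 100,
                    end=center + 100,
                    tf_symbol=symbol_of[tf_id],
                    score=float(rng.integers(100, 1000)),
                    signal_value=float(np.round(rng.uniform(1, 50), 3)),
                    summit=100,
                )
            )
        if rng.random() < params.literature_flag_prob:
            literature_flags.add((tf_id, region.gene_id))
    # decoy peaks outside any promoter
    far = 10_000 + (n_prom + 10) * _PROMOTER_SPACING
    for k in range(params.n_tfs // 10):
        start = far + 500 * k
        peaks.append(
            ChipPeak(
                chrom="chr1",
                start=start,
                end=start + 200,
                tf_symbol=symbol_of[tf_ids[int(rng.integers(params.n_tfs))]],
                score=200.0,
                summit=100,
            )
        )

    # --- mutation and alignment summaries ------------------------------------
    mutation_summaries = []
    for tf_id in tf_ids:
        total = 1000
        mutated = int(rng.binomial(total, rng.uniform(0.0, 0.3)))
        synonymous = int(rng.binomial(mutated, 0.3)) if mutated else 0
        mutation_summaries.append(MutationSummary(tf_id, total, mutated, synonymous))

    alignment_summaries = []
    for pid in promoter_ids:
        fraction = float(rng.uniform(0.05, 0.60))
        alignment_summaries.append(
            AlignmentSummary(pid, "pMW3", 1000, int(round(1000 * fraction)))
        )
        alignment_summaries.append(
            AlignmentSummary(pid, "pMW2", 1000, int(rng.integers(0, 1000)))
        )

    return SyntheticWorld(
        params=params,
        tfs=tfs,
        genes=genes,
        promoters=promoters,
        truth_edges=truth_edges,
        truth_pair_relations=truth_pair_relations,
        tf_pairs=tf_pairs,
        ey1h_readouts=ey1h_readouts,
        py1h_readouts=py1h_readouts,
        peaks=peaks,
        literature_flags=literature_flags,
        mutation_summaries=mutation_summaries,
        alignment_summaries=alignment_summaries,
        autoactive_promoters=autoactive_promoters,
    )


def emit_files(world: SyntheticWorld, directory: str | Path) -> dict[str, str]:
    """Write the full world file set; returns {relative path: sha256}."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    io.write_promoter_bed(world.promoters.values(), directory / "promoters.bed")
    io.write_readout_table(world.ey1h_readouts, directory / "ey1h_readouts.tsv")
    io.write_readout_table(world.py1h_readouts, directory / "py1h_readouts.tsv")
    io.write_tf_table(world.tfs, directory / "tf_annotations.tsv")
    io.write_gene_table(world.genes, directory / "gene_annotations.tsv")
    io.write_narrowpeak(world.peaks, directory / "peaks.narrowPeak")
    io.write_literature_flags(world.literature_flags, directory / "literature_flags.tsv")
    io.write_mutation_table(world.mutation_summaries, directory / "mutations.tsv")
    io.write_alignment_table(world.alignment_summaries, directory / "alignments.tsv")
    truth = pd.DataFrame(sorted(world.truth_edges), columns=["tf_id", "promoter_id"])
    truth.to_csv(directory / "truth_edges.tsv", sep="\t", index=False)
    pairs = pd.DataFrame(
        [
            {"tf1_id": a, "tf2_id": b, "promoter_id": p, "relation": rel}
            for (a, b, p), rel in sorted(world.truth_pair_relations.items())
        ],
        columns=["tf1_id", "tf2_id", "promoter_id", "relation"],
    )
    pairs.to_csv(directory / "truth_pairs.tsv", sep="\t", index=False)

    manifest = {}
    for path in sorted(directory.iterdir()):
        if path.name == "world.manifest":
            continue
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    with open(directory / "world.manifest", "w") as fh:
        fh.write(f"seed\t{world.params.seed}\n")
        for name, digest in manifest.items():
            fh.write(f"{name}\t{digest}\n")
    return manifest


# --- planted scenarios -------------------------------------------------------


def make_planted_study(seed: int = 0) -> dict[str, object]:
    """Synthetic stand-in for the study's supplementary call tables.

    Constructs interaction and TF-pair outcome tables (plus promoter/TF/gene
    annotations) whose summary statistics are planted to match the published
    screen exactly: 1,350 interactions between 265 TFs and 108 of 136 genes
    (152 promoters); 117 TFs of promoter-degree 1 and 36 of degree >= 10 with
    a maximum of 54; evidence classes 543 ChIP-only + 21 literature-only + 61
    both + 725 novel; one degree-36 TF split 19 ChIP / 2 literature / 15
    novel; and 90 cooperative + 136 antagonistic pair calls over 67 TF pairs
    and 66 promoters.  All content is synthetic; only the count structure is
    planted.
    """
    rng = np.random.default_rng(seed)
    n_genes, n_alt, n_covered_genes = 136, 16, 108
    gene_ids, promoters = _make_promoters(n_genes, n_alt / n_genes)
    # promoters of the first 108 genes are the ones bound in the network
    covered_promoters = [
        p for p, r in promoters.items() if int(r.gene_id[1:]) <= n_covered_genes
    ]
    single_promoter_genes = {
        g for g in gene_ids[:n_covered_genes] if int(g[1:]) > n_alt
    }

    # degree sequence: 117 x 1; 112 mid (2..9, 14 each); hubs 54, 36, 17x15, 17x16
    hub_degrees = [54, 36] + [15] * 17 + [16] * 17
    mid_degrees = [d for d in range(2, 10) for _ in range(14)]
    degree_sequence = hub_degrees + mid_degrees + [1] * 117
    assert sum(degree_sequence) == 1350 and len(degree_sequence) == 265

    tf_ids = [f"TF{i + 1:04d}" for i in range(265)]
    grhl3_like = tf_ids[1]  # the planted degree-36 TF
    pointer = 0
    edges: list[tuple[str, str]] = []
    for tf, d in zip(tf_ids, degree_sequence):
        for _ in range(d):
            edges.append((tf, covered_promoters[pointer % len(covered_promoters)]))
            pointer += 1

    # evidence classes: planted TF gets 19 chip / 2 lit / 15 novel; global
    # totals 543 chip-only, 21 literature-only, 61 both, 725 novel.
    quotas = {"chip_only": 543 - 19, "literature_only": 21 - 2, "both": 61, "novel": 725 - 15}
    planted_classes = ["chip_only"] * 19 + ["literature_only"] * 2 + ["novel"] * 15
    classes: list[str] = []
    for tf, pid in edges:
        gene = promoters[pid].gene_id
        if tf == grhl3_like:
            classes.append(planted_classes.pop(0))
            continue
        if gene in single_promoter_genes and quotas["both"] > 0:
            cls = "both"
        elif gene in single_promoter_genes and quotas["literature_only"] > 0:
            cls = "literature_only"
        elif quotas["chip_only"] > 0:
            cls = "chip_only"
        else:
            cls = "novel"
        quotas[cls] -= 1
        classes.append(cls)

    # 30 of the 265 TFs stand for heterodimeric (pair-strain) binders
    hetero = set(tf_ids[-30:])
    interactions = pd.DataFrame(
        {
            "tf_id": [t for t, _ in edges],
            "promoter_id": [p for _, p in edges],
            "gene_id": [promoters[p].gene_id for _, p in edges],
            "assay": ["pY1H_pair" if t in hetero else "eY1H" for t, _ in edges],
            "evidence_class": classes,
        }
    )

    # evidence layers consistent with the planted classes
    peaks: list[ChipPeak] = []
    literature_flags: set[tuple[str, str]] = set()
    for (tf, pid), cls in zip(edges, classes):
        region = promoters[pid]
        if cls in ("chip_only", "both"):
            center = (region.start + region.end) // 2
            peaks.append(
                ChipPeak(region.chrom, center - 100, center + 100, f"Sym{tf}", 500.0, summit=100)
            )
        if cls in ("literature_only", "both"):
            literature_flags.add((tf, region.gene_id))

    # pair outcomes: 67 pairs, 90 cooperative + 136 antagonistic, 66 promoters
    pair_tfs = [(f"PT{2 * k + 1:03d}", f"PT{2 * k + 2:03d}") for k in range(67)]
    coop_counts = [3] * 30 + [0] * 37  # pairs 1..23 coop-only, 24..30 both
    antag_counts = [0] * 23 + [4] * 4 + [3] * 40
    assert sum(coop_counts) == 90 and sum(antag_counts) == 136
    event_promoters = covered_promoters[:66]
    rows = []
    cursor = 0
    for (tf1, tf2), nc, na in zip(pair_tfs, coop_counts, antag_counts):
        for _ in range(nc):
            pid = event_promoters[cursor % 66]
            cursor += 1
            rows.append(
                {
                    "tf1_id": tf1,
                    "tf2_id": tf2,
                    "promoter_id": pid,
                    "verdict": "cooperative",
                    "antagonized_tfs": "",
                    "cooperativity_index": 3,
                    "antagonism_index_1": -3,
                    "antagonism_index_2": -3,
                }
            )
        for _ in range(na):
            pid = event_promoters[cursor % 66]
            cursor += 1
            rows.append(
                {
                    "tf1_id": tf1,
                    "tf2_id": tf2,
                    "promoter_id": pid,
                    "verdict": "antagonistic",
                    "antagonized_tfs": tf1,
                    "cooperativity_index": -3,
                    "antagonism_index_1": 3,
                    "antagonism_index_2": 0,
                }
            )
    pair_outcomes = pd.DataFrame(rows, columns=io.PAIR_COLUMNS)

    tf_records = [
        TFRecord(tf, f"Sym{tf}", "other", "unknown", True, tf in hetero)
        for tf in tf_ids
    ]
    labels = _sample_categorical(
        rng,
        {"poor": 0.35, "good": 0.35, "cancer_dependent": 0.10, "unknown": 0.20},
        n_genes,
    )
    gene_records = [
        GeneRecord(g, f"Sym{g}", "oncogene" if i < 66 else "tsg", labels[i])
        for i, g in enumerate(gene_ids)
    ]
    return {
        "interactions": interactions,
        "pair_outcomes": pair_outcomes,
        "promoters": promoters,
        "tf_records": tf_records,
        "gene_records": gene_records,
        "peaks": peaks,
        "literature_flags": literature_flags,
        "grhl3_like": grhl3_like,
    }


def make_planted_nomination(
    n_oncogenes: int = 51,
    n_with_nominee: int = 25,
    seed: int = 0,
) -> tuple[RegulatoryNetwork, dict[str, TFRecord]]:
    """Synthetic world where exactly ``n_with_nominee`` oncogenes have a
    qualifying activator/bifunctional TF with prognosis score > 0.33.

    Each "nominatable" oncogene is bound by one activator that also binds two
    poor-prognosis genes (score 2/3); the remaining oncogenes are bound only
    by a repressor and by an activator biased toward good-prognosis targets
    (score -2/3), so neither qualifies.
    """
    if n_with_nominee > n_oncogenes:
        raise ValueError("cannot plant more nominatable oncogenes than oncogenes")
    rng = np.random.default_rng(seed)
    genes: list[GeneRecord] = []
    promoters: dict[str, PromoterRegion] = {}
    calls: list[tuple[str, str, str]] = []
    tf_records: dict[str, TFRecord] = {}

    def add_gene(gene_id: str, role: str, label: str) -> str:
        k = len(promoters)
        pid = f"{gene_id}.P1"
        pos = 10_000 + k * _PROMOTER_SPACING
        promoters[pid] = PromoterRegion(
            pid, gene_id, "chr1", pos, pos + _PROMOTER_LENGTH, "+", pos + _PROMOTER_LENGTH
        )
        genes.append(GeneRecord(gene_id, f"Sym{gene_id}", role, label))
        return pid

    label_pool = ["unknown", "cancer_dependent"]
    for i in range(n_oncogenes):
        onc_pid = add_gene(f"ONC{i + 1:03d}", "oncogene", str(rng.choice(label_pool)))
        tf_id = f"ATF{i + 1:03d}"
        if i < n_with_nominee:
            effector, bias = "activator", "poor"
        else:
            effector, bias = "activator", "good"
        tf_records[tf_id] = TFRecord(tf_id, f"Sym{tf_id}", "other", effector)
        calls.append((tf_id, onc_pid, "eY1H"))
        for j in range(2):
            side_pid = add_gene(f"SIDE{i + 1:03d}{j}", "other", bias)
            calls.append((tf_id, side_pid, "eY1H"))
        # every oncogene also gets a repressor that never qualifies
        rep_id = f"RTF{i + 1:03d}"
        tf_records[rep_id] = TFRecord(rep_id, f"Sym{rep_id}", "other", "repressor")
        calls.append((rep_id, onc_pid, "eY1H"))

    network = build_network(
        calls, promoters, tf_records, {g.gene_id: g for g in genes}
    )
    return network, tf_records


def null_world_network(
    n_tfs: int = 200,
    n_genes: int = 8000,
    degree_range: tuple[int, int] = (300, 700),
    seed: int = 0,
) -> RegulatoryNetwork:
    """Random network whose gene labels are independent of its edges.

    Used to check that permutation p-values are approximately uniform under
    the null.  The world is deliberately dense: the empirical two-sided
    p-value counts ties in its numerator and is therefore conservative on
    coarse score distributions, so high degrees (near-continuous scores) and
    a large gene universe (weak target overlap between TFs) are needed to
    isolate the permutation machinery itself from that discreteness.
    """
    rng = np.random.default_rng(seed)
    gene_ids, promoters = _make_promoters(n_genes, 0.0)
    labels = _sample_categorical(
        rng,
        {"poor": 0.35, "good": 0.35, "cancer_dependent": 0.10, "unknown": 0.20},
        n_genes,
    )
    genes = {
        g: GeneRecord(g, f"Sym{g}", "other", labels[i]) for i, g in enumerate(gene_ids)
    }
    promoter_ids = list(promoters)
    calls = []
    for i in range(n_tfs):
        d = int(rng.integers(degree_range[0], degree_range[1] + 1))
        for j in rng.choice(len(promoter_ids), size=d, replace=False):
            calls.append((f"TF{i + 1:04d}", promoter_ids[j], "eY1H"))
    return build_network(calls, promoters, gene_annotations=genes)
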