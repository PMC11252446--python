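import numpy as np
import pytest
from scipy import stats as sps

from y1hnet.model import GeneRecord, TFRecord
from y1hnet.network import build_network
from y1hnet.prognosis import (
    nominate_targetable,
    permutation_null,
    prognosis_score,
    score_all,
)
from y1hnet.simulate import make_planted_nomination, null_world_network
from .conftest import make_promoter


def star_network(labels, tf_id="TF1", effector="activator"):
    """One TF bound to one single-promoter gene per label."""
    promoters, genes, calls = {}, {}, []
    for i, label in enumerate(labels):
        gid, pid = f"G{i}", f"G{i}.P1"
        promoters[pid] = make_promoter(pid, gid, 1000 + 10_000 * i, 3000 + 10_000 * i)
        genes[gid] = GeneRecord(gid, gid, "other", label)
        calls.append((tf_id, pid, "eY1H"))
    tf_ann = {tf_id: TFRecord(tf_id, tf_id, "other", effector)}
    return build_network(calls, promoters, tf_ann, genes)


def test_prognosis_score_printed_counts():
    """27 targets, 7 poor, 4 good -> (7-4)/27."""
    labels = ["poor"] * 7 + ["good"] * 4 + ["unknown"] * 16
    score = prognosis_score(star_network(labels), "TF1")
    assert (score.n_targets, score.n_poor, score.n_good) == (27, 7, 4)
    assert score.score == pytest.approx(3 / 27)


def test_prognosis_score_bounds_and_symmetry():
    assert prognosis_score(star_network(["poor"] * 5), "TF1").score == 1.0
    assert prognosis_score(star_network(["poor", "good"] * 3), "TF1").score == 0.0


def test_prognosis_score_antisymmetric_under_label_swap():
    labels = ["poor"] * 5 + ["good"] * 2 + ["cancer_dependent"] * 3
    swapped = ["good"] * 5 + ["poor"] * 2 + ["cancer_dependent"] * 3
    assert prognosis_score(star_network(labels), "TF1").score == pytest.approx(
        -prognosis_score(star_network(swapped), "TF1").score
    )


def test_prognosis_score_labeled_only_denominator():
    labels = ["poor"] * 3 + ["good"] + ["unknown"] * 6
    assert prognosis_score(star_network(labels), "TF1").score == pytest.approx(0.2)
    assert prognosis_score(star_network(labels), "TF1", labeled_only=True).score == (
        pytest.approx(0.5)
    )


def test_prognosis_score_unknown_tf_raises(toy_network):
    with pytest.raises(KeyError):
        prognosis_score(toy_network, "NOPE")


# --- permutation null --------------------------------------------------------


def test_full_coverage_tf_has_p_one():
    """A TF targeting every gene is invariant under label shuffling."""
    net = star_network(["poor"] * 4 + ["good"] * 3 + ["unknown"] * 3)
    ens = permutation_null(net, n_perm=200, seed=0)
    assert np.allclose(ens.null_scores, ens.observed[:, None])
    assert ens.p_values[0] == 1.0


def test_permutation_same_seed_is_bit_identical():
    net = null_world_network(n_tfs=30, n_genes=300, degree_range=(5, 30), seed=5)
    a = permutation_null(net, n_perm=100, seed=9)
    b = permutation_null(net, n_perm=100, seed=9)
    assert np.array_equal(a.null_scores, b.null_scores)
    assert np.array_equal(a.p_values, b.p_values)


def test_permutation_preserves_degrees_and_p_range():
    net = null_world_network(n_tfs=30, n_genes=300, degree_range=(5, 30), seed=5)
    ens = permutation_null(net, n_perm=100, seed=1)
    gene_deg = net.gene_degree()
    assert np.array_equal(ens.degrees, gene_deg[ens.tf_ids].to_numpy())
    assert (ens.p_values > 0).all() and (ens.p_values <= 1).all()
    assert ens.null_scores.shape == (30, 100)
    # every null score is a valid score for that TF's degree: k / degree
    numerators = ens.null_scores * ens.degrees[:, None]
    assert np.allclose(numerators, np.round(numerators))
    assert (np.abs(ens.null_scores) <= 1 + 1e-12).all()


def test_permutation_pvalues_uniform_under_null():
    """Labels independent of edges -> empirical p-values ~ Uniform(0,1)."""
    net = null_world_network(seed=2)
    ens = permutation_null(net, n_perm=1000, seed=12)
    ks = sps.kstest(ens.p_values, "uniform").statistic
    assert ks < 0.1


def test_permutation_rejects_bad_n_perm(toy_network):
    with pytest.raises(ValueError):
        permutation_null(toy_network, n_perm=0, seed=0)


# --- nomination --------------------------------------------------------------


def nomination_world(score_target):
    """Activator bound to one oncogene plus labeled side targets."""
    promoters, genes, calls = {}, {}, []
    promoters["ONC.P1"] = make_promoter("ONC.P1", "ONC", 1000, 3000)
    genes["ONC"] = GeneRecord("ONC", "ONC", "oncogene", "unknown")
    calls.append(("TF1", "ONC.P1", "eY1H"))
    n_side = 99
    n_poor = round(score_target * 100)
    for i in range(n_side):
        gid, pid = f"S{i}", f"S{i}.P1"
        promoters[pid] = make_promoter(pid, gid, 10_000 + 10_000 * i, 12_000 + 10_000 * i)
        genes[gid] = GeneRecord(gid, gid, "other", "poor" if i < n_poor else "unknown")
        calls.append(("TF1", pid, "eY1H"))
    tf_ann = {"TF1": TFRecord("TF1", "TF1", "other", "activator")}
    return build_network(calls, promoters, tf_ann, genes)


def test_nomination_strict_threshold():
    # score 34/100 qualifies; score 33/100 does not (strict inequality)
    above = nominate_targetable(nomination_world(0.34))
    assert above.nominations["ONC"] == ("TF1",)
    at = nominate_targetable(nomination_world(0.33))
    assert at.nominations["ONC"] == ()
    assert at.n_oncogenes_with_nominee == 0


def test_nomination_requires_activating_effector():
    net = nomination_world(0.5)
    net.tf_annotations["TF1"] = TFRecord("TF1", "TF1", "other", "repressor")
    assert nominate_targetable(net).n_oncogenes_with_nominee == 0
    net.tf_annotations["TF1"] = TFRecord("TF1", "TF1", "other", "bifunctional")
    assert nominate_targetable(net).n_oncogenes_with_nominee == 1


def test_nomination_planted_world_count_recovered():
    network, _ = make_planted_nomination(n_oncogenes=51, n_with_nominee=25, seed=4)
    result = nominate_targetable(network)
    assert result.n_oncogenes_tested == 51
    assert result.n_oncogenes_with_nominee == 25


def test_score_all_matches_single_scores(toy_network):
    frame = score_all(toy_network)
    for row in frame.itertuples(index=False):
        assert row.score == prognosis_score(toy_network, row.tf_id).score
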