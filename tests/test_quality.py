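"""Quality measures: NC, EC/ICS/S3, LCCS, GO correctness, correlations."""

import numpy as np
import pandas as pd
import pytest

from netalign import (
    Alignment,
    AnnotationMap,
    Network,
    QualityReport,
    TruthMapping,
    evaluate_alignment,
    go_correctness,
    measure_correlations,
    node_correctness,
    topological_scores,
)
from netalign.benchmark import make_clique, make_cycle

from conftest import random_network


def identity_alignment(net):
    return Alignment({n: n for n in net.nodes})


# ---------------------------------------------------------------------------
# node correctness
# ---------------------------------------------------------------------------


def test_nc_extremes_and_fraction():
    f = Alignment({"a": "x", "b": "y", "c": "z", "d": "w"})
    assert node_correctness(f, TruthMapping(f.mapping)) == 100.0
    wrong = TruthMapping({"a": "w", "b": "x", "c": "y", "d": "z"})
    assert node_correctness(f, wrong) == 0.0
    partial = TruthMapping({"a": "x", "b": "y", "c": "z", "d": "q"})
    assert node_correctness(f, partial) == 75.0


def test_nc_partial_truth_excluded_from_denominator():
    f = Alignment({"a": "x", "b": "y"})
    truth = TruthMapping({"a": "x"})  # b has no known truth
    assert node_correctness(f, truth) == 100.0


# ---------------------------------------------------------------------------
# topological measures
# ---------------------------------------------------------------------------


def test_identity_c6_all_measures_100(c6):
    ec, ics, s3, lccs_n, lccs_e, lccs = topological_scores(c6, c6, identity_alignment(c6))
    assert (ec, ics, s3, lccs_n, lccs_e, lccs) == (100.0,) * 6


def test_cycle_into_clique_worked_example(c4, k4):
    """C4 injected into K4: every C4 edge is conserved (EC=100) but K4's
    6 induced edges dilute ICS and S3 to 4/6."""
    mapping = dict(zip(c4.nodes, k4.nodes))
    ec, ics, s3, *_ = topological_scores(c4, k4, Alignment(mapping))
    assert ec == 100.0
    assert ics == pytest.approx(100 * 4 / 6)
    assert s3 == pytest.approx(100 * 4 / (4 + 6 - 4))


def test_ec_same_for_cycle_to_cycle_and_cycle_to_clique():
    for k in (4, 5, 6):
        ck = make_cycle(k)
        kk = make_clique(k)
        ec_cycle, *_ = topological_scores(ck, ck, identity_alignment(ck))
        ec_clique, *_ = topological_scores(
            ck, kk, Alignment(dict(zip(ck.nodes, kk.nodes))))
        assert ec_cycle == ec_clique == 100.0


def test_no_conserved_edges_all_zero():
    net1 = Network("a", "ab", [("a", "b")])
    net2 = Network("b", "wxyz", [("w", "x"), ("y", "z")])
    ec, ics, s3, lccs_n, lccs_e, lccs = topological_scores(
        net1, net2, Alignment({"a": "w", "b": "y"}))
    assert (ec, ics, s3, lccs, lccs_n, lccs_e) == (0.0,) * 6


def test_ics_undefined_flag_when_image_has_no_edges():
    net1 = Network("a", "ab", [("a", "b")])
    net2 = Network("b", "wxyz", [("w", "x")])
    report = evaluate_alignment(net1, net2, Alignment({"a": "w", "b": "y"}))
    assert report.ICS == 0.0 and not report.ics_defined


def test_lccs_hand_example():
    """Conserved graph = one triangle + one isolated conserved edge; the
    LCCS is the triangle: N = 3/5 nodes, E = 3/3 induced edges."""
    net1 = Network("a", "abcde",
                   [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("c", "d")])
    net2 = Network("b", "vwxyz",
                   [("v", "w"), ("w", "x"), ("v", "x"), ("y", "z")])
    f = Alignment({"a": "v", "b": "w", "c": "x", "d": "y", "e": "z"})
    ec, ics, s3, lccs_n, lccs_e, lccs = topological_scores(net1, net2, f)
    assert ec == pytest.approx(100 * 4 / 5)
    assert lccs_n == pytest.approx(100 * 3 / 5)
    assert lccs_e == pytest.approx(100.0)
    assert lccs == pytest.approx(np.sqrt(lccs_n * lccs_e))


def test_s3_bounded_by_ec_and_ics_on_random_alignments():
    rng = np.random.default_rng(17)
    for seed in range(30):
        net1 = random_network(int(rng.integers(4, 10)), 0.5, seed, name="a")
        if net1.number_of_edges() == 0:
            continue
        n2 = net1.number_of_nodes() + int(rng.integers(0, 6))
        net2 = random_network(n2, 0.5, seed + 1000, name="b")
        targets = list(net2.nodes)
        pick = rng.choice(n2, size=net1.number_of_nodes(), replace=False)
        f = Alignment({u: targets[j] for u, j in zip(net1.nodes, pick)})
        ec, ics, s3, *_ = topological_scores(net1, net2, f)
        assert s3 <= ec + 1e-9 and s3 <= ics + 1e-9


def test_measures_invariant_under_consistent_relabeling():
    net1 = random_network(7, 0.5, 3, name="a")
    net2 = random_network(9, 0.4, 4, name="b")
    rng = np.random.default_rng(5)
    targets = list(net2.nodes)
    pick = rng.choice(9, size=7, replace=False)
    f = Alignment({u: targets[j] for u, j in zip(net1.nodes, pick)})
    base = topological_scores(net1, net2, f)

    m1 = {lab: f"p{i:02d}" for i, lab in enumerate(net1.nodes)}
    m2 = {lab: f"q{i:02d}" for i, lab in enumerate(net2.nodes)}
    r1 = Network("a2", m1.values(), ((m1[a], m1[b]) for a, b in net1.edges))
    r2 = Network("b2", m2.values(), ((m2[a], m2[b]) for a, b in net2.edges))
    f2 = Alignment({m1[u]: m2[v] for u, v in f.items()})
    assert topological_scores(r1, r2, f2) == pytest.approx(base)


def test_total_alignment_required(c6):
    with pytest.raises(ValueError, match="total"):
        topological_scores(c6, c6, Alignment({c6.nodes[0]: c6.nodes[0]}))


# ---------------------------------------------------------------------------
# GO correctness
# ---------------------------------------------------------------------------


def make_ann(entries):
    return AnnotationMap({p: {(t, ev) for t, ev in anns} for p, anns in entries.items()})


def test_go_correctness_counts_only_annotated_pairs():
    ann = make_ann({
        "a": [("GO:1", "IEA")], "a2": [("GO:1", "IEA")],
        "b": [("GO:2", "IEA")], "b2": [("GO:3", "IEA")],
        "c2": [("GO:4", "IEA")],  # c unannotated
    })
    f = Alignment({"a": "a2", "b": "b2", "c": "c2"})
    assert go_correctness(f, ann) == 50.0


def test_go_correctness_all_share():
    ann = make_ann({"a": [("GO:1", "IDA")], "x": [("GO:1", "IDA")]})
    assert go_correctness(Alignment({"a": "x"}), ann) == 100.0


def test_go_correctness_undefined_is_none():
    assert go_correctness(Alignment({"a": "x"}), make_ann({})) is None


def test_exp_variant_filters_evidence():
    ann = make_ann({
        "a": [("GO:1", "IEA")], "x": [("GO:1", "IEA")],
        "b": [("GO:2", "IDA")], "y": [("GO:2", "IMP")],
    })
    f = Alignment({"a": "x", "b": "y"})
    assert go_correctness(f, ann) == 100.0
    # only the experimentally evidenced pair survives the filter
    assert go_correctness(f, ann, experimental_only=True) == 100.0
    ann2 = make_ann({"a": [("GO:1", "IEA")], "x": [("GO:1", "IEA")]})
    assert go_correctness(Alignment({"a": "x"}), ann2, experimental_only=True) is None


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------


def reports_from_columns(**cols):
    n = len(next(iter(cols.values())))
    reports = []
    for i in range(n):
        r = QualityReport()
        for name, values in cols.items():
            setattr(r, name, values[i])
        reports.append(r)
    return reports


def test_equal_measures_correlate_perfectly():
    reports = reports_from_columns(EC=[10, 50, 90], S3=[10, 50, 90])
    corr = measure_correlations(reports, "pearson")
    assert corr.loc["EC", "S3"] == pytest.approx(1.0)
    assert corr.loc["EC", "EC"] == 1.0


def test_anticorrelated_measures():
    reports = reports_from_columns(EC=[10, 50, 90], ICS=[90, 50, 10])
    corr = measure_correlations(reports, "pearson")
    assert corr.loc["EC", "ICS"] == pytest.approx(-1.0)


def test_spearman_invariant_under_monotone_transform():
    ec = [10.0, 30.0, 60.0, 90.0]
    reports_lin = reports_from_columns(EC=ec, S3=[5.0, 20.0, 45.0, 80.0])
    # strictly monotone transform of S3 leaves ranks unchanged
    reports_sq = reports_from_columns(EC=ec, S3=[x**1.7 / 100 for x in [5.0, 20.0, 45.0, 80.0]])
    c1 = measure_correlations(reports_lin, "spearman").loc["EC", "S3"]
    c2 = measure_correlations(reports_sq, "spearman").loc["EC", "S3"]
    assert c1 == pytest.approx(c2) == pytest.approx(1.0)
    # matches a direct rank-based computation
    ranks = pd.Series(ec).rank()
    assert c1 == pytest.approx(np.corrcoef(ranks, pd.Series([5, 20, 45, 80]).rank())[0, 1])


def test_zero_variance_measure_reported_na():
    reports = reports_from_columns(EC=[50, 50, 50], S3=[10, 20, 30])
    corr = measure_correlations(reports, "pearson")
    assert np.isnan(corr.loc["EC", "S3"]) and np.isnan(corr.loc["EC", "EC"])
    assert corr.loc["S3", "S3"] == 1.0


def test_correlations_need_three_reports():
    with pytest.raises(ValueError):
        measure_correlations(reports_from_columns(EC=[1, 2], S3=[1, 2]))
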