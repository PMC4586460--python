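"""Call annotation: lead-off gene rule, pTSS, clustering, gene subgroups,
hypergeometric enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from episcan.annotate import (annotate_calls, cluster_calls, enrichment,
                              feature_summary, select_gene_subgroups)
from episcan.outliers import ScanResult


def _calls(probe_ids, directions=None, samples=None, deltas=None):
    n = len(probe_ids)
    df = pd.DataFrame({
        "probe_id": probe_ids,
        "sample_id": samples or ["s1"] * n,
        "beta": 0.5,
        "delta_beta": deltas if deltas is not None
        else [0.3 if d == "hyper" else -0.3
              for d in (directions or ["hyper"] * n)],
        "direction": directions or ["hyper"] * n,
        "grubbs_g": 5.0, "p_raw": 1e-9, "p_bonf": 1e-4, "snp_flagged": False,
    })
    return ScanResult(calls=df, provenance={})


def test_lead_off_gene_and_feature_rule(toy_manifest):
    annotated = annotate_calls(_calls(["cg00000001"]), toy_manifest)
    row = annotated.iloc[0]
    assert row["lead_gene"] == "GENEA"       # first of "GENEA;GENEB"
    assert row["lead_feature"] == "TSS200"   # first of "TSS200;Body"
    assert row["ptss"]
    assert row["cgi_group"] == "island"


def test_intergenic_and_body_calls_not_ptss(toy_manifest):
    annotated = annotate_calls(_calls(["cg00000004", "cg00000007"]), toy_manifest)
    inter, body = annotated.iloc[0], annotated.iloc[1]
    assert inter["lead_gene"] == "intergenic" and not inter["ptss"]
    assert not inter["genic"]
    assert body["lead_gene"] == "BGENE1" and body["lead_feature"] == "Body"
    assert body["genic"] and not body["ptss"]


def test_unsorted_manifest_rejected(toy_manifest):
    shuffled = toy_manifest.sample(frac=1.0, random_state=0).reset_index(drop=True)
    with pytest.raises(ValueError, match="sorted"):
        annotate_calls(_calls(["cg00000001"]), shuffled)


def test_adjacent_same_direction_calls_cluster(toy_manifest):
    res = _calls(["cg00000001", "cg00000002", "cg00000003"])
    annotated = annotate_calls(res, toy_manifest)
    clustered = cluster_calls(annotated, toy_manifest)
    assert clustered["clustered"].all()
    assert clustered["cluster_id"].nunique() == 1
    assert (clustered["cluster_size"] == 3).all()


def test_isolated_and_chromosome_break(toy_manifest):
    # cg00000004 (chr1 row 3) and cg00000005 (chr2 row 4) are consecutive
    # manifest rows but on different chromosomes
    res = _calls(["cg00000004", "cg00000005"])
    clustered = cluster_calls(annotate_calls(res, toy_manifest), toy_manifest)
    assert not clustered["clustered"].any()
    assert clustered["cluster_id"].isna().all()


def test_direction_and_sample_homogeneous_clusters(toy_manifest):
    res = _calls(["cg00000001", "cg00000002"], directions=["hyper", "hypo"])
    clustered = cluster_calls(annotate_calls(res, toy_manifest), toy_manifest)
    assert not clustered["clustered"].any()
    res2 = _calls(["cg00000001", "cg00000002"], samples=["s1", "s2"])
    ann2 = annotate_calls(res2, toy_manifest)
    assert not cluster_calls(ann2, toy_manifest)["clustered"].any()
    assert cluster_calls(ann2, toy_manifest, same_sample=False)["clustered"].all()


def test_cluster_assignment_invariant_to_call_order(toy_manifest):
    res = _calls(["cg00000003", "cg00000001", "cg00000002"])
    annotated = annotate_calls(res, toy_manifest)
    c1 = cluster_calls(annotated, toy_manifest)
    c2 = cluster_calls(annotated.iloc[::-1].reset_index(drop=True), toy_manifest)
    m1 = c1.set_index("probe_id")[["clustered", "cluster_size"]]
    m2 = c2.set_index("probe_id")[["clustered", "cluster_size"]]
    pd.testing.assert_frame_equal(m1.sort_index(), m2.sort_index())


def test_max_gap_breaks_distant_neighbours(toy_manifest):
    # cg00000005 at 100 and cg00000006 at 150 on chr2 are adjacent rows
    res = _calls(["cg00000005", "cg00000006"])
    annotated = annotate_calls(res, toy_manifest)
    assert cluster_calls(annotated, toy_manifest)["clustered"].all()
    tight = cluster_calls(annotated, toy_manifest, max_gap_bp=10)
    assert not tight["clustered"].any()


def test_clustered_plus_isolated_partition(small_pipeline):
    calls = small_pipeline.calls
    for direction in ("hyper", "hypo"):
        sub = calls[calls["direction"] == direction]
        assert (sub["clustered"].sum() + (~sub["clustered"]).sum()) == len(sub)
    fs = feature_summary(calls)
    for direction, entry in fs.items():
        assert math.isclose(sum(entry["features"].values()), 1.0, rel_tol=1e-9)
        assert math.isclose(sum(entry["cgi"].values()), 1.0, rel_tol=1e-9)


def test_gene_subgroup_truth_table(toy_manifest):
    # five probes, hand-enumerated memberships
    res = _calls(
        ["cg00000001", "cg00000002", "cg00000005", "cg00000006", "cg00000007"],
        directions=["hyper"] * 5,
        samples=["s1", "s1", "s1", "s1", "s2"],  # cg7 isolated (own subject)
        deltas=[0.25, 0.15, 0.21, 0.2, 0.5])
    annotated = annotate_calls(res, toy_manifest)
    clustered = cluster_calls(annotated, toy_manifest)
    groups = select_gene_subgroups(clustered)
    # GENEA: probes 1+2 clustered, pTSS, max delta 0.25
    # GENEC: probes 5+6 clustered, pTSS, deltas 0.21 / 0.20 (0.2 excluded: strict)
    # BGENE1: isolated Body call, delta 0.5
    assert groups["hyper_all"] == {"GENEA", "GENEC", "BGENE1"}
    assert groups["hyper_high_delta"] == {"GENEA", "GENEC", "BGENE1"}
    assert groups["hyper_ptss"] == {"GENEA", "GENEC"}
    assert groups["hyper_clustered"] == {"GENEA", "GENEC"}
    assert groups["hyper_high_clustered_ptss"] == {"GENEA", "GENEC"}
    assert groups["hypo_all"] == set()


def test_delta_threshold_is_strict(toy_manifest):
    res = _calls(["cg00000005"], deltas=[0.2])
    clustered = cluster_calls(annotate_calls(res, toy_manifest), toy_manifest)
    groups = select_gene_subgroups(clustered)
    assert groups["hyper_high_delta"] == set()
    assert groups["hyper_all"] == {"GENEC"}


def test_enrichment_exact_tail():
    universe = {f"g{i}" for i in range(10)}
    term = {f"g{i}" for i in range(5)}
    res = enrichment(term, universe, {"T": term})
    row = res.iloc[0]
    # all 5 query genes inside a 5-gene term: p = 1/C(10,5)
    assert row["p"] == pytest.approx(1 / 252)
    assert row["fold_enrichment"] == pytest.approx(2.0)


def test_enrichment_identity_query():
    universe = {f"g{i}" for i in range(20)}
    sets = {"A": {f"g{i}" for i in range(7)}, "B": {f"g{i}" for i in range(3, 12)}}
    res = enrichment(universe, universe, sets)
    assert np.allclose(res["fold_enrichment"], 1.0)
    assert np.allclose(res["p"], 1.0)


def test_enrichment_fold_formula_consistency():
    # algebraic fixture: k/n = 157/1001 against K/N chosen to give 1.70
    N, n, k = 18_000, 1001, 157
    K = round((k / n) * N / 1.70)
    universe = {f"g{i}" for i in range(N)}
    term = {f"g{i}" for i in range(K)}
    query = {f"g{i}" for i in range(k)} | {f"g{i}" for i in range(K, K + n - k)}
    res = enrichment(query, universe, {"T": term})
    assert res.iloc[0]["fold_enrichment"] == pytest.approx(1.70, abs=0.01)


def test_enrichment_rejects_gene_outside_universe():
    with pytest.raises(ValueError, match="outside the universe"):
        enrichment({"x"}, {"a", "b"}, {"T": {"a"}})
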