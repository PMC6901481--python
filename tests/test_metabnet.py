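import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from pahomics import metabnet as mn
from pahomics.omics_io import GeneSetCollection, IntensityMatrix
from pahomics.proximity import NodeSet
from pahomics.synthio import SimConfig, generate_metabolome


def _metab_matrix(values, n_case, n_control):
    cols = [f"c{i}" for i in range(n_case)] + \
        [f"k{i}" for i in range(n_control)]
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=[f"M{i}" for i in range(len(values))],
                      columns=cols)
    groups = {c: ("case" if c.startswith("c") else "control") for c in cols}
    return IntensityMatrix(values=df, groups=groups)


def test_identical_groups_give_p_one():
    m = _metab_matrix([[2.0, 4.0, 2.0, 4.0], [8.0, 16.0, 8.0, 16.0]], 2, 2)
    res = mn.metabolite_diff(m)
    np.testing.assert_allclose(res["p"], 1.0)
    assert (res["direction"] == "ns").all()


def test_exact_separation_flagged():
    m = _metab_matrix([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]], 3, 3)
    res = mn.metabolite_diff(m)
    assert bool(res["exact_separation"].iloc[0])
    assert 0 < res["p"].iloc[0] < 1e-100


def test_metabolite_diff_sensitivity_on_simulation():
    cfg = SimConfig(seed=47, n_metabolites=400, metab_frac_de=0.15,
                    metab_effect_log2fc=1.0,
                    metab_samples_per_group=(30, 12))
    sim, _ = generate_metabolome(cfg)
    res = mn.metabolite_diff(sim.matrix)
    truth = sim.truth.set_index("feature_id")["is_de"]
    called = set(res.loc[res["direction"] != "ns", "feature_id"])
    true_de = set(truth[truth].index)
    assert len(called & true_de) / len(true_de) > 0.5


def _diff_frame(n_total, sig_ids):
    ids = [f"M{i}" for i in range(n_total)]
    p = [0.01 if f in sig_ids else 0.5 for f in ids]
    return pd.DataFrame({"feature_id": ids, "p": p,
                         "q": p, "log2fc": 1.0})


def test_enrichment_closed_form():
    """N=20, K=10, m=5, k=5: fold 2.0, p = C(10,5)/C(20,5) = 252/15504."""
    sig = {f"M{i}" for i in range(10)}
    diff = _diff_frame(20, sig)
    pathways = GeneSetCollection(sets={"p": [f"M{i}" for i in range(5)]})
    res = mn.pathway_enrichment(diff, pathways)
    row = res.iloc[0]
    assert row["k"] == 5 and row["m"] == 5
    assert row["fold_enrichment"] == pytest.approx(2.0)
    assert row["p"] == pytest.approx(252 / 15504)
    assert bool(row["dysregulated"])


def test_enrichment_boundary_fold_one_never_flagged():
    sig = {f"M{i}" for i in range(10)}  # K/N = 0.5
    diff = _diff_frame(20, sig)
    # pathway of 4 with exactly 2 significant: fold exactly 1
    pathways = GeneSetCollection(
        sets={"p": ["M0", "M1", "M15", "M16"]})
    res = mn.pathway_enrichment(diff, pathways)
    assert res.iloc[0]["fold_enrichment"] == pytest.approx(1.0)
    assert not bool(res.iloc[0]["dysregulated"])


def test_enrichment_no_significant_members():
    diff = _diff_frame(20, set())
    pathways = GeneSetCollection(sets={"p": ["M0", "M1"]})
    res = mn.pathway_enrichment(diff, pathways)
    assert res.iloc[0]["fold_enrichment"] == 0.0
    assert res.iloc[0]["p"] == 1.0
    assert not res["dysregulated"].any()


def test_enrichment_skips_unmeasured_pathway(caplog):
    diff = _diff_frame(10, {"M0"})
    pathways = GeneSetCollection(sets={"p": ["ZZ1", "ZZ2"],
                                       "q": ["M0", "M1"]})
    with caplog.at_level("WARNING"):
        res = mn.pathway_enrichment(diff, pathways)
    assert list(res["pathway"]) == ["q"]
    assert any("no measured members" in r.message for r in caplog.records)


def test_enrichment_matches_enumeration_small_universe(rng):
    """Hypergeometric tail equals explicit enumeration for N <= 25."""
    for _ in range(20):
        n_total = int(rng.integers(5, 26))
        n_sig = int(rng.integers(0, n_total + 1))
        m_size = int(rng.integers(1, n_total + 1))
        ids = [f"M{i}" for i in range(n_total)]
        sig = set(rng.choice(ids, size=n_sig, replace=False))
        members = list(rng.choice(ids, size=m_size, replace=False))
        diff = _diff_frame(n_total, sig)
        res = mn.pathway_enrichment(diff, GeneSetCollection(
            sets={"p": members}))
        k = len(set(members) & sig)
        expected = sum(
            comb(n_sig, j) * comb(n_total - n_sig, m_size - j)
            for j in range(k, min(m_size, n_sig) + 1)) / comb(n_total, m_size)
        assert res.iloc[0]["p"] == pytest.approx(expected, rel=1e-9)


# --------------------------------------------------------------------------
# metabolite-enzyme network

def _chain_table():
    return pd.DataFrame({
        "enzyme_gene": ["E1", "E2"],
        "metabolite_id": ["m1", "m1"],
        "reaction_id": ["R1", "R2"]})


def test_build_network_bipartite_and_duplicates_merge():
    table = pd.concat([_chain_table(), _chain_table()])
    net = mn.build_met_enz_network(table)
    assert net.enzymes == {"E1", "E2"}
    assert net.metabolites == {"m1"}
    assert net.graph.number_of_edges() == 2
    assert net.is_bipartite()


def test_build_network_rejects_mixed_role_id():
    table = pd.DataFrame({"enzyme_gene": ["E1", "m1"],
                          "metabolite_id": ["m1", "m2"],
                          "reaction_id": ["R1", "R2"]})
    with pytest.raises(mn.MetabNetError, match="both enzyme and metabolite"):
        mn.build_met_enz_network(table)


def test_map_dysregulated_chain_bridging():
    net = mn.build_met_enz_network(_chain_table())
    sub, comps = mn.map_dysregulated(net, NodeSet("e", ["E1", "E2"]),
                                     NodeSet("m", []), max_hops=2)
    assert set(sub.graph.nodes) == {"E1", "m1", "E2"}
    assert len(comps) == 1
    assert comps.iloc[0]["n_significant"] == 2
    assert comps.iloc[0]["size"] == 3


def test_map_dysregulated_zero_hops_induced_only():
    net = mn.build_met_enz_network(_chain_table())
    sub, comps = mn.map_dysregulated(net, NodeSet("e", ["E1", "E2"]),
                                     NodeSet("m", []), max_hops=0)
    assert set(sub.graph.nodes) == {"E1", "E2"}
    assert len(comps) == 2  # no bridge without the metabolite


def test_map_dysregulated_separate_components():
    table = pd.DataFrame({
        "enzyme_gene": ["E1", "E2"],
        "metabolite_id": ["m1", "m2"],
        "reaction_id": ["R1", "R2"]})
    net = mn.build_met_enz_network(table)
    _, comps = mn.map_dysregulated(net, NodeSet("e", ["E1", "E2"]),
                                   NodeSet("m", []), max_hops=2)
    assert len(comps) == 2


def test_map_dysregulated_empty_warns_not_errors(caplog):
    net = mn.build_met_enz_network(_chain_table())
    with caplog.at_level("WARNING"):
        sub, comps = mn.map_dysregulated(net, NodeSet("e", ["ZZ"]),
                                         NodeSet("m", []), max_hops=2)
    assert sub.graph.number_of_nodes() == 0
    assert len(comps) == 0


def test_map_dysregulated_monotone_in_max_hops(rng):
    cfg = SimConfig(seed=53, n_reactions=60)
    enzymes = [f"E{i}" for i in range(15)]
    mets = [f"m{i}" for i in range(20)]
    from pahomics.synthio import generate_reaction_network
    table = generate_reaction_network(cfg, enzymes, mets)
    net = mn.build_met_enz_network(table)
    sig_e = NodeSet("e", rng.choice(enzymes, size=4, replace=False))
    sig_m = NodeSet("m", rng.choice(mets, size=4, replace=False))
    prev = set()
    for hops in (0, 1, 2, 3, 4):
        sub, _ = mn.map_dysregulated(net, sig_e, sig_m, max_hops=hops)
        nodes = set(sub.graph.nodes)
        assert prev <= nodes
        assert sub.is_bipartite() or sub.graph.number_of_edges() == 0
        prev = nodes
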