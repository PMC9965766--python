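import numpy as np
import networkx as nx
import pandas as pd
import pytest

from metabonet import data_io
from metabonet.data_io import GroupPair
from metabonet.pclrc import AssociationNetwork


def test_wide_csv_round_trip_is_identity(small_matrix, tmp_path):
    path = tmp_path / "t.csv"
    data_io.write_abundance_table(small_matrix, path)
    back = data_io.read_abundance_table(path)
    assert back.sample_ids == small_matrix.sample_ids
    assert back.metabolite_names == small_matrix.metabolite_names
    assert (back.groups == small_matrix.groups).all()
    np.testing.assert_array_equal(back.values.to_numpy(), small_matrix.values.to_numpy())


def test_all_ones_table(tmp_path):
    path = tmp_path / "ones.csv"
    path.write_text("sample_id,group,m1,m2\ns1,A,1.0,1.0\ns2,B,1.0,1.0\n")
    am = data_io.read_abundance_table(path)
    assert am.n_samples == 2 and am.n_metabolites == 2
    assert (am.values.to_numpy() == 1.0).all()


@pytest.mark.parametrize(
    "body,err_match",
    [
        ("sample_id,group,m1\ns1,A,1\ns1,B,2\n", "duplicate sample"),
        ("sample_id,group,m1,m1\ns1,A,1,2\ns2,B,1,2\n", "duplicate metabolite"),
        ("sample_id,group,m1\ns1,A,abc\ns2,B,2\n", "non-numeric"),
        ("sample_id,group,m1\ns1,A,-3\ns2,B,2\n", "negative"),
    ],
)
def test_reader_hard_errors(tmp_path, body, err_match):
    path = tmp_path / "bad.csv"
    path.write_text(body)
    with pytest.raises(ValueError, match=err_match):
        data_io.read_abundance_table(path)


def test_unknown_group_label_lists_allowed(tmp_path):
    path = tmp_path / "g.csv"
    path.write_text("sample_id,group,m1\ns1,Weird,1\ns2,CTR,2\n")
    with pytest.raises(ValueError, match="allowed labels"):
        data_io.read_abundance_table(path, allowed_groups=["CRC", "PP", "CTR"])


def test_group_aliases_are_case_insensitive(tmp_path):
    path = tmp_path / "a.csv"
    path.write_text("sample_id,group,m1\ns1,Healthy,1\ns2,cancer,2\n")
    am = data_io.read_abundance_table(
        path, group_aliases=data_io.DEFAULT_GROUP_ALIASES,
        allowed_groups=["CRC", "CTR"],
    )
    assert sorted(am.groups) == ["CRC", "CTR"]


def test_mwtab_flat_block(tmp_path):
    text = (
        "header junk\n"
        "MS_METABOLITE_DATA_START\n"
        "Samples\ts1\ts2\ts3\n"
        "Factors\tDiagnosis:CRC\tDiagnosis:CTR\tDiagnosis:CTR\n"
        "glucose\t1.5\t2.5\t3.5\n"
        "lactate\t10\t20\t30\n"
        "MS_METABOLITE_DATA_END\n"
    )
    path = tmp_path / "x.txt"
    path.write_text(text)
    am = data_io.read_abundance_table(path, "mwtab_flat")
    assert am.n_samples == 3 and am.n_metabolites == 2
    assert am.metabolite_names == ["glucose", "lactate"]
    assert list(am.groups) == ["CRC", "CTR", "CTR"]
    assert am.values.loc["s2", "lactate"] == 20


def test_missing_values_flagged_then_imputed(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text(
        "sample_id,group,m1,m2\ns1,A,,4\ns2,A,2,4\ns3,A,8,4\ns4,A,5,4\ns5,A,6,4\n"
        "s6,B,2,4\ns7,B,4,4\ns8,B,6,4\n"
    )
    am = data_io.read_abundance_table(path)
    assert am.has_missing
    imp = am.impute_missing()
    # half the minimum positive value of m1 (min positive = 2)
    assert imp.values.loc["s1", "m1"] == 1.0
    assert not imp.has_missing


def test_too_many_missing_per_group_rejected(tmp_path):
    path = tmp_path / "m.csv"
    path.write_text(
        "sample_id,group,m1\ns1,A,\ns2,A,2\ns3,A,3\ns4,B,1\ns5,B,2\ns6,B,3\n"
    )
    am = data_io.read_abundance_table(path)
    with pytest.raises(ValueError, match="missing in group A"):
        am.impute_missing(max_missing_frac=0.2)


def _triangle_network():
    g = nx.Graph()
    g.add_edge("a", "b", weight=0.7, probability=0.99)
    g.add_edge("b", "c", weight=-0.8, probability=0.97)
    g.add_edge("a", "c", weight=0.9, probability=1.0)
    g.add_node("isolated")
    return AssociationNetwork(graph=g, p_min=0.95, r_min=0.6)


@pytest.mark.parametrize("fmt", ["graphml", "edge_tsv"])
def test_network_round_trip(tmp_path, fmt):
    net = _triangle_network()
    path = tmp_path / f"net.{fmt}"
    data_io.write_network(net, path, fmt)
    back = data_io.read_network(path, fmt)
    assert set(back.graph.nodes) == set(net.graph.nodes)
    assert set(map(frozenset, back.graph.edges)) == set(map(frozenset, net.graph.edges))
    for u, v, d in net.graph.edges(data=True):
        assert back.graph[u][v]["weight"] == pytest.approx(d["weight"], abs=1e-12)
        assert back.graph[u][v]["probability"] == pytest.approx(d["probability"], abs=1e-12)


def test_empty_network_written_with_isolated_nodes(tmp_path):
    g = nx.Graph()
    g.add_nodes_from(["x", "y", "z"])
    net = AssociationNetwork(graph=g, p_min=0.95, r_min=0.6)
    path = tmp_path / "e.tsv"
    data_io.write_network(net, path, "edge_tsv")
    back = data_io.read_network(path, "edge_tsv")
    assert set(back.graph.nodes) == {"x", "y", "z"}
    assert back.graph.number_of_edges() == 0


def test_results_table_round_trip_and_order(tmp_path):
    rows = [
        {"metabolite": "b_met", "comparison": "CRC_vs_CTR", "p_value": 0.123456789},
        {"metabolite": "a_met", "comparison": "CRC_vs_CTR", "p_value": 1e-7},
    ]
    path = tmp_path / "r.tsv"
    data_io.write_results_table(rows, path)
    back = pd.read_csv(path, sep="\t")
    assert list(back["metabolite"]) == ["a_met", "b_met"]  # deterministic sort
    assert back["p_value"].iloc[0] == pytest.approx(1e-7, rel=1e-6)
    assert back["p_value"].iloc[1] == pytest.approx(0.123456789, rel=1e-6)


def test_results_table_empty_writes_header_only(tmp_path):
    path = tmp_path / "empty.tsv"
    data_io.write_results_table(pd.DataFrame(columns=["metabolite", "p_value"]), path)
    lines = path.read_text().strip().splitlines()
    assert lines == ["metabolite\tp_value"]


def test_group_pair_requires_distinct_groups():
    with pytest.raises(ValueError):
        GroupPair("CRC", "CRC")
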