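import networkx as nx
import pandas as pd
import pytest

from vesnet.io import IdentificationTable


@pytest.fixture
def three_row_table(tmp_path):
    """The 3-row reader fixture: 2 proteins over 2 batches."""
    path = tmp_path / "ident.tsv"
    path.write_text(
        "protein_id\tgene_id\tcondition\tbatch\tspectral_count\tfdr\n"
        "P1\tGENE1\tNBE\tb1\t12\t0.001\n"
        "P1\tGENE1\tNBE\tb2\t0\t0.001\n"
        "P2\tGENE2\tNBE\tb1\t3\t0.02\n")
    return path


def make_table(rows):
    """rows: (protein, gene, condition, batch, count, fdr) tuples."""
    return IdentificationTable(pd.DataFrame(
        rows, columns=["protein_id", "gene_id", "condition", "batch",
                       "spectral_count", "fdr"]))


@pytest.fixture
def small_graph():
    """Edges a-b, b-c, c-d, a-c (the worked coherence example)."""
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("C", "D"), ("A", "C")])
    return g


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A complete synthetic fixture directory shared across tests."""
    from vesnet.simulate import write_fixture_dir
    out = tmp_path_factory.mktemp("fixture")
    truth = write_fixture_dir(out, seed=11, n_proteins=300, n_up=30,
                              network_nodes=600, edge_prob=0.01)
    return out, truth
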