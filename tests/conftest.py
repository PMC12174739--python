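import logging

import pytest

# The default synthetic config intentionally plants more genes than the
# smallest list holds; silence the advisory so test output stays readable.
logging.getLogger("degmeta.synthetic_data").setLevel(logging.ERROR)


@pytest.fixture()
def deg_table(tmp_path):
    """A small well-formed DEG table on disk, with one linear-FC column."""
    path = tmp_path / "degs.tsv"
    path.write_text(
        "symbol\tfc\tpval\tfdr\n"
        "GENE1\t1.5\t0.01\t0.04\n"
        "GENE2\t-2.0\t0.001\t0.01\n"
        "GENE3\t0.5\t0.2\t0.5\n"
    )
    return path


@pytest.fixture()
def default_schema():
    return {"gene_symbol": "symbol", "fold_change": "fc", "p_value": "pval", "adj_p_value": "fdr"}
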