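import pandas as pd
import pytest

from drugrepo.simulate import SimulationConfig


@pytest.fixture
def small_config():
    """Desk-scale generator configuration used across module tests."""
    return SimulationConfig(
        seed=42,
        n_genes=100,
        n_gene_hits=12,
        n_protein_hits=8,
        n_metabolites=10,
        overlap_fraction=0.25,
        mean_links_per_metabolite=3.0,
        n_drug_projects=60,
        n_instances=40,
        tag_size=5,
    )


@pytest.fixture
def write_tsv(tmp_path):
    """Write a list of row dicts as a TSV and return the path."""

    def _write(name, rows, columns=None):
        path = tmp_path / name
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        return path

    return _write
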