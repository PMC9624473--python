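"""Shared fixtures: a small synthetic study generated once per session."""

import io

import pandas as pd
import pytest
from hypothesis import settings

from clonolink import clonotypes as ct
from clonolink import synth, vdj

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_config():
    """A reduced study: 2 mice per group, a few hundred cells per sample."""
    return synth.SyntheticConfig(
        n_mice_per_group=2,
        n_cells_til=300,
        n_cells_spleen=150,
        n_top_clonotypes=4,
        n_tail_clonotypes=60,
        n_genes=200,
        n_planted_deg=10,
        synonymous_variant_fraction=0.5,
    )


@pytest.fixture(scope="session")
def tiny_data(tiny_config):
    return synth.generate_repertoire(tiny_config, seed=7)


@pytest.fixture(scope="session")
def tiny_cells(tiny_data):
    """Cells assembled through the real ingest path from the synthetic
    contig tables (in-memory CSV round-trip)."""
    tables, _ = tiny_data
    frames = []
    for sample, table in tables.items():
        contigs = vdj.read_contigs(io.StringIO(table.to_csv(index=False)), sample)
        cells, _ = vdj.assemble_cells(vdj.filter_contigs(contigs))
        frames.append(cells)
    return ct.add_receptor_keys(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def tiny_tables(tiny_cells):
    return {
        s: ct.abundance_table(tiny_cells[tiny_cells["sample_id"] == s], s)
        for s in sorted(tiny_cells["sample_id"].unique())
    }


@pytest.fixture(scope="session")
def tiny_adata(tiny_config, tiny_data):
    _, truth = tiny_data
    return synth.generate_expression(tiny_config, truth, seed=11)
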