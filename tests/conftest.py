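import numpy as np
import pytest

from intrisol.curation import build_task_table, curate_s0
from intrisol.molgraph import build_graph
from intrisol.synthdata import GeneratorConfig, simulate_dataset


def make_table(n=50, seed=1, noise_sd=0.0):
    """Simulate, curate and assemble an eight-task table plus graphs."""
    cfg = GeneratorConfig(n_compounds=n, seed=seed, noise_sd=noise_sd)
    entries, true_s0, labels, records, tasks = simulate_dataset(cfg)
    s0 = curate_s0(entries, records)
    ok = s0[s0.status == "ok"]
    task_values = {"S0": dict(zip(ok.compound_id, ok.log_s0))}
    task_values.update(tasks)
    smiles = {e.compound_id: e.smiles for e in entries}
    hq = dict(zip(ok.compound_id, ok.high_quality.astype(bool)))
    table = build_task_table(task_values, smiles, hq)
    graphs = [build_graph(s) for s in table.smiles]
    return table, graphs, true_s0


@pytest.fixture(scope="session")
def small_dataset():
    """50-compound noise-free table + graphs, shared across model tests."""
    return make_table(n=50, seed=1, noise_sd=0.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
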