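import numpy as np
import pytest

from halovir.config import RunConfig
from halovir.pipeline import PipelineInputs, run_pipeline
from halovir.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_config():
    """Small-but-structured synthetic study for the unit suite."""
    return SimConfig(seed=11, n_votus=30, n_decoys=10)


@pytest.fixture(scope="session")
def dataset(sim_config):
    return simulate_dataset(sim_config)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(n_permutations=199, seed=11)


@pytest.fixture(scope="session")
def pipeline_result(dataset, run_config):
    return run_pipeline(PipelineInputs.from_dataset(dataset), run_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate_subs(rng, seq, rate):
    """Substitution-only mutant (always to a different base)."""
    arr = list(seq)
    k = rng.binomial(len(arr), rate)
    for p in rng.choice(len(arr), size=k, replace=False):
        arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
    return "".join(arr)


def truth_label_maps(dataset, votus, delimiter="||"):
    """(per-member truth labels, per-recovered-vOTU truth labels)."""
    truth = dataset.truth
    member_true, member_pred = [], []
    votu_true = {}
    for v in votus:
        rep_base = v.representative.split(delimiter)[0]
        votu_true[v.votu_id] = truth.votu_assignment[rep_base]
        for m in v.members:
            member_pred.append(v.votu_id)
            member_true.append(truth.votu_assignment[m.split(delimiter)[0]])
    return (member_true, member_pred), votu_true
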