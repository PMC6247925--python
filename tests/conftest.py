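import numpy as np
import pandas as pd
import pytest

from methylfn.synthetic import SimulationParams, make_manifest, simulate_dataset
from methylfn.qc import build_qc_object


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(n_samples=12, n_cpg_probes=480, n_snp_probes=10,
                            n_control_per_type=5, k_true=2, seed=11)


@pytest.fixture(scope="session")
def small_manifest(small_params):
    return make_manifest(small_params.platform, small_params)


@pytest.fixture(scope="session")
def small_dataset(small_manifest, small_params):
    dataset, truth = simulate_dataset(small_manifest, small_params)
    return dataset, truth


@pytest.fixture(scope="session")
def small_qcs(small_dataset, small_manifest):
    dataset, _ = small_dataset
    return [build_qc_object(s, small_manifest, n_q=40) for s in dataset.samples]


def toy_manifest(rows):
    """Build a Manifest from (probe_id, probe_type, channel, target,
    control_type, chromosome) tuples."""
    from methylfn.io import Manifest
    return Manifest(pd.DataFrame(
        rows, columns=["probe_id", "probe_type", "channel", "target",
                       "control_type", "chromosome"]))
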