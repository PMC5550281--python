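import numpy as np
import pandas as pd
import pytest

from alphalobe.model import (
    Connectome,
    Neuron,
    PresynapticSite,
    Skeleton,
    SynapticContact,
)
from alphalobe.synthetic import GeneratorConfig, generate


def build_connectome(neurons, sites, contacts, skeletons=None):
    """Convenience wrapper: records in, validated Connectome out."""
    return Connectome.from_records(
        [Neuron(*n) for n in neurons],
        [PresynapticSite(*s) for s in sites],
        [SynapticContact(*c) for c in contacts],
        skeletons=skeletons,
    )


@pytest.fixture
def tiny_connectome():
    """2 KCs, 1 MBON, 1 DAN; one polyadic KC site, one DAN site."""
    return build_connectome(
        neurons=[
            ("kc1", "KC-ab-s"),
            ("kc2", "KC-ab-s"),
            ("m1", "MBON-a3", "A"),
            ("d1", "PPL1-a3", "A"),
        ],
        sites=[
            ("s1", "kc1", (100.0, 100.0, 40100.0), "a3"),
            ("s2", "kc2", (200.0, 100.0, 40200.0), "a3"),
            ("s3", "d1", (5000.0, 5000.0, 45000.0), "a3"),
        ],
        contacts=[
            ("s1", "m1"),
            ("s1", "kc2"),
            ("s1", "d1"),
            ("s2", "m1"),
            ("s3", "kc1"),
        ],
    )


SMALL_CONFIG = GeneratorConfig(
    n_kc_per_subtype={"KC-ab-s": 30, "KC-ab-p": 10},
    cells_per_compartment={
        "a2": [("MBON-a2sc", 1), ("PPL1-ap2a2", 2)],
        "a3": [("MBON-a3", 2), ("PPL1-a3", 1)],
    },
    wiring_rate={
        ("KC-ab-s", "MBON-a3", "a3"): 4.0,
        ("KC-ab-p", "MBON-a3", "a3"): 2.0,
        ("KC-ab-s", "MBON-a2sc", "a2"): 3.0,
        ("KC-ab-s", "PPL1-a3", "a3"): 1.0,
        ("PPL1-a3", "KC-ab-s", "a3"): 0.8,
        ("PPL1-ap2a2", "KC-ab-s", "a2"): 0.5,
        ("PPL1-a3", "MBON-a3", "a3"): 20.0,
    },
    convergence_rate=0.5,
    rosette_rate=0.5,
    seed=42,
)


@pytest.fixture(scope="session")
def small_generated():
    """A small but structurally complete synthetic lobe (two compartments)."""
    connectome, truth = generate(SMALL_CONFIG)
    return connectome, truth


def path_skeleton(step_nm=1000.0, n=11):
    """Straight path skeleton along x with node spacing ``step_nm``."""
    node_ids = list(range(1, n + 1))
    positions = np.column_stack(
        [np.arange(n) * step_nm, np.zeros(n), np.zeros(n)]
    )
    parents = [-1] + node_ids[:-1]
    return Skeleton(node_ids, positions, parents)
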