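"""Distance-from-root profiles of synaptic inputs on a skeletonized arbor.

Builds a simple branched dendrite, places feedforward inputs either near the
root or uniformly along the cable, and shows that the geodesic input profile
plus a KS test separates the two arrangements.
"""

import numpy as np

from alphalobe import ks_two_sample
from alphalobe.geometry import input_profile
from alphalobe.model import (
    Connectome,
    Neuron,
    PresynapticSite,
    Skeleton,
    SynapticContact,
)

# a 100 um path skeleton along x, 1 um node spacing, root at node 1
n_nodes = 101
positions = np.column_stack(
    [np.arange(n_nodes) * 1000.0, np.zeros(n_nodes), np.zeros(n_nodes)]
)
skeleton = Skeleton(
    list(range(1, n_nodes + 1)), positions, [-1] + list(range(1, n_nodes))
)


def build(arcs_um, label):
    neurons = [Neuron("mbon", "MBON-a1", "A"), Neuron("ff", "MBON-b1-ff")]
    sites = [
        PresynapticSite(f"s{i}", "ff", (1000.0 * a, 0.0, 0.0), "a1")
        for i, a in enumerate(arcs_um)
    ]
    contacts = [SynapticContact(f"s{i}", "mbon") for i in range(len(arcs_um))]
    conn = Connectome.from_records(neurons, sites, contacts, skeletons={"mbon": skeleton})
    prof = input_profile(conn, "mbon", "feedforward", root_node=1)
    print(f"{label}: {len(prof.distances_um)} inputs, "
          f"mean distance from root {prof.mean_distance_um:.1f} um")
    return prof


rng = np.random.default_rng(9)
proximal = build(np.round(rng.uniform(0, 25, 100)), "root-biased inputs")
uniform = build(np.round(rng.uniform(0, 100, 100)), "uniform inputs   ")

d, p = ks_two_sample(proximal.distances_um, uniform.distances_um)
print(f"\nKS two-sample: D = {d:.2f}, p = {p:.2e}")
print(
    "A root-biased input arrangement concentrates synaptic drive where it "
    "most influences spike output; the KS test distinguishes it from a "
    "uniform arrangement already at 100 inputs."
)
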