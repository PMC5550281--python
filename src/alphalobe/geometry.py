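"""Distance-from-root analysis of synaptic input positions on arbors.

Each synaptic contact onto a skeletonized neuron is snapped to the nearest
skeleton node (Euclidean, within a tolerance) and its distance from a chosen
root node — the point where the dendrites collect into the axon — is measured
geodesically along the tree. The root is an explicit user input: identifying
it is an anatomical judgment, not something computable from the skeleton
alone. Distances are reported in microns.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import Connectome, ConnectomeError, Skeleton

__all__ = ["InputPositionProfile", "geodesic_from_root", "input_profile"]

log = logging.getLogger("alphalobe")

NM_PER_UM = 1000.0


@dataclass
class InputPositionProfile:
    """Distances of one cell's synaptic inputs from the root of its arbor."""

    post_neuron: str
    root_node: int
    distances_um: np.ndarray  # one entry per mapped contact
    bin_edges_um: np.ndarray  # log-spaced histogram edges
    histogram: np.ndarray
    mean_distance_um: float
    n_unmapped: int


def geodesic_from_root(skeleton: Skeleton, root_node: int | None = None) -> pd.Series:
    """Geodesic distance (µm) from the root to every skeleton node.

    The distance is the sum of Euclidean edge lengths along the unique tree
    path. ``root_node`` defaults to the skeleton's anatomical root; any node
    may serve as the measuring origin.
    """
    if root_node is None:
        root_node = skeleton.root_id
    root_idx = skeleton.index_of(root_node)  # raises if absent
    n = skeleton.n_nodes()
    adjacency: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for (child, parent), length in zip(skeleton.edges(), skeleton.edge_lengths()):
        adjacency[child].append((parent, length))
        adjacency[parent].append((child, length))
    dist = np.full(n, np.nan)
    dist[root_idx] = 0.0
    queue = deque([root_idx])
    while queue:
        u = queue.popleft()
        for v, length in adjacency[u]:
            if np.isnan(dist[v]):
                dist[v] = dist[u] + length
                queue.append(v)
    return pd.Series(dist / NM_PER_UM, index=skeleton.node_ids, name="distance_um")


def input_profile(
    connectome: Connectome,
    post_neuron: str,
    pre_selector,
    root_node: int | None = None,
    n_bins: int = 20,
    snap_tolerance: float = 500.0,
    metric: str = "geodesic",
) -> InputPositionProfile:
    """Distance-from-root profile of the inputs a cell receives.

    Contacts from ``pre_selector`` onto ``post_neuron`` are snapped to the
    nearest skeleton node; contacts farther than ``snap_tolerance`` (nm) from
    every node are excluded (and counted). ``metric`` is ``"geodesic"`` (path
    length along the arbor) or ``"euclidean"`` (straight-line from the root).
    The histogram uses log-spaced bins from 0.1 µm to the maximum distance.
    """
    if post_neuron not in connectome.skeletons:
        raise ConnectomeError(f"no skeleton available for {post_neuron!r}")
    skeleton = connectome.skeletons[post_neuron]
    if root_node is None:
        root_node = skeleton.root_id

    pre_cells = connectome.select_neurons(pre_selector)
    t = connectome.contact_table()
    sub = t[(t["post_neuron"] == post_neuron) & (t["pre_neuron"].isin(pre_cells))]
    pos = sub[["x", "y", "z"]].to_numpy(dtype=float)

    tree = cKDTree(skeleton.positions)
    snap_dist, node_idx = tree.query(pos) if len(pos) else (np.empty(0), np.empty(0, int))
    mapped = snap_dist <= snap_tolerance
    n_unmapped = int((~mapped).sum())
    if n_unmapped:
        log.info(
            "input_profile(%s): %d contact(s) beyond %.0f nm snap tolerance excluded",
            post_neuron,
            n_unmapped,
            snap_tolerance,
        )
    node_idx = np.asarray(node_idx, dtype=int)[mapped]

    if metric == "geodesic":
        per_node = geodesic_from_root(skeleton, root_node).to_numpy()
        distances = per_node[node_idx]
    elif metric == "euclidean":
        root_pos = skeleton.positions[skeleton.index_of(root_node)]
        distances = (
            np.linalg.norm(skeleton.positions[node_idx] - root_pos, axis=1) / NM_PER_UM
        )
    else:
        raise ValueError("metric must be 'geodesic' or 'euclidean'")

    max_d = float(distances.max()) if len(distances) else 1.0
    upper = max(max_d, 0.2)
    edges = np.logspace(np.log10(0.1), np.log10(upper * 1.0001), n_bins + 1)
    edges[0] = 0.0  # contacts at/near the root land in the first bin
    hist, _ = np.histogram(distances, bins=edges)
    return InputPositionProfile(
        post_neuron=post_neuron,
        root_node=int(root_node),
        distances_um=distances,
        bin_edges_um=edges,
        histogram=hist,
        mean_distance_um=float(distances.mean()) if len(distances) else float("nan"),
        n_unmapped=n_unmapped,
    )
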