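"""Geometric synaptic motifs and dopamine volume-transmission coverage.

A *convergence* is a tight spatial grouping (default within 300 nm) of
presynaptic sites from at least two distinct KCs that share a postsynaptic
neuron; clusters are single-linkage connected components of the radius graph
over that neuron's KC presynaptic sites. A *rosette* is a convergence that
additionally contains a KC>KC contact between two member KCs, and a
KC<>KC>MBON *triangle* is the corresponding (KC, KC, MBON) triple.

Coverage analysis treats neuromodulation as purely geometric: a KC>MBON
synapse is "covered" at radius r if some dopaminergic presynaptic site lies
within the closed ball of radius r around it. Distances are Euclidean in nm,
measured site-to-site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from sklearn.neighbors import radius_neighbors_graph

from .model import Connectome, ConnectomeError

__all__ = [
    "ConvergenceCluster",
    "CoverageCurve",
    "find_convergences",
    "find_rosettes",
    "motif_fractions",
    "triangle_motifs",
    "dan_proximity_fraction",
    "coverage_curve",
    "nearest_modulation_stats",
]

DEFAULT_RADIUS = 300.0  # nm


@dataclass
class ConvergenceCluster:
    """A single-linkage cluster of convergent KC presynaptic sites."""

    post_neuron: str
    member_sites: tuple[str, ...]
    member_kcs: tuple[str, ...]
    radius: float
    is_rosette: bool = False
    kc_kc_contacts: tuple[tuple[str, str], ...] = ()  # (site_id, post_kc)


@dataclass
class CoverageCurve:
    """Fraction of KC>MBON synapses with a DAN site within each radius."""

    radii: np.ndarray
    same_compartment_fraction: np.ndarray
    adjacent_compartment_fraction: np.ndarray
    n_synapses: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "radius_nm": self.radii,
                "same_compartment": self.same_compartment_fraction,
                "adjacent_compartment": self.adjacent_compartment_fraction,
            }
        )


def _kc_site_positions(connectome: Connectome, site_ids: pd.Index) -> np.ndarray:
    pos = connectome.sites.loc[site_ids, ["x", "y", "z"]]
    if pos.isna().any().any():
        bad = pos.index[pos.isna().any(axis=1)][0]
        raise ConnectomeError(f"missing coordinates for site {bad!r}")
    return pos.to_numpy(dtype=float)


def find_convergences(
    connectome: Connectome,
    post_selector=None,
    radius: float = DEFAULT_RADIUS,
) -> list[ConvergenceCluster]:
    """Single-linkage convergence clusters of KC sites per postsynaptic neuron.

    For each selected postsynaptic neuron, the KC presynaptic sites with at
    least one contact onto it are linked whenever two sites are within
    ``radius`` (closed ball); connected components with sites from >= 2
    distinct KCs are returned. A site belongs to at most one cluster per
    postsynaptic neuron.
    """
    t = connectome.contact_table()
    kc_contacts = t[t["pre_class"] == "KC"]
    if post_selector is not None:
        selected = connectome.select_neurons(post_selector)
        kc_contacts = kc_contacts[kc_contacts["post_neuron"].isin(selected)]
    clusters: list[ConvergenceCluster] = []
    for post, grp in kc_contacts.groupby("post_neuron", sort=True):
        # one entry per site (a polyadic site counts once toward this target)
        sites = grp.drop_duplicates("site_id")
        site_ids = pd.Index(sites["site_id"])
        if len(site_ids) < 2:
            continue
        pos = _kc_site_positions(connectome, site_ids)
        graph = radius_neighbors_graph(
            pos, radius=radius, mode="connectivity", include_self=False
        )
        n_comp, labels = connected_components(graph, directed=False)
        pre = sites["pre_neuron"].to_numpy()
        for c in range(n_comp):
            members = np.flatnonzero(labels == c)
            kcs = pd.unique(pre[members])
            if len(members) >= 2 and len(kcs) >= 2:
                clusters.append(
                    ConvergenceCluster(
                        post_neuron=str(post),
                        member_sites=tuple(site_ids[members]),
                        member_kcs=tuple(sorted(map(str, kcs))),
                        radius=radius,
                    )
                )
    return clusters


def find_rosettes(
    clusters: list[ConvergenceCluster], connectome: Connectome
) -> list[ConvergenceCluster]:
    """Mark clusters containing a KC>KC contact between member KCs.

    A cluster is a rosette iff some KC>KC contact's presynaptic site lies
    within the cluster radius of a member site and both its pre and post
    neurons are member KCs. Returns the same cluster objects, updated.
    """
    t = connectome.contact_table()
    kk = t[(t["pre_class"] == "KC") & (t["post_class"] == "KC")]
    if len(kk) == 0 or not clusters:
        return clusters
    kk_sites = kk.drop_duplicates(subset=["site_id", "post_neuron"])
    kk_pos = _kc_site_positions(connectome, pd.Index(kk_sites["site_id"]))
    tree = cKDTree(kk_pos)
    kk_pre = kk_sites["pre_neuron"].to_numpy()
    kk_post = kk_sites["post_neuron"].to_numpy()
    kk_sid = kk_sites["site_id"].to_numpy()
    for cluster in clusters:
        member_pos = _kc_site_positions(connectome, pd.Index(cluster.member_sites))
        near = sorted(
            {j for idx in tree.query_ball_point(member_pos, cluster.radius) for j in idx}
        )
        members = set(cluster.member_kcs)
        support = [
            (str(kk_sid[j]), str(kk_post[j]))
            for j in near
            if kk_pre[j] in members and kk_post[j] in members
        ]
        cluster.is_rosette = bool(support)
        cluster.kc_kc_contacts = tuple(support)
    return clusters


def motif_fractions(
    connectome: Connectome,
    post_type: str,
    radius: float = DEFAULT_RADIUS,
    clusters: list[ConvergenceCluster] | None = None,
) -> tuple[float, float]:
    """Percent of KC presynaptic sites (targeting ``post_type``) in motifs.

    Returns ``(percent_in_convergence, percent_in_rosette)``. The denominator
    is the number of KC presynaptic sites with >= 1 contact onto a cell of the
    selected postsynaptic type.
    """
    post_cells = set(connectome.select_neurons(post_type))
    t = connectome.contact_table()
    eligible = t[(t["pre_class"] == "KC") & (t["post_neuron"].isin(post_cells))]
    denominator = eligible["site_id"].nunique()
    if denominator == 0:
        raise ConnectomeError(
            f"no KC presynaptic sites target {post_type!r}; fractions undefined"
        )
    if clusters is None:
        clusters = find_rosettes(
            find_convergences(connectome, post_selector=post_type, radius=radius),
            connectome,
        )
    conv_sites: set[str] = set()
    ros_sites: set[str] = set()
    for c in clusters:
        if c.post_neuron in post_cells:
            conv_sites.update(c.member_sites)
            if c.is_rosette:
                ros_sites.update(c.member_sites)
    return (
        100.0 * len(conv_sites) / denominator,
        100.0 * len(ros_sites) / denominator,
    )


def triangle_motifs(
    connectome: Connectome,
    radius: float = DEFAULT_RADIUS,
    clusters: list[ConvergenceCluster] | None = None,
) -> list[tuple[str, str, str]]:
    """KC<>KC>MBON triangles: (kc_a, kc_b, mbon) triples, kc_a < kc_b.

    A triple is reported when a KC>KC contact (either direction) is supported
    inside a convergence cluster on an MBON and both KCs are cluster members
    (hence both synapse onto that MBON within the cluster).
    """
    mbons = set(
        connectome.neurons.index[connectome.neurons["type_class"] == "MBON"]
    )
    if clusters is None:
        clusters = find_convergences(connectome, radius=radius)
    clusters = find_rosettes(clusters, connectome)
    sid_to_pre = connectome.sites["pre_neuron"]
    triples: set[tuple[str, str, str]] = set()
    for c in clusters:
        if c.post_neuron not in mbons:
            continue
        for site_id, post_kc in c.kc_kc_contacts:
            pre_kc = str(sid_to_pre[site_id])
            a, b = sorted((pre_kc, str(post_kc)))
            triples.add((a, b, c.post_neuron))
    return sorted(triples)


def _contact_positions_and_mask(
    connectome: Connectome, pre_class: str, post_class: str
) -> pd.DataFrame:
    t = connectome.contact_table()
    return t[(t["pre_class"] == pre_class) & (t["post_class"] == post_class)]


def dan_proximity_fraction(
    connectome: Connectome, radius: float = DEFAULT_RADIUS
) -> float:
    """Fraction of KC>MBON synapses with a DAN presynaptic site within radius.

    Distance is Euclidean from the KC presynaptic site position to the nearest
    dopaminergic presynaptic site; ties at exactly the radius count as within.
    """
    km = _contact_positions_and_mask(connectome, "KC", "MBON")
    if len(km) == 0:
        return 0.0
    dan_sites = connectome.sites[
        connectome.sites["pre_neuron"]
        .map(connectome.neurons["type_class"])
        .eq("DAN")
    ]
    if len(dan_sites) == 0:
        return 0.0
    tree = cKDTree(dan_sites[["x", "y", "z"]].to_numpy(dtype=float))
    pos = km[["x", "y", "z"]].to_numpy(dtype=float)
    dist, _ = tree.query(pos, k=1)
    return float(np.mean(dist <= radius))


def coverage_curve(
    connectome: Connectome,
    radii: np.ndarray | None = None,
) -> CoverageCurve:
    """Volume-transmission coverage of KC>MBON synapses by DAN release sites.

    For each radius r, computes the fraction of KC>MBON synapses with at least
    one DAN presynaptic site of the *same* compartment within r, and likewise
    for DAN sites of an *adjacent* compartment (serial adjacency a1-a2-a3).
    The default radii grid spans 0-5000 nm in 100 nm steps.
    """
    if radii is None:
        radii = np.arange(0.0, 5001.0, 100.0)
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be strictly increasing")
    km = _contact_positions_and_mask(connectome, "KC", "MBON")
    n = len(km)
    if n == 0:
        raise ConnectomeError("no KC>MBON synapses")
    dan_sites = connectome.sites[
        connectome.sites["pre_neuron"]
        .map(connectome.neurons["type_class"])
        .eq("DAN")
    ]
    trees = {
        comp: cKDTree(grp[["x", "y", "z"]].to_numpy(dtype=float))
        for comp, grp in dan_sites.groupby("compartment")
    }
    nearest_same = np.full(n, np.inf)
    nearest_adj = np.full(n, np.inf)
    for comp, grp in km.groupby("compartment"):
        if comp not in connectome.compartment_order:
            continue
        idx = km.index.get_indexer(grp.index)
        pos = grp[["x", "y", "z"]].to_numpy(dtype=float)
        if comp in trees:
            nearest_same[idx], _ = trees[comp].query(pos, k=1)
        best = np.full(len(pos), np.inf)
        for adj in connectome.adjacent_compartments(comp):
            if adj in trees:
                d, _ = trees[adj].query(pos, k=1)
                best = np.minimum(best, d)
        nearest_adj[idx] = best
    same = np.array([np.mean(nearest_same <= r) for r in radii])
    adj = np.array([np.mean(nearest_adj <= r) for r in radii])
    return CoverageCurve(
        radii=radii,
        same_compartment_fraction=same,
        adjacent_compartment_fraction=adj,
        n_synapses=n,
    )


def nearest_modulation_stats(connectome: Connectome) -> tuple[float, float]:
    """Distance from KC>MBON synapses to the nearest DAN>KC synapse.

    Returns ``(mean nearest distance in nm, mean number of other presynaptic
    sites strictly closer than that nearest DAN>KC synapse)``.
    """
    km = _contact_positions_and_mask(connectome, "KC", "MBON")
    dk = _contact_positions_and_mask(connectome, "DAN", "KC")
    if len(dk) == 0:
        raise ConnectomeError("no DAN>KC synapses present")
    if len(km) == 0:
        raise ConnectomeError("no KC>MBON synapses present")
    dk_sites = dk.drop_duplicates("site_id")
    dan_tree = cKDTree(dk_sites[["x", "y", "z"]].to_numpy(dtype=float))
    pos = km[["x", "y", "z"]].to_numpy(dtype=float)
    nearest, _ = dan_tree.query(pos, k=1)

    all_sites = connectome.sites
    all_pos = all_sites[["x", "y", "z"]].to_numpy(dtype=float)
    site_tree = cKDTree(all_pos)
    site_row = {sid: i for i, sid in enumerate(all_sites.index)}
    own_row = np.array([site_row[s] for s in km["site_id"]])
    interspersed = np.empty(len(pos))
    for i, (p, d) in enumerate(zip(pos, nearest)):
        neighbors = np.asarray(site_tree.query_ball_point(p, d), dtype=int)
        if len(neighbors) == 0:
            interspersed[i] = 0
            continue
        dists = np.linalg.norm(all_pos[neighbors] - p, axis=1)
        # strictly closer than the nearest DAN>KC synapse; exclude the
        # synapse's own site and anything exactly at distance d
        closer = dists < d
        closer &= neighbors != own_row[i]
        interspersed[i] = int(closer.sum())
    return float(nearest.mean()), float(interspersed.mean())
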