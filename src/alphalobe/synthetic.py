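"""Seeded generator of alpha-lobe-like connectomes with known ground truth.

The generated lobe is a cylinder whose axis is z, split into three contiguous
axial compartments (a1, a2, a3). KC axons are straight axial lines with small
radial jitter; compartment-specific cells (MBONs, DANs) innervate the full
compartment cross-section. For every (presynaptic cell, postsynaptic cell)
pair of configured types the synapse count is an independent Poisson draw with
the configured per-pair mean, which makes all ground-truth wiring statistics
analytic.

Spatial motif structure is planted explicitly: a configurable fraction of
KC>MBON synapses is placed in *convergences* (two sites from distinct KCs
within the clustering radius of each other, sharing the postsynaptic cell), a
configurable fraction of convergences additionally receives a KC>KC contact
inside the cluster (*rosettes*). Planted motifs, per-pathway rates and the
seed are recorded in :class:`GroundTruth`.

The default census and rates emulate the published alpha-lobe reconstruction:
480 surface / 132 outer-core / 259 inner-core / 78 posterior KCs, two
MBON-a3 + two PPL1-a3 DANs in a3, one MBON-a2sc + two MBON-a2p3p + one
MBON-a2sp + two PPL1-a'2a2 DANs in a2, two MBON-a1 + sixteen PAM-a1 DANs in
a1, with per-pair Poisson means derived from the census's connected-cell
counts and synapse totals.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .model import CELL_TYPE_CLASS, Connectome, ConnectomeError

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "PlantedCluster",
    "GenerationError",
    "default_wiring_rate",
    "generate",
    "plant_null_independent_pair",
]


class GenerationError(ConnectomeError):
    """Configured geometry cannot honor the requested spatial constraints."""


def default_wiring_rate() -> dict[tuple[str, str, str], float]:
    """Per-ordered-cell-pair Poisson means emulating the alpha-lobe census.

    Keys are (pre cell type, post cell type, compartment); values are mean
    synapses per (pre cell, post cell) pair, lambda = A*C/B averaged over the
    cells of the post type.
    """
    rate: dict[tuple[str, str, str], float] = {}
    # KC -> MBON, per compartment (from the sampling census A/B x C)
    kc_mbon = {
        ("MBON-a3", "a3"): {"KC-ab-s": 16.10, "KC-ab-c-o": 12.84, "KC-ab-c-i": 11.31, "KC-ab-p": 7.67},
        ("MBON-a2sc", "a2"): {"KC-ab-s": 14.13, "KC-ab-c-o": 13.67, "KC-ab-c-i": 10.14, "KC-ab-p": 0.86},
        ("MBON-a2p3p", "a2"): {"KC-ab-s": 0.42, "KC-ab-c-o": 0.11, "KC-ab-c-i": 0.014, "KC-ab-p": 10.03},
        ("MBON-a2sp", "a2"): {"KC-ab-s": 4.24, "KC-ab-c-o": 3.53, "KC-ab-c-i": 1.29, "KC-ab-p": 8.90},
        ("MBON-a1", "a1"): {"KC-ab-s": 10.80, "KC-ab-c-o": 8.28, "KC-ab-c-i": 7.47, "KC-ab-p": 13.93},
    }
    for (mbon, comp), per_kc in kc_mbon.items():
        for kc_type, lam in per_kc.items():
            rate[(kc_type, mbon, comp)] = lam
    # KC <-> DAN and DAN -> MBON (uniform across KC subtypes)
    for kc_type in ("KC-ab-s", "KC-ab-c-o", "KC-ab-c-i", "KC-ab-p"):
        rate[(kc_type, "PPL1-a3", "a3")] = 2.65
        rate[(kc_type, "PPL1-ap2a2", "a2")] = 0.84
        rate[(kc_type, "PAM-a1", "a1")] = 0.20
        rate[("PPL1-a3", kc_type, "a3")] = 1.57
        rate[("PPL1-ap2a2", kc_type, "a2")] = 0.77
        rate[("PAM-a1", kc_type, "a1")] = 0.13
    rate[("PPL1-a3", "MBON-a3", "a3")] = 226.8
    rate[("PPL1-ap2a2", "MBON-a2sc", "a2")] = 123.0
    rate[("PPL1-ap2a2", "MBON-a2p3p", "a2")] = 9.5
    rate[("PPL1-ap2a2", "MBON-a2sp", "a2")] = 45.5
    rate[("PAM-a1", "MBON-a1", "a1")] = 45.7
    return rate


def _default_kc_census() -> dict[str, int]:
    return {"KC-ab-s": 480, "KC-ab-c-o": 132, "KC-ab-c-i": 259, "KC-ab-p": 78}


def _default_cells() -> dict[str, list[tuple[str, int]]]:
    return {
        "a1": [("MBON-a1", 2), ("PAM-a1", 16)],
        "a2": [("MBON-a2sc", 1), ("MBON-a2p3p", 2), ("MBON-a2sp", 1), ("PPL1-ap2a2", 2)],
        "a3": [("MBON-a3", 2), ("PPL1-a3", 2)],
    }


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic alpha lobe.

    Lengths are in nm; rates are per ordered cell pair; probabilities in [0, 1].
    ``min_site_separation`` (when set) enforces that cluster centers and
    unclustered sites targeting the same postsynaptic cell keep at least that
    mutual distance, which guarantees planted clusters are geometrically
    unambiguous; it is feasible only at low site density.
    """

    n_kc_per_subtype: dict[str, int] = field(default_factory=_default_kc_census)
    cells_per_compartment: dict[str, list[tuple[str, int]]] = field(
        default_factory=_default_cells
    )
    wiring_rate: dict[tuple[str, str, str], float] = field(
        default_factory=default_wiring_rate
    )
    lobe_radius: float = 10_000.0
    compartment_length: float = 20_000.0
    axon_jitter: float = 150.0
    cluster_radius: float = 300.0
    convergence_rate: float = 0.6
    rosette_rate: float = 0.7
    min_site_separation: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_kc_per_subtype.values()):
            raise ValueError("KC counts must be >= 0")
        if any(lam < 0 for lam in self.wiring_rate.values()):
            raise ValueError("wiring rates must be >= 0")
        for p in (self.convergence_rate, self.rosette_rate):
            if not 0 <= p <= 1:
                raise ValueError("rates must be probabilities in [0, 1]")

    @property
    def compartment_intervals(self) -> dict[str, tuple[float, float]]:
        L = self.compartment_length
        return {"a1": (0.0, L), "a2": (L, 2 * L), "a3": (2 * L, 3 * L)}


@dataclass
class PlantedCluster:
    """One planted convergence (optionally rosette) and its member sites."""

    post_neuron: str
    compartment: str
    site_ids: tuple[str, str]
    kc_ids: tuple[str, str]
    is_rosette: bool
    center: tuple[float, float, float]


@dataclass
class GroundTruth:
    """Everything the generator knows that an analysis must recover."""

    seed: int
    config: GeneratorConfig
    pair_counts: pd.DataFrame
    clusters: list[PlantedCluster]
    convergence_fraction: dict[str, float]  # realized, per post cell

    @property
    def rosettes(self) -> list[PlantedCluster]:
        return [c for c in self.clusters if c.is_rosette]


def _instance_labels(n: int) -> list[str]:
    letters = string.ascii_uppercase
    if n <= len(letters):
        return list(letters[:n])
    return [f"{letters[i % 26]}{i // 26}" for i in range(n)]


def _disk_points(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = 2 * np.pi * rng.random(n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _ball_offsets(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * radius * rng.random(n)[:, None] ** (1 / 3)


def _separated(
    rng: np.random.Generator,
    n: int,
    sampler,
    min_sep: float,
    max_tries: int = 200,
) -> np.ndarray:
    """Draw n points from ``sampler`` keeping pairwise distance >= min_sep."""
    accepted = np.empty((0, 3))
    tries = 0
    while len(accepted) < n:
        cand = sampler(1)[0]
        if len(accepted) == 0 or np.min(
            np.linalg.norm(accepted - cand, axis=1)
        ) >= min_sep:
            accepted = np.vstack([accepted, cand])
            tries = 0
        else:
            tries += 1
            if tries > max_tries:
                raise GenerationError(
                    f"geometry too small: could not place {n} sites with "
                    f"min separation {min_sep} nm"
                )
    return accepted


def generate(config: GeneratorConfig | None = None) -> tuple[Connectome, GroundTruth]:
    """Generate a synthetic connectome and its ground truth.

    Identical (config, seed) produce a bit-identical connectome: the RNG is a
    counter-based Philox generator seeded with ``config.seed`` and all
    iteration orders are fixed.
    """
    config = config if config is not None else GeneratorConfig()
    rng = np.random.Generator(np.random.Philox(config.seed))
    intervals = config.compartment_intervals

    # ---- roster ---------------------------------------------------------
    neuron_rows: list[tuple[str, str, str, str]] = []
    kc_ids_by_type: dict[str, list[str]] = {}
    for kc_type in sorted(config.n_kc_per_subtype):
        n = config.n_kc_per_subtype[kc_type]
        ids = [f"{kc_type}-{i:04d}" for i in range(n)]
        kc_ids_by_type[kc_type] = ids
        neuron_rows += [(i, kc_type, CELL_TYPE_CLASS[kc_type], "") for i in ids]
    cells_by_type_comp: dict[tuple[str, str], list[str]] = {}
    seen: set[str] = set()
    for comp in sorted(config.cells_per_compartment):
        for cell_type, n in config.cells_per_compartment[comp]:
            labels = _instance_labels(n)
            ids = [f"{cell_type}-{lab}" for lab in labels]
            cells_by_type_comp[(cell_type, comp)] = ids
            # a cell type listed in several compartments (e.g. APL, DPM) is the
            # same set of spanning cells, not new ones per compartment
            neuron_rows += [
                (i, cell_type, CELL_TYPE_CLASS[cell_type], lab)
                for i, lab in zip(ids, labels)
                if i not in seen
            ]
            seen.update(ids)
    neurons = pd.DataFrame(
        neuron_rows, columns=["neuron_id", "cell_type", "type_class", "instance_label"]
    ).set_index("neuron_id")

    all_kcs = [i for ids in kc_ids_by_type.values() for i in ids]
    kc_xy = dict(zip(all_kcs, _disk_points(rng, len(all_kcs), config.lobe_radius * 0.95)))

    def _cells_of(cell_type: str, comp: str) -> list[str]:
        if cell_type in kc_ids_by_type:
            return kc_ids_by_type[cell_type]
        return cells_by_type_comp.get((cell_type, comp), [])

    # ---- Poisson draws per ordered cell pair ----------------------------
    # Each record: (pre_id, post_id, compartment, is_kc_pre, is_kc_mbon)
    syn_pre: list[str] = []
    syn_post: list[str] = []
    syn_comp: list[str] = []
    syn_kc_mbon: list[bool] = []
    pair_rows = []
    for key in sorted(config.wiring_rate):
        pre_type, post_type, comp = key
        lam = config.wiring_rate[key]
        pre_cells = _cells_of(pre_type, comp)
        post_cells = _cells_of(post_type, comp)
        if not pre_cells or not post_cells or lam == 0:
            continue
        counts = rng.poisson(lam, size=(len(pre_cells), len(post_cells)))
        pair_rows.append(
            {
                "pre_type": pre_type,
                "post_type": post_type,
                "compartment": comp,
                "n_pre": len(pre_cells),
                "n_post": len(post_cells),
                "lam": lam,
                "total_synapses": int(counts.sum()),
            }
        )
        pre_idx, post_idx = np.nonzero(counts)
        reps = counts[pre_idx, post_idx]
        kc_mbon = (
            CELL_TYPE_CLASS[pre_type] == "KC" and CELL_TYPE_CLASS[post_type] == "MBON"
        )
        for pi, qi, r in zip(pre_idx, post_idx, reps):
            syn_pre += [pre_cells[pi]] * int(r)
            syn_post += [post_cells[qi]] * int(r)
            syn_comp += [comp] * int(r)
            syn_kc_mbon += [kc_mbon] * int(r)
    pair_counts = pd.DataFrame(
        pair_rows,
        columns=[
            "pre_type", "post_type", "compartment",
            "n_pre", "n_post", "lam", "total_synapses",
        ],
    )

    n_syn = len(syn_pre)
    syn_pre_arr = np.asarray(syn_pre, dtype=object)
    syn_post_arr = np.asarray(syn_post, dtype=object)
    syn_comp_arr = np.asarray(syn_comp, dtype=object)
    syn_kc_mbon_arr = np.asarray(syn_kc_mbon, dtype=bool)

    # ---- positions and motif planting -----------------------------------
    positions = np.zeros((n_syn, 3))
    cluster_of = np.full(n_syn, -1)  # planted-cluster index per synapse
    clusters: list[PlantedCluster] = []
    conv_fraction: dict[str, float] = {}

    order = np.arange(n_syn)
    group_keys = pd.DataFrame(
        {"post": syn_post_arr, "comp": syn_comp_arr, "i": order}
    )
    member_offset = config.cluster_radius / 3.0
    for (post, comp), grp in group_keys.groupby(["post", "comp"], sort=True):
        idx = grp["i"].to_numpy()
        lo, hi = intervals[comp]
        is_km = syn_kc_mbon_arr[idx]
        km_idx = idx[is_km]
        other_idx = idx[~is_km]

        # pair up a convergence_rate fraction of this cell's KC>MBON synapses
        chosen = km_idx[rng.random(len(km_idx)) < config.convergence_rate]
        rng.shuffle(chosen)
        pairs = []
        leftovers = list(km_idx[~np.isin(km_idx, chosen)])
        for a, b in zip(chosen[0::2], chosen[1::2]):
            if syn_pre_arr[a] != syn_pre_arr[b]:
                pairs.append((a, b))
            else:  # same-KC pair cannot form a two-KC convergence
                leftovers += [a, b]
        if len(chosen) % 2:
            leftovers.append(chosen[-1])
        leftovers = np.asarray(sorted(leftovers), dtype=int)

        def _sample_centers(n, _lo=lo, _hi=hi):
            xy = _disk_points(rng, n, config.lobe_radius)
            z = rng.uniform(_lo, _hi, n)
            return np.column_stack([xy, z])

        n_anchor = len(pairs) + len(leftovers)
        if config.min_site_separation is not None:
            anchors = _separated(
                rng, n_anchor, _sample_centers, config.min_site_separation
            )
        else:
            anchors = _sample_centers(n_anchor)

        # clusters first, then singletons
        for ci, (a, b) in enumerate(pairs):
            center = anchors[ci]
            offsets = _ball_offsets(rng, 2, member_offset)
            positions[a] = center + offsets[0]
            positions[b] = center + offsets[1]
            cluster_of[a] = cluster_of[b] = len(clusters)
            clusters.append(
                PlantedCluster(
                    post_neuron=post,
                    compartment=comp,
                    site_ids=("", ""),  # filled once site ids exist
                    kc_ids=(str(syn_pre_arr[a]), str(syn_pre_arr[b])),
                    is_rosette=False,
                    center=tuple(center),
                )
            )
        single_anchors = anchors[len(pairs):]
        for si, s in enumerate(leftovers):
            base = single_anchors[si]
            if syn_kc_mbon_arr[s] or str(syn_pre_arr[s]).startswith("KC"):
                # KC presynaptic sites sit on the cell's (jittered) axon line
                xy = kc_xy[str(syn_pre_arr[s])] + rng.normal(0, config.axon_jitter, 2)
                if config.min_site_separation is None:
                    base = np.array([xy[0], xy[1], base[2]])
            positions[s] = base
        # other (non KC>MBON) synapses of this post cell: axon or uniform
        for s in other_idx:
            pre = str(syn_pre_arr[s])
            if pre in kc_xy:
                xy = kc_xy[pre] + rng.normal(0, config.axon_jitter, 2)
            else:
                xy = _disk_points(rng, 1, config.lobe_radius)[0]
            positions[s] = [xy[0], xy[1], rng.uniform(lo, hi)]
        if len(km_idx):
            conv_fraction[str(post)] = 2 * len(pairs) / len(km_idx)

    # keep every synapse inside its compartment's axial span, then shift to
    # non-negative coordinates
    for comp, (lo, hi) in intervals.items():
        m = syn_comp_arr == comp
        positions[m, 2] = np.clip(positions[m, 2], lo, hi - 1e-6)
    shift = config.lobe_radius * 1.05
    positions[:, 0] += shift
    positions[:, 1] += shift
    np.maximum(positions, 0.0, out=positions)

    # ---- assemble sites and contacts ------------------------------------
    site_ids = np.array([f"s{i:07d}" for i in range(n_syn)], dtype=object)
    sites = pd.DataFrame(
        {
            "pre_neuron": syn_pre_arr,
            "x": positions[:, 0],
            "y": positions[:, 1],
            "z": positions[:, 2],
            "compartment": syn_comp_arr,
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    contact_site = list(site_ids)
    contact_post = list(syn_post_arr)

    # rosettes: add a KC>KC contact on the first member site of the cluster
    members_by_cluster: dict[int, list[int]] = {}
    for i, c in enumerate(cluster_of):
        if c >= 0:
            members_by_cluster.setdefault(int(c), []).append(i)
    for ci, members in sorted(members_by_cluster.items()):
        a, b = members
        clusters[ci].site_ids = (str(site_ids[a]), str(site_ids[b]))
        if rng.random() < config.rosette_rate:
            contact_site.append(str(site_ids[a]))
            contact_post.append(str(syn_pre_arr[b]))
            clusters[ci].is_rosette = True
    contacts = pd.DataFrame({"site_id": contact_site, "post_neuron": contact_post})

    connectome = Connectome(neurons, sites, contacts)
    truth = GroundTruth(
        seed=config.seed,
        config=config,
        pair_counts=pair_counts,
        clusters=clusters,
        convergence_fraction=conv_fraction,
    )
    return connectome, truth


def plant_null_independent_pair(
    n_kc: int = 949,
    p_a: float = 0.5,
    p_b: float = 0.5,
    seed: int = 0,
    compartment: str = "a2",
) -> tuple[Connectome, dict[str, set[str]]]:
    """Two same-type DANs connecting to KCs independently (the Fisher null).

    Each KC receives a connection from DAN A with probability ``p_a`` and,
    independently, from DAN B with probability ``p_b``. Returns the connectome
    and the ground-truth partner sets ``{"A": ..., "B": ...}``.
    """
    rng = np.random.Generator(np.random.Philox(seed))
    config = GeneratorConfig()
    lo, hi = config.compartment_intervals[compartment]
    kcs = [f"KC-ab-s-{i:04d}" for i in range(n_kc)]
    dan_type = {"a1": "PAM-a1", "a2": "PPL1-ap2a2", "a3": "PPL1-a3"}[compartment]
    dans = [f"{dan_type}-A", f"{dan_type}-B"]
    rows = [(k, "KC-ab-s", "KC", "") for k in kcs] + [
        (d, dan_type, "DAN", lab) for d, lab in zip(dans, "AB")
    ]
    neurons = pd.DataFrame(
        rows, columns=["neuron_id", "cell_type", "type_class", "instance_label"]
    ).set_index("neuron_id")

    hit_a = rng.random(n_kc) < p_a
    hit_b = rng.random(n_kc) < p_b
    site_rows = []
    contact_rows = []
    shift = config.lobe_radius * 1.05
    for dan, hits in zip(dans, [hit_a, hit_b]):
        for i in np.flatnonzero(hits):
            sid = f"{dan}-s{i:05d}"
            xy = _disk_points(rng, 1, config.lobe_radius)[0] + shift
            site_rows.append(
                (sid, dan, xy[0], xy[1], rng.uniform(lo, hi), compartment)
            )
            contact_rows.append((sid, kcs[i]))
    sites = pd.DataFrame(
        site_rows, columns=["site_id", "pre_neuron", "x", "y", "z", "compartment"]
    ).set_index("site_id")
    contacts = pd.DataFrame(contact_rows, columns=["site_id", "post_neuron"])
    conn = Connectome(neurons, sites, contacts)
    truth = {
        "A": {kcs[i] for i in np.flatnonzero(hit_a)},
        "B": {kcs[i] for i in np.flatnonzero(hit_b)},
        "universe": set(kcs),
    }
    return conn, truth
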