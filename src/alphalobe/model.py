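"""Domain model for a synapse-level connectome of the mushroom-body alpha lobe.

The central container is :class:`Connectome`, which holds three tables:

* ``neurons`` — one row per cell (identity, cell type, type class, instance label);
* ``sites`` — one row per presynaptic release site (T-bar), each belonging to
  exactly one presynaptic neuron and carrying an xyz position in nanometres and a
  compartment label;
* ``contacts`` — one row per (presynaptic site, postsynaptic neuron) pairing.

A presynaptic site is *polyadic*: it may contact several postsynaptic partners.
The counting convention throughout the package is that **one synapse is one
contact** — a site with four postsynaptic partners contributes four synapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELL_TYPE_CLASS",
    "COMPARTMENTS",
    "Neuron",
    "PresynapticSite",
    "SynapticContact",
    "Skeleton",
    "Connectome",
    "ConnectomeError",
    "assign_compartment",
]

#: Controlled vocabulary: cell type token -> type class.
CELL_TYPE_CLASS: dict[str, str] = {
    # Kenyon cells (alpha/beta subtypes: surface, core inner/outer, posterior)
    "KC-ab-s": "KC",
    "KC-ab-c-i": "KC",
    "KC-ab-c-o": "KC",
    "KC-ab-p": "KC",
    # Output neurons with dendrites in the alpha lobe
    "MBON-a3": "MBON",
    "MBON-a2sc": "MBON",
    "MBON-a2p3p": "MBON",
    "MBON-a2sp": "MBON",
    "MBON-a1": "MBON",
    # Dopaminergic neurons
    "PPL1-a3": "DAN",
    "PPL1-ap2a2": "DAN",
    "PAM-a1": "DAN",
    # Lobe-wide modulatory cells
    "APL": "modulatory",
    "DPM": "modulatory",
    "SIFamide": "modulatory",
    # Feedforward output neurons projecting in from other lobes
    "MBON-b1-ff": "feedforward",
    "MBON-g1pedc-ff": "feedforward",
}

#: Ordered compartments along the lobe axis; adjacency is a1<->a2 and a2<->a3.
COMPARTMENTS: tuple[str, ...] = ("a1", "a2", "a3")

#: Valid compartment labels for a presynaptic site.
SITE_COMPARTMENTS: tuple[str, ...] = COMPARTMENTS + ("outside",)


class ConnectomeError(ValueError):
    """Raised when a connectome (or one of its input tables) is invalid."""


@dataclass(frozen=True)
class Neuron:
    """A single reconstructed cell."""

    neuron_id: str
    cell_type: str
    instance_label: str = ""

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPE_CLASS:
            raise ConnectomeError(
                f"unknown cell_type {self.cell_type!r} for neuron {self.neuron_id!r}; "
                f"valid tokens: {sorted(CELL_TYPE_CLASS)}"
            )

    @property
    def type_class(self) -> str:
        return CELL_TYPE_CLASS[self.cell_type]


@dataclass(frozen=True)
class PresynapticSite:
    """One polyadic presynaptic release site (T-bar)."""

    site_id: str
    pre_neuron: str
    position: tuple[float, float, float]
    compartment: str = "outside"

    def __post_init__(self) -> None:
        if self.compartment not in SITE_COMPARTMENTS:
            raise ConnectomeError(
                f"site {self.site_id!r}: compartment must be one of "
                f"{SITE_COMPARTMENTS}, got {self.compartment!r}"
            )
        if len(self.position) != 3 or any(c < 0 for c in self.position):
            raise ConnectomeError(
                f"site {self.site_id!r}: position must be 3 non-negative nm coordinates"
            )


@dataclass(frozen=True)
class SynapticContact:
    """One (presynaptic site, postsynaptic neuron) pairing = one counted synapse."""

    site_id: str
    post_neuron: str


class Skeleton:
    """A neuronal arbor as a rooted tree of 3-D nodes (positions in nm).

    Edge length is the Euclidean distance between the two node positions and
    must be strictly positive.
    """

    def __init__(
        self,
        node_ids: Sequence[int],
        positions: np.ndarray,
        parents: Sequence[int],
        root_id: int | None = None,
    ) -> None:
        self.node_ids = np.asarray(node_ids, dtype=np.int64)
        self.positions = np.asarray(positions, dtype=float).reshape(len(node_ids), 3)
        self.parents = np.asarray(parents, dtype=np.int64)  # -1 marks the root
        if len(self.node_ids) != len(set(self.node_ids.tolist())):
            raise ConnectomeError("skeleton node ids are not unique")
        roots = self.node_ids[self.parents == -1]
        if len(roots) != 1:
            raise ConnectomeError(
                f"skeleton must have exactly one root, found {len(roots)}"
            )
        self.root_id = int(roots[0])
        if root_id is not None and int(root_id) != self.root_id:
            raise ConnectomeError(
                f"declared root {root_id} does not match parentless node {self.root_id}"
            )
        self._index = {int(n): i for i, n in enumerate(self.node_ids)}
        for node, parent in zip(self.node_ids, self.parents):
            if parent != -1 and int(parent) not in self._index:
                raise ConnectomeError(
                    f"skeleton node {int(node)} references missing parent {int(parent)}"
                )
        self._check_connected_acyclic()
        if np.any(self.edge_lengths() <= 0):
            raise ConnectomeError("skeleton has a zero-length edge (coincident nodes)")

    def _check_connected_acyclic(self) -> None:
        # A parent-pointer forest with one root and all parents resolving is a
        # connected tree iff following parents from every node terminates at the
        # root without revisiting (no cycles among parent pointers).
        state = {}  # node -> 0 visiting, 1 done
        for start in self.node_ids:
            chain = []
            node = int(start)
            while node != self.root_id and state.get(node) is None:
                state[node] = 0
                chain.append(node)
                node = int(self.parents[self._index[node]])
                if node in chain:
                    raise ConnectomeError("skeleton parent pointers contain a cycle")
            for n in chain:
                state[n] = 1

    def index_of(self, node_id: int) -> int:
        try:
            return self._index[int(node_id)]
        except KeyError:
            raise ConnectomeError(f"node {node_id} not in skeleton") from None

    def n_nodes(self) -> int:
        return len(self.node_ids)

    def edges(self) -> np.ndarray:
        """(n_edges, 2) array of (child_index, parent_index) pairs."""
        child = np.flatnonzero(self.parents != -1)
        parent = np.array([self._index[int(p)] for p in self.parents[child]])
        return np.column_stack([child, parent])

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.positions[e[:, 0]] - self.positions[e[:, 1]], axis=1)

    @property
    def total_cable_length(self) -> float:
        """Total cable length in nm."""
        return float(self.edge_lengths().sum())


def assign_compartment(z: float, intervals: Mapping[str, tuple[float, float]]) -> str:
    """Compartment of an axial coordinate under half-open intervals [lo, hi).

    Falls back to ``"outside"`` when no interval contains ``z``. Used when sites
    carry no explicit compartment annotation.
    """
    for name, (lo, hi) in intervals.items():
        if lo <= z < hi:
            return name
    return "outside"


def _neuron_frame(neurons: Iterable[Neuron]) -> pd.DataFrame:
    rows = [(n.neuron_id, n.cell_type, n.type_class, n.instance_label) for n in neurons]
    df = pd.DataFrame(
        rows, columns=["neuron_id", "cell_type", "type_class", "instance_label"]
    )
    return df.set_index("neuron_id")


def _site_frame(sites: Iterable[PresynapticSite]) -> pd.DataFrame:
    rows = [
        (s.site_id, s.pre_neuron, *s.position, s.compartment) for s in sites
    ]
    df = pd.DataFrame(
        rows, columns=["site_id", "pre_neuron", "x", "y", "z", "compartment"]
    )
    return df.set_index("site_id")


def _contact_frame(contacts: Iterable[SynapticContact]) -> pd.DataFrame:
    rows = [(c.site_id, c.post_neuron) for c in contacts]
    return pd.DataFrame(rows, columns=["site_id", "post_neuron"])


class Connectome:
    """Validated container of neurons, presynaptic sites and synaptic contacts.

    Parameters
    ----------
    neurons
        Indexed by ``neuron_id`` with columns ``cell_type``, ``type_class``,
        ``instance_label``.
    sites
        Indexed by ``site_id`` with columns ``pre_neuron``, ``x``, ``y``, ``z``
        (nm) and ``compartment``.
    contacts
        Columns ``site_id`` and ``post_neuron``; one row per synapse.
    skeletons
        Optional mapping ``neuron_id -> Skeleton``.
    """

    compartment_order = COMPARTMENTS

    def __init__(
        self,
        neurons: pd.DataFrame,
        sites: pd.DataFrame,
        contacts: pd.DataFrame,
        skeletons: Mapping[str, Skeleton] | None = None,
        validate: bool = True,
    ) -> None:
        self.neurons = neurons
        self.sites = sites
        self.contacts = contacts.reset_index(drop=True)
        self.skeletons: dict[str, Skeleton] = dict(skeletons or {})
        self._contact_table: pd.DataFrame | None = None
        if validate:
            self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_records(
        cls,
        neurons: Iterable[Neuron],
        sites: Iterable[PresynapticSite] = (),
        contacts: Iterable[SynapticContact] = (),
        skeletons: Mapping[str, Skeleton] | None = None,
    ) -> "Connectome":
        return cls(
            _neuron_frame(neurons),
            _site_frame(sites),
            _contact_frame(contacts),
            skeletons=skeletons,
        )

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        if self.neurons.index.duplicated().any():
            dup = self.neurons.index[self.neurons.index.duplicated()][0]
            raise ConnectomeError(f"duplicate neuron_id {dup!r}")
        bad_type = ~self.neurons["cell_type"].isin(CELL_TYPE_CLASS)
        if bad_type.any():
            tok = self.neurons.loc[bad_type, "cell_type"].iloc[0]
            raise ConnectomeError(
                f"unknown cell_type token {tok!r}; valid tokens: "
                f"{sorted(CELL_TYPE_CLASS)}"
            )
        expected = self.neurons["cell_type"].map(CELL_TYPE_CLASS)
        if (self.neurons["type_class"] != expected).any():
            raise ConnectomeError("type_class inconsistent with cell_type vocabulary")

        if self.sites.index.duplicated().any():
            dup = self.sites.index[self.sites.index.duplicated()][0]
            raise ConnectomeError(f"duplicate site_id {dup!r}")
        coords = self.sites[["x", "y", "z"]]
        if coords.isna().any().any() or (coords < 0).any().any():
            bad = self.sites.index[coords.isna().any(axis=1) | (coords < 0).any(axis=1)]
            raise ConnectomeError(f"malformed coordinates for site(s) {list(bad[:5])}")
        bad_comp = ~self.sites["compartment"].isin(SITE_COMPARTMENTS)
        if bad_comp.any():
            raise ConnectomeError(
                f"invalid compartment label(s) "
                f"{sorted(self.sites.loc[bad_comp, 'compartment'].unique())}"
            )
        missing_pre = ~self.sites["pre_neuron"].isin(self.neurons.index)
        if missing_pre.any():
            sid = self.sites.index[missing_pre][0]
            raise ConnectomeError(
                f"site {sid!r} references unknown presynaptic neuron "
                f"{self.sites.loc[sid, 'pre_neuron']!r}"
            )

        missing_site = ~self.contacts["site_id"].isin(self.sites.index)
        if missing_site.any():
            row = int(np.flatnonzero(missing_site.to_numpy())[0])
            raise ConnectomeError(
                f"contact row {row} references unknown site_id "
                f"{self.contacts.loc[row, 'site_id']!r}"
            )
        missing_post = ~self.contacts["post_neuron"].isin(self.neurons.index)
        if missing_post.any():
            row = int(np.flatnonzero(missing_post.to_numpy())[0])
            raise ConnectomeError(
                f"contact row {row} references unknown postsynaptic neuron "
                f"{self.contacts.loc[row, 'post_neuron']!r}"
            )
        if self.contacts.duplicated(subset=["site_id", "post_neuron"]).any():
            row = int(
                np.flatnonzero(
                    self.contacts.duplicated(subset=["site_id", "post_neuron"]).to_numpy()
                )[0]
            )
            raise ConnectomeError(
                f"duplicate (site_id, post_neuron) contact at row {row}: "
                f"{tuple(self.contacts.loc[row, ['site_id', 'post_neuron']])}"
            )
        for nid in self.skeletons:
            if nid not in self.neurons.index:
                raise ConnectomeError(f"skeleton attached to unknown neuron {nid!r}")

    # -- basic quantities ---------------------------------------------------

    @property
    def n_synapses(self) -> int:
        """Total synapse count = number of contacts (not sites)."""
        return len(self.contacts)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def contact_table(self) -> pd.DataFrame:
        """Contacts joined with site geometry and pre/post annotations.

        Columns: site_id, post_neuron, pre_neuron, x, y, z, compartment,
        pre_type, pre_class, post_type, post_class. Cached; one row per synapse.
        """
        if self._contact_table is None:
            t = self.contacts.join(self.sites, on="site_id")
            t["pre_type"] = t["pre_neuron"].map(self.neurons["cell_type"])
            t["pre_class"] = t["pre_neuron"].map(self.neurons["type_class"])
            t["post_type"] = t["post_neuron"].map(self.neurons["cell_type"])
            t["post_class"] = t["post_neuron"].map(self.neurons["type_class"])
            self._contact_table = t
        return self._contact_table

    # -- selection ----------------------------------------------------------

    def select_neurons(self, selector) -> pd.Index:
        """Resolve a selector to neuron ids.

        A selector may be a neuron id, a cell-type token, a type class
        (``"KC"``, ``"MBON"``, ``"DAN"``, ``"modulatory"``, ``"feedforward"``),
        or an iterable of any of these.
        """
        if isinstance(selector, str):
            if selector in self.neurons.index:
                return pd.Index([selector])
            if selector in set(CELL_TYPE_CLASS.values()):
                return self.neurons.index[self.neurons["type_class"] == selector]
            if selector in CELL_TYPE_CLASS:
                return self.neurons.index[self.neurons["cell_type"] == selector]
            raise ConnectomeError(f"selector {selector!r} matches no neuron/type/class")
        out: list[str] = []
        for item in selector:
            out.extend(self.select_neurons(item))
        return pd.Index(pd.unique(np.asarray(out, dtype=object)))

    def adjacent_compartments(self, compartment: str) -> tuple[str, ...]:
        """Serial adjacency along the lobe axis: a1<->a2 and a2<->a3 only."""
        order = list(self.compartment_order)
        i = order.index(compartment)
        out = []
        if i > 0:
            out.append(order[i - 1])
        if i < len(order) - 1:
            out.append(order[i + 1])
        return tuple(out)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Connectome(neurons={self.n_neurons}, sites={self.n_sites}, "
            f"synapses={self.n_synapses}, skeletons={len(self.skeletons)})"
        )
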