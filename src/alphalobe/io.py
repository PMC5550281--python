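"""Readers and writers for synapse tables, cell annotations, skeletons and edges.

File dialect: tab- or comma-delimited text with a header row, UTF-8. The three
tables of a connectome are

* sites:        ``site_id, pre_neuron, x, y, z[, compartment]``
* contacts:     ``site_id, post_neuron``
* annotations:  ``neuron_id, cell_type[, instance_label]``

Coordinates are nanometres. Skeletons are standard 7-column SWC with parent -1
marking the root; SWC coordinates are interpreted as nm unless ``scale`` says
otherwise.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import (
    CELL_TYPE_CLASS,
    Connectome,
    ConnectomeError,
    SITE_COMPARTMENTS,
    Skeleton,
    assign_compartment,
)

__all__ = [
    "read_synapse_table",
    "write_connectome",
    "read_skeleton",
    "write_skeleton",
    "export_edges",
    "export_graphml",
]

log = logging.getLogger("alphalobe")


def _read_delimited(path) -> pd.DataFrame:
    """Read a CSV/TSV with header, sniffing the delimiter."""
    return pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")


def read_synapse_table(
    site_file,
    contact_file,
    annotation_file,
    compartment_intervals: Mapping[str, tuple[float, float]] | None = None,
) -> Connectome:
    """Read and validate a connectome from three delimited tables.

    When the site table lacks a ``compartment`` column, labels are derived from
    ``compartment_intervals`` — half-open axial intervals ``{name: (z_lo, z_hi)}``
    applied to the z coordinate — else every site is labelled ``"outside"``.
    """
    ann = _read_delimited(annotation_file)
    _require(ann, ["neuron_id", "cell_type"], annotation_file)
    bad = ~ann["cell_type"].isin(CELL_TYPE_CLASS)
    if bad.any():
        raise ConnectomeError(
            f"{annotation_file}: unknown cell_type {ann.loc[bad, 'cell_type'].iloc[0]!r}"
            f"; valid tokens: {sorted(CELL_TYPE_CLASS)}"
        )
    neurons = pd.DataFrame(
        {
            "cell_type": ann["cell_type"].to_numpy(),
            "type_class": ann["cell_type"].map(CELL_TYPE_CLASS).to_numpy(),
            "instance_label": ann.get(
                "instance_label", pd.Series([""] * len(ann))
            ).fillna("").to_numpy(),
        },
        index=pd.Index(ann["neuron_id"], name="neuron_id"),
    )

    raw_sites = _read_delimited(site_file)
    _require(raw_sites, ["site_id", "pre_neuron", "x", "y", "z"], site_file)
    coords = {}
    for axis in ("x", "y", "z"):
        converted = pd.to_numeric(raw_sites[axis], errors="coerce")
        if converted.isna().any():
            row = int(converted.index[converted.isna()][0])
            raise ConnectomeError(
                f"{site_file}: malformed {axis} coordinate in data row {row} "
                f"(value {raw_sites.loc[row, axis]!r})"
            )
        coords[axis] = converted.to_numpy(dtype=float)
    if "compartment" in raw_sites.columns:
        compartment = raw_sites["compartment"].to_numpy()
    elif compartment_intervals is not None:
        compartment = np.array(
            [assign_compartment(z, compartment_intervals) for z in coords["z"]]
        )
    else:
        compartment = np.full(len(raw_sites), "outside", dtype=object)
    sites = pd.DataFrame(
        {
            "pre_neuron": raw_sites["pre_neuron"].to_numpy(),
            "x": coords["x"],
            "y": coords["y"],
            "z": coords["z"],
            "compartment": compartment,
        },
        index=pd.Index(raw_sites["site_id"], name="site_id"),
    )

    raw_contacts = _read_delimited(contact_file)
    if len(raw_contacts) == 0:
        contacts = pd.DataFrame(columns=["site_id", "post_neuron"])
    else:
        _require(raw_contacts, ["site_id", "post_neuron"], contact_file)
        contacts = raw_contacts[["site_id", "post_neuron"]].copy()

    conn = Connectome(neurons, sites, contacts)
    per_type = conn.neurons["cell_type"].value_counts().to_dict()
    log.info(
        "read connectome: %d sites, %d contacts, %d neurons (%s)",
        conn.n_sites,
        conn.n_synapses,
        conn.n_neurons,
        ", ".join(f"{t}={n}" for t, n in sorted(per_type.items())),
    )
    return conn


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ConnectomeError(f"{path}: missing required column(s) {missing}")


def write_connectome(connectome: Connectome, outdir, sep: str = ",") -> dict[str, Path]:
    """Write the three tables (sites/contacts/annotations) under ``outdir``.

    Output of :func:`write_connectome` round-trips through
    :func:`read_synapse_table` to an identical connectome.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": outdir / "sites.csv",
        "contacts": outdir / "contacts.csv",
        "annotations": outdir / "annotations.csv",
    }
    connectome.sites.reset_index().to_csv(paths["sites"], sep=sep, index=False)
    connectome.contacts.to_csv(paths["contacts"], sep=sep, index=False)
    ann = connectome.neurons.reset_index()[["neuron_id", "cell_type", "instance_label"]]
    ann.to_csv(paths["annotations"], sep=sep, index=False)
    return paths


def read_skeleton(swc_file, scale: float = 1.0) -> Skeleton:
    """Read a standard SWC file into a validated :class:`Skeleton`.

    SWC rows are ``id type x y z radius parent`` with parent -1 for the root.
    Coordinates are multiplied by ``scale`` (use e.g. 1000 for SWC in microns
    when nm are wanted).
    """
    node_ids, xyz, parents = [], [], []
    with open(swc_file) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 7:
                raise ConnectomeError(
                    f"{swc_file}:{lineno}: expected 7 SWC columns, got {len(fields)}"
                )
            node_ids.append(int(fields[0]))
            xyz.append([float(fields[2]), float(fields[3]), float(fields[4])])
            parents.append(int(fields[6]))
    if not node_ids:
        raise ConnectomeError(f"{swc_file}: no SWC nodes")
    return Skeleton(node_ids, np.asarray(xyz) * scale, parents)


def write_skeleton(skeleton: Skeleton, swc_file, scale: float = 1.0) -> None:
    with open(swc_file, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid, pos, parent in zip(
            skeleton.node_ids, skeleton.positions * scale, skeleton.parents
        ):
            fh.write(
                f"{int(nid)} 0 {pos[0]:.3f} {pos[1]:.3f} {pos[2]:.3f} 1.0 {int(parent)}\n"
            )


def export_edges(
    connectome: Connectome, group_by: str = "neuron", path=None
) -> pd.DataFrame:
    """Aggregate contacts into an edge list (pre, post, compartment, n_synapses).

    ``group_by`` is ``"neuron"`` (per-cell edges) or ``"cell_type"`` (type-level
    edges). The sum of ``n_synapses`` always equals the total contact count.
    If ``path`` is given the table is also written as delimited text.
    """
    t = connectome.contact_table()
    if group_by == "neuron":
        keys = ["pre_neuron", "post_neuron", "compartment"]
    elif group_by == "cell_type":
        keys = ["pre_type", "post_type", "compartment"]
    else:
        raise ValueError("group_by must be 'neuron' or 'cell_type'")
    edges = (
        t.groupby(keys, observed=True)
        .size()
        .rename("n_synapses")
        .reset_index()
        .rename(columns={keys[0]: "pre", keys[1]: "post"})
        .sort_values(["pre", "post", "compartment"], kind="mergesort")
        .reset_index(drop=True)
    )
    if path is not None:
        edges.to_csv(path, index=False)
    return edges


def export_graphml(connectome: Connectome, path) -> None:
    """Write the cell-type graph (edges weighted by synapse count) as GraphML."""
    import networkx as nx

    edges = export_edges(connectome, group_by="cell_type")
    g = nx.MultiDiGraph()
    for cell_type in sorted(connectome.neurons["cell_type"].unique()):
        g.add_node(cell_type, type_class=CELL_TYPE_CLASS[cell_type])
    for row in edges.itertuples(index=False):
        g.add_edge(
            row.pre, row.post, compartment=row.compartment, n_synapses=int(row.n_synapses)
        )
    nx.write_graphml(g, path)
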