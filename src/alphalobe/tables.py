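"""Aggregation of a connectome into wiring tables and derived statistics.

These are the type-level and cell-level summaries a connectomics analysis
reports: per-cell synapse-count vectors, connected-cell counts and per-cell
means, subtype breakdowns of each target's input, sampling profiles (how a
postsynaptic cell samples the available KCs of each subtype), and the full
cell-type connectivity matrix stratified by compartment.

Means are reported over *connected* cells (cells with at least one synapse);
zero-inclusive vectors are available from :func:`per_cell_counts` for the
distribution fits, which require the zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .model import Connectome, ConnectomeError

__all__ = [
    "WiringSummary",
    "SamplingProfile",
    "per_cell_counts",
    "wiring_summary",
    "sampling_profile",
    "type_matrix",
    "class_ratio",
]

KC_SUBTYPES = ("KC-ab-s", "KC-ab-c-o", "KC-ab-c-i", "KC-ab-p")


@dataclass
class WiringSummary:
    """Aggregate of one (pre selection, post selection, compartment) block."""

    pre_selector: object
    post_selector: object
    compartment: str | None
    n_pre_connected: int
    n_post_connected: int
    total_synapses: int
    mean_per_connected_pre: float
    subtype_breakdown: dict[str, tuple[int, float]]

    def __post_init__(self) -> None:
        if self.n_pre_connected:
            assert np.isclose(
                self.mean_per_connected_pre * self.n_pre_connected,
                self.total_synapses,
            )


@dataclass
class SamplingProfile:
    """Per-subtype "A/B x C" sampling of the KC population by one post cell.

    For each KC subtype: A = number of connected KCs, B = number available,
    C = mean synapses among connected KCs.
    """

    post_cell: str
    entries: dict[str, tuple[int, int, float]]

    def recombined_total(self) -> float:
        """Sum of A*C over subtypes; equals the cell's total KC input."""
        return float(sum(a * c for a, _, c in self.entries.values()))


def per_cell_counts(
    connectome: Connectome,
    pre_selector,
    post_cell: str,
    compartment: str | None = None,
) -> pd.Series:
    """Synapse counts from each selected presynaptic cell onto ``post_cell``.

    The result is indexed by presynaptic neuron id and includes explicit zeros
    for selected cells with no contacts, as required for distribution fits.
    """
    pre_cells = connectome.select_neurons(pre_selector)
    if len(pre_cells) == 0:
        raise ConnectomeError(f"empty presynaptic selection {pre_selector!r}")
    post_cells = connectome.select_neurons(post_cell)
    if len(post_cells) == 0:
        raise ConnectomeError(f"empty postsynaptic selection {post_cell!r}")
    t = connectome.contact_table()
    mask = t["pre_neuron"].isin(pre_cells) & t["post_neuron"].isin(post_cells)
    if compartment is not None:
        mask &= t["compartment"] == compartment
    counts = t.loc[mask].groupby("pre_neuron").size()
    return counts.reindex(pre_cells, fill_value=0).rename("n_synapses")


def wiring_summary(
    connectome: Connectome,
    pre_selector,
    post_selector,
    compartment: str | None = None,
) -> WiringSummary:
    """Connected-cell counts, synapse totals, per-cell means and subtype split."""
    pre_cells = connectome.select_neurons(pre_selector)
    post_cells = connectome.select_neurons(post_selector)
    if len(pre_cells) == 0 or len(post_cells) == 0:
        raise ConnectomeError("empty selection")
    t = connectome.contact_table()
    mask = t["pre_neuron"].isin(pre_cells) & t["post_neuron"].isin(post_cells)
    if compartment is not None:
        mask &= t["compartment"] == compartment
    sub = t.loc[mask]
    total = len(sub)
    n_pre = sub["pre_neuron"].nunique()
    n_post = sub["post_neuron"].nunique()
    breakdown: dict[str, tuple[int, float]] = {}
    by_subtype = sub.groupby("pre_type").size()
    for subtype, count in by_subtype.items():
        breakdown[str(subtype)] = (int(count), 100.0 * count / total if total else 0.0)
    return WiringSummary(
        pre_selector=pre_selector,
        post_selector=post_selector,
        compartment=compartment,
        n_pre_connected=int(n_pre),
        n_post_connected=int(n_post),
        total_synapses=int(total),
        mean_per_connected_pre=total / n_pre if n_pre else float("nan"),
        subtype_breakdown=breakdown,
    )


def sampling_profile(connectome: Connectome, post_cell: str) -> SamplingProfile:
    """How ``post_cell`` samples the KCs of each subtype (A/B x C entries)."""
    if post_cell not in connectome.neurons.index:
        raise ConnectomeError(f"unknown post cell {post_cell!r}")
    entries: dict[str, tuple[int, int, float]] = {}
    for subtype in KC_SUBTYPES:
        available = connectome.select_neurons(subtype)
        if len(available) == 0:
            continue
        counts = per_cell_counts(connectome, subtype, post_cell)
        connected = counts[counts > 0]
        a, b = len(connected), len(available)
        c = float(connected.mean()) if a else 0.0
        entries[subtype] = (a, b, c)
    return SamplingProfile(post_cell=post_cell, entries=entries)


def type_matrix(
    connectome: Connectome, by_compartment: bool = True
) -> pd.DataFrame:
    """Cell-type connectivity matrix: synapse counts pre type x post type.

    With ``by_compartment=True`` the rows carry a (compartment, pre_type)
    MultiIndex. The grand total equals the connectome's contact count.
    """
    t = connectome.contact_table()
    if by_compartment:
        mat = (
            t.groupby(["compartment", "pre_type", "post_type"], observed=True)
            .size()
            .unstack("post_type", fill_value=0)
        )
    else:
        mat = (
            t.groupby(["pre_type", "post_type"], observed=True)
            .size()
            .unstack("post_type", fill_value=0)
        )
    return mat.sort_index()


def class_ratio(
    connectome: Connectome,
    numerator: tuple[str, str],
    denominator: tuple[str, str],
    compartment: str | None = None,
) -> float:
    """Ratio of synapse counts between two (pre class, post class) pathways.

    E.g. ``class_ratio(conn, ("KC", "DAN"), ("DAN", "KC"))`` is the whole-lobe
    KC>DAN / DAN>KC ratio.
    """
    t = connectome.contact_table()
    if compartment is not None:
        t = t[t["compartment"] == compartment]

    def _count(pair: tuple[str, str]) -> int:
        pre, post = pair
        return int(((t["pre_class"] == pre) & (t["post_class"] == post)).sum())

    denom = _count(denominator)
    if denom == 0:
        raise ZeroDivisionError(f"no synapses on pathway {denominator}")
    return _count(numerator) / denom
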