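"""Reference wiring tables of the densely reconstructed alpha-lobe connectome.

These small tables, shipped as package data, transcribe the published
cell-level wiring census of the adult Drosophila mushroom-body alpha lobe:

* :func:`kc_mbon_inputs` — per-MBON KC input (connected KCs, synapse totals,
  surface/core vs posterior split);
* :func:`kc_sampling` — per-(MBON, KC subtype) sampling entries "A/B x C"
  (A connected out of B available, mean C among connected);
* :func:`dan_kc_outputs` / :func:`kc_dan_inputs` — per-DAN synapse totals with
  the KC population, per compartment;
* :func:`dan_mbon` — direct DAN to MBON synapse counts.

The derivation helpers below recompute the census's headline ratios from the
raw counts; they are used both as worked examples and as cross-table
consistency checks. Note that a few of the table's *printed* percentages are
not exactly count/denominator (the ``printed_percent`` column is retained for
comparison); all derived values here are computed from the counts.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "kc_mbon_inputs",
    "kc_sampling",
    "dan_kc_outputs",
    "kc_dan_inputs",
    "dan_mbon",
    "mean_per_connected_kc",
    "dan_input_percent",
    "whole_lobe_dan_mbon_percent",
    "kc_dan_to_dan_kc_ratio",
    "recombined_kc_input",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("alphalobe.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def kc_mbon_inputs() -> pd.DataFrame:
    return _load("kc_mbon_inputs.csv")


def kc_sampling() -> pd.DataFrame:
    return _load("kc_sampling.csv")


def dan_kc_outputs() -> pd.DataFrame:
    return _load("dan_kc_outputs.csv")


def kc_dan_inputs() -> pd.DataFrame:
    return _load("kc_dan_inputs.csv")


def dan_mbon() -> pd.DataFrame:
    return _load("dan_mbon.csv")


def mean_per_connected_kc(mbon: str) -> float:
    """Mean KC>MBON synapses per connected KC: total / connected-cell count."""
    t = kc_mbon_inputs().set_index("mbon")
    row = t.loc[mbon]
    return float(row["total_synapses"] / row["n_connected_kc"])


def dan_input_percent(mbon: str) -> float:
    """Direct DAN>MBON input as a percent of the cell's KC>MBON input."""
    dan = dan_mbon().set_index("mbon")["total_synapses"]
    kc = kc_mbon_inputs().set_index("mbon")["total_synapses"]
    return float(100.0 * dan[mbon] / kc[mbon])


def whole_lobe_dan_mbon_percent() -> float:
    """Whole-lobe DAN>MBON synapse count as a percent of KC>MBON synapses."""
    return float(
        100.0
        * dan_mbon()["total_synapses"].sum()
        / kc_mbon_inputs()["total_synapses"].sum()
    )


def kc_dan_to_dan_kc_ratio(compartment: str | None = None) -> float:
    """Ratio of KC>DAN to DAN>KC synapse counts (whole lobe or one compartment)."""
    fwd = kc_dan_inputs()
    rev = dan_kc_outputs()
    if compartment is not None:
        fwd = fwd[fwd["compartment"] == compartment]
        rev = rev[rev["compartment"] == compartment]
    return float(fwd["total_synapses"].sum() / rev["total_synapses"].sum())


def recombined_kc_input(mbon: str) -> float:
    """Sum of A*C over KC subtypes — should match the census total within rounding."""
    t = kc_sampling()
    t = t[t["mbon"] == mbon]
    return float((t["n_connected"] * t["mean_among_connected"]).sum())
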