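"""Wiring tables: per-cell counts, summaries, sampling profiles, type matrix.

Reproduces the census-style derivations on the transcribed reference tables
(the published alpha-lobe wiring counts shipped as package data) and on a
synthetic connectome.
"""

from alphalobe import GeneratorConfig, generate, sampling_profile, wiring_summary
from alphalobe import reference

# --- derivations from the published census (transcribed fixtures) ---------
mean = reference.mean_per_connected_kc("MBON-a2sc")
print(f"KC>MBON synapses per connected KC, MBON-a2sc: {mean:.2f}")
print(f"DAN input to MBON-a3-A as % of its KC input:  {reference.dan_input_percent('MBON-a3-A'):.2f}%")
print(f"whole-lobe DAN>MBON / KC>MBON:                {reference.whole_lobe_dan_mbon_percent():.1f}%")
print(f"whole-lobe KC>DAN / DAN>KC ratio:             {reference.kc_dan_to_dan_kc_ratio():.1f}")

# --- the same operations on a synthetic lobe ------------------------------
config = GeneratorConfig(
    n_kc_per_subtype={"KC-ab-s": 60, "KC-ab-c-o": 17, "KC-ab-c-i": 33, "KC-ab-p": 10},
    seed=1,
)
connectome, _ = generate(config)
ws = wiring_summary(connectome, "KC", "MBON-a3-A")
print(
    f"\nsynthetic MBON-a3-A: {ws.n_pre_connected} connected KCs, "
    f"{ws.total_synapses} synapses, {ws.mean_per_connected_pre:.2f} per connected KC"
)
prof = sampling_profile(connectome, "MBON-a3-A")
for subtype, (a, b, c) in prof.entries.items():
    print(f"  {subtype}: {a}/{b} x {c:.2f}")
print(
    "Each entry is A/B x C: A connected KCs out of B available, making C "
    "synapses on average; sum(A*C) recombines to the cell's total KC input."
)
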