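"""Generate a synthetic alpha-lobe connectome and inspect its census.

Builds a 1/8-scale lobe with the default per-pair Poisson wiring rates,
then prints the cell census and synapse totals. The ground truth records
every planted convergence and rosette for later recovery checks.
"""

from alphalobe import GeneratorConfig, generate

config = GeneratorConfig(
    n_kc_per_subtype={"KC-ab-s": 60, "KC-ab-c-o": 17, "KC-ab-c-i": 33, "KC-ab-p": 10},
    seed=1,
)
connectome, truth = generate(config)

print(connectome)
print("\ncells per type:")
print(connectome.neurons["cell_type"].value_counts().to_string())
print(f"\nplanted convergences: {len(truth.clusters)}")
print(f"planted rosettes:     {len(truth.rosettes)}")
print(
    "\nEach synapse is one (presynaptic site, postsynaptic neuron) contact; "
    "polyadic sites contribute several synapses, so synapses > sites."
)
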