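# Methods

This note records the models, conventions and numerical choices behind
`alphalobe`, and what the synthetic-data tests do and do not establish about
real reconstructions.

## Data model and counting conventions

A connectome is three tables: neurons (id, cell type, type class, instance
label), presynaptic sites (id, presynaptic neuron, xyz in nm, compartment),
and contacts (site id, postsynaptic neuron). Sites are polyadic; **one
synapse = one (site, partner) contact**, so a site with four partners
contributes four synapses. This convention is what makes type-level synapse
totals exceed presynaptic-site totals, and it is applied uniformly: every
aggregate in `tables` and every motif denominator is defined in terms of
either contacts or sites, never a mixture.

Coordinates are nm, non-negative, axis-aligned; the lobe axis is z.
Compartments (`a1`, `a2`, `a3`) are serially adjacent along the axis
(`a1↔a2`, `a2↔a3` only). Compartment membership comes from an explicit
per-site label when present, else from configured half-open axial intervals
`[z_lo, z_hi)`; it is an annotation, not geometry, because the tissue shows
no boundary structure between compartments.

Multiple contacts between the same neuron pair at different sites are
distinct synapses and never merged. Means in wiring summaries are over
*connected* cells; zero-inclusive per-cell vectors (required by the
distribution fits) come from `per_cell_counts`.

## Poisson wiring null model

With `M` candidate cells receiving `N` synapses in total, independent
uniform assignment gives per-cell counts ~ Poisson(λ = N/M) and expected
bin contents `c_k = M · λ^k e^(−λ) / k!`, with Var = c_k (SD reported as
√c_k). The untruncated `Σ_k c_k = M` is asserted as an invariant.

Goodness of fit: χ² = Σ (o−e)²/e over all bins with expected ≥ 0.5
(`min_expected`, configurable). The **default degrees of freedom equal the
number of retained bins** — the convention under which the package's worked
example gives χ² = 5.3 with 7 df for 7 bins. This convention is
conservative: it ignores that the bin total is fixed (−1) and that λ is
estimated from the same data (−1 more). `chi2_gof(..., df_adjust=1)` matches
a fixed-total multinomial null (validated against 10⁵-replicate multinomial
resampling on a large-count toy, where the asymptotic tail is accurate
below the Monte-Carlo resolution), and `df_adjust=2` is the calibrated
choice for fitted wiring data: under truly-Poisson synthetic wiring it
yields an empirical type-I error of ≈0.05 at the p ≤ 0.05 threshold,
whereas the default convention rejects at ≈0.03. Fit classes: green
(p > 0.05), magenta (p < 0.003, more than three sigma), yellow between.

A note on the displayed closed form: only the leading factor `M` (cells, not
synapses) reproduces the worked expectations 21.8 / 21.1 / 13.6 for M = 78,
N = 151 and the χ² above; the implementation therefore uses `M · pmf(k; λ)`
throughout. The k = 0 expectation for that population is 11.26 (= 78·e^−λ);
a sometimes-quoted 11.1 is inconsistent with the k = 1 value from the same
formula and is treated as a transcription error, so k = 0 is not used as a
reference point.

## Shared-partner independence, correlation, KS

`fisher_shared_partners` builds the 2×2 both/only-A/only-B/neither table
over an explicit candidate universe and attaches a two-sided Fisher exact
p-value (summing tables with probability ≤ the observed; sidedness is a
package convention since either side is of interest). Pearson correlation of
paired per-cell count vectors raises `ZeroVarianceError` on constant input
rather than returning NaN. The two-sample KS test uses the asymptotic tail.

## Rosette repeat permutation test

The statistic is the number of unordered KC pairs that co-occur in ≥2
rosettes. The null preserves rosette sizes and redraws each rosette's
members without replacement from the KC universe. The default p-value is the
standard `(1 + #{perm ≥ obs}) / (n_perm + 1)` — valid but conservative,
because the statistic is integer-valued and ties with the observed value are
common. For calibration studies `tie_break="random"` randomizes over tied
permutations (the randomized permutation p-value), which is exactly uniform
under the null; the package's own uniformity check uses it, since a strict
KS-against-uniform comparison is only meaningful for a continuous p.

## Spatial motifs

Convergence clusters are **single-linkage** connected components at the
300 nm threshold over the KC presynaptic sites sharing a postsynaptic
*neuron* (the weakest rule consistent with "pairs within 300 nm"; target
identity is resolved at the neuron level, the testable choice). Distances
are Euclidean, site-to-site, with ties at the threshold counting as within
(closed ball). A cluster needs ≥2 distinct KCs; same-KC site groupings are
not convergences. Rosette status requires a KC>KC contact whose presynaptic
site lies within the radius of the cluster and whose endpoints are both
member KCs; triangles are the induced (KC, KC, MBON) triples. A KD-tree /
radius-graph accelerates detection, and tests require exact agreement with
O(n²) all-pairs and exhaustive-enumeration oracles.

Coverage curves report, per radius over a default 0–5000 nm grid in 100 nm
steps (covering the 2–2.5 µm range relevant to dopamine diffusion), the
fraction of KC>MBON synapses with ≥1 DAN presynaptic site of the same
(respectively an adjacent) compartment within the radius. Coverage is purely
geometric — no diffusion PDE is implied.

## Dendritic input profiles

Skeletons are rooted trees with strictly positive Euclidean edge lengths;
the root — where the dendrites become a single axonal fiber — is an explicit
user input. Contacts snap to the nearest skeleton node with a default
tolerance of 500 nm (contacts sit on the membrane, the skeleton at the
centerline); farther contacts are excluded and counted. Distances are
geodesic along the arbor (µm); a Euclidean-from-root metric is available
behind a flag. Histograms use log₁₀-spaced bins from 0.1 µm to the maximum
distance, with the first bin extended to zero so root contacts are counted.

## Synthetic generator

The generator is the package's study-condition definition, not a fixture:
its defaults are the α-lobe census (KC subtypes 480 s / 132 c(o) / 259 c(i)
/ 78 p; a3: 2 MBON-a3 + 2 PPL1-a3; a2: 1 MBON-a2sc + 2 MBON-a2p3p +
1 MBON-a2sp + 2 PPL1-α′2α2; a1: 2 MBON-a1 + 16 PAM-a1) with per-ordered-pair
Poisson rates λ = A·C/B derived from the census's connected-cell counts and
means (e.g. λ ≈ 16 for surface-KC→MBON-a3 pairs, ≈0.2 for KC→PAM pairs).
Draws are per ordered cell pair — this makes ground truth analytic (the
per-pathway total is Poisson with known mean) at the cost of not modeling
any pre-cell synapse budget.

Geometry is a modeling choice the census does not constrain: a cylinder of
radius 10 µm with three 20 µm compartments; KC axons are straight axial
lines with 150 nm radial jitter; DAN and MBON innervation spans the full
compartment cross-section; synapse z positions are uniform within the
compartment. Real lobes are neither cylindrical nor uniform, so absolute
coverage numbers from the defaults are illustrative (at a 2.5 µm diffusion
range the default lobe gives ≈99% same-compartment and ≈9% adjacent
coverage; the real compartments, being longer, leak less).

Motif planting: a configurable fraction (default 0.6) of each target's
KC>MBON synapses is placed in two-site clusters of distinct KCs within the
300 nm radius; a configurable fraction of clusters (default 0.7) receives a
KC>KC contact on a member site, making it a rosette and a triangle. The
optional `min_site_separation` (used by the recovery tests at 3× the
clustering radius) enforces separation between cluster centers and singleton
sites *within each (post cell, compartment) group* — detection conditions on
a shared target, so only same-target pairs can merge spuriously; a global
separation constraint would be geometrically impossible at realistic
density, which is also why recovery on dense default-scale output is
reported rather than asserted. KC>KC background wiring beyond rosette
planting is available via explicit `wiring_rate` entries but is off by
default, keeping ground truth analytic.

Randomness: one counter-based Philox generator seeded from the config;
iteration orders are sorted, so identical (config, seed) produce
bit-identical output.

## What the synthetic tests do and do not show

Passing tests establish that the implementations are correct against
independent oracles (closed forms, brute-force scans, resampling) and
well-calibrated under the generator's assumptions: Poisson pair wiring,
uniform axial synapse placement, isotropic jitter, cleanly separated planted
clusters. They do not establish robustness to features of real data the
generator omits: curved axons and non-convex compartment shapes,
density-dependent cluster merging at realistic synapse density (recovery
degrades gracefully and is reported, not asserted, without separation),
annotation noise, partial reconstruction, or membrane-vs-centerline offsets
larger than the snap tolerance.

## Problem sizes and numerical notes

Test and demo runs use scaled-down lobes (tens to low hundreds of KCs,
10³–10⁴ synapses) chosen so the whole suite and the demo pipeline execute in
about a minute while keeping every statistical check at the sample sizes its
tolerance assumes (e.g. 100 seeds for parameter recovery, 1000 replicates
for type-I calibration, 200 replicates for p-uniformity, 30 replicates for
the coverage closed form). Full-census generation (~10⁵ synapses) runs in a
few seconds. Displayed values round half-up to 2 decimals; internal values
are unrounded. The pipeline's `metrics.json` serializes the resolved
configuration minus the output path, so identical analyses into different
directories compare byte-identical.

## Known limitations

* Single-linkage at 300 nm is an explicit stand-in for the unpublished
  cluster-growing rule behind reported rosette percentages; percentages
  depend on the linkage at high density.
* Published per-MBON percent columns are not always exactly
  count/denominator; derived percentages here are always recomputed from raw
  counts, and the transcribed `printed_percent` column is retained for
  comparison only.
* No image handling, segmentation, proofreading tools, or diffusion
  modeling; feedforward-MBON and APL/DPM pathways are supported as cell
  classes but have no dedicated default wiring rates.
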