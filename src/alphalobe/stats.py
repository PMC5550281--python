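"""Poisson wiring null model and the statistics built around it.

The null model: each of N synapses is assigned independently and uniformly at
random among M candidate cells, so per-cell synapse counts are Poisson with
rate lambda = N/M and the expected number of cells with exactly k synapses is

    c_k = M * (N/M)^k * exp(-N/M) / k!

There are no free parameters and the variance of each c_k equals c_k (SD
reported as sqrt(c_k)). Goodness of fit is a chi-square over all count bins
whose expected value is at least ``min_expected`` (default 0.5); by the
convention used throughout, the degrees of freedom equal the number of
retained bins (``df_adjust`` subtracts the usual corrections for estimated
parameters when a calibrated test is wanted — see docs/methods.md).

Fits are classified by p-value into ``green`` (indistinguishable from Poisson,
p > 0.05), ``magenta`` (more than three sigma different, p < 0.003) and
``yellow`` (intermediate).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import Connectome

__all__ = [
    "PoissonFit",
    "SharedPartnerTable",
    "ZeroVarianceError",
    "poisson_expected_counts",
    "chi2_gof",
    "classify_fit",
    "poisson_fit",
    "fit_grid",
    "fisher_shared_partners",
    "paired_target_correlation",
    "ks_two_sample",
    "rosette_repeat_test",
]


class ZeroVarianceError(ValueError):
    """A correlation was requested for a constant vector."""


@dataclass
class PoissonFit:
    """A fitted Poisson wiring null for one (pre population, post target) pair."""

    m_cells: int
    n_synapses: int
    lam: float
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float
    fit_class: str


@dataclass
class SharedPartnerTable:
    """2x2 partner-sharing table for two cells against a candidate universe."""

    both: int
    only_a: int
    only_b: int
    neither: int
    p_value: float

    @property
    def total(self) -> int:
        return self.both + self.only_a + self.only_b + self.neither


def poisson_expected_counts(n_synapses: int, m_cells: int, k_max: int) -> np.ndarray:
    """Expected number of cells with k = 0..k_max synapses under the null.

    ``c_k = M * pmf_Poisson(k; N/M)``. The untruncated sum over all k equals M.
    """
    if m_cells < 1:
        raise ValueError("m_cells must be >= 1")
    if n_synapses < 0:
        raise ValueError("n_synapses must be >= 0")
    lam = n_synapses / m_cells
    k = np.arange(k_max + 1)
    return m_cells * sps.poisson.pmf(k, lam)


def chi2_gof(
    observed: Sequence[float],
    expected: Sequence[float],
    min_expected: float = 0.5,
    df_adjust: int = 0,
) -> tuple[float, int, float]:
    """Chi-square goodness of fit using only bins with expected >= min_expected.

    Returns ``(chi2, df, p)`` with ``chi2 = sum (o-e)^2/e`` over retained bins
    and ``df = (number of retained bins) - df_adjust``. The default
    ``df_adjust=0`` is the convention used for the wiring tables (see module
    docstring); pass 1 when the bin total is fixed (multinomial sampling) or 2
    when additionally the mean was estimated from the data.
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("observed and expected must have equal length")
    if np.any(e < 0):
        raise ValueError("expected counts must be non-negative")
    keep = e >= min_expected
    if not keep.any():
        raise ValueError(f"no bin has expected count >= {min_expected}")
    chi2 = float(np.sum((o[keep] - e[keep]) ** 2 / e[keep]))
    df = int(keep.sum()) - df_adjust
    if df < 1:
        raise ValueError("df < 1 after adjustment")
    p = float(sps.chi2.sf(chi2, df))
    return chi2, df, p


def classify_fit(p_value: float) -> str:
    """Colour class of a Poisson fit: green / yellow / magenta (see module doc)."""
    if not 0 <= p_value <= 1:
        raise ValueError("p_value must lie in [0, 1]")
    if p_value > 0.05:
        return "green"
    if p_value < 0.003:
        return "magenta"
    return "yellow"


def poisson_fit(
    counts: Sequence[int],
    min_expected: float = 0.5,
    df_adjust: int = 0,
) -> PoissonFit:
    """Fit the Poisson wiring null to a vector of per-cell synapse counts.

    ``counts`` must include cells with zero synapses (M = len(counts),
    N = sum(counts)). The observed histogram runs over k = 0..max(count).
    """
    counts = np.asarray(counts, dtype=int)
    m = len(counts)
    n = int(counts.sum())
    k_max = int(counts.max()) if m else 0
    observed = np.bincount(counts, minlength=k_max + 1).astype(float)
    expected = poisson_expected_counts(n, m, k_max)
    chi2, df, p = chi2_gof(observed, expected, min_expected, df_adjust)
    return PoissonFit(
        m_cells=m,
        n_synapses=n,
        lam=n / m,
        observed=observed,
        expected=expected,
        chi2=chi2,
        df=df,
        p_value=p,
        fit_class=classify_fit(p),
    )


def fit_grid(
    connectome: Connectome,
    pre_types: Iterable[str] | None = None,
    post_cells: Iterable[str] | None = None,
    direction: str = "kc_pre",
    min_expected: float = 0.5,
    df_adjust: int = 0,
    min_total: int = 1,
) -> pd.DataFrame:
    """Poisson-fit p-value grid across (KC subtype, partner cell) pairs.

    For ``direction="kc_pre"`` each cell of the grid fits the distribution of
    synapse counts from the KCs of one subtype onto one partner cell; for
    ``"kc_post"`` counts of synapses received by the KCs from one partner cell.
    Returns a tidy frame with columns pre/post, M, N, chi2, df, p_value and
    fit_class, mirroring the colour-grid view of wiring statistics.
    """
    from .tables import per_cell_counts  # local import to avoid cycle

    t = connectome.contact_table()
    kc_types = sorted(
        connectome.neurons.loc[
            connectome.neurons["type_class"] == "KC", "cell_type"
        ].unique()
    )
    if pre_types is not None:
        kc_types = [k for k in kc_types if k in set(pre_types)]
    if post_cells is None:
        partners = sorted(
            connectome.neurons.index[
                connectome.neurons["type_class"].isin(
                    ["MBON", "DAN", "modulatory", "feedforward"]
                )
            ]
        )
    else:
        partners = list(post_cells)
    rows = []
    for kc_type in kc_types:
        for partner in partners:
            if direction == "kc_pre":
                counts = per_cell_counts(connectome, kc_type, partner)
            elif direction == "kc_post":
                sub = t[(t["pre_neuron"] == partner) & (t["post_type"] == kc_type)]
                kcs = connectome.select_neurons(kc_type)
                counts = (
                    sub.groupby("post_neuron").size().reindex(kcs, fill_value=0)
                )
            else:
                raise ValueError("direction must be 'kc_pre' or 'kc_post'")
            if counts.sum() < min_total:
                continue
            fit = poisson_fit(counts.to_numpy(), min_expected, df_adjust)
            rows.append(
                {
                    "kc_type": kc_type,
                    "partner": partner,
                    "direction": direction,
                    "m_cells": fit.m_cells,
                    "n_synapses": fit.n_synapses,
                    "lambda": fit.lam,
                    "chi2": fit.chi2,
                    "df": fit.df,
                    "p_value": fit.p_value,
                    "fit_class": fit.fit_class,
                }
            )
    return pd.DataFrame(rows)


def fisher_shared_partners(
    targets_a: Iterable, targets_b: Iterable, universe: Iterable
) -> SharedPartnerTable:
    """Independence of two cells' partner sets over a shared candidate universe.

    Builds the 2x2 table (both / only A / only B / neither) over ``universe``
    and attaches a two-sided Fisher exact p-value (summing all tables with the
    observed margins whose probability does not exceed the observed table's).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    a = set(targets_a)
    b = set(targets_b)
    if not a <= universe or not b <= universe:
        raise ValueError("targets must be subsets of the universe")
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = len(universe - a - b)
    _, p = sps.fisher_exact([[both, only_a], [only_b, neither]], alternative="two-sided")
    return SharedPartnerTable(both, only_a, only_b, neither, float(p))


def paired_target_correlation(
    counts_a: Sequence[float], counts_b: Sequence[float]
) -> float:
    """Pearson correlation of two per-cell synapse-count vectors.

    Measures whether the cells a presynaptic population connects to strongly
    in one target are also its strong partners in a second target. Raises
    :class:`ZeroVarianceError` when either vector is constant.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("counts_a and counts_b must be equal-length vectors")
    if len(a) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ZeroVarianceError("correlation undefined: a vector has zero variance")
    return float(sps.pearsonr(a, b).statistic)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def _count_repeated_pairs(memberships: list[np.ndarray]) -> int:
    """Number of unordered cell pairs co-occurring in >= 2 of the given groups."""
    codes = []
    for members in memberships:
        m = np.sort(members)
        if len(m) < 2:
            continue
        i, j = np.triu_indices(len(m), k=1)
        codes.append(m[i].astype(np.int64) * np.int64(1 << 32) + m[j])
    if not codes:
        return 0
    allcodes = np.concatenate(codes)
    _, counts = np.unique(allcodes, return_counts=True)
    return int((counts >= 2).sum())


def rosette_repeat_test(
    rosette_memberships: Sequence[Iterable],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    universe: Iterable | None = None,
    tie_break: str = "conservative",
) -> tuple[int, float]:
    """Do cell pairs that co-occur in one rosette co-occur again elsewhere?

    The statistic is the number of unordered KC pairs appearing together in at
    least two rosettes. The null fixes the rosette sizes and redraws each
    rosette's members without replacement from the KC universe (by default the
    union of all observed members). With ``tie_break="conservative"`` (default)
    the p-value is the permutation tail probability with the standard +1
    correction, which is valid but slightly conservative because the statistic
    is discrete; ``tie_break="random"`` randomizes over permutations tied with
    the observed statistic, which makes the p-value exactly uniform under the
    null (useful for calibration studies).
    """
    memberships = [set(m) for m in rosette_memberships]
    if len(memberships) < 2:
        raise ValueError("need at least 2 rosettes")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value", stacklevel=2)
    if universe is None:
        pool = sorted(set().union(*memberships), key=repr)
    else:
        pool = sorted(set(universe), key=repr)
    index = {cell: i for i, cell in enumerate(pool)}
    encoded = [np.array([index[c] for c in m], dtype=np.int64) for m in memberships]
    observed = _count_repeated_pairs(encoded)

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.Generator(np.random.Philox(seed))
    )
    sizes = [len(m) for m in encoded]
    k = len(pool)
    greater = 0
    equal = 0
    # Vectorised resampling: one random key per (perm, rosette, cell); the
    # smallest `size` keys of each row are that rosette's resampled members.
    for start in range(0, n_perm, 200):
        block = min(200, n_perm - start)
        keys = rng.random((block * len(sizes), k))
        order = np.argsort(keys, axis=1)
        for b in range(block):
            perm_groups = [
                order[b * len(sizes) + gi, :s] for gi, s in enumerate(sizes)
            ]
            stat = _count_repeated_pairs(perm_groups)
            if stat > observed:
                greater += 1
            elif stat == observed:
                equal += 1
    if tie_break == "conservative":
        p = (1 + greater + equal) / (n_perm + 1)
    elif tie_break == "random":
        p = (greater + rng.random() * (equal + 1)) / (n_perm + 1)
    else:
        raise ValueError("tie_break must be 'conservative' or 'random'")
    return observed, float(p)
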