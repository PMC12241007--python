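"""Mutual information between stimulus and discretized population response.

Plugin (maximum-likelihood) estimator: MI = H(R) - H(R|S) with empirical
P(s), P(r), P(r|s) and entropies in bits (0 * log 0 := 0). The plugin
estimate carries a positive limited-sampling bias, corrected by subtracting
the Panzeri-Treves term

    bias = [sum_s (R_s - 1) - (R - 1)] / (2 * N * ln 2)

where ``R_s`` and ``R`` estimate the number of effectively occupied response
bins per stimulus and overall (naive occupancy count by default; Bayesian
refinement optional). Corrected values may be slightly negative.

Population responses are built as tuples of per-unit equipopulated
(quantile) bins; MI as a function of population size averages the corrected
estimate over seeded random unit subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .recording import Recording


@dataclass(frozen=True)
class MIEstimate:
    mi_bits: float
    h_response_bits: float
    h_noise_bits: float
    correction: str
    n_trials: int
    n_stimuli: int
    n_response_bins: int


@dataclass(frozen=True)
class MICurve:
    population_sizes: tuple[int, ...]
    mi_mean_bits: tuple[float, ...]
    mi_sem_bits: tuple[float, ...]
    n_subsets: int
    seed: int


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _encode(labels) -> tuple[np.ndarray, int]:
    _, inv = np.unique(np.asarray(labels, dtype=object).astype(str), return_inverse=True)
    return inv, int(inv.max()) + 1


def plugin_mi(stimuli, responses) -> MIEstimate:
    """Plugin MI (bits) between stimulus labels and discrete response symbols."""
    s, n_s = _encode(stimuli)
    r, n_r = _encode(responses)
    if s.size != r.size:
        raise ValueError("stimuli and responses must have equal length")
    if s.size == 0:
        raise ValueError("empty input")
    n = s.size

    joint = np.zeros((n_s, n_r))
    np.add.at(joint, (s, r), 1.0)
    joint /= n
    p_s = joint.sum(axis=1)
    p_r = joint.sum(axis=0)

    h_r = _entropy_bits(p_r)
    h_r_given_s = 0.0
    for si in range(n_s):
        if p_s[si] == 0:
            continue
        cond = joint[si] / p_s[si]
        h_r_given_s += p_s[si] * _entropy_bits(cond)
    mi = h_r - h_r_given_s
    return MIEstimate(
        mi_bits=float(mi),
        h_response_bits=h_r,
        h_noise_bits=float(h_r_given_s),
        correction="none",
        n_trials=n,
        n_stimuli=n_s,
        n_response_bins=n_r,
    )


def _bayes_bin_count(occupied: int, n: int) -> float:
    """Bayesian estimate of the number of effectively occupied bins.

    Solves ``R * (1 - (1 - 1/R)**n) = occupied`` for R >= occupied (the
    expected occupancy of R equiprobable bins after n draws). When every
    sample landed in a distinct bin no finite solution exists and the naive
    count is returned.
    """
    if occupied <= 1:
        return float(occupied)
    if occupied >= n:
        return float(occupied)

    def g(r: float) -> float:
        return r * (1.0 - (1.0 - 1.0 / r) ** n) - occupied

    hi = float(occupied)
    while g(hi) < 0 and hi < 1e9:
        hi *= 2.0
    if g(hi) < 0:
        return float(occupied)
    return float(brentq(g, occupied * (1 + 1e-12), hi))


def pt_bias_bits(stimuli, responses, bayesian: bool = False) -> float:
    """Panzeri-Treves bias term (bits) for the plugin MI estimate."""
    s, n_s = _encode(stimuli)
    r, _ = _encode(responses)
    n = s.size
    estimate = _bayes_bin_count if bayesian else (lambda occ, _n: float(occ))

    r_total = estimate(int(np.unique(r).size), n)
    r_per_s = 0.0
    for si in range(n_s):
        sel = s == si
        r_per_s += estimate(int(np.unique(r[sel]).size), int(sel.sum())) - 1.0
    return (r_per_s - (r_total - 1.0)) / (2.0 * n * np.log(2.0))


def pt_corrected_mi(stimuli, responses, bayesian: bool = False) -> MIEstimate:
    """Bias-corrected MI: plugin estimate minus the Panzeri-Treves term."""
    plugin = plugin_mi(stimuli, responses)
    bias = pt_bias_bits(stimuli, responses, bayesian=bayesian)
    return MIEstimate(
        mi_bits=plugin.mi_bits - bias,
        h_response_bits=plugin.h_response_bits,
        h_noise_bits=plugin.h_noise_bits,
        correction="panzeri_treves",
        n_trials=plugin.n_trials,
        n_stimuli=plugin.n_stimuli,
        n_response_bins=plugin.n_response_bins,
    )


def quantize_responses(counts: np.ndarray, n_bins: int = 2) -> tuple[np.ndarray, int]:
    """Per-unit equipopulated binning; returns population symbols.

    ``counts`` is (n_trials, n_units). Each unit is discretized by its own
    quantile edges (duplicate edges merged, so a constant unit contributes a
    single symbol); the population response is the tuple of per-unit bin
    indices, encoded as integers. Returns (symbols, n_distinct_symbols).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.atleast_2d(np.asarray(counts, dtype=float))
    if x.ndim != 2:
        raise ValueError("counts must be (n_trials, n_units)")
    n_trials, n_units = x.shape
    digit = np.zeros((n_trials, n_units), dtype=np.int64)
    for u in range(n_units):
        qs = np.quantile(x[:, u], np.linspace(0, 1, n_bins + 1)[1:-1])
        edges = np.unique(qs)
        digit[:, u] = np.searchsorted(edges, x[:, u], side="left")
    _, symbols = np.unique(digit, axis=0, return_inverse=True)
    return symbols.ravel(), int(symbols.max()) + 1


def stimulus_response_arrays(
    rec: Recording, unit_ids=None, include_blank: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a Recording into per-trial stimulus labels and count rows."""
    unit_ids = list(unit_ids) if unit_ids is not None else rec.unit_ids
    uix = [rec.unit_index(u) for u in unit_ids]
    conds = list(rec.protocol.conditions)
    if not include_blank:
        conds = [c for c in conds if c != "BLANK"]
    stim, resp = [], []
    for cond in conds:
        ci = rec.condition_index(cond)
        for s in range(rec.protocol.n_sweeps):
            stim.append(str(cond))
            resp.append(rec.counts[ci, s, uix])
    return np.asarray(stim), np.asarray(resp, dtype=float)


def mi_vs_population_size(
    rec: Recording,
    sizes,
    n_subsets: int = 20,
    n_bins: int = 2,
    seed: int = 0,
    include_blank: bool = True,
    corrected: bool = True,
) -> MICurve:
    """Mean +/- SEM corrected MI over seeded random unit subsets per size."""
    sizes = [int(m) for m in sizes]
    if not sizes:
        raise ValueError("sizes must be non-empty")
    if max(sizes) > rec.n_units:
        raise ValueError("population size exceeds number of units")
    rng = np.random.default_rng(seed)
    stim, resp = stimulus_response_arrays(rec, include_blank=include_blank)
    estimator = pt_corrected_mi if corrected else plugin_mi

    means, sems = [], []
    for m in sizes:
        vals = []
        for _ in range(n_subsets):
            subset = rng.choice(rec.n_units, size=m, replace=False)
            symbols, _ = quantize_responses(resp[:, subset], n_bins=n_bins)
            vals.append(estimator(stim, symbols).mi_bits)
        vals = np.asarray(vals)
        means.append(float(vals.mean()))
        sems.append(float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0)
    return MICurve(
        population_sizes=tuple(sizes),
        mi_mean_bits=tuple(means),
        mi_sem_bits=tuple(sems),
        n_subsets=n_subsets,
        seed=seed,
    )
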