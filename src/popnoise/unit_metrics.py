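"""Single-unit response metrics: ROC-based SNR and Fano factors.

The SNR is the area under the ROC curve comparing the distribution of
response bins at the optimal orientation against spontaneous (blank)
response bins, with the threshold swept over every observed value. The AUC
equals the pairwise-comparison statistic with ties counted 1/2 (0.5 =
chance, 1.0 = perfect separation).

The Fano factor is the variance-to-mean ratio of spike counts across
repeats of the same condition, computed with the unbiased (n-1) variance
and averaged over grating conditions. Multi-unit activity (MUA) sums all
simultaneously recorded units per trial before the same computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import BLANK, Recording, mean_rate, optimal_condition


@dataclass(frozen=True)
class RocResult:
    """ROC curve and its area for an evoked-vs-spontaneous comparison."""

    auc: float
    roc_points: tuple[tuple[float, float], ...]
    n_evoked_bins: int
    n_spont_bins: int


@dataclass(frozen=True)
class FanoResult:
    """Variance-to-mean ratio of trial counts, averaged over conditions."""

    ff: float
    variance: float
    mean: float
    scope: str = "single-unit"
    per_condition: dict = field(default_factory=dict)


def roc_snr(evoked_bins, spont_bins) -> RocResult:
    """ROC AUC discriminating evoked from spontaneous response bins.

    The threshold is swept over all distinct observed values; TPR is the
    fraction of evoked bins exceeding the threshold, FPR the fraction of
    spontaneous bins exceeding it. The area is the trapezoidal integral of
    the (FPR, TPR) curve, identical to the Mann-Whitney U statistic divided
    by n*m with ties counted 1/2.
    """
    ev = np.asarray(evoked_bins, dtype=float)
    sp = np.asarray(spont_bins, dtype=float)
    if ev.size == 0 or sp.size == 0:
        raise ValueError("evoked and spontaneous bin lists must be non-empty")

    thresholds = np.unique(np.concatenate([ev, sp]))[::-1]
    points = [(0.0, 0.0)]
    for t in thresholds:
        fpr = float(np.mean(sp > t))
        tpr = float(np.mean(ev > t))
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))

    fprs = np.array([p[0] for p in points])
    tprs = np.array([p[1] for p in points])
    auc = float(np.trapezoid(tprs, fprs))
    return RocResult(
        auc=auc,
        roc_points=tuple(points),
        n_evoked_bins=int(ev.size),
        n_spont_bins=int(sp.size),
    )


def make_response_bins(
    rec: Recording, unit_id: str, condition, bin_s: float = 0.1
) -> np.ndarray:
    """Per-trial response bins for one unit and condition, pooled over sweeps.

    With spike times present, each trial is divided into consecutive bins of
    ``bin_s`` seconds within the stimulus window. Without spike times the
    counts-only fallback returns one bin per trial (the trial count).
    """
    dur = rec.protocol.stimulus_duration_s
    if bin_s <= 0:
        raise ValueError("bin_s must be > 0")
    n_bins = dur / bin_s
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_s={bin_s} does not divide the {dur} s stimulus window")
    n_bins = int(round(n_bins))

    ci = rec.condition_index(condition)
    have_times = rec.spike_times is not None and any(
        k[0] == condition and k[2] == unit_id for k in rec.spike_times
    )
    if not have_times:
        return rec.counts[ci, :, rec.unit_index(unit_id)].astype(np.int64)

    edges = np.linspace(0.0, dur, n_bins + 1)
    out = []
    for s in range(rec.protocol.n_sweeps):
        times = rec.spike_times.get((condition, s, unit_id), np.empty(0))
        hist, _ = np.histogram(times, bins=edges)
        out.append(hist)
    return np.concatenate(out)


def fano_factor(counts_by_condition: dict, scope: str = "single-unit") -> FanoResult:
    """Fano factor per condition (unbiased variance), averaged over conditions.

    Conditions with zero mean are skipped; if every condition has zero mean
    the Fano factor is undefined and an error is raised.
    """
    per_condition: dict = {}
    for cond, counts in counts_by_condition.items():
        c = np.asarray(counts, dtype=float)
        if c.size < 2:
            raise ValueError(f"condition {cond!r}: need >= 2 trials")
        m = float(np.mean(c))
        if m == 0:
            continue
        v = float(np.var(c, ddof=1))
        per_condition[cond] = {"ff": v / m, "variance": v, "mean": m}
    if not per_condition:
        raise ValueError("Fano factor undefined: all conditions have zero mean")
    ffs = [d["ff"] for d in per_condition.values()]
    return FanoResult(
        ff=float(np.mean(ffs)),
        variance=float(np.mean([d["variance"] for d in per_condition.values()])),
        mean=float(np.mean([d["mean"] for d in per_condition.values()])),
        scope=scope,
        per_condition=per_condition,
    )


def unit_fano(rec: Recording, unit_id: str, optimal_only: bool = False) -> FanoResult:
    """Fano factor of one unit across grating conditions (or the optimal one)."""
    if optimal_only:
        best = optimal_condition(rec, unit_id)
        conds = {best: rec.counts_for(unit_id, best)}
    else:
        conds = rec.grating_counts(unit_id)
    return fano_factor(conds)


def mua_fano(rec: Recording) -> FanoResult:
    """Fano factor of the summed (multi-unit) activity across grating trials."""
    if rec.n_units < 2:
        raise ValueError("MUA Fano factor needs >= 2 units")
    summed = rec.counts.sum(axis=2)  # (condition, sweep)
    conds = {
        d: summed[rec.condition_index(d), :] for d in rec.grating_conditions
    }
    return fano_factor(conds, scope="MUA")


def evoked_rate_split(
    rec: Recording, unit_ids=None, threshold_hz: float = 6.0
) -> dict[str, list[str]]:
    """Split units by evoked rate (peak minus spontaneous): > threshold vs <=.

    Mirrors the high/low evoked-firing-rate grouping used when comparing
    SNR distributions; the high group is strict ``>``.
    """
    from .recording import peak_rate, spontaneous_rate

    unit_ids = list(unit_ids) if unit_ids is not None else rec.unit_ids
    high, low = [], []
    for uid in unit_ids:
        evoked = peak_rate(rec, uid) - spontaneous_rate(rec, uid)
        (high if evoked > threshold_hz else low).append(uid)
    return {"high": high, "low": low}


def unit_snr(rec: Recording, unit_id: str, bin_s: float = 0.1) -> RocResult:
    """ROC-SNR of one unit: optimal-orientation bins vs blank bins."""
    best = optimal_condition(rec, unit_id)
    evoked = make_response_bins(rec, unit_id, best, bin_s=bin_s)
    spont = make_response_bins(rec, unit_id, BLANK, bin_s=bin_s)
    return roc_snr(evoked, spont)
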