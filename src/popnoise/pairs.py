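"""Pairwise population metrics: trial z-scores, noise correlation,
covariance, binned relationships, and the FS-RS decorrelation index.

Noise correlation (r_sc) is the Pearson correlation of two units'
within-condition z-scored trial counts, pooled over grating conditions in a
fixed (condition, sweep) order; conditions where either unit has zero
standard deviation are dropped for both. Spontaneous r_sc uses the same
machinery on the single blank condition.

Covariance is the population-form expectation identity
``cov(N1, N2) = E(N1*N2) - E(N1)*E(N2)`` on raw counts pooled across
grating conditions. Note this mixes signal and noise covariance; the raw
formula is applied as printed rather than residualized.

The decorrelation index of an FS-RS pair is ``min(0, rsc_evoked -
rsc_spont)``: positive differences (no decorrelation) are assigned zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .recording import BLANK, Recording, mean_rate

#: Default bin edges for the r_sc relationships (half-open [lo, hi) bins).
DEFAULT_EDGES = {
    "rate": tuple(np.arange(0.0, 51.0, 10.0)),
    "distance": tuple(np.arange(0.0, 301.0, 50.0)),
    "delta_po": tuple(np.arange(0.0, 91.0, 30.0)),
}


def trial_z_scores(counts_by_condition: dict) -> np.ndarray:
    """Within-condition z-scores pooled across conditions in fixed order.

    Each condition's trials are standardized by that condition's mean and
    (population, ddof=0) standard deviation; zero-SD conditions are dropped.
    """
    blocks = []
    for cond in counts_by_condition:
        c = np.asarray(counts_by_condition[cond], dtype=float)
        if c.size < 2:
            raise ValueError(f"condition {cond!r}: need >= 2 trials")
        sd = np.std(c)
        if sd == 0:
            continue
        blocks.append((c - c.mean()) / sd)
    if not blocks:
        raise ValueError("no condition with non-zero SD")
    return np.concatenate(blocks)


def paired_z_scores(counts_a: dict, counts_b: dict) -> tuple[np.ndarray, np.ndarray]:
    """Jointly pooled z-scores for a unit pair.

    Conditions where either unit has zero SD are dropped for both members so
    the pooled vectors stay aligned trial-by-trial.
    """
    if list(counts_a) != list(counts_b):
        raise ValueError("pair members must share the same condition keys/order")
    za, zb = [], []
    for cond in counts_a:
        a = np.asarray(counts_a[cond], dtype=float)
        b = np.asarray(counts_b[cond], dtype=float)
        if a.size != b.size:
            raise ValueError(f"condition {cond!r}: trial count mismatch")
        sda, sdb = np.std(a), np.std(b)
        if sda == 0 or sdb == 0:
            continue
        za.append((a - a.mean()) / sda)
        zb.append((b - b.mean()) / sdb)
    if not za:
        raise ValueError("no condition with non-zero SD for both units")
    return np.concatenate(za), np.concatenate(zb)


def noise_correlation(za, zb) -> float:
    """Pearson correlation of two pooled z-score vectors."""
    za = np.asarray(za, dtype=float)
    zb = np.asarray(zb, dtype=float)
    if za.size != zb.size:
        raise ValueError("z vectors must have equal length")
    if za.size < 3:
        raise ValueError("need >= 3 pooled trials")
    if np.std(za) == 0 or np.std(zb) == 0:
        raise ValueError("zero variance after pooling: correlation undefined")
    return float(np.corrcoef(za, zb)[0, 1])


def response_covariance(na, nb) -> float:
    """Population-form covariance E(N1*N2) - E(N1)*E(N2) (divide by n)."""
    na = np.asarray(na, dtype=float)
    nb = np.asarray(nb, dtype=float)
    if na.size != nb.size:
        raise ValueError("count lists must have equal length")
    if na.size < 2:
        raise ValueError("need >= 2 trials")
    return float(np.mean(na * nb) - np.mean(na) * np.mean(nb))


def decorrelation_index(rsc_evoked: float, rsc_spont: float) -> float:
    """min(0, evoked - spontaneous): zero when no decorrelation is present."""
    return min(0.0, float(rsc_evoked) - float(rsc_spont))


def pair_rsc(rec: Recording, unit_a: str, unit_b: str, epoch: str = "evoked") -> float:
    """Noise correlation of one pair, evoked (gratings) or spontaneous (blank)."""
    if epoch == "evoked":
        ca = rec.grating_counts(unit_a)
        cb = rec.grating_counts(unit_b)
    elif epoch == "spont":
        ca = {BLANK: rec.counts_for(unit_a, BLANK)}
        cb = {BLANK: rec.counts_for(unit_b, BLANK)}
    else:
        raise ValueError(f"unknown epoch {epoch!r}")
    za, zb = paired_z_scores(ca, cb)
    return noise_correlation(za, zb)


def compute_pair_stats(
    rec: Recording,
    preferred_orientations: dict[str, float] | None = None,
    unit_classes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """All-pairs statistics for one recording.

    One row per unordered pair of simultaneously recorded units: probe
    distance, evoked/spontaneous r_sc, raw-count covariance pooled across
    gratings, arithmetic and geometric pair rates, and, when preferred
    orientations / FS-RS classes are supplied, delta-PO and the FS-RS
    decorrelation index (NaN for other pairs).
    """
    from .tuning import delta_po

    depths = {u.unit_id: u.depth_um for u in rec.units}
    evoked_rates = {
        uid: float(np.mean([mean_rate(rec, uid, d) for d in rec.grating_conditions]))
        for uid in rec.unit_ids
    }
    rows = []
    for ua, ub in combinations(rec.unit_ids, 2):
        row = {
            "unit_a": ua,
            "unit_b": ub,
            "distance_um": abs(depths[ua] - depths[ub]),
            "rate_mean_hz": 0.5 * (evoked_rates[ua] + evoked_rates[ub]),
            "rate_geom_hz": float(np.sqrt(evoked_rates[ua] * evoked_rates[ub])),
        }
        try:
            row["rsc_evoked"] = pair_rsc(rec, ua, ub, "evoked")
        except ValueError:
            row["rsc_evoked"] = np.nan
        try:
            row["rsc_spont"] = pair_rsc(rec, ua, ub, "spont")
        except ValueError:
            row["rsc_spont"] = np.nan

        na = np.concatenate([rec.counts_for(ua, d) for d in rec.grating_conditions])
        nb = np.concatenate([rec.counts_for(ub, d) for d in rec.grating_conditions])
        row["covariance"] = response_covariance(na, nb)
        row["n_trials_used"] = int(na.size)

        if preferred_orientations is not None and ua in preferred_orientations and ub in preferred_orientations:
            row["delta_po_deg"] = delta_po(
                preferred_orientations[ua], preferred_orientations[ub]
            )
        else:
            row["delta_po_deg"] = np.nan

        if unit_classes is not None and {unit_classes.get(ua), unit_classes.get(ub)} == {"FS", "RS"}:
            if np.isfinite(row["rsc_evoked"]) and np.isfinite(row["rsc_spont"]):
                row["decorrelation"] = decorrelation_index(
                    row["rsc_evoked"], row["rsc_spont"]
                )
            else:
                row["decorrelation"] = np.nan
        else:
            row["decorrelation"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class BinnedRelation:
    """Mean r_sc in half-open bins of a pair covariate."""

    key: str
    bin_edges: tuple[float, ...]
    bin_means: tuple[float, ...]
    bin_sems: tuple[float, ...]
    bin_ns: tuple[int, ...]
    overflow_n: int
    overflow_mean: float


def bin_relation(pairs: pd.DataFrame, key: str, edges=None, value: str = "rsc_evoked") -> BinnedRelation:
    """Bin pair r_sc values by rate, distance, or delta-PO.

    Bins are half-open ``[lo, hi)``; values at or beyond the final edge go
    to a separately reported overflow bin.
    """
    columns = {"rate": "rate_mean_hz", "distance": "distance_um", "delta_po": "delta_po_deg"}
    if key not in columns:
        raise ValueError(f"unknown bin key {key!r}; expected one of {sorted(columns)}")
    if edges is None:
        edges = DEFAULT_EDGES[key]
    edges = np.asarray(edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be ascending with >= 2 values")

    df = pairs[[columns[key], value]].dropna()
    x = df[columns[key]].to_numpy()
    y = df[value].to_numpy()

    means, sems, ns = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (x >= lo) & (x < hi)
        n = int(sel.sum())
        ns.append(n)
        means.append(float(np.mean(y[sel])) if n else np.nan)
        sems.append(float(np.std(y[sel], ddof=1) / np.sqrt(n)) if n > 1 else np.nan)
    over = x >= edges[-1]
    n_over = int(over.sum())
    return BinnedRelation(
        key=key,
        bin_edges=tuple(edges),
        bin_means=tuple(means),
        bin_sems=tuple(sems),
        bin_ns=tuple(ns),
        overflow_n=n_over,
        overflow_mean=float(np.mean(y[over])) if n_over else np.nan,
    )
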