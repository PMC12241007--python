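"""End-to-end orchestration: simulate/load -> per-unit metrics -> pairs ->
MI curves -> group comparisons, written as tab-separated tables.

Deterministic given the master seed: per-animal simulation seeds and the MI
subset seed are derived from it by fixed offsets so individual stages can be
re-run in isolation. A ``manifest.json`` records every parameter, derived
seed, and exclusion count (3-sigma outliers, goodness-of-fit filtering).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import info, pairs, recording, simulate, stats, tuning, unit_metrics, waveforms

#: Seed offsets for per-stage RNG derivation from the master seed.
SEED_OFFSET_ANIMAL = 10_000
SEED_OFFSET_MI = 777

DEFAULT_CONFIG = {
    "groups": {
        "young": {"preset": "young", "n_animals": 10},
        "aged": {"preset": "aged", "n_animals": 10},
        "met": {"preset": "met", "n_animals": 10},
    },
    "n_units": 24,
    "n_sweeps": 10,
    "gof_threshold": 0.6,
    "roc_bin_s": 0.1,
    "mi_sizes": [1, 2, 3],
    "mi_subsets": 10,
    "mi_bins": 2,
    "seed": 0,
}

#: Per-metric comparison plan: (metric column, table, descriptive family).
COMPARISON_METRICS = [
    "spont_rate_hz",
    "peak_rate_hz",
    "osi",
    "snr_auc",
    "ff",
    "mua_ff",
    "rsc_evoked",
    "covariance",
    "decorrelation",
    "mi_bits",
]


def build_group_recordings(config: dict) -> dict[str, list[recording.Recording]]:
    """Simulate (or load) the per-group recordings specified by the config."""
    master = int(config.get("seed", 0))
    proto = simulate.default_protocol(n_sweeps=int(config.get("n_sweeps", 10)))
    out: dict[str, list[recording.Recording]] = {}
    for gi, (name, spec) in enumerate(sorted(config["groups"].items())):
        recs = []
        if "bundles" in spec:
            for p in spec["bundles"]:
                recs.append(recording.read_recording(p))
        else:
            base = simulate.PRESETS[spec["preset"]]
            for ai in range(int(spec.get("n_animals", 10))):
                params = dataclasses.replace(
                    base,
                    n_units=int(config.get("n_units", base.n_units)),
                    seed=master * SEED_OFFSET_ANIMAL + gi * 1000 + ai,
                )
                recs.append(
                    simulate.simulate_recording(params, proto, group_label=name)
                )
        out[name] = recs
    return out


def analyze_recording(
    rec: recording.Recording,
    animal: str,
    gof_threshold: float = 0.6,
    roc_bin_s: float = 0.1,
    mi_sizes=(1, 2, 3),
    mi_subsets: int = 10,
    mi_bins: int = 2,
    mi_seed: int = 0,
) -> dict:
    """All per-animal analyses; returns unit, pair, and summary tables."""
    directions = np.array(rec.grating_conditions, dtype=float)

    unit_rows, fits, classes, pref_orient = [], {}, {}, {}
    for uid in rec.unit_ids:
        rates = [recording.mean_rate(rec, uid, d) for d in rec.grating_conditions]
        fit = tuning.fit_double_von_mises(directions, rates)
        fits[uid] = fit
        feat = waveforms.extract_features(
            rec.units[rec.unit_index(uid)].waveform, rec.protocol.sampling_rate_hz
        )
        cls = waveforms.classify_unit(feat)
        classes[uid] = cls
        if fit.gof > gof_threshold:
            pref_orient[uid] = fit.preferred_orientation_deg
        snr = unit_metrics.unit_snr(rec, uid, bin_s=roc_bin_s)
        ff = unit_metrics.unit_fano(rec, uid)
        unit_rows.append(
            {
                "animal": animal,
                "unit_id": uid,
                "group": rec.units[rec.unit_index(uid)].group_label,
                "class": cls,
                "spont_rate_hz": recording.spontaneous_rate(rec, uid),
                "peak_rate_hz": recording.peak_rate(rec, uid),
                "evoked_minus_spont_hz": recording.peak_rate(rec, uid)
                - recording.spontaneous_rate(rec, uid),
                "snr_auc": snr.auc,
                "ff": ff.ff,
                "theta1_deg": fit.theta1_deg,
                "k1": fit.k1,
                "k2": fit.k2,
                "mu_hz": fit.mu,
                "amplitude_hz": fit.amplitude,
                "gof": fit.gof,
                "osi": fit.osi if fit.gof > gof_threshold else np.nan,
                "preferred_orientation_deg": fit.preferred_orientation_deg,
                "trough_peak_ms": feat.trough_peak_ms,
                "peak_trough_ratio": feat.peak_trough_ratio,
                "end_slope": feat.end_slope,
            }
        )

    pair_df = pairs.compute_pair_stats(rec, pref_orient, classes)
    pair_df.insert(0, "animal", animal)

    curve = info.mi_vs_population_size(
        rec, sizes=mi_sizes, n_subsets=mi_subsets, n_bins=mi_bins, seed=mi_seed
    )
    mua = unit_metrics.mua_fano(rec)
    summary = {
        "animal": animal,
        "n_units": rec.n_units,
        "n_fs": sum(1 for c in classes.values() if c == waveforms.FS),
        "n_gof_retained": len(pref_orient),
        "mua_ff": mua.ff,
        "mi_bits": curve.mi_mean_bits[-1],
    }
    mi_rows = [
        {
            "animal": animal,
            "population_size": m,
            "mi_mean_bits": mu_,
            "mi_sem_bits": se,
        }
        for m, mu_, se in zip(
            curve.population_sizes, curve.mi_mean_bits, curve.mi_sem_bits
        )
    ]
    return {
        "units": pd.DataFrame(unit_rows),
        "pairs": pair_df,
        "mi": pd.DataFrame(mi_rows),
        "summary": summary,
    }


def _metric_values(tables: dict, metric: str) -> np.ndarray:
    if metric in ("rsc_evoked", "covariance", "decorrelation"):
        v = tables["pairs"][metric].to_numpy(dtype=float)
    elif metric in ("mua_ff", "mi_bits"):
        v = tables["summary"][metric].to_numpy(dtype=float)
    else:
        v = tables["units"][metric].to_numpy(dtype=float)
    return v[np.isfinite(v)]


def compare_groups(group_tables: dict[str, dict], exclusions: dict | None = None) -> pd.DataFrame:
    """Pairwise group comparisons over every headline metric.

    Values are pooled across animals within a group, 3-sigma outliers are
    excluded per metric per group, and each comparison reports the
    Mann-Whitney U, p, Cliff's delta, descriptives, and the sign of the
    median difference (b relative to a).
    """
    names = list(group_tables)
    rows = []
    for metric in COMPARISON_METRICS:
        cleaned = {}
        for g in names:
            v = _metric_values(group_tables[g], metric)
            if v.size >= 2:
                kept = stats.exclude_outliers_3sigma(v)
            else:
                kept = v
            cleaned[g] = kept
            if exclusions is not None:
                exclusions.setdefault(metric, {})[g] = int(v.size - kept.size)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                va, vb = cleaned[a], cleaned[b]
                if va.size == 0 or vb.size == 0:
                    continue
                cmp = stats.mann_whitney(va, vb)
                med_a = float(np.median(va))
                med_b = float(np.median(vb))
                rows.append(
                    {
                        "metric": metric,
                        "group_a": a,
                        "group_b": b,
                        "n_a": cmp.n_a,
                        "n_b": cmp.n_b,
                        "median_a": med_a,
                        "median_b": med_b,
                        "iqr_a": cmp.descriptives["a"]["iqr"],
                        "iqr_b": cmp.descriptives["b"]["iqr"],
                        "u_statistic": cmp.statistic,
                        "p_value": cmp.p_value,
                        "cliffs_delta": cmp.effect_size,
                        "sign_b_minus_a": int(np.sign(med_b - med_a)),
                    }
                )
    return pd.DataFrame(rows)


def run_full(config: dict, out_dir: str | Path) -> dict:
    """Run the whole pipeline and write tables + manifest to ``out_dir``."""
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(cfg["seed"])

    groups = build_group_recordings(cfg)
    group_tables: dict[str, dict] = {}
    for name, recs in groups.items():
        units, pair_list, mi_list, summaries = [], [], [], []
        for ai, rec in enumerate(recs):
            res = analyze_recording(
                rec,
                animal=f"{name}_{ai:02d}",
                gof_threshold=cfg["gof_threshold"],
                roc_bin_s=cfg["roc_bin_s"],
                mi_sizes=cfg["mi_sizes"],
                mi_subsets=cfg["mi_subsets"],
                mi_bins=cfg["mi_bins"],
                mi_seed=master + SEED_OFFSET_MI + ai,
            )
            units.append(res["units"])
            pair_list.append(res["pairs"])
            mi_list.append(res["mi"])
            summaries.append(res["summary"])
        group_tables[name] = {
            "units": pd.concat(units, ignore_index=True),
            "pairs": pd.concat(pair_list, ignore_index=True),
            "mi": pd.concat(mi_list, ignore_index=True),
            "summary": pd.DataFrame(summaries),
        }
        for kind in ("units", "pairs", "mi", "summary"):
            group_tables[name][kind].to_csv(
                out / f"{name}_{kind}.tsv", sep="\t", index=False, lineterminator="\n"
            )

    exclusions: dict = {}
    comparisons = compare_groups(group_tables, exclusions=exclusions)
    comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False, lineterminator="\n")

    manifest = {
        "config": {k: v for k, v in cfg.items()},
        "derived_seeds": {
            "animal_seed_formula": "seed*10000 + group_index*1000 + animal_index",
            "mi_seed_formula": "seed + 777 + animal_index",
        },
        "exclusions_3sigma": exclusions,
        "groups": {
            name: {
                "n_animals": len(recs),
                "n_units_total": int(sum(r.n_units for r in recs)),
            }
            for name, recs in groups.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return {"tables": group_tables, "comparisons": comparisons, "manifest": manifest}
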