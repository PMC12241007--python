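# popnoise

Population-coding analysis of trial-structured visual-cortex recordings:
orientation tuning, response reliability, pairwise and population noise,
mutual information, fast-spiking/regular-spiking classification,
evoked-vs-spontaneous decorrelation, and group statistics — driven by a
synthetic-recording generator that emulates the drifting-grating protocol
(12 directions in 30° steps plus a blank, 10 pseudorandom sweeps, 1 s
trials, linear-probe geometry).

## Package layout

| module | contents |
| --- | --- |
| `popnoise.recording` | data model (`Protocol`, `UnitRecord`, `Recording`), plain-text bundle I/O, mean rates |
| `popnoise.simulate` | shared-gain Poisson simulator, young/aged/met presets, analytic r_sc and Fano oracles |
| `popnoise.tuning` | double von Mises fits, goodness-of-fit filter (> 0.6), OSI, ΔPO |
| `popnoise.unit_metrics` | ROC-based SNR (AUC), response bins, single-unit and MUA Fano factors |
| `popnoise.pairs` | trial z-scores, noise correlation, covariance, binned relations, decorrelation index |
| `popnoise.info` | plugin mutual information, Panzeri–Treves bias correction, MI vs population size |
| `popnoise.waveforms` | waveform features (trough-peak, peak/trough ratio, end slope), FS/RS classifier |
| `popnoise.stats` | 3σ outlier exclusion, Mann–Whitney U, Cliff's delta, Cohen's d, two-way ANOVA |
| `popnoise.pipeline` / `popnoise.cli` | end-to-end orchestration and the `popnoise` command |

## Recording bundles

A recording is a directory of UTF-8, LF-terminated text files:
`protocol.json`, `units.tsv` (unit metadata + comma-joined waveform),
`trials.tsv` (condition, sweep, unit_id, count), and optionally
`spike_times.tsv`. `read_recording` / `write_recording` round-trip exactly.

## CLI

```bash
popnoise simulate --preset aged --n-units 24 --seed 7 --out scratch/aged0
popnoise tuning   --in scratch/aged0 --gof-threshold 0.6 --out tuning.tsv
popnoise metrics  --in scratch/aged0 --roc-bin-s 0.1 --out metrics.tsv
popnoise pairs    --in scratch/aged0 --out pairs.tsv
popnoise mi       --in scratch/aged0 --sizes 1:6 --subsets 20 --seed 0 --out mi.tsv
popnoise classify --in scratch/aged0 --out classes.tsv
popnoise compare  --a scratch/young0 --b scratch/aged0 --out compare.tsv
popnoise run      --config run.yaml --out scratch/report
```

`popnoise run` simulates every configured group, analyzes each animal, and
writes per-group unit/pair/MI tables plus a `comparisons.tsv` with
Mann–Whitney p-values, Cliff's deltas and the sign of each group contrast,
and a `manifest.json` recording parameters, derived seeds, and exclusion
counts. Runs are deterministic given the master seed.

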