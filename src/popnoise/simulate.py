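"""Synthetic trial-structured recordings with controllable noise structure.

The generative model is a doubly-stochastic (shared-gain) Poisson process:
each trial draws one latent multiplicative gain ``g ~ Normal(1, sd)``
(truncated at zero, with the SD depending on whether the trial is a grating
or a blank), and every unit's count is Poisson with rate

    rate_i(condition) * duration * max(0, 1 + c_i * (g - 1))

where ``c_i`` is 1 for RS units and an epoch-specific coupling for FS units.
This is the minimal model producing jointly controllable super-Poisson Fano
factors and positive pairwise noise correlations, with an FS coupling knob
that implements evoked-vs-spontaneous decorrelation.

Analytic oracles (:func:`expected_pair_rsc`, :func:`expected_fano`) follow
from the law of total variance and are used by the recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.special import i0

from .recording import BLANK, Protocol, Recording, UnitRecord
from .waveforms import make_waveform

#: Canonical stimulus protocol: 12 directions in 30 degree steps plus a
#: blank, 10 pseudorandom sweeps, 1 s trials, 30 kHz waveform sampling.
def default_protocol(n_sweeps: int = 10) -> Protocol:
    return Protocol(
        directions=tuple(range(0, 360, 30)),
        has_blank=True,
        stimulus_duration_s=1.0,
        n_sweeps=n_sweeps,
        sampling_rate_hz=30_000.0,
    )


@dataclass(frozen=True)
class PopulationParams:
    """Forward-model parameters for one simulated animal."""

    n_units: int = 24
    fs_fraction: float = 0.15
    baseline_rate_hz: float = 3.0
    amplitude_hz: float = 15.0
    concentration: float = 2.5
    preferred_dirs: tuple[float, ...] | str = "uniform"
    gain_sd_evoked: float = 0.25
    gain_sd_spont: float = 0.35
    fs_gain_coupling_evoked: float = 0.1
    fs_gain_coupling_spont: float = 1.0
    probe_spacing_um: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fs_fraction <= 1.0):
            raise ValueError("fs_fraction must be in [0, 1]")
        if self.baseline_rate_hz < 0 or self.amplitude_hz < 0:
            raise ValueError("rates must be >= 0")
        if self.gain_sd_evoked < 0 or self.gain_sd_spont < 0:
            raise ValueError("gain SDs must be >= 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")

    def coupling(self, is_fs: bool, epoch: str) -> float:
        """Gain coupling of a unit for an epoch (``"evoked"`` or ``"spont"``)."""
        if not is_fs:
            return 1.0
        if epoch == "evoked":
            return self.fs_gain_coupling_evoked
        if epoch == "spont":
            return self.fs_gain_coupling_spont
        raise ValueError(f"unknown epoch {epoch!r}")

    def gain_sd(self, epoch: str) -> float:
        if epoch == "evoked":
            return self.gain_sd_evoked
        if epoch == "spont":
            return self.gain_sd_spont
        raise ValueError(f"unknown epoch {epoch!r}")


#: Group presets. Magnitudes are tuning knobs chosen only to reproduce the
#: direction of every group contrast (aged noisier / less selective, met
#: close to young with a lower baseline), not any particular printed value.
PRESETS: dict[str, PopulationParams] = {
    "young": PopulationParams(),
    "aged": PopulationParams(
        baseline_rate_hz=5.0,
        concentration=1.2,
        gain_sd_evoked=0.45,
        gain_sd_spont=0.5,
        fs_gain_coupling_evoked=1.0,
        fs_gain_coupling_spont=1.0,
    ),
    "met": PopulationParams(
        baseline_rate_hz=1.5,
        fs_gain_coupling_evoked=0.0,
    ),
}

#: FS/RS waveform template parameters: (trough_peak_ms, ratio, end_slope/ms).
FS_TEMPLATE = (0.18, 1.0, -0.06)
RS_TEMPLATE = (0.45, 0.5, -0.02)


def tuning_rate(
    direction_deg: float,
    theta1_deg: float,
    theta2_deg: float,
    k1: float,
    k2: float,
    mu: float,
    amplitude: float,
) -> float:
    """Double von Mises tuning curve evaluated at one direction (Hz).

    Sum of two von Mises densities centred at ``theta1`` and ``theta2``
    (normally 180 degrees apart) scaled by ``amplitude``, plus baseline
    ``mu``. With both concentrations zero the curve is flat at
    ``amplitude / pi + mu``.
    """
    if k1 < 0 or k2 < 0:
        raise ValueError("concentrations must be >= 0")
    x = np.deg2rad(direction_deg)
    t1 = np.deg2rad(theta1_deg)
    t2 = np.deg2rad(theta2_deg)
    vm1 = np.exp(k1 * np.cos(x - t1)) / (2.0 * np.pi * i0(k1))
    vm2 = np.exp(k2 * np.cos(x - t2)) / (2.0 * np.pi * i0(k2))
    return float(amplitude * (vm1 + vm2) + mu)


def _preferred_directions(params: PopulationParams, rng: np.random.Generator) -> np.ndarray:
    if isinstance(params.preferred_dirs, str):
        if params.preferred_dirs != "uniform":
            raise ValueError(f"unknown preferred_dirs spec {params.preferred_dirs!r}")
        base = np.linspace(0.0, 360.0, params.n_units, endpoint=False)
        jitter = rng.uniform(-10.0, 10.0, size=params.n_units)
        return (base + jitter) % 360.0
    dirs = np.asarray(params.preferred_dirs, dtype=float)
    if dirs.size != params.n_units:
        raise ValueError("preferred_dirs length must equal n_units")
    return dirs % 360.0


def unit_rates(params: PopulationParams, protocol: Protocol, pd_deg: np.ndarray) -> np.ndarray:
    """Target mean rate (Hz) per (condition, unit) under the forward model."""
    rates = np.empty((protocol.n_conditions, params.n_units))
    for ci, cond in enumerate(protocol.conditions):
        for ui in range(params.n_units):
            if cond == BLANK:
                rates[ci, ui] = params.baseline_rate_hz
            else:
                rates[ci, ui] = tuning_rate(
                    float(cond),
                    pd_deg[ui],
                    pd_deg[ui] + 180.0,
                    params.concentration,
                    params.concentration,
                    params.baseline_rate_hz,
                    params.amplitude_hz,
                )
    return rates


def simulate_recording(
    params: PopulationParams,
    protocol: Protocol | None = None,
    group_label: str = "",
    with_spike_times: bool = False,
) -> Recording:
    """Simulate one animal's recording session.

    Deterministic given ``params.seed``. FS units are drawn so their number
    equals ``round(n_units * fs_fraction)``; waveforms come from jittered
    FS/RS templates; depths follow the linear probe geometry.
    """
    if params.n_units < 2:
        raise ValueError("n_units must be >= 2 (pair statistics undefined otherwise)")
    protocol = protocol or default_protocol()
    rng = np.random.default_rng(params.seed)

    pd_deg = _preferred_directions(params, rng)
    n_fs = int(round(params.n_units * params.fs_fraction))
    fs_idx = rng.choice(params.n_units, size=n_fs, replace=False)
    is_fs = np.zeros(params.n_units, dtype=bool)
    is_fs[fs_idx] = True

    units = []
    for ui in range(params.n_units):
        tp, ratio, slope = FS_TEMPLATE if is_fs[ui] else RS_TEMPLATE
        tp = tp + rng.uniform(-0.02, 0.02)
        ratio = ratio + rng.uniform(-0.05, 0.05)
        wf = make_waveform(tp, ratio, slope, sampling_rate_hz=protocol.sampling_rate_hz)
        units.append(
            UnitRecord(
                unit_id=f"u{ui:03d}",
                channel_index=ui,
                depth_um=ui * params.probe_spacing_um,
                waveform=wf,
                group_label=group_label,
            )
        )

    rates = unit_rates(params, protocol, pd_deg)
    dur = protocol.stimulus_duration_s
    counts = np.zeros((protocol.n_conditions, protocol.n_sweeps, params.n_units), dtype=np.int64)
    spike_times: dict | None = {} if with_spike_times else None
    for ci, cond in enumerate(protocol.conditions):
        epoch = "spont" if cond == BLANK else "evoked"
        sd = params.gain_sd(epoch)
        for s in range(protocol.n_sweeps):
            g = max(rng.normal(1.0, sd), 0.0) if sd > 0 else 1.0
            for ui in range(params.n_units):
                c = params.coupling(is_fs[ui], epoch)
                lam = rates[ci, ui] * dur * max(0.0, 1.0 + c * (g - 1.0))
                n = int(rng.poisson(lam))
                counts[ci, s, ui] = n
                if spike_times is not None and n > 0:
                    spike_times[(cond, s, units[ui].unit_id)] = np.sort(
                        rng.uniform(0.0, dur, size=n)
                    )

    return Recording(protocol=protocol, units=units, counts=counts, spike_times=spike_times)


def expected_pair_rsc(
    params: PopulationParams,
    lam_a_hz: float,
    lam_b_hz: float,
    epoch: str = "evoked",
    is_fs_a: bool = False,
    is_fs_b: bool = False,
    duration_s: float = 1.0,
) -> float:
    """Analytic pairwise count correlation under the shared-gain model.

    With per-trial count rates ``la = lam_a * duration`` etc., couplings
    ``ca, cb`` and gain SD ``sg``:

        cov   = ca * cb * la * lb * sg**2
        var_i = li + ci**2 * li**2 * sg**2

    and the correlation is ``cov / sqrt(var_a * var_b)`` (law of total
    variance for a Poisson mixture).
    """
    if lam_a_hz <= 0 or lam_b_hz <= 0:
        raise ValueError("rates must be > 0")
    sg = params.gain_sd(epoch)
    ca = params.coupling(is_fs_a, epoch)
    cb = params.coupling(is_fs_b, epoch)
    la = lam_a_hz * duration_s
    lb = lam_b_hz * duration_s
    var_a = la + ca**2 * la**2 * sg**2
    var_b = lb + cb**2 * lb**2 * sg**2
    if var_a <= 0 or var_b <= 0:
        raise ValueError("zero variance: correlation undefined")
    return float(ca * cb * la * lb * sg**2 / np.sqrt(var_a * var_b))


def expected_fano(lam_hz: float, gain_sd: float, duration_s: float = 1.0, coupling: float = 1.0) -> float:
    """Analytic Fano factor of a shared-gain Poisson unit: 1 + c^2 * lam * sd^2."""
    return 1.0 + coupling**2 * lam_hz * duration_s * gain_sd**2
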