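"""Trial-structured recording data model and plain-text bundle I/O.

A :class:`Recording` holds everything one recording session produces that the
downstream analyses consume: the stimulus protocol, per-unit metadata
(probe position, mean waveform, group tag), a dense ``condition x sweep x
unit`` array of spike counts, and optionally per-trial spike times.

The on-disk representation is a directory bundle of plain-text files:

``protocol.json``
    directions (integer degrees), ``has_blank``, ``duration_s``,
    ``n_sweeps``, ``sampling_rate_hz``.
``units.tsv``
    ``unit_id  channel_index  depth_um  group_label  waveform`` where the
    waveform column is a comma-joined list of amplitude samples.
``trials.tsv``
    ``condition  sweep  unit_id  count``, one row per trial cell.
``spike_times.tsv`` (optional)
    ``condition  sweep  unit_id  time_s``, one row per spike, times relative
    to stimulus onset.

All files are UTF-8 with LF line endings and a header row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Reserved condition label for blank (gray-screen) trials.
BLANK = "BLANK"

ConditionLabel = "int | str"


class BundleFormatError(ValueError):
    """A bundle file is missing or cannot be parsed."""


class BundleIntegrityError(ValueError):
    """Bundle contents violate a Recording invariant."""


def _parse_condition(token: str) -> int | str:
    token = str(token).strip()
    if token == BLANK:
        return BLANK
    try:
        return int(token)
    except ValueError as exc:
        raise BundleFormatError(f"unparseable condition label {token!r}") from exc


@dataclass(frozen=True)
class Protocol:
    """Stimulus protocol: directions shown, trial timing, and sweep count."""

    directions: tuple[int, ...]
    has_blank: bool = True
    stimulus_duration_s: float = 1.0
    n_sweeps: int = 10
    sampling_rate_hz: float = 30_000.0

    def __post_init__(self) -> None:
        dirs = tuple(int(d) for d in self.directions)
        if len(set(dirs)) != len(dirs):
            raise ValueError("directions must be distinct")
        if any(not (0 <= d < 360) for d in dirs):
            raise ValueError("directions must lie in [0, 360)")
        if self.stimulus_duration_s <= 0:
            raise ValueError("stimulus_duration_s must be > 0")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        object.__setattr__(self, "directions", dirs)

    @property
    def conditions(self) -> tuple[int | str, ...]:
        """All condition labels in canonical order (directions, then BLANK)."""
        labels: tuple[int | str, ...] = self.directions
        if self.has_blank:
            labels = labels + (BLANK,)
        return labels

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)


@dataclass
class UnitRecord:
    """One isolated unit: identity, probe position, mean waveform, group tag."""

    unit_id: str
    channel_index: int
    depth_um: float
    waveform: np.ndarray
    group_label: str = ""

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.size < 3:
            raise ValueError(f"unit {self.unit_id}: waveform needs >= 3 samples")
        if self.depth_um < 0:
            raise ValueError(f"unit {self.unit_id}: depth_um must be >= 0")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UnitRecord):
            return NotImplemented
        return (
            self.unit_id == other.unit_id
            and self.channel_index == other.channel_index
            and self.depth_um == other.depth_um
            and self.group_label == other.group_label
            and np.array_equal(self.waveform, other.waveform)
        )


@dataclass
class Recording:
    """One session: protocol, units, and the condition x sweep x unit counts.

    ``counts[c, s, u]`` is the spike count of unit ``u`` on sweep ``s`` of
    condition ``protocol.conditions[c]``. ``spike_times`` maps
    ``(condition, sweep, unit_id)`` to an array of within-trial spike times
    in seconds; it is optional and may cover only some trials.
    """

    protocol: Protocol
    units: list[UnitRecord]
    counts: np.ndarray
    spike_times: dict[tuple[int | str, int, str], np.ndarray] | None = None
    _unit_index: dict[str, int] = field(init=False, repr=False)
    _cond_index: dict[int | str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        expected = (self.protocol.n_conditions, self.protocol.n_sweeps, len(self.units))
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        ids = [u.unit_id for u in self.units]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate unit_id")
        self._unit_index = {uid: i for i, uid in enumerate(ids)}
        self._cond_index = {c: i for i, c in enumerate(self.protocol.conditions)}

    # -- lookups ---------------------------------------------------------

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def unit_ids(self) -> list[str]:
        return [u.unit_id for u in self.units]

    def unit_index(self, unit_id: str) -> int:
        try:
            return self._unit_index[unit_id]
        except KeyError:
            raise KeyError(f"unknown unit {unit_id!r}") from None

    def condition_index(self, condition: int | str) -> int:
        try:
            return self._cond_index[condition]
        except KeyError:
            raise KeyError(f"unknown condition {condition!r}") from None

    @property
    def grating_conditions(self) -> tuple[int, ...]:
        return self.protocol.directions

    def counts_for(self, unit_id: str, condition: int | str) -> np.ndarray:
        """Spike counts of one unit across sweeps of one condition."""
        return self.counts[self.condition_index(condition), :, self.unit_index(unit_id)]

    def grating_counts(self, unit_id: str) -> dict[int, np.ndarray]:
        """Per-grating-condition trial counts for one unit."""
        return {d: self.counts_for(unit_id, d) for d in self.grating_conditions}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        same = (
            self.protocol == other.protocol
            and self.units == other.units
            and np.array_equal(self.counts, other.counts)
        )
        if not same:
            return False
        a, b = self.spike_times, other.spike_times
        if (a is None) != (b is None):
            return False
        if a is not None:
            if set(a) != set(b):
                return False
            return all(np.allclose(a[k], b[k]) for k in a)
        return True


def mean_rate(rec: Recording, unit_id: str, condition: int | str) -> float:
    """Mean firing rate (spikes/s) of a unit in a condition across sweeps."""
    counts = rec.counts_for(unit_id, condition)
    return float(np.mean(counts)) / rec.protocol.stimulus_duration_s


def spontaneous_rate(rec: Recording, unit_id: str) -> float:
    """Mean rate on blank trials (the spontaneous response)."""
    if not rec.protocol.has_blank:
        raise ValueError("recording has no blank condition")
    return mean_rate(rec, unit_id, BLANK)


def peak_rate(rec: Recording, unit_id: str) -> float:
    """Largest mean rate over grating conditions (the evoked peak response)."""
    return max(mean_rate(rec, unit_id, d) for d in rec.grating_conditions)


def optimal_condition(rec: Recording, unit_id: str) -> int:
    """Grating direction with the highest mean rate (raw argmax)."""
    return max(rec.grating_conditions, key=lambda d: mean_rate(rec, unit_id, d))


# -- bundle I/O ----------------------------------------------------------


def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a Recording as a plain-text directory bundle."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    proto = rec.protocol
    (path / "protocol.json").write_text(
        json.dumps(
            {
                "directions": list(proto.directions),
                "has_blank": proto.has_blank,
                "duration_s": proto.stimulus_duration_s,
                "n_sweeps": proto.n_sweeps,
                "sampling_rate_hz": proto.sampling_rate_hz,
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )

    with open(path / "units.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("unit_id\tchannel_index\tdepth_um\tgroup_label\twaveform\n")
        for u in rec.units:
            wf = ",".join(repr(float(v)) for v in u.waveform)
            fh.write(
                f"{u.unit_id}\t{u.channel_index}\t{repr(float(u.depth_um))}\t"
                f"{u.group_label}\t{wf}\n"
            )

    with open(path / "trials.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("condition\tsweep\tunit_id\tcount\n")
        for ci, cond in enumerate(proto.conditions):
            for s in range(proto.n_sweeps):
                for ui, u in enumerate(rec.units):
                    fh.write(f"{cond}\t{s}\t{u.unit_id}\t{int(rec.counts[ci, s, ui])}\n")

    times_path = path / "spike_times.tsv"
    if rec.spike_times is not None:
        with open(times_path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("condition\tsweep\tunit_id\ttime_s\n")
            for (cond, sweep, uid), times in sorted(
                rec.spike_times.items(), key=lambda kv: (str(kv[0][0]), kv[0][1], kv[0][2])
            ):
                for t in np.asarray(times, dtype=float):
                    fh.write(f"{cond}\t{sweep}\t{uid}\t{repr(float(t))}\n")
    elif times_path.exists():
        times_path.unlink()


def read_recording(path: str | Path) -> Recording:
    """Read a directory bundle written by :func:`write_recording`."""
    path = Path(path)
    for name in ("protocol.json", "units.tsv", "trials.tsv"):
        if not (path / name).exists():
            raise BundleFormatError(f"missing bundle file {name} in {path}")

    try:
        meta = json.loads((path / "protocol.json").read_text(encoding="utf-8"))
        protocol = Protocol(
            directions=tuple(int(d) for d in meta["directions"]),
            has_blank=bool(meta["has_blank"]),
            stimulus_duration_s=float(meta["duration_s"]),
            n_sweeps=int(meta["n_sweeps"]),
            sampling_rate_hz=float(meta["sampling_rate_hz"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise BundleFormatError(f"bad protocol.json: {exc}") from exc

    units_df = pd.read_csv(path / "units.tsv", sep="\t", dtype=str, keep_default_na=False)
    required = {"unit_id", "channel_index", "depth_um", "group_label", "waveform"}
    if not required.issubset(units_df.columns):
        raise BundleFormatError(f"units.tsv missing columns {required - set(units_df.columns)}")
    units = [
        UnitRecord(
            unit_id=row.unit_id,
            channel_index=int(row.channel_index),
            depth_um=float(row.depth_um),
            waveform=np.array([float(v) for v in row.waveform.split(",")]),
            group_label=row.group_label,
        )
        for row in units_df.itertuples()
    ]
    unit_pos = {u.unit_id: i for i, u in enumerate(units)}

    trials = pd.read_csv(path / "trials.tsv", sep="\t", dtype=str, keep_default_na=False)
    if not {"condition", "sweep", "unit_id", "count"}.issubset(trials.columns):
        raise BundleFormatError("trials.tsv missing required columns")

    cond_pos = {c: i for i, c in enumerate(protocol.conditions)}
    counts = np.full((protocol.n_conditions, protocol.n_sweeps, len(units)), -1, dtype=np.int64)
    rows = zip(trials["condition"], trials["sweep"], trials["unit_id"], trials["count"])
    for cond_tok, sweep_tok, uid, count_tok in rows:
        cond = _parse_condition(cond_tok)
        sweep = int(sweep_tok)
        n = int(count_tok)
        if cond not in cond_pos:
            raise BundleIntegrityError(f"condition {cond!r} not in protocol")
        if not (0 <= sweep < protocol.n_sweeps):
            raise BundleIntegrityError(f"sweep {sweep} out of range")
        if uid not in unit_pos:
            raise BundleIntegrityError(f"unit {uid!r} not in units.tsv")
        if n < 0:
            raise BundleIntegrityError(f"negative count at ({cond!r}, {sweep}, {uid!r})")
        ci, ui = cond_pos[cond], unit_pos[uid]
        if counts[ci, sweep, ui] != -1:
            raise BundleIntegrityError(
                f"duplicate trial row for ({cond!r}, sweep {sweep}, unit {uid!r})"
            )
        counts[ci, sweep, ui] = n
    if np.any(counts < 0):
        ci, si, ui = map(int, np.argwhere(counts < 0)[0])
        raise BundleIntegrityError(
            f"missing trial row for ({protocol.conditions[ci]!r}, sweep {si}, "
            f"unit {units[ui].unit_id!r})"
        )

    spike_times = None
    if (path / "spike_times.tsv").exists():
        st = pd.read_csv(path / "spike_times.tsv", sep="\t", dtype=str, keep_default_na=False)
        spike_times = {}
        for row in st.itertuples():
            key = (_parse_condition(row.condition), int(row.sweep), row.unit_id)
            spike_times.setdefault(key, []).append(float(row.time_s))
        spike_times = {k: np.asarray(sorted(v)) for k, v in spike_times.items()}

    return Recording(protocol=protocol, units=units, counts=counts, spike_times=spike_times)
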