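"""Domain types, validation and file I/O for IMS and GC-QEPAS sensor payloads.

Units are fixed at the boundary and never inferred: drift time in ms, GC time
in s, wavelength in um, ion current in nA, positions in m, concentrations in
ppb.  Every type validates its invariants at construction.

On-disk layout
--------------
A reading is either a single JSON document (``fmt="json"``) or a CSV trace
plus a JSON sidecar (``fmt="csv"``).  CSV headers are ``drift_time_ms,
current_nA`` for plasmagrams and ``time_s,signal`` / ``wavelength_um,signal``
for the two GC-QEPAS channels.  A scene directory holds one sub-directory per
sample: ``scene/<sample-id>/<sensor>.csv`` (+ ``.json`` sidecars) and a
``sample.json`` with the label and concentration.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence, Union

import numpy as np

__all__ = [
    "ValidationError",
    "ParseError",
    "AxisGrid",
    "Plasmagram",
    "Chromatogram",
    "IRSpectrum",
    "GCQepasPayload",
    "SensorPosition",
    "SensorReading",
    "Sample",
    "FeatureBlock",
    "LabelledDataset",
    "DEVICE_SIGMA",
    "IR_RANGE_UM",
    "read_reading",
    "write_reading",
    "read_scene",
    "write_scene",
    "assemble_dataset",
]


class ValidationError(ValueError):
    """An invariant of a domain type was violated at construction."""


class ParseError(ValueError):
    """A file could not be parsed into a valid domain object."""


AXIS_UNITS = ("ms", "s", "um")

#: Default 1-sigma position measurement error per device class (m):
#: the smallest tape division, and the laser distance meter's manual value.
DEVICE_SIGMA = {"tape": 0.01, "laser": 0.0015}

#: Spectral coverage of the photoacoustic detector (um).
IR_RANGE_UM = (7.4, 10.7)


def _as_1d_float(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite values")
    arr = arr.copy()
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True)
class AxisGrid:
    """Strictly increasing variable axis (drift time, GC time or wavelength)."""

    values: np.ndarray
    unit: str

    def __post_init__(self):
        object.__setattr__(self, "values", _as_1d_float(self.values, "axis values"))
        if self.unit not in AXIS_UNITS:
            raise ValidationError(f"axis unit must be one of {AXIS_UNITS}, got {self.unit!r}")
        if self.values.size < 2:
            raise ValidationError("axis needs at least 2 points")
        if not np.all(np.diff(self.values) > 0):
            raise ValidationError("axis values must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.values.size)

    def __eq__(self, other):
        return (
            isinstance(other, AxisGrid)
            and self.unit == other.unit
            and np.array_equal(self.values, other.values)
        )

    __hash__ = None


def _check_trace(axis: AxisGrid, signal: np.ndarray, expected_unit: str, what: str):
    if axis.unit != expected_unit:
        raise ValidationError(f"{what} axis unit must be {expected_unit!r}, got {axis.unit!r}")
    if signal.size != axis.n:
        raise ValidationError(
            f"{what} signal length {signal.size} != axis length {axis.n}"
        )


@dataclass(frozen=True)
class Plasmagram:
    """IMS trace: ion current (nA) versus drift time (ms).

    Pressure (mbar) and temperature (K) of the drift tube are carried as
    instrument context for mobility work.
    """

    drift_time: AxisGrid
    current: np.ndarray
    polarity: str = "negative"
    pressure: float = 600.0
    temperature: float = 300.0

    def __post_init__(self):
        object.__setattr__(self, "current", _as_1d_float(self.current, "current"))
        _check_trace(self.drift_time, self.current, "ms", "plasmagram")
        if self.polarity not in ("positive", "negative"):
            raise ValidationError(f"polarity must be positive/negative, got {self.polarity!r}")
        if not self.pressure > 0:
            raise ValidationError("pressure must be > 0")
        if not self.temperature > 0:
            raise ValidationError("temperature must be > 0")


@dataclass(frozen=True)
class Chromatogram:
    """GC trace: detector signal versus retention time (s)."""

    time: AxisGrid
    signal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "signal", _as_1d_float(self.signal, "signal"))
        _check_trace(self.time, self.signal, "s", "chromatogram")
        if np.any(self.time.values < 0):
            raise ValidationError("chromatogram time values must be >= 0")


@dataclass(frozen=True)
class IRSpectrum:
    """Photoacoustic IR spectrum on the mid-IR wavelength grid (um)."""

    wavelength: AxisGrid
    signal: np.ndarray
    allowed_range: tuple = IR_RANGE_UM

    def __post_init__(self):
        object.__setattr__(self, "signal", _as_1d_float(self.signal, "signal"))
        _check_trace(self.wavelength, self.signal, "um", "IR spectrum")
        lo, hi = self.allowed_range
        w = self.wavelength.values
        if w[0] < lo - 1e-9 or w[-1] > hi + 1e-9:
            raise ValidationError(
                f"wavelengths must lie within [{lo}, {hi}] um, got [{w[0]}, {w[-1]}]"
            )


@dataclass(frozen=True)
class GCQepasPayload:
    """The two channels produced by one GC-QEPAS acquisition."""

    chromatogram: Chromatogram
    spectrum: IRSpectrum


@dataclass(frozen=True)
class SensorPosition:
    """3-D sensor position relative to the scene reference point 000 (m).

    The per-axis 1-sigma measurement errors default by device class (tape or
    laser distance meter) but may be overridden per reading.
    """

    x: float
    y: float
    z: float
    device: str = "tape"
    sigma_x: float = None
    sigma_y: float = None
    sigma_z: float = None

    def __post_init__(self):
        if self.device not in DEVICE_SIGMA:
            raise ValidationError(f"device must be one of {sorted(DEVICE_SIGMA)}, got {self.device!r}")
        default = DEVICE_SIGMA[self.device]
        for name in ("sigma_x", "sigma_y", "sigma_z"):
            value = getattr(self, name)
            if value is None:
                object.__setattr__(self, name, default)
            elif not value > 0:
                raise ValidationError(f"{name} must be > 0, got {value}")
        for name in ("x", "y", "z"):
            if not np.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} must be finite")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([self.sigma_x, self.sigma_y, self.sigma_z], dtype=float)


SENSOR_KINDS = ("IMS", "GCQEPAS")


@dataclass(frozen=True)
class SensorReading:
    """One sensor acquisition: payload + position + timestamp (s)."""

    sensor: str
    timestamp: float
    position: SensorPosition
    payload: Union[Plasmagram, GCQepasPayload]

    def __post_init__(self):
        if self.sensor not in SENSOR_KINDS:
            raise ValidationError(f"sensor must be one of {SENSOR_KINDS}, got {self.sensor!r}")
        if self.sensor == "IMS" and not isinstance(self.payload, Plasmagram):
            raise ValidationError("IMS reading requires a Plasmagram payload")
        if self.sensor == "GCQEPAS" and not isinstance(self.payload, GCQepasPayload):
            raise ValidationError("GCQEPAS reading requires a GCQepasPayload payload")
        if not np.isfinite(self.timestamp):
            raise ValidationError("timestamp must be finite")


@dataclass(frozen=True)
class Sample:
    """A (possibly labelled) physical sample with its sensor readings."""

    label: str = None
    concentration: float = None
    readings: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "readings", tuple(self.readings))
        if self.concentration is not None and not self.concentration > 0:
            raise ValidationError("concentration, if present, must be > 0")
        for r in self.readings:
            if not isinstance(r, SensorReading):
                raise ValidationError("readings must be SensorReading instances")

    def reading(self, sensor: str) -> SensorReading:
        for r in self.readings:
            if r.sensor == sensor:
                return r
        raise KeyError(f"sample has no {sensor} reading")


@dataclass(frozen=True)
class FeatureBlock:
    """n_samples x n_variables matrix with preprocessing provenance."""

    name: str
    matrix: np.ndarray
    variable_axis: AxisGrid = None
    provenance: tuple = ()

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise ValidationError(f"feature matrix must be 2-D, got shape {m.shape}")
        m = m.copy()
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "provenance", tuple(self.provenance))
        if self.variable_axis is not None and self.variable_axis.n != m.shape[1]:
            raise ValidationError(
                f"variable_axis length {self.variable_axis.n} != n_variables {m.shape[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variables(self) -> int:
        return self.matrix.shape[1]

    def with_step(self, matrix: np.ndarray, step: str, variable_axis=None) -> "FeatureBlock":
        """Return a new block with ``step`` appended to the provenance."""
        return FeatureBlock(
            name=self.name,
            matrix=matrix,
            variable_axis=variable_axis,
            provenance=self.provenance + (step,),
        )


@dataclass(frozen=True)
class LabelledDataset:
    """Named feature blocks sharing rows, plus labels and concentrations."""

    blocks: Mapping[str, FeatureBlock]
    labels: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "blocks", dict(self.blocks))
        labels = np.asarray(self.labels, dtype=object)
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "concentrations", conc)
        if not self.blocks:
            raise ValidationError("dataset needs at least one block")
        n = {b.n_samples for b in self.blocks.values()}
        if len(n) != 1:
            raise ValidationError(f"blocks disagree on n_samples: {sorted(n)}")
        n = n.pop()
        if labels.size != n or conc.size != n:
            raise ValidationError("labels/concentrations length must equal n_samples")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    def subset(self, idx) -> "LabelledDataset":
        idx = np.asarray(idx)
        return LabelledDataset(
            blocks={
                k: FeatureBlock(b.name, b.matrix[idx], b.variable_axis, b.provenance)
                for k, b in self.blocks.items()
            },
            labels=self.labels[idx],
            concentrations=self.concentrations[idx],
        )


# ---------------------------------------------------------------------------
# JSON (de)serialization helpers
# ---------------------------------------------------------------------------

def _position_to_dict(p: SensorPosition) -> dict:
    return {
        "x": p.x, "y": p.y, "z": p.z, "device": p.device,
        "sigma_x": p.sigma_x, "sigma_y": p.sigma_y, "sigma_z": p.sigma_z,
    }


def _position_from_dict(d: dict) -> SensorPosition:
    try:
        return SensorPosition(
            x=float(d["x"]), y=float(d["y"]), z=float(d["z"]),
            device=d.get("device", "tape"),
            sigma_x=d.get("sigma_x"), sigma_y=d.get("sigma_y"), sigma_z=d.get("sigma_z"),
        )
    except KeyError as e:
        raise ParseError(f"position is missing required field {e.args[0]!r}") from e


def _payload_to_dict(payload) -> dict:
    if isinstance(payload, Plasmagram):
        return {
            "kind": "plasmagram",
            "drift_time_ms": payload.drift_time.values.tolist(),
            "current_nA": payload.current.tolist(),
            "polarity": payload.polarity,
            "pressure": payload.pressure,
            "temperature": payload.temperature,
        }
    return {
        "kind": "gcqepas",
        "time_s": payload.chromatogram.time.values.tolist(),
        "chromatogram_signal": payload.chromatogram.signal.tolist(),
        "wavelength_um": payload.spectrum.wavelength.values.tolist(),
        "spectrum_signal": payload.spectrum.signal.tolist(),
    }


def _payload_from_dict(d: dict):
    kind = d.get("kind")
    try:
        if kind == "plasmagram":
            return Plasmagram(
                drift_time=AxisGrid(d["drift_time_ms"], "ms"),
                current=d["current_nA"],
                polarity=d.get("polarity", "negative"),
                pressure=float(d.get("pressure", 600.0)),
                temperature=float(d.get("temperature", 300.0)),
            )
        if kind == "gcqepas":
            return GCQepasPayload(
                chromatogram=Chromatogram(AxisGrid(d["time_s"], "s"), d["chromatogram_signal"]),
                spectrum=IRSpectrum(AxisGrid(d["wavelength_um"], "um"), d["spectrum_signal"]),
            )
    except KeyError as e:
        raise ParseError(f"payload is missing required field {e.args[0]!r}") from e
    except ValidationError as e:
        raise ParseError(f"invalid payload: {e}") from e
    raise ParseError(f"unknown payload kind {kind!r}")


def _reading_to_dict(reading: SensorReading, with_traces: bool = True) -> dict:
    d = {
        "sensor": reading.sensor,
        "timestamp": reading.timestamp,
        "position": _position_to_dict(reading.position),
    }
    payload = _payload_to_dict(reading.payload)
    if not with_traces:
        for key in ("drift_time_ms", "current_nA", "time_s", "chromatogram_signal",
                    "wavelength_um", "spectrum_signal"):
            payload.pop(key, None)
    d["payload"] = payload
    return d


def _reading_from_dict(d: dict) -> SensorReading:
    for key in ("sensor", "position", "payload"):
        if key not in d:
            raise ParseError(f"reading is missing required field {key!r}")
    try:
        return SensorReading(
            sensor=d["sensor"],
            timestamp=float(d.get("timestamp", 0.0)),
            position=_position_from_dict(d["position"]),
            payload=_payload_from_dict(d["payload"]),
        )
    except ValidationError as e:
        raise ParseError(str(e)) from e


# ---------------------------------------------------------------------------
# CSV trace helpers
# ---------------------------------------------------------------------------

def _write_trace_csv(path: Path, header: tuple, cols: tuple):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in zip(*cols):
            w.writerow([repr(float(v)) for v in row])


def _read_trace_csv(path: Path, expected_header: tuple) -> tuple:
    try:
        with open(path, newline="") as fh:
            r = csv.reader(fh)
            header = next(r, None)
            if header is None or tuple(h.strip() for h in header) != expected_header:
                raise ParseError(
                    f"{path.name}: expected header {','.join(expected_header)!r}, got {header}"
                )
            rows = [row for row in r if row]
    except OSError as e:
        raise ParseError(f"cannot read {path}: {e}") from e
    try:
        cols = tuple(np.array([float(row[i]) for row in rows]) for i in range(len(expected_header)))
    except (ValueError, IndexError) as e:
        raise ParseError(f"{path.name}: malformed numeric row ({e})") from e
    return cols


def _base(path) -> Path:
    path = Path(path)
    if path.suffix in (".csv", ".json"):
        path = path.with_suffix("")
    return path


def write_reading(reading: SensorReading, path, fmt: str = "json") -> None:
    """Write a reading to ``path``; re-readable by :func:`read_reading`.

    ``fmt="json"`` writes one self-contained JSON file.  ``fmt="csv"`` treats
    ``path`` as a basename and writes the numeric trace(s) as CSV next to a
    JSON metadata sidecar.
    """
    if fmt not in ("csv", "json"):
        raise ValueError(f"fmt must be 'csv' or 'json', got {fmt!r}")
    path = Path(path)
    if fmt == "json":
        if path.suffix != ".json":
            path = path.with_suffix(".json")
        with open(path, "w") as fh:
            json.dump(_reading_to_dict(reading, with_traces=True), fh, indent=1)
        return
    base = _base(path)
    meta = _reading_to_dict(reading, with_traces=False)
    if isinstance(reading.payload, Plasmagram):
        _write_trace_csv(
            base.with_suffix(".csv"), ("drift_time_ms", "current_nA"),
            (reading.payload.drift_time.values, reading.payload.current),
        )
        meta["payload"]["trace"] = base.name + ".csv"
    else:
        _write_trace_csv(
            base.parent / (base.name + ".chromatogram.csv"), ("time_s", "signal"),
            (reading.payload.chromatogram.time.values, reading.payload.chromatogram.signal),
        )
        _write_trace_csv(
            base.parent / (base.name + ".spectrum.csv"), ("wavelength_um", "signal"),
            (reading.payload.spectrum.wavelength.values, reading.payload.spectrum.signal),
        )
        meta["payload"]["traces"] = [base.name + ".chromatogram.csv", base.name + ".spectrum.csv"]
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_reading(path, fmt: str = "json") -> SensorReading:
    """Read a reading written by :func:`write_reading`."""
    if fmt not in ("csv", "json"):
        raise ValueError(f"fmt must be 'csv' or 'json', got {fmt!r}")
    path = Path(path)
    if fmt == "json":
        if path.suffix != ".json":
            path = path.with_suffix(".json")
        try:
            with open(path) as fh:
                d = json.load(fh)
        except OSError as e:
            raise ParseError(f"cannot read {path}: {e}") from e
        except json.JSONDecodeError as e:
            raise ParseError(f"{path.name}: invalid JSON ({e})") from e
        return _reading_from_dict(d)
    base = _base(path)
    try:
        with open(base.with_suffix(".json")) as fh:
            meta = json.load(fh)
    except OSError as e:
        raise ParseError(f"cannot read sidecar {base.with_suffix('.json')}: {e}") from e
    except json.JSONDecodeError as e:
        raise ParseError(f"{base.name}.json: invalid JSON ({e})") from e
    payload = meta.get("payload", {})
    kind = payload.get("kind")
    if kind == "plasmagram":
        td, cur = _read_trace_csv(base.with_suffix(".csv"), ("drift_time_ms", "current_nA"))
        payload = dict(payload, drift_time_ms=td, current_nA=cur)
    elif kind == "gcqepas":
        t, sig = _read_trace_csv(
            base.parent / (base.name + ".chromatogram.csv"), ("time_s", "signal"))
        w, ssig = _read_trace_csv(
            base.parent / (base.name + ".spectrum.csv"), ("wavelength_um", "signal"))
        payload = dict(payload, time_s=t, chromatogram_signal=sig,
                       wavelength_um=w, spectrum_signal=ssig)
    else:
        raise ParseError(f"{base.name}.json: unknown payload kind {kind!r}")
    return _reading_from_dict(dict(meta, payload=payload))


# ---------------------------------------------------------------------------
# Scene directory I/O
# ---------------------------------------------------------------------------

_SENSOR_BASENAME = {"IMS": "ims", "GCQEPAS": "gcqepas"}


def write_scene(samples: Sequence[Sample], directory, fmt: str = "csv") -> None:
    """Write samples to ``directory`` in the scene layout."""
    samples = list(samples)
    if not samples:
        raise ValidationError("refusing to write an empty scene")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, sample in enumerate(samples):
        sdir = directory / f"sample-{i:03d}"
        sdir.mkdir(exist_ok=True)
        with open(sdir / "sample.json", "w") as fh:
            json.dump({"label": sample.label, "concentration": sample.concentration}, fh)
        for reading in sample.readings:
            write_reading(reading, sdir / _SENSOR_BASENAME[reading.sensor], fmt=fmt)


def read_scene(directory, fmt: str = "csv") -> list:
    """Read back a scene directory written by :func:`write_scene`."""
    directory = Path(directory)
    samples = []
    for sdir in sorted(p for p in directory.iterdir() if p.is_dir()):
        meta_path = sdir / "sample.json"
        if not meta_path.exists():
            continue
        with open(meta_path) as fh:
            meta = json.load(fh)
        readings = []
        for base in _SENSOR_BASENAME.values():
            if (sdir / f"{base}.json").exists():
                readings.append(read_reading(sdir / base, fmt=fmt))
        samples.append(Sample(label=meta.get("label"),
                              concentration=meta.get("concentration"),
                              readings=readings))
    if not samples:
        raise ParseError(f"no samples found under {directory}")
    return samples


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def _channel_ims(sample: Sample):
    p = sample.reading("IMS").payload
    return p.drift_time, p.current


def _channel_spectrum(sample: Sample):
    p = sample.reading("GCQEPAS").payload.spectrum
    return p.wavelength, p.signal


def _channel_chromatogram(sample: Sample):
    p = sample.reading("GCQEPAS").payload.chromatogram
    return p.time, p.signal


_CHANNELS = {
    "ims": _channel_ims,
    "spectrum": _channel_spectrum,
    "chromatogram": _channel_chromatogram,
}


def assemble_dataset(
    samples: Sequence[Sample],
    block_spec: Mapping[str, Union[str, Callable[[Sample], np.ndarray]]],
) -> LabelledDataset:
    """Stack per-sample channels into named feature blocks, one row per sample.

    ``block_spec`` maps a block name to a channel name (``"ims"``,
    ``"spectrum"``, ``"chromatogram"``) or to a callable returning a row
    vector for a sample.  All samples must share variable axes per channel;
    resample first otherwise.
    """
    samples = list(samples)
    if not samples:
        raise ValidationError("cannot assemble a dataset from zero samples")
    blocks = {}
    for name, channel in block_spec.items():
        if callable(channel):
            rows = [np.atleast_1d(np.asarray(channel(s), dtype=float)) for s in samples]
            widths = {r.size for r in rows}
            if len(widths) != 1:
                raise ValidationError(f"block {name!r}: rows have differing widths {sorted(widths)}")
            blocks[name] = FeatureBlock(name, np.vstack(rows))
            continue
        if channel not in _CHANNELS:
            raise ValidationError(
                f"block {name!r} names unknown channel {channel!r}; "
                f"expected one of {sorted(_CHANNELS)} or a callable"
            )
        extract = _CHANNELS[channel]
        try:
            axes_rows = [extract(s) for s in samples]
        except KeyError as e:
            raise ValidationError(f"block {name!r}: {e.args[0]}") from e
        axis0 = axes_rows[0][0]
        for axis, _ in axes_rows[1:]:
            if axis != axis0:
                raise ValidationError(
                    f"block {name!r}: samples have mismatched {channel} axes; "
                    "resample payloads onto a common grid first"
                )
        blocks[name] = FeatureBlock(
            name, np.vstack([row for _, row in axes_rows]), variable_axis=axis0
        )
    labels = np.array([s.label for s in samples], dtype=object)
    conc = np.array(
        [np.nan if s.concentration is None else s.concentration for s in samples], dtype=float
    )
    return LabelledDataset(blocks=blocks, labels=labels, concentrations=conc)
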