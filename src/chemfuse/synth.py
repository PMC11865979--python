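"""Seeded generator of realistic plasmagrams, chromatograms and IR spectra.

Every downstream stage of the package is testable without recorded data: the
generator emulates the signal phenomenology that matters for fusion --
concentration-dependent Gaussian analyte peaks (including a secondary DMMP
peak that appears only above a concentration gate), a reactant-ion peak that
depletes as analyte concentration rises, Gaussian retention-time scatter,
additive IR absorption bands, a slowly varying baseline drift, and white
detector noise.  It does not model ionization chemistry, photoacoustic
transduction or GC column dynamics.

The detector response follows a saturating (Langmuir-like) law
``a(c) = a_max * c / (c + c_half)``: amplitudes are monotone nondecreasing
in concentration and bounded by the detector full scale.

Determinism: identical (template, concentration, noise, seed) inputs produce
bit-identical outputs; corpus/scene generators derive independent per-sample
substreams from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .core import (
    AxisGrid,
    Chromatogram,
    GCQepasPayload,
    IRSpectrum,
    IR_RANGE_UM,
    LabelledDataset,
    Plasmagram,
    Sample,
    SensorPosition,
    SensorReading,
    ValidationError,
    assemble_dataset,
)
from .preprocess import MobilityCalibration, extract_rt

__all__ = [
    "AnalyteTemplate",
    "NoiseModel",
    "Instrument",
    "default_instrument",
    "default_noise",
    "default_templates",
    "default_concentrations",
    "load_config",
    "generate_plasmagram",
    "generate_gcqepas",
    "generate_scene",
    "generate_training_corpus",
]


@dataclass(frozen=True)
class AnalyteTemplate:
    """Signal template of one analyte across the three channels.

    ``ims_peaks`` entries are (reduced mobility in cm^2 V^-1 s^-1, relative
    amplitude, minimum concentration in ppb at which the peak appears).
    ``ir_bands`` entries are (centre um, Gaussian width um, relative
    amplitude).
    """

    name: str
    ims_peaks: tuple
    rt_mean: float
    rt_sd: float
    ir_bands: tuple

    def __post_init__(self):
        object.__setattr__(self, "ims_peaks", tuple(tuple(p) for p in self.ims_peaks))
        object.__setattr__(self, "ir_bands", tuple(tuple(b) for b in self.ir_bands))
        if not self.ims_peaks:
            raise ValidationError("template needs at least one IMS peak")
        if not self.rt_sd > 0:
            raise ValidationError("rt_sd must be > 0")
        lo, hi = IR_RANGE_UM
        for center, width, amp in self.ir_bands:
            if not (lo <= center <= hi):
                raise ValidationError(f"IR band centre {center} um outside [{lo}, {hi}]")
            if width <= 0:
                raise ValidationError("IR band width must be > 0")
        for K0, amp, min_c in self.ims_peaks:
            if K0 <= 0:
                raise ValidationError("reduced mobility must be > 0")
            if min_c < 0:
                raise ValidationError("min_concentration must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-variation model shared by all channels.

    ``baseline_sd`` and ``drift_amplitude`` are fractions of the detector
    full-scale response (white pixel noise and the amplitude of a random
    sinusoidal baseline wander emulating day-to-day/operator variation);
    ``rt_jitter_sd`` (s) is extra retention scatter on top of the template's;
    ``amplitude_jitter_sd`` is the relative standard deviation of a
    per-reading multiplicative gain factor modelling run-to-run sample
    intake/delivery variability, the dominant variation of repeated vapour
    measurements.  ``band_ratio_jitter`` is the half-range of a uniform
    per-reading factor on the intensity of the secondary IR bands relative
    to the strongest band: QEPAS source-profile and pressure-broadening
    variations change relative band intensities by a few percent between
    runs while leaving band positions fixed.
    """

    baseline_sd: float = 0.0005
    drift_amplitude: float = 0.0
    rt_jitter_sd: float = 0.0
    amplitude_jitter_sd: float = 0.02
    band_ratio_jitter: float = 0.05

    def __post_init__(self):
        for name in ("baseline_sd", "drift_amplitude", "rt_jitter_sd",
                     "amplitude_jitter_sd", "band_ratio_jitter"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


def _grid(start, stop, step, unit) -> AxisGrid:
    n = int(round((stop - start) / step)) + 1
    return AxisGrid(start + step * np.arange(n), unit)


@dataclass(frozen=True)
class Instrument:
    """Calibration constants of the emulated sensor pair."""

    drift_grid: AxisGrid = field(default_factory=lambda: _grid(5.0, 16.0, 0.02, "ms"))
    mobility_cal: MobilityCalibration = field(
        default_factory=lambda: MobilityCalibration(2.2, 10.0)
    )
    ims_full_scale_nA: float = 20.0
    ims_peak_sigma_ms: float = 0.10
    rip_max_nA: float = 12.0  # reactant-ion peak at zero analyte load
    # Fraction of the reactant-ion charge consumed by the analyte at full
    # detector response.  At trace (ppb) loads the analyte takes a
    # negligible share of the reactant-ion population, so the nominal model
    # keeps the RIP at its full amplitude (0.0); raise this to emulate the
    # charge-competition regime, where the RIP shrinks as the analyte peak
    # grows.
    rip_depletion: float = 0.0
    time_grid: AxisGrid = field(default_factory=lambda: _grid(0.0, 120.0, 0.5, "s"))
    gc_peak_sigma_s: float = 1.5
    wavelength_grid: AxisGrid = field(default_factory=lambda: _grid(7.4, 10.7, 0.01, "um"))
    ir_full_scale: float = 1.0
    response_half_ppb: float = 10.0  # Langmuir half-saturation concentration
    pressure_mbar: float = 600.0
    temperature_K: float = 300.0

    def __post_init__(self):
        if not 0.0 <= self.rip_depletion <= 1.0:
            raise ValidationError("rip_depletion must be in [0, 1]")

    def response(self, concentration: float) -> float:
        """Saturating fractional detector response in [0, 1)."""
        return concentration / (concentration + self.response_half_ppb)


def default_instrument() -> Instrument:
    return Instrument()


def _config_dict() -> dict:
    with resources.files("chemfuse.data").joinpath("templates.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_config(path=None) -> dict:
    """Load templates/noise/concentrations from YAML (package default config
    when ``path`` is None).  Returns ``{"templates": {name: AnalyteTemplate},
    "noise": NoiseModel, "concentrations": [ppb...]}``."""
    if path is None:
        raw = _config_dict()
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    templates = {}
    for name, t in raw.get("analytes", {}).items():
        templates[name] = AnalyteTemplate(
            name=name,
            ims_peaks=[
                (p["reduced_mobility"], p["relative_amplitude"], p.get("min_concentration", 0.0))
                for p in t["ims_peaks"]
            ],
            rt_mean=float(t["rt_mean"]),
            rt_sd=float(t["rt_sd"]),
            ir_bands=[
                (b["center"], b["width"], b["relative_amplitude"]) for b in t.get("ir_bands", [])
            ],
        )
    noise_raw = raw.get("noise", {})
    noise = NoiseModel(**noise_raw) if noise_raw else NoiseModel()
    return {
        "templates": templates,
        "noise": noise,
        "concentrations": [float(c) for c in raw.get("concentrations", [2.8, 5.7, 50.0, 500.0])],
    }


def default_templates() -> dict:
    return load_config()["templates"]


def default_noise() -> NoiseModel:
    return load_config()["noise"]


def default_concentrations() -> list:
    return load_config()["concentrations"]


# ---------------------------------------------------------------------------
# Trace generators
# ---------------------------------------------------------------------------

def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _baseline(rng: np.random.Generator, grid: np.ndarray, noise: NoiseModel,
              full_scale: float, with_drift: bool = False):
    """White detector noise, optionally plus a sinusoidal baseline wander.

    The wander has a fixed spatial period and amplitude with a random phase,
    emulating the slowly varying state of the IMS drift tube (temperature,
    pressure, moisture): across samples it sweeps a bounded two-dimensional
    ring, as slow periodic drifts do, rather than acting as extra white
    noise.  The QEPAS channels are generated without it (``with_drift``
    False): lock-in photoacoustic detection rejects baseline drift, and
    chromatograms are baseline-corrected by the instrument.
    """
    white = rng.normal(0.0, noise.baseline_sd * full_scale, size=grid.size)
    if not with_drift or noise.drift_amplitude == 0.0:
        return white
    span = grid[-1] - grid[0]
    phase = rng.uniform(0.0, 2.0 * np.pi)
    amplitude = noise.drift_amplitude * full_scale
    drift = amplitude * np.sin(2.0 * np.pi * (grid - grid[0]) / span + phase)
    return drift + white


def _check_concentration(concentration: float):
    if not concentration > 0:
        raise ValidationError(f"concentration must be > 0, got {concentration}")


def _gain(rng: np.random.Generator, noise: NoiseModel) -> float:
    """Per-reading multiplicative sample-delivery gain (nonnegative)."""
    return max(float(rng.normal(1.0, noise.amplitude_jitter_sd)), 0.0)


def _plasmagram_from_rng(template, concentration, noise, rng, instrument) -> Plasmagram:
    td = instrument.drift_grid.values
    response = min(instrument.response(concentration) * _gain(rng, noise), 1.0)
    current = np.zeros_like(td)
    for K0, rel_amp, min_c in template.ims_peaks:
        if concentration < min_c:
            continue
        centre = instrument.mobility_cal.drift_time_for(K0)
        current += rel_amp * response * instrument.ims_full_scale_nA * _gauss(
            td, centre, instrument.ims_peak_sigma_ms
        )
    # reactant-ion peak; shrinks with analyte response only when the
    # instrument models charge competition (rip_depletion > 0)
    rip_td = instrument.mobility_cal.reference_drift_time
    rip_amp = instrument.rip_max_nA * (1.0 - instrument.rip_depletion * response)
    current += rip_amp * _gauss(td, rip_td, instrument.ims_peak_sigma_ms)
    current += _baseline(rng, td, noise, instrument.ims_full_scale_nA, with_drift=True)
    return Plasmagram(
        drift_time=instrument.drift_grid,
        current=current,
        polarity="negative",
        pressure=instrument.pressure_mbar,
        temperature=instrument.temperature_K,
    )


def generate_plasmagram(
    template: AnalyteTemplate,
    concentration: float,
    noise: NoiseModel = None,
    seed: int = 0,
    instrument: Instrument = None,
) -> Plasmagram:
    """Plasmagram with one Gaussian peak per template mobility whose
    concentration gate is open, plus the reactant-ion peak and baseline."""
    _check_concentration(concentration)
    noise = noise or NoiseModel()
    instrument = instrument or default_instrument()
    rng = np.random.default_rng(seed)
    return _plasmagram_from_rng(template, concentration, noise, rng, instrument)


def _gcqepas_from_rng(template, concentration, noise, rng, instrument):
    response = min(instrument.response(concentration) * _gain(rng, noise), 1.0)
    apex_sd = float(np.hypot(template.rt_sd, noise.rt_jitter_sd))
    apex = rng.normal(template.rt_mean, apex_sd)
    t = instrument.time_grid.values
    chrom = response * instrument.ir_full_scale * _gauss(t, apex, instrument.gc_peak_sigma_s)
    chrom += _baseline(rng, t, noise, instrument.ir_full_scale)
    w = instrument.wavelength_grid.values
    spec = np.zeros_like(w)
    # secondary bands share one run-specific relative-intensity factor
    ratio_gain = 1.0 + rng.uniform(-noise.band_ratio_jitter, noise.band_ratio_jitter)
    for i, (center, width, rel_amp) in enumerate(template.ir_bands):
        if i > 0:
            rel_amp = rel_amp * ratio_gain
        spec += rel_amp * response * instrument.ir_full_scale * _gauss(w, center, width)
    spec += _baseline(rng, w, noise, instrument.ir_full_scale)
    return (
        Chromatogram(instrument.time_grid, chrom),
        IRSpectrum(instrument.wavelength_grid, spec),
    )


def generate_gcqepas(
    template: AnalyteTemplate,
    concentration: float,
    noise: NoiseModel = None,
    seed: int = 0,
    instrument: Instrument = None,
):
    """(Chromatogram, IRSpectrum) pair: one dominant GC peak with Gaussian
    retention scatter, and the concentration-scaled sum of IR bands."""
    _check_concentration(concentration)
    noise = noise or NoiseModel()
    instrument = instrument or default_instrument()
    rng = np.random.default_rng(seed)
    return _gcqepas_from_rng(template, concentration, noise, rng, instrument)


def noiseless_spectrum(template: AnalyteTemplate, instrument: Instrument = None) -> IRSpectrum:
    """Analytic band sum at unit response (reference/template spectrum)."""
    instrument = instrument or default_instrument()
    w = instrument.wavelength_grid.values
    spec = np.zeros_like(w)
    for center, width, rel_amp in template.ir_bands:
        spec += rel_amp * instrument.ir_full_scale * _gauss(w, center, width)
    return IRSpectrum(instrument.wavelength_grid, spec)


# ---------------------------------------------------------------------------
# Scene and corpus generators
# ---------------------------------------------------------------------------

def _sample_from_streams(template, concentration, noise, instrument, position_ims,
                         position_gc, timestamp, rng_ims, rng_gc) -> Sample:
    plasma = _plasmagram_from_rng(template, concentration, noise, rng_ims, instrument)
    chrom, spec = _gcqepas_from_rng(template, concentration, noise, rng_gc, instrument)
    return Sample(
        label=template.name,
        concentration=concentration,
        readings=(
            SensorReading("IMS", timestamp, position_ims, plasma),
            SensorReading("GCQEPAS", timestamp, position_gc, GCQepasPayload(chrom, spec)),
        ),
    )


def generate_scene(
    analytes,
    ims_position: SensorPosition,
    gc_position: SensorPosition,
    noise: NoiseModel = None,
    seed: int = 0,
    instrument: Instrument = None,
) -> list:
    """Paired IMS + GC-QEPAS readings for each (template, concentration)."""
    noise = noise or NoiseModel()
    instrument = instrument or default_instrument()
    analytes = list(analytes)
    samples = []
    streams = np.random.SeedSequence(seed).spawn(max(2 * len(analytes), 1))
    for i, (template, concentration) in enumerate(analytes):
        _check_concentration(concentration)
        samples.append(
            _sample_from_streams(
                template, concentration, noise, instrument,
                ims_position, gc_position, timestamp=10.0 * i,
                rng_ims=np.random.default_rng(streams[2 * i]),
                rng_gc=np.random.default_rng(streams[2 * i + 1]),
            )
        )
    return samples


def generate_training_corpus(
    templates,
    n_per_analyte: int,
    concentrations=None,
    seed: int = 0,
    noise: NoiseModel = None,
    instrument: Instrument = None,
) -> LabelledDataset:
    """Balanced labelled corpus: analytes x concentrations x replicates.

    ``n_per_analyte`` is the number of replicates per (analyte,
    concentration) cell, so the corpus holds ``len(templates) *
    len(concentrations) * n_per_analyte`` rows.  Blocks: ``ims`` (plasmagram
    current), ``qepas`` (IR signal) and ``rt`` (one column, apex retention
    time in s).
    """
    if isinstance(templates, dict):
        templates = list(templates.values())
    else:
        templates = list(templates)
    if n_per_analyte < 1:
        raise ValidationError("n_per_analyte must be >= 1")
    if concentrations is None:
        concentrations = default_concentrations()
    concentrations = [float(c) for c in concentrations]
    if not concentrations:
        raise ValidationError("concentration list must be nonempty")
    n_rep = n_per_analyte
    noise = noise or NoiseModel()
    instrument = instrument or default_instrument()
    position = SensorPosition(0.0, 0.0, 0.0)
    n_total = len(templates) * len(concentrations) * n_rep
    streams = np.random.SeedSequence(seed).spawn(2 * n_total)
    samples = []
    i = 0
    for template in templates:
        for c in concentrations:
            for _ in range(n_rep):
                samples.append(
                    _sample_from_streams(
                        template, c, noise, instrument, position, position,
                        timestamp=0.0,
                        rng_ims=np.random.default_rng(streams[2 * i]),
                        rng_gc=np.random.default_rng(streams[2 * i + 1]),
                    )
                )
                i += 1
    return assemble_dataset(
        samples,
        {
            "ims": "ims",
            "qepas": "spectrum",
            "rt": lambda s: [extract_rt(s.reading("GCQEPAS").payload.chromatogram)],
        },
    )
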