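"""Preprocessing operators and signal utilities.

Implements the two row/column scalings used ahead of fusion (column-wise
autoscaling for IMS matrices, row-wise standard normal variate for IR
spectra), linear grid resampling, plasmagram peak picking with the 1 nA
intensity floor, the single-reference drift-time -> reduced-mobility (K0)
conversion, and retention-time extraction from chromatograms.

Sample standard deviations (denominator n-1) are used throughout for
consistency between autoscaling and SNV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .core import AxisGrid, Chromatogram, FeatureBlock, Plasmagram, ValidationError

__all__ = [
    "AutoscaleModel",
    "autoscale_fit",
    "autoscale_apply",
    "snv",
    "snv_block",
    "resample",
    "MobilityCalibration",
    "drift_to_K0",
    "PlasmagramPeak",
    "detect_peaks",
    "extract_rt",
]

_EPS_VAR = 1e-12  # below this sample sd a column counts as zero-variance


@dataclass(frozen=True)
class AutoscaleModel:
    """Per-variable training means/sds; zero-variance columns are dropped.

    The boolean ``kept`` mask makes apply reproducible: the same columns are
    dropped at fit and at apply time.
    """

    means: np.ndarray
    sds: np.ndarray
    kept: np.ndarray

    def __post_init__(self):
        if not (self.means.shape == self.sds.shape == self.kept.shape):
            raise ValidationError("autoscale model arrays must share shape")
        if np.any(self.sds[self.kept] <= 0):
            raise ValidationError("retained variables must have sd > 0")

    @property
    def n_variables(self) -> int:
        return self.means.size


def autoscale_fit(block: FeatureBlock, rel_var_floor: float = 1e-2) -> AutoscaleModel:
    """Fit column means and sample standard deviations on training data.

    Columns whose standard deviation is below ``rel_var_floor`` times the
    largest column standard deviation are dropped (near-zero-variance
    filtering): autoscaling would otherwise inflate channels that vary by
    less than 1% of the dominant channel -- i.e. detector noise -- to the
    same unit variance as real signal.
    """
    if block.n_samples < 2:
        raise ValidationError("autoscaling needs at least 2 training samples")
    if not 0.0 <= rel_var_floor < 1.0:
        raise ValidationError("rel_var_floor must be in [0, 1)")
    means = block.matrix.mean(axis=0)
    sds = block.matrix.std(axis=0, ddof=1)
    kept = sds > max(_EPS_VAR, rel_var_floor * float(sds.max(initial=0.0)))
    if not np.any(kept):
        raise ValidationError("all columns have (near-)zero variance")
    return AutoscaleModel(means=means, sds=sds, kept=kept)


def autoscale_apply(block: FeatureBlock, model: AutoscaleModel) -> FeatureBlock:
    """Z-score each retained column with the training statistics."""
    if block.n_variables != model.n_variables:
        raise ValidationError(
            f"block has {block.n_variables} variables, model expects {model.n_variables}"
        )
    scaled = (block.matrix[:, model.kept] - model.means[model.kept]) / model.sds[model.kept]
    n_dropped = int((~model.kept).sum())
    return block.with_step(scaled, f"autoscale(n_dropped={n_dropped})")


def snv(spectrum) -> np.ndarray:
    """Standard normal variate: row-wise centre and scale to unit sample sd.

    Idempotent and invariant to positive affine rescaling of the input.
    Undefined (error) for constant spectra.
    """
    x = np.asarray(spectrum, dtype=float)
    if x.ndim != 1:
        raise ValidationError("snv expects a 1-D spectrum")
    if x.size < 2:
        raise ValidationError("snv needs at least 2 points")
    sd = x.std(ddof=1)
    if sd <= _EPS_VAR:
        raise ValidationError("SNV is undefined for a constant spectrum")
    return (x - x.mean()) / sd


def snv_block(block: FeatureBlock) -> FeatureBlock:
    """Apply SNV to every row of a block (spectra as rows)."""
    out = np.vstack([snv(row) for row in block.matrix])
    return block.with_step(out, "snv", variable_axis=block.variable_axis)


def resample(values, from_grid: AxisGrid, to_grid: AxisGrid) -> np.ndarray:
    """Linear interpolation of a trace onto a new grid (no extrapolation)."""
    values = np.asarray(values, dtype=float)
    if values.size != from_grid.n:
        raise ValidationError("values length must match from_grid")
    if from_grid.unit != to_grid.unit:
        raise ValidationError(
            f"cannot resample between units {from_grid.unit!r} and {to_grid.unit!r}"
        )
    if to_grid.values[0] < from_grid.values[0] - 1e-12 or to_grid.values[-1] > from_grid.values[-1] + 1e-12:
        raise ValidationError("to_grid extends beyond from_grid span; extrapolation refused")
    return np.interp(to_grid.values, from_grid.values, values)


@dataclass(frozen=True)
class MobilityCalibration:
    """Single-point calibration tying one reference K0 to its drift time.

    Drift time is inversely proportional to mobility at fixed tube
    conditions, so one (K0, drift time) reference pair fixes the conversion.
    """

    reference_peak_K0: float
    reference_drift_time: float

    def __post_init__(self):
        if not self.reference_peak_K0 > 0:
            raise ValidationError("reference K0 must be > 0")
        if not self.reference_drift_time > 0:
            raise ValidationError("reference drift time must be > 0")

    def drift_time_for(self, K0: float) -> float:
        """Inverse of :func:`drift_to_K0` (used by the signal generator)."""
        if not K0 > 0:
            raise ValidationError("K0 must be > 0")
        return self.reference_drift_time * self.reference_peak_K0 / K0


def drift_to_K0(drift_time: float, calib: MobilityCalibration) -> float:
    """Reduced mobility from drift time: K0 = K0_ref * td_ref / td."""
    if not drift_time > 0:
        raise ValidationError("drift time must be > 0")
    return calib.reference_peak_K0 * calib.reference_drift_time / drift_time


@dataclass(frozen=True)
class PlasmagramPeak:
    """A detected plasmagram peak with its reduced mobility."""

    drift_time: float
    intensity: float
    reduced_mobility: float

    def __post_init__(self):
        if not self.intensity > 0:
            raise ValidationError("peak intensity must be > 0")
        if not self.reduced_mobility > 0:
            raise ValidationError("reduced mobility must be > 0")


def detect_peaks(
    p: Plasmagram,
    calib: MobilityCalibration,
    min_intensity: float = 1.0,
    smooth_window: int = 5,
) -> list:
    """Local maxima of the (moving-average smoothed) trace above the floor.

    A centred moving average (default 5 points) stabilizes local-maxima
    detection on noisy traces; peaks with smoothed intensity strictly greater
    than ``min_intensity`` (default 1 nA) are returned in drift-time order,
    each annotated with its reduced mobility.
    """
    if smooth_window < 1:
        raise ValidationError("smooth_window must be >= 1")
    y = p.current
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(y, pad, mode="edge")
        y = np.convolve(padded, kernel, mode="valid")[: p.current.size]
    idx, _ = find_peaks(y)
    peaks = []
    for i in idx:
        if y[i] > min_intensity:
            td = float(p.drift_time.values[i])
            peaks.append(
                PlasmagramPeak(
                    drift_time=td,
                    intensity=float(y[i]),
                    reduced_mobility=drift_to_K0(td, calib),
                )
            )
    return peaks


def extract_rt(c: Chromatogram) -> float:
    """Retention time: apex of the globally highest chromatogram peak.

    The apex is refined below the sampling interval by fitting a parabola
    through the maximum point and its two neighbours (standard vertex
    interpolation); otherwise the retention time would be quantized to the
    chromatogram grid, aliasing run-to-run retention variability.
    """
    sig = c.signal
    if np.ptp(sig) <= 0:
        raise ValidationError("flat chromatogram: no peak to extract")
    t = c.time.values
    i = int(np.argmax(sig))
    if 0 < i < sig.size - 1:
        denom = sig[i - 1] - 2.0 * sig[i] + sig[i + 1]
        if denom < 0:  # strict local maximum: parabola vertex offset
            delta = 0.5 * (sig[i - 1] - sig[i + 1]) / denom
            if abs(delta) <= 0.5:
                step = t[i + 1] - t[i] if delta >= 0 else t[i] - t[i - 1]
                return float(t[i] + delta * step)
    return float(t[i])
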