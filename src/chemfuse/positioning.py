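"""Spatial co-location gate for sensor fusion.

Two readings may only be fused when their sensors sampled (approximately)
the same spot: per-axis separations |dx|, |dy|, |dz| and the Euclidean
distance d are computed from the sensor positions, measurement errors are
propagated in quadrature, and the gate admits the pair only when every
separation -- inflated by its propagated uncertainty, which deliberately
counts against fusion -- stays below the cutoff (1 m per axis indoors by
default).  A temporal window complements the spatial rule because a vapour
cloud disperses over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SensorPosition, SensorReading, ValidationError

__all__ = [
    "DistanceResult",
    "GateDecision",
    "GateRefusalError",
    "distance",
    "gate",
    "require_fusable",
    "DEFAULT_CUTOFF_M",
    "DEFAULT_TIME_WINDOW_S",
]

DEFAULT_CUTOFF_M = 1.0
DEFAULT_TIME_WINDOW_S = 300.0

GATE_MODES = ("per_axis", "euclidean")


class GateRefusalError(RuntimeError):
    """Raised when fusion is requested for readings that fail the gate."""

    def __init__(self, decision: "GateDecision"):
        self.decision = decision
        super().__init__(
            f"co-location gate refused fusion: separations "
            f"(dx={decision.result.dx:.3f}, dy={decision.result.dy:.3f}, "
            f"dz={decision.result.dz:.3f}) m vs cutoff {decision.cutoff} m "
            f"(mode={decision.mode})"
        )


@dataclass(frozen=True)
class DistanceResult:
    """Axis separations, Euclidean distance and propagated uncertainty (m)."""

    dx: float
    dy: float
    dz: float
    d: float
    sigma_axes: tuple
    sigma_d: float

    def __post_init__(self):
        if min(self.dx, self.dy, self.dz, self.d) < 0:
            raise ValidationError("separations must be nonnegative")


@dataclass(frozen=True)
class GateDecision:
    fused: bool
    result: DistanceResult
    cutoff: float
    mode: str
    time_delta_s: float = None


def distance(p1: SensorPosition, p2: SensorPosition) -> DistanceResult:
    """Per-axis and Euclidean separation with first-order error propagation.

    Per axis, sigma_axis = sqrt(sigma1^2 + sigma2^2); for the Euclidean
    distance, sigma_d = sqrt(sum((delta_axis/d)^2 * sigma_axis^2)), with
    sigma_d = max axis sigma in the degenerate d = 0 case.
    """
    delta = np.abs(p1.xyz - p2.xyz)
    d = float(np.linalg.norm(delta))
    sigma_axes = np.sqrt(p1.sigmas**2 + p2.sigmas**2)
    if d == 0.0:
        sigma_d = float(sigma_axes.max())
    else:
        sigma_d = float(np.sqrt(np.sum((delta / d) ** 2 * sigma_axes**2)))
    return DistanceResult(
        dx=float(delta[0]),
        dy=float(delta[1]),
        dz=float(delta[2]),
        d=d,
        sigma_axes=tuple(float(s) for s in sigma_axes),
        sigma_d=sigma_d,
    )


def gate(
    p1: SensorPosition,
    p2: SensorPosition,
    cutoff: float = DEFAULT_CUTOFF_M,
    mode: str = "per_axis",
) -> GateDecision:
    """Fuse/no-fuse decision from two sensor positions.

    ``per_axis`` (default): fused iff every axis separation plus its
    propagated sigma is strictly below the cutoff.  ``euclidean``: fused iff
    d + sigma_d < cutoff.  Uncertainty always counts against fusion.
    """
    if not cutoff > 0:
        raise ValidationError("cutoff must be > 0")
    if mode not in GATE_MODES:
        raise ValidationError(f"mode must be one of {GATE_MODES}, got {mode!r}")
    r = distance(p1, p2)
    if mode == "per_axis":
        fused = all(
            sep + sig < cutoff
            for sep, sig in zip((r.dx, r.dy, r.dz), r.sigma_axes)
        )
    else:
        fused = r.d + r.sigma_d < cutoff
    return GateDecision(fused=bool(fused), result=r, cutoff=cutoff, mode=mode)


def require_fusable(
    r1: SensorReading,
    r2: SensorReading,
    cutoff: float = DEFAULT_CUTOFF_M,
    mode: str = "per_axis",
    time_window_s: float = DEFAULT_TIME_WINDOW_S,
) -> GateDecision:
    """Gate decision for a pair of readings from two distinct sensors.

    Readings must also fall within ``time_window_s`` of each other; a stale
    pairing is treated as not co-located.  Downstream fusion refuses to run
    when the returned decision has ``fused=False``.
    """
    if r1.sensor == r2.sensor:
        raise ValidationError(
            f"co-location gate needs two distinct sensors, got {r1.sensor} twice"
        )
    decision = gate(r1.position, r2.position, cutoff=cutoff, mode=mode)
    dt = abs(r1.timestamp - r2.timestamp)
    fused = decision.fused and dt <= time_window_s
    return GateDecision(
        fused=fused,
        result=decision.result,
        cutoff=decision.cutoff,
        mode=decision.mode,
        time_delta_s=float(dt),
    )
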