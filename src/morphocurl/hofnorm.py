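"""Hof dimensionless normalization for gait quantities.

Renders mechanical quantities dimensionless using body mass ``m``, gravity
``g`` and leg length ``l0`` (hip-to-ground in quiet standing):

=================  =======================
kind               normalization
=================  =======================
force              F / (m g)
length, position   l / l0
velocity           v / sqrt(g l0)
angular_velocity   w / sqrt(g / l0)
=================  =======================

Angles (already dimensionless, rad) pass through untouched by convention;
callers simply do not route them through :func:`hof_normalize`.

Two bodies in geometrically similar states at equal Froude number
``v**2 / (g l0)`` map to identical normalized values, which is what makes a
single policy and a single reward scale transferable across body sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

ArrayLike = Union[float, np.ndarray]

_KINDS = ("force", "length", "position", "velocity", "angular_velocity")


@dataclass(frozen=True)
class HofScales:
    """Characteristic scales of one body: mass (kg), gravity (m/s^2), leg length (m)."""

    m: float
    g: float
    l0: float

    def __post_init__(self) -> None:
        for name in ("m", "g", "l0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"HofScales.{name} must be > 0, got {getattr(self, name)!r}")

    @property
    def force(self) -> float:
        return self.m * self.g

    @property
    def length(self) -> float:
        return self.l0

    @property
    def velocity(self) -> float:
        return float(np.sqrt(self.g * self.l0))

    @property
    def angular_velocity(self) -> float:
        return float(np.sqrt(self.g / self.l0))


def _scale_for(kind: str, scales: HofScales) -> float:
    if kind == "force":
        return scales.force
    if kind in ("length", "position"):
        return scales.length
    if kind == "velocity":
        return scales.velocity
    if kind == "angular_velocity":
        return scales.angular_velocity
    raise ValueError(f"unknown normalization kind {kind!r}; expected one of {_KINDS}")


def hof_normalize(value: ArrayLike, kind: str, scales: HofScales) -> ArrayLike:
    """Return ``value`` divided by the Hof scale for ``kind``."""
    return value / _scale_for(kind, scales)


def hof_denormalize(value: ArrayLike, kind: str, scales: HofScales) -> ArrayLike:
    """Exact inverse of :func:`hof_normalize`."""
    return value * _scale_for(kind, scales)


def froude_number(v: float, scales: HofScales) -> float:
    """Froude number v^2 / (g l0); equal values indicate dynamic similarity."""
    return v * v / (scales.g * scales.l0)
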