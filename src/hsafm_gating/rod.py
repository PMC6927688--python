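"""Elastic-rod estimates of thermally activated bending of a long membrane helix.

A protein α-helix is treated as a semiflexible rod with persistence length
``L_p`` (≈100 nm for α-helices) and contour length ``L``.  The bending
stiffness is ``K_S = L_p · k_BT``.  Restricting the rod to circular arcs of
radius ``r`` the stored elastic energy is

    E(r) = L_p · L / (2 r²)        [k_BT]

so the radius reachable at thermal energy ``E`` is ``r = sqrt(L_p·L/(2E))``.
The lateral movement of the rod's free end follows from arc geometry,
``d = r·(1 − cos(L/r))``, or its small-angle limit ``d = L²/(2r)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["RodModel", "bending_energy", "radius_at_energy", "end_deflection"]


@dataclass(frozen=True)
class RodModel:
    """Semiflexible rod in thermal units (energies in k_BT, lengths in nm)."""

    persistence_length: float = 100.0  # nm
    contour_length: float = 11.0  # nm

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be > 0")
        if self.contour_length <= 0:
            raise ValueError("contour_length must be > 0")


def bending_energy(rod: RodModel, radius: float) -> float:
    """Elastic energy (k_BT) of the rod bent as a circular arc of ``radius`` nm."""
    if radius <= 0:
        raise ValueError("radius of curvature must be > 0")
    return rod.persistence_length * rod.contour_length / (2.0 * radius**2)


def radius_at_energy(rod: RodModel, energy: float) -> float:
    """Radius of curvature (nm) at which the rod stores ``energy`` k_BT.

    Exact inverse of :func:`bending_energy`.
    """
    if energy <= 0:
        raise ValueError("energy must be > 0")
    return math.sqrt(rod.persistence_length * rod.contour_length / (2.0 * energy))


def end_deflection(rod: RodModel, radius: float, mode: str = "arc") -> float:
    """Lateral displacement (nm) of the free end of the bent rod.

    ``mode='arc'`` uses the exact circular-arc chord drop r·(1 − cos(L/r));
    ``mode='small_angle'`` uses the leading-order L²/(2r).  Both agree to
    first order as L/r → 0.  The model is only meaningful for bends well
    short of a quarter circle, hence the L/r < π/2 guard.
    """
    if radius <= 0:
        raise ValueError("radius of curvature must be > 0")
    theta = rod.contour_length / radius
    if theta >= math.pi / 2:
        raise ValueError("L/r >= pi/2: circular-arc small-bend model invalid")
    if mode == "arc":
        return radius * (1.0 - math.cos(theta))
    if mode == "small_angle":
        return rod.contour_length**2 / (2.0 * radius)
    raise ValueError(f"unknown mode {mode!r}")
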