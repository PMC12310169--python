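"""Magnetostatic field model of the multi-layer head solenoid.

The drive coil is described by its winding schedule (layers x turns, length,
inner winding diameter, wire gauge) and expanded into a stack of filamentary
circular loops, one per turn.  The field efficiency -- flux density per ampere
of coil current, in uT/A -- at an arbitrary (r, z) position is the
superposition of the analytic field of each loop, evaluated with complete
elliptic integrals off axis and with the textbook closed form on axis.

Conventions (configurable where the hardware drawing is ambiguous):

* the inner winding diameter names the *inner surface* of the innermost
  layer's wire, so layer k sits at radius
  ``D_in/2 + d_wire/2 + k*d_wire``;
* the turns of each layer are spread evenly over the full coil length with
  pitch ``L/turns_per_layer``, centered on z = 0 (a close-wound layer of
  4 mm wire would span only 72 mm, short of the stated 110 mm).

The hollow conductor is collapsed onto a filament at the wire center; the
current-distribution detail it discards is well below the few-percent
accuracy of interest here.  Eddy-current / proximity redistribution at kHz
frequencies is likewise not modeled, so the numbers are magnetostatic (DC)
efficiencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ellipe, ellipk

MU0 = 4e-7 * np.pi  # vacuum permeability, T*m/A

__all__ = [
    "CoilGeometry",
    "LoopStack",
    "FieldSample",
    "HEAD_SOLENOID",
    "build_loop_stack",
    "loop_field",
    "field_at",
    "efficiency_profile",
]


@dataclass(frozen=True)
class CoilGeometry:
    """Winding schedule of a layer-wound solenoid.

    Parameters
    ----------
    n_layers, turns_per_layer
        Winding counts; the product is the total number of turns.
    coil_length
        Axial extent of the winding in meters.
    inner_winding_diameter
        Diameter of the inner surface of the innermost wire layer, meters.
    wire_outer_diameter
        Outer diameter of the (possibly hollow) conductor, meters.
    """

    n_layers: int
    turns_per_layer: int
    coil_length: float
    inner_winding_diameter: float
    wire_outer_diameter: float

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.turns_per_layer < 1:
            raise ValueError("layer and turn counts must be positive integers")
        for name in ("coil_length", "inner_winding_diameter", "wire_outer_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.coil_length < self.wire_outer_diameter:
            raise ValueError("coil_length must be at least one wire diameter")

    @property
    def total_turns(self) -> int:
        return self.n_layers * self.turns_per_layer


#: The head solenoid used throughout: 3 layers x 18 turns of 4 mm hollow Cu
#: wire, 11 cm long, 27 cm inner winding diameter (54 turns total).
HEAD_SOLENOID = CoilGeometry(
    n_layers=3,
    turns_per_layer=18,
    coil_length=0.11,
    inner_winding_diameter=0.27,
    wire_outer_diameter=0.004,
)


@dataclass(frozen=True)
class LoopStack:
    """Filamentary-loop discretization of a winding: one loop per turn."""

    radii: np.ndarray  # m, shape (n_turns,)
    axial_positions: np.ndarray  # m, shape (n_turns,)

    def __post_init__(self) -> None:
        object.__setattr__(self, "radii", np.asarray(self.radii, dtype=float))
        object.__setattr__(
            self, "axial_positions", np.asarray(self.axial_positions, dtype=float)
        )
        if self.radii.shape != self.axial_positions.shape:
            raise ValueError("radii and axial_positions must have equal length")
        if np.any(self.radii <= 0):
            raise ValueError("loop radii must be > 0")

    def __len__(self) -> int:
        return self.radii.size


@dataclass(frozen=True)
class FieldSample:
    """Per-ampere field at one (r, z) position, in uT/A."""

    r: float
    z: float
    B_r: float  # uT/A
    B_z: float  # uT/A
    efficiency: float = field(default=0.0)  # |B| per ampere, uT/A

    def __post_init__(self) -> None:
        object.__setattr__(self, "efficiency", float(np.hypot(self.B_r, self.B_z)))


def build_loop_stack(geometry: CoilGeometry) -> LoopStack:
    """Expand a winding schedule into filamentary loops.

    Layer ``k`` (k = 0 .. n_layers-1) is placed at radius
    ``D_in/2 + d_wire/2 + k*d_wire`` (wire centers); each layer's turns are
    evenly spaced with pitch ``coil_length/turns_per_layer``, centered on
    z = 0, so the wire envelope spans exactly the stated coil length.
    """
    g = geometry
    n = g.turns_per_layer
    pitch = g.coil_length / n
    z = (np.arange(n) - (n - 1) / 2.0) * pitch
    radii = []
    zs = []
    for k in range(g.n_layers):
        a = g.inner_winding_diameter / 2 + g.wire_outer_diameter / 2 + k * g.wire_outer_diameter
        radii.append(np.full(n, a))
        zs.append(z)
    return LoopStack(np.concatenate(radii), np.concatenate(zs))


def loop_field(a: float, z0: float, r: float, z: float) -> tuple[float, float]:
    """Field (B_r, B_z) in tesla per ampere of a circular filament.

    The filament has radius ``a`` and lies in the plane ``z = z0``.  Off axis
    the standard complete-elliptic-integral expressions are used; on axis the
    closed form mu0*a^2 / (2*(a^2+h^2)^{3/2}).

    Raises
    ------
    ValueError
        If the evaluation point lies on the filament (field singular).
    """
    h = z - z0
    if r == 0.0:
        return 0.0, MU0 * a * a / (2.0 * (a * a + h * h) ** 1.5)
    if abs(r - a) < 1e-12 and abs(h) < 1e-12:
        raise ValueError("field evaluation point lies on a filament (singular)")
    k2 = 4.0 * a * r / ((a + r) ** 2 + h * h)
    K = ellipk(k2)
    E = ellipe(k2)
    den = (a - r) ** 2 + h * h
    pre = MU0 / (2.0 * np.pi * np.sqrt((a + r) ** 2 + h * h))
    B_z = pre * (K + (a * a - r * r - h * h) / den * E)
    B_r = pre * (h / r) * (-K + (a * a + r * r + h * h) / den * E)
    return B_r, B_z


def field_at(stack: LoopStack, r: float, z: float, min_distance: float = 1e-9) -> FieldSample:
    """Per-ampere field of the whole stack at (r, z), in uT/A.

    Superposition over all loops.  Points closer than ``min_distance`` to any
    filament are rejected (the filament field diverges there; physically the
    point would be inside the conductor).
    """
    d = np.hypot(stack.radii - r, stack.axial_positions - z)
    if np.any(d < min_distance):
        raise ValueError(
            f"evaluation point (r={r}, z={z}) lies on a filament; "
            "move at least one wire radius away from the winding"
        )
    Br = 0.0
    Bz = 0.0
    for a, z0 in zip(stack.radii, stack.axial_positions):
        br, bz = loop_field(float(a), float(z0), r, z)
        Br += br
        Bz += bz
    return FieldSample(r=r, z=z, B_r=Br * 1e6, B_z=Bz * 1e6)


def efficiency_profile(
    stack: LoopStack, axis: str, positions) -> list[FieldSample]:
    """Field-efficiency line profile along the radial (z=0) or axial (r=0) axis.

    Parameters
    ----------
    axis
        ``"radial"`` evaluates at (p, 0) for each position p; ``"axial"`` at
        (0, p).
    positions
        Offsets in meters.
    """
    if axis not in ("radial", "axial"):
        raise ValueError("axis must be 'radial' or 'axial'")
    out = []
    for p in np.asarray(positions, dtype=float):
        if axis == "radial":
            out.append(field_at(stack, float(p), 0.0))
        else:
            out.append(field_at(stack, 0.0, float(p)))
    return out
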