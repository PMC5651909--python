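"""Cantilever spring-sheet force calibration for tissue stretching.

A dissected tissue can be stretched by a spring sheet acting as a cantilever
beam clamped at one end.  For a displacement ``d`` of the free end the
restoring force follows beam theory::

    F = -(E * a^3 * b) / (4 * L^3) * d

with elastic modulus ``E`` (Pa), thickness ``a`` (m), width ``b`` (m) and
length ``L`` (m).  The sign convention is that the force opposes the
displacement; magnitudes are typically reported in micronewtons.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CantileverSpec", "cantilever_force", "cantilever_force_un"]


@dataclass(frozen=True)
class CantileverSpec:
    """Geometry and material of the spring sheet.

    Attributes
    ----------
    elastic_modulus : float
        Young's modulus ``E`` of the sheet material, in Pa.
    thickness : float
        Sheet thickness ``a`` in m (enters cubed; dominates stiffness).
    width : float
        Sheet width ``b`` in m.
    length : float
        Free cantilever length ``L`` in m (enters as ``1/L^3``).
    """

    elastic_modulus: float
    thickness: float
    width: float
    length: float

    def __post_init__(self) -> None:
        for name in ("elastic_modulus", "thickness", "width", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CantileverSpec.{name} must be strictly positive")

    @property
    def spring_constant(self) -> float:
        """Cantilever spring constant k = E a^3 b / (4 L^3), in N/m."""
        return (
            self.elastic_modulus
            * self.thickness**3
            * self.width
            / (4.0 * self.length**3)
        )


def cantilever_force(spec: CantileverSpec, displacement: float) -> float:
    """Restoring force (N) of the spring sheet for an end displacement (m).

    Returns the signed force ``F = -k d``; use :func:`cantilever_force_un`
    for the magnitude in µN as usually quoted for tissue-stretching rigs.
    """
    return -spec.spring_constant * displacement


def cantilever_force_un(spec: CantileverSpec, displacement: float) -> float:
    """Magnitude of the cantilever force in micronewtons."""
    return abs(cantilever_force(spec, displacement)) * 1e6
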