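"""Radionuclide physical constants used by the dosimetry stage.

Half-lives are stored in hours (the unit biodistribution schedules are
reported in) and converted to seconds exactly once, inside the derived
``decay_constant_per_s`` / ``half_life_s`` properties, so every product with
the decay constant or the mean energy per transition is formed in SI units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from ritpipe.errors import UnknownNuclideError, ValidationError

LN2 = math.log(2.0)
SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class Nuclide:
    """Physical constants of a radionuclide.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"Y-90"``.
    half_life_h:
        Physical half-life in hours; must be positive.
    mean_energy_per_transition:
        Mean energy emitted per nuclear transition expressed as absorbed
        dose per cumulated activity per unit mass, Gy·kg·(Bq·s)⁻¹.  Present
        only for nuclides used as dose emitters.
    """

    name: str
    half_life_h: float
    mean_energy_per_transition: float | None = None

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise ValidationError(f"half_life_h must be > 0, got {self.half_life_h}")
        if self.mean_energy_per_transition is not None and not self.mean_energy_per_transition > 0:
            raise ValidationError(
                "mean_energy_per_transition must be > 0 when present, "
                f"got {self.mean_energy_per_transition}"
            )

    @property
    def half_life_s(self) -> float:
        return self.half_life_h * SECONDS_PER_HOUR

    @property
    def decay_constant_per_s(self) -> float:
        """λ = ln 2 / t½ in s⁻¹."""
        return LN2 / self.half_life_s

    @property
    def decay_constant_per_h(self) -> float:
        return LN2 / self.half_life_h


#: Imaging / therapy pair shipped by default.  Y-90 carries the mean energy
#: per transition constant (pure β-emitter, all energy assumed locally
#: absorbed); In-111 is imaging-only and carries none.
BUILTIN_NUCLIDES: dict[str, Nuclide] = {
    "In-111": Nuclide("In-111", half_life_h=67.4),
    "Y-90": Nuclide("Y-90", half_life_h=64.1, mean_energy_per_transition=1.495e-13),
}


def builtin_nuclide(name: str) -> Nuclide:
    """Return a registered nuclide by name.

    Raises
    ------
    UnknownNuclideError
        If ``name`` is not in the built-in registry.
    """
    try:
        return BUILTIN_NUCLIDES[name]
    except KeyError:
        known = ", ".join(sorted(BUILTIN_NUCLIDES))
        raise UnknownNuclideError(f"unknown nuclide {name!r}; registered: {known}") from None


def registry_from_config(entries: Mapping[str, Mapping[str, float]] | None) -> dict[str, Nuclide]:
    """Build a nuclide registry: built-ins plus/overridden-by config entries.

    ``entries`` maps name -> {"half_life_h": float, "delta_gy_kg_per_bq_s": float | absent}.
    """
    registry = dict(BUILTIN_NUCLIDES)
    if entries:
        for name, spec in entries.items():
            registry[name] = Nuclide(
                name=name,
                half_life_h=float(spec["half_life_h"]),
                mean_energy_per_transition=(
                    float(spec["delta_gy_kg_per_bq_s"])
                    if spec.get("delta_gy_kg_per_bq_s") is not None
                    else None
                ),
            )
    return registry


def decay_factor(nuclide: Nuclide, t_h: float) -> float:
    """Fraction of activity remaining after ``t_h`` hours, e^(−λt) ∈ (0, 1].

    Raises
    ------
    ValidationError
        If ``t_h`` is negative.
    """
    if t_h < 0:
        raise ValidationError(f"elapsed time must be >= 0, got {t_h} h")
    return math.exp(-nuclide.decay_constant_per_s * t_h * SECONDS_PER_HOUR)
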