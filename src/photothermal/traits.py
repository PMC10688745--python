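"""Derived trait calculations.

Two harvest-time quality statistics are derived from the raw mass
measurements rather than measured directly:

* dry matter concentration (DMC), g dry mass per kg fresh mass — a crop
  "toning"/quality indicator;
* leaf fresh mass fraction, leaf fresh mass / total fresh mass — a
  biomass-partitioning statistic in [0, 1].
"""

from __future__ import annotations

import math

from .errors import DomainError


def compute_dmc(dry_mass_g: float, fresh_mass_g: float) -> float:
    """Dry matter concentration in g·kg⁻¹: dry/fresh × 1000.

    Requires ``fresh_mass_g > 0`` and ``0 <= dry_mass_g <= fresh_mass_g``.
    """
    if not (math.isfinite(dry_mass_g) and math.isfinite(fresh_mass_g)):
        raise DomainError("masses must be finite")
    if fresh_mass_g <= 0:
        raise DomainError(f"fresh mass must be > 0, got {fresh_mass_g}")
    if dry_mass_g < 0:
        raise DomainError(f"dry mass must be >= 0, got {dry_mass_g}")
    if dry_mass_g > fresh_mass_g:
        raise DomainError(
            f"dry mass ({dry_mass_g}) exceeds fresh mass ({fresh_mass_g})")
    return dry_mass_g / fresh_mass_g * 1000.0


def compute_leaf_mass_fraction(leaf_fresh_g: float, total_fresh_g: float) -> float:
    """Leaf fresh mass fraction in [0, 1]: leaf fresh / total fresh."""
    if not (math.isfinite(leaf_fresh_g) and math.isfinite(total_fresh_g)):
        raise DomainError("masses must be finite")
    if total_fresh_g <= 0:
        raise DomainError(f"total fresh mass must be > 0, got {total_fresh_g}")
    if leaf_fresh_g < 0:
        raise DomainError(f"leaf fresh mass must be >= 0, got {leaf_fresh_g}")
    if leaf_fresh_g > total_fresh_g:
        raise DomainError(
            f"leaf fresh mass ({leaf_fresh_g}) exceeds total ({total_fresh_g})")
    return leaf_fresh_g / total_fresh_g
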