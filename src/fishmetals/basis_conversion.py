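"""Wet-weight <-> dry-weight conversion of tissue concentrations.

A concentration on a wet-weight basis relates to its dry-weight counterpart
through the tissue moisture fraction ``m``::

    C_dw = C_ww / (1 - m)          C_ww = C_dw * (1 - m)

Moisture is never guessed: the study reports it only for muscle (0.832) and
liver (0.805), so converting gills or guts requires the caller to supply a
fraction explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .core_data import Concentration, TISSUES, ValidationError

__all__ = [
    "MoistureSpec",
    "BasisError",
    "MoistureError",
    "moisture_for",
    "to_dry",
    "to_wet",
    "convert",
]

log = logging.getLogger(__name__)


class BasisError(ValueError):
    """A conversion was requested for a concentration already on that basis."""


class MoistureError(ValueError):
    """No moisture fraction is available (or the supplied one is invalid)."""


@dataclass(frozen=True)
class MoistureSpec:
    """Moisture fraction for a tissue; overrides of the fixtures are logged."""

    tissue: str
    moisture_fraction: float

    def __post_init__(self) -> None:
        _check_m(self.moisture_fraction)
        default = TISSUES.get(self.tissue)
        if default is not None and default.moisture_fraction is not None:
            if self.moisture_fraction != default.moisture_fraction:
                log.warning(
                    "moisture override for %s: %.4f (study value %.4f)",
                    self.tissue, self.moisture_fraction, default.moisture_fraction,
                )


def _check_m(m: float) -> None:
    if not (0.0 <= m < 1.0):
        raise MoistureError(f"moisture fraction must be in [0,1): {m!r}")


def moisture_for(tissue: str, override: float | None = None) -> float:
    """Resolve the moisture fraction for a tissue.

    Returns ``override`` if given (validated and logged), else the study
    value; raises :class:`MoistureError` for tissues without one (gills, guts).
    """
    if override is not None:
        return MoistureSpec(tissue, override).moisture_fraction
    t = TISSUES.get(tissue)
    if t is None or t.moisture_fraction is None:
        raise MoistureError(
            f"no moisture fraction known for tissue {tissue!r}; supply one explicitly"
        )
    return t.moisture_fraction


def to_dry(c: Concentration, m: float) -> Concentration:
    """Convert a wet-weight concentration to dry weight: value / (1 - m)."""
    _check_m(m)
    if c.basis != "ww":
        raise BasisError(f"to_dry expects a ww concentration, got basis {c.basis!r}")
    return Concentration(c.value / (1.0 - m), "dw")


def to_wet(c: Concentration, m: float) -> Concentration:
    """Convert a dry-weight concentration to wet weight: value * (1 - m)."""
    _check_m(m)
    if c.basis != "dw":
        raise BasisError(f"to_wet expects a dw concentration, got basis {c.basis!r}")
    return Concentration(c.value * (1.0 - m), "ww")


def convert(c: Concentration, basis: str, m: float) -> Concentration:
    """Convert ``c`` to ``basis`` (no-op if already there)."""
    if basis not in ("ww", "dw"):
        raise ValidationError(f"basis must be 'ww' or 'dw': {basis!r}")
    if c.basis == basis:
        return c
    return to_dry(c, m) if basis == "dw" else to_wet(c, m)
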