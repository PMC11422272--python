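"""Maximum-permissible-limit registry and compliance checking.

The registry holds the food-safety limits the study compares against
(all expressed wet weight): Mexico-NOM Cd 0.5, EU Cd 0.3, US-FDA Cd 0.5 and
Pb 1.3, Australia Cu 10 and Zn 150, India Cu 10 and Zn 50 µg/g ww.
Because tissue concentrations are usually reported dry weight, each limit
can be re-expressed in dw through the muscle moisture fraction; the
``display`` form reproduces the precision such converted limits are
conventionally quoted at (e.g. EU Cd 1.8, US-FDA Pb 7.74, Australia Zn
900 µg/g dw).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .basis_conversion import convert, to_dry
from .core_data import Concentration, load_fixtures

__all__ = [
    "RegulatoryLimit",
    "ComplianceVerdict",
    "load_limits",
    "limit_in_dw",
    "check_compliance",
    "round_sig",
]


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class RegulatoryLimit:
    jurisdiction: str
    metal: str
    limit: float  # µg/g
    basis: str = "ww"
    display_sigfigs: int = 2


@dataclass(frozen=True)
class ComplianceVerdict:
    compliant: bool          # non-strict: value exactly at the limit passes
    margin: float            # limit - concentration, on the comparison basis
    basis: str               # basis the comparison was made on


def load_limits() -> list[RegulatoryLimit]:
    """The registry, read from the packaged ``limits.yaml``."""
    return [
        RegulatoryLimit(
            jurisdiction=e["jurisdiction"],
            metal=e["metal"],
            limit=float(e["limit"]),
            basis=e["basis"],
            display_sigfigs=int(e["display_sigfigs"]),
        )
        for e in load_fixtures().limits
    ]


def limit_in_dw(limit: RegulatoryLimit, m: float) -> tuple[float, float]:
    """Re-express a wet-weight limit on dry weight.

    Returns ``(raw, display)`` where ``raw = limit / (1 - m)`` and
    ``display`` is rounded to the limit's registered significant figures.
    """
    raw = to_dry(Concentration(limit.limit, limit.basis), m).value
    return raw, round_sig(raw, limit.display_sigfigs)


def check_compliance(
    c: Concentration, limit: RegulatoryLimit, m: float | None = None
) -> ComplianceVerdict:
    """Compare a concentration against a limit on a common basis.

    If the bases differ the concentration is converted to the limit's basis,
    which requires a moisture fraction ``m``. The verdict is independent of
    which basis ``c`` was supplied in (given the same ``m``).
    """
    if c.basis != limit.basis:
        if m is None:
            raise ValueError(
                f"concentration is {c.basis} but limit is {limit.basis}; "
                "a moisture fraction is required"
            )
        c = convert(c, limit.basis, m)
    return ComplianceVerdict(
        compliant=c.value <= limit.limit,
        margin=limit.limit - c.value,
        basis=limit.basis,
    )
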