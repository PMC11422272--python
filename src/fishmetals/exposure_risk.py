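"""Dietary exposure-risk engine: THQ, HI, CDI, CR and PTI-based safe intake.

Model
-----
Non-carcinogenic risk is the target hazard quotient per metal,

    THQ = (EF · ED · FIR · C) · 10⁻³ / (RfD · BW · AT)

with EF the exposure frequency (365 days/year), ED the exposure duration
(70 years), FIR the fish ingestion rate (g/day), C the mean metal
concentration in edible tissue (mg/kg wet weight), RfD the oral reference
dose (mg/kg BW/day), BW the body weight (kg) and AT the averaging time in
days. The 10⁻³ converts FIR from grams to kilograms. The hazard index is
HI = ΣTHQ; a THQ or HI above 1 flags potential risk.

Carcinogenic risk uses the chronic daily intake CDI = C · FIR · 10⁻³ / BW
(mg/kg BW/day) and a slope factor: CR = CDI · SF (Cd and Pb only).

The maximum tolerable weekly intake of edible tissue inverts a provisional
tolerable intake (PTI, per kg BW over a stated period):

    intake (g/week) = PTI_daily (µg/kg BW/day) · 7 · BW / C (µg/g ww)

Monthly PTIs (Cd, 25 µg/kg BW/month) are normalised with 30 days/month.

Constants and conventions follow the source study verbatim, including
AT = 25,500 days (even though EF·ED = 25,550) and the elected protective
Pb value of 0.01 µg/kg BW/day used as both RfD and PTI. Cu has no RfD
("not evaluated") — a THQ request for Cu yields an explicit
:class:`Unevaluated` outcome, never 0 or NaN; likewise CR for metals
without a slope factor.

Population strata (BW kg): men 75, women 65, teenagers 50, children 20.
Consumption scenarios (g/day): FIR1 5.7 (tilapia-specific national intake),
FIR2 33.1 (total national fish intake).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .core_data import Concentration, load_fixtures
from .regulatory import round_sig

__all__ = [
    "ExposureConstants",
    "PopulationStratum",
    "IntakeScenario",
    "ToxProfile",
    "Unevaluated",
    "RiskCell",
    "RiskReport",
    "load_exposure_inputs",
    "thq",
    "hazard_index",
    "cdi",
    "cancer_risk",
    "safe_weekly_intake",
    "risk_matrix",
    "format_quotient",
    "format_cr",
    "format_weekly_intake",
    "conc_from_thq",
    "conc_from_cr",
    "back_derived_pb_grand_mean",
    "conc_from_safe_intake",
]


# ---------------------------------------------------------------------------
# Inputs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureConstants:
    EF: float = 365.0     # days/year
    ED: float = 70.0      # years
    AT: float = 25500.0   # days (study value, kept verbatim)


@dataclass(frozen=True)
class PopulationStratum:
    label: str
    BW: float  # kg


@dataclass(frozen=True)
class IntakeScenario:
    label: str
    FIR: float       # g/day
    weekly_g: float
    annual_kg: float

    def __post_init__(self) -> None:
        # the daily and weekly forms both derive from the annual per-capita rate
        if round(self.annual_kg * 1000.0 / 365.0, 1) != round(self.FIR, 1):
            raise ValueError(f"{self.label}: daily rate inconsistent with annual_kg")
        if round(self.annual_kg * 7000.0 / 365.0, 1) != round(self.weekly_g, 1):
            raise ValueError(f"{self.label}: weekly rate inconsistent with annual_kg")


@dataclass(frozen=True)
class ToxProfile:
    """Per-metal toxicology: RfD, slope factor, and PTI with its period."""

    metal: str
    rfd: float | None = None           # mg/kg BW/day; None = not evaluated
    sf: float | None = None            # per mg/kg BW/day; None = not classified
    pti_value: float | None = None
    pti_unit: str | None = None        # "ug" | "mg"
    pti_period: str | None = None      # "day" | "month"

    def pti_daily_ug(self, days_per_month: float = 30.0) -> float:
        """PTI normalised to µg per kg BW per day."""
        if self.pti_value is None:
            raise ValueError(f"no PTI for {self.metal}")
        v = self.pti_value * (1000.0 if self.pti_unit == "mg" else 1.0)
        if self.pti_period == "month":
            v /= days_per_month
        elif self.pti_period != "day":
            raise ValueError(f"unknown PTI period {self.pti_period!r}")
        return v


@dataclass(frozen=True)
class Unevaluated:
    """Explicit outcome where toxicology provides no constant (no RfD / no SF)."""

    metal: str
    reason: str

    def __bool__(self) -> bool:  # keeps `if result:` honest
        return False


def load_exposure_inputs(tox: Mapping | None = None):
    """Build (constants, strata, scenarios, profiles, days_per_month) from
    the packaged ``tox_constants.yaml`` (or an override mapping of the same
    shape)."""
    if tox is None:
        tox = load_fixtures().tox
    exp = tox["exposure"]
    constants = ExposureConstants(
        EF=float(exp["EF_days_per_year"]), ED=float(exp["ED_years"]), AT=float(exp["AT_days"])
    )
    strata = [PopulationStratum(k, float(v)) for k, v in tox["strata"].items()]
    scenarios = [
        IntakeScenario(k, float(v["daily_g"]), float(v["weekly_g"]), float(v["annual_kg"]))
        for k, v in tox["scenarios"].items()
    ]
    rfd = tox["rfd_mg_per_kg_day"]
    sf = tox["slope_factor_per_mg_kg_day"]
    pti = tox["pti"]
    profiles = {}
    for metal in ("Cd", "Cu", "Pb", "Zn"):
        p = pti.get(metal)
        profiles[metal] = ToxProfile(
            metal=metal,
            rfd=None if rfd.get(metal) is None else float(rfd[metal]),
            sf=None if sf.get(metal) is None else float(sf[metal]),
            pti_value=None if p is None else float(p["value"]),
            pti_unit=None if p is None else p["unit"],
            pti_period=None if p is None else p["period"],
        )
    return constants, strata, scenarios, profiles, float(tox.get("days_per_month", 30))


# ---------------------------------------------------------------------------
# Core quotients
# ---------------------------------------------------------------------------

def thq(
    C: float,
    FIR: float,
    BW: float,
    rfd: float | None,
    constants: ExposureConstants = ExposureConstants(),
    metal: str = "?",
) -> float | Unevaluated:
    """Target hazard quotient; C in mg/kg ww, FIR in g/day, BW in kg."""
    if rfd is None:
        return Unevaluated(metal, "no reference dose")
    if C < 0 or FIR < 0:
        raise ValueError("C and FIR must be non-negative")
    if rfd <= 0 or BW <= 0:
        raise ValueError("RfD and BW must be positive")
    return (constants.EF * constants.ED * FIR * C * 1e-3) / (rfd * BW * constants.AT)


def hazard_index(thqs: Iterable[float | Unevaluated]) -> float:
    """HI = sum of finite THQs; Unevaluated entries are excluded."""
    vals = [t for t in thqs if not isinstance(t, Unevaluated)]
    if not vals:
        raise ValueError("hazard_index needs at least one evaluated THQ")
    return float(sum(vals))


def cdi(C: float, FIR: float, BW: float) -> float:
    """Chronic daily intake, mg/kg BW/day; C in mg/kg ww, FIR in g/day."""
    if C < 0 or FIR < 0:
        raise ValueError("C and FIR must be non-negative")
    if BW <= 0:
        raise ValueError("BW must be positive")
    return C * FIR * 1e-3 / BW


def cancer_risk(cdi_value: float, sf: float | None, metal: str = "?") -> float | Unevaluated:
    """Lifetime incremental cancer risk CR = CDI × SF."""
    if sf is None:
        return Unevaluated(metal, "not classified as carcinogen")
    return cdi_value * sf


def safe_weekly_intake(
    C: float,
    profile: ToxProfile,
    BW: float,
    days_per_month: float = 30.0,
) -> float:
    """Maximum tolerable weekly intake of edible tissue, g/week.

    Inverts the weekly allowance 7 · PTI_daily · BW (µg/week) at tissue
    concentration ``C`` (µg/g ww). ``C = 0`` means no constraint and
    returns ``inf`` (flagged, not raised).
    """
    if BW <= 0:
        raise ValueError("BW must be positive")
    allowance_ug = profile.pti_daily_ug(days_per_month) * 7.0 * BW
    if C == 0:
        return math.inf
    if C < 0:
        raise ValueError("C must be non-negative")
    return allowance_ug / C


# ---------------------------------------------------------------------------
# Display formatting (study conventions)
# ---------------------------------------------------------------------------

def format_quotient(x: float) -> str:
    """THQ/HI display: two decimals, with a '< 0.01' floor below 0.005."""
    if x < 0.005:
        return "< 0.01"
    return f"{x:.2f}"


def format_weekly_intake(g: float) -> str:
    """Safe-intake display: 0.1-kg precision, grams when below a kilogram."""
    if math.isinf(g):
        return "no constraint"
    if g < 1000.0:
        return f"{g:.1f} g"
    return f"{g / 1000.0:.1f} kg"


def format_cr(x: float) -> str:
    """CR display: two significant figures, scientific notation."""
    if x == 0:
        return "0"
    return f"{round_sig(x, 2):.1e}"


# ---------------------------------------------------------------------------
# Full matrix
# ---------------------------------------------------------------------------

@dataclass
class RiskCell:
    """One (stratum, scenario) cell of the risk report."""

    stratum: str
    scenario: str
    thq: dict[str, float | Unevaluated]
    hi: float
    cr: dict[str, float | Unevaluated]
    flagged: bool                      # any THQ > 1 or HI > 1
    flagged_metals: list[str]

    @property
    def thq_display(self) -> dict[str, str]:
        return {
            m: (v.reason if isinstance(v, Unevaluated) else format_quotient(v))
            for m, v in self.thq.items()
        }

    @property
    def hi_display(self) -> str:
        return format_quotient(self.hi)

    @property
    def cr_display(self) -> dict[str, str]:
        return {
            m: (v.reason if isinstance(v, Unevaluated) else format_cr(v))
            for m, v in self.cr.items()
        }


@dataclass
class RiskReport:
    """Risk matrix over strata × scenarios plus per-stratum safe intakes."""

    cells: list[RiskCell]
    safe_intake_g: dict[tuple[str, str], float]  # (metal, stratum) -> g/week
    excluded_thq: list[str] = field(default_factory=list)  # metals with no RfD

    def cell(self, stratum: str, scenario: str) -> RiskCell:
        for c in self.cells:
            if c.stratum == stratum and c.scenario == scenario:
                return c
        raise KeyError((stratum, scenario))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table with raw and display values."""
        rows = []
        for c in self.cells:
            for m, v in c.thq.items():
                raw = None if isinstance(v, Unevaluated) else v
                rows.append(
                    dict(index=f"THQ_{m}", stratum=c.stratum, scenario=c.scenario,
                         raw=raw, display=c.thq_display[m])
                )
            rows.append(
                dict(index="HI", stratum=c.stratum, scenario=c.scenario,
                     raw=c.hi, display=c.hi_display)
            )
            for m, v in c.cr.items():
                raw = None if isinstance(v, Unevaluated) else v
                rows.append(
                    dict(index=f"CR_{m}", stratum=c.stratum, scenario=c.scenario,
                         raw=raw, display=c.cr_display[m])
                )
        for (m, stratum), g in self.safe_intake_g.items():
            rows.append(
                dict(index=f"SafeWeekly_{m}", stratum=stratum, scenario="-",
                     raw=g, display=format_weekly_intake(g))
            )
        return pd.DataFrame(rows)


def risk_matrix(
    grand_means_ww: Mapping[str, Concentration],
    profiles: Mapping[str, ToxProfile],
    strata: Iterable[PopulationStratum],
    scenarios: Iterable[IntakeScenario],
    constants: ExposureConstants = ExposureConstants(),
    days_per_month: float = 30.0,
) -> RiskReport:
    """Full risk report from wet-weight grand-mean concentrations.

    Per-metal "no RfD" / "no SF" outcomes are carried through as
    :class:`Unevaluated` cells without aborting the matrix; HI sums only the
    evaluated THQs and the excluded metals are listed on the report.
    """
    for m, c in grand_means_ww.items():
        if c.basis != "ww":
            raise ValueError(
                f"grand mean for {m} is on {c.basis}; convert to ww first"
            )
    strata = list(strata)
    scenarios = list(scenarios)
    cells = []
    excluded = sorted(
        m for m in grand_means_ww if m in profiles and profiles[m].rfd is None
    )
    for st in strata:
        for sc in scenarios:
            thqs = {
                m: thq(c.value, sc.FIR, st.BW, profiles[m].rfd, constants, metal=m)
                for m, c in grand_means_ww.items()
            }
            crs = {
                m: cancer_risk(cdi(c.value, sc.FIR, st.BW), profiles[m].sf, metal=m)
                for m, c in grand_means_ww.items()
                if profiles[m].sf is not None
            }
            hi = hazard_index(thqs.values())
            flagged_metals = [
                m for m, v in thqs.items()
                if not isinstance(v, Unevaluated) and v > 1.0
            ]
            cells.append(
                RiskCell(
                    stratum=st.label, scenario=sc.label, thq=thqs, hi=hi, cr=crs,
                    flagged=bool(flagged_metals) or hi > 1.0,
                    flagged_metals=flagged_metals,
                )
            )
    safe = {
        (m, st.label): safe_weekly_intake(c.value, profiles[m], st.BW, days_per_month)
        for m, c in grand_means_ww.items()
        if profiles[m].pti_value is not None
        for st in strata
    }
    return RiskReport(cells=cells, safe_intake_g=safe, excluded_thq=excluded)


# ---------------------------------------------------------------------------
# Back-derivation (inverting printed risk values to a concentration)
# ---------------------------------------------------------------------------

def conc_from_thq(
    thq_value: float, FIR: float, BW: float, rfd: float,
    constants: ExposureConstants = ExposureConstants(),
) -> float:
    """Concentration (mg/kg ww) implied by a THQ value."""
    return thq_value * rfd * BW * constants.AT / (constants.EF * constants.ED * FIR * 1e-3)


def conc_from_cr(cr_value: float, FIR: float, BW: float, sf: float) -> float:
    """Concentration (mg/kg ww) implied by a cancer-risk value."""
    return cr_value * BW / (FIR * 1e-3 * sf)


def back_derived_pb_grand_mean(
    constants: ExposureConstants | None = None,
) -> Concentration:
    """Pb muscle grand mean (µg/g ww) reconstructed from published indices.

    The Pb muscle concentration is never printed; it is implied by the
    published THQ_Pb for men under the tilapia-specific scenario (0.29 at
    FIR 5.7 g/day, BW 75 kg, RfD 1e-5 mg/kg BW/day). Computed at run time
    from the packaged expected-risk fixture.
    """
    fx = load_fixtures()
    t2 = fx.table2_expected
    row = t2[(t2.risk_index == "THQ_Pb") & (t2.scenario == "FIR1") & (t2.stratum == "men")]
    thq_pb = float(row.display.iloc[0])
    _, _, scenarios, profiles, _ = load_exposure_inputs(fx.tox)
    fir1 = next(s.FIR for s in scenarios if s.label == "FIR1")
    bw_men = float(fx.tox["strata"]["men"])
    c = conc_from_thq(thq_pb, fir1, bw_men, profiles["Pb"].rfd,
                      constants or ExposureConstants())
    return Concentration(c, "ww")


def conc_from_safe_intake(
    intake_g: float, profile: ToxProfile, BW: float, days_per_month: float = 30.0
) -> float:
    """Concentration (µg/g ww) implied by a safe weekly intake figure."""
    return profile.pti_daily_ug(days_per_month) * 7.0 * BW / intake_g
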