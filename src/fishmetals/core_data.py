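"""Domain types, packaged study fixtures, and specimen-table ingest.

The study design this package models: blue tilapia (*Oreochromis aureus*)
collected from 11 reservoirs (dams) in a mining-influenced watershed over
two seasons (dry, rainy); four tissues (muscle, gills, liver, guts) analysed
for four metals (Cd, Cu, Pb, Zn). Concentrations are in µg/g and always
carry an explicit wet-weight (``ww``) or dry-weight (``dw``) basis.

Packaged fixtures (``fishmetals/data``):

* ``table1_dams.csv`` — reservoir metadata (area, storage capacity,
  fishermen, mining sites per sub-basin, geothermal influence).
* ``table3_summaries.csv`` — per-dam mean ± SD muscle and liver
  concentrations (µg/g dw) of Cd, Cu and Zn.
* ``table2_expected.csv`` — published risk-index display values, used only
  by tests as expected output.
* ``tox_constants.yaml`` / ``limits.yaml`` — toxicological constants and
  regulatory limits (see :mod:`fishmetals.exposure_risk`,
  :mod:`fishmetals.regulatory`).

Fixture integrity is asserted on load through the published aggregate
totals (storage capacity, surface area, fishermen, basin-deduplicated
mining-site count).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "METALS",
    "TISSUES",
    "SEASONS",
    "SEXES",
    "DAM_IDS",
    "Metal",
    "Tissue",
    "Concentration",
    "SpecimenRecord",
    "DamMetadata",
    "TissueSummary",
    "Fixtures",
    "ReadResult",
    "RejectedRow",
    "SchemaError",
    "ValidationError",
    "FixtureError",
    "read_specimens",
    "write_specimens",
    "load_fixtures",
    "grand_mean",
]


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """A value violates a domain-type invariant."""


class FixtureError(RuntimeError):
    """A packaged fixture failed its integrity checksum."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Metal:
    """One of the four study metals; ``essential`` marks Cu/Zn as nutrients."""

    code: str
    essential: bool


METALS: Mapping[str, Metal] = {
    "Cd": Metal("Cd", essential=False),
    "Cu": Metal("Cu", essential=True),
    "Pb": Metal("Pb", essential=False),
    "Zn": Metal("Zn", essential=True),
}


@dataclass(frozen=True)
class Tissue:
    """A sampled tissue; moisture_fraction is set only where reported."""

    name: str
    moisture_fraction: float | None = None

    def __post_init__(self) -> None:
        m = self.moisture_fraction
        if m is not None and not (0.0 <= m < 1.0):
            raise ValidationError(f"moisture_fraction must be in [0,1): {m!r}")


TISSUES: Mapping[str, Tissue] = {
    "muscle": Tissue("muscle", moisture_fraction=0.832),
    "gills": Tissue("gills"),
    "liver": Tissue("liver", moisture_fraction=0.805),
    "guts": Tissue("guts"),
}

SEASONS = ("dry", "rainy")
SEXES = ("F", "M", "unknown")
DAM_IDS = tuple(range(1, 12))


@dataclass(frozen=True)
class Concentration:
    """A tissue metal concentration in µg/g with an explicit basis."""

    value: float
    basis: str  # "ww" | "dw"

    def __post_init__(self) -> None:
        if self.basis not in ("ww", "dw"):
            raise ValidationError(f"basis must be 'ww' or 'dw': {self.basis!r}")
        if not math.isfinite(self.value) or self.value < 0:
            raise ValidationError(
                f"concentration must be finite and non-negative: {self.value!r}"
            )


@dataclass
class SpecimenRecord:
    """One fish: provenance, biometrics, and per-tissue metal concentrations."""

    dam_id: int
    season: str
    sex: str
    total_length_cm: float
    weight_g: float
    concentrations: dict[str, dict[str, Concentration]]
    specimen_id: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.dam_id not in DAM_IDS:
            raise ValidationError(f"dam_id out of 1..11: {self.dam_id!r}")
        if self.season not in SEASONS:
            raise ValidationError(f"season must be dry|rainy: {self.season!r}")
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be F|M|unknown: {self.sex!r}")
        if not (self.total_length_cm > 0):
            raise ValidationError(f"total_length_cm must be > 0: {self.total_length_cm!r}")
        if not (self.weight_g > 0):
            raise ValidationError(f"weight_g must be > 0: {self.weight_g!r}")
        if not self.concentrations:
            raise ValidationError("at least one tissue must be present")
        for tissue, metals in self.concentrations.items():
            if tissue not in TISSUES:
                raise ValidationError(f"unknown tissue: {tissue!r}")
            for metal, conc in metals.items():
                if metal not in METALS:
                    raise ValidationError(f"unknown metal: {metal!r}")
                if not isinstance(conc, Concentration):
                    raise ValidationError(f"{tissue}/{metal}: not a Concentration")


@dataclass(frozen=True)
class DamMetadata:
    """Reservoir-level metadata.

    ``basin_group`` deduplicates mining-site counts shared by dams draining
    the same upstream basin; ``annual_production_t`` is kept verbatim (a
    range string) and never parsed.
    """

    dam_id: int
    name: str
    river: str
    area_ha: float
    capacity_Mm3: float
    mining_sites: int
    basin_group: str
    geothermal: bool
    fishermen: int | None = None
    annual_production_t: str | None = None
    water_temp_c: str | None = None

    def __post_init__(self) -> None:
        if self.dam_id not in DAM_IDS:
            raise ValidationError(f"dam_id out of 1..11: {self.dam_id!r}")
        if self.mining_sites < 0:
            raise ValidationError("mining_sites must be non-negative")
        if self.fishermen is not None and self.fishermen < 0:
            raise ValidationError("fishermen must be non-negative")


@dataclass(frozen=True)
class TissueSummary:
    """Per-dam mean ± SD concentration for one (tissue, metal)."""

    dam_id: int
    tissue: str
    metal: str
    mean: float
    sd: float
    basis: str

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(f"sd must be >= 0: {self.sd!r}")
        if self.basis not in ("ww", "dw"):
            raise ValidationError(f"basis must be 'ww' or 'dw': {self.basis!r}")


# ---------------------------------------------------------------------------
# Specimen ingest
# ---------------------------------------------------------------------------

#: canonical column names of the long (one row per specimen-tissue-metal) layout
LONG_COLUMNS = (
    "specimen_id",
    "dam_id",
    "season",
    "sex",
    "total_length_cm",
    "weight_g",
    "tissue",
    "metal",
    "value",
    "basis",
)


@dataclass(frozen=True)
class RejectedRow:
    line: int
    message: str


@dataclass
class ReadResult:
    """Outcome of an ingest: parsed records plus per-line rejects."""

    records: list[SpecimenRecord]
    rejects: list[RejectedRow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _resolve_columns(header: Sequence[str], schema: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical long-layout names to actual file columns."""
    schema = dict(schema or {})
    mapping = {}
    for canon in LONG_COLUMNS:
        actual = schema.get(canon, canon)
        if actual not in header:
            raise SchemaError(f"missing required column: {actual!r} (for {canon!r})")
        mapping[canon] = actual
    return mapping


def read_specimens(path: str | Path, schema: Mapping[str, str] | None = None) -> ReadResult:
    """Read specimen records from a delimited-text file (long layout).

    The long layout has one row per specimen-tissue-metal measurement; rows
    sharing a ``specimen_id`` are assembled into one :class:`SpecimenRecord`.
    ``schema`` maps canonical column names to the file's actual names.
    Invalid rows are collected (with 1-based line numbers) in
    :attr:`ReadResult.rejects`; they are never silently dropped.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"empty input file: {path}")
        cols = _resolve_columns(reader.fieldnames, schema)

        # accumulate measurement rows per specimen, remembering line numbers
        meta: dict[str, dict] = {}
        concs: dict[str, dict[str, dict[str, Concentration]]] = {}
        lines: dict[str, int] = {}
        rejects: list[RejectedRow] = []
        order: list[str] = []

        for lineno, row in enumerate(reader, start=2):  # header is line 1
            try:
                sid = row[cols["specimen_id"]]
                dam_id = int(row[cols["dam_id"]])
                if dam_id not in DAM_IDS:
                    raise ValidationError(f"dam_id out of 1..11: {dam_id}")
                tissue = row[cols["tissue"]]
                metal = row[cols["metal"]]
                if tissue not in TISSUES:
                    raise ValidationError(f"unknown tissue: {tissue!r}")
                if metal not in METALS:
                    raise ValidationError(f"unknown metal: {metal!r}")
                conc = Concentration(float(row[cols["value"]]), row[cols["basis"]])
                rec_meta = dict(
                    dam_id=dam_id,
                    season=row[cols["season"]],
                    sex=row[cols["sex"]],
                    total_length_cm=float(row[cols["total_length_cm"]]),
                    weight_g=float(row[cols["weight_g"]]),
                )
            except (ValidationError, ValueError, KeyError) as exc:
                rejects.append(RejectedRow(lineno, str(exc)))
                continue
            if sid not in meta:
                meta[sid] = rec_meta
                concs[sid] = {}
                lines[sid] = lineno
                order.append(sid)
            elif meta[sid] != rec_meta:
                rejects.append(
                    RejectedRow(lineno, f"specimen {sid!r}: metadata differs from line {lines[sid]}")
                )
                continue
            concs[sid].setdefault(tissue, {})[metal] = conc

        records: list[SpecimenRecord] = []
        for sid in order:
            try:
                records.append(
                    SpecimenRecord(specimen_id=sid, concentrations=concs[sid], **meta[sid])
                )
            except ValidationError as exc:
                rejects.append(RejectedRow(lines[sid], f"specimen {sid!r}: {exc}"))
        return ReadResult(records=records, rejects=rejects)


def write_specimens(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    """Write records to CSV in the long layout accepted by :func:`read_specimens`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LONG_COLUMNS)
        for i, rec in enumerate(records):
            sid = rec.specimen_id if rec.specimen_id is not None else f"S{i:04d}"
            for tissue in sorted(rec.concentrations):
                for metal in sorted(rec.concentrations[tissue]):
                    c = rec.concentrations[tissue][metal]
                    writer.writerow(
                        [sid, rec.dam_id, rec.season, rec.sex,
                         repr(rec.total_length_cm), repr(rec.weight_g),
                         tissue, metal, repr(c.value), c.basis]
                    )


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("fishmetals.data").joinpath(name)


@dataclass
class Fixtures:
    """The packaged study tables and constants, integrity-checked on load."""

    dams: list[DamMetadata]
    summaries: list[TissueSummary]
    tox: dict
    limits: list[dict]
    table2_expected: pd.DataFrame


# published aggregate totals used as integrity checksums
_CHECKSUMS = {
    "capacity_Mm3": 20512,
    "area_ha": 71417,
    "fishermen": 1928,
    "mining_sites_dedup": 139,
}


def dedup_mining_sites(dams: Iterable[DamMetadata]) -> int:
    """Total mining sites, counting each shared basin_group's count once."""
    seen: dict[str, int] = {}
    for d in dams:
        prev = seen.get(d.basin_group)
        if prev is not None and prev != d.mining_sites:
            raise FixtureError(
                f"basin_group {d.basin_group!r} has inconsistent mining counts"
            )
        seen[d.basin_group] = d.mining_sites
    return sum(seen.values())


def load_fixtures() -> Fixtures:
    """Load the packaged tables and verify their integrity checksums."""
    t1 = pd.read_csv(_data_path("table1_dams.csv"))
    dams = [
        DamMetadata(
            dam_id=int(r.dam_id),
            name=r.name_,
            river=r.river,
            area_ha=float(r.area_ha),
            capacity_Mm3=float(r.capacity_Mm3),
            mining_sites=int(r.mining_sites),
            basin_group=r.basin_group,
            geothermal=bool(r.geothermal),
            fishermen=None if pd.isna(r.fishermen) else int(r.fishermen),
            annual_production_t=None if pd.isna(r.annual_production_t) else str(r.annual_production_t),
            water_temp_c=None if pd.isna(r.water_temp_c) else str(r.water_temp_c),
        )
        for r in t1.rename(columns={"name": "name_"}).itertuples(index=False)
    ]
    if len(dams) != 11:
        raise FixtureError(f"expected 11 dams, got {len(dams)}")

    checks = {
        "capacity_Mm3": sum(d.capacity_Mm3 for d in dams),
        "area_ha": sum(d.area_ha for d in dams),
        "fishermen": sum(d.fishermen for d in dams if d.fishermen is not None),
        "mining_sites_dedup": dedup_mining_sites(dams),
    }
    for key, expected in _CHECKSUMS.items():
        if round(checks[key]) != expected:
            raise FixtureError(
                f"fixture checksum failed for {key}: got {checks[key]}, expected {expected}"
            )

    t3 = pd.read_csv(_data_path("table3_summaries.csv"))
    summaries = [
        TissueSummary(int(r.dam_id), r.tissue, r.metal, float(r.mean), float(r.sd), r.basis)
        for r in t3.itertuples(index=False)
    ]

    with _data_path("tox_constants.yaml").open() as fh:
        tox = yaml.safe_load(fh)
    with _data_path("limits.yaml").open() as fh:
        limits = yaml.safe_load(fh)["limits"]
    table2 = pd.read_csv(_data_path("table2_expected.csv"))
    return Fixtures(dams=dams, summaries=summaries, tox=tox, limits=limits,
                    table2_expected=table2)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def grand_mean(
    summaries: Iterable[TissueSummary], tissue: str, metal: str
) -> Concentration:
    """Unweighted mean of per-dam mean concentrations for (tissue, metal).

    All selected summaries must share a basis; mixed bases raise, demanding
    explicit conversion first (:mod:`fishmetals.basis_conversion`).
    """
    sel = [s for s in summaries if s.tissue == tissue and s.metal == metal]
    if not sel:
        raise ValueError(f"no summaries for tissue={tissue!r}, metal={metal!r}")
    bases = {s.basis for s in sel}
    if len(bases) > 1:
        raise ValidationError(
            f"mixed bases {sorted(bases)} for ({tissue}, {metal}); convert first"
        )
    return Concentration(sum(s.mean for s in sel) / len(sel), sel[0].basis)
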