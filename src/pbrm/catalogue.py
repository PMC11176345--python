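"""Cost catalogue: reimbursement items, role rates, visit definitions.

A *reimbursement item* is a lump sum for one study activity (e.g. taking a
spirometry, documenting a ward day). Its cost is composed of per-role time
efforts priced at tariff-derived per-minute rates (study personnel SP,
physician PH, medical specialist MS), plus material costs and an optional
overhead fraction. Where a component cost is stated explicitly it takes
precedence over ``minutes × rate`` — tariff rates for the MS role vary by
activity, so catalogues typically carry explicit component costs.

A *visit definition* lists how often each item is performed at one visit of a
given type; the cost of a case follows from the visits it completed. The
*case fee* is the expected cost of a whole case, either configured directly
or derived as the expectation over a distribution of visit paths.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from decimal import Decimal
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from ._money import ZERO, as_decimal, money_str, round2
from .errors import (
    CatalogueError,
    CatalogueLookupError,
    SpecificationError,
    UnresolvedRateError,
)

SCHEMA_VERSION = "1"


class Role(str, Enum):
    """Staff roles priced in the catalogue."""

    SP = "SP"  # study personnel (study nurse / coordinator)
    PH = "PH"  # physician
    MS = "MS"  # medical specialist (incl. specialist and senior physician)


class Cohort(str, Enum):
    HAP = "HAP"    # high-resolution, deep-phenotyping inpatient cohort
    POP = "POP"    # population-based cohort with a single on-site visit
    SUEP = "SUEP"  # cross-sectoral cohort (AMC and non-AMC centres)


class CentreClass(str, Enum):
    AMC = "AMC"
    NON_AMC = "non-AMC"


@dataclass(frozen=True)
class RoleRate:
    """Per-minute personnel rate for one role.

    ``tariff_percent_per_min`` is opaque tariff metadata (the fraction of a
    reference salary consumed per minute) kept only for provenance.
    """

    role: Role
    rate_eur_per_min: Decimal
    tariff_percent_per_min: Optional[Decimal] = None

    def __post_init__(self):
        if self.rate_eur_per_min < 0:
            raise CatalogueError(f"negative rate for role {self.role.value}")


@dataclass(frozen=True)
class RoleEffort:
    """One role's contribution to an item: minutes and/or an explicit cost."""

    role: Role
    minutes: Decimal = ZERO
    explicit_cost_eur: Optional[Decimal] = None

    def __post_init__(self):
        if self.minutes < 0:
            raise CatalogueError(f"negative minutes for role {self.role.value}")
        if self.explicit_cost_eur is not None and self.explicit_cost_eur < 0:
            raise CatalogueError(f"negative cost for role {self.role.value}")


@dataclass(frozen=True)
class ReimbursementItem:
    """A lump-sum study activity.

    ``printed_total_eur`` is optional provenance metadata: the total a source
    document printed for the item, which may disagree with the component sum
    at the cent level. Pricing always uses the components.
    """

    item_id: str
    label: str
    role_efforts: tuple[RoleEffort, ...] = ()
    material_cost_eur: Decimal = ZERO
    overhead_rate: Decimal = ZERO
    data_points: Optional[int] = None
    printed_total_eur: Optional[Decimal] = None

    def __post_init__(self):
        if self.material_cost_eur < 0:
            raise CatalogueError(f"{self.item_id}: negative material cost")
        if self.overhead_rate < 0:
            raise CatalogueError(f"{self.item_id}: negative overhead rate")
        roles = [e.role for e in self.role_efforts]
        if len(roles) != len(set(roles)):
            raise CatalogueError(f"{self.item_id}: duplicate role effort")


@dataclass(frozen=True)
class VisitDefinition:
    """Item multiplicities performed at one visit of a given type."""

    visit_type_id: str
    item_multiplicities: tuple[tuple[str, int], ...]
    cohort: Optional[Cohort] = None
    centre_class: Optional[CentreClass] = None

    def __post_init__(self):
        for item_id, count in self.item_multiplicities:
            if not isinstance(count, int) or count < 0:
                raise CatalogueError(
                    f"visit {self.visit_type_id}: count for {item_id} must be a "
                    f"non-negative integer, got {count!r}"
                )


@dataclass(frozen=True)
class CaseFeeSpec:
    """Expected mean reimbursement per case for one cohort/centre class.

    Either a configured constant or a distribution over ordered visit paths;
    a configured constant takes precedence.
    """

    cohort: Cohort
    centre_class: Optional[CentreClass] = None
    configured_fee_eur: Optional[Decimal] = None
    path_distribution: Optional[tuple[tuple[tuple[str, ...], Decimal], ...]] = None

    def __post_init__(self):
        if self.path_distribution is not None:
            total = sum((p for _, p in self.path_distribution), Decimal(0))
            if abs(total - 1) > Decimal("1e-9"):
                raise SpecificationError(
                    f"path probabilities sum to {total}, expected 1"
                )


#: Expected case fees per cohort/centre class (euros), as configured for the
#: first funding period.
DEFAULT_CASE_FEES: dict[tuple[Cohort, Optional[CentreClass]], Decimal] = {
    (Cohort.HAP, None): Decimal("12871.70"),
    (Cohort.POP, None): Decimal("3400.76"),
    (Cohort.SUEP, CentreClass.AMC): Decimal("2904.67"),
    (Cohort.SUEP, CentreClass.NON_AMC): Decimal("1071.23"),
}


def default_case_fee(cohort: Cohort | str, centre_class: CentreClass | str | None = None) -> Decimal:
    """Look up the configured case fee for a cohort (and centre class for SUEP)."""
    cohort = Cohort(cohort)
    if cohort is Cohort.SUEP:
        if centre_class is None:
            raise SpecificationError("SUEP case fee requires a centre class")
        return DEFAULT_CASE_FEES[(cohort, CentreClass(centre_class))]
    return DEFAULT_CASE_FEES[(cohort, None)]


@dataclass
class CostCatalogue:
    """The full catalogue: rates, items, visit definitions."""

    rates: dict[Role, RoleRate] = field(default_factory=dict)
    items: dict[str, ReimbursementItem] = field(default_factory=dict)
    visits: dict[str, VisitDefinition] = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def item(self, item_id: str) -> ReimbursementItem:
        try:
            return self.items[item_id]
        except KeyError:
            raise CatalogueLookupError(f"unknown reimbursement item {item_id!r}") from None

    def visit(self, visit_type_id: str) -> VisitDefinition:
        try:
            return self.visits[visit_type_id]
        except KeyError:
            raise CatalogueLookupError(f"unknown visit type {visit_type_id!r}") from None

    def item_cost(self, item_id: str) -> Decimal:
        return item_total_cost(self.item(item_id), self.rates)

    def validate(self) -> None:
        for visit in self.visits.values():
            for item_id, _ in visit.item_multiplicities:
                if item_id not in self.items:
                    raise CatalogueLookupError(
                        f"visit {visit.visit_type_id} references unknown item {item_id!r}"
                    )


# ---------------------------------------------------------------------------
# Pricing operations
# ---------------------------------------------------------------------------

def effort_cost(effort: RoleEffort, rates: Mapping[Role, RoleRate]) -> Decimal:
    """Cost of one role effort: explicit cost if given, else minutes × rate.

    Each component is rounded to cents before summation.
    """
    if effort.explicit_cost_eur is not None:
        return round2(effort.explicit_cost_eur)
    rate = rates.get(effort.role)
    if rate is None:
        raise UnresolvedRateError(
            f"no rate for role {effort.role.value} and no explicit cost"
        )
    return round2(effort.minutes * rate.rate_eur_per_min)


def item_total_cost(item: ReimbursementItem, rates: Mapping[Role, RoleRate]) -> Decimal:
    """Total lump sum of an item: (Σ role costs + material) × (1 + overhead)."""
    total = sum((effort_cost(e, rates) for e in item.role_efforts), ZERO)
    total += round2(item.material_cost_eur)
    return round2(total * (1 + item.overhead_rate))


def visit_cost(visit: VisitDefinition, catalogue: CostCatalogue) -> Decimal:
    """Σ over items of multiplicity × item total cost."""
    total = ZERO
    for item_id, count in visit.item_multiplicities:
        total += count * catalogue.item_cost(item_id)
    return round2(total)


def path_cost(path: Sequence[str], catalogue: CostCatalogue) -> Decimal:
    """Cost of an ordered sequence of visit types."""
    return round2(sum((visit_cost(catalogue.visit(v), catalogue) for v in path), ZERO))


def expected_case_fee(spec: CaseFeeSpec, catalogue: CostCatalogue | None = None) -> Decimal:
    """Expected mean reimbursement per case.

    A configured constant wins; otherwise the expectation over the visit-path
    distribution is computed against the catalogue.
    """
    if spec.configured_fee_eur is not None:
        return round2(spec.configured_fee_eur)
    if spec.path_distribution is not None:
        if catalogue is None:
            raise SpecificationError("a catalogue is required to price visit paths")
        total = sum(
            (prob * path_cost(path, catalogue) for path, prob in spec.path_distribution),
            Decimal(0),
        )
        return round2(total)
    raise SpecificationError(
        "case-fee spec needs a configured fee or a path distribution"
    )


# ---------------------------------------------------------------------------
# Serialisation (single JSON document or items/rates/visits CSV triplet)
# ---------------------------------------------------------------------------

_EFFORT_COLS = {
    Role.SP: ("sp_minutes", "sp_cost_eur"),
    Role.PH: ("ph_minutes", "ph_cost_eur"),
    Role.MS: ("ms_minutes", "ms_cost_eur"),
}

ITEM_COLUMNS = (
    ["item_id", "label", "data_points"]
    + [c for pair in _EFFORT_COLS.values() for c in pair]
    + ["material_cost_eur", "overhead_rate", "printed_total_eur"]
)


def _opt(value: Optional[object]) -> str:
    return "" if value is None else str(value)


def _item_to_row(item: ReimbursementItem) -> dict[str, str]:
    row = {
        "item_id": item.item_id,
        "label": item.label,
        "data_points": _opt(item.data_points),
        "material_cost_eur": money_str(item.material_cost_eur),
        "overhead_rate": str(item.overhead_rate),
        "printed_total_eur": (
            "" if item.printed_total_eur is None else money_str(item.printed_total_eur)
        ),
    }
    for role, (mcol, ccol) in _EFFORT_COLS.items():
        row[mcol] = ""
        row[ccol] = ""
    for e in item.role_efforts:
        mcol, ccol = _EFFORT_COLS[e.role]
        row[mcol] = str(e.minutes)
        row[ccol] = "" if e.explicit_cost_eur is None else money_str(e.explicit_cost_eur)
    return row


def _row_to_item(row: Mapping[str, str], where: str) -> ReimbursementItem:
    efforts = []
    for role, (mcol, ccol) in _EFFORT_COLS.items():
        minutes = row.get(mcol, "").strip()
        cost = row.get(ccol, "").strip()
        if not minutes and not cost:
            continue
        efforts.append(
            RoleEffort(
                role=role,
                minutes=as_decimal(minutes) if minutes else ZERO,
                explicit_cost_eur=as_decimal(cost) if cost else None,
            )
        )
    try:
        return ReimbursementItem(
            item_id=row["item_id"],
            label=row.get("label", row["item_id"]),
            role_efforts=tuple(efforts),
            material_cost_eur=as_decimal(row.get("material_cost_eur") or "0"),
            overhead_rate=as_decimal(row.get("overhead_rate") or "0"),
            data_points=int(row["data_points"]) if row.get("data_points") else None,
            printed_total_eur=(
                as_decimal(row["printed_total_eur"]) if row.get("printed_total_eur") else None
            ),
        )
    except CatalogueError as exc:
        raise CatalogueError(f"{where}: {exc}") from None


def catalogue_to_dict(catalogue: CostCatalogue) -> dict:
    """JSON-ready representation; money is serialised as strings."""
    return {
        "schema_version": catalogue.schema_version,
        "rates": [
            {
                "role": r.role.value,
                "rate_eur_per_min": str(r.rate_eur_per_min),
                "tariff_percent_per_min": _opt(r.tariff_percent_per_min) or None,
            }
            for r in catalogue.rates.values()
        ],
        "items": [_item_to_row(item) for item in catalogue.items.values()],
        "visits": [
            {
                "visit_type_id": v.visit_type_id,
                "cohort": v.cohort.value if v.cohort else None,
                "centre_class": v.centre_class.value if v.centre_class else None,
                "items": [{"item_id": i, "count": c} for i, c in v.item_multiplicities],
            }
            for v in catalogue.visits.values()
        ],
    }


def catalogue_from_dict(doc: Mapping) -> CostCatalogue:
    rates: dict[Role, RoleRate] = {}
    for idx, rrow in enumerate(doc.get("rates", [])):
        role = Role(rrow["role"])
        if role in rates:
            raise CatalogueError(f"rates: duplicate role {role.value} (entry {idx + 1})")
        rates[role] = RoleRate(
            role=role,
            rate_eur_per_min=as_decimal(rrow["rate_eur_per_min"]),
            tariff_percent_per_min=(
                as_decimal(rrow["tariff_percent_per_min"])
                if rrow.get("tariff_percent_per_min")
                else None
            ),
        )
    items: dict[str, ReimbursementItem] = {}
    bad_rows: list[int] = []
    for idx, irow in enumerate(doc.get("items", [])):
        item = _row_to_item(irow, where=f"items entry {idx + 1}")
        if item.item_id in items:
            bad_rows.append(idx + 1)
            continue
        items[item.item_id] = item
    if bad_rows:
        raise CatalogueError(f"duplicate item_id in items entries {bad_rows}")
    visits: dict[str, VisitDefinition] = {}
    for idx, vrow in enumerate(doc.get("visits", [])):
        vid = vrow["visit_type_id"]
        if vid in visits:
            raise CatalogueError(f"duplicate visit_type_id {vid!r} (entry {idx + 1})")
        visits[vid] = VisitDefinition(
            visit_type_id=vid,
            item_multiplicities=tuple(
                (e["item_id"], int(e["count"])) for e in vrow.get("items", [])
            ),
            cohort=Cohort(vrow["cohort"]) if vrow.get("cohort") else None,
            centre_class=(
                CentreClass(vrow["centre_class"]) if vrow.get("centre_class") else None
            ),
        )
    catalogue = CostCatalogue(
        rates=rates,
        items=items,
        visits=visits,
        schema_version=str(doc.get("schema_version", SCHEMA_VERSION)),
    )
    catalogue.validate()
    return catalogue


def write_catalogue(catalogue: CostCatalogue, path: str | Path) -> None:
    """Write a catalogue: ``.json`` file, or a directory of CSV files."""
    path = Path(path)
    doc = catalogue_to_dict(catalogue)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
        return
    path.mkdir(parents=True, exist_ok=True)
    _write_csv(
        path / "rates.csv",
        ["role", "rate_eur_per_min", "tariff_percent_per_min"],
        [
            {
                "role": r["role"],
                "rate_eur_per_min": r["rate_eur_per_min"],
                "tariff_percent_per_min": r["tariff_percent_per_min"] or "",
            }
            for r in doc["rates"]
        ],
    )
    _write_csv(path / "items.csv", ITEM_COLUMNS, doc["items"])
    visit_rows = []
    for v in doc["visits"]:
        for e in v["items"]:
            visit_rows.append(
                {
                    "visit_type_id": v["visit_type_id"],
                    "cohort": v["cohort"] or "",
                    "centre_class": v["centre_class"] or "",
                    "item_id": e["item_id"],
                    "count": str(e["count"]),
                }
            )
        if not v["items"]:
            visit_rows.append(
                {
                    "visit_type_id": v["visit_type_id"],
                    "cohort": v["cohort"] or "",
                    "centre_class": v["centre_class"] or "",
                    "item_id": "",
                    "count": "",
                }
            )
    _write_csv(
        path / "visits.csv",
        ["visit_type_id", "cohort", "centre_class", "item_id", "count"],
        visit_rows,
    )
    _write_csv(
        path / "meta.csv",
        ["key", "value"],
        [{"key": "schema_version", "value": catalogue.schema_version}],
    )


def read_catalogue(path: str | Path) -> CostCatalogue:
    """Read a catalogue from a JSON document or a CSV directory."""
    path = Path(path)
    if path.is_file():
        return catalogue_from_dict(json.loads(path.read_text(encoding="utf-8")))
    if not path.is_dir():
        raise CatalogueError(f"catalogue path {path} does not exist")
    doc: dict = {"rates": [], "items": [], "visits": []}
    meta = path / "meta.csv"
    if meta.exists():
        for row in _read_csv(meta):
            if row["key"] == "schema_version":
                doc["schema_version"] = row["value"]
    rates_f = path / "rates.csv"
    if rates_f.exists():
        doc["rates"] = [
            {
                "role": row["role"],
                "rate_eur_per_min": row["rate_eur_per_min"],
                "tariff_percent_per_min": row.get("tariff_percent_per_min") or None,
            }
            for row in _read_csv(rates_f)
        ]
    items_f = path / "items.csv"
    if items_f.exists():
        doc["items"] = list(_read_csv(items_f))
    visits_f = path / "visits.csv"
    if visits_f.exists():
        grouped: dict[str, dict] = {}
        for row in _read_csv(visits_f):
            vid = row["visit_type_id"]
            entry = grouped.setdefault(
                vid,
                {
                    "visit_type_id": vid,
                    "cohort": row.get("cohort") or None,
                    "centre_class": row.get("centre_class") or None,
                    "items": [],
                },
            )
            if row.get("item_id"):
                entry["items"].append({"item_id": row["item_id"], "count": row["count"]})
        doc["visits"] = list(grouped.values())
    return catalogue_from_dict(doc)


def _write_csv(path: Path, columns: Sequence[str], rows: Iterable[Mapping[str, str]]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), lineterminator="\n")
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in columns})


def _read_csv(path: Path) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.DictReader(fh))


def reference_catalogue() -> CostCatalogue:
    """The packaged reference catalogue.

    Eight exemplary reimbursement items with explicit per-role component
    costs (documentation of screening/baseline, ward day, ICU day; clinical
    status; electrocardiography; PBMC sampling; spirometry; transthoracic
    echocardiogram), the SP/PH per-minute rates, and the visit definitions
    used by the synthetic-cohort presets.
    """
    with resources.files("pbrm.data").joinpath("reference_catalogue.json").open(
        "r", encoding="utf-8"
    ) as fh:
        return catalogue_from_dict(json.load(fh))
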