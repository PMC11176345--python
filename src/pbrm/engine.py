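"""Reimbursement engine: case statements, imputation, aggregation, reports.

The engine prices billable lines against the cost catalogue into itemised
case statements, imputes announced-but-undocumented visits that fall after
the documentation freeze (valued at experience values learned from the run
itself), aggregates statements to centre and cohort summaries, and emits
versioned, audience-scoped CSV/Markdown reports. All totals are exact
fixed-point sums, so conservation (cohort = Σ centres = Σ cases = Σ lines)
holds to the cent by construction.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._money import ZERO, as_decimal, money_str, round1, round2
from .catalogue import CentreClass, Cohort, CostCatalogue
from .errors import (
    CatalogueLookupError,
    ConfigurationError,
    ImputationError,
    PbrmError,
    SamplingError,
)
from .qc_eligibility import (
    BillableLine,
    BioRule,
    EligibilityRuleSet,
    ImgRule,
    MappingTable,
    QcVerdict,
    Reason,
    billable_lines,
)
from .study_data import CaseDossier, CentreRecord, LinkResult, link_cases

SOURCES = ("ecrf", "bio", "imaging")


@dataclass(frozen=True)
class StatementLine:
    visit_id: str
    visit_type_id: str
    item_id: str
    count: int
    unit_cost_eur: Decimal
    amount_eur: Decimal
    source: str
    imputed: bool = False


@dataclass
class CaseStatement:
    """Itemised, quality-gated reimbursement statement of one case."""

    case_id: str
    centre_id: str
    cohort: Cohort
    lines: list[StatementLine] = field(default_factory=list)

    @property
    def total_eur(self) -> Decimal:
        return round2(sum((l.amount_eur for l in self.lines), ZERO))

    @property
    def totals_by_source(self) -> dict[str, Decimal]:
        totals = {s: ZERO for s in SOURCES}
        for l in self.lines:
            totals[l.source] = totals[l.source] + l.amount_eur
        return {s: round2(v) for s, v in totals.items()}


@dataclass(frozen=True)
class AnnouncedVisit:
    case_id: str
    visit_type_id: str
    due_date: _dt.date


@dataclass
class ImputationSpec:
    """Imputation of future activities after the documentation freeze.

    Announced visits due in the period but not yet documented at the freeze
    are valued at *experience values*: the mean cost of completed visits of
    the same type, resolved centre-level first, then cohort-level, then a
    configured default.
    """

    documentation_freeze_date: _dt.date
    announced: Sequence[AnnouncedVisit] = ()
    configured_defaults: Mapping[str, Decimal] = field(default_factory=dict)

    def __post_init__(self):
        for vt, v in self.configured_defaults.items():
            if as_decimal(v) < 0:
                raise ConfigurationError(f"negative experience default for {vt!r}")


class ExperienceValues:
    """Mean completed-visit cost per (centre, visit type) with fallbacks."""

    def __init__(
        self,
        centre_means: Mapping[tuple[str, str], Decimal],
        cohort_means: Mapping[str, Decimal],
        configured: Mapping[str, Decimal],
    ):
        self._centre = dict(centre_means)
        self._cohort = dict(cohort_means)
        self._configured = {k: as_decimal(v) for k, v in configured.items()}

    @classmethod
    def from_statements(
        cls,
        statements: Sequence[CaseStatement],
        configured: Mapping[str, Decimal] | None = None,
    ) -> "ExperienceValues":
        centre_visit_costs: dict[tuple[str, str], list[Decimal]] = {}
        cohort_visit_costs: dict[str, list[Decimal]] = {}
        for st in statements:
            per_visit: dict[tuple[str, str], Decimal] = {}
            for l in st.lines:
                if l.imputed or not l.visit_type_id:
                    continue
                key = (l.visit_id, l.visit_type_id)
                per_visit[key] = per_visit.get(key, ZERO) + l.amount_eur
            for (_, vtype), cost in per_visit.items():
                centre_visit_costs.setdefault((st.centre_id, vtype), []).append(cost)
                cohort_visit_costs.setdefault(vtype, []).append(cost)
        centre_means = {
            key: round2(sum(v, ZERO) / len(v)) for key, v in centre_visit_costs.items()
        }
        cohort_means = {
            key: round2(sum(v, ZERO) / len(v)) for key, v in cohort_visit_costs.items()
        }
        return cls(centre_means, cohort_means, configured or {})

    def resolve(self, centre_id: str, visit_type_id: str) -> tuple[Decimal, str]:
        """Return (value, provenance) with provenance in
        {centre-level, cohort-level, configured}."""
        key = (centre_id, visit_type_id)
        if key in self._centre:
            return self._centre[key], "centre-level"
        if visit_type_id in self._cohort:
            return self._cohort[visit_type_id], "cohort-level"
        if visit_type_id in self._configured:
            return round2(self._configured[visit_type_id]), "configured"
        raise ImputationError(
            f"no experience value resolvable for visit type {visit_type_id!r} "
            f"(centre {centre_id!r})"
        )


@dataclass
class CentreSummary:
    centre_id: str
    cohort: Cohort
    centre_class: CentreClass
    n_recruited: int
    n_reimbursable: int
    total_eur: Decimal
    mean_per_case_eur: Optional[Decimal]
    source_shares_pct: dict[str, Decimal]
    fu_fulfilment_pct: Optional[Decimal] = None
    initiation_fee_eur: Decimal = ZERO
    target_cases: Decimal = ZERO

    @property
    def grand_total_eur(self) -> Decimal:
        """Case-derived total plus the study initiation fee, if granted."""
        return round2(self.total_eur + self.initiation_fee_eur)


# ---------------------------------------------------------------------------
# Statement computation
# ---------------------------------------------------------------------------

def compute_case_statement(
    case_id: str,
    centre_id: str,
    cohort: Cohort,
    lines: Sequence[BillableLine],
    catalogue: CostCatalogue,
) -> CaseStatement:
    """Price billable lines: amount = count × unit cost; total = exact sum."""
    priced: list[StatementLine] = []
    for line in lines:
        unit = catalogue.item_cost(line.item_id)  # raises on unknown item
        priced.append(
            StatementLine(
                visit_id=line.visit_id,
                visit_type_id=line.visit_type_id,
                item_id=line.item_id,
                count=line.count,
                unit_cost_eur=unit,
                amount_eur=round2(line.count * unit),
                source=line.source,
            )
        )
    return CaseStatement(case_id=case_id, centre_id=centre_id, cohort=cohort, lines=priced)


def impute_future_visits(
    statement: CaseStatement,
    spec: ImputationSpec,
    experience: ExperienceValues,
) -> tuple[CaseStatement, list[str]]:
    """Add one imputed line per announced-but-undocumented due visit.

    Original lines are untouched; the returned provenance list parallels the
    appended imputed lines.
    """
    documented_types = Counter(
        vtype
        for _vid, vtype in {
            (l.visit_id, l.visit_type_id) for l in statement.lines if not l.imputed
        }
    )
    provenances: list[str] = []
    new_lines = list(statement.lines)
    pending = [
        a
        for a in spec.announced
        if a.case_id == statement.case_id and a.due_date >= spec.documentation_freeze_date
    ]
    for ann in sorted(pending, key=lambda a: (a.due_date, a.visit_type_id)):
        if documented_types.get(ann.visit_type_id, 0) > 0:
            documented_types[ann.visit_type_id] -= 1
            continue
        value, provenance = experience.resolve(statement.centre_id, ann.visit_type_id)
        new_lines.append(
            StatementLine(
                visit_id=f"imputed-{ann.visit_type_id}-{ann.due_date.isoformat()}",
                visit_type_id=ann.visit_type_id,
                item_id="__imputed__",
                count=1,
                unit_cost_eur=value,
                amount_eur=value,
                source="ecrf",
                imputed=True,
            )
        )
        provenances.append(provenance)
    return (
        CaseStatement(
            case_id=statement.case_id,
            centre_id=statement.centre_id,
            cohort=statement.cohort,
            lines=new_lines,
        ),
        provenances,
    )


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

#: Minimum number of reimbursable cases for the SUEP non-AMC initiation fee.
INITIATION_FEE_MIN_CASES = 5


def aggregate_centre(
    statements: Sequence[CaseStatement],
    centre: CentreRecord,
    *,
    n_recruited: Optional[int] = None,
    fu_fulfilment_pct: Optional[Decimal] = None,
    initiation_fee_eur: Decimal = ZERO,
) -> CentreSummary:
    """Centre totals, mean per case, and source shares.

    The study initiation fee is granted only for SUEP non-AMC centres with at
    least ``INITIATION_FEE_MIN_CASES`` reimbursable cases; its amount is
    configuration, not catalogue content.
    """
    foreign = [s.centre_id for s in statements if s.centre_id != centre.centre_id]
    if foreign:
        raise PbrmError(
            f"statements for centre {centre.centre_id!r} include other centres: "
            f"{sorted(set(foreign))}"
        )
    n = len(statements)
    total = round2(sum((s.total_eur for s in statements), ZERO))
    by_source = {s: ZERO for s in SOURCES}
    for st in statements:
        for src, amount in st.totals_by_source.items():
            by_source[src] = by_source[src] + amount
    shares = {
        src: (round1(100 * by_source[src] / total) if total > 0 else round1(0))
        for src in SOURCES
    }
    fee = ZERO
    if (
        centre.cohort is Cohort.SUEP
        and centre.centre_class is CentreClass.NON_AMC
        and n >= INITIATION_FEE_MIN_CASES
    ):
        fee = round2(initiation_fee_eur)
    return CentreSummary(
        centre_id=centre.centre_id,
        cohort=centre.cohort,
        centre_class=centre.centre_class,
        n_recruited=n if n_recruited is None else n_recruited,
        n_reimbursable=n,
        total_eur=total,
        mean_per_case_eur=round2(total / n) if n else None,
        source_shares_pct=shares,
        fu_fulfilment_pct=fu_fulfilment_pct,
        initiation_fee_eur=fee,
        target_cases=centre.target_cases,
    )


def aggregate_cohort(summaries: Sequence[CentreSummary]) -> dict[str, Decimal | int]:
    """Cohort totals as exact sums over centre summaries."""
    total = round2(sum((s.total_eur for s in summaries), ZERO))
    n = sum(s.n_reimbursable for s in summaries)
    return {
        "n_reimbursable": n,
        "total_eur": total,
        "mean_per_case_eur": round2(total / n) if n else ZERO,
        "initiation_fees_eur": round2(sum((s.initiation_fee_eur for s in summaries), ZERO)),
    }


def fu_fulfilment(
    documented: Mapping[str, Iterable[str]],
    expected: Mapping[str, Sequence[str]],
) -> Optional[Decimal]:
    """Percentage of protocol-expected follow-up visits actually documented.

    ``expected`` maps case_id to the FU visit types due for that case;
    ``documented`` maps case_id to the visit types actually documented.
    Returns None when nothing was expected.
    """
    n_expected = 0
    n_documented = 0
    for case_id, visit_types in expected.items():
        have = Counter(documented.get(case_id, ()))
        for vt in visit_types:
            n_expected += 1
            if have.get(vt, 0) > 0:
                have[vt] -= 1
                n_documented += 1
    if n_expected == 0:
        return None
    return round1(Decimal(100) * n_documented / n_expected)


def random_audit_sample(
    statements: Sequence[CaseStatement], n: int = 10, seed: int = 0
) -> list[CaseStatement]:
    """Uniform sample of statements without replacement, reproducible by seed."""
    if n > len(statements):
        raise SamplingError(
            f"audit sample of {n} requested from only {len(statements)} statements"
        )
    ordered = sorted(statements, key=lambda s: s.case_id)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ordered), size=n, replace=False)
    return [ordered[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# Run pipeline and ledger
# ---------------------------------------------------------------------------

@dataclass
class RunLedger:
    run_id: str
    input_digests: dict[str, str]
    catalogue_version: str
    timestamp: str
    iteration: int = 1

    def to_json(self) -> str:
        return json.dumps(
            {
                "run_id": self.run_id,
                "input_digests": self.input_digests,
                "catalogue_version": self.catalogue_version,
                "timestamp": self.timestamp,
                "iteration": self.iteration,
            },
            indent=2,
            sort_keys=True,
        ) + "\n"


def _digest(payload: bytes) -> str:
    return hashlib.sha256(payload).hexdigest()


@dataclass
class RunResult:
    statements: list[CaseStatement]
    verdicts: dict[str, QcVerdict]
    summaries: list[CentreSummary]
    cohort_totals: dict[str, dict]
    orphans: dict[str, list]
    exclusions: Counter
    unmapped: Counter
    imputation_provenance: dict[str, list[str]]
    ledger: RunLedger
    centres: list[CentreRecord]


def run_reimbursement(
    catalogue: CostCatalogue,
    exports: Mapping[str, Sequence],
    mapping: MappingTable,
    rules: EligibilityRuleSet,
    bio_rules: Sequence[BioRule] = (),
    img_rules: Sequence[ImgRule] = (),
    imputation: Optional[ImputationSpec] = None,
    fu_schedule: Optional[Mapping[str, Sequence[str]]] = None,
    initiation_fee_eur: Decimal = ZERO,
    iteration: int = 1,
) -> RunResult:
    """Full run: link → eligibility → filter → map → price → impute → aggregate.

    ``exports`` holds the five record sets under keys ecrf/bio/imaging/
    centres/linkage (as produced by :func:`pbrm.study_data.read_exports_dir`).
    """
    mapping.validate_against(catalogue)
    linked: LinkResult = link_cases(
        exports["linkage"], exports["ecrf"], exports["bio"], exports["imaging"],
        exports["centres"],
    )

    statements: list[CaseStatement] = []
    verdicts: dict[str, QcVerdict] = {}
    exclusions: Counter = Counter()
    unmapped: Counter = Counter()
    for dossier in linked.dossiers:
        verdict, lines, events, unmapped_items = billable_lines(
            dossier, rules, mapping, bio_rules, img_rules, catalogue
        )
        verdicts[dossier.case_id] = verdict
        exclusions.update(events.excluded)
        unmapped.update(unmapped_items)
        if verdict.reimbursable:
            statements.append(
                compute_case_statement(
                    dossier.case_id, dossier.centre_id, dossier.cohort, lines, catalogue
                )
            )

    imputation_provenance: dict[str, list[str]] = {}
    if imputation is not None and imputation.announced:
        experience = ExperienceValues.from_statements(
            statements, imputation.configured_defaults
        )
        imputed: list[CaseStatement] = []
        for st in statements:
            new_st, provenances = impute_future_visits(st, imputation, experience)
            if provenances:
                imputation_provenance[st.case_id] = provenances
            imputed.append(new_st)
        statements = imputed

    by_centre: dict[str, list[CaseStatement]] = {}
    for st in statements:
        by_centre.setdefault(st.centre_id, []).append(st)

    dossiers_by_centre: Counter = Counter(d.centre_id for d in linked.dossiers)
    fu_by_centre: dict[str, Optional[Decimal]] = {}
    if fu_schedule:
        documented_all = {
            d.case_id: [
                vtype
                for _vid, vtype in {
                    (r.visit_id, r.visit_type_id) for r in d.ecrf if r.submitted
                }
            ]
            for d in linked.dossiers
        }
        for centre_id in dossiers_by_centre:
            cases = [d.case_id for d in linked.dossiers if d.centre_id == centre_id]
            fu_by_centre[centre_id] = fu_fulfilment(
                {c: documented_all.get(c, []) for c in cases},
                {c: fu_schedule[c] for c in cases if c in fu_schedule},
            )

    summaries = []
    for centre in sorted(exports["centres"], key=lambda c: c.centre_id):
        centre_statements = by_centre.get(centre.centre_id, [])
        if not centre_statements and centre.centre_id not in dossiers_by_centre:
            continue  # centre contributed no cases at all
        summaries.append(
            aggregate_centre(
                centre_statements,
                centre,
                n_recruited=dossiers_by_centre.get(centre.centre_id, 0),
                fu_fulfilment_pct=fu_by_centre.get(centre.centre_id),
                initiation_fee_eur=initiation_fee_eur,
            )
        )

    cohort_totals: dict[str, dict] = {}
    for cohort in sorted({s.cohort.value for s in summaries}):
        cohort_totals[cohort] = aggregate_cohort(
            [s for s in summaries if s.cohort.value == cohort]
        )

    digests = {
        which: _digest(
            "\n".join(
                sorted(repr(r) for r in records)
            ).encode("utf-8")
        )
        for which, records in exports.items()
    }
    digests["mapping"] = _digest(
        "\n".join(sorted(repr(r) for r in mapping.rows)).encode("utf-8")
    )
    run_id = _digest(
        json.dumps(
            {"inputs": digests, "catalogue": catalogue.schema_version, "iteration": iteration},
            sort_keys=True,
        ).encode("utf-8")
    )[:16]
    ledger = RunLedger(
        run_id=run_id,
        input_digests=digests,
        catalogue_version=catalogue.schema_version,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        iteration=iteration,
    )
    return RunResult(
        statements=statements,
        verdicts=verdicts,
        summaries=summaries,
        cohort_totals=cohort_totals,
        orphans=linked.orphans,
        exclusions=exclusions,
        unmapped=unmapped,
        imputation_provenance=imputation_provenance,
        ledger=ledger,
        centres=list(exports["centres"]),
    )


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

STATEMENT_COLUMNS = [
    "case_id", "centre_id", "cohort", "visit_id", "visit_type_id", "item_id",
    "count", "unit_cost_eur", "amount_eur", "source", "imputed",
]

SUMMARY_COLUMNS = [
    "centre_id", "cohort", "centre_class", "n_recruited", "n_reimbursable",
    "total_eur", "mean_per_case_eur", "share_ecrf_pct", "share_bio_pct",
    "share_imaging_pct", "fu_fulfilment_pct", "initiation_fee_eur",
    "grand_total_eur", "target_cases",
]


def _statement_rows(statements: Sequence[CaseStatement]) -> list[list[str]]:
    rows = []
    for st in sorted(statements, key=lambda s: s.case_id):
        for l in st.lines:
            rows.append(
                [
                    st.case_id, st.centre_id, st.cohort.value, l.visit_id,
                    l.visit_type_id, l.item_id, str(l.count),
                    money_str(l.unit_cost_eur), money_str(l.amount_eur),
                    l.source, "true" if l.imputed else "false",
                ]
            )
    return rows


def _summary_rows(summaries: Sequence[CentreSummary]) -> list[list[str]]:
    rows = []
    for s in sorted(summaries, key=lambda x: (x.cohort.value, x.centre_id)):
        rows.append(
            [
                s.centre_id, s.cohort.value, s.centre_class.value,
                str(s.n_recruited), str(s.n_reimbursable), money_str(s.total_eur),
                "" if s.mean_per_case_eur is None else money_str(s.mean_per_case_eur),
                str(s.source_shares_pct["ecrf"]), str(s.source_shares_pct["bio"]),
                str(s.source_shares_pct["imaging"]),
                "" if s.fu_fulfilment_pct is None else str(s.fu_fulfilment_pct),
                money_str(s.initiation_fee_eur), money_str(s.grand_total_eur),
                str(s.target_cases),
            ]
        )
    return rows


def _write_table(path: Path, columns: Sequence[str], rows: Sequence[Sequence[str]]) -> None:
    lines = [",".join(columns)]
    lines += [",".join(row) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def generate_reports(
    run: RunResult,
    audience: str,
    out_dir: str | Path,
    centre_id: Optional[str] = None,
) -> list[Path]:
    """Write audience-scoped statement/summary CSVs and a Markdown report.

    ``centre`` audience sees only the named centre's cases; ``coordination``
    sees everything. Output bytes depend only on run content (run_id, not the
    timestamp), so regenerating from the same run is byte-identical.
    """
    if audience not in {"centre", "coordination"}:
        raise ConfigurationError(f"unknown audience {audience!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    statements = run.statements
    summaries = run.summaries
    if audience == "centre":
        if centre_id is None:
            raise ConfigurationError("centre audience requires a centre_id")
        known = {c.centre_id for c in run.centres}
        if centre_id not in known:
            raise CatalogueLookupError(f"unknown centre {centre_id!r}")
        statements = [s for s in statements if s.centre_id == centre_id]
        summaries = [s for s in summaries if s.centre_id == centre_id]
        prefix = f"centre_{centre_id}_"
    else:
        prefix = "coordination_"

    paths = []
    p = out_dir / f"{prefix}statements.csv"
    _write_table(p, STATEMENT_COLUMNS, _statement_rows(statements))
    paths.append(p)
    p = out_dir / f"{prefix}centre_summary.csv"
    _write_table(p, SUMMARY_COLUMNS, _summary_rows(summaries))
    paths.append(p)

    md = [f"# Reimbursement report (run {run.ledger.run_id}, iteration {run.ledger.iteration})", ""]
    md.append(f"Audience: {audience}" + (f" ({centre_id})" if centre_id else ""))
    md.append("")
    md.append("| Centre | Cohort | Reimbursable cases | Total [EUR] | Mean/case [EUR] |")
    md.append("|---|---|---:|---:|---:|")
    for s in sorted(summaries, key=lambda x: (x.cohort.value, x.centre_id)):
        mean = "" if s.mean_per_case_eur is None else money_str(s.mean_per_case_eur)
        md.append(
            f"| {s.centre_id} | {s.cohort.value} | {s.n_reimbursable} "
            f"| {money_str(s.grand_total_eur)} | {mean} |"
        )
    if audience == "coordination":
        md.append("")
        md.append("## Quality gates")
        md.append("")
        for reason in Reason:
            md.append(f"- {reason.value}: {run.exclusions.get(reason, 0)} records")
        md.append(
            f"- orphans: ecrf {len(run.orphans['ecrf'])}, "
            f"bio {len(run.orphans['bio'])}, imaging {len(run.orphans['imaging'])}"
        )
        md.append(f"- unmapped eCRF items: {sum(run.unmapped.values())}")
    p = out_dir / f"{prefix}report.md"
    p.write_text("\n".join(md) + "\n", encoding="utf-8")
    paths.append(p)
    return paths


def write_run_outputs(run: RunResult, out_dir: str | Path) -> None:
    """Write the canonical run outputs (coordination scope + ledger)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_table(out_dir / "statements.csv", STATEMENT_COLUMNS, _statement_rows(run.statements))
    _write_table(out_dir / "centre_summary.csv", SUMMARY_COLUMNS, _summary_rows(run.summaries))
    cohort_rows = [
        [
            cohort, str(t["n_reimbursable"]), money_str(t["total_eur"]),
            money_str(t["mean_per_case_eur"]), money_str(t["initiation_fees_eur"]),
        ]
        for cohort, t in sorted(run.cohort_totals.items())
    ]
    _write_table(
        out_dir / "cohort_summary.csv",
        ["cohort", "n_reimbursable", "total_eur", "mean_per_case_eur", "initiation_fees_eur"],
        cohort_rows,
    )
    (out_dir / "run_ledger.json").write_text(run.ledger.to_json(), encoding="utf-8")
    generate_reports(run, "coordination", out_dir)
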