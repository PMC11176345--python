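"""Quality gates: case eligibility, record filtering, and item mapping.

A case is *recruited* once an informed consent is registered, and
*reimbursable* only if every required eCRF form of the anchoring visits was
submitted (baseline + discharge for inpatient cohorts, initial interview +
on-site visit for the population cohort) and — where a cohort demands it —
every sub-form passed the local case review. A non-reimbursable case yields
no billable lines at all.

Individual records then pass through record-level gates: eCRF items must be
submitted and pass the automated plausibility checks; biosamples must match a
configured rule (sample type with at least the minimum registered aliquot
count); imaging records must be uploaded with at least one series. Surviving
eCRF items are mapped to reimbursement items of the cost catalogue through a
reviewed mapping table; unmapped items are counted and reported, never
billed. Every exclusion lands in exactly one coded reason bucket so that
reports are machine-diffable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .catalogue import Cohort, CostCatalogue
from .errors import ConfigurationError
from .study_data import BiosampleRecord, CaseDossier, EcrfRecord, ImagingRecord


class Reason(str, Enum):
    """Closed vocabulary of exclusion / ineligibility reasons."""

    NO_CONSENT = "NO_CONSENT"
    FORMS_MISSING = "FORMS_MISSING"
    CASE_REVIEW_MISSING = "CASE_REVIEW_MISSING"
    PLAUSIBILITY_FAIL = "PLAUSIBILITY_FAIL"
    ALIQUOTS_BELOW_MIN = "ALIQUOTS_BELOW_MIN"
    NOT_UPLOADED = "NOT_UPLOADED"
    UNMAPPED_ITEM = "UNMAPPED_ITEM"


class MappingCondition(str, Enum):
    ALWAYS = "always"
    VALUE_PRESENT = "value-present"
    PLAUSIBILITY_PASS = "plausibility-pass"


@dataclass(frozen=True)
class EligibilityRuleSet:
    """Minimum criteria a case must meet to be reimbursable.

    ``required_forms`` maps a stage name (e.g. ``baseline``/``discharge``) to
    the set of form_ids that must each be submitted at least once.
    """

    cohort: Cohort
    required_forms: Mapping[str, frozenset[str]]
    require_consent: bool = True
    require_case_review: bool = False

    def __post_init__(self):
        if not self.required_forms or any(not fs for fs in self.required_forms.values()):
            raise ConfigurationError("required form sets must be non-empty")


@dataclass(frozen=True)
class MappingRow:
    ecrf_item_id: str
    reimbursement_item_id: str
    condition: MappingCondition = MappingCondition.ALWAYS
    reviewed: bool = False


@dataclass
class MappingTable:
    rows: list[MappingRow]

    def __post_init__(self):
        self._by_item: dict[str, list[MappingRow]] = {}
        for row in self.rows:
            self._by_item.setdefault(row.ecrf_item_id, []).append(row)

    def lookup(self, ecrf_item_id: str) -> list[MappingRow]:
        return self._by_item.get(ecrf_item_id, [])

    def validate_against(self, catalogue: CostCatalogue) -> None:
        unknown = sorted(
            {r.reimbursement_item_id for r in self.rows}
            - set(catalogue.items)
        )
        if unknown:
            raise ConfigurationError(
                f"mapping references unknown catalogue item(s): {unknown}"
            )

    @classmethod
    def from_csv(cls, path: str | Path) -> "MappingTable":
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"ecrf_item_id", "reimbursement_item_id", "condition"}
        if not required <= set(df.columns):
            raise ConfigurationError(
                f"mapping file misses column(s) {sorted(required - set(df.columns))}"
            )
        rows = [
            MappingRow(
                ecrf_item_id=r["ecrf_item_id"],
                reimbursement_item_id=r["reimbursement_item_id"],
                condition=MappingCondition(r["condition"] or "always"),
                reviewed=str(r.get("reviewed", "")).lower() in {"true", "1", "yes"},
            )
            for _, r in df.iterrows()
        ]
        return cls(rows)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "ecrf_item_id": r.ecrf_item_id,
                    "reimbursement_item_id": r.reimbursement_item_id,
                    "condition": r.condition.value,
                    "reviewed": "true" if r.reviewed else "false",
                }
                for r in self.rows
            ],
            columns=["ecrf_item_id", "reimbursement_item_id", "condition", "reviewed"],
        ).to_csv(path, index=False, lineterminator="\n")


@dataclass(frozen=True)
class BioRule:
    sample_type: str
    min_aliquots: int
    fee_item_id: str

    def __post_init__(self):
        if self.min_aliquots < 0:
            raise ConfigurationError("min_aliquots must be >= 0")


@dataclass(frozen=True)
class ImgRule:
    modality: str
    fee_item_id: str
    require_upload: bool = True


@dataclass
class QcVerdict:
    case_id: str
    reimbursable: bool
    reasons: tuple[Reason, ...]
    form_flags: dict[str, bool] = field(default_factory=dict)  # form_id -> ok

    def __post_init__(self):
        if self.reimbursable and self.reasons:
            raise ValueError("a reimbursable verdict cannot carry reasons")


@dataclass
class EligibleEvents:
    """Record-level filter output: survivors plus per-reason exclusions."""

    ecrf: list[EcrfRecord]
    bio: list[tuple[BiosampleRecord, str]]      # (record, fee item)
    imaging: list[tuple[ImagingRecord, str]]    # (record, fee item)
    excluded: Counter  # Reason -> count
    excluded_records: dict[Reason, list] = field(default_factory=dict)


@dataclass(frozen=True)
class BillableLine:
    """One reimbursable activity of one case, before pricing."""

    case_id: str
    visit_id: str
    visit_type_id: str
    item_id: str
    count: int
    source: str  # ecrf | bio | imaging


# ---------------------------------------------------------------------------
# Default rule sets
# ---------------------------------------------------------------------------

def default_rules(cohort: Cohort | str) -> EligibilityRuleSet:
    """Built-in minimum criteria per cohort.

    Inpatient cohorts require the baseline and discharge form; the population
    cohort requires the initial interview and on-site forms. The
    cross-sectoral cohort additionally requires passed case reviews.
    """
    cohort = Cohort(cohort)
    if cohort is Cohort.POP:
        required = {
            "initial-interview": frozenset({"pop-initial-interview-form"}),
            "onsite": frozenset({"pop-onsite-form"}),
        }
    else:
        required = {
            "baseline": frozenset({"baseline-form"}),
            "discharge": frozenset({"discharge-form"}),
        }
    return EligibilityRuleSet(
        cohort=cohort,
        required_forms=required,
        require_consent=True,
        require_case_review=(cohort is Cohort.SUEP),
    )


def load_rules(path: str | Path) -> tuple[EligibilityRuleSet, list[BioRule], list[ImgRule]]:
    """Load eligibility, biosample and imaging rules from a YAML document."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigurationError(f"rules file {path}: expected a mapping")
    try:
        rules = EligibilityRuleSet(
            cohort=Cohort(doc["cohort"]),
            required_forms={
                stage: frozenset(forms)
                for stage, forms in doc["required_forms"].items()
            },
            require_consent=bool(doc.get("require_consent", True)),
            require_case_review=bool(doc.get("require_case_review", False)),
        )
        bio_rules = [
            BioRule(
                sample_type=b["sample_type"],
                min_aliquots=int(b.get("min_aliquots", 0)),
                fee_item_id=b["fee_item_id"],
            )
            for b in doc.get("bio_rules", [])
        ]
        img_rules = [
            ImgRule(
                modality=i["modality"],
                fee_item_id=i["fee_item_id"],
                require_upload=bool(i.get("require_upload", True)),
            )
            for i in doc.get("img_rules", [])
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"rules file {path}: {exc}") from None
    return rules, bio_rules, img_rules


def dump_rules(
    rules: EligibilityRuleSet,
    bio_rules: Sequence[BioRule],
    img_rules: Sequence[ImgRule],
    path: str | Path,
) -> None:
    doc = {
        "cohort": rules.cohort.value,
        "require_consent": rules.require_consent,
        "require_case_review": rules.require_case_review,
        "required_forms": {
            stage: sorted(forms) for stage, forms in rules.required_forms.items()
        },
        "bio_rules": [
            {
                "sample_type": b.sample_type,
                "min_aliquots": b.min_aliquots,
                "fee_item_id": b.fee_item_id,
            }
            for b in bio_rules
        ],
        "img_rules": [
            {
                "modality": i.modality,
                "fee_item_id": i.fee_item_id,
                "require_upload": i.require_upload,
            }
            for i in img_rules
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def evaluate_case(dossier: CaseDossier, rules: EligibilityRuleSet) -> QcVerdict:
    """Case-level verdict: consent, required forms, case reviews.

    Failures are verdict reasons, never exceptions.
    """
    reasons: list[Reason] = []
    if rules.require_consent and not any(r.consent_registered for r in dossier.ecrf):
        reasons.append(Reason.NO_CONSENT)

    submitted_forms = {r.form_id for r in dossier.ecrf if r.submitted}
    required = {f for forms in rules.required_forms.values() for f in forms}
    if not all(f in submitted_forms for f in required):
        reasons.append(Reason.FORMS_MISSING)

    # A never-submitted form is a FORMS_MISSING failure only; a submitted
    # form whose records failed the local case review is CASE_REVIEW_MISSING.
    form_flags: dict[str, bool] = {}
    if rules.require_case_review:
        for form_id in sorted(required & submitted_forms):
            recs = [r for r in dossier.ecrf if r.form_id == form_id and r.submitted]
            form_flags[form_id] = all(r.case_review_pass for r in recs)
        if not all(form_flags.values()):
            reasons.append(Reason.CASE_REVIEW_MISSING)

    return QcVerdict(
        case_id=dossier.case_id,
        reimbursable=not reasons,
        reasons=tuple(reasons),
        form_flags=form_flags,
    )


def filter_records(
    dossier: CaseDossier,
    rules: EligibilityRuleSet,
    bio_rules: Sequence[BioRule] = (),
    img_rules: Sequence[ImgRule] = (),
) -> EligibleEvents:
    """Record-level gates; every excluded record lands in one reason bucket.

    eCRF items survive if submitted and plausibility-passed (an unsubmitted
    record counts as FORMS_MISSING, a submitted-but-implausible one as
    PLAUSIBILITY_FAIL). Biosamples survive if registered, matching a rule's
    sample type, and at or above its aliquot minimum. Imaging records survive
    if uploaded with at least one series and a matching modality rule; records
    of types/modalities without any rule are reported as UNMAPPED_ITEM.
    """
    excluded: Counter = Counter()
    excluded_records: dict[Reason, list] = {}

    def _exclude(reason: Reason, record) -> None:
        excluded[reason] += 1
        excluded_records.setdefault(reason, []).append(record)

    ecrf_ok: list[EcrfRecord] = []
    for rec in dossier.ecrf:
        if not rec.submitted:
            _exclude(Reason.FORMS_MISSING, rec)
        elif not rec.plausibility_pass:
            _exclude(Reason.PLAUSIBILITY_FAIL, rec)
        else:
            ecrf_ok.append(rec)

    bio_by_type = {b.sample_type: b for b in bio_rules}
    bio_ok: list[tuple[BiosampleRecord, str]] = []
    for rec in dossier.bio:
        rule = bio_by_type.get(rec.sample_type)
        if rule is None:
            _exclude(Reason.UNMAPPED_ITEM, rec)
        elif not rec.registered:
            _exclude(Reason.NOT_UPLOADED, rec)
        elif rec.aliquot_count < rule.min_aliquots:
            _exclude(Reason.ALIQUOTS_BELOW_MIN, rec)
        else:
            bio_ok.append((rec, rule.fee_item_id))

    img_by_modality = {i.modality: i for i in img_rules}
    img_ok: list[tuple[ImagingRecord, str]] = []
    for rec in dossier.imaging:
        rule = img_by_modality.get(rec.modality)
        if rule is None:
            _exclude(Reason.UNMAPPED_ITEM, rec)
        elif rule.require_upload and (not rec.uploaded or rec.series_count < 1):
            _exclude(Reason.NOT_UPLOADED, rec)
        else:
            img_ok.append((rec, rule.fee_item_id))

    return EligibleEvents(
        ecrf=ecrf_ok,
        bio=bio_ok,
        imaging=img_ok,
        excluded=excluded,
        excluded_records=excluded_records,
    )


def _condition_met(row: MappingRow, record: EcrfRecord) -> bool:
    if row.condition is MappingCondition.ALWAYS:
        return True
    if row.condition is MappingCondition.VALUE_PRESENT:
        return record.value.strip() != ""
    return record.submitted and record.plausibility_pass


def apply_mapping(
    events: EligibleEvents,
    mapping: MappingTable,
    catalogue: Optional[CostCatalogue] = None,
) -> tuple[list[BillableLine], Counter]:
    """Join eligible events with the mapping table into billable lines.

    Returns the lines plus a counter of unmapped eCRF items (reported, never
    billed). Bio/imaging events carry their fee item from their rule.
    """
    if catalogue is not None:
        mapping.validate_against(catalogue)
    visit_types = {r.visit_id: r.visit_type_id for r in events.ecrf}

    lines: list[BillableLine] = []
    unmapped: Counter = Counter()
    for rec in events.ecrf:
        rows = mapping.lookup(rec.item_id)
        if not rows:
            unmapped[rec.item_id] += 1
            continue
        for row in rows:
            if _condition_met(row, rec):
                lines.append(
                    BillableLine(
                        case_id="",  # filled by caller context
                        visit_id=rec.visit_id,
                        visit_type_id=rec.visit_type_id,
                        item_id=row.reimbursement_item_id,
                        count=1,
                        source="ecrf",
                    )
                )
    for rec, fee_item in events.bio:
        lines.append(
            BillableLine(
                case_id="",
                visit_id=rec.visit_id,
                visit_type_id=visit_types.get(rec.visit_id, ""),
                item_id=fee_item,
                count=1,
                source="bio",
            )
        )
    for rec, fee_item in events.imaging:
        lines.append(
            BillableLine(
                case_id="",
                visit_id=rec.visit_id,
                visit_type_id=visit_types.get(rec.visit_id, ""),
                item_id=fee_item,
                count=1,
                source="imaging",
            )
        )
    return lines, unmapped


def billable_lines(
    dossier: CaseDossier,
    rules: EligibilityRuleSet,
    mapping: MappingTable,
    bio_rules: Sequence[BioRule] = (),
    img_rules: Sequence[ImgRule] = (),
    catalogue: Optional[CostCatalogue] = None,
) -> tuple[QcVerdict, list[BillableLine], EligibleEvents, Counter]:
    """Full per-case gate: verdict, then filtered and mapped lines.

    A non-reimbursable case yields zero billable lines.
    """
    verdict = evaluate_case(dossier, rules)
    events = filter_records(dossier, rules, bio_rules, img_rules)
    if not verdict.reimbursable:
        return verdict, [], events, Counter()
    raw_lines, unmapped = apply_mapping(events, mapping, catalogue)
    lines = [
        BillableLine(
            case_id=dossier.case_id,
            visit_id=l.visit_id,
            visit_type_id=l.visit_type_id,
            item_id=l.item_id,
            count=l.count,
            source=l.source,
        )
        for l in raw_lines
    ]
    return verdict, lines, events, unmapped
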