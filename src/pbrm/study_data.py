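"""System exports, centre registry, pseudonym linkage, and case dossiers.

Three pseudonymised data-management systems feed the reimbursement engine:
clinical documentation (eCRF), biosampling, and imaging uploads. Each system
uses its own pseudonym namespace; a trusted-third-party style linkage table
maps the per-system pseudonyms onto one reimbursement case without any
identity fields ever entering the model. The eCRF is the anchor system: a
case without eCRF records is not reimbursable and can only appear in the
orphan report.

All exports are flat UTF-8 CSV files (comma separator, dot decimal, ISO-8601
dates) with fixed, documented headers; an equivalent JSON-lines form with
identical field names is also read.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, fields as _dc_fields
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

from ._money import as_decimal
from .catalogue import CentreClass, Cohort
from .errors import ExportValidationError, LinkageIntegrityError

ExportKind = Literal["ecrf", "bio", "imaging", "centres", "linkage"]


@dataclass(frozen=True)
class CentreRecord:
    centre_id: str
    display_letter: str
    cohort: Cohort
    centre_class: CentreClass
    target_cases: Decimal  # fractional targets (e.g. 73.5) are allowed


@dataclass(frozen=True)
class EcrfRecord:
    """One documented eCRF data item.

    ``consent_registered`` is a case-level flag replicated onto each record;
    ``case_review_pass`` applies to the record's sub-form.
    """

    ecrf_pseudonym: str
    centre_id: str
    visit_id: str
    visit_type_id: str
    visit_date: _dt.date
    form_id: str
    item_id: str
    value: str
    submitted: bool
    plausibility_pass: bool
    case_review_pass: bool
    consent_registered: bool


@dataclass(frozen=True)
class BiosampleRecord:
    bio_pseudonym: str
    visit_id: str
    sample_type: str
    aliquot_count: int
    registered: bool


@dataclass(frozen=True)
class ImagingRecord:
    img_pseudonym: str
    visit_id: str
    modality: str
    series_count: int
    uploaded: bool


@dataclass(frozen=True)
class LinkageRow:
    case_id: str
    ecrf_pseudonym: str
    bio_pseudonym: Optional[str] = None
    img_pseudonym: Optional[str] = None


@dataclass
class CaseDossier:
    """All records of one reimbursement case, linked across systems."""

    case_id: str
    centre_id: str
    cohort: Cohort
    ecrf: list[EcrfRecord]
    bio: list[BiosampleRecord]
    imaging: list[ImagingRecord]


@dataclass
class LinkResult:
    dossiers: list[CaseDossier]
    orphans: dict[str, list]  # system -> records that could not be linked


# ---------------------------------------------------------------------------
# Schemas
# ---------------------------------------------------------------------------

EXPORT_COLUMNS: dict[str, list[str]] = {
    "ecrf": [
        "ecrf_pseudonym", "centre_id", "visit_id", "visit_type_id", "visit_date",
        "form_id", "item_id", "value", "submitted", "plausibility_pass",
        "case_review_pass", "consent_registered",
    ],
    "bio": ["bio_pseudonym", "visit_id", "sample_type", "aliquot_count", "registered"],
    "imaging": ["img_pseudonym", "visit_id", "modality", "series_count", "uploaded"],
    "centres": ["centre_id", "display_letter", "cohort", "centre_class", "target_cases"],
    "linkage": ["case_id", "ecrf_pseudonym", "bio_pseudonym", "img_pseudonym"],
}

EXPORT_FILENAMES: dict[str, str] = {
    "ecrf": "ecrf.csv",
    "bio": "biosamples.csv",
    "imaging": "imaging.csv",
    "centres": "centres.csv",
    "linkage": "linkage.csv",
}

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(value: str, column: str, row: int) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ExportValidationError(f"column {column!r}: unparsable flag {value!r}", [row])


def _parse_int(value: str, column: str, row: int, minimum: int = 0) -> int:
    try:
        out = int(value)
    except ValueError:
        raise ExportValidationError(f"column {column!r}: unparsable integer {value!r}", [row])
    if out < minimum:
        raise ExportValidationError(f"column {column!r}: value {out} below {minimum}", [row])
    return out


def _parse_date(value: str, column: str, row: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(value)
    except ValueError:
        raise ExportValidationError(f"column {column!r}: unparsable ISO date {value!r}", [row])


def _load_rows(path: Path, which: str) -> list[tuple[int, dict[str, str]]]:
    """Rows as (1-based file row number, field dict); CSV or JSON-lines."""
    expected = EXPORT_COLUMNS[which]
    if path.suffix in {".jsonl", ".ndjson"}:
        rows = []
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                obj = json.loads(line)
                unknown = set(obj) - set(expected)
                if unknown:
                    raise ExportValidationError(
                        f"{path.name}: unknown column(s) {sorted(unknown)}", [i]
                    )
                rows.append((i, {c: str(obj.get(c, "")) for c in expected}))
        return rows
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = set(df.columns) - set(expected)
    missing = set(expected) - set(df.columns)
    if unknown or missing:
        parts = []
        if unknown:
            parts.append(f"unknown column(s) {sorted(unknown)}")
        if missing:
            parts.append(f"missing column(s) {sorted(missing)}")
        raise ExportValidationError(f"{path.name}: " + "; ".join(parts))
    # +2: header is file row 1
    return [(i + 2, {c: row[c] for c in expected}) for i, row in df.iterrows()]


def _check_unique(keys: Iterable[tuple[int, tuple]], what: str) -> None:
    seen: dict[tuple, int] = {}
    for row, key in keys:
        if key in seen:
            raise ExportValidationError(
                f"duplicate {what} {key!r}", [seen[key], row]
            )
        seen[key] = row


def read_export(path: str | Path, which: ExportKind) -> list:
    """Read and validate one system export; returns typed records.

    Row numbers refer to the source file (header = row 1) and are included in
    every validation error.
    """
    path = Path(path)
    if which not in EXPORT_COLUMNS:
        raise ExportValidationError(f"unknown export kind {which!r}")
    if not path.exists():
        raise ExportValidationError(f"export file not found: {path}")
    rows = _load_rows(path, which)

    if which == "ecrf":
        records = [
            EcrfRecord(
                ecrf_pseudonym=r["ecrf_pseudonym"],
                centre_id=r["centre_id"],
                visit_id=r["visit_id"],
                visit_type_id=r["visit_type_id"],
                visit_date=_parse_date(r["visit_date"], "visit_date", n),
                form_id=r["form_id"],
                item_id=r["item_id"],
                value=r["value"],
                submitted=_parse_bool(r["submitted"], "submitted", n),
                plausibility_pass=_parse_bool(r["plausibility_pass"], "plausibility_pass", n),
                case_review_pass=_parse_bool(r["case_review_pass"], "case_review_pass", n),
                consent_registered=_parse_bool(r["consent_registered"], "consent_registered", n),
            )
            for n, r in rows
        ]
        _check_unique(
            (
                (n, (r["ecrf_pseudonym"], r["visit_id"], r["form_id"], r["item_id"]))
                for n, r in rows
            ),
            "(pseudonym, visit, form, item) key",
        )
        return records
    if which == "bio":
        return [
            BiosampleRecord(
                bio_pseudonym=r["bio_pseudonym"],
                visit_id=r["visit_id"],
                sample_type=r["sample_type"],
                aliquot_count=_parse_int(r["aliquot_count"], "aliquot_count", n),
                registered=_parse_bool(r["registered"], "registered", n),
            )
            for n, r in rows
        ]
    if which == "imaging":
        return [
            ImagingRecord(
                img_pseudonym=r["img_pseudonym"],
                visit_id=r["visit_id"],
                modality=r["modality"],
                series_count=_parse_int(r["series_count"], "series_count", n),
                uploaded=_parse_bool(r["uploaded"], "uploaded", n),
            )
            for n, r in rows
        ]
    if which == "centres":
        records = []
        for n, r in rows:
            try:
                target = as_decimal(r["target_cases"])
            except (InvalidOperation, ValueError):
                raise ExportValidationError(
                    f"column 'target_cases': unparsable number {r['target_cases']!r}", [n]
                )
            if target < 0:
                raise ExportValidationError("column 'target_cases': negative target", [n])
            try:
                records.append(
                    CentreRecord(
                        centre_id=r["centre_id"],
                        display_letter=r["display_letter"],
                        cohort=Cohort(r["cohort"]),
                        centre_class=CentreClass(r["centre_class"]),
                        target_cases=target,
                    )
                )
            except ValueError as exc:
                raise ExportValidationError(str(exc), [n])
        _check_unique(((n, (r["centre_id"],)) for n, r in rows), "centre_id")
        _check_unique(
            ((n, (r["cohort"], r["display_letter"])) for n, r in rows),
            "(cohort, display_letter)",
        )
        return records
    # linkage
    records = [
        LinkageRow(
            case_id=r["case_id"],
            ecrf_pseudonym=r["ecrf_pseudonym"],
            bio_pseudonym=r["bio_pseudonym"] or None,
            img_pseudonym=r["img_pseudonym"] or None,
        )
        for n, r in rows
    ]
    for col in ("ecrf_pseudonym", "bio_pseudonym", "img_pseudonym"):
        _check_unique(
            ((n, (r[col],)) for n, r in rows if r[col]), f"{col} in linkage"
        )
    _check_unique(((n, (r["case_id"],)) for n, r in rows), "case_id in linkage")
    return records


def _record_to_row(record) -> dict[str, str]:
    out = {}
    for f in _dc_fields(record):
        v = getattr(record, f.name)
        if isinstance(v, bool):
            out[f.name] = "true" if v else "false"
        elif v is None:
            out[f.name] = ""
        elif isinstance(v, (Cohort, CentreClass)):
            out[f.name] = v.value
        elif isinstance(v, _dt.date):
            out[f.name] = v.isoformat()
        else:
            out[f.name] = str(v)
    return out


def write_export(records: Sequence, path: str | Path, which: ExportKind) -> None:
    """Write records in the canonical CSV dialect (deterministic byte output)."""
    columns = EXPORT_COLUMNS[which]
    df = pd.DataFrame([_record_to_row(r) for r in records], columns=columns)
    df.to_csv(path, index=False, lineterminator="\n")


def read_exports_dir(directory: str | Path) -> dict[str, list]:
    """Read all five exports from a directory using the standard file names."""
    directory = Path(directory)
    return {
        which: read_export(directory / name, which)  # type: ignore[arg-type]
        for which, name in EXPORT_FILENAMES.items()
    }


# ---------------------------------------------------------------------------
# Linkage
# ---------------------------------------------------------------------------

def link_cases(
    linkage: Sequence[LinkageRow],
    ecrf: Sequence[EcrfRecord],
    bio: Sequence[BiosampleRecord],
    imaging: Sequence[ImagingRecord],
    centres: Sequence[CentreRecord],
) -> LinkResult:
    """Assemble one dossier per case; unlinkable records become orphans.

    The eCRF anchors a case: bio/imaging records whose pseudonym links to a
    case without any eCRF record are orphaned, not silently dropped. Output
    order is by case_id, independent of input row order.
    """
    ecrf_to_case: dict[str, str] = {}
    bio_to_case: dict[str, str] = {}
    img_to_case: dict[str, str] = {}
    for row in linkage:
        for mapping, pseud in (
            (ecrf_to_case, row.ecrf_pseudonym),
            (bio_to_case, row.bio_pseudonym),
            (img_to_case, row.img_pseudonym),
        ):
            if not pseud:
                continue
            if pseud in mapping and mapping[pseud] != row.case_id:
                raise LinkageIntegrityError(
                    f"pseudonym {pseud!r} appears under case_ids "
                    f"{mapping[pseud]!r} and {row.case_id!r}"
                )
            mapping[pseud] = row.case_id

    centre_by_id = {c.centre_id: c for c in centres}

    by_case_ecrf: dict[str, list[EcrfRecord]] = {}
    orphans: dict[str, list] = {"ecrf": [], "bio": [], "imaging": []}
    for rec in ecrf:
        case_id = ecrf_to_case.get(rec.ecrf_pseudonym)
        if case_id is None:
            orphans["ecrf"].append(rec)
        else:
            by_case_ecrf.setdefault(case_id, []).append(rec)

    anchored = set(by_case_ecrf)
    by_case_bio: dict[str, list[BiosampleRecord]] = {}
    for rec in bio:
        case_id = bio_to_case.get(rec.bio_pseudonym)
        if case_id is None or case_id not in anchored:
            orphans["bio"].append(rec)
        else:
            by_case_bio.setdefault(case_id, []).append(rec)
    by_case_img: dict[str, list[ImagingRecord]] = {}
    for rec in imaging:
        case_id = img_to_case.get(rec.img_pseudonym)
        if case_id is None or case_id not in anchored:
            orphans["imaging"].append(rec)
        else:
            by_case_img.setdefault(case_id, []).append(rec)

    def _sort_key(rec: EcrfRecord):
        return (rec.visit_date, rec.visit_id, rec.form_id, rec.item_id)

    dossiers = []
    for case_id in sorted(anchored):
        records = sorted(by_case_ecrf[case_id], key=_sort_key)
        centre_ids = {r.centre_id for r in records}
        if len(centre_ids) > 1:
            raise LinkageIntegrityError(
                f"case {case_id!r} carries records from several centres: "
                f"{sorted(centre_ids)}"
            )
        centre_id = records[0].centre_id
        centre = centre_by_id.get(centre_id)
        if centre is None:
            raise LinkageIntegrityError(
                f"case {case_id!r} references unknown centre {centre_id!r}"
            )
        dossiers.append(
            CaseDossier(
                case_id=case_id,
                centre_id=centre_id,
                cohort=centre.cohort,
                ecrf=records,
                bio=sorted(
                    by_case_bio.get(case_id, []),
                    key=lambda r: (r.visit_id, r.sample_type, r.aliquot_count),
                ),
                imaging=sorted(
                    by_case_img.get(case_id, []),
                    key=lambda r: (r.visit_id, r.modality, r.series_count),
                ),
            )
        )
    return LinkResult(dossiers=dossiers, orphans=orphans)
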