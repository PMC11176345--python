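"""Shared fixtures and record builders for the test suite."""

from __future__ import annotations

import datetime as dt

import pytest

from pbrm import (
    BiosampleRecord,
    CaseDossier,
    Cohort,
    EcrfRecord,
    ImagingRecord,
    reference_catalogue,
)


@pytest.fixture(scope="session")
def catalogue():
    return reference_catalogue()


def ecrf_rec(
    pseud="E00001",
    centre="HAP-A",
    visit="V01",
    vtype="baseline",
    date="2021-03-01",
    form="baseline-form",
    item="ecrf:ecg",
    value="x",
    submitted=True,
    plausible=True,
    review=True,
    consent=True,
) -> EcrfRecord:
    return EcrfRecord(
        ecrf_pseudonym=pseud,
        centre_id=centre,
        visit_id=visit,
        visit_type_id=vtype,
        visit_date=dt.date.fromisoformat(date),
        form_id=form,
        item_id=item,
        value=value,
        submitted=submitted,
        plausibility_pass=plausible,
        case_review_pass=review,
        consent_registered=consent,
    )


def bio_rec(pseud="B00001", visit="V01", stype="edta-pbmc", aliquots=4, registered=True):
    return BiosampleRecord(
        bio_pseudonym=pseud,
        visit_id=visit,
        sample_type=stype,
        aliquot_count=aliquots,
        registered=registered,
    )


def img_rec(pseud="I00001", visit="V01", modality="echo", series=2, uploaded=True):
    return ImagingRecord(
        img_pseudonym=pseud,
        visit_id=visit,
        modality=modality,
        series_count=series,
        uploaded=uploaded,
    )


def make_dossier(case_id="C00001", centre="HAP-A", cohort=Cohort.HAP,
                 ecrf=(), bio=(), imaging=()) -> CaseDossier:
    return CaseDossier(
        case_id=case_id,
        centre_id=centre,
        cohort=cohort,
        ecrf=list(ecrf),
        bio=list(bio),
        imaging=list(imaging),
    )


def minimal_reimbursable_ecrf(case_no=1, centre="HAP-A"):
    """Baseline + discharge form records meeting the minimum criteria."""
    pseud = f"E{case_no:05d}"
    return [
        ecrf_rec(pseud=pseud, centre=centre, visit="V01", vtype="baseline",
                 form="baseline-form", item="ecrf:ecg"),
        ecrf_rec(pseud=pseud, centre=centre, visit="V02", vtype="discharge",
                 date="2021-03-05", form="discharge-form", item="ecrf:clinical-status"),
    ]
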