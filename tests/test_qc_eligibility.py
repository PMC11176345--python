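"""Eligibility verdicts, record-level quality gates, and item mapping."""

import random
from collections import Counter

import pytest

from pbrm import (
    BioRule,
    Cohort,
    ImgRule,
    MappingCondition,
    MappingRow,
    MappingTable,
    Reason,
    apply_mapping,
    billable_lines,
    default_rules,
    evaluate_case,
    filter_records,
)
from pbrm.errors import ConfigurationError

from conftest import bio_rec, ecrf_rec, img_rec, make_dossier, minimal_reimbursable_ecrf

BIO_RULES = [BioRule("edta-pbmc", 1, "pbmc")]
IMG_RULES = [ImgRule("echo", "echocardiogram")]


# ---------------------------------------------------------------------------
# Case verdicts
# ---------------------------------------------------------------------------

def test_complete_case_is_reimbursable():
    dossier = make_dossier(ecrf=minimal_reimbursable_ecrf())
    verdict = evaluate_case(dossier, default_rules(Cohort.HAP))
    assert verdict.reimbursable and verdict.reasons == ()


def test_missing_case_review_blocks_suep_case():
    recs = minimal_reimbursable_ecrf(centre="SUEP-A")
    failed = ecrf_rec(pseud=recs[0].ecrf_pseudonym, centre="SUEP-A", visit="V02",
                      vtype="discharge", date="2021-03-05", form="discharge-form",
                      item="ecrf:spirometry", review=False)
    dossier = make_dossier(centre="SUEP-A", cohort=Cohort.SUEP, ecrf=recs + [failed])
    verdict = evaluate_case(dossier, default_rules(Cohort.SUEP))
    assert not verdict.reimbursable
    assert verdict.reasons == (Reason.CASE_REVIEW_MISSING,)


def test_case_review_ignored_where_not_required():
    recs = [r for r in minimal_reimbursable_ecrf()]
    flawed = [ecrf_rec(visit="V03", vtype="ward-day", form="ward-day-form",
                       item="ecrf:doc-ward", review=False)]
    verdict = evaluate_case(make_dossier(ecrf=recs + flawed), default_rules(Cohort.HAP))
    assert verdict.reimbursable


def test_empty_dossier_fails_consent_and_forms():
    verdict = evaluate_case(make_dossier(ecrf=[]), default_rules(Cohort.HAP))
    assert not verdict.reimbursable
    assert set(verdict.reasons) == {Reason.NO_CONSENT, Reason.FORMS_MISSING}


def test_unsubmitted_required_form_is_forms_missing_only():
    recs = [
        ecrf_rec(form="baseline-form"),
        ecrf_rec(visit="V02", vtype="discharge", form="discharge-form",
                 item="ecrf:clinical-status", submitted=False, review=False),
    ]
    verdict = evaluate_case(make_dossier(cohort=Cohort.SUEP, ecrf=recs),
                            default_rules(Cohort.SUEP))
    assert verdict.reasons == (Reason.FORMS_MISSING,)


def test_pop_rules_require_interview_and_onsite():
    rules = default_rules(Cohort.POP)
    recs = [
        ecrf_rec(centre="POP-A", vtype="pop-initial-interview",
                 form="pop-initial-interview-form", item="ecrf:clinical-status"),
        ecrf_rec(centre="POP-A", visit="V02", vtype="pop-onsite",
                 form="pop-onsite-form", item="ecrf:ecg"),
    ]
    assert evaluate_case(make_dossier(centre="POP-A", cohort=Cohort.POP, ecrf=recs),
                         rules).reimbursable
    assert not evaluate_case(make_dossier(centre="POP-A", cohort=Cohort.POP,
                                          ecrf=recs[:1]), rules).reimbursable


# ---------------------------------------------------------------------------
# Record filtering
# ---------------------------------------------------------------------------

def test_all_passing_records_survive():
    dossier = make_dossier(
        ecrf=minimal_reimbursable_ecrf(),
        bio=[bio_rec()],
        imaging=[img_rec()],
    )
    events = filter_records(dossier, default_rules(Cohort.HAP), BIO_RULES, IMG_RULES)
    assert len(events.ecrf) == 2 and len(events.bio) == 1 and len(events.imaging) == 1
    assert sum(events.excluded.values()) == 0


def test_constructed_failures_match_record_by_record_oracle():
    """10 records with 3 constructed failures: survivors equal a brute-force
    record-by-record check."""
    recs = []
    for i in range(8):
        recs.append(
            ecrf_rec(visit=f"V{i:02d}", item=f"ecrf:item{i}",
                     submitted=(i != 2),        # failure 1: unsubmitted
                     plausible=(i != 5))        # failure 2: implausible
        )
    bio = [bio_rec(aliquots=0)]                  # failure 3: below aliquot minimum
    bio.append(bio_rec(visit="V09", aliquots=2))
    dossier = make_dossier(ecrf=recs, bio=bio)
    events = filter_records(dossier, default_rules(Cohort.HAP), BIO_RULES, IMG_RULES)

    oracle_ecrf = [r for r in recs if r.submitted and r.plausibility_pass]
    oracle_bio = [r for r in bio if r.registered and r.aliquot_count >= 1]
    assert events.ecrf == oracle_ecrf
    assert [r for r, _ in events.bio] == oracle_bio
    assert len(events.ecrf) + len(events.bio) == 7
    assert events.excluded[Reason.FORMS_MISSING] == 1
    assert events.excluded[Reason.PLAUSIBILITY_FAIL] == 1
    assert events.excluded[Reason.ALIQUOTS_BELOW_MIN] == 1


@pytest.mark.parametrize(
    "record_kw,reason",
    [
        (dict(aliquots=0), Reason.ALIQUOTS_BELOW_MIN),
        (dict(registered=False), Reason.NOT_UPLOADED),
        (dict(stype="unknown-sample"), Reason.UNMAPPED_ITEM),
    ],
)
def test_bio_exclusion_reasons(record_kw, reason):
    dossier = make_dossier(ecrf=minimal_reimbursable_ecrf(), bio=[bio_rec(**record_kw)])
    events = filter_records(dossier, default_rules(Cohort.HAP), BIO_RULES, IMG_RULES)
    assert events.bio == []
    assert events.excluded[reason] == 1


@pytest.mark.parametrize(
    "record_kw,reason",
    [
        (dict(uploaded=False), Reason.NOT_UPLOADED),
        (dict(series=0), Reason.NOT_UPLOADED),
        (dict(modality="mri"), Reason.UNMAPPED_ITEM),
    ],
)
def test_imaging_exclusion_reasons(record_kw, reason):
    dossier = make_dossier(ecrf=minimal_reimbursable_ecrf(), imaging=[img_rec(**record_kw)])
    events = filter_records(dossier, default_rules(Cohort.HAP), BIO_RULES, IMG_RULES)
    assert events.imaging == []
    assert events.excluded[reason] == 1


def _random_dossier(seed):
    rng = random.Random(seed)
    ecrf = [
        ecrf_rec(visit=f"V{i:02d}", item=f"ecrf:i{i}",
                 submitted=rng.random() < 0.8, plausible=rng.random() < 0.8)
        for i in range(rng.randint(0, 15))
    ]
    bio = [
        bio_rec(visit=f"V{i:02d}", aliquots=rng.randint(0, 4),
                registered=rng.random() < 0.9,
                stype=rng.choice(["edta-pbmc", "serum"]))
        for i in range(rng.randint(0, 5))
    ]
    imaging = [
        img_rec(visit=f"V{i:02d}", uploaded=rng.random() < 0.9,
                series=rng.randint(0, 3), modality=rng.choice(["echo", "ct"]))
        for i in range(rng.randint(0, 5))
    ]
    return make_dossier(ecrf=ecrf, bio=bio, imaging=imaging)


@pytest.mark.parametrize("seed", range(10))
def test_every_record_in_exactly_one_bucket(seed):
    dossier = _random_dossier(seed)
    events = filter_records(dossier, default_rules(Cohort.HAP), BIO_RULES, IMG_RULES)
    survivors = len(events.ecrf) + len(events.bio) + len(events.imaging)
    total = len(dossier.ecrf) + len(dossier.bio) + len(dossier.imaging)
    assert survivors + sum(events.excluded.values()) == total
    # excluded_records partition matches the counter
    assert sum(len(v) for v in events.excluded_records.values()) == sum(
        events.excluded.values()
    )


@pytest.mark.parametrize("seed", range(5))
def test_filtering_is_idempotent(seed):
    dossier = _random_dossier(seed)
    rules = default_rules(Cohort.HAP)
    once = filter_records(dossier, rules, BIO_RULES, IMG_RULES)
    again = filter_records(
        make_dossier(ecrf=once.ecrf, bio=[r for r, _ in once.bio],
                     imaging=[r for r, _ in once.imaging]),
        rules, BIO_RULES, IMG_RULES,
    )
    assert again.ecrf == once.ecrf
    assert again.bio == once.bio
    assert again.imaging == once.imaging
    assert sum(again.excluded.values()) == 0


def test_removing_a_record_never_adds_billable_lines():
    mapping = MappingTable(
        [MappingRow(f"ecrf:i{i}", "ecg", MappingCondition.ALWAYS) for i in range(15)]
    )
    rules = default_rules(Cohort.HAP)
    for seed in range(5):
        dossier = _random_dossier(seed)
        dossier.ecrf.extend(minimal_reimbursable_ecrf())
        base_lines = billable_lines(dossier, rules, mapping, BIO_RULES, IMG_RULES)[1]
        for drop in range(len(dossier.ecrf)):
            reduced = make_dossier(
                ecrf=dossier.ecrf[:drop] + dossier.ecrf[drop + 1:],
                bio=dossier.bio, imaging=dossier.imaging,
            )
            reduced_lines = billable_lines(reduced, rules, mapping, BIO_RULES, IMG_RULES)[1]
            assert len(reduced_lines) <= len(base_lines)


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

def test_condition_plausibility_pass_blocks_failed_record():
    mapping = MappingTable([MappingRow("ecrf:x", "ecg", MappingCondition.PLAUSIBILITY_PASS)])
    rec = ecrf_rec(item="ecrf:x", plausible=False)
    events = filter_records(make_dossier(ecrf=[rec]), default_rules(Cohort.HAP))
    lines, unmapped = apply_mapping(events, mapping)
    assert lines == [] and not unmapped


def test_condition_value_present():
    mapping = MappingTable([MappingRow("ecrf:x", "ecg", MappingCondition.VALUE_PRESENT)])
    events = filter_records(
        make_dossier(ecrf=[ecrf_rec(item="ecrf:x", value=""),
                           ecrf_rec(visit="V02", item="ecrf:x", value="7")]),
        default_rules(Cohort.HAP),
    )
    lines, _ = apply_mapping(events, mapping)
    assert len(lines) == 1 and lines[0].visit_id == "V02"


def test_toy_mapping_matches_enumeration_oracle():
    """3 mapping rows over 5 events: the line multiset equals a brute-force join."""
    mapping_rows = [
        MappingRow("ecrf:a", "ecg", MappingCondition.ALWAYS),
        MappingRow("ecrf:a", "clinical-status", MappingCondition.ALWAYS),  # multi-map
        MappingRow("ecrf:b", "doc-ward", MappingCondition.ALWAYS),
    ]
    mapping = MappingTable(mapping_rows)
    events_items = ["ecrf:a", "ecrf:b", "ecrf:a", "ecrf:c", "ecrf:b"]
    recs = [ecrf_rec(visit=f"V{i}", item=item) for i, item in enumerate(events_items)]
    events = filter_records(make_dossier(ecrf=recs), default_rules(Cohort.HAP))
    lines, unmapped = apply_mapping(events, mapping)

    oracle = Counter()
    for rec in recs:
        for row in mapping_rows:
            if row.ecrf_item_id == rec.item_id:
                oracle[(rec.visit_id, row.reimbursement_item_id)] += 1
    assert Counter((l.visit_id, l.item_id) for l in lines) == oracle
    assert unmapped == Counter({"ecrf:c": 1})


def test_unmapped_items_counted_never_billed(catalogue):
    mapping = MappingTable([MappingRow("ecrf:known", "ecg", MappingCondition.ALWAYS)])
    recs = [ecrf_rec(item="ecrf:known"), ecrf_rec(visit="V02", item="ecrf:mystery")]
    events = filter_records(make_dossier(ecrf=recs), default_rules(Cohort.HAP))
    lines, unmapped = apply_mapping(events, mapping, catalogue)
    assert [l.item_id for l in lines] == ["ecg"]
    assert unmapped["ecrf:mystery"] == 1


def test_mapping_to_unknown_catalogue_item_rejected(catalogue):
    mapping = MappingTable([MappingRow("ecrf:x", "no-such-item", MappingCondition.ALWAYS)])
    with pytest.raises(ConfigurationError, match="no-such-item"):
        mapping.validate_against(catalogue)


def test_non_reimbursable_case_yields_no_lines(catalogue):
    mapping = MappingTable([MappingRow("ecrf:ecg", "ecg", MappingCondition.ALWAYS)])
    dossier = make_dossier(ecrf=[ecrf_rec(consent=False)], bio=[bio_rec()])
    verdict, lines, events, unmapped = billable_lines(
        dossier, default_rules(Cohort.HAP), mapping, BIO_RULES, IMG_RULES, catalogue
    )
    assert not verdict.reimbursable
    assert lines == []


def test_mapping_csv_round_trip(tmp_path):
    mapping = MappingTable(
        [
            MappingRow("ecrf:a", "ecg", MappingCondition.ALWAYS, reviewed=True),
            MappingRow("ecrf:b", "pbmc", MappingCondition.PLAUSIBILITY_PASS),
        ]
    )
    mapping.to_csv(tmp_path / "m.csv")
    back = MappingTable.from_csv(tmp_path / "m.csv")
    assert back.rows == mapping.rows
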