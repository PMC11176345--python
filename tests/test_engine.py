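"""Statement pricing, imputation, aggregation, reports, audit sampling."""

import datetime as dt
import random
from collections import Counter
from decimal import Decimal

import numpy as np
import pytest

from pbrm import (
    AnnouncedVisit,
    BillableLine,
    CaseStatement,
    CentreClass,
    CentreRecord,
    Cohort,
    ExperienceValues,
    ImputationSpec,
    StatementLine,
    aggregate_centre,
    aggregate_cohort,
    compute_case_statement,
    fu_fulfilment,
    generate_reports,
    impute_future_visits,
    random_audit_sample,
)
from pbrm.errors import (
    CatalogueLookupError,
    ImputationError,
    PbrmError,
    SamplingError,
)

D = Decimal


def line(item_id, count=1, visit="V01", vtype="baseline", source="ecrf"):
    return BillableLine(case_id="C1", visit_id=visit, visit_type_id=vtype,
                        item_id=item_id, count=count, source=source)


HAP_CENTRE = CentreRecord("HAP-A", "A", Cohort.HAP, CentreClass.AMC, D("73.5"))


# ---------------------------------------------------------------------------
# Case statements
# ---------------------------------------------------------------------------

def test_statement_total_sums_item_costs(catalogue):
    st = compute_case_statement(
        "C1", "HAP-A", Cohort.HAP,
        [line("doc-ward"), line("doc-icu"), line("ecg")],
        catalogue,
    )
    assert st.total_eur == D("66.00") + D("123.00") + D("17.67") == D("206.67")


def test_empty_statement_is_zero(catalogue):
    st = compute_case_statement("C1", "HAP-A", Cohort.HAP, [], catalogue)
    assert st.total_eur == D("0.00")


def test_unknown_item_raises(catalogue):
    with pytest.raises(CatalogueLookupError):
        compute_case_statement("C1", "HAP-A", Cohort.HAP, [line("bogus")], catalogue)


def test_random_lines_match_multiply_and_sum_oracle(catalogue):
    rng = random.Random(99)
    items = list(catalogue.items)
    lines = [
        line(rng.choice(items), count=rng.randint(1, 5),
             source=rng.choice(["ecrf", "bio", "imaging"]))
        for _ in range(200)
    ]
    st = compute_case_statement("C1", "HAP-A", Cohort.HAP, lines, catalogue)
    # independent oracle: per-line multiplication and one flat sum
    oracle = sum(
        (catalogue.item_cost(l.item_id) * l.count for l in lines), D(0)
    )
    assert st.total_eur == oracle.quantize(D("0.01"))
    assert sum(st.totals_by_source.values(), D(0)) == st.total_eur


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------

def _statement_with_visits(case_id, centre, visits):
    """visits: list of (visit_id, visit_type, amount)"""
    return CaseStatement(
        case_id=case_id, centre_id=centre, cohort=Cohort.HAP,
        lines=[
            StatementLine(visit_id=v, visit_type_id=t, item_id="x", count=1,
                          unit_cost_eur=D(a), amount_eur=D(a), source="ecrf")
            for v, t, a in visits
        ],
    )


FREEZE = dt.date(2021, 12, 31)


def test_no_announced_visits_leaves_statement_unchanged():
    st = _statement_with_visits("C1", "HAP-A", [("V1", "fu-3mo", "100.00")])
    spec = ImputationSpec(FREEZE, announced=[])
    exp = ExperienceValues({}, {}, {})
    out, prov = impute_future_visits(st, spec, exp)
    assert out.lines == st.lines and prov == []


def test_imputed_value_is_centre_mean():
    history = [
        _statement_with_visits(f"C{i}", "HAP-A", [(f"V{i}", "fu-3mo", a)])
        for i, a in enumerate(["100.00", "120.00", "140.00"])
    ]
    pending = _statement_with_visits("C9", "HAP-A", [("V1", "baseline", "50.00")])
    exp = ExperienceValues.from_statements(history + [pending])
    spec = ImputationSpec(
        FREEZE, announced=[AnnouncedVisit("C9", "fu-3mo", dt.date(2022, 1, 15))]
    )
    out, prov = impute_future_visits(pending, spec, exp)
    imputed = [l for l in out.lines if l.imputed]
    assert len(imputed) == 1
    assert imputed[0].amount_eur == D("120.00")  # arithmetic mean oracle
    assert prov == ["centre-level"]
    # originals untouched
    assert [l for l in out.lines if not l.imputed] == pending.lines


def test_fallback_to_cohort_mean_then_configured():
    other_centre = _statement_with_visits("C1", "HAP-B", [("V1", "fu-3mo", "90.00")])
    pending = _statement_with_visits("C9", "HAP-A", [("V1", "baseline", "50.00")])
    exp = ExperienceValues.from_statements([other_centre, pending])
    spec = ImputationSpec(
        FREEZE, announced=[AnnouncedVisit("C9", "fu-3mo", dt.date(2022, 1, 15))]
    )
    out, prov = impute_future_visits(pending, spec, exp)
    assert [l.amount_eur for l in out.lines if l.imputed] == [D("90.00")]
    assert prov == ["cohort-level"]

    exp2 = ExperienceValues.from_statements([pending], configured={"fu-3mo": D("77.00")})
    out2, prov2 = impute_future_visits(pending, spec, exp2)
    assert [l.amount_eur for l in out2.lines if l.imputed] == [D("77.00")]
    assert prov2 == ["configured"]


def test_unresolvable_experience_value_raises():
    pending = _statement_with_visits("C9", "HAP-A", [("V1", "baseline", "50.00")])
    exp = ExperienceValues.from_statements([pending])
    spec = ImputationSpec(
        FREEZE, announced=[AnnouncedVisit("C9", "fu-3mo", dt.date(2022, 1, 15))]
    )
    with pytest.raises(ImputationError, match="fu-3mo"):
        impute_future_visits(pending, spec, exp)


def test_documented_visit_not_imputed():
    st = _statement_with_visits("C9", "HAP-A", [("V1", "fu-3mo", "100.00")])
    exp = ExperienceValues.from_statements([st])
    spec = ImputationSpec(
        FREEZE, announced=[AnnouncedVisit("C9", "fu-3mo", dt.date(2022, 1, 15))]
    )
    out, _ = impute_future_visits(st, spec, exp)
    assert not any(l.imputed for l in out.lines)


def test_pre_freeze_announced_visits_are_not_imputed():
    st = _statement_with_visits("C9", "HAP-A", [("V1", "baseline", "50.00")])
    exp = ExperienceValues({}, {}, {"fu-3mo": D("10.00")})
    spec = ImputationSpec(
        FREEZE, announced=[AnnouncedVisit("C9", "fu-3mo", dt.date(2021, 6, 1))]
    )
    out, _ = impute_future_visits(st, spec, exp)
    assert not any(l.imputed for l in out.lines)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def _flat_statement(case_id, centre, amounts_by_source):
    lines = [
        StatementLine(visit_id="V1", visit_type_id="baseline", item_id="x", count=1,
                      unit_cost_eur=D(a), amount_eur=D(a), source=src)
        for src, a in amounts_by_source
    ]
    return CaseStatement(case_id=case_id, centre_id=centre, cohort=Cohort.HAP, lines=lines)


def test_identical_statements_mean_and_shares():
    sts = [
        _flat_statement(f"C{i}", "HAP-A", [("ecrf", "80.00"), ("bio", "20.00")])
        for i in range(10)
    ]
    summary = aggregate_centre(sts, HAP_CENTRE)
    assert summary.total_eur == D("1000.00")
    assert summary.mean_per_case_eur == D("100.00")
    assert summary.source_shares_pct == {"ecrf": D("80.0"), "bio": D("20.0"),
                                         "imaging": D("0.0")}
    assert sum(summary.source_shares_pct.values()) == D("100.0")


def test_random_statements_match_flat_resummation_oracle():
    rng = random.Random(5)
    sts = []
    for i in range(40):
        sources = [
            (rng.choice(["ecrf", "bio", "imaging"]), f"{rng.randrange(1, 50000) / 100:.2f}")
            for _ in range(rng.randint(1, 6))
        ]
        sts.append(_flat_statement(f"C{i}", "HAP-A", sources))
    summary = aggregate_centre(sts, HAP_CENTRE)
    oracle = sum((l.amount_eur for st in sts for l in st.lines), D(0))
    assert summary.total_eur == oracle
    assert summary.mean_per_case_eur == (oracle / len(sts)).quantize(D("0.01"))


def test_statement_from_other_centre_rejected():
    st = _flat_statement("C1", "HAP-B", [("ecrf", "10.00")])
    with pytest.raises(PbrmError, match="HAP-B"):
        aggregate_centre([st], HAP_CENTRE)


@pytest.mark.parametrize("n_cases,fee", [(4, "0.00"), (5, "2500.00"), (7, "2500.00")])
def test_initiation_fee_threshold(n_cases, fee):
    centre = CentreRecord("SUEP-N", "N", Cohort.SUEP, CentreClass.NON_AMC, D("25"))
    sts = [
        CaseStatement(
            case_id=f"C{i}", centre_id="SUEP-N", cohort=Cohort.SUEP,
            lines=[StatementLine("V1", "baseline", "x", 1, D("10.00"), D("10.00"), "ecrf")],
        )
        for i in range(n_cases)
    ]
    summary = aggregate_centre(sts, centre, initiation_fee_eur=D("2500.00"))
    assert summary.initiation_fee_eur == D(fee)
    assert summary.grand_total_eur == summary.total_eur + D(fee)


def test_initiation_fee_never_for_amc_centres():
    sts = [
        _flat_statement(f"C{i}", "HAP-A", [("ecrf", "10.00")]) for i in range(9)
    ]
    summary = aggregate_centre(sts, HAP_CENTRE, initiation_fee_eur=D("2500.00"))
    assert summary.initiation_fee_eur == D("0.00")


def test_cohort_total_is_sum_of_centres():
    a = [_flat_statement(f"C{i}", "HAP-A", [("ecrf", "33.33")]) for i in range(3)]
    b_centre = CentreRecord("HAP-B", "B", Cohort.HAP, CentreClass.AMC, D("73.5"))
    b = [_flat_statement(f"D{i}", "HAP-B", [("bio", "11.11")]) for i in range(2)]
    summaries = [aggregate_centre(a, HAP_CENTRE), aggregate_centre(b, b_centre)]
    totals = aggregate_cohort(summaries)
    assert totals["total_eur"] == D("99.99") + D("22.22")
    assert totals["n_reimbursable"] == 5


# ---------------------------------------------------------------------------
# Follow-up fulfilment
# ---------------------------------------------------------------------------

def test_fu_fulfilment_ratios():
    expected = {f"C{i}": ["fu-3mo"] for i in range(10)}
    all_documented = {f"C{i}": ["fu-3mo"] for i in range(10)}
    seven = {f"C{i}": (["fu-3mo"] if i < 7 else []) for i in range(10)}
    assert fu_fulfilment(all_documented, expected) == D("100.0")
    assert fu_fulfilment(seven, expected) == D("70.0")
    assert fu_fulfilment({}, {}) is None


# ---------------------------------------------------------------------------
# Audit sampling
# ---------------------------------------------------------------------------

def _n_statements(n):
    return [
        CaseStatement(case_id=f"C{i:03d}", centre_id="HAP-A", cohort=Cohort.HAP)
        for i in range(n)
    ]


def test_audit_sample_whole_population():
    sts = _n_statements(7)
    assert {s.case_id for s in random_audit_sample(sts, n=7, seed=1)} == {
        s.case_id for s in sts
    }


def test_audit_sample_reproducible_and_order_free():
    sts = _n_statements(30)
    first = [s.case_id for s in random_audit_sample(sts, n=10, seed=42)]
    second = [s.case_id for s in random_audit_sample(list(reversed(sts)), n=10, seed=42)]
    assert first == second


def test_audit_sample_too_large_raises():
    with pytest.raises(SamplingError):
        random_audit_sample(_n_statements(3), n=4, seed=0)


def test_audit_sample_inclusion_is_uniform():
    """5-from-20 draws: empirical inclusion frequency matches the
    hypergeometric inclusion probability 0.25."""
    sts = _n_statements(20)
    counts = Counter()
    n_rep = 2000
    for seed in range(n_rep):
        for s in random_audit_sample(sts, n=5, seed=seed):
            counts[s.case_id] += 1
    freqs = np.array([counts[s.case_id] / n_rep for s in sts])
    se = np.sqrt(0.25 * 0.75 / n_rep)
    assert np.all(np.abs(freqs - 0.25) < 5 * se)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_run(catalogue):
    from pbrm import make_config, run_reimbursement, simulate

    cfg = make_config(seed=21, cohort="HAP", n_centres=3, cases_per_centre=[5, 8, 3],
                      p_missing_form=0.05)
    bundle = simulate(cfg)
    return run_reimbursement(
        catalogue, bundle.exports(), bundle.mapping, bundle.rules,
        bundle.bio_rules, bundle.img_rules, fu_schedule=bundle.fu_schedule,
    )


def test_centre_report_sees_only_its_cases(tmp_path, small_run):
    paths = generate_reports(small_run, "centre", tmp_path, centre_id="HAP-B")
    statements = (tmp_path / "centre_HAP-B_statements.csv").read_text()
    assert "HAP-A" not in statements and "HAP-C" not in statements
    assert all(p.exists() for p in paths)


def test_report_regeneration_is_byte_identical(tmp_path, small_run):
    d1, d2 = tmp_path / "one", tmp_path / "two"
    generate_reports(small_run, "coordination", d1)
    generate_reports(small_run, "coordination", d2)
    for p1 in sorted(d1.iterdir()):
        p2 = d2 / p1.name
        assert p1.read_bytes() == p2.read_bytes()


def test_coordination_rows_partition_into_centre_rows(tmp_path, small_run):
    generate_reports(small_run, "coordination", tmp_path)
    coord_rows = (tmp_path / "coordination_statements.csv").read_text().strip().splitlines()
    centre_rows = 0
    for centre in ("HAP-A", "HAP-B", "HAP-C"):
        generate_reports(small_run, "centre", tmp_path, centre_id=centre)
        rows = (tmp_path / f"centre_{centre}_statements.csv").read_text().strip().splitlines()
        centre_rows += len(rows) - 1
    assert len(coord_rows) - 1 == centre_rows


def test_unknown_centre_rejected(tmp_path, small_run):
    with pytest.raises(CatalogueLookupError, match="HAP-Z"):
        generate_reports(small_run, "centre", tmp_path, centre_id="HAP-Z")
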