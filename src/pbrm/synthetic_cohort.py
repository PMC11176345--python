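"""Seeded synthetic multi-centre study bundles.

The generator emulates the structure the reimbursement engine is built for:
heterogeneous centres (recruitment spanning single-digit to >150 cases per
centre), inpatient visit paths whose length depends on disease severity
(ward / ICU length of stay), a standardized follow-up schedule with imperfect
compliance, and the quality problems seen in practice — unsubmitted forms,
implausible records, missed case reviews, biosamples below the aliquot
minimum, failed imaging uploads.

Every bundle carries its own ground truth (per-case eligibility and the exact
reimbursable amount implied by the generated records), computed directly from
the generated record flags and the catalogue — never by running the engine —
so pipeline tests have an independent oracle. All randomness flows from one
seeded generator; the same seed yields a byte-identical bundle.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError, model_validator

from ._money import ZERO, money_str, round2
from .catalogue import CentreClass, Cohort, CostCatalogue, reference_catalogue
from .engine import AnnouncedVisit
from .errors import ConfigurationError
from .qc_eligibility import (
    BioRule,
    EligibilityRuleSet,
    ImgRule,
    MappingCondition,
    MappingRow,
    MappingTable,
    default_rules,
    dump_rules,
)
from .study_data import (
    BiosampleRecord,
    CentreRecord,
    EcrfRecord,
    ImagingRecord,
    LinkageRow,
    write_export,
)

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class SimConfig(BaseModel):
    """Configuration of one synthetic study bundle.

    Probabilities are per-event; lengths of stay follow a geometric law
    (memoryless discharge) by default, negative binomial as alternative.
    """

    model_config = {"extra": "forbid"}

    seed: int
    cohort: Cohort = Cohort.HAP
    centre_class: CentreClass = CentreClass.AMC
    n_centres: int = Field(default=10, ge=1, le=26)
    target_cases: float = Field(default=73.5, ge=0)

    # recruitment heterogeneity: lognormal counts clipped to [min, max]
    cases_per_centre: Optional[list[int]] = None  # explicit override
    recruit_log_mean: float = 3.4
    recruit_log_sigma: float = Field(default=1.1, ge=0)
    recruit_min: int = Field(default=1, ge=1)
    recruit_max: int = Field(default=164, ge=1)

    # severity / length of stay (inpatient cohorts)
    p_icu: float = Field(default=0.3, ge=0, le=1)
    los_dist: Literal["geometric", "nbinom"] = "geometric"
    ward_los_mean: float = Field(default=6.0, gt=0)
    icu_los_mean: float = Field(default=4.0, gt=0)
    nbinom_dispersion: float = Field(default=2.0, gt=0)
    fixed_path: Optional[list[str]] = None  # override: identical path for every case

    # follow-up
    fu_visit_types: list[str] = Field(default_factory=lambda: ["fu-3mo"])
    fu_compliance: float = Field(default=0.6, ge=0, le=1)
    dropout: float = Field(default=0.0, ge=0, le=1)
    announced_post_freeze: float = Field(default=0.0, ge=0, le=1)

    # documentation quality
    p_no_consent: float = Field(default=0.0, ge=0, le=1)
    p_missing_form: float = Field(default=0.0, ge=0, le=1)
    p_plausibility_fail: float = Field(default=0.0, ge=0, le=1)
    p_case_review_fail: float = Field(default=0.0, ge=0, le=1)

    # biosampling and imaging
    bio_participation: float = Field(default=0.8, ge=0, le=1)
    aliquot_mean: float = Field(default=4.0, ge=0)
    bio_sample_type: str = "edta-pbmc"
    bio_min_aliquots: int = Field(default=1, ge=0)
    imaging_participation: float = Field(default=0.5, ge=0, le=1)
    p_upload_fail: float = Field(default=0.0, ge=0, le=1)
    img_modality: str = "echo"

    # calendar
    recruit_start: _dt.date = _dt.date(2021, 1, 1)
    recruit_window_days: int = Field(default=180, ge=1)
    freeze_date: _dt.date = _dt.date(2021, 12, 31)

    @model_validator(mode="after")
    def _check(self):
        if self.recruit_max < self.recruit_min:
            raise ValueError("recruit_max must be >= recruit_min")
        if self.cases_per_centre is not None:
            if len(self.cases_per_centre) != self.n_centres:
                raise ValueError("cases_per_centre must have n_centres entries")
            if any(c < 1 for c in self.cases_per_centre):
                raise ValueError("cases_per_centre entries must be >= 1")
        return self


def preset(name: str) -> SimConfig:
    """Named configurations mirroring the three cohort platforms."""
    presets = {
        "hap_like": dict(
            seed=0, cohort=Cohort.HAP, centre_class=CentreClass.AMC,
            n_centres=10, target_cases=73.5,
            recruit_log_mean=3.4, recruit_log_sigma=1.1, recruit_max=164,
            p_icu=0.3, ward_los_mean=6.0, icu_los_mean=4.0,
            fu_visit_types=["fu-3mo"], fu_compliance=0.5, dropout=0.05,
            p_missing_form=0.01, p_plausibility_fail=0.02,
            bio_participation=0.85, imaging_participation=0.4,
        ),
        "pop_like": dict(
            seed=0, cohort=Cohort.POP, centre_class=CentreClass.AMC,
            n_centres=3, target_cases=330.0,
            recruit_log_mean=6.0, recruit_log_sigma=0.7,
            recruit_min=30, recruit_max=1700,
            fu_visit_types=[], fu_compliance=1.0,
            p_missing_form=0.005, p_plausibility_fail=0.02,
            bio_participation=0.6, imaging_participation=0.1,
        ),
        "suep_amc_like": dict(
            seed=0, cohort=Cohort.SUEP, centre_class=CentreClass.AMC,
            n_centres=15, target_cases=98.1,
            recruit_log_mean=3.3, recruit_log_sigma=1.0, recruit_max=164,
            p_icu=0.15, ward_los_mean=5.0, icu_los_mean=3.0,
            fu_visit_types=["fu-3mo"], fu_compliance=0.63, dropout=0.05,
            p_missing_form=0.01, p_plausibility_fail=0.02,
            p_case_review_fail=0.02,
            bio_participation=0.8, imaging_participation=0.3,
        ),
        "suep_nonamc_like": dict(
            seed=0, cohort=Cohort.SUEP, centre_class=CentreClass.NON_AMC,
            n_centres=8, target_cases=25.0,
            recruit_log_mean=2.5, recruit_log_sigma=1.0, recruit_max=120,
            p_icu=0.05, ward_los_mean=4.0, icu_los_mean=2.0,
            fu_visit_types=["fu-3mo"], fu_compliance=0.7, dropout=0.05,
            p_missing_form=0.02, p_plausibility_fail=0.02,
            p_case_review_fail=0.02,
            bio_participation=0.0, imaging_participation=0.1,
        ),
    }
    if name not in presets:
        raise ConfigurationError(
            f"unknown preset {name!r}; choose from {sorted(presets)}"
        )
    return SimConfig(**presets[name])


def make_config(**kwargs) -> SimConfig:
    """Validated SimConfig; invalid parameters raise ConfigurationError."""
    try:
        return SimConfig(**kwargs)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from None


def default_mapping(catalogue: CostCatalogue) -> MappingTable:
    """1:1 mapping of synthetic eCRF item ids onto catalogue items.

    The generator names eCRF items ``ecrf:<catalogue item>`` (with an ``:k``
    suffix for repeats within a visit); every row reimburses on
    plausibility-pass.
    """
    rows = []
    max_count: dict[str, int] = {}
    for visit in catalogue.visits.values():
        for item_id, count in visit.item_multiplicities:
            max_count[item_id] = max(max_count.get(item_id, 1), count)
    for item_id in catalogue.items:
        rows.append(
            MappingRow(
                ecrf_item_id=f"ecrf:{item_id}",
                reimbursement_item_id=item_id,
                condition=MappingCondition.PLAUSIBILITY_PASS,
                reviewed=True,
            )
        )
        for k in range(2, max_count.get(item_id, 1) + 1):
            rows.append(
                MappingRow(
                    ecrf_item_id=f"ecrf:{item_id}:{k}",
                    reimbursement_item_id=item_id,
                    condition=MappingCondition.PLAUSIBILITY_PASS,
                    reviewed=True,
                )
            )
    return MappingTable(rows)


@dataclass
class SimBundle:
    """Synthetic exports plus linkage, rules, mapping and ground truth."""

    config: SimConfig
    centres: list[CentreRecord]
    ecrf: list[EcrfRecord]
    bio: list[BiosampleRecord]
    imaging: list[ImagingRecord]
    linkage: list[LinkageRow]
    announced: list[AnnouncedVisit]
    ground_truth: pd.DataFrame  # case_id, centre_id, eligible, true_total_eur
    mapping: MappingTable
    rules: EligibilityRuleSet
    bio_rules: list[BioRule]
    img_rules: list[ImgRule]
    fu_schedule: dict[str, list[str]] = field(default_factory=dict)

    def exports(self) -> dict[str, list]:
        return {
            "ecrf": self.ecrf,
            "bio": self.bio,
            "imaging": self.imaging,
            "centres": self.centres,
            "linkage": self.linkage,
        }

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_export(self.ecrf, out_dir / "ecrf.csv", "ecrf")
        write_export(self.bio, out_dir / "biosamples.csv", "bio")
        write_export(self.imaging, out_dir / "imaging.csv", "imaging")
        write_export(self.centres, out_dir / "centres.csv", "centres")
        write_export(self.linkage, out_dir / "linkage.csv", "linkage")
        self.mapping.to_csv(out_dir / "mapping.csv")
        dump_rules(self.rules, self.bio_rules, self.img_rules, out_dir / "rules.yaml")
        self.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False, lineterminator="\n")
        pd.DataFrame(
            [
                {
                    "case_id": a.case_id,
                    "visit_type_id": a.visit_type_id,
                    "due_date": a.due_date.isoformat(),
                }
                for a in self.announced
            ],
            columns=["case_id", "visit_type_id", "due_date"],
        ).to_csv(out_dir / "announced.csv", index=False, lineterminator="\n")


def _draw_los(rng: np.random.Generator, config: SimConfig, mean: float) -> int:
    """Length of stay in days, support >= 1."""
    if config.los_dist == "geometric":
        return int(rng.geometric(1.0 / mean))
    # negative binomial shifted by 1, parameterised by mean and dispersion r
    r = config.nbinom_dispersion
    mu = mean - 1.0
    p = r / (r + mu) if mu > 0 else 1.0
    return 1 + int(rng.negative_binomial(r, p))


def _case_path(rng: np.random.Generator, config: SimConfig) -> list[str]:
    if config.fixed_path is not None:
        return list(config.fixed_path)
    if config.cohort is Cohort.POP:
        return ["pop-initial-interview", "pop-onsite"]
    path = ["baseline"]
    path += ["ward-day"] * _draw_los(rng, config, config.ward_los_mean)
    if rng.random() < config.p_icu:
        path += ["icu-day"] * _draw_los(rng, config, config.icu_los_mean)
    path.append("discharge")
    return path


def _form_for_visit(visit_type_id: str) -> str:
    # one sub-form per visit; required-form ids follow the same convention
    return f"{visit_type_id}-form"


def simulate(config: SimConfig, catalogue: Optional[CostCatalogue] = None) -> SimBundle:
    """Generate one bundle; deterministic under ``config.seed``."""
    catalogue = catalogue or reference_catalogue()
    rng = np.random.default_rng(config.seed)
    cohort = config.cohort
    rules = default_rules(cohort)
    mapping = default_mapping(catalogue)
    bio_rules = [
        BioRule(
            sample_type=config.bio_sample_type,
            min_aliquots=config.bio_min_aliquots,
            fee_item_id="pbmc",
        )
    ]
    img_rules = [ImgRule(modality=config.img_modality, fee_item_id="echocardiogram")]
    unit_cost = {item_id: catalogue.item_cost(item_id) for item_id in catalogue.items}
    required_forms = {f for forms in rules.required_forms.values() for f in forms}

    centres = [
        CentreRecord(
            centre_id=f"{cohort.value}-{_LETTERS[i]}",
            display_letter=_LETTERS[i],
            cohort=cohort,
            centre_class=config.centre_class,
            target_cases=Decimal(str(config.target_cases)),
        )
        for i in range(config.n_centres)
    ]
    if config.cases_per_centre is not None:
        counts = list(config.cases_per_centre)
    else:
        raw = rng.lognormal(config.recruit_log_mean, config.recruit_log_sigma, config.n_centres)
        counts = [int(min(max(round(x), config.recruit_min), config.recruit_max)) for x in raw]

    ecrf: list[EcrfRecord] = []
    bio: list[BiosampleRecord] = []
    imaging: list[ImagingRecord] = []
    linkage: list[LinkageRow] = []
    announced: list[AnnouncedVisit] = []
    truth_rows: list[dict] = []
    fu_schedule: dict[str, list[str]] = {}

    case_no = 0
    for centre, n_cases in zip(centres, counts):
        for _ in range(n_cases):
            case_no += 1
            case_id = f"C{case_no:05d}"
            e_pseud, b_pseud, i_pseud = (
                f"E{case_no:05d}", f"B{case_no:05d}", f"I{case_no:05d}",
            )
            linkage.append(LinkageRow(case_id, e_pseud, b_pseud, i_pseud))
            consent = rng.random() >= config.p_no_consent
            recruit_date = config.recruit_start + _dt.timedelta(
                days=int(rng.integers(0, config.recruit_window_days))
            )

            path = _case_path(rng, config)
            dropped = rng.random() < config.dropout

            # follow-up: announced for every scheduled FU visit; post-freeze
            # visits stay undocumented (imputation handles them)
            documented_fu: list[str] = []
            if cohort is not Cohort.POP and config.fu_visit_types:
                fu_schedule[case_id] = list(config.fu_visit_types)
                for k, fu_type in enumerate(config.fu_visit_types):
                    post_freeze = rng.random() < config.announced_post_freeze
                    if post_freeze:
                        due = config.freeze_date + _dt.timedelta(
                            days=1 + int(rng.integers(0, 60))
                        )
                    else:
                        due = recruit_date + _dt.timedelta(days=90 * (k + 1))
                    announced.append(AnnouncedVisit(case_id, fu_type, due))
                    if not post_freeze and not dropped and rng.random() < config.fu_compliance:
                        documented_fu.append(fu_type)

            full_path = path + documented_fu
            true_total = ZERO
            forms_ok = True
            reviews_ok = True
            visit_date = recruit_date
            for seq, visit_type in enumerate(full_path, start=1):
                visit_id = f"{case_id}-V{seq:02d}"
                form_id = _form_for_visit(visit_type)
                form_missing = rng.random() < config.p_missing_form
                review_fail = (
                    rules.require_case_review
                    and rng.random() < config.p_case_review_fail
                )
                if form_id in required_forms:
                    if form_missing:
                        forms_ok = False
                    elif review_fail:
                        reviews_ok = False
                item_counts: dict[str, int] = {}
                for item_id, count in catalogue.visit(visit_type).item_multiplicities:
                    for _rep in range(count):
                        item_counts[item_id] = item_counts.get(item_id, 0) + 1
                        rep = item_counts[item_id]
                        ecrf_item = f"ecrf:{item_id}" if rep == 1 else f"ecrf:{item_id}:{rep}"
                        plaus = rng.random() >= config.p_plausibility_fail
                        ecrf.append(
                            EcrfRecord(
                                ecrf_pseudonym=e_pseud,
                                centre_id=centre.centre_id,
                                visit_id=visit_id,
                                visit_type_id=visit_type,
                                visit_date=visit_date,
                                form_id=form_id,
                                item_id=ecrf_item,
                                value="x",
                                submitted=not form_missing,
                                plausibility_pass=plaus,
                                case_review_pass=not review_fail,
                                consent_registered=consent,
                            )
                        )
                        if not form_missing and plaus:
                            true_total += unit_cost[item_id]
                # biosampling / imaging opportunities at anchoring visits
                if visit_type in ("baseline", "discharge", "pop-onsite"):
                    if rng.random() < config.bio_participation:
                        aliquots = int(rng.poisson(config.aliquot_mean))
                        bio.append(
                            BiosampleRecord(
                                bio_pseudonym=b_pseud,
                                visit_id=visit_id,
                                sample_type=config.bio_sample_type,
                                aliquot_count=aliquots,
                                registered=True,
                            )
                        )
                        if aliquots >= config.bio_min_aliquots:
                            true_total += unit_cost["pbmc"]
                if visit_type in ("baseline", "pop-onsite"):
                    if rng.random() < config.imaging_participation:
                        uploaded = rng.random() >= config.p_upload_fail
                        imaging.append(
                            ImagingRecord(
                                img_pseudonym=i_pseud,
                                visit_id=visit_id,
                                modality=config.img_modality,
                                series_count=1 + int(rng.poisson(1.0)),
                                uploaded=uploaded,
                            )
                        )
                        if uploaded:
                            true_total += unit_cost["echocardiogram"]
                visit_date = visit_date + _dt.timedelta(days=1)

            eligible = consent and forms_ok and reviews_ok
            truth_rows.append(
                {
                    "case_id": case_id,
                    "centre_id": centre.centre_id,
                    "eligible": eligible,
                    "true_total_eur": money_str(true_total if eligible else ZERO),
                    "visit_path": "|".join(full_path),
                }
            )

    ground_truth = pd.DataFrame(
        truth_rows,
        columns=["case_id", "centre_id", "eligible", "true_total_eur", "visit_path"],
    )
    return SimBundle(
        config=config,
        centres=centres,
        ecrf=ecrf,
        bio=bio,
        imaging=imaging,
        linkage=linkage,
        announced=announced,
        ground_truth=ground_truth,
        mapping=mapping,
        rules=rules,
        bio_rules=bio_rules,
        img_rules=img_rules,
        fu_schedule=fu_schedule,
    )


# ---------------------------------------------------------------------------
# Analytic expectation for convergence checks
# ---------------------------------------------------------------------------

def config_path_distribution(
    config: SimConfig, tail_mass: float = 1e-12
) -> list[tuple[tuple[str, ...], Decimal]]:
    """The visit-path distribution implied by a config (record noise aside).

    Geometric lengths of stay are truncated where the remaining tail mass
    drops below ``tail_mass``; the truncation point absorbs the tail so the
    probabilities still sum to one. Only geometric lengths of stay and at most
    the configured follow-up visits are expanded; follow-up compliance enters
    as independent per-visit inclusion.
    """
    if config.fixed_path is not None:
        return [(tuple(config.fixed_path), Decimal(1))]
    if config.cohort is Cohort.POP:
        return [(("pop-initial-interview", "pop-onsite"), Decimal(1))]
    if config.los_dist != "geometric":
        raise ConfigurationError(
            "analytic path distribution implemented for geometric stays only"
        )

    def _geom_probs(mean: float) -> list[tuple[int, float]]:
        p = 1.0 / mean
        out, k, cum = [], 1, 0.0
        while 1.0 - cum > tail_mass and k < 10_000:
            pk = p * (1 - p) ** (k - 1)
            out.append((k, pk))
            cum += pk
            k += 1
        out[-1] = (out[-1][0], out[-1][1] + (1.0 - cum))  # absorb the tail
        return out

    ward = _geom_probs(config.ward_los_mean)
    icu = _geom_probs(config.icu_los_mean)
    fu_types = [] if config.cohort is Cohort.POP else list(config.fu_visit_types)
    p_fu = (1.0 - config.dropout) * (1.0 - config.announced_post_freeze) * config.fu_compliance

    paths: list[tuple[tuple[str, ...], Decimal]] = []
    fu_subsets: list[tuple[list[str], float]] = [([], 1.0)]
    for fu in fu_types:
        fu_subsets = [
            (subset + ([fu] if take else []), prob * (p_fu if take else 1 - p_fu))
            for subset, prob in fu_subsets
            for take in (True, False)
        ]
    for w, pw in ward:
        for icu_days, p_icu_days in [(0, 1.0 - config.p_icu)] + [
            (k, config.p_icu * pk) for k, pk in icu
        ]:
            base = ["baseline"] + ["ward-day"] * w + ["icu-day"] * icu_days + ["discharge"]
            for fu_subset, p_subset in fu_subsets:
                prob = pw * p_icu_days * p_subset
                if prob <= 0:
                    continue
                paths.append((tuple(base + fu_subset), Decimal(repr(prob))))
    total = sum(p for _, p in paths)
    return [(path, p / total) for path, p in paths]


def analytic_mean_case_cost(config: SimConfig, catalogue: Optional[CostCatalogue] = None) -> float:
    """Expected engine total per *eligible* case, in euros (float).

    Valid for configs without documentation noise (missing forms,
    plausibility or case-review failures, consent gaps): the expectation is
    the path-distribution case fee plus the expected biosampling and imaging
    fees at the anchoring visits.
    """
    from .catalogue import CaseFeeSpec, expected_case_fee

    for name in ("p_no_consent", "p_missing_form", "p_plausibility_fail", "p_case_review_fail"):
        if getattr(config, name) > 0:
            raise ConfigurationError(
                f"analytic expectation requires {name} = 0 (record noise biases it)"
            )
    catalogue = catalogue or reference_catalogue()
    dist = config_path_distribution(config)
    spec = CaseFeeSpec(cohort=config.cohort, path_distribution=tuple(dist))
    visit_fee = float(expected_case_fee(spec, catalogue))

    # expected bio/imaging fees per opportunity visit
    n_bio_ops = 0.0
    n_img_ops = 0.0
    for path, prob in dist:
        p = float(prob)
        n_bio_ops += p * sum(1 for v in path if v in ("baseline", "discharge", "pop-onsite"))
        n_img_ops += p * sum(1 for v in path if v in ("baseline", "pop-onsite"))
    from scipy import stats

    if config.bio_min_aliquots > 0:
        p_enough_aliquots = float(
            stats.poisson.sf(config.bio_min_aliquots - 1, config.aliquot_mean)
        )
    else:
        p_enough_aliquots = 1.0
    bio_fee = (
        n_bio_ops
        * config.bio_participation
        * p_enough_aliquots
        * float(catalogue.item_cost("pbmc"))
    )
    img_fee = (
        n_img_ops
        * config.imaging_participation
        * (1.0 - config.p_upload_fail)
        * float(catalogue.item_cost("echocardiogram"))
    )
    return visit_fee + bio_fee + img_fee
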