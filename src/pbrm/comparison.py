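"""Funding-model comparison: fixed-rate and up-front allocation vs PBRM.

Three funding models are compared per centre:

* **PBRM** — the performance-based result: mean reimbursement per case times
  the number of reimbursed cases. It is the 100 % reference.
* **FRM** (fixed-rate model) — a fixed case fee per reimbursed case.
* **UFAM** (up-front allocation model) — staffing (physician and study-nurse
  FTEs, each rounded to the nearest quarter FTE) plus consumables times the
  *targeted* case number, paid regardless of realised recruitment.

For over-recruiting centres the comparison reference is capped at the target
case number (a centre funded up-front would have stopped recruiting there).
FRM percentages reduce to the fee/mean ratio per case and are therefore
computed uncapped. Cost-efficiency is expressed as cases affordable per
budget unit (default 10,000 EUR), summarised per cohort with a t-based 95 %
confidence interval, and group differences between models are assessed with
a classical one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._money import as_decimal, round1, round2
from .catalogue import (
    CentreClass,
    Cohort,
    DEFAULT_CASE_FEES,
    default_case_fee,
)
from .engine import CentreSummary
from .errors import AnalysisError, ComparisonUndefinedError, ConfigurationError

BUDGET_UNIT_EUR = Decimal("10000")


@dataclass(frozen=True)
class FrmSpec:
    """Fixed case fee per (cohort, centre class)."""

    fees: Mapping[tuple[Cohort, Optional[CentreClass]], Decimal] = field(
        default_factory=lambda: dict(DEFAULT_CASE_FEES)
    )

    def fee(self, cohort: Cohort, centre_class: Optional[CentreClass]) -> Decimal:
        key = (cohort, centre_class if cohort is Cohort.SUEP else None)
        if key not in self.fees:
            raise ConfigurationError(
                f"no case fee configured for {cohort.value}/{centre_class}"
            )
        fee = self.fees[key]
        if fee <= 0:
            raise ConfigurationError(f"case fee for {key} must be positive")
        return fee


@dataclass(frozen=True)
class UfamCentreSpec:
    """Up-front allocation inputs for one centre.

    Either a directly supplied lump sum, or the FTE composition (raw FTEs are
    rounded to the nearest quarter before costing) plus consumables per
    targeted case.
    """

    centre_id: str
    lump_sum_eur: Optional[Decimal] = None
    physician_fte_raw: Optional[Decimal] = None
    nurse_fte_raw: Optional[Decimal] = None
    physician_fte_cost_eur: Decimal = Decimal(0)
    nurse_fte_cost_eur: Decimal = Decimal(0)
    consumables_per_case_eur: Decimal = Decimal(0)

    def __post_init__(self):
        for name in (
            "lump_sum_eur", "physician_fte_raw", "nurse_fte_raw",
            "physician_fte_cost_eur", "nurse_fte_cost_eur",
            "consumables_per_case_eur",
        ):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ConfigurationError(f"{self.centre_id}: negative {name}")


@dataclass(frozen=True)
class UfamSpec:
    centres: Mapping[str, UfamCentreSpec]

    def for_centre(self, centre_id: str) -> UfamCentreSpec:
        if centre_id not in self.centres:
            raise ConfigurationError(f"no UFAM spec for centre {centre_id!r}")
        return self.centres[centre_id]


QUARTER = Decimal("0.25")


def round_quarter(fte) -> Decimal:
    """Round an FTE to the nearest quarter, ties away from zero."""
    fte = as_decimal(fte)
    return (fte / QUARTER).quantize(Decimal("1"), rounding=ROUND_HALF_UP) * QUARTER


def frm_funding(n_reimbursable: int, case_fee_eur: Decimal) -> Decimal:
    """Fixed-rate funding: case fee × reimbursed cases."""
    if n_reimbursable < 0:
        raise ConfigurationError("n_reimbursable must be non-negative")
    return round2(case_fee_eur * n_reimbursable)


def ufam_funding(spec: UfamCentreSpec, target_cases: Decimal) -> Decimal:
    """Up-front funding: quarter-rounded FTE staffing + consumables × target."""
    if spec.lump_sum_eur is not None:
        return round2(spec.lump_sum_eur)
    if spec.physician_fte_raw is None or spec.nurse_fte_raw is None:
        raise ConfigurationError(
            f"{spec.centre_id}: UFAM needs a lump sum or full FTE composition"
        )
    staffing = (
        round_quarter(spec.physician_fte_raw) * spec.physician_fte_cost_eur
        + round_quarter(spec.nurse_fte_raw) * spec.nurse_fte_cost_eur
    )
    return round2(staffing + spec.consumables_per_case_eur * target_cases)


def pbrm_reference(
    mean_per_case_eur: Decimal,
    n_reimbursable: int,
    target_cases: Decimal,
    cap: bool = True,
) -> Decimal:
    """PBRM comparison reference; capped at the target for over-recruiters."""
    n = Decimal(n_reimbursable)
    if cap:
        n = min(n, as_decimal(target_cases))
    return round2(mean_per_case_eur * n)


def relative_to_pbrm(
    model_funding_eur: Decimal,
    mean_per_case_eur: Decimal,
    n_reimbursable: int,
    target_cases: Decimal,
    cap: bool = True,
) -> Decimal:
    """Model funding as a percentage of the PBRM reference, 1 decimal half-up."""
    reference = pbrm_reference(mean_per_case_eur, n_reimbursable, target_cases, cap)
    if reference == 0:
        raise ComparisonUndefinedError("PBRM reference is zero; percentage undefined")
    return round1(Decimal(100) * as_decimal(model_funding_eur) / reference)


@dataclass
class EfficiencyResult:
    """Cases affordable per budget unit: per-centre values, mean, 95 % CI."""

    per_centre: dict[str, float]
    mean: float
    ci95: Optional[tuple[float, float]]  # None when n = 1

    def rounded(self) -> tuple[float, Optional[tuple[float, float]]]:
        mean = float(round1(self.mean))
        if self.ci95 is None:
            return mean, None
        return mean, (float(round1(self.ci95[0])), float(round1(self.ci95[1])))


def t_confidence_interval(values: Sequence[float], level: float = 0.95):
    """Two-sided t-interval for the mean; None for n < 2."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return None
    sem = arr.std(ddof=1) / np.sqrt(arr.size)
    if sem == 0:
        return (float(arr.mean()), float(arr.mean()))
    tcrit = stats.t.ppf(0.5 + level / 2, df=arr.size - 1)
    half = tcrit * sem
    return (float(arr.mean() - half), float(arr.mean() + half))


def cases_per_budget_unit(
    cost_per_case: Mapping[str, Decimal],
    budget_eur: Decimal = BUDGET_UNIT_EUR,
) -> EfficiencyResult:
    """Cases recruitable per budget unit under a model.

    ``cost_per_case`` maps centre_id to the model's effective per-case cost.
    The cohort value is the mean of per-centre ratios with a t-based CI.
    """
    per_centre: dict[str, float] = {}
    for centre_id, cost in cost_per_case.items():
        cost = as_decimal(cost)
        if cost <= 0:
            raise ComparisonUndefinedError(
                f"centre {centre_id!r}: zero cost per case, efficiency undefined"
            )
        per_centre[centre_id] = float(as_decimal(budget_eur) / cost)
    values = list(per_centre.values())
    return EfficiencyResult(
        per_centre=per_centre,
        mean=float(np.mean(values)),
        ci95=t_confidence_interval(values),
    )


def anova_one_way(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA: between/within mean-square F and its p-value.

    Degenerate cases are resolved explicitly: identical constants across all
    groups give (F=0, p=1); zero within-group variance with real separation
    gives (F=inf, p=0).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrays)
    if k < 2 or any(a.size < 1 for a in arrays):
        raise AnalysisError("ANOVA needs >= 2 groups, each with >= 1 value")
    n = sum(a.size for a in arrays)
    if n <= k:
        raise AnalysisError("ANOVA needs more observations than groups")
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between, df_within = k - 1, n - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_between == 0:
        return 0.0, 1.0
    if ms_within == 0:
        return float("inf"), 0.0
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    return float(f), p


@dataclass
class ComparisonResult:
    """Per-centre funding table plus per-model efficiency and ANOVA."""

    table: pd.DataFrame
    efficiency: dict[str, EfficiencyResult]
    anova: tuple[float, float]
    budget_eur: Decimal


def compare_models(
    summaries: Sequence[CentreSummary],
    frm: Optional[FrmSpec] = None,
    ufam: Optional[UfamSpec] = None,
    budget_eur: Decimal = BUDGET_UNIT_EUR,
    include_non_amc: bool = False,
) -> ComparisonResult:
    """Compare PBRM, FRM and (if specified) UFAM across the given centres.

    SUEP non-AMC centres are excluded by default (different financing
    structure). Centres without reimbursable cases are skipped: their PBRM
    reference is zero and no percentage is defined.
    """
    frm = frm or FrmSpec()
    rows = []
    pbrm_cost: dict[str, Decimal] = {}
    frm_cost: dict[str, Decimal] = {}
    ufam_cost: dict[str, Decimal] = {}
    for s in sorted(summaries, key=lambda x: (x.cohort.value, x.centre_id)):
        if (
            not include_non_amc
            and s.cohort is Cohort.SUEP
            and s.centre_class is CentreClass.NON_AMC
        ):
            continue
        if s.n_reimbursable == 0 or s.mean_per_case_eur is None:
            continue
        fee = frm.fee(s.cohort, s.centre_class)
        funding_frm = frm_funding(s.n_reimbursable, fee)
        pct_frm = relative_to_pbrm(
            funding_frm, s.mean_per_case_eur, s.n_reimbursable, s.target_cases, cap=False
        )
        row = {
            "centre_id": s.centre_id,
            "cohort": s.cohort.value,
            "n_reimbursable": s.n_reimbursable,
            "target_cases": float(s.target_cases),
            "pbrm_uncapped_eur": float(
                pbrm_reference(s.mean_per_case_eur, s.n_reimbursable, s.target_cases, cap=False)
            ),
            "pbrm_capped_eur": float(
                pbrm_reference(s.mean_per_case_eur, s.n_reimbursable, s.target_cases, cap=True)
            ),
            "frm_eur": float(funding_frm),
            "pct_frm_of_pbrm": float(pct_frm),
            "ufam_eur": np.nan,
            "pct_ufam_of_pbrm": np.nan,
        }
        pbrm_cost[s.centre_id] = s.mean_per_case_eur
        frm_cost[s.centre_id] = fee
        if ufam is not None:
            funding_ufam = ufam_funding(ufam.for_centre(s.centre_id), s.target_cases)
            row["ufam_eur"] = float(funding_ufam)
            row["pct_ufam_of_pbrm"] = float(
                relative_to_pbrm(
                    funding_ufam, s.mean_per_case_eur, s.n_reimbursable,
                    s.target_cases, cap=True,
                )
            )
            capped_n = min(Decimal(s.n_reimbursable), as_decimal(s.target_cases))
            ufam_cost[s.centre_id] = round2(funding_ufam / capped_n)
        rows.append(row)
    if not rows:
        raise AnalysisError("no comparable centres with reimbursable cases")

    table = pd.DataFrame(rows)
    efficiency = {
        "PBRM": cases_per_budget_unit(pbrm_cost, budget_eur),
        "FRM": cases_per_budget_unit(frm_cost, budget_eur),
    }
    if ufam is not None:
        efficiency["UFAM"] = cases_per_budget_unit(ufam_cost, budget_eur)
    groups = [list(res.per_centre.values()) for res in efficiency.values()]
    anova = anova_one_way(groups) if len(groups) >= 2 and len(rows) >= 2 else (np.nan, np.nan)
    return ComparisonResult(
        table=table, efficiency=efficiency, anova=anova, budget_eur=budget_eur
    )


def write_comparison(result: ComparisonResult, out_dir) -> None:
    """Write comparison.csv and efficiency.csv."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out_dir / "comparison.csv", index=False, lineterminator="\n")
    rows = []
    for model, res in result.efficiency.items():
        mean, ci = res.rounded()
        rows.append(
            {
                "model": model,
                "cases_per_unit_mean": mean,
                "ci95_low": "" if ci is None else ci[0],
                "ci95_high": "" if ci is None else ci[1],
                "n_centres": len(res.per_centre),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "efficiency.csv", index=False, lineterminator="\n")
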