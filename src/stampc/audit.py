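"""Documentation-completeness audit.

Each of the 16 parameters gets a documentation rate with a
category-appropriate denominator:

* generalizable parameters — documented reports / whole cohort, always in
  [0, 100]%;
* patient-specific parameters — documented reports / intraoperative
  occurrence count, which may exceed 100% when radiologists over-call
  sub-threshold findings.

Category and overall summaries are medians with ranges over those rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .catalog import CATALOG, PARAMETER_IDS, Category, ParameterDef
from .dataset import RegistryRecord, ReportAbstraction
from .simulate import _TRUTH_FIELD


class AuditError(ValueError):
    pass


@dataclass(frozen=True)
class DocumentationRate:
    parameter_id: str
    category: Category
    numerator: int
    denominator: int

    @property
    def rate_pct(self) -> float:
        return 100.0 * self.numerator / self.denominator


@dataclass(frozen=True)
class CompletenessSummary:
    scope: str  # generalizable | patient_specific | overall
    median_pct: float
    min_pct: float
    max_pct: float
    rates: tuple[DocumentationRate, ...]


def occurrence_count(param: ParameterDef, registry: list[RegistryRecord]) -> int:
    """Ground-truth occurrence count of a patient-specific parameter.

    For the old mesh plane the occurrence is the prior-mesh-present count:
    a plane exists for exactly the patients carrying mesh.
    """
    if param.category is not Category.PATIENT_SPECIFIC:
        raise AuditError(
            f"occurrence_count is defined only for patient-specific "
            f"parameters, not {param.id!r}"
        )
    field = _TRUTH_FIELD[param.id]
    return sum(1 for r in registry if getattr(r, field))


def documented_count(param_id: str, reports: list[ReportAbstraction]) -> int:
    return sum(1 for r in reports if r.documented[param_id])


def documentation_rate(
    param: ParameterDef,
    reports: list[ReportAbstraction],
    registry: list[RegistryRecord],
) -> DocumentationRate:
    """Per-parameter rate with the category-appropriate denominator."""
    numerator = documented_count(param.id, reports)
    if param.category is Category.GENERALIZABLE:
        denominator = len(reports)
        if denominator == 0:
            raise AuditError("empty report list")
    else:
        denominator = occurrence_count(param, registry)
        if denominator == 0:
            raise AuditError(
                f"{param.id}: zero ground-truth occurrences; rate undefined "
                f"(suppressed, not 0)"
            )
    return DocumentationRate(param.id, param.category, numerator, denominator)


def audit_rates(
    reports: list[ReportAbstraction], registry: list[RegistryRecord]
) -> list[DocumentationRate]:
    """All 16 per-parameter rates in catalog order."""
    return [documentation_rate(p, reports, registry) for p in CATALOG]


def category_summary(
    rates: list[DocumentationRate], scope: str
) -> CompletenessSummary:
    """Median (midpoint convention) and range over a homogeneous rate list."""
    if not rates:
        raise AuditError("cannot summarize an empty rate list")
    if scope in ("generalizable", "patient_specific"):
        if any(r.category.value != scope for r in rates):
            raise AuditError(f"rate list is not homogeneous for scope {scope!r}")
    elif scope != "overall":
        raise AuditError(f"unknown scope {scope!r}")
    pcts = np.array([r.rate_pct for r in rates])
    return CompletenessSummary(
        scope=scope,
        median_pct=float(np.median(pcts)),
        min_pct=float(pcts.min()),
        max_pct=float(pcts.max()),
        rates=tuple(rates),
    )


def overall_summary(all_rates: list[DocumentationRate]) -> CompletenessSummary:
    """Pooled median over all 16 rates, both categories together."""
    have = {r.parameter_id for r in all_rates}
    missing = set(PARAMETER_IDS) - have
    if missing:
        raise AuditError(f"missing rates for: {sorted(missing)}")
    return category_summary(list(all_rates), "overall")


def summarize(
    rates: list[DocumentationRate],
) -> dict[str, CompletenessSummary]:
    """The three headline summaries: generalizable, patient-specific, overall."""
    gen = [r for r in rates if r.category is Category.GENERALIZABLE]
    ps = [r for r in rates if r.category is Category.PATIENT_SPECIFIC]
    return {
        "generalizable": category_summary(gen, "generalizable"),
        "patient_specific": category_summary(ps, "patient_specific"),
        "overall": overall_summary(rates),
    }


def rates_from_counts(
    documented: dict[str, int],
    occurrence: dict[str, int],
    cohort_n: int,
) -> list[DocumentationRate]:
    """Build rates directly from printed numerator/denominator counts.

    Lets published summary tables be re-analyzed without patient-level data:
    generalizable denominators are the cohort size, patient-specific ones the
    occurrence counts.
    """
    out = []
    for p in CATALOG:
        if p.category is Category.GENERALIZABLE:
            den = cohort_n
        else:
            den = occurrence[p.id]
        out.append(DocumentationRate(p.id, p.category, documented[p.id], den))
    return out


def format_pct(x: float) -> str:
    """Display convention: percent rounded half-up to one decimal."""
    from decimal import ROUND_HALF_UP, Decimal

    return str(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
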