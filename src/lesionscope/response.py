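"""Mixed-response classification and survival comparison.

Patients on PD-1 blockade monotherapy are classified from their
per-lesion diameter trajectories within the first six months of
treatment (183 days, inclusive):

* **nonmixed responder** — every evaluable lesion regresses and no new
  lesion appears;
* **mixed responder** — at least one lesion regresses while another
  progresses or a new lesion appears;
* **nonmixed nonresponder** — at least one lesion progresses (or is new)
  and none regresses.

Per-lesion regression/progression uses RECIST-style thresholds on the
percent change from baseline diameter (any scan <= -30% regressing, any
scan >= +20% or a new lesion progressing); a lesion that does both in
the window counts toward both regression and progression.  Patients
whose lesions are all stable fall outside the three-group taxonomy and
receive the label ``stable_unclassified``, excluded from group
comparisons.

The module also computes tumor burden (sum of lesion diameters at a
scan), a simplified target-lesion RECIST category (CR/PR/SD/PD on the
burden, with PD measured from the nadir), cohort frequency summaries,
and PFS/OS comparisons via the in-house Kaplan–Meier and log-rank
implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np

from .stats import KaplanMeierFit, LogrankResult, km_estimate, logrank_test

__all__ = [
    "LesionObservation",
    "PatientRecord",
    "ResponseGroup",
    "LesionAssessment",
    "lesion_change",
    "classify_response",
    "tumor_burden",
    "recist_category",
    "cohort_summary",
    "survival_by_group",
    "round_percent",
    "DEFAULT_WINDOW_DAYS",
]

DEFAULT_WINDOW_DAYS = 183  # six months, inclusive
REGRESSION_THRESHOLD = -30.0  # percent change from baseline
PROGRESSION_THRESHOLD = 20.0

CANCER_TYPES = ("melanoma", "NSCLC", "gastric", "head_and_neck")


class ResponseGroup(str, Enum):
    NONMIXED_RESPONDER = "nonmixed_responder"
    MIXED_RESPONDER = "mixed_responder"
    NONMIXED_NONRESPONDER = "nonmixed_nonresponder"
    # All-stable patients have no bin in the three-group taxonomy.
    STABLE_UNCLASSIFIED = "stable_unclassified"


@dataclass(frozen=True)
class LesionObservation:
    """One lesion diameter measurement (mm) at a scan time (days)."""

    patient: str
    lesion: str
    time_days: float
    diameter_mm: float
    is_new_lesion: bool = False

    def __post_init__(self) -> None:
        if self.diameter_mm < 0:
            raise ValueError("diameter must be >= 0")


@dataclass
class PatientRecord:
    patient: str
    cancer_type: str
    lesions: list[LesionObservation] = field(default_factory=list)
    pfs_days: float = float("nan")
    pfs_event: bool = False
    os_days: float = float("nan")
    os_event: bool = False
    local_therapy: bool = False


@dataclass
class LesionAssessment:
    lesion: str
    best_change_pct: Optional[float]  # most negative % change; None if new
    regressing: bool
    progressing: bool
    evaluable: bool


def lesion_change(
    observations: Sequence[LesionObservation],
    window_days: float = DEFAULT_WINDOW_DAYS,
    regression_threshold: float = REGRESSION_THRESHOLD,
    progression_threshold: float = PROGRESSION_THRESHOLD,
) -> LesionAssessment:
    """Assess one lesion's trajectory within the assessment window.

    Percent change from baseline is evaluated at every in-window scan.
    The lesion is regressing if any scan reaches ``regression_threshold``
    and progressing if any scan reaches ``progression_threshold`` — both
    flags may be set, since responses can evolve within the window.  A
    lesion first detected after baseline is progressing by definition.
    Lesions with no baseline or no in-window post-baseline scan are
    inevaluable.
    """
    obs = sorted(observations, key=lambda o: o.time_days)
    name = obs[0].lesion if obs else "?"
    if any(o.is_new_lesion for o in obs):
        return LesionAssessment(name, None, regressing=False,
                                progressing=True, evaluable=True)
    baseline = next((o for o in obs if o.time_days == 0), None)
    if baseline is None or baseline.diameter_mm <= 0:
        return LesionAssessment(name, None, False, False, evaluable=False)
    in_window = [
        o for o in obs if 0 < o.time_days <= window_days
    ]
    if not in_window:
        return LesionAssessment(name, None, False, False, evaluable=False)
    changes = [
        100.0 * (o.diameter_mm - baseline.diameter_mm) / baseline.diameter_mm
        for o in in_window
    ]
    return LesionAssessment(
        lesion=name,
        best_change_pct=min(changes),
        regressing=any(c <= regression_threshold for c in changes),
        progressing=any(c >= progression_threshold for c in changes),
        evaluable=True,
    )


def classify_response(
    patient: PatientRecord,
    window_days: float = DEFAULT_WINDOW_DAYS,
    regression_threshold: float = REGRESSION_THRESHOLD,
    progression_threshold: float = PROGRESSION_THRESHOLD,
) -> ResponseGroup:
    """Three-group mixed-response classification from lesion trajectories.

    Requires at least one evaluable lesion.  Lesion order never affects
    the outcome.
    """
    by_lesion: dict[str, list[LesionObservation]] = {}
    for o in patient.lesions:
        by_lesion.setdefault(o.lesion, []).append(o)
    assessments = [
        lesion_change(v, window_days, regression_threshold, progression_threshold)
        for v in by_lesion.values()
    ]
    evaluable = [a for a in assessments if a.evaluable]
    if not evaluable:
        raise ValueError(f"patient {patient.patient} has no evaluable lesion")
    any_reg = any(a.regressing for a in evaluable)
    any_prog = any(a.progressing for a in evaluable)
    all_reg = all(a.regressing for a in evaluable)
    if any_reg and any_prog:
        return ResponseGroup.MIXED_RESPONDER
    if all_reg and not any_prog:
        return ResponseGroup.NONMIXED_RESPONDER
    if any_prog and not any_reg:
        return ResponseGroup.NONMIXED_NONRESPONDER
    return ResponseGroup.STABLE_UNCLASSIFIED


def tumor_burden(patient: PatientRecord, time_days: float) -> float:
    """Total tumor burden: sum of measured lesion diameters at a scan."""
    return sum(
        o.diameter_mm for o in patient.lesions if o.time_days == time_days
    )


def recist_category(
    patient: PatientRecord, window_days: float = DEFAULT_WINDOW_DAYS
) -> Optional[str]:
    """Simplified target-lesion RECIST on total burden: CR / PR / SD / PD.

    Best in-window response on the burden sum: CR when the burden reaches
    0, PR at <= -30% from baseline; PD at >= +20% from the nadir
    (including baseline) or on a new lesion; SD otherwise.  Node-size
    rules, non-target lesions and confirmation scans are ignored — this
    is a deliberately simplified surrogate.  Returns None when
    inevaluable.
    """
    times = sorted({o.time_days for o in patient.lesions})
    if 0 not in times:
        return None
    baseline = tumor_burden(patient, 0)
    if baseline <= 0:
        return None
    scan_times = [t for t in times if 0 < t <= window_days]
    if not scan_times:
        return None
    new_lesion = any(
        o.is_new_lesion and o.time_days <= window_days for o in patient.lesions
    )
    burdens = [tumor_burden(patient, t) for t in scan_times]
    best_change = 100.0 * (min(burdens) - baseline) / baseline
    nadir = baseline
    pd_flag = new_lesion
    for b in burdens:
        if nadir > 0 and 100.0 * (b - nadir) / nadir >= PROGRESSION_THRESHOLD:
            pd_flag = True
        nadir = min(nadir, b)
    if pd_flag:
        return "PD"
    if min(burdens) == 0:
        return "CR"
    if best_change <= REGRESSION_THRESHOLD:
        return "PR"
    return "SD"


def round_percent(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to one decimal (as printed in reports)."""
    if denominator == 0:
        return 0.0
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def cohort_summary(
    patients: Sequence[PatientRecord],
    window_days: float = DEFAULT_WINDOW_DAYS,
) -> dict:
    """Response-group frequencies per cancer type and per RECIST category.

    Returns counts and percentages (one decimal, half-up) for each cancer
    type, each RECIST category, and a pooled row, plus the local-therapy
    rate among mixed responders.
    """
    groups = {p.patient: classify_response(p, window_days) for p in patients}
    recist = {p.patient: recist_category(p, window_days) for p in patients}

    def freq_table(keys: Iterable, key_of) -> dict:
        table = {}
        for key in keys:
            members = [p for p in patients if key_of(p) == key]
            n = len(members)
            counts = {
                g.value: sum(1 for p in members if groups[p.patient] == g)
                for g in ResponseGroup
            }
            table[key] = {
                "n": n,
                "counts": counts,
                "percent": {
                    g: round_percent(c, n) for g, c in counts.items()
                },
            }
        return table

    cancer_types = sorted({p.cancer_type for p in patients})
    recist_cats = sorted({c for c in recist.values() if c is not None})
    n_total = len(patients)
    mixed = [
        p for p in patients
        if groups[p.patient] == ResponseGroup.MIXED_RESPONDER
    ]
    n_mixed = len(mixed)
    n_local = sum(1 for p in mixed if p.local_therapy)
    pooled_counts = {
        g.value: sum(1 for p in patients if groups[p.patient] == g)
        for g in ResponseGroup
    }
    return {
        "n_patients": n_total,
        "groups": {p.patient: groups[p.patient].value for p in patients},
        "pooled": {
            "counts": pooled_counts,
            "percent": {
                g: round_percent(c, n_total) for g, c in pooled_counts.items()
            },
        },
        "by_cancer_type": freq_table(cancer_types, lambda p: p.cancer_type),
        "by_recist": freq_table(recist_cats, lambda p: recist[p.patient]),
        "mixed_local_therapy": {
            "n_mixed": n_mixed,
            "n_local_therapy": n_local,
            "percent": round_percent(n_local, n_mixed),
        },
    }


def survival_by_group(
    patients: Sequence[PatientRecord],
    endpoint: str = "pfs",
    window_days: float = DEFAULT_WINDOW_DAYS,
) -> dict:
    """Kaplan–Meier fits per response group and the log-rank comparison.

    ``endpoint`` is ``"pfs"`` or ``"os"``.  Stable-unclassified patients
    are excluded from the comparison.  Returns per-group fits and the
    k-sample log-rank result.
    """
    if endpoint not in ("pfs", "os"):
        raise ValueError("endpoint must be 'pfs' or 'os'")
    labels, times, events = [], [], []
    for p in patients:
        g = classify_response(p, window_days)
        if g == ResponseGroup.STABLE_UNCLASSIFIED:
            continue
        labels.append(g.value)
        times.append(p.pfs_days if endpoint == "pfs" else p.os_days)
        events.append(
            int(p.pfs_event if endpoint == "pfs" else p.os_event)
        )
    fits: dict[str, KaplanMeierFit] = {}
    for g in sorted(set(labels)):
        idx = [i for i, lab in enumerate(labels) if lab == g]
        fits[g] = km_estimate([times[i] for i in idx], [events[i] for i in idx])
    result: Optional[LogrankResult] = None
    if len(fits) >= 2:
        result = logrank_test(labels, times, events)
    return {"endpoint": endpoint, "km": fits, "logrank": result}
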