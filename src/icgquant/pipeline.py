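"""End-to-end cohort pipeline: analyze curves, classify, evaluate.

Glues the stages together the way the clinical study ran them: every
patient's curve is parameterized, trichotomized against the cut-offs,
assigned a risk zone, and the cohort-level diagnostics (2x2 table, ROC,
zone rates, odds ratio) are computed against the outcome labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import AnalysisConfig, PerfusionModel
from .classify import ClassificationConfig, classify_params
from .exceptions import InvalidSpecificationError, UndefinedStatisticError
from .simulate import Cohort, CohortSpec, generate_cohort
from .stats import (
    ContingencyTable2x2,
    diagnostic_values,
    odds_ratio,
    roc_analysis,
    zone_rates,
)

__all__ = ["analyze_cohort", "evaluate_cohort", "run_synthetic_study",
           "CohortEvaluation"]

#: ROC orientation per factor: larger time values indicate complication,
#: larger slope is protective.
FACTOR_DIRECTIONS = {"slope": "lower", "t_half_max": "higher", "tr": "higher"}


def analyze_cohort(
    cohort: Cohort,
    analysis_config: AnalysisConfig | None = None,
    class_config: ClassificationConfig | None = None,
) -> pd.DataFrame:
    """Parameterize and classify every member curve of a cohort.

    Returns one row per patient with the measured perfusion parameters,
    per-factor categories, the risk zone and the outcome label.

    A curve with no detectable inflow (no sustained rise above the
    baseline noise within the analysis window -- the intraoperative
    analogue of observing no blood flow within the capped waiting time)
    is flagged `no_perfusion` and ranked maximally abnormal: TR 1, zero
    slope, times at the window cap, every category slow, critical zone.
    """
    from .classify import Category, RiskZone
    from .exceptions import NoPerfusionError

    analysis_config = analysis_config or AnalysisConfig()
    class_config = class_config or ClassificationConfig()
    rows = []
    for i, member in enumerate(cohort):
        if member.curve is None:
            raise InvalidSpecificationError(
                f"cohort member {i} has no curve; generate with curves enabled"
            )
        row = {"patient": i, "group": member.group, "outcome": member.outcome,
               "no_perfusion": False}
        try:
            res = PerfusionModel(member.curve, analysis_config).fit()
        except NoPerfusionError:
            cap = analysis_config.analysis_window
            row.update({
                "f_min": float(np.mean(member.curve.intensities)),
                "delta_f": np.nan,
                "slope_au_per_s": 0.0,
                "t_onset_s": np.nan,
                "t_max_s": cap,
                "t_half_max_s": cap,
                "tr": 1.0,
                "censored": True,
                "no_perfusion": True,
            })
            row.update({f"cat_{k}": Category.SLOW.value
                        for k in ("slope", "t_half_max", "tr")})
            row["risk_zone"] = RiskZone.CRITICAL.value
            rows.append(row)
            continue
        status = classify_params(res.params, class_config)
        row.update(res.params.to_dict())
        row.update(
            {f"cat_{k}": v.value for k, v in status.categories.items()}
        )
        row["risk_zone"] = status.risk_zone.value
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortEvaluation:
    """Cohort-level evaluation of one perfusion factor."""

    factor: str
    cutoff: float
    table: ContingencyTable2x2
    diagnostics: object
    roc: object
    odds_ratio: object
    zone_rates: dict
    incidence: float

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "cutoff": self.cutoff,
            "table": {
                "tp": self.table.tp, "fp": self.table.fp,
                "fn": self.table.fn, "tn": self.table.tn,
            },
            "diagnostics": self.diagnostics.to_dict(),
            "roc": self.roc.to_dict(),
            "odds_ratio": (
                self.odds_ratio.to_dict() if self.odds_ratio is not None else None
            ),
            "zone_rates": {str(k): str(v) for k, v in self.zone_rates.items()},
            "incidence": self.incidence,
        }


def evaluate_cohort(
    analyzed: pd.DataFrame,
    factor: str = "tr",
    cutoff: float | None = None,
    class_config: ClassificationConfig | None = None,
) -> CohortEvaluation:
    """Diagnostics of one factor's slow/not-slow split on an analyzed cohort.

    `cutoff` defaults to the factor's slow bound from the classification
    config; "slow" means above it for the time factors and below it for
    slope.  ROC, the 2x2 diagnostics, zone rates over the per-factor
    categories, and the 2x2 odds ratio are all computed against the
    outcome column.
    """
    class_config = class_config or ClassificationConfig()
    col = {"slope": "slope_au_per_s", "t_half_max": "t_half_max_s", "tr": "tr"}.get(
        factor
    )
    if col is None or col not in analyzed.columns:
        raise InvalidSpecificationError(f"unknown or missing factor {factor!r}")
    values = analyzed[col].to_numpy(dtype=float)
    outcomes = analyzed["outcome"].to_numpy(dtype=int)
    direction = FACTOR_DIRECTIONS[factor]
    if cutoff is None:
        cutoff = {
            "slope": class_config.slope_slow_lt,
            "t_half_max": class_config.thalf_slow_gt,
            "tr": class_config.tr_slow_gt,
        }[factor]
    slow = values > cutoff if direction == "higher" else values < cutoff
    table = ContingencyTable2x2.from_predictions(slow, outcomes)
    diag = diagnostic_values(table)
    roc = roc_analysis(values, outcomes, direction=direction)
    try:
        orr = odds_ratio(table)
    except UndefinedStatisticError:
        orr = None
    rates = zone_rates(analyzed[f"cat_{factor}"].tolist(), outcomes)
    return CohortEvaluation(
        factor=factor,
        cutoff=float(cutoff),
        table=table,
        diagnostics=diag,
        roc=roc,
        odds_ratio=orr,
        zone_rates=rates,
        incidence=float(np.mean(outcomes)),
    )


def run_synthetic_study(
    seed: int = 0,
    spec: CohortSpec | None = None,
    factor: str = "tr",
    analysis_config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, CohortEvaluation]:
    """Generate a calibrated cohort, analyze it and evaluate one factor."""
    if spec is None:
        spec = CohortSpec(random_seed=seed)
    cohort = generate_cohort(spec)
    analyzed = analyze_cohort(cohort, analysis_config)
    return analyzed, evaluate_cohort(analyzed, factor=factor)
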