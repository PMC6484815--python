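"""Perfusion-status classification: fast/moderate/slow per factor and risk zones.

Each perfusion factor is trichotomized against published cut-offs (values
between the bounds, inclusive of the bounds themselves, are "moderate" --
the published inequalities are strict and equality is left undefined, so
boundary values conservatively fall in the middle band):

    slope      fast > 1.0 AU/s     slow < 0.7 AU/s
    T_1/2MAX   fast < 10 s         slow > 18 s
    TR         fast < 0.4          slow > 0.6

The two time factors then feed a step-by-step risk stratification:
T_1/2MAX (high sensitivity) screens first, TR (high specificity) refines.
Four zones are exposed -- safe, intermediate, dangerous, critical, in
increasing severity -- with both factors fast mapping to safe, exactly one
factor slow to dangerous, both slow to critical, and the remaining
(moderate) combinations to intermediate.  The mapping ships in the config
and can be overridden to reproduce alternative zone nomenclatures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import yaml

from .exceptions import InvalidSpecificationError
from . import reference

__all__ = [
    "Category",
    "RiskZone",
    "ClassificationConfig",
    "PerfusionStatus",
    "classify_factor",
    "risk_zone",
    "classify_params",
]


class Category(str, Enum):
    FAST = "fast"
    MODERATE = "moderate"
    SLOW = "slow"


class RiskZone(str, Enum):
    SAFE = "safe"
    INTERMEDIATE = "intermediate"
    DANGEROUS = "dangerous"
    CRITICAL = "critical"

    @property
    def severity(self) -> int:
        """Ordinal severity: safe=0 ... critical=3."""
        return _ZONE_ORDER.index(self)


_ZONE_ORDER = [
    RiskZone.SAFE,
    RiskZone.INTERMEDIATE,
    RiskZone.DANGEROUS,
    RiskZone.CRITICAL,
]

#: Informational surgical guidance per zone (never a decision).
ZONE_GUIDANCE = {
    RiskZone.SAFE: "fast perfusion; minimal anastomotic risk expected",
    RiskZone.INTERMEDIATE: "moderate perfusion; standard management",
    RiskZone.DANGEROUS: (
        "delayed perfusion; consider improving inflow (splenic flexure "
        "mobilization, low IMA ligation) or diverting ileostomy"
    ),
    RiskZone.CRITICAL: (
        "severely delayed perfusion; consider moving the transection line "
        "proximally or end colostomy instead of primary anastomosis"
    ),
}


def _default_zone_map() -> dict:
    """(T_1/2MAX category, TR category) -> zone, for all nine combinations."""
    out = {}
    for th in Category:
        for tr in Category:
            if th is Category.SLOW and tr is Category.SLOW:
                zone = RiskZone.CRITICAL
            elif th is Category.SLOW or tr is Category.SLOW:
                zone = RiskZone.DANGEROUS
            elif th is Category.FAST and tr is Category.FAST:
                zone = RiskZone.SAFE
            else:
                zone = RiskZone.INTERMEDIATE
            out[(th, tr)] = zone
    return out


@dataclass(frozen=True)
class ClassificationConfig:
    """Cut-offs defining fast/moderate/slow per factor, plus the zone map.

    Invariant: the fast and slow bounds must leave room for a moderate
    band (slope: fast bound > slow bound; time factors: fast bound <
    slow bound).
    """

    slope_fast_gt: float = reference.CUTOFFS["slope"]["fast_gt"]
    slope_slow_lt: float = reference.CUTOFFS["slope"]["slow_lt"]
    thalf_fast_lt: float = reference.CUTOFFS["t_half_max"]["fast_lt"]
    thalf_slow_gt: float = reference.CUTOFFS["t_half_max"]["slow_gt"]
    tr_fast_lt: float = reference.CUTOFFS["tr"]["fast_lt"]
    tr_slow_gt: float = reference.CUTOFFS["tr"]["slow_gt"]
    zone_map: dict = field(default_factory=_default_zone_map, compare=False)

    def __post_init__(self) -> None:
        if not self.slope_fast_gt > self.slope_slow_lt:
            raise InvalidSpecificationError(
                "slope: fast bound must exceed slow bound"
            )
        if not self.thalf_fast_lt < self.thalf_slow_gt:
            raise InvalidSpecificationError(
                "t_half_max: fast bound must be below slow bound"
            )
        if not self.tr_fast_lt < self.tr_slow_gt:
            raise InvalidSpecificationError("tr: fast bound must be below slow bound")
        missing = {(a, b) for a in Category for b in Category} - set(self.zone_map)
        if missing:
            raise InvalidSpecificationError(f"zone_map missing combinations: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "ClassificationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "zone_map" in data:
            data["zone_map"] = {
                (Category(k.split("/")[0]), Category(k.split("/")[1])): RiskZone(v)
                for k, v in data["zone_map"].items()
            }
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {
            "slope_fast_gt": self.slope_fast_gt,
            "slope_slow_lt": self.slope_slow_lt,
            "thalf_fast_lt": self.thalf_fast_lt,
            "thalf_slow_gt": self.thalf_slow_gt,
            "tr_fast_lt": self.tr_fast_lt,
            "tr_slow_gt": self.tr_slow_gt,
            "zone_map": {
                f"{k[0].value}/{k[1].value}": v.value for k, v in self.zone_map.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


FACTORS = ("slope", "t_half_max", "tr")


def classify_factor(
    value: float, factor_name: str, config: ClassificationConfig | None = None
) -> Category:
    """Trichotomize one perfusion factor with strict published inequalities.

    Values equal to a bound are moderate.  Note that the slope direction
    is reversed relative to the time factors: a *large* slope is fast flow.
    """
    config = config or ClassificationConfig()
    if not np.isfinite(value):
        raise InvalidSpecificationError(f"non-finite value for {factor_name}")
    if factor_name == "slope":
        if value > config.slope_fast_gt:
            return Category.FAST
        if value < config.slope_slow_lt:
            return Category.SLOW
        return Category.MODERATE
    if factor_name == "t_half_max":
        fast_lt, slow_gt = config.thalf_fast_lt, config.thalf_slow_gt
    elif factor_name == "tr":
        fast_lt, slow_gt = config.tr_fast_lt, config.tr_slow_gt
    else:
        raise InvalidSpecificationError(
            f"unknown factor {factor_name!r}; expected one of {FACTORS}"
        )
    if value < fast_lt:
        return Category.FAST
    if value > slow_gt:
        return Category.SLOW
    return Category.MODERATE


#: Per-factor 3-zone view: the factor's own category maps 1:1 onto a zone.
_FACTOR_ZONE = {
    Category.FAST: RiskZone.SAFE,
    Category.MODERATE: RiskZone.INTERMEDIATE,
    Category.SLOW: RiskZone.DANGEROUS,
}


@dataclass(frozen=True)
class PerfusionStatus:
    """Classified perfusion status of one patient.

    `categories` holds fast/moderate/slow per factor, `factor_zones` the
    per-factor 3-zone view (fast -> safe, moderate -> intermediate,
    slow -> dangerous), and `risk_zone` the two-factor 4-zone assignment
    from the step-by-step flow chart.
    """

    categories: dict
    risk_zone: RiskZone
    censored: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "slow_flags",
            {k: v is Category.SLOW for k, v in self.categories.items()},
        )
        object.__setattr__(
            self,
            "factor_zones",
            {k: _FACTOR_ZONE[v] for k, v in self.categories.items()},
        )

    @property
    def guidance(self) -> str:
        """Informational management text attached to the zone."""
        return ZONE_GUIDANCE[self.risk_zone]

    def to_dict(self) -> dict:
        return {
            "categories": {k: v.value for k, v in self.categories.items()},
            "slow_flags": dict(self.slow_flags),
            "factor_zones": {k: v.value for k, v in self.factor_zones.items()},
            "risk_zone": self.risk_zone.value,
            "censored": self.censored,
            "note": self.note,
            "guidance": self.guidance,
        }


def risk_zone(params, config: ClassificationConfig | None = None) -> RiskZone:
    """Two-factor risk zone from the step-by-step flow chart.

    Step 1 screens on the T_1/2MAX category, step 2 refines on TR; the
    configured zone map resolves all nine combinations.  A censored
    time-to-maximum (curve still rising at the window end) forces at
    least the dangerous zone, since the measured times are lower bounds.
    """
    config = config or ClassificationConfig()
    th_cat = classify_factor(params.t_half_max, "t_half_max", config)
    tr_cat = classify_factor(params.tr, "tr", config)
    zone = config.zone_map[(th_cat, tr_cat)]
    if getattr(params, "censored", False) and zone.severity < RiskZone.DANGEROUS.severity:
        zone = RiskZone.DANGEROUS
    return zone


def classify_params(
    params, config: ClassificationConfig | None = None
) -> PerfusionStatus:
    """Full perfusion status: per-factor categories plus the risk zone."""
    config = config or ClassificationConfig()
    categories = {
        "slope": classify_factor(params.slope, "slope", config),
        "t_half_max": classify_factor(params.t_half_max, "t_half_max", config),
        "tr": classify_factor(params.tr, "tr", config),
    }
    zone = risk_zone(params, config)
    censored = bool(getattr(params, "censored", False))
    note = (
        "time-to-maximum censored at window end; zone floored at dangerous"
        if censored
        else ""
    )
    return PerfusionStatus(
        categories=categories, risk_zone=zone, censored=censored, note=note
    )
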