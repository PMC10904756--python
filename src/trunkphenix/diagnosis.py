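"""Trunk-disease staging and foliar-symptom-history comparisons.

The staging model grades a vine from the tissue composition of the region
around the trunk head (signed geodesic position -2..+2 cm): the white-rot
share separates healthy (<8%), affected (8-15%) and critical (>15%) vines,
while an intact share at or below 30% forces the critical stage regardless of
white rot.  History categories encode how a vine's yearly foliar-symptom (FS)
record relates to the observation year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .phantom import TISSUE_CLASSES, SymptomHistory
from .quantification import TissueSummary

HISTORY_CATEGORY_NAMES: tuple[str, ...] = (
    "asymptomatic_always",
    "asymptomatic_resilient",
    "symptomatic_neo",
    "symptomatic_apoplectic",
    "symptomatic_recurrent",
)

STAGES: tuple[str, ...] = ("low", "moderate", "critical")


@dataclass(frozen=True)
class HistoryCategory:
    """External sanitary category of a vine, with its derivation."""

    name: str
    notes: str = ""

    def __post_init__(self) -> None:
        if self.name not in HISTORY_CATEGORY_NAMES:
            raise ValueError(f"unknown history category {self.name!r}")


def classify_history(history: SymptomHistory, observation_year: int) -> HistoryCategory:
    """Map a yearly FS record to its sanitary category at the observation year.

    The four sampling categories (always/resilient/neo/apoplectic) are
    completed by ``symptomatic_recurrent`` (FS in the observation year after
    earlier FS years) so that every flag pattern maps to exactly one category.
    """
    if observation_year not in history.flags:
        raise ValueError(
            f"observation year {observation_year} outside the record of {history.vine_id}")
    latest = history.flag(observation_year)
    prior = any(v for y, v in history.flags.items() if y < observation_year)
    if history.apoplexy_year is not None and history.apoplexy_year == observation_year:
        return HistoryCategory("symptomatic_apoplectic", "died of apoplexy in the observation year")
    if not latest and not prior:
        return HistoryCategory("asymptomatic_always", "no FS in any recorded year")
    if not latest:
        return HistoryCategory("asymptomatic_resilient", "FS in earlier years only")
    if not prior:
        return HistoryCategory("symptomatic_neo", "first FS in the observation year")
    return HistoryCategory("symptomatic_recurrent", "FS in the observation year and earlier")


# ---------------------------------------------------------------------------
# Staging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StagingThresholds:
    """Stage boundaries in percent of the tissue total.

    Boundary conventions follow the published inequalities: white rot is
    "low" strictly below ``white_rot_low`` and "critical" strictly above
    ``white_rot_critical`` (both boundaries belong to the moderate band);
    an intact share of ``intact_min`` or less forces the critical stage.
    """

    white_rot_low: float = 8.0
    white_rot_critical: float = 15.0
    intact_min: float = 30.0


@dataclass
class StageCall:
    """A staged vine: inputs echoed with the decisive rule."""

    stage: str
    intact_pct: float
    white_rot_pct: float
    rule: str
    thresholds: StagingThresholds


def stage_vine(region_summary: TissueSummary | tuple[float, float],
               thresholds: Optional[StagingThresholds] = None) -> StageCall:
    """Grade trunk damage from the tissue composition near the trunk head.

    Accepts either a :class:`TissueSummary` of the -2..+2 cm region or an
    ``(intact_pct, white_rot_pct)`` pair.  Critical dominates: very limited
    intact tissue is critical whatever the white-rot share.
    """
    t = thresholds or StagingThresholds()
    if isinstance(region_summary, TissueSummary):
        if not region_summary.defined:
            raise ValueError(f"tissue fractions undefined in region {region_summary.region!r}")
        intact = region_summary.fraction_pct("intact")
        white_rot = region_summary.fraction_pct("white_rot")
    else:
        intact, white_rot = map(float, region_summary)
        if not (np.isfinite(intact) and np.isfinite(white_rot)):
            raise ValueError("tissue fractions must be finite")

    if intact <= t.intact_min:
        stage, rule = "critical", f"intact {intact:.1f}% <= {t.intact_min:g}%"
    elif white_rot > t.white_rot_critical:
        stage, rule = "critical", f"white rot {white_rot:.1f}% > {t.white_rot_critical:g}%"
    elif white_rot < t.white_rot_low:
        stage, rule = "low", (f"white rot {white_rot:.1f}% < {t.white_rot_low:g}% "
                              f"and intact {intact:.1f}% > {t.intact_min:g}%")
    else:
        stage, rule = "moderate", (f"white rot {white_rot:.1f}% in "
                                   f"[{t.white_rot_low:g}%, {t.white_rot_critical:g}%]")
    return StageCall(stage=stage, intact_pct=intact, white_rot_pct=white_rot,
                     rule=rule, thresholds=t)


# ---------------------------------------------------------------------------
# History vs internal-content correlations
# ---------------------------------------------------------------------------

@dataclass
class CorrelationReport:
    """Signed Pearson correlations of tissue fractions vs history covariates."""

    table: pd.DataFrame   # index: tissue classes; columns: covariates
    n: int
    method: str = "pearson_r"


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")   # degenerate covariate: undefined, not zero
    return float(np.corrcoef(x, y)[0, 1])


def correlate_history(summaries: Mapping[str, TissueSummary],
                      histories: Mapping[str, SymptomHistory],
                      observation_year: int) -> CorrelationReport:
    """Correlate per-vine tissue fractions with three FS-history covariates.

    Covariates: the observation-year symptom flag, the cumulative number of
    symptomatic years, and the first-symptom year (never-symptomatic vines are
    excluded from the latter).  Coefficients are signed Pearson r.
    """
    vines = sorted(summaries)
    if len(vines) < 3:
        raise ValueError("correlations need at least 3 vines")
    fractions = {name: np.array([summaries[v].fraction_pct(name) for v in vines])
                 for name in TISSUE_CLASSES}
    latest = np.array([float(histories[v].flag(observation_year)) for v in vines])
    cumulative = np.array([float(histories[v].cumulative_symptomatic_years(observation_year))
                           for v in vines])
    first = np.array([np.nan if histories[v].first_symptom_year() is None
                      else float(histories[v].first_symptom_year()) for v in vines])

    covariates = {"latest_flag": latest, "cumulative_years": cumulative,
                  "first_symptom_year": first}
    table = pd.DataFrame(index=list(TISSUE_CLASSES), columns=list(covariates), dtype=float)
    for tname, frac in fractions.items():
        for cname, cov in covariates.items():
            table.loc[tname, cname] = _pearson(frac, cov)
    return CorrelationReport(table=table, n=len(vines))
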