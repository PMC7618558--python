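"""Sensitivity grid, robustness checklist, specificity comparison, reverse
MR, and sample-overlap diagnostics.

The checklist condenses the sensitivity programme into six named criteria:

1. pleiotropy-robust estimators agree: the Egger intercept test is null
   (p >= 0.05), or significant together with a significant causal slope;
   and Egger, weighted median, and weighted mode all share the primary
   estimate's sign;
2. estimates are directionally consistent across the LD r^2 threshold grid;
3. ... and across the p-value threshold grid;
4. the collider-corrected estimate is directionally consistent;
5. the Steiger-filtered estimate is directionally consistent (or no
   variants were removed);
6. reverse MR shows no significant positive outcome->exposure association.

A criterion whose inputs are missing is reported ``"not-evaluated"``, never
silently true.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .instruments import DEFAULT_WINDOW_BP, LDMatrix, select_instruments
from .mr_core import MRResult, SteigerResult, dispatch_mr
from .sumstats_io import HarmonizedSet, harmonize_pair

#: Default sensitivity grid mirroring the standard practice of centring the
#: conventional thresholds (p < 5e-8, r^2 < 0.001) within a fixed-interval
#: range.
DEFAULT_P_GRID = (5e-4, 5e-6, 5e-8, 5e-10)
DEFAULT_R2_GRID = (1e-4, 1e-3, 1e-2, 1e-1)

CriterionValue = bool | Literal["not-evaluated"]

CHECKLIST_CRITERIA = (
    "egger_and_robust_estimators_consistent",
    "consistent_across_r2_grid",
    "consistent_across_p_grid",
    "collider_corrected_consistent",
    "steiger_filtered_consistent",
    "no_reverse_association",
)


@dataclass(frozen=True)
class GridSpec:
    """P-value and LD r^2 threshold grids for instrument re-selection."""

    p_thresholds: tuple[float, ...] = DEFAULT_P_GRID
    r2_thresholds: tuple[float, ...] = DEFAULT_R2_GRID

    def __post_init__(self) -> None:
        if not self.p_thresholds or not self.r2_thresholds:
            raise ValueError("grids must be non-empty")
        for axis in (self.p_thresholds, self.r2_thresholds):
            if list(axis) not in (sorted(axis), sorted(axis, reverse=True)):
                raise ValueError("grid axes must be strictly ordered")


@dataclass
class SpecificityVerdict:
    """How a comparator exposure's estimate relates to the primary one."""

    within_primary_ci: bool
    nominal_positive: bool


@dataclass
class RobustnessReport:
    """Grid results plus the six-criterion checklist and specificity verdicts."""

    grid_results: dict[tuple[float, float], MRResult | None]
    checklist: dict[str, CriterionValue]
    directional_consistency: bool
    specificity_verdicts: dict[str, SpecificityVerdict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if tuple(self.checklist) != CHECKLIST_CRITERIA:
            raise ValueError("checklist must contain exactly the six named criteria")


class NotEvaluableMR:
    """Typed outcome for an analysis that could not be run (no instruments)."""

    def __init__(self, reason: str) -> None:
        self.reason = reason

    def __repr__(self) -> str:  # pragma: no cover
        return f"NotEvaluableMR({self.reason!r})"


def sensitivity_grid(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    ld: LDMatrix,
    grid: GridSpec = GridSpec(),
    window_bp: int = DEFAULT_WINDOW_BP,
) -> dict[tuple[float, float], MRResult | None]:
    """Re-run instrument selection, harmonization, and dispatch per grid cell.

    Cells where no instrument survives are marked ``None`` (empty), not
    failed; an all-empty grid raises.
    """
    results: dict[tuple[float, float], MRResult | None] = {}
    for p in grid.p_thresholds:
        for r2 in grid.r2_thresholds:
            try:
                inst = select_instruments(exposure, ld, p, r2, window_bp)
                h = harmonize_pair(inst.variants, outcome)
                results[(p, r2)] = dispatch_mr(h)
            except ValueError:
                results[(p, r2)] = None
    if all(v is None for v in results.values()):
        raise ValueError("no grid cell yielded any instrument")
    return results


def _same_sign(a: float, b: float) -> bool:
    return math.copysign(1.0, a) == math.copysign(1.0, b)


def _grid_consistent(
    primary: MRResult,
    grid: Mapping[tuple[float, float], MRResult | None],
    axis: Literal["p", "r2"],
    fixed_value: float,
) -> CriterionValue:
    """Directional consistency along one grid axis at the fixed other value."""
    cells = [
        res for (p, r2), res in grid.items()
        if res is not None and (r2 == fixed_value if axis == "p" else p == fixed_value)
    ]
    if not cells:
        return "not-evaluated"
    return all(_same_sign(res.beta, primary.beta) for res in cells)


def robustness_checklist(
    primary: MRResult,
    egger: MRResult | None = None,
    wmedian: MRResult | None = None,
    wmode: MRResult | None = None,
    grid: Mapping[tuple[float, float], MRResult | None] | None = None,
    slopehunter: MRResult | None = None,
    steiger: tuple[MRResult, SteigerResult] | None = None,
    reverse: MRResult | NotEvaluableMR | None = None,
    primary_p_threshold: float = 5e-8,
    primary_r2_threshold: float = 1e-3,
    alpha: float = 0.05,
) -> dict[str, CriterionValue]:
    """Evaluate the six robustness criteria (see module docstring).

    Grid criteria compare every non-empty cell along the relevant axis (the
    other axis held at the primary threshold) against the primary estimate's
    sign; empty cells are excluded rather than counted as failures.
    """
    checklist: dict[str, CriterionValue] = {}

    if egger is None or wmedian is None or wmode is None:
        checklist[CHECKLIST_CRITERIA[0]] = "not-evaluated"
    else:
        intercept_ok = (
            egger.egger_intercept_pval >= alpha
            or (egger.egger_intercept_pval < alpha and egger.pval < alpha)
        )
        signs_ok = all(
            _same_sign(r.beta, primary.beta) for r in (egger, wmedian, wmode)
        )
        checklist[CHECKLIST_CRITERIA[0]] = bool(intercept_ok and signs_ok)

    if grid is None:
        checklist[CHECKLIST_CRITERIA[1]] = "not-evaluated"
        checklist[CHECKLIST_CRITERIA[2]] = "not-evaluated"
    else:
        checklist[CHECKLIST_CRITERIA[1]] = _grid_consistent(
            primary, grid, "r2", primary_p_threshold
        )
        checklist[CHECKLIST_CRITERIA[2]] = _grid_consistent(
            primary, grid, "p", primary_r2_threshold
        )

    if slopehunter is None:
        checklist[CHECKLIST_CRITERIA[3]] = "not-evaluated"
    else:
        checklist[CHECKLIST_CRITERIA[3]] = _same_sign(slopehunter.beta, primary.beta)

    if steiger is None:
        checklist[CHECKLIST_CRITERIA[4]] = "not-evaluated"
    else:
        filtered_result, steiger_detail = steiger
        checklist[CHECKLIST_CRITERIA[4]] = (
            steiger_detail.n_removed == 0
            or _same_sign(filtered_result.beta, primary.beta)
        )

    if reverse is None:
        checklist[CHECKLIST_CRITERIA[5]] = "not-evaluated"
    elif isinstance(reverse, NotEvaluableMR):
        checklist[CHECKLIST_CRITERIA[5]] = "not-evaluated"
    else:
        checklist[CHECKLIST_CRITERIA[5]] = not (reverse.pval < alpha and reverse.beta > 0)

    return checklist


def build_report(
    grid: dict[tuple[float, float], MRResult | None],
    checklist: dict[str, CriterionValue],
    specificity_verdicts: dict[str, SpecificityVerdict] | None = None,
) -> RobustnessReport:
    """Assemble the grid, checklist, and specificity verdicts into a report.

    ``directional_consistency`` summarizes the two grid criteria: true only
    when both evaluated true.
    """
    consistent = (
        checklist[CHECKLIST_CRITERIA[1]] is True
        and checklist[CHECKLIST_CRITERIA[2]] is True
    )
    return RobustnessReport(
        grid_results=grid,
        checklist=checklist,
        directional_consistency=consistent,
        specificity_verdicts=specificity_verdicts or {},
    )


def specificity_compare(
    primary: MRResult,
    comparators: Mapping[str, MRResult],
) -> dict[str, SpecificityVerdict]:
    """Check each comparator's estimate against the primary association.

    A comparator is "within" when its point estimate lies inside the
    primary's 95% CI, and "nominal positive" when it is positive with
    p < 0.05.
    """
    if not (math.isfinite(primary.ci_low) and math.isfinite(primary.ci_high)):
        raise ValueError("primary result must have a finite CI")
    out = {}
    for label, res in comparators.items():
        out[label] = SpecificityVerdict(
            within_primary_ci=bool(primary.ci_low <= res.beta <= primary.ci_high),
            nominal_positive=bool(res.pval < 0.05 and res.beta > 0),
        )
    return out


def reverse_mr(
    outcome_as_exposure: pd.DataFrame,
    exposure_as_outcome: pd.DataFrame,
    ld: LDMatrix,
    p_thresholds: tuple[float, ...] = (5e-8, 5e-6),
    r2_threshold: float = 0.001,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> MRResult | NotEvaluableMR:
    """Run the full forward machinery with exposure and outcome roles swapped.

    Thresholds are tried in order; the first one yielding instruments is
    used (the dispatch rule is unchanged).  Returns a typed not-evaluable
    outcome when no threshold yields an instrument.
    """
    for p in p_thresholds:
        try:
            inst = select_instruments(outcome_as_exposure, ld, p, r2_threshold, window_bp)
        except ValueError:
            continue
        h = harmonize_pair(inst.variants, exposure_as_outcome,
                           exposure_label="reverse_exposure",
                           outcome_label="reverse_outcome")
        return dispatch_mr(h)
    return NotEvaluableMR(
        f"no instrument at any threshold in {tuple(p_thresholds)}"
    )


def effective_sample_size(n_case: float, n_control: float) -> float:
    """Case-control effective sample size: 4 n_case n_control / (n_case + n_control)."""
    if n_case <= 0 or n_control <= 0:
        raise ValueError("counts must be positive")
    return 4 * n_case * n_control / (n_case + n_control)


def effective_overlap(
    n_case_1: float, n_control_1: float,
    n_case_2: float, n_control_2: float,
    n_shared_eff: float,
) -> float:
    """Shared effective sample size as a fraction of the smaller cohort's.

    Used to gauge bias risk from participant overlap between the exposure
    and outcome GWAS.
    """
    n_eff_1 = effective_sample_size(n_case_1, n_control_1)
    n_eff_2 = effective_sample_size(n_case_2, n_control_2)
    smaller = min(n_eff_1, n_eff_2)
    if n_shared_eff < 0 or n_shared_eff > smaller:
        raise ValueError("n_shared_eff must lie in [0, min effective size]")
    return n_shared_eff / smaller


def forest_plot(results: Mapping[str, MRResult], path, title: str | None = None) -> None:
    """Basic forest plot of odds ratios with 95% CIs (one row per label)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(results)
    ors = [results[k].odds_ratio for k in labels]
    lo = [results[k].or_ci_low for k in labels]
    hi = [results[k].or_ci_high for k in labels]
    y = np.arange(len(labels))[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(labels) + 1.5))
    ax.errorbar(ors, y, xerr=[np.subtract(ors, lo), np.subtract(hi, ors)],
                fmt="s", color="navy", ecolor="gray", capsize=3)
    ax.axvline(1.0, color="black", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(labels)
    ax.set_xlabel("Odds ratio (95% CI)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
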