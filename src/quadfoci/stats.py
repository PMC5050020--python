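"""Per-experiment normalization and group comparison of per-cell metrics.

Staining intensity varies between experiments, so each experiment is
analyzed separately: every cell line's per-cell value is divided by the
per-cell value of the average control cell of that experiment (all
control cells pooled, i.e. a cell-count-weighted mean over control
lines).  Normalized values from all experiments are then compared with
an unpaired t-test, case lines as one group and control lines as the
other; the fold change is the ratio of normalized group means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .io import QuadfociError, logger

CONTROL = "control"
CASE = "case"

STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class ExperimentRecord:
    """One cell line's per-cell metric within one staining experiment."""

    experiment_id: str
    line_id: str
    group: str  # "control" or "case"
    value: float  # foci_per_cell or area_per_cell (one metric per table)
    n_cells: int

    def __post_init__(self) -> None:
        if self.group not in (CONTROL, CASE):
            raise QuadfociError(f"group must be control/case, got {self.group!r}")
        if self.value < 0 or self.n_cells < 0:
            raise QuadfociError("value and n_cells must be nonnegative")


@dataclass
class GroupComparison:
    metric: str
    n_case_replicates: int
    n_control_replicates: int
    fold_change: float
    t_statistic: float
    p_value: float
    stars: str


def significance_stars(p_value: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p_value < threshold:
            return stars
    return "ns"


def normalize_to_control(records: list[ExperimentRecord]) -> list[ExperimentRecord]:
    """Divide each value by its experiment's average-control-cell value.

    The control reference pools all control cells in the experiment:
    sum(value_i * n_cells_i) / sum(n_cells_i) over control lines.  After
    normalization the cell-weighted control mean is 1 in every
    experiment.
    """
    out = []
    for exp in sorted({r.experiment_id for r in records}):
        exp_records = [r for r in records if r.experiment_id == exp]
        controls = [r for r in exp_records if r.group == CONTROL]
        if not controls:
            raise QuadfociError(f"experiment {exp!r} has no control lines")
        total_cells = sum(r.n_cells for r in controls)
        if total_cells == 0:
            raise QuadfociError(f"experiment {exp!r}: control lines have zero cells")
        ref = sum(r.value * r.n_cells for r in controls) / total_cells
        if ref == 0:
            raise QuadfociError(
                f"experiment {exp!r}: average control cell value is zero"
            )
        out.extend(replace(r, value=r.value / ref) for r in exp_records)
    return out


def compare_groups(
    records: list[ExperimentRecord],
    metric: str = "value",
    equal_var: bool = True,
) -> GroupComparison | None:
    """Unpaired t-test of case vs control normalized values.

    Student's pooled-variance test by default; ``equal_var=False`` gives
    Welch's test.  Degenerate zero-variance inputs are resolved by the
    means: equal means give p = 1, different means p = 0.
    """
    case = np.array([r.value for r in records if r.group == CASE], dtype=float)
    ctrl = np.array([r.value for r in records if r.group == CONTROL], dtype=float)
    if len(case) < 2 or len(ctrl) < 2:
        logger.warning(
            "comparison skipped: need >=2 replicates per group (%d case, %d control)",
            len(case),
            len(ctrl),
        )
        return None
    fold = case.mean() / ctrl.mean() if ctrl.mean() != 0 else float("inf")
    if case.var(ddof=1) == 0 and ctrl.var(ddof=1) == 0:
        if case.mean() == ctrl.mean():
            t, p = 0.0, 1.0
        else:
            t = float("inf") if case.mean() > ctrl.mean() else float("-inf")
            p = 0.0
    else:
        t, p = sps.ttest_ind(case, ctrl, equal_var=equal_var)
        t, p = float(t), float(p)
    return GroupComparison(
        metric=metric,
        n_case_replicates=len(case),
        n_control_replicates=len(ctrl),
        fold_change=float(fold),
        t_statistic=t,
        p_value=p,
        stars=significance_stars(p),
    )


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values across a family of metrics (clearly a re-ranking
    of the raw per-metric p-values, reported alongside them)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


@dataclass
class RnaseReport:
    reduction_control_pct: float
    reduction_case_pct: float
    implied_untreated_ratio: float


def percent_reduction(untreated: float, treated: float) -> float:
    """(untreated - treated) / untreated, as %."""
    if untreated == 0:
        raise QuadfociError("reduction undefined for untreated value 0")
    return 100.0 * (untreated - treated) / untreated


def implied_untreated_ratio(
    treated_case: float,
    treated_control: float,
    reduction_case_pct: float,
    reduction_control_pct: float,
) -> float:
    """Case:control ratio of untreated values back-computed from the
    post-treatment values and the percent reductions."""
    untreated_case = treated_case / (1 - reduction_case_pct / 100.0)
    untreated_control = treated_control / (1 - reduction_control_pct / 100.0)
    return untreated_case / untreated_control


def rnase_comparison(
    untreated: dict[str, float], treated: dict[str, float]
) -> RnaseReport:
    """Percent reduction in foci per cell after RNAse, per group.

    ``untreated`` and ``treated`` map group ("control"/"case") to the
    group's mean foci per cell under each condition.
    """
    red_ctrl = percent_reduction(untreated[CONTROL], treated[CONTROL])
    red_case = percent_reduction(untreated[CASE], treated[CASE])
    return RnaseReport(
        reduction_control_pct=red_ctrl,
        reduction_case_pct=red_case,
        implied_untreated_ratio=implied_untreated_ratio(
            treated[CASE], treated[CONTROL], red_case, red_ctrl
        ),
    )
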