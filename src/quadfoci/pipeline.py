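"""End-to-end composition: images -> per-line records -> group comparison.

Aggregation convention: within one experiment, a cell line's per-cell
value is the sum of its images' foci counts (or stained areas) divided
by the sum of its cell counts, i.e. cells are pooled across the line's
fields of view before any normalization.
"""

from __future__ import annotations

import pandas as pd

from .foci import FociQuantResult, ThresholdConfig, quantify_image
from .io import MultichannelImage
from .stats import (
    ExperimentRecord,
    GroupComparison,
    compare_groups,
    normalize_to_control,
    percent_reduction,
)


def quantify_cohort(entries, config: ThresholdConfig | None = None) -> pd.DataFrame:
    """Per-image foci quantification of a generated or loaded cohort.

    ``entries`` is an iterable of objects with experiment_id, line_id,
    group, condition and image attributes (e.g. simulate.CohortEntry).
    """
    config = config or ThresholdConfig()
    rows = []
    for ent in entries:
        res: FociQuantResult = quantify_image(ent.image, config)
        rows.append(
            {
                "image_id": res.image_id,
                "experiment": ent.experiment_id,
                "line": ent.line_id,
                "group": ent.group,
                "condition": ent.condition,
                "n_objects": len(res.objects),
                "area_total_px": res.area_total_px,
                "area_total_um2": res.area_total_um2,
                "trimmed_mean_area_px": res.trimmed_mean_area_px,
                "foci_count": res.foci_count,
                "n_cells": res.n_cells,
                "foci_per_cell": res.foci_per_cell,
                "area_per_cell_um2": res.area_per_cell_um2,
            }
        )
    return pd.DataFrame(rows)


_METRIC_TOTALS = {"foci_per_cell": "foci_count", "area_per_cell_um2": "area_total_um2"}


def line_records(df: pd.DataFrame, metric: str) -> list[ExperimentRecord]:
    """Collapse per-image results to one record per experiment x line."""
    total_col = _METRIC_TOTALS[metric]
    grouped = (
        df.groupby(["experiment", "line", "group"], as_index=False)
        .agg(total=(total_col, "sum"), n_cells=("n_cells", "sum"))
    )
    return [
        ExperimentRecord(
            experiment_id=row.experiment,
            line_id=row.line,
            group=row.group,
            value=row.total / row.n_cells if row.n_cells else 0.0,
            n_cells=int(row.n_cells),
        )
        for row in grouped.itertuples()
    ]


def fold_change_analysis(
    df: pd.DataFrame, metric: str = "foci_per_cell"
) -> GroupComparison | None:
    """Normalize per experiment and compare case vs control."""
    records = normalize_to_control(line_records(df, metric))
    return compare_groups(records, metric=metric)


def rnase_reductions(df: pd.DataFrame) -> dict:
    """Percent reduction in foci per cell by group from a paired
    untreated/treated cohort table (condition column set)."""
    out = {}
    for group in ("control", "case"):
        sub = df[df["group"] == group]
        means = {}
        for cond in ("untreated", "treated"):
            c = sub[sub["condition"] == cond]
            means[cond] = c["foci_count"].sum() / c["n_cells"].sum()
        out[group] = {
            "untreated_foci_per_cell": means["untreated"],
            "treated_foci_per_cell": means["treated"],
            "reduction_pct": percent_reduction(means["untreated"], means["treated"]),
        }
    return out
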