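"""Percent exon inclusion (PSI) from band densitometry and its group
analysis.

Each RT-PCR lane yields two band intensities, inclusion and exclusion;
PSI = 100 * incl / (incl + excl).  Per-patient means over replicates are
compared between groups per exon with an unpaired t-test.  For the
significant exons, each case patient's mean PSI across the exon set
orders the patients by splicing severity, and each gene's PSI is
regressed on that per-patient mean; genes coupled to overall severity
show positive slopes, anti-coupled genes negative slopes.  Severity can
also be correlated (Spearman) with disease duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import QuadfociError, logger
from .stats import significance_stars


@dataclass
class GeneRegression:
    gene: str
    slope: float
    intercept: float
    slope_sign: int
    r_squared: float


def compute_psi(
    incl_intensity: float,
    excl_intensity: float,
    incl_label_sites: int | None = None,
    excl_label_sites: int | None = None,
) -> float:
    """PSI (%) from an inclusion/exclusion band pair.

    When labeled-nucleotide counts are given, each intensity is first
    divided by its product's count (label incorporation scales with the
    number of labeled positions); by default raw intensities are used.
    """
    if incl_intensity < 0 or excl_intensity < 0:
        raise QuadfociError("band intensities must be nonnegative")
    if incl_intensity + excl_intensity == 0:
        raise QuadfociError("unquantifiable lane: both band intensities are zero")
    if (incl_label_sites is None) != (excl_label_sites is None):
        raise QuadfociError("label-site correction needs counts for both products")
    if incl_label_sites is not None:
        incl_intensity = incl_intensity / incl_label_sites
        excl_intensity = excl_intensity / excl_label_sites
    return 100.0 * incl_intensity / (incl_intensity + excl_intensity)


def psi_table(bands: pd.DataFrame, exclude: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-lane PSI from a bands table (columns per the 'bands' schema).

    Lanes with both intensities zero are dropped with a log message.
    ``exclude`` optionally lists (sample, gene, replicate) artifact lanes
    to omit.
    """
    df = bands.copy()
    if exclude is not None and len(exclude):
        key = ["sample", "gene", "replicate"]
        merged = df.merge(exclude[key].assign(_drop=True), on=key, how="left")
        df = df[merged["_drop"].isna().to_numpy()]
    total = df["incl_intensity"] + df["excl_intensity"]
    bad = total == 0
    if bad.any():
        logger.warning("dropping %d unquantifiable lanes (both bands zero)", bad.sum())
        df = df[~bad]
        total = total[~bad]
    df = df.assign(psi=100.0 * df["incl_intensity"] / total)
    return df


def patient_means(psi_df: pd.DataFrame) -> pd.DataFrame:
    """Mean PSI per sample x gene over replicates."""
    out = (
        psi_df.groupby(["sample", "group", "gene"], as_index=False)
        .agg(psi=("psi", "mean"), n_replicates=("psi", "size"))
    )
    return out


def compare_exons(
    means: pd.DataFrame, alpha: float = 0.05, equal_var: bool = True
) -> pd.DataFrame:
    """Per-exon unpaired t-test of case vs control patient means.

    Exons with fewer than two patients in either group are skipped.
    Single-isoform exons (all PSI 0 or all 100 in both groups, zero
    variance and equal means) come out non-significant by construction
    but should be excluded upstream when known.
    """
    rows = []
    for gene, sub in means.groupby("gene"):
        case = sub.loc[sub["group"] == "case", "psi"].to_numpy()
        ctrl = sub.loc[sub["group"] == "control", "psi"].to_numpy()
        if len(case) < 2 or len(ctrl) < 2:
            logger.warning("exon %s skipped: <2 patients in a group", gene)
            continue
        t, p = sps.ttest_ind(case, ctrl, equal_var=equal_var)
        rows.append(
            {
                "gene": gene,
                "n_case": len(case),
                "n_control": len(ctrl),
                "mean_case": case.mean(),
                "mean_control": ctrl.mean(),
                "delta_psi": case.mean() - ctrl.mean(),
                "t_statistic": float(t),
                "p_value": float(p),
                "significant": bool(p < alpha),
                "stars": significance_stars(float(p)),
            }
        )
    return pd.DataFrame(rows)


def severity_regression(
    means: pd.DataFrame, genes: list[str] | None = None
) -> tuple[list[GeneRegression], pd.DataFrame]:
    """Per-gene OLS of PSI against the per-patient mean PSI (case samples).

    x is each case patient's unweighted mean PSI over the gene set; the
    returned patient table is ordered from lowest to highest mean
    inclusion (most to least severe).  Genes missing a value for any
    patient are dropped with a warning.
    """
    case = means[means["group"] == "case"]
    if genes is None:
        genes = sorted(case["gene"].unique())
    wide = case.pivot_table(index="sample", columns="gene", values="psi")
    wide = wide.reindex(columns=genes)
    complete = [g for g in genes if g in wide and not wide[g].isna().any()]
    for g in genes:
        if g not in complete:
            logger.warning("gene %s dropped from regression: missing patient values", g)
    if len(wide) < 3:
        raise QuadfociError("severity regression needs >=3 case patients")
    x = wide[complete].mean(axis=1)
    order = x.sort_values().index
    patients = pd.DataFrame(
        {"sample": order, "mean_psi": x.loc[order].to_numpy()}
    ).reset_index(drop=True)
    regs = []
    for g in complete:
        fit = sps.linregress(x.to_numpy(), wide[g].to_numpy())
        regs.append(
            GeneRegression(
                gene=g,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                slope_sign=int(np.sign(fit.slope)),
                r_squared=float(fit.rvalue**2),
            )
        )
    return regs, patients


def duration_correlation(
    patients: pd.DataFrame, metadata: pd.DataFrame
) -> tuple[float, float]:
    """Spearman correlation of per-patient mean PSI with disease duration.

    ``patients`` comes from severity_regression; ``metadata`` supplies
    disease_duration_months per sample.  Missing durations are excluded;
    ties use mid-ranks (scipy default).
    """
    merged = patients.merge(
        metadata[["sample", "disease_duration_months"]], on="sample", how="left"
    ).dropna(subset=["disease_duration_months"])
    if len(merged) < 3:
        raise QuadfociError("duration correlation needs >=3 patients with durations")
    rho, p = sps.spearmanr(
        merged["mean_psi"].to_numpy(),
        merged["disease_duration_months"].to_numpy(),
    )
    return float(rho), float(p)
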