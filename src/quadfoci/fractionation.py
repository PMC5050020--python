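"""Sarkosyl-fractionation insolubility, co-IP quantification, and
gel-shift binding-curve fitting.

Percent insoluble protein is the sarkosyl-insoluble band intensity over
the sum of all three fractions, which cancels per-sample loading
differences.  Co-IP signals may be background-corrected by subtracting a
matched beads-alone lane.  Gel-shift titrations are fit to the one-site
specific-binding model f = Bmax * P / (Kd + P), valid because the probe
concentration (0.3 nM) is far below the Kd, so free protein ~ total
protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit

from .io import QuadfociError, logger
from .stats import significance_stars


def percent_insoluble(
    soluble: float, sarkosyl_soluble: float, sarkosyl_insoluble: float
) -> float:
    """Percentage of protein in the sarkosyl-insoluble fraction."""
    total = soluble + sarkosyl_soluble + sarkosyl_insoluble
    if total <= 0:
        raise QuadfociError("unquantifiable replicate: fraction intensities sum to 0")
    return 100.0 * sarkosyl_insoluble / total


def insolubility_summary(fractions: pd.DataFrame, equal_var: bool = True) -> dict:
    """Per-sample mean percent insoluble, group means, ratio and t-test.

    ``fractions`` follows the 'fractions' schema; replicates are averaged
    per sample before the group comparison.
    """
    df = fractions.copy()
    total = df["soluble"] + df["sarkosyl_soluble"] + df["sarkosyl_insoluble"]
    bad = total <= 0
    if bad.any():
        logger.warning("dropping %d unquantifiable fraction replicates", bad.sum())
        df, total = df[~bad], total[~bad]
    df = df.assign(pct_insoluble=100.0 * df["sarkosyl_insoluble"] / total)
    per_sample = (
        df.groupby(["sample", "group"], as_index=False)["pct_insoluble"].mean()
    )
    case = per_sample.loc[per_sample["group"] == "case", "pct_insoluble"].to_numpy()
    ctrl = per_sample.loc[per_sample["group"] == "control", "pct_insoluble"].to_numpy()
    result = {
        "per_sample": per_sample,
        "mean_case": float(case.mean()) if len(case) else float("nan"),
        "mean_control": float(ctrl.mean()) if len(ctrl) else float("nan"),
    }
    result["ratio"] = result["mean_case"] / result["mean_control"]
    if len(case) >= 2 and len(ctrl) >= 2:
        t, p = sps.ttest_ind(case, ctrl, equal_var=equal_var)
        result.update(t_statistic=float(t), p_value=float(p), stars=significance_stars(p))
    return result


def coip_quant(
    ip: pd.DataFrame, beads_only: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, float]:
    """Background-corrected co-IP values and the case:control group ratio.

    ``ip`` needs columns sample, group, replicate, signal; ``beads_only``
    (optional) the same, matched by sample and replicate.  Corrected
    values below zero are floored at 0 and logged.  The ratio is over
    per-sample replicate means.
    """
    df = ip.copy()
    if beads_only is not None:
        merged = df.merge(
            beads_only[["sample", "replicate", "signal"]],
            on=["sample", "replicate"],
            how="left",
            suffixes=("", "_bg"),
        )
        if merged["signal_bg"].isna().any():
            raise QuadfociError("beads-only background missing for some sample lanes")
        corrected = merged["signal"] - merged["signal_bg"]
        n_neg = int((corrected < 0).sum())
        if n_neg:
            logger.warning("%d co-IP values negative after subtraction; floored to 0", n_neg)
        df = merged.assign(value=corrected.clip(lower=0))
    else:
        df = df.assign(value=df["signal"])
    per_sample = df.groupby(["sample", "group"], as_index=False)["value"].mean()
    case = per_sample.loc[per_sample["group"] == "case", "value"].to_numpy()
    ctrl = per_sample.loc[per_sample["group"] == "control", "value"].to_numpy()
    if not len(case) or not len(ctrl) or ctrl.mean() == 0:
        raise QuadfociError("co-IP group ratio undefined")
    return per_sample, float(case.mean() / ctrl.mean())


def fraction_bound(bound_intensity, free_intensity):
    """Fraction of probe shifted: bound / (bound + free).

    Supershifted multimeric complexes should be summed into
    ``bound_intensity`` before calling.
    """
    bound = np.asarray(bound_intensity, dtype=float)
    free = np.asarray(free_intensity, dtype=float)
    total = bound + free
    if np.any(total <= 0):
        raise QuadfociError("lane with zero total intensity")
    return bound / total


@dataclass
class BindingFit:
    kd_nM: float
    bmax: float
    kd_se: float
    bmax_se: float
    rss: float
    converged: bool


def _one_site(p, kd, bmax):
    return bmax * p / (kd + p)


def fit_binding_curve(
    protein_conc_nM, frac_bound, n_restarts: int = 5, restart_seed: int = 0
) -> BindingFit:
    """Nonlinear least-squares fit of the one-site binding model.

    Bmax is free (gels rarely shift to completion).  Initialization: Kd0
    is the concentration nearest half the maximal observed fraction
    bound, Bmax0 the maximum observed; on failure up to ``n_restarts``
    jittered restarts are tried with a fixed seed.  Non-convergence is
    reported via the flag with NaN parameters.
    """
    p = np.asarray(protein_conc_nM, dtype=float)
    f = np.asarray(frac_bound, dtype=float)
    if len(np.unique(p)) < 4:
        raise QuadfociError("binding fit needs >=4 distinct concentrations")
    fmax = f.max()
    if fmax <= 0:
        raise QuadfociError("no binding signal: all fractions bound are 0")
    half_idx = np.argmin(np.abs(f - fmax / 2))
    kd0 = max(float(p[half_idx]), 1e-3)
    bmax0 = float(fmax)
    rng = np.random.default_rng(restart_seed)
    starts = [(kd0, bmax0)] + [
        (kd0 * rng.uniform(0.2, 5.0), bmax0 * rng.uniform(0.5, 1.2))
        for _ in range(n_restarts)
    ]
    for start in starts:
        try:
            popt, pcov = curve_fit(
                _one_site,
                p,
                f,
                p0=start,
                bounds=([1e-6, 1e-6], [np.inf, 1.5]),
                maxfev=10000,
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except RuntimeError:
            continue
        resid = f - _one_site(p, *popt)
        se = np.sqrt(np.diag(pcov))
        return BindingFit(
            kd_nM=float(popt[0]),
            bmax=float(popt[1]),
            kd_se=float(se[0]),
            bmax_se=float(se[1]),
            rss=float(resid @ resid),
            converged=True,
        )
    logger.warning("binding fit failed to converge after %d restarts", n_restarts)
    return BindingFit(
        kd_nM=float("nan"),
        bmax=float("nan"),
        kd_se=float("nan"),
        bmax_se=float("nan"),
        rss=float("nan"),
        converged=False,
    )


def fit_binding_table(binding: pd.DataFrame) -> dict[str, BindingFit]:
    """Fit each titration series in a 'binding'-schema table."""
    out = {}
    for series, sub in binding.groupby("series"):
        f = fraction_bound(sub["bound_intensity"], sub["free_intensity"])
        out[str(series)] = fit_binding_curve(sub["protein_conc_nM"], f)
    return out
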