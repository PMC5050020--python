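import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadfoci.io import QuadfociError
from quadfoci.psi import (
    compare_exons,
    compute_psi,
    duration_correlation,
    patient_means,
    psi_table,
    severity_regression,
)
from quadfoci.simulate import generate_duration_metadata, generate_psi_table


def test_compute_psi_basic():
    assert compute_psi(75, 25) == 75.0
    assert compute_psi(0, 40) == 0.0
    assert compute_psi(40, 0) == 100.0


def test_compute_psi_both_zero_unquantifiable():
    with pytest.raises(QuadfociError, match="unquantifiable"):
        compute_psi(0, 0)


def test_compute_psi_label_site_correction():
    # equal molar products, inclusion product has twice the labeled sites
    assert compute_psi(100, 50, incl_label_sites=20, excl_label_sites=10) == 50.0
    with pytest.raises(QuadfociError):
        compute_psi(10, 10, incl_label_sites=5)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    incl=st.floats(0.01, 1e5),
    excl=st.floats(0.01, 1e5),
    scale=st.floats(1e-3, 1e3),
)
def test_psi_invariant_to_lane_rescaling(incl, excl, scale):
    assert compute_psi(incl * scale, excl * scale) == pytest.approx(
        compute_psi(incl, excl), rel=1e-9
    )


def test_psi_table_drops_unquantifiable_lanes():
    bands = pd.DataFrame(
        {
            "sample": ["P1", "P1"],
            "group": ["case", "case"],
            "gene": ["G1", "G1"],
            "replicate": [1, 2],
            "incl_intensity": [60.0, 0.0],
            "excl_intensity": [40.0, 0.0],
        }
    )
    out = psi_table(bands)
    assert len(out) == 1
    assert out["psi"].iloc[0] == 60.0


def test_psi_table_exclusion_list():
    bands = pd.DataFrame(
        {
            "sample": ["P1"] * 3,
            "group": ["case"] * 3,
            "gene": ["G1"] * 3,
            "replicate": [1, 2, 3],
            "incl_intensity": [60.0, 10.0, 55.0],
            "excl_intensity": [40.0, 90.0, 45.0],
        }
    )
    exclude = pd.DataFrame({"sample": ["P1"], "gene": ["G1"], "replicate": [2]})
    means = patient_means(psi_table(bands, exclude=exclude))
    assert means["n_replicates"].iloc[0] == 2
    assert means["psi"].iloc[0] == pytest.approx(57.5)


def test_noiseless_bands_recover_truth_exactly():
    true_psi = {"G1": (70.0, 45.0), "G2": (20.0, 35.0)}
    bands, truth = generate_psi_table(true_psi, noise_sd=0.0, severity_sd=0.0, seed=0)
    means = patient_means(psi_table(bands))
    merged = means.merge(truth, on=["sample", "group", "gene"])
    np.testing.assert_allclose(merged["psi"], merged["true_psi"], rtol=1e-9)


def test_patient_mean_recovery_under_noise():
    errs = []
    for seed in range(100):
        bands, _ = generate_psi_table(
            {"G1": (62.0, 62.0)}, n_patients=(1, 0), n_replicates=4,
            noise_sd=0.03, seed=seed,
        )
        means = patient_means(psi_table(bands))
        errs.append(abs(means["psi"].iloc[0] - 62.0))
    assert max(errs) < 3.0


def test_compare_exons_null_and_forced():
    rng = np.random.default_rng(0)
    rows = []
    for g, shift in (("NULL", 0.0), ("SHIFT", 30.0)):
        for grp, n, base in (("control", 7, 50.0), ("case", 7, 50.0)):
            for i in range(n):
                psi = base + (shift if grp == "case" else 0) + rng.normal(0, 2)
                rows.append({"sample": f"{grp}{i}", "group": grp, "gene": g, "psi": psi})
    out = compare_exons(pd.DataFrame(rows))
    by_gene = out.set_index("gene")
    assert bool(by_gene.loc["SHIFT", "significant"])
    assert not bool(by_gene.loc["NULL", "significant"])


def test_exon_detection_and_false_positive_rates():
    """12 shifted exons (10 PSI points, sd 3) and 6 nulls, 7 vs 7 patients."""
    detected, false_pos = [], []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(18):
            shift = 10.0 if g < 12 else 0.0
            for grp, base in (("control", 50.0), ("case", 50.0 + shift)):
                for i in range(7):
                    rows.append(
                        {
                            "sample": f"{grp}{i}",
                            "group": grp,
                            "gene": f"G{g}",
                            "psi": base + rng.normal(0, 3),
                        }
                    )
        out = compare_exons(pd.DataFrame(rows)).set_index("gene")
        detected.append(sum(out.loc[f"G{g}", "significant"] for g in range(12)))
        false_pos.append(sum(out.loc[f"G{g}", "significant"] for g in range(12, 18)))
    assert np.mean(detected) >= 11
    assert np.mean(false_pos) <= 1


def _means_frame(values: dict[str, dict[str, float]]) -> pd.DataFrame:
    rows = [
        {"sample": s, "group": "case", "gene": g, "psi": v}
        for s, genes in values.items()
        for g, v in genes.items()
    ]
    return pd.DataFrame(rows)


def test_regression_identity_slope_one():
    # every gene equals the patient mean -> slope 1, r^2 1
    values = {f"P{i}": {f"G{j}": 30.0 + 5 * i for j in range(4)} for i in range(5)}
    regs, patients = severity_regression(_means_frame(values))
    assert all(r.slope == pytest.approx(1.0) for r in regs)
    assert all(r.r_squared == pytest.approx(1.0) for r in regs)
    assert patients["mean_psi"].is_monotonic_increasing


def test_regression_anti_correlated_gene_negative_slope():
    values = {}
    for i in range(5):
        tracking = 30.0 + 5 * i
        values[f"P{i}"] = {"G1": tracking, "G2": tracking, "G3": 100.0 - tracking}
    regs, _ = severity_regression(_means_frame(values))
    signs = {r.gene: r.slope_sign for r in regs}
    assert signs["G1"] == 1 and signs["G2"] == 1 and signs["G3"] == -1


def test_mean_of_slopes_is_one_on_complete_data():
    # x is the unweighted mean of the same genes, so slopes average to 1
    rng = np.random.default_rng(3)
    values = {
        f"P{i}": {f"G{j}": rng.uniform(20, 80) for j in range(6)} for i in range(7)
    }
    regs, _ = severity_regression(_means_frame(values))
    assert np.mean([r.slope for r in regs]) == pytest.approx(1.0, abs=1e-9)


def test_slope_sign_recovery_synthetic_cohort():
    """14 positively and 4 negatively severity-coupled genes: all slope
    signs recovered in every one of 50 seeded cohorts."""
    true_psi = {f"POS{i}": (70.0, 50.0) for i in range(14)}
    true_psi.update({f"NEG{i}": (30.0, 50.0) for i in range(4)})
    coupling = {f"POS{i}": 1.0 + 0.1 * i for i in range(14)}
    coupling.update({f"NEG{i}": -(1.0 + 0.2 * i) for i in range(4)})
    for seed in range(50):
        bands, _ = generate_psi_table(true_psi, coupling, seed=seed)
        means = patient_means(psi_table(bands))
        regs, _ = severity_regression(means, sorted(true_psi))
        for r in regs:
            assert (r.slope_sign > 0) == (coupling[r.gene] > 0), (seed, r.gene)


def test_duration_correlation_monotone_cases():
    patients = pd.DataFrame({"sample": list("ABCD"), "mean_psi": [10, 20, 30, 40.0]})
    meta = pd.DataFrame(
        {"sample": list("ABCD"), "disease_duration_months": [5, 10, 20, 40.0]}
    )
    rho, _ = duration_correlation(patients, meta)
    assert rho == pytest.approx(1.0)
    meta_rev = meta.assign(disease_duration_months=[40, 20, 10, 5.0])
    rho, _ = duration_correlation(patients, meta_rev)
    assert rho == pytest.approx(-1.0)


def test_duration_correlation_recovery():
    true_psi = {f"G{i}": (70.0, 50.0) for i in range(10)}
    coupling = {f"G{i}": 1.0 for i in range(10)}
    rhos = []
    for seed in range(200):
        bands, truth = generate_psi_table(true_psi, coupling, seed=seed)
        means = patient_means(psi_table(bands))
        _, patients = severity_regression(means, sorted(true_psi))
        meta = generate_duration_metadata(truth, rho=0.8, seed=seed)
        rho, _ = duration_correlation(patients, meta)
        rhos.append(rho)
    assert abs(np.mean(rhos) - 0.8) < 0.15
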