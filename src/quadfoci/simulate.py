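"""Synthetic multichannel microscopy and densitometry with known truth.

Every input the pipeline consumes can be generated here with planted
ground truth: images with elliptical DAPI nuclei surrounded by a dim
DAPI-positive cytoplasm ring, red (BG4) and green (hnRNP H) foci drawn
as disks with Poisson per-cell counts and lognormal radii, and CSV
tables of band, fraction and binding intensities.  Named presets
reproduce the effect sizes of the biological study conditions (patient
vs control foci ratios, RNAse-removable fractions, binding constants) so
that downstream stages can be scored end to end.

Foci intensities are drawn strictly above the 0.1 detection threshold,
so failures reflect the measurement algorithm rather than rendering; the
"dim" preset deliberately straddles the threshold.  All generators are
bit-reproducible for a fixed seed; per-image substreams are derived from
the run seed and the image's indices, so generation order is irrelevant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import draw

from .io import MultichannelImage, QuadfociError, logger, save_image, write_table

QUANT_LEVELS = 65535  # planes are snapped to the uint16 grid they round-trip through


@dataclass(frozen=True)
class SimImageSpec:
    """Parameters of one synthetic field of view.

    Lengths are in micrometres, intensities on the normalized [0, 1]
    scale.  ``foci_per_cell_mean`` is a Poisson rate; focus radii are
    lognormal with the given mean and coefficient of variation.
    ``coloc_fraction`` is the probability that a red focus carries a
    matching green focus (a colocalization event), placed in the
    cytoplasm ring with probability ``coloc_cyto_fraction`` and in the
    nucleus otherwise.  ``rna_removable_fraction`` marks red foci as
    RNA-dependent; when ``apply_rnase`` is set those foci are not
    rendered (simulated RNAse treatment), while the random stream is
    unchanged so treated/untreated pairs generated from the same seed
    are pixel-matched apart from the removed foci.
    """

    shape: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.15
    n_cells: int = 16
    nucleus_radius_um: tuple[float, float] = (3.1, 3.9)
    nucleus_axis_ratio: tuple[float, float] = (0.8, 1.0)
    nucleus_intensity: tuple[float, float] = (0.5, 0.9)
    cytoplasm_width_um: float = 1.8
    cytoplasm_intensity: tuple[float, float] = (0.04, 0.06)
    foci_per_cell_mean: float = 7.0
    focus_radius_um: float = 0.32
    focus_radius_cv: float = 0.15
    focus_intensity: tuple[float, float] = (0.3, 0.8)
    green_foci_per_cell_mean: float = 2.0
    green_radius_um: float = 0.40
    green_radius_cv: float = 0.15
    green_intensity: tuple[float, float] = (0.3, 0.8)
    green_large_fraction: float = 0.0
    green_large_radius_um: tuple[float, float] = (0.45, 0.8)
    coloc_fraction: float = 0.0
    coloc_radius_um: float = 0.6
    coloc_radius_cv: float = 0.10
    coloc_cyto_fraction: float = 0.0
    rna_removable_fraction: float = 0.0
    apply_rnase: bool = False
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        for name in ("coloc_fraction", "coloc_cyto_fraction", "rna_removable_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise QuadfociError(f"{name} must lie in [0, 1], got {v}")
        if self.foci_per_cell_mean < 0 or self.green_foci_per_cell_mean < 0:
            raise QuadfociError("foci rates must be nonnegative")
        if self.pixel_size_um <= 0:
            raise QuadfociError("pixel_size_um must be > 0")


@dataclass
class CellTruth:
    centroid: tuple[float, float]
    nucleus_area_px: int
    n_red_foci: int = 0
    red_area_px: int = 0
    n_green_foci: int = 0
    n_coloc_nuclear: int = 0
    n_coloc_cytoplasmic: int = 0


@dataclass
class GroundTruth:
    """Planted per-cell truth for one image, with image-level aggregates."""

    image_id: str
    cells: list[CellTruth] = field(default_factory=list)
    green_max_dims_um: list[float] = field(default_factory=list)
    n_red_removed: int = 0

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_red_foci(self) -> int:
        return sum(c.n_red_foci for c in self.cells)

    @property
    def red_area_px(self) -> int:
        return sum(c.red_area_px for c in self.cells)

    @property
    def n_green_foci(self) -> int:
        return sum(c.n_green_foci for c in self.cells)

    @property
    def n_coloc_nuclear(self) -> int:
        return sum(c.n_coloc_nuclear for c in self.cells)

    @property
    def n_coloc_cytoplasmic(self) -> int:
        return sum(c.n_coloc_cytoplasmic for c in self.cells)


# ---------------------------------------------------------------------------
# geometry helpers


def _rot(theta: float, dr: float, dc: float) -> tuple[float, float]:
    return (
        dr * math.cos(theta) - dc * math.sin(theta),
        dr * math.sin(theta) + dc * math.cos(theta),
    )


def _place_nuclei(spec: SimImageSpec, rng: np.random.Generator) -> list[dict]:
    """Rejection-sample non-overlapping nuclei (with cytoplasm clearance)."""
    px = spec.pixel_size_um
    rows, cols = spec.shape
    w_px = spec.cytoplasm_width_um / px
    cells: list[dict] = []
    for _ in range(spec.n_cells):
        a_um = rng.uniform(*spec.nucleus_radius_um)
        b_um = a_um * rng.uniform(*spec.nucleus_axis_ratio)
        a, b = a_um / px, b_um / px
        theta = rng.uniform(0, math.pi)
        placed = False
        for _try in range(3000):
            margin = a + w_px + 1
            r = rng.uniform(margin, rows - margin)
            c = rng.uniform(margin, cols - margin)
            ok = all(
                math.hypot(r - other["r"], c - other["c"])
                >= a + other["a"] + w_px + 2
                for other in cells
            )
            if ok:
                cells.append(
                    {
                        "r": r,
                        "c": c,
                        "a": a,
                        "b": b,
                        "theta": theta,
                        "intensity": rng.uniform(*spec.nucleus_intensity),
                    }
                )
                placed = True
                break
        if not placed:
            logger.warning("could not place all %d nuclei; image has %d", spec.n_cells, len(cells))
            break
    return cells


def _point_in_nucleus(cell: dict, margin: float, rng: np.random.Generator):
    u = math.sqrt(rng.uniform())
    phi = rng.uniform(0, 2 * math.pi)
    ar = max(cell["a"] - margin, 0.5)
    br = max(cell["b"] - margin, 0.5)
    dr, dc = _rot(cell["theta"], u * ar * math.cos(phi), u * br * math.sin(phi))
    return cell["r"] + dr, cell["c"] + dc


def _point_in_cytoplasm(cell: dict, w_px: float, margin: float, rng: np.random.Generator):
    phi = rng.uniform(0, 2 * math.pi)
    a, b = cell["a"], cell["b"]
    r_in = 1.0 / math.hypot(math.cos(phi) / a, math.sin(phi) / b)
    r_out = 1.0 / math.hypot(math.cos(phi) / (a + w_px), math.sin(phi) / (b + w_px))
    lo, hi = r_in + margin, r_out - margin
    if hi <= lo:  # ring too narrow for this focus; fall back to mid-ring
        d = 0.5 * (r_in + r_out)
    else:
        d = rng.uniform(lo, hi)
    dr, dc = _rot(cell["theta"], d * math.cos(phi), d * math.sin(phi))
    return cell["r"] + dr, cell["c"] + dc


def _render_disk(plane: np.ndarray, r: float, c: float, radius_px: float, intensity: float):
    rr, cc = draw.disk((r, c), radius_px, shape=plane.shape)
    plane[rr, cc] = np.maximum(plane[rr, cc], intensity)
    if len(rr) == 0:
        return 0, 0.0
    max_dim_px = max(rr.max() - rr.min() + 1, cc.max() - cc.min() + 1)
    return len(rr), float(max_dim_px)


def _lognormal_radius(mean_um: float, cv: float, rng: np.random.Generator) -> float:
    sigma = math.sqrt(math.log(1 + cv**2))
    mu = math.log(mean_um) - sigma**2 / 2
    return float(rng.lognormal(mu, sigma))


def generate_image(
    spec: SimImageSpec, seed, image_id: str = "sim"
) -> tuple[MultichannelImage, GroundTruth]:
    """Render one field of view and its planted truth.

    ``seed`` may be an int, a sequence of ints, or a Generator.
    Deterministic: the same spec and seed give bit-identical images.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    px = spec.pixel_size_um
    rows, cols = spec.shape
    red = np.zeros(spec.shape)
    green = np.zeros(spec.shape)
    blue = np.zeros(spec.shape)
    w_px = spec.cytoplasm_width_um / px

    cells = _place_nuclei(spec, rng)
    truth = GroundTruth(image_id=image_id)

    # nuclei + cytoplasm rings
    for cell in cells:
        rr, cc = draw.ellipse(
            cell["r"], cell["c"], cell["a"] + w_px, cell["b"] + w_px,
            shape=spec.shape, rotation=cell["theta"],
        )
        cyto_int = rng.uniform(*spec.cytoplasm_intensity)
        blue[rr, cc] = np.maximum(blue[rr, cc], cyto_int)
        rr, cc = draw.ellipse(
            cell["r"], cell["c"], cell["a"], cell["b"],
            shape=spec.shape, rotation=cell["theta"],
        )
        blue[rr, cc] = cell["intensity"]
        truth.cells.append(
            CellTruth(centroid=(cell["r"], cell["c"]), nucleus_area_px=len(rr))
        )

    # foci; a global exclusion list keeps all rendered disks disjoint
    placed: list[tuple[float, float, float]] = []
    n_dropped = 0

    def _try_place(sampler, radius_px: float, max_tries: int = 300):
        for _ in range(max_tries):
            r, c = sampler()
            if all(
                math.hypot(r - pr, c - pc) >= radius_px + prad + 1.5
                for pr, pc, prad in placed
            ):
                placed.append((r, c, radius_px))
                return r, c
        return None

    for idx, cell in enumerate(cells):
        ct = truth.cells[idx]
        n_red = rng.poisson(spec.foci_per_cell_mean)
        for _ in range(n_red):
            is_coloc = rng.uniform() < spec.coloc_fraction
            removable = rng.uniform() < spec.rna_removable_fraction
            if is_coloc:
                radius_um = _lognormal_radius(spec.coloc_radius_um, spec.coloc_radius_cv, rng)
                in_cyto = rng.uniform() < spec.coloc_cyto_fraction
            else:
                radius_um = _lognormal_radius(spec.focus_radius_um, spec.focus_radius_cv, rng)
                in_cyto = False
            radius_px = max(radius_um / px, 1.0)
            intensity = rng.uniform(*spec.focus_intensity)
            green_int = rng.uniform(*spec.green_intensity)
            if in_cyto:
                sampler = lambda: _point_in_cytoplasm(cell, w_px, radius_px + 1, rng)  # noqa: B023
            else:
                sampler = lambda: _point_in_nucleus(cell, radius_px + 1, rng)  # noqa: B023
            pos = _try_place(sampler, radius_px)
            if pos is None:
                n_dropped += 1
                continue
            if spec.apply_rnase and removable:
                truth.n_red_removed += 1
                continue
            area, _dim = _render_disk(red, pos[0], pos[1], radius_px, intensity)
            ct.n_red_foci += 1
            ct.red_area_px += area
            if is_coloc:
                dim_px = _render_disk(green, pos[0], pos[1], radius_px, green_int)[1]
                ct.n_green_foci += 1
                truth.green_max_dims_um.append(dim_px * px)
                if in_cyto:
                    ct.n_coloc_cytoplasmic += 1
                else:
                    ct.n_coloc_nuclear += 1

        n_green = rng.poisson(spec.green_foci_per_cell_mean)
        for _ in range(n_green):
            if rng.uniform() < spec.green_large_fraction:
                radius_um = rng.uniform(*spec.green_large_radius_um)
            else:
                radius_um = _lognormal_radius(spec.green_radius_um, spec.green_radius_cv, rng)
            radius_px = max(radius_um / px, 1.0)
            intensity = rng.uniform(*spec.green_intensity)
            pos = _try_place(lambda: _point_in_nucleus(cell, radius_px + 1, rng), radius_px)  # noqa: B023
            if pos is None:
                continue
            dim_px = _render_disk(green, pos[0], pos[1], radius_px, intensity)[1]
            ct.n_green_foci += 1
            truth.green_max_dims_um.append(dim_px * px)

    if n_dropped:
        logger.warning(
            "%s: %d foci dropped (overlap budget exceeded); truth reflects placed objects",
            image_id, n_dropped,
        )
    # background noise, clipped, snapped to the uint16 grid for exact
    # write/read round trips
    planes = []
    for plane in (red, green, blue):
        noisy = plane + rng.normal(0, spec.noise_sd, size=spec.shape)
        np.clip(noisy, 0, 1, out=noisy)
        planes.append(np.round(noisy * QUANT_LEVELS) / QUANT_LEVELS)

    image = MultichannelImage(
        red=planes[0], green=planes[1], blue=planes[2],
        pixel_size_um=px, source_id=image_id,
    )
    return image, truth


# ---------------------------------------------------------------------------
# cohort presets

#: Preset parameters.  Ratios are the planted case:control effect sizes;
#: the case focus radius is scaled by sqrt(area_ratio / rate_ratio) so that
#: both the per-cell count ratio and the per-cell stained-area ratio hold.
PRESETS: dict[str, dict] = {
    "fibroblast": dict(
        n_case_lines=7, n_control_lines=5, n_experiments=4, images_per_line=7,
        rate_ratio=1.8, area_ratio=2.8,
        spec=SimImageSpec(),
    ),
    "astrocyte": dict(
        n_case_lines=1, n_control_lines=1, n_experiments=3, images_per_line=7,
        rate_ratio=2.0, area_ratio=2.3,
        spec=SimImageSpec(
            n_cells=12,
            nucleus_radius_um=(3.8, 4.8),
            foci_per_cell_mean=12.0,
            focus_radius_um=0.30,
        ),
    ),
    "rnase": dict(
        n_case_lines=1, n_control_lines=1, n_experiments=1, images_per_line=8,
        rate_ratio=2.7, area_ratio=2.7,
        removable_control=0.27, removable_case=0.76,
        spec=SimImageSpec(
            n_cells=12,
            nucleus_radius_um=(4.0, 5.0),
            foci_per_cell_mean=20.0,
            focus_radius_um=0.22,
            focus_radius_cv=0.12,
        ),
    ),
    "mn": dict(
        # motor-neuron-like sections: green foci only, a subset large
        n_case_lines=1, n_control_lines=1, n_experiments=1, images_per_line=4,
        rate_ratio=1.0, area_ratio=1.0,
        spec=SimImageSpec(
            n_cells=10,
            nucleus_radius_um=(4.0, 5.0),
            foci_per_cell_mean=0.0,
            green_foci_per_cell_mean=6.0,
            green_large_fraction=0.4,
        ),
    ),
    "blank": dict(
        n_case_lines=1, n_control_lines=1, n_experiments=1, images_per_line=1,
        rate_ratio=1.0, area_ratio=1.0,
        spec=SimImageSpec(foci_per_cell_mean=0.0, green_foci_per_cell_mean=0.0),
    ),
    "dim": dict(
        # stress preset: red intensities straddle the 0.1 threshold
        n_case_lines=1, n_control_lines=1, n_experiments=1, images_per_line=2,
        rate_ratio=1.0, area_ratio=1.0,
        spec=SimImageSpec(focus_intensity=(0.05, 0.2)),
    ),
}

#: One-site binding presets: (true Kd in nM, max concentration in nM)
BINDING_PRESETS: dict[str, tuple[float, float]] = {
    "4R": (75.5, 640.0),
    "4R-7dG": (13.5, 160.0),
}


@dataclass
class CohortEntry:
    experiment_id: str
    line_id: str
    group: str  # control | case
    condition: str  # "" or untreated/treated
    image: MultichannelImage
    truth: GroundTruth


def _case_spec(spec: SimImageSpec, preset: dict, rate_factor: float) -> SimImageSpec:
    radius_factor = math.sqrt(preset["area_ratio"] / preset["rate_ratio"])
    return replace(
        spec,
        foci_per_cell_mean=spec.foci_per_cell_mean * preset["rate_ratio"] * rate_factor,
        focus_radius_um=spec.focus_radius_um * radius_factor,
    )


def generate_cohort(
    preset_name: str,
    seed: int,
    n_experiments: int | None = None,
    images_per_line: int | None = None,
    line_rate_cv: float = 0.05,
    **spec_overrides,
) -> list[CohortEntry]:
    """Generate a full multi-experiment cohort in memory.

    Each (experiment, line) draws a lognormal biological rate factor
    with coefficient of variation ``line_rate_cv``, emulating
    line-to-line and staining-batch variability around the planted group
    means.  For the "rnase" preset each image is emitted twice, as a
    pixel-matched untreated/treated pair.
    """
    if preset_name not in PRESETS:
        raise QuadfociError(
            f"unknown preset {preset_name!r}; available: {sorted(PRESETS)}"
        )
    preset = PRESETS[preset_name]
    base_spec: SimImageSpec = preset["spec"]
    if spec_overrides:
        base_spec = replace(base_spec, **spec_overrides)
    n_exp = n_experiments or preset["n_experiments"]
    n_img = images_per_line or preset["images_per_line"]
    lines = [("case", f"C9-{i+1}") for i in range(preset["n_case_lines"])] + [
        ("control", f"CTRL-{i+1}") for i in range(preset["n_control_lines"])
    ]
    sigma = math.sqrt(math.log(1 + line_rate_cv**2))
    entries = []
    for e in range(n_exp):
        exp_id = f"E{e+1}"
        for li, (group, line_id) in enumerate(lines):
            line_rng = np.random.default_rng([seed, e, li])
            rate_factor = float(line_rng.lognormal(-sigma**2 / 2, sigma))
            spec = base_spec
            if group == "case":
                spec = _case_spec(base_spec, preset, rate_factor)
                removable = preset.get("removable_case", 0.0)
            else:
                spec = replace(
                    base_spec,
                    foci_per_cell_mean=base_spec.foci_per_cell_mean * rate_factor,
                )
                removable = preset.get("removable_control", 0.0)
            for i in range(n_img):
                image_id = f"{exp_id}_{line_id}_im{i+1}"
                if preset_name == "rnase":
                    for condition, apply in (("untreated", False), ("treated", True)):
                        s = replace(
                            spec,
                            rna_removable_fraction=removable,
                            apply_rnase=apply,
                        )
                        img, truth = generate_image(
                            s, [seed, e, li, i], f"{image_id}_{condition}"
                        )
                        entries.append(
                            CohortEntry(exp_id, line_id, group, condition, img, truth)
                        )
                else:
                    img, truth = generate_image(spec, [seed, e, li, i], image_id)
                    entries.append(CohortEntry(exp_id, line_id, group, "", img, truth))
    return entries


def generate_experiment(
    preset_name: str,
    out_dir,
    seed: int,
    n_experiments: int | None = None,
    images_per_line: int | None = None,
    **spec_overrides,
) -> list[CohortEntry]:
    """Generate a cohort and write it as TIFFs plus CSV tables.

    Emits ``<image_id>.tif`` per image, ``cells.csv`` (planted cell
    counts), ``design.csv`` (image -> experiment/line/group) and
    ``truth.csv`` (per-image planted truth).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = generate_cohort(
        preset_name, seed, n_experiments, images_per_line, **spec_overrides
    )
    cells_rows, design_rows, truth_rows = [], [], []
    for ent in entries:
        save_image(ent.image, out / f"{ent.truth.image_id}.tif")
        cells_rows.append({"image_id": ent.truth.image_id, "cell_count": ent.truth.n_cells})
        design_rows.append(
            {
                "image_id": ent.truth.image_id,
                "experiment": ent.experiment_id,
                "line": ent.line_id,
                "group": ent.group,
            }
        )
        truth_rows.append(
            {
                "image_id": ent.truth.image_id,
                "n_cells": ent.truth.n_cells,
                "n_red_foci": ent.truth.n_red_foci,
                "red_area_px": ent.truth.red_area_px,
                "n_green_foci": ent.truth.n_green_foci,
                "n_coloc_nuclear": ent.truth.n_coloc_nuclear,
                "n_coloc_cytoplasmic": ent.truth.n_coloc_cytoplasmic,
            }
        )
    write_table(pd.DataFrame(cells_rows), out / "cells.csv")
    write_table(pd.DataFrame(design_rows), out / "design.csv")
    write_table(pd.DataFrame(truth_rows), out / "truth.csv")
    return entries


# ---------------------------------------------------------------------------
# tabular generators


def generate_psi_table(
    true_psi: dict[str, tuple[float, float]],
    coupling: dict[str, float] | None = None,
    n_patients: tuple[int, int] = (7, 7),
    n_replicates: int = 4,
    noise_sd: float = 0.03,
    severity_sd: float = 5.0,
    seed: int = 0,
):
    """Band-intensity table from planted per-gene PSI.

    ``true_psi`` maps gene -> (control PSI, case PSI).  ``coupling``
    (gene -> coefficient) adds a shared per-patient severity term to case
    patients: PSI_gi = case_mean_g + coupling_g * s_i with s_i ~
    N(0, severity_sd); positive coefficients couple the gene to overall
    severity, negative ones anti-couple it.  Band intensities are
    (psi, 100 - psi) scaled by a random lane loading factor with
    multiplicative noise of log-sd ``noise_sd``.

    Returns (bands DataFrame in the 'bands' schema, truth DataFrame with
    per sample x gene true PSI and the per-patient severity).
    """
    rng = np.random.default_rng(seed)
    coupling = coupling or {}
    n_ctrl, n_case = n_patients
    samples = [("control", f"CTRL-{i+1}", 0.0) for i in range(n_ctrl)]
    severities = rng.normal(0, severity_sd, size=n_case)
    samples += [("case", f"C9-{i+1}", float(severities[i])) for i in range(n_case)]
    band_rows, truth_rows = [], []
    for group, sample, s in samples:
        for gene, (psi_ctrl, psi_case) in true_psi.items():
            if group == "control":
                psi = psi_ctrl
            else:
                psi = psi_case + coupling.get(gene, 0.0) * s
            psi = float(np.clip(psi, 0.5, 99.5))
            truth_rows.append(
                {"sample": sample, "group": group, "gene": gene,
                 "true_psi": psi, "severity": s}
            )
            for rep in range(1, n_replicates + 1):
                lane = rng.lognormal(0, 0.2)
                incl = lane * psi * rng.lognormal(0, noise_sd)
                excl = lane * (100 - psi) * rng.lognormal(0, noise_sd)
                band_rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "gene": gene,
                        "replicate": rep,
                        "incl_intensity": incl,
                        "excl_intensity": excl,
                    }
                )
    return pd.DataFrame(band_rows), pd.DataFrame(truth_rows)


def generate_duration_metadata(
    truth: pd.DataFrame, rho: float = 0.8, duration_mean: float = 36.0,
    duration_sd: float = 12.0, seed: int = 0
) -> pd.DataFrame:
    """Disease durations correlated with per-patient severity.

    Patients with lower mean inclusion (more severe missplicing) get
    shorter durations: duration is drawn with target correlation ``rho``
    against the patient's mean true PSI.
    """
    # distinct substream: the same run seed is typically shared with
    # generate_psi_table, whose first draws must not reappear here
    rng = np.random.default_rng([seed, 104729])
    per_patient = (
        truth[truth["group"] == "case"]
        .groupby("sample", as_index=False)["true_psi"].mean()
    )
    x = per_patient["true_psi"].to_numpy()
    z = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    noise = rng.normal(size=len(z))
    y = rho * z + math.sqrt(max(1 - rho**2, 0)) * noise
    durations = duration_mean + duration_sd * y
    rows = [
        {"sample": s, "group": "case",
         "disease_duration_months": float(max(d, 1.0))}
        for s, d in zip(per_patient["sample"], durations)
    ]
    return pd.DataFrame(rows)


def generate_fraction_table(
    group_means: tuple[float, float] = (30.0, 56.1),
    n_per_group: int = 7,
    n_replicates: int = 2,
    between_sd: float = 8.0,
    replicate_sd: float = 3.0,
    seed: int = 0,
):
    """Three-fraction densitometry table with planted percent insoluble.

    ``group_means`` are (control, case) mean percent insoluble.  Each
    sample's true percentage varies around its group mean with
    ``between_sd``; replicates add ``replicate_sd``.  Loading differs
    per replicate by a lognormal factor, which percent-insoluble must
    cancel.  Setting both sds to 0 reproduces the group means exactly.
    """
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for group, mean, prefix in (
        ("control", group_means[0], "CTRL"),
        ("case", group_means[1], "C9"),
    ):
        for i in range(n_per_group):
            sample = f"{prefix}-{i+1}"
            true_pct = float(np.clip(rng.normal(mean, between_sd), 1, 99))
            if between_sd == 0:
                true_pct = mean
            truth_rows.append({"sample": sample, "group": group, "true_pct_insoluble": true_pct})
            for rep in range(1, n_replicates + 1):
                pct = float(np.clip(rng.normal(true_pct, replicate_sd), 0.5, 99.5))
                if replicate_sd == 0:
                    pct = true_pct
                loading = rng.lognormal(0, 0.3)
                insol = loading * pct
                rest = loading * (100 - pct)
                rows.append(
                    {
                        "sample": sample,
                        "group": group,
                        "replicate": rep,
                        "soluble": rest * 0.8,
                        "sarkosyl_soluble": rest * 0.2,
                        "sarkosyl_insoluble": insol,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def generate_binding_data(
    preset: str = "4R",
    bmax: float = 0.95,
    noise_sd: float = 0.03,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Gel-shift titration table for a named RNA preset.

    Concentrations follow a 2-fold dilution series up to the preset's
    maximum (plus a zero-protein lane), as in a 0-640 nM titration.
    Fraction bound follows the one-site model with the preset's true Kd
    plus Gaussian noise; intensities are reported as bound/free pairs
    under a random total lane intensity.
    """
    if preset not in BINDING_PRESETS:
        raise QuadfociError(
            f"unknown binding preset {preset!r}; available: {sorted(BINDING_PRESETS)}"
        )
    kd, cmax = BINDING_PRESETS[preset]
    rng = np.random.default_rng(seed)
    concs = [0.0]
    c = cmax
    while c > cmax / 512:
        concs.append(c)
        c /= 2
    concs = sorted(concs)
    rows = []
    for rep in range(1, n_replicates + 1):
        for p in concs:
            f_true = bmax * p / (kd + p)
            f_obs = float(np.clip(f_true + rng.normal(0, noise_sd), 0, 1))
            total = rng.lognormal(math.log(1000), 0.1)
            rows.append(
                {
                    "series": f"{preset}:rep{rep}",
                    "protein_conc_nM": p,
                    "bound_intensity": total * f_obs,
                    "free_intensity": total * (1 - f_obs),
                }
            )
    truth = {"preset": preset, "kd_nM": kd, "bmax": bmax}
    return pd.DataFrame(rows), truth
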