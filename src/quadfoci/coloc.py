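"""Red/green colocalization events and their compartment classification.

A colocalization event is a connected region where BG4 (red) and hnRNP H
(green) staining coincide above threshold.  Events are classed as nuclear
when their centroid falls inside a DAPI nucleus, cytoplasmic when it
falls in DAPI-positive cytoplasm (dim DAPI signal outside nuclei), and
unassigned otherwise.  Incidence is summarized per cell line both as
events per cell and as the fraction of cells containing at least one
event.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .foci import (
    FociObject,
    ThresholdConfig,
    _skimage_connectivity,
    label_objects,
    threshold_channel,
)
from .io import MultichannelImage, QuadfociError, logger

NUCLEAR = "nuclear"
CYTOPLASMIC = "cytoplasmic"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class ColocConfig:
    """Thresholds of the colocalization stage.

    ``min_coloc_area_um2`` suppresses single-pixel chance overlaps.
    ``cytoplasm_threshold`` is the dim-DAPI level that admits cytoplasm;
    any appreciable DAPI signal counts (hence the low default).
    ``large_focus_min_dim_um`` is the size criterion applied to foci in
    tissue sections (longest dimension at least 0.5 um).
    """

    red_threshold: float = 0.1
    green_threshold: float = 0.1
    blue_threshold: float = 0.1
    cytoplasm_threshold: float = 0.02
    min_nucleus_area_um2: float = 20.0
    min_coloc_area_um2: float = 0.25
    large_focus_min_dim_um: float = 0.5
    connectivity: int = 8


@dataclass
class ColocEvent:
    image_id: str
    area_um2: float
    centroid: tuple[float, float]
    compartment: str = UNASSIGNED
    cell_index: int | None = None  # nearest nucleus within the image


@dataclass
class ColocSummary:
    line_id: str
    n_cells: int
    n_events_nuclear: int
    n_events_cytoplasmic: int
    incidence_events_nuclear: float | None  # events / cells, %
    incidence_events_cytoplasmic: float | None
    incidence_cells_nuclear: float | None  # % of cells with >=1 event
    incidence_cells_cytoplasmic: float | None
    n_green_only_foci: int
    n_large_foci: int


def _nucleus_masks(image: MultichannelImage, config: ColocConfig):
    """Labelled nuclei (min-area filtered) and the cytoplasm mask."""
    conn = _skimage_connectivity(config.connectivity)
    blue_mask = threshold_channel(image.blue, config.blue_threshold)
    labels = measure.label(blue_mask, connectivity=conn)
    min_px = config.min_nucleus_area_um2 / image.pixel_size_um**2
    keep = [r.label for r in measure.regionprops(labels) if r.area >= min_px]
    nuclei = np.isin(labels, keep) & (labels > 0)
    labels = labels * nuclei
    cytoplasm = threshold_channel(image.blue, config.cytoplasm_threshold) & ~nuclei
    centroids = {r.label: r.centroid for r in measure.regionprops(labels)}
    return labels, cytoplasm, centroids


def detect_coloc_events(
    image: MultichannelImage, config: ColocConfig | None = None
) -> list[ColocEvent]:
    """Connected components of red AND green above their thresholds.

    Events below min_coloc_area_um2 are discarded; each surviving event
    is compartment-classified and attributed to its nearest nucleus.
    """
    config = config or ColocConfig()
    red = threshold_channel(image.red, config.red_threshold)
    green = threshold_channel(image.green, config.green_threshold)
    overlap = red & green
    objects = label_objects(overlap, config.connectivity, image.pixel_size_um)
    nuclei_labels, cytoplasm, centroids = _nucleus_masks(image, config)
    events = []
    for obj in objects:
        if obj.area_um2 < config.min_coloc_area_um2:
            continue
        ev = ColocEvent(
            image_id=image.source_id, area_um2=obj.area_um2, centroid=obj.centroid
        )
        ev.compartment = _classify(obj.centroid, nuclei_labels, cytoplasm)
        ev.cell_index = _nearest_cell(obj.centroid, nuclei_labels, centroids)
        events.append(ev)
    return events


def _classify(centroid, nuclei_labels, cytoplasm) -> str:
    r, c = (int(round(x)) for x in centroid)
    r = min(max(r, 0), nuclei_labels.shape[0] - 1)
    c = min(max(c, 0), nuclei_labels.shape[1] - 1)
    if nuclei_labels[r, c] > 0:
        return NUCLEAR
    if cytoplasm[r, c]:
        return CYTOPLASMIC
    return UNASSIGNED


def _nearest_cell(centroid, nuclei_labels, centroids) -> int | None:
    r, c = (int(round(x)) for x in centroid)
    r = min(max(r, 0), nuclei_labels.shape[0] - 1)
    c = min(max(c, 0), nuclei_labels.shape[1] - 1)
    if nuclei_labels[r, c] > 0:
        return int(nuclei_labels[r, c])
    if not centroids:
        return None
    dists = {
        lab: (cen[0] - centroid[0]) ** 2 + (cen[1] - centroid[1]) ** 2
        for lab, cen in centroids.items()
    }
    return int(min(dists, key=dists.get))


def classify_compartment(
    event: ColocEvent, image: MultichannelImage, config: ColocConfig | None = None
) -> str:
    """Compartment of a single event; used when events come from elsewhere."""
    config = config or ColocConfig()
    nuclei_labels, cytoplasm, _ = _nucleus_masks(image, config)
    return _classify(event.centroid, nuclei_labels, cytoplasm)


def detect_green_foci(
    image: MultichannelImage, config: ColocConfig | None = None
) -> tuple[list[FociObject], list[bool]]:
    """Green objects plus a parallel flag: True when the object touches red.

    Objects that never touch red staining are "green-only" foci (free
    hnRNP H puncta).
    """
    config = config or ColocConfig()
    green = threshold_channel(image.green, config.green_threshold)
    red = threshold_channel(image.red, config.red_threshold)
    conn = _skimage_connectivity(config.connectivity)
    labels = measure.label(green, connectivity=conn)
    objects = label_objects(green, config.connectivity, image.pixel_size_um)
    touched = set(np.unique(labels[red & (labels > 0)]))
    return objects, [o.label in touched for o in objects]


def filter_large_foci(
    objects: list[FociObject], min_dim_um: float = 0.5
) -> list[FociObject]:
    """Foci whose longest dimension reaches the size cutoff."""
    return [o for o in objects if o.max_dim_um >= min_dim_um]


def incidence(n_events: int, n_cells: int) -> float:
    """Events per hundred cells (%)."""
    if n_cells <= 0:
        raise QuadfociError("incidence undefined for zero cells")
    return 100.0 * n_events / n_cells


def summarize_coloc(
    events_by_image: dict[str, list[ColocEvent]],
    cell_counts: dict[str, int],
    line_of_image: dict[str, str],
    green_by_image: dict[str, tuple[list[FociObject], list[bool]]] | None = None,
    large_focus_min_dim_um: float = 0.5,
) -> dict[str, ColocSummary]:
    """Aggregate events per cell line into both incidence metrics."""
    per_line_events: dict[str, list[ColocEvent]] = defaultdict(list)
    per_line_cells: dict[str, int] = defaultdict(int)
    per_line_green: dict[str, int] = defaultdict(int)
    per_line_large: dict[str, int] = defaultdict(int)
    for image_id, events in events_by_image.items():
        line = line_of_image[image_id]
        per_line_events[line].extend(events)
    for image_id, n in cell_counts.items():
        per_line_cells[line_of_image[image_id]] += n
    if green_by_image:
        for image_id, (objects, touches_red) in green_by_image.items():
            line = line_of_image[image_id]
            per_line_green[line] += sum(1 for t in touches_red if not t)
            per_line_large[line] += len(
                filter_large_foci(objects, large_focus_min_dim_um)
            )

    out = {}
    for line in sorted(set(per_line_events) | set(per_line_cells)):
        events = per_line_events.get(line, [])
        n_cells = per_line_cells.get(line, 0)
        n_nuc = sum(1 for e in events if e.compartment == NUCLEAR)
        n_cyt = sum(1 for e in events if e.compartment == CYTOPLASMIC)
        if n_cells > 0:
            inc_ev_nuc = incidence(n_nuc, n_cells)
            inc_ev_cyt = incidence(n_cyt, n_cells)
            cells_nuc = {
                (e.image_id, e.cell_index)
                for e in events
                if e.compartment == NUCLEAR and e.cell_index is not None
            }
            cells_cyt = {
                (e.image_id, e.cell_index)
                for e in events
                if e.compartment == CYTOPLASMIC and e.cell_index is not None
            }
            inc_cells_nuc = incidence(len(cells_nuc), n_cells)
            inc_cells_cyt = incidence(len(cells_cyt), n_cells)
        else:
            logger.warning("line %s has zero cells; incidences undefined", line)
            inc_ev_nuc = inc_ev_cyt = inc_cells_nuc = inc_cells_cyt = None
        out[line] = ColocSummary(
            line_id=line,
            n_cells=n_cells,
            n_events_nuclear=n_nuc,
            n_events_cytoplasmic=n_cyt,
            incidence_events_nuclear=inc_ev_nuc,
            incidence_events_cytoplasmic=inc_ev_cyt,
            incidence_cells_nuclear=inc_cells_nuc,
            incidence_cells_cytoplasmic=inc_cells_cyt,
            n_green_only_foci=per_line_green.get(line, 0),
            n_large_foci=per_line_large.get(line, 0),
        )
    return out
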