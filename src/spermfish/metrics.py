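"""Per-cell nuclear-architecture metrics: ITD and CTA with QC.

ITD = Euclidean distance between the two telomere spot centers (um)
divided by nucleus length (um).  CTA = territory area divided by nucleus
area (both um2).  ``measure_cell`` composes segmentation, geometry QC,
spot detection and territory measurement in a fixed order so the first
failing stage determines ``qc_reason`` deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import pandas as pd

from .io import CalibratedImage
from .quantify import (
    Spot,
    SpotCountError,
    SpotParams,
    TerritoryMeasurement,
    detect_telomere_spots,
    measure_territory,
    select_telomere_pair,
)
from .segmentation import (
    NucleusGeometry,
    QCLimits,
    SegmentationError,
    qc_geometry,
    segment_nucleus,
)

#: ITD may slightly exceed 1: a diagonal spot pair can be longer than the
#: Feret-normalized nucleus length only through measurement noise, but a
#: hard cap at 1.0 would clip valid borderline cells.
ITD_MAX = 1.5


@dataclass
class CellMeasurement:
    cell_id: str
    subject_id: str
    score_class: str
    itd: float | None
    cta: float | None
    qc_pass: bool
    qc_reason: str

    def to_row(self) -> dict:
        row = asdict(self)
        row["class"] = row.pop("score_class")
        return row


def compute_itd(spots: tuple[Spot, Spot], geometry: NucleusGeometry) -> float:
    """Inter-telomeric distance over nucleus length (dimensionless)."""
    if len(spots) != 2:
        raise SpotCountError(f"need exactly 2 spots, got {len(spots)}")
    if geometry.length_um <= 0:
        raise ValueError("nucleus length must be positive")
    (r1, c1), (r2, c2) = spots[0].center, spots[1].center
    dist_um = math.hypot(r1 - r2, c1 - c2) * geometry.pixel_size_um
    return dist_um / geometry.length_um


def compute_cta(territory: TerritoryMeasurement, geometry: NucleusGeometry) -> float:
    """Territory area over nucleus area (dimensionless)."""
    if geometry.area_um2 <= 0:
        raise ValueError("nucleus area must be positive")
    return territory.area_um2 / geometry.area_um2


def measure_cell(
    image: CalibratedImage,
    cell_id: str = "",
    subject_id: str = "",
    score_class: str = "",
    qc_limits: QCLimits | None = None,
    spot_params: SpotParams | None = None,
) -> CellMeasurement:
    """Run the full per-cell pipeline with deterministic QC ordering.

    QC stages, in order: segmentation, geometry limits, spot count,
    territory.  On the first failure the measurement is returned with
    ``qc_pass=False``, that stage's reason, and no metric values.
    """

    def fail(reason: str) -> CellMeasurement:
        return CellMeasurement(cell_id, subject_id, score_class, None, None, False, reason)

    try:
        geometry = segment_nucleus(image)
    except SegmentationError:
        return fail("segmentation")

    ok, reason = qc_geometry(geometry, qc_limits)
    if not ok:
        return fail(reason)

    spots = detect_telomere_spots(image, geometry, spot_params)
    try:
        pair = select_telomere_pair(spots, spot_params)
    except SpotCountError:
        return fail("spot_count")

    territory = measure_territory(image, geometry)
    if territory.degenerate:
        return fail("territory")

    itd = compute_itd(pair, geometry)
    cta = compute_cta(territory, geometry)
    if not (0 <= itd <= ITD_MAX and 0 <= cta <= 1):
        return fail("metric_out_of_range")
    return CellMeasurement(cell_id, subject_id, score_class, itd, cta, True, "")


def measure_dataset(
    images,
    labels: pd.DataFrame,
    qc_limits: QCLimits | None = None,
    spot_params: SpotParams | None = None,
) -> pd.DataFrame:
    """Measure a sequence of images with per-cell labels.

    ``labels`` needs columns cell_id, subject_id, class (row-aligned with
    ``images``).  Returns the per-cell measurement table
    (cell_id, subject_id, class, itd, cta, qc_pass, qc_reason).
    """
    if len(images) != len(labels):
        raise ValueError(f"{len(images)} images vs {len(labels)} label rows")
    rows = []
    for img, (_, lab) in zip(images, labels.iterrows()):
        m = measure_cell(
            img,
            cell_id=str(lab["cell_id"]),
            subject_id=str(lab["subject_id"]),
            score_class=str(lab["class"]),
            qc_limits=qc_limits,
            spot_params=spot_params,
        )
        rows.append(m.to_row())
    df = pd.DataFrame(rows)
    return df[["cell_id", "subject_id", "class", "itd", "cta", "qc_pass", "qc_reason"]]
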