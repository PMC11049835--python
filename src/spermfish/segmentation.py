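"""Sperm nucleus segmentation and head morphometry.

The counterstain channel is thresholded globally (Otsu), the largest
connected component is kept and hole-filled, and the head is measured:
area (um2), length (um) as the maximum Feret diameter, and its defining
endpoint pair.  The endpoint nearer the midpiece stub — a dim structure
just outside the mask at the insertion point — is labelled the base;
without a detectable stub the endpoint nearer the mask's wider half is
used.  Nucleus length here means the base-to-tip extent of the head, the
standard axis for the ITD denominator; the measured value does not depend
on which endpoint is labelled base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.filters import threshold_otsu
from skimage.measure import label

from .io import CalibratedImage


class SegmentationError(RuntimeError):
    """Counterstain channel unusable (empty, constant, or no component)."""


@dataclass
class NucleusGeometry:
    """Segmented nucleus mask with physical measurements."""

    mask: np.ndarray
    area_um2: float
    length_um: float
    base_point: tuple[float, float]   # (row, col) px
    tip_point: tuple[float, float]
    centroid: tuple[float, float]
    pixel_size_um: float

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class QCLimits:
    """Plausibility band for a human sperm head (defaults in um2 / um)."""

    area_um2: tuple[float, float] = (3.0, 30.0)
    length_um: tuple[float, float] = (2.0, 8.0)


def _feret_endpoints(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Maximum pixel-center caliper distance over the mask's convex hull."""
    pts = np.argwhere(mask).astype(float)
    if len(pts) < 2:
        raise SegmentationError("mask too small for a length measurement")
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear masks: fall back to all points
            pass
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    return pts[i], pts[j], float(d[i, j])


def segment_nucleus(image: CalibratedImage, counterstain_channel: int = 0) -> NucleusGeometry:
    """Segment the nucleus and measure area, Feret length and endpoints.

    Raises :class:`SegmentationError` on a constant or empty channel; size
    plausibility is *not* enforced here (see :func:`qc_geometry`).
    """
    chan = image.channel(counterstain_channel).astype(float)
    if chan.size == 0 or np.ptp(chan) == 0:
        raise SegmentationError("counterstain channel is empty or constant")
    thr = threshold_otsu(chan)
    binary = chan > thr
    if not binary.any():
        raise SegmentationError("no foreground above Otsu threshold")
    labels = label(binary)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = ndimage.binary_fill_holes(labels == np.argmax(counts))

    p_end1, p_end2, length_px = _feret_endpoints(mask)
    px = image.pixel_size_um
    area_um2 = float(mask.sum()) * px * px
    length_um = length_px * px
    centroid = tuple(np.argwhere(mask).mean(axis=0))

    base, tip = _orient_base_tip(chan, mask, p_end1, p_end2)
    return NucleusGeometry(
        mask=mask,
        area_um2=area_um2,
        length_um=length_um,
        base_point=tuple(base),
        tip_point=tuple(tip),
        centroid=centroid,
        pixel_size_um=px,
    )


def _probe_outside(chan: np.ndarray, mask: np.ndarray, endpoint, direction,
                   reach: float = 5.0, radius: float = 3.5) -> float:
    """Mean intensity in a small off-mask disk beyond an axis endpoint."""
    ctr = np.asarray(endpoint) + reach * direction
    rr, cc = np.mgrid[0 : chan.shape[0], 0 : chan.shape[1]]
    disk = (rr - ctr[0]) ** 2 + (cc - ctr[1]) ** 2 <= radius**2
    probe = disk & ~mask
    return float(chan[probe].mean()) if probe.any() else 0.0


def _orient_base_tip(chan, mask, p1, p2):
    axis = p2 - p1
    axis = axis / np.linalg.norm(axis)
    s1 = _probe_outside(chan, mask, p1, -axis)
    s2 = _probe_outside(chan, mask, p2, axis)
    if s1 != s2:
        return (p1, p2) if s1 > s2 else (p2, p1)
    # no stub signal: base = endpoint nearer the wider half of the mask
    pts = np.argwhere(mask).astype(float)
    mid = (p1 + p2) / 2
    along = (pts - mid) @ axis
    perp = np.abs((pts - mid) @ np.array([-axis[1], axis[0]]))
    w1 = perp[along < 0].mean() if (along < 0).any() else 0.0
    w2 = perp[along > 0].mean() if (along > 0).any() else 0.0
    return (p1, p2) if w1 >= w2 else (p2, p1)


def qc_geometry(geometry: NucleusGeometry, limits: QCLimits | None = None) -> tuple[bool, str]:
    """Check the measured head against plausibility limits.

    Returns ``(True, "")`` on pass, else ``(False, reason)`` with reason
    ``"area_out_of_range"`` or ``"length_out_of_range"`` (area checked
    first).
    """
    limits = limits or QCLimits()
    lo, hi = limits.area_um2
    if not lo <= geometry.area_um2 <= hi:
        return False, "area_out_of_range"
    lo, hi = limits.length_um
    if not lo <= geometry.length_um <= hi:
        return False, "length_out_of_range"
    return True, ""
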