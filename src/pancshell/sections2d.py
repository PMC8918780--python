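"""2D tissue-section analysis: the section-based counterpart of the 3D pipeline.

Regularly spaced sections (default every 30 µm) are segmented into single
cells from the nuclear counterstain (watershed split of touching nuclei),
classified by marker intensity within the nuclear footprint (Ecad ->
epithelial takes precedence, ERG -> endothelial, neither -> mesenchymal),
and measured against the 2D epithelium profile with the same half-open
7.5 / 15 µm layer conventions as the 3D analysis: the first-layer contact
fraction per section, and cell-type abundance pooled over all sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .proximity import FIRST_LAYER_UM, MAX_DISTANCE_UM, CompositionSummary

__all__ = [
    "SectionImage",
    "SectionSegmentation",
    "segment_nuclei_2d",
    "classify_cells_2d",
    "epithelium_roi_2d",
    "record_distances_2d",
    "contact_fraction_2d",
    "abundance_over_sections",
    "analyze_section",
]


@dataclass
class SectionImage:
    """One multi-channel 2D section.

    ``channels`` must contain at least ``nuclear``; ``ecad`` (epithelial
    marker) and ``erg`` (endothelial marker) enable classification.
    ``pixel_size`` is ``(dy, dx)`` in µm; ``z_position`` the section's
    depth in the tissue, µm.
    """

    channels: dict[str, np.ndarray]
    pixel_size: tuple[float, float]
    z_position: float = 0.0

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels must be congruent, got shapes {shapes}")
        if any(p <= 0 for p in self.pixel_size):
            raise ValueError("pixel size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_area(self) -> float:
        return float(self.pixel_size[0] * self.pixel_size[1])


@dataclass
class SectionSegmentation:
    """Nuclear instance segmentation of one section: records + label image."""

    records: pd.DataFrame  # id, x, y (µm), class, distance
    labels: np.ndarray  # int32 label image, 0 = background


def segment_nuclei_2d(
    section: SectionImage,
    smoothing_sigma: float = 1.5,
    threshold: float | str = "otsu",
    min_distance: float = 4.0,
    min_area_um2: float = 10.0,
) -> SectionSegmentation:
    """Watershed split of the thresholded nuclear channel into single nuclei.

    Gaussian smoothing (µm), Otsu (or explicit) threshold, then a watershed
    on the inverted smoothed intensity seeded at intensity maxima at least
    ``min_distance`` µm apart (nuclei are intensity blobs, so touching
    nuclei keep distinct peaks even when their thresholded footprints
    merge); objects below ``min_area_um2`` are dropped.  Centroids in µm.
    """
    if "nuclear" not in section.channels:
        raise ValueError("section has no 'nuclear' channel")
    pix = np.asarray(section.pixel_size, dtype=float)
    img = section.channels["nuclear"].astype(np.float32)
    if img.max() <= img.min():
        raise ValueError("nuclear channel is empty/constant")
    if smoothing_sigma > 0:
        img = ndi.gaussian_filter(img, smoothing_sigma / pix, output=np.float32)
    thr = float(threshold_otsu(img)) if threshold == "otsu" else float(threshold)
    mask = img >= thr
    if not mask.any():
        raise ValueError(f"no nuclei above threshold {thr:.4g}")

    min_dist_px = max(1, int(round(min_distance / pix.min())))
    seeds = peak_local_max(img, min_distance=min_dist_px, labels=mask, exclude_border=False)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(seeds.T)] = np.arange(1, len(seeds) + 1)
    labels = watershed(-img, markers, mask=mask).astype(np.int32)

    rows = []
    next_id = 0
    min_px = min_area_um2 / section.pixel_area
    for k, sl in enumerate(ndi.find_objects(labels), start=1):
        if sl is None:
            continue
        obj = labels[sl] == k
        if obj.sum() < min_px:
            labels[sl][obj] = 0
            continue
        cy, cx = ndi.center_of_mass(obj)
        rows.append(
            {
                "id": next_id,
                "x": (sl[1].start + cx) * pix[1],
                "y": (sl[0].start + cy) * pix[0],
                "class": "unassigned",
                "distance": np.nan,
                "label": k,
            }
        )
        next_id += 1
    records = pd.DataFrame(rows, columns=["id", "x", "y", "class", "distance", "label"])
    return SectionSegmentation(records=records, labels=labels)


def classify_cells_2d(
    seg: SectionSegmentation,
    section: SectionImage,
    epithelial_channel: str = "ecad",
    endothelial_channel: str = "erg",
    rel_threshold: float = 0.25,
) -> SectionSegmentation:
    """Classify nuclei by marker intensity within the nuclear footprint.

    The per-cell statistic is the *median* intensity over the footprint —
    robust against bright membrane spill clipping a footprint's edge — cut
    at ``rel_threshold`` x the channel's robust (99.9th percentile) maximum.
    Ecad (epithelial) takes precedence over ERG (endothelial); cells with
    neither marker are mesenchymal.
    """
    records = seg.records.copy()
    if len(records) == 0:
        return SectionSegmentation(records, seg.labels)

    def _median_in_footprint(channel: str) -> np.ndarray:
        img = section.channels[channel].astype(np.float32)
        meds = ndi.median(img, labels=seg.labels, index=records["label"].to_numpy())
        return np.asarray(meds)

    cls = np.full(len(records), "mesenchymal", dtype=object)
    for channel, assign in ((endothelial_channel, "endothelial"), (epithelial_channel, "epithelial")):
        if channel not in section.channels:
            continue
        cut = rel_threshold * float(np.percentile(section.channels[channel], 99.9))
        cls[_median_in_footprint(channel) >= cut] = assign
    records["class"] = cls
    return SectionSegmentation(records, seg.labels)


def epithelium_roi_2d(
    section: SectionImage,
    shell_width: float = MAX_DISTANCE_UM,
    epithelial_channel: str = "ecad",
    smoothing_sigma: float = 1.5,
    threshold: float | str = "half-max",
    min_area_um2: float = 200.0,
    roi_polygon: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Epithelium mask + surrounding distance shell for one section.

    The epithelium is segmented from the marker channel (largest component,
    holes filled); the default half-maximum threshold localizes the tissue
    boundary at the membrane-marker crest, like the 3D reference
    segmentation.  Alternatively a manually delineated ROI polygon
    (``(x, y)`` µm vertices) can be supplied.  Returns ``epithelium`` and
    ``shell`` boolean masks plus the 2D distance map ``dmap`` (µm).
    """
    if shell_width <= 0:
        raise ValueError("shell_width must be > 0 µm")
    pix = np.asarray(section.pixel_size, dtype=float)
    if roi_polygon is not None:
        from skimage.draw import polygon2mask

        poly = np.asarray(roi_polygon, dtype=float)
        mask = polygon2mask(section.shape, np.column_stack([poly[:, 1] / pix[0], poly[:, 0] / pix[1]]))
    else:
        if epithelial_channel not in section.channels:
            raise ValueError(f"section has no {epithelial_channel!r} channel and no ROI polygon")
        img = ndi.gaussian_filter(
            section.channels[epithelial_channel].astype(np.float32), smoothing_sigma / pix, output=np.float32
        )
        if threshold == "otsu":
            thr = float(threshold_otsu(img))
        elif threshold == "half-max":
            thr = 0.5 * float(np.percentile(img, 99.9))
        else:
            thr = float(threshold)
        mask = ndi.binary_fill_holes(img >= thr)
        lab, n = ndi.label(mask)
        if n == 0:
            raise ValueError(f"empty epithelium (threshold {thr:.4g})")
        sizes = np.bincount(lab.ravel())[1:]
        mask = lab == (int(np.argmax(sizes)) + 1)
        if sizes.max() * section.pixel_area < min_area_um2:
            raise ValueError("epithelium below minimum area")
    if not mask.any():
        raise ValueError("empty epithelium ROI")
    dmap = ndi.distance_transform_edt(~mask, sampling=pix)
    shell = (dmap > 0) & (dmap < shell_width)
    if not shell.any():
        raise ValueError("empty shell around the epithelium")
    return {"epithelium": mask, "shell": shell, "dmap": dmap}


def record_distances_2d(
    seg: SectionSegmentation,
    roi: dict[str, np.ndarray],
    section: SectionImage,
) -> SectionSegmentation:
    """Fill each record's distance to the 2D epithelium (0 inside it)."""
    records = seg.records.copy()
    if len(records) == 0:
        return SectionSegmentation(records, seg.labels)
    pix = np.asarray(section.pixel_size, dtype=float)
    iy = np.clip(np.rint(records["y"].to_numpy() / pix[0]).astype(int), 0, section.shape[0] - 1)
    ix = np.clip(np.rint(records["x"].to_numpy() / pix[1]).astype(int), 0, section.shape[1] - 1)
    inside = roi["epithelium"][iy, ix]
    records["distance"] = np.where(inside, 0.0, roi["dmap"][iy, ix])
    return SectionSegmentation(records, seg.labels)


def contact_fraction_2d(
    records: pd.DataFrame,
    cls: str = "endothelial",
    first_layer: float = FIRST_LAYER_UM,
    max_distance: float = MAX_DISTANCE_UM,
) -> float:
    """% of ``cls`` cells in direct contact (d < 7.5 µm) among those within
    15 µm of the epithelium; same half-open boundaries as the 3D layers."""
    sub = records[(records["class"] == cls) & (records["distance"] < max_distance)]
    if len(sub) == 0:
        raise ValueError(f"no {cls} cells within {max_distance} µm")
    return 100.0 * float((sub["distance"] < first_layer).sum()) / len(sub)


def abundance_over_sections(
    section_records: list[pd.DataFrame],
    max_distance: float = MAX_DISTANCE_UM,
    classes: tuple[str, ...] = ("epithelial", "endothelial", "mesenchymal"),
) -> CompositionSummary:
    """Pooled cell-type composition within the 15 µm ROI across sections."""
    if not section_records:
        raise ValueError("no sections")
    pooled = pd.concat(section_records, ignore_index=True)
    sel = pooled[(pooled["distance"] < max_distance) & pooled["class"].isin(classes)]
    total = len(sel)
    if total == 0:
        raise ValueError("no cells within the ROI across sections")
    counts = {c: int((sel["class"] == c).sum()) for c in classes}
    pct = {c: 100.0 * counts[c] / total for c in classes}
    return CompositionSummary(counts=counts, percentages=pct, total=total, shell=(0.0, max_distance))


def analyze_section(section: SectionImage, **kwargs) -> pd.DataFrame:
    """Convenience: segment, classify and measure one section end-to-end."""
    seg = segment_nuclei_2d(section)
    seg = classify_cells_2d(seg, section)
    roi = epithelium_roi_2d(section, **kwargs)
    seg = record_distances_2d(seg, roi, section)
    return seg.records
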