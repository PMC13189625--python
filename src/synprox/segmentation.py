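"""Puncta detection: Triangle auto-threshold over a z-stack, projection,
connected-component particle analysis and ROI-restricted measurement.

Thresholding follows the Triangle (Zack) construction: the intensity
histogram is pooled over every slice of the channel, a straight line is
drawn from the histogram peak to the far end of its longer tail, and the
threshold is the bin whose histogram point lies farthest (perpendicular
distance) from that line. Foreground is strictly above the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from .stacks import ImageStack, ROIBox


class ContrastError(ValueError):
    """Raised when a histogram carries no contrast to threshold."""


def triangle_threshold(histogram: np.ndarray) -> int:
    """Triangle (Zack) threshold of an intensity histogram.

    Parameters
    ----------
    histogram
        Counts per intensity bin (bin width one intensity level).

    Returns
    -------
    int
        Threshold bin index; foreground is ``intensity > threshold``.

    Notes
    -----
    Dialect pinned for reproducibility: the histogram is mirrored first if
    the peak lies nearer the bright end, the line runs from the peak bin to
    the last nonzero bin, the threshold maximizes perpendicular distance to
    that line over the bins strictly after the peak (first bin on ties),
    and the result is mapped back through the mirroring.
    """
    hist = np.asarray(histogram, dtype=float)
    if hist.ndim != 1:
        raise ValueError("histogram must be one-dimensional")
    nz = np.flatnonzero(hist)
    if nz.size == 0:
        raise ContrastError("empty histogram")
    if nz.size == 1:
        raise ContrastError("histogram has a single nonzero bin (no contrast)")

    peak = int(np.argmax(hist))
    first, last = int(nz[0]), int(nz[-1])
    mirrored = (last - peak) < (peak - first)
    if mirrored:
        hist = hist[::-1]
        n = hist.size
        peak = n - 1 - peak
        last = n - 1 - first

    # line from (peak, h[peak]) to (last, h[last]); maximize perpendicular
    # distance over bins strictly between peak and the tail end
    xs = np.arange(peak + 1, last + 1)
    if xs.size == 0:
        raise ContrastError("no bins between peak and tail")
    x0, y0 = peak, hist[peak]
    x1, y1 = last, hist[last]
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    dist = np.abs(dy * (xs - x0) - dx * (hist[xs] - y0)) / norm
    t = int(xs[int(np.argmax(dist))])

    if mirrored:
        t = hist.size - 1 - t
    return t


def stack_histogram(stack: ImageStack, channel: int) -> np.ndarray:
    """Histogram pooled over every slice of one channel (bin width 1)."""
    data = stack.channel(channel)
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError("stack_histogram expects integer intensity data")
    return np.bincount(data.ravel(), minlength=int(data.max()) + 1)


@dataclass
class SegmentationConfig:
    """Particle-analysis options.

    ``projection`` reduces the stack before 2D component labeling:
    ``"max"`` (maximum-intensity projection, default) or ``"per_slice_or"``
    (threshold each slice, OR the foregrounds). ``connectivity`` is the
    pixel adjacency (8 = edges+corners). ``size_exclusion_px2_for_coloc``
    is carried to the colocalization step, where candidate objects larger
    than this pixel area are excluded.
    """

    projection: str = "max"
    connectivity: int = 8
    min_area_px: int = 0
    max_area_px: int | None = None
    size_exclusion_px2_for_coloc: int | None = 10000

    def validate(self) -> None:
        if self.projection not in ("max", "per_slice_or"):
            raise ValueError("projection must be 'max' or 'per_slice_or'")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.max_area_px is not None and self.min_area_px > self.max_area_px:
            raise ValueError("min_area_px must not exceed max_area_px")


@dataclass
class PunctaSet:
    """Segmented objects of one channel after projection.

    ``labels`` is a 2D label image (0 = background); ``objects`` one row
    per object with pixel and physical measurements. ``error`` is set (and
    the set left empty) when thresholding failed, e.g. on a blank channel.
    """

    channel: int
    mask: np.ndarray
    labels: np.ndarray
    objects: pd.DataFrame
    pixel_size_um: float
    threshold: int | None = None
    error: str | None = None

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def filtered_mask(self, max_area_px: int | None) -> np.ndarray:
        """Boolean mask excluding objects larger than ``max_area_px``."""
        if max_area_px is None or self.n_objects == 0:
            return self.mask.astype(bool)
        keep = self.objects.loc[self.objects["area_px"] <= max_area_px, "label"]
        return np.isin(self.labels, keep.to_numpy())


_EMPTY_OBJECTS = pd.DataFrame(
    columns=["label", "area_px", "area_um2", "centroid_row", "centroid_col",
             "bbox_min_row", "bbox_min_col", "bbox_max_row", "bbox_max_col"]
)


def label_mask(mask: np.ndarray, pixel_size_um: float, channel: int = 0,
               connectivity: int = 8, min_area_px: int = 0,
               max_area_px: int | None = None,
               threshold: int | None = None) -> PunctaSet:
    """Connected-component analysis of a binary mask into a PunctaSet."""
    conn = 2 if connectivity == 8 else 1
    labels = measure.label(mask, connectivity=conn)
    props = measure.regionprops(labels)
    rows = []
    for p in props:
        if p.area < min_area_px or (max_area_px is not None and p.area > max_area_px):
            labels[labels == p.label] = 0
            continue
        rows.append({
            "label": p.label,
            "area_px": int(p.area),
            "area_um2": float(p.area) * pixel_size_um ** 2,
            "centroid_row": p.centroid[0],
            "centroid_col": p.centroid[1],
            "bbox_min_row": p.bbox[0], "bbox_min_col": p.bbox[1],
            "bbox_max_row": p.bbox[2], "bbox_max_col": p.bbox[3],
        })
    if rows:
        objects = pd.DataFrame(rows)
        # relabel contiguously from 1 in raster order of the old labels
        remap = {old: new for new, old in enumerate(objects["label"], start=1)}
        out = np.zeros_like(labels)
        for old, new in remap.items():
            out[labels == old] = new
        labels = out
        objects["label"] = np.arange(1, len(objects) + 1)
    else:
        objects = _EMPTY_OBJECTS.copy()
        labels = np.zeros_like(labels)
    return PunctaSet(
        channel=channel, mask=labels > 0, labels=labels, objects=objects,
        pixel_size_um=pixel_size_um, threshold=threshold,
    )


def segment_puncta(stack: ImageStack, channel: int,
                   config: SegmentationConfig | None = None) -> PunctaSet:
    """Threshold one channel of a stack and measure its puncta.

    The Triangle threshold is computed on the histogram pooled over the
    entire z-stack, the stack is reduced to 2D by the configured
    projection, and connected components within the size window are kept.
    A blank (no-contrast) channel yields an empty PunctaSet with ``error``
    set rather than raising.
    """
    config = config or SegmentationConfig()
    config.validate()
    data = stack.channel(channel)
    try:
        t = triangle_threshold(stack_histogram(stack, channel))
    except ContrastError as exc:
        shape = stack.shape_yx
        return PunctaSet(
            channel=channel, mask=np.zeros(shape, bool),
            labels=np.zeros(shape, np.int32), objects=_EMPTY_OBJECTS.copy(),
            pixel_size_um=stack.pixel_size_um, threshold=None, error=str(exc),
        )
    if config.projection == "max":
        fg = data.max(axis=0) > t
    else:
        fg = (data > t).any(axis=0)
    return label_mask(
        fg, stack.pixel_size_um, channel=channel,
        connectivity=config.connectivity, min_area_px=config.min_area_px,
        max_area_px=config.max_area_px, threshold=t,
    )


def measure_puncta(puncta: PunctaSet, roi: ROIBox,
                   image_shape_yx: tuple[int, int] | None = None) -> dict:
    """Density and size summary of the puncta whose centroids fall in a ROI.

    Membership uses the half-open box [origin, origin + extent). Returns a
    dict with ``count``, ``density_per_um2``, ``mean_area_um2`` and
    ``sd_area_um2`` (NaN when the ROI holds no puncta).
    """
    shape = image_shape_yx or puncta.mask.shape
    roi.validate_inside(shape, puncta.pixel_size_um)
    if puncta.n_objects:
        inside = puncta.objects.apply(
            lambda r: roi.contains(r["centroid_row"], r["centroid_col"],
                                   puncta.pixel_size_um),
            axis=1,
        )
        sel = puncta.objects[inside]
    else:
        sel = puncta.objects
    count = len(sel)
    return {
        "roi": roi.label,
        "count": count,
        "density_per_um2": count / roi.area_um2,
        "mean_area_um2": float(sel["area_um2"].mean()) if count else float("nan"),
        "sd_area_um2": float(sel["area_um2"].std(ddof=1)) if count > 1 else float("nan"),
    }
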