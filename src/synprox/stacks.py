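"""Calibrated multi-channel image stacks and rectangular analysis regions."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageStack:
    """Two-(or more-)channel confocal z-stack with physical calibration.

    ``data`` is ordered (channel, slice, row, column). ``pixel_size_um`` is
    the lateral sampling (default 0.05 um, i.e. 50 nm pixels as acquired
    with an Airyscan detector); ``z_step_um`` the axial slice spacing.
    """

    data: np.ndarray
    pixel_size_um: float = 0.05
    z_step_um: float = 0.18
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected (C, Z, Y, X) array, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one channel")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")
        if np.issubdtype(self.data.dtype, np.integer) and (self.data < 0).any():
            raise ValueError("intensities must be non-negative")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    @property
    def field_um(self) -> tuple[float, float]:
        """Physical (height, width) of the field in microns."""
        h, w = self.shape_yx
        return h * self.pixel_size_um, w * self.pixel_size_um

    def channel(self, index: int) -> np.ndarray:
        """The (Z, Y, X) sub-stack of one channel."""
        if not 0 <= index < self.n_channels:
            raise IndexError(
                f"channel {index} out of range for {self.n_channels}-channel stack"
            )
        return self.data[index]


@dataclass
class ROIBox:
    """Rectangular analysis region, physically sized, pixel-anchored.

    The default extent 20.07 x 32.91 um^2 matches the region used to sample
    one sublayer of the retinal inner plexiform layer. Membership of objects
    is by centroid within the half-open box [origin, origin + extent).
    """

    origin: tuple[int, int] = (0, 0)
    height_um: float = 20.07
    width_um: float = 32.91
    label: str = "roi"

    def __post_init__(self) -> None:
        if self.height_um <= 0 or self.width_um <= 0:
            raise ValueError("ROI extent must be positive")

    @property
    def area_um2(self) -> float:
        return self.height_um * self.width_um

    def extent_px(self, pixel_size_um: float) -> tuple[int, int]:
        """(rows, cols) spanned by the box at a given pixel size."""
        return (
            int(round(self.height_um / pixel_size_um)),
            int(round(self.width_um / pixel_size_um)),
        )

    def validate_inside(self, shape_yx: tuple[int, int], pixel_size_um: float) -> None:
        rows, cols = self.extent_px(pixel_size_um)
        r0, c0 = self.origin
        if r0 < 0 or c0 < 0 or r0 + rows > shape_yx[0] or c0 + cols > shape_yx[1]:
            raise ValueError(
                f"ROI {self.label!r} ({rows}x{cols} px at {self.origin}) does not fit "
                f"inside image of shape {shape_yx}"
            )

    def contains(self, row: float, col: float, pixel_size_um: float) -> bool:
        """Half-open membership test for a (row, col) pixel coordinate."""
        rows, cols = self.extent_px(pixel_size_um)
        r0, c0 = self.origin
        return r0 <= row < r0 + rows and c0 <= col < c0 + cols


def full_image_roi(shape_yx: tuple[int, int], pixel_size_um: float,
                   label: str = "full") -> ROIBox:
    """An ROI covering the whole field."""
    return ROIBox(
        origin=(0, 0),
        height_um=shape_yx[0] * pixel_size_um,
        width_um=shape_yx[1] * pixel_size_um,
        label=label,
    )
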