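"""Seeded simulation of two-channel punctate confocal z-stacks.

The simulator emulates an Airyscan-style acquisition of synaptic puncta:
both channels contain small bright disks scattered over a flat field. A
configurable fraction of *candidate*-channel puncta is planted so that its
ground-truth disk overlaps a *reference*-channel disk (the colocalized
fraction); the rest are placed uniformly at random. Each punctum is a hard
disk with a Gaussian axial profile (sd = one slice), the scene is blurred
with a Gaussian PSF, and shot (Poisson) plus Gaussian read noise is added.
Ground truth (centers, radii, planted-colocalization flags) is returned
alongside the stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stacks import ImageStack

REF_CHANNEL = 0
CAND_CHANNEL = 1


@dataclass
class ImageSimConfig:
    """Acquisition and scene parameters for one simulated field.

    Defaults: a 512x512 field at 50 nm pixels (25.6 um square), seven
    slices spanning 1.08 um, ~0.08 puncta/um^2 per channel with 0.15 um
    mean punctum radius.
    """

    width_px: int = 512
    height_px: int = 512
    n_slices: int = 7
    pixel_size_um: float = 0.05
    z_step_um: float = 0.18
    ref_density_per_um2: float = 0.08
    cand_density_per_um2: float = 0.08
    punctum_radius_um_mean: float = 0.15
    punctum_radius_um_sd: float = 0.03
    coloc_fraction: float = 0.5
    psf_sigma_um: float = 0.08
    photon_scale: float | None = 200.0
    read_noise_sd: float = 1.0
    background_level: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if min(self.width_px, self.height_px, self.n_slices) <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")
        if self.ref_density_per_um2 < 0 or self.cand_density_per_um2 < 0:
            raise ValueError("densities must be non-negative")
        per_px = self.pixel_size_um ** 2
        if max(self.ref_density_per_um2, self.cand_density_per_um2) * per_px > 1.0:
            raise ValueError("density implies more than one punctum per pixel")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.punctum_radius_um_mean <= 0:
            raise ValueError("punctum_radius_um_mean must be positive")
        if self.read_noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def field_area_um2(self) -> float:
        return self.width_px * self.height_px * self.pixel_size_um ** 2


@dataclass
class PunctaTruth:
    """Ground truth of a simulated field, in physical (um) coordinates.

    Centers are (row_um, col_um); ``planted_colocalized[i]`` marks the i-th
    candidate punctum as planted to overlap a reference disk.
    """

    ref_centers_um: np.ndarray
    ref_radii_um: np.ndarray
    ref_z_slice: np.ndarray
    cand_centers_um: np.ndarray
    cand_radii_um: np.ndarray
    cand_z_slice: np.ndarray
    planted_colocalized: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    @property
    def n_ref(self) -> int:
        return len(self.ref_centers_um)

    @property
    def n_cand(self) -> int:
        return len(self.cand_centers_um)

    def to_dict(self) -> dict:
        return {
            "ref_centers_um": self.ref_centers_um.tolist(),
            "ref_radii_um": self.ref_radii_um.tolist(),
            "ref_z_slice": self.ref_z_slice.tolist(),
            "cand_centers_um": self.cand_centers_um.tolist(),
            "cand_radii_um": self.cand_radii_um.tolist(),
            "cand_z_slice": self.cand_z_slice.tolist(),
            "planted_colocalized": [bool(x) for x in self.planted_colocalized],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PunctaTruth":
        def arr(k, dtype=float):
            return np.asarray(d[k], dtype=dtype)
        return cls(
            ref_centers_um=arr("ref_centers_um").reshape(-1, 2),
            ref_radii_um=arr("ref_radii_um"),
            ref_z_slice=arr("ref_z_slice"),
            cand_centers_um=arr("cand_centers_um").reshape(-1, 2),
            cand_radii_um=arr("cand_radii_um"),
            cand_z_slice=arr("cand_z_slice"),
            planted_colocalized=arr("planted_colocalized", bool),
        )


def render_scene(centers_um: np.ndarray, radii_um: np.ndarray, z_slices: np.ndarray,
                 shape_zyx: tuple[int, int, int], pixel_size_um: float,
                 amplitudes: np.ndarray | None = None) -> np.ndarray:
    """Paint hard disks with Gaussian z-profiles into a float (Z, Y, X) scene.

    The axial profile has sd = one slice around each punctum's z center;
    intensities are additive.
    """
    nz, ny, nx = shape_zyx
    scene = np.zeros(shape_zyx, dtype=np.float32)
    if len(centers_um) == 0:
        return scene
    if amplitudes is None:
        amplitudes = np.ones(len(centers_um))
    z_idx = np.arange(nz)
    for (r_um, c_um), rad, z0, amp in zip(centers_um, radii_um, z_slices, amplitudes):
        r_px, c_px = r_um / pixel_size_um, c_um / pixel_size_um
        rad_px = rad / pixel_size_um
        r0, r1 = int(np.floor(r_px - rad_px)) - 1, int(np.ceil(r_px + rad_px)) + 2
        c0, c1 = int(np.floor(c_px - rad_px)) - 1, int(np.ceil(c_px + rad_px)) + 2
        r0, c0 = max(r0, 0), max(c0, 0)
        r1, c1 = min(r1, ny), min(c1, nx)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        disk = ((yy + 0.5 - r_px) ** 2 + (xx + 0.5 - c_px) ** 2) <= rad_px ** 2
        zw = np.exp(-0.5 * (z_idx - z0) ** 2)
        scene[:, r0:r1, c0:c1] += (
            amp * zw[:, None, None] * disk[None].astype(np.float32)
        )
    return scene


def _sample_puncta(rng: np.random.Generator, n: int, config: ImageSimConfig):
    h_um = config.height_px * config.pixel_size_um
    w_um = config.width_px * config.pixel_size_um
    centers = rng.uniform([0, 0], [h_um, w_um], size=(n, 2))
    radii = np.clip(
        rng.normal(config.punctum_radius_um_mean, config.punctum_radius_um_sd, n),
        0.33 * config.punctum_radius_um_mean, None,
    )
    z = rng.uniform(1.0, config.n_slices - 2.0, n)
    return centers, radii, z


def simulate_puncta_image(config: ImageSimConfig) -> tuple[ImageStack, PunctaTruth]:
    """Simulate a two-channel punctate stack with known colocalization.

    Channel 0 is the reference (e.g. the connexin), channel 1 the candidate
    label. ``round(coloc_fraction * n_cand)`` candidate puncta are placed
    with their center displaced from a randomly chosen reference center by
    a uniform draw inside a disk of radius ``0.5 * (r_ref + r_cand)``, which
    guarantees the two ground-truth disks intersect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    area = config.field_area_um2
    h_um = config.height_px * config.pixel_size_um
    w_um = config.width_px * config.pixel_size_um

    n_ref = rng.poisson(config.ref_density_per_um2 * area)
    n_cand = rng.poisson(config.cand_density_per_um2 * area)
    ref_centers, ref_radii, ref_z = _sample_puncta(rng, n_ref, config)
    cand_centers, cand_radii, cand_z = _sample_puncta(rng, n_cand, config)

    planted = np.zeros(n_cand, dtype=bool)
    n_coloc = int(round(config.coloc_fraction * n_cand))
    if n_coloc and n_ref:
        which = rng.choice(n_cand, size=n_coloc, replace=False)
        hosts = rng.integers(0, n_ref, size=n_coloc)
        # uniform draw in a disk of radius 0.5*(r_ref + r_cand): intersection
        # of the ground-truth disks is guaranteed
        rmax = 0.5 * (ref_radii[hosts] + cand_radii[which])
        rho = rmax * np.sqrt(rng.random(n_coloc))
        theta = rng.uniform(0, 2 * np.pi, n_coloc)
        shift = np.stack([rho * np.sin(theta), rho * np.cos(theta)], axis=1)
        cand_centers[which] = np.clip(
            ref_centers[hosts] + shift, [0, 0], [h_um, w_um]
        )
        cand_z[which] = ref_z[hosts]
        planted[which] = True

    shape = (config.n_slices, config.height_px, config.width_px)
    amp_ref = rng.uniform(0.7, 1.3, n_ref)
    amp_cand = rng.uniform(0.7, 1.3, n_cand)
    scenes = [
        render_scene(ref_centers, ref_radii, ref_z, shape, config.pixel_size_um, amp_ref),
        render_scene(cand_centers, cand_radii, cand_z, shape, config.pixel_size_um, amp_cand),
    ]

    sigma_px = config.psf_sigma_um / config.pixel_size_um
    data = np.empty((2, *shape), dtype=np.uint16)
    for ch, scene in enumerate(scenes):
        if sigma_px > 0:
            scene = ndimage.gaussian_filter(scene, sigma=(0, sigma_px, sigma_px))
        scene = scene + config.background_level
        if config.photon_scale is not None:
            img = rng.poisson(scene * config.photon_scale).astype(np.float64)
            if config.read_noise_sd > 0:
                img = img + rng.normal(0, config.read_noise_sd, img.shape)
        else:
            img = scene * 1000.0
        data[ch] = np.clip(np.round(img), 0, 65535).astype(np.uint16)

    stack = ImageStack(
        data=data,
        pixel_size_um=config.pixel_size_um,
        z_step_um=config.z_step_um,
        channel_names=["reference", "candidate"],
    )
    truth = PunctaTruth(
        ref_centers_um=ref_centers, ref_radii_um=ref_radii, ref_z_slice=ref_z,
        cand_centers_um=cand_centers, cand_radii_um=cand_radii, cand_z_slice=cand_z,
        planted_colocalized=planted,
    )
    return stack, truth
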