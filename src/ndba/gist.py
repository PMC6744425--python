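"""GIST-style image descriptors and the descriptor-level cross-decoding control.

A descriptor summarizes localized orientation and spatial-frequency energy:
the image is filtered with a bank of log-Gabor filters (``orientations`` x
``scales``, octave-spaced center frequencies), the filter-energy image is
averaged within each cell of a ``grid`` x ``grid`` partition, and the block
averages are concatenated (block-major, then orientation, then scale). With
the defaults (4x4 grid, 8 orientations, 4 scales) this yields 512 values.

The cross-decoding control asks whether a linear classifier trained on the
descriptors of one cluster pair (matched on the orthogonal dimension)
generalizes to the complementary pair — i.e. whether low-level image
statistics carry generalizable shape or animacy information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lda import cross_decode


@dataclass
class GistDescriptor:
    """Filter-energy block averages, block-major then orientation then scale."""

    values: np.ndarray
    grid: int
    orientations: int
    scales: int

    def __post_init__(self) -> None:
        expected = self.grid**2 * self.orientations * self.scales
        if self.values.shape != (expected,):
            raise ValueError(f"descriptor length must be {expected}")

    def index(self, block: int, orientation: int, scale: int) -> int:
        return (block * self.orientations + orientation) * self.scales + scale


def gabor_bank(
    orientations: int = 8,
    scales: int = 4,
    image_size: int = 128,
    f_max: float = 0.25,
) -> np.ndarray:
    """Frequency-domain log-Gabor filter bank, shape (orientations, scales, H, W).

    Orientations tile [0, pi) uniformly; center frequencies are octave-spaced
    downward from ``f_max`` cycles/pixel. Filters are one-sided (analytic) so
    the magnitude of the filtered image is a smooth local-energy envelope.
    """
    if orientations < 1 or scales < 1:
        raise ValueError("orientations and scales must be >= 1")
    f_min = f_max / 2 ** (scales - 1)
    if image_size * f_min < 2:
        raise ValueError(
            f"image_size {image_size} too small for lowest frequency {f_min:.4g}"
        )
    fy = np.fft.fftfreq(image_size)[:, None]
    fx = np.fft.fftfreq(image_size)[None, :]
    f = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)
    sigma_theta = np.pi / (2 * orientations)
    sigma_log = np.log(2.0) / 2.0  # half-octave radial bandwidth
    bank = np.zeros((orientations, scales, image_size, image_size))
    with np.errstate(divide="ignore"):
        logf = np.where(f > 0, np.log(f), -np.inf)
    for o in range(orientations):
        theta0 = np.pi * o / orientations
        dtheta = np.angle(np.exp(1j * (theta - theta0)))  # wrapped, one-sided
        ang = np.exp(-(dtheta**2) / (2 * sigma_theta**2))
        for s in range(scales):
            f0 = f_max / 2**s
            rad = np.exp(-((logf - np.log(f0)) ** 2) / (2 * sigma_log**2))
            g = ang * rad
            g[f == 0] = 0.0  # band-pass: no DC response
            bank[o, s] = g
    return bank


def _block_average(energy: np.ndarray, grid: int) -> np.ndarray:
    rows = np.array_split(energy, grid, axis=0)
    out = np.empty(grid * grid)
    k = 0
    for r in rows:
        for c in np.array_split(r, grid, axis=1):
            out[k] = c.mean()
            k += 1
    return out


def compute_gist(
    image: np.ndarray,
    grid: int = 4,
    orientations: int = 8,
    scales: int = 4,
    bank: np.ndarray | None = None,
    normalize: bool = True,
) -> GistDescriptor:
    """Descriptor of a greyscale image.

    The image is intensity-normalized (zero mean, unit variance) before
    filtering so descriptors are invariant to luminance and contrast offsets.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be a 2-D greyscale array")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    if min(image.shape) < grid:
        raise ValueError("image smaller than the descriptor grid")
    if image.shape[0] != image.shape[1]:
        n = min(image.shape)
        image = image[:n, :n]
    if normalize:
        image = image - image.mean()
        sd = image.std()
        if sd > 0:
            image = image / sd
    if bank is None:
        bank = gabor_bank(orientations, scales, image_size=image.shape[0])
    F = np.fft.fft2(image)
    n_blocks = grid * grid
    values = np.empty(n_blocks * orientations * scales)
    for o in range(orientations):
        for s in range(scales):
            energy = np.abs(np.fft.ifft2(F * bank[o, s]))
            blocks = _block_average(energy, grid)
            for b in range(n_blocks):
                values[(b * orientations + o) * scales + s] = blocks[b]
    return GistDescriptor(
        values=values, grid=grid, orientations=orientations, scales=scales
    )


def compute_gist_batch(
    images: np.ndarray, grid: int = 4, orientations: int = 8, scales: int = 4
) -> np.ndarray:
    """Descriptors for a stack of same-size images; rows are stimuli."""
    images = np.asarray(images, dtype=float)
    bank = gabor_bank(orientations, scales, image_size=min(images.shape[1:]))
    return np.stack(
        [
            compute_gist(img, grid=grid, orientations=orientations, scales=scales, bank=bank).values
            for img in images
        ]
    )


def crossdecode_descriptors(
    descriptors: np.ndarray,
    design,
    dimension: str,
    shrinkage: float | str = "auto",
) -> tuple[float, list[float]]:
    """Cross-decode a dimension from per-stimulus descriptors.

    Descriptors are z-scored per feature on the training stimuli before
    classification. Returns (mean accuracy, per-fold accuracies).
    """
    descriptors = np.asarray(descriptors, dtype=float)
    if descriptors.shape[0] != design.n_stimuli:
        raise ValueError("one descriptor row per stimulus is required")
    return cross_decode(
        descriptors,
        design.stimulus_id,
        design,
        dimension,
        shrinkage=shrinkage,
        zscore=True,
    )
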