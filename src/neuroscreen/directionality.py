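"""Fourier-spectrum directionality histogram.

The cross-check for the vesselness pathway: the 2D power spectrum of a
(windowed, mean-subtracted) image is binned by orientation.  Spectral
energy of a structure oriented at theta lies along the perpendicular of
theta, so each frequency sample contributes its power to the bin of its
orientation rotated by 90 degrees — the histogram therefore reports
*structure* orientation and is directly comparable with the vesselness
orientation field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._angles import axial_difference, wrap_axial
from .errors import DegenerateInputError

__all__ = [
    "DirectionalityHistogram",
    "directionality_histogram",
    "histogram_alignment",
    "spectral_samples",
    "DEFAULT_N_BINS",
]

DEFAULT_N_BINS = 90  # 2-degree bins
DEFAULT_EXCLUSION_RADIUS = 3.0  # frequency samples around DC excluded


@dataclass
class DirectionalityHistogram:
    bin_centers_deg: np.ndarray  # axial angles covering [-90, 90)
    mass: np.ndarray  # nonnegative, sums to 1

    def __post_init__(self) -> None:
        self.bin_centers_deg = np.asarray(self.bin_centers_deg, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.bin_centers_deg.shape != self.mass.shape:
            raise ValueError("bin_centers_deg and mass must have the same length")
        if np.any(self.mass < 0) or not np.isclose(self.mass.sum(), 1.0, atol=1e-9):
            raise ValueError("mass must be nonnegative and sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.mass)

    @property
    def bin_width_deg(self) -> float:
        return 180.0 / self.n_bins

    def modal_angle_deg(self) -> float:
        return float(self.bin_centers_deg[int(np.argmax(self.mass))])


def spectral_samples(
    image: np.ndarray, exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frequency-sample (structure orientation deg, power) of an image.

    The image is mean-subtracted and windowed with a 2D Hann window before
    the FFT; the DC component and a small low-frequency disc are excluded.
    Orientations are already rotated by 90 degrees into structure space.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if np.ptp(image) == 0:
        raise DegenerateInputError("constant image has no directionality")

    h, w = image.shape
    win = np.outer(np.hanning(h), np.hanning(w))
    spec = np.fft.fftshift(np.fft.fft2((image - image.mean()) * win))
    power = np.abs(spec) ** 2

    fr = np.arange(h) - h // 2  # frequency index along rows (fftshifted)
    fc = np.arange(w) - w // 2
    fr2d, fc2d = np.meshgrid(fr, fc, indexing="ij")
    radius = np.hypot(fr2d, fc2d)
    # restrict to the inscribed Nyquist disc: the square spectrum corners
    # sample diagonal orientations more densely and would bias the histogram
    keep = (radius > exclusion_radius) & (radius < min(h, w) / 2.0)

    # orientation of the frequency vector, then rotated 90 deg to report
    # the orientation of the underlying structure
    spectral_angle = np.degrees(np.arctan2(-fr2d[keep], fc2d[keep]))
    structure_angle = wrap_axial(spectral_angle + 90.0)
    return structure_angle, power[keep]


def directionality_histogram(
    image: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    exclusion_radius: float = DEFAULT_EXCLUSION_RADIUS,
) -> DirectionalityHistogram:
    """Orientation histogram of image structures from the Fourier power spectrum."""
    if n_bins < 6:
        raise ValueError("n_bins must be >= 6")
    structure_angle, power = spectral_samples(image, exclusion_radius)

    width = 180.0 / n_bins
    idx = np.floor((structure_angle + 90.0) / width).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    mass = np.bincount(idx, weights=power, minlength=n_bins)
    total = mass.sum()
    if total <= 0:
        raise DegenerateInputError("image carries no spectral power outside DC")
    centers = -90.0 + (np.arange(n_bins) + 0.5) * width
    return DirectionalityHistogram(bin_centers_deg=centers, mass=mass / total)


def histogram_alignment(
    hist: DirectionalityHistogram, pattern_angle_deg: float, cutoff_deg: float = 30.0
) -> float:
    """Percent of histogram mass within ``cutoff_deg`` of the pattern angle."""
    if not 0.0 < cutoff_deg < 90.0:
        raise ValueError("cutoff_deg must lie in (0, 90)")
    diffs = axial_difference(hist.bin_centers_deg, wrap_axial(pattern_angle_deg))
    return 100.0 * float(hist.mass[diffs < cutoff_deg].sum())
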