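"""Multiscale Frangi vesselness with per-pixel ridge orientation.

The alignment statistic of the screening method: a neurite-only image is
filtered with the 2D Frangi vesselness filter at several Gaussian scales;
every pixel whose vesselness likelihood surpasses a threshold contributes
its local ridge orientation, and the alignment percentage is the share of
those pixels whose axial orientation lies within a cutoff (default 30
degrees) of the substrate pattern direction.  Under an isotropic neurite
distribution this percentage is 60/180 = 33.3%.

Vesselness follows the 2D formulation for bright curvilinear structures on
a dark background: with Hessian eigenvalues ordered |l1| <= |l2|,

    V = exp(-R_B^2 / (2 beta^2)) * (1 - exp(-S^2 / (2 c^2))),   l2 < 0
    V = 0,                                                      l2 >= 0

where R_B = |l1|/|l2| penalises blob-like structure and S = sqrt(l1^2+l2^2)
(the Frobenius norm) penalises low contrast.  The Hessian is computed from
Gaussian derivatives and scale-normalised by sigma^2; the ridge direction
is the eigenvector belonging to l1 (the low-curvature, along-ridge axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ._angles import angle_from_vector, axial_difference, wrap_axial

__all__ = [
    "OrientationField",
    "AlignmentResult",
    "frangi_vesselness",
    "alignment_fraction",
    "axial_difference",
    "DEFAULT_SCALES",
    "DEFAULT_BETA",
    "DEFAULT_VESSELNESS_THRESHOLD",
]

DEFAULT_SCALES = (1.0, 1.5, 2.0, 3.0)  # px; neurites render 2-4 px wide
DEFAULT_BETA = 0.5
DEFAULT_VESSELNESS_THRESHOLD = 0.15


@dataclass
class OrientationField:
    """Per-pixel ridge orientation and vesselness likelihood.

    ``orientation_deg`` is the axial along-ridge angle in [-90, 90),
    NaN where no meaningful direction exists (degenerate Hessian or zero
    vesselness).  ``scale_of_max`` is the sigma giving the maximal
    response at each pixel.
    """

    orientation_deg: np.ndarray
    vesselness: np.ndarray
    scale_of_max: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.vesselness.shape

    def support_mask(self, threshold: float) -> np.ndarray:
        """Pixels whose likelihood surpasses ``threshold`` and carry a direction."""
        return (self.vesselness > threshold) & np.isfinite(self.orientation_deg)


@dataclass
class AlignmentResult:
    percent_aligned: float  # NaN when undefined (empty support)
    n_support_pixels: int
    pattern_angle_deg: float
    cutoff_deg: float

    @property
    def defined(self) -> bool:
        return self.n_support_pixels > 0


def _hessian_eigensystem(image: np.ndarray, sigma: float):
    """Scale-normalised Hessian eigenvalues (|l1|<=|l2|) and l1-eigenvector."""
    s2 = sigma * sigma
    h_rr = s2 * gaussian_filter(image, sigma, order=(2, 0))
    h_rc = s2 * gaussian_filter(image, sigma, order=(1, 1))
    h_cc = s2 * gaussian_filter(image, sigma, order=(0, 2))

    half_trace = 0.5 * (h_rr + h_cc)
    disc = np.sqrt(0.25 * (h_rr - h_cc) ** 2 + h_rc**2)
    mu_hi = half_trace + disc
    mu_lo = half_trace - disc
    swap = np.abs(mu_hi) >= np.abs(mu_lo)
    l1 = np.where(swap, mu_lo, mu_hi)  # smaller magnitude
    l2 = np.where(swap, mu_hi, mu_lo)  # larger magnitude

    # eigenvector of l1: (h_rc, l1 - h_rr), falling back to (l1 - h_cc, h_rc)
    v_r = h_rc.copy()
    v_c = l1 - h_rr
    norm = np.hypot(v_r, v_c)
    alt_r = l1 - h_cc
    alt_c = h_rc
    alt_norm = np.hypot(alt_r, alt_c)
    use_alt = alt_norm > norm
    v_r = np.where(use_alt, alt_r, v_r)
    v_c = np.where(use_alt, alt_c, v_c)
    norm = np.maximum(norm, alt_norm)
    degenerate = norm <= 1e-12 * np.maximum(np.abs(l2), 1e-300)
    return l1, l2, v_r, v_c, degenerate


def frangi_vesselness(
    image: np.ndarray,
    scales=DEFAULT_SCALES,
    beta: float = DEFAULT_BETA,
    c: float | None = None,
    dark_ridges: bool = False,
) -> OrientationField:
    """Multiscale Frangi filter returning vesselness and ridge orientation.

    Parameters
    ----------
    image
        2D intensity raster (finite values).
    scales
        Gaussian sigmas in pixels; the response is maximised per pixel
        over scales and the orientation taken at the maximising scale.
    beta
        Blobness sensitivity of the R_B term.
    c
        Structureness sensitivity.  ``None`` (default) adapts per scale to
        half the maximum Frobenius norm S observed at that scale.
    dark_ridges
        Detect dark ridges on bright background instead (image negated).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("image must be 2D")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    scales = tuple(float(s) for s in np.atleast_1d(scales))
    if not scales:
        raise ValueError("scales must be nonempty")
    if any(s <= 0 for s in scales):
        raise ValueError("all scales must be > 0")
    if beta <= 0 or (c is not None and c <= 0):
        raise ValueError("beta and c must be > 0")
    if dark_ridges:
        image = -image
    # the truncated derivative-of-Gaussian kernels do not sum exactly to
    # zero; removing the DC level keeps constant images exactly flat
    image = image - image.mean()

    best_v = np.zeros(image.shape, dtype=float)
    best_angle = np.full(image.shape, np.nan)
    best_scale = np.full(image.shape, np.nan)
    for sigma in scales:
        l1, l2, v_r, v_c, degenerate = _hessian_eigensystem(image, sigma)
        with np.errstate(divide="ignore", invalid="ignore"):
            rb2 = np.where(l2 != 0, (l1 / l2) ** 2, 0.0)
        s_norm = np.hypot(l1, l2)
        s_max = float(s_norm.max())
        if s_max <= 1e-9 * max(1.0, float(np.abs(image).max())):
            continue  # numerically flat at this scale
        c_eff = c if c is not None else 0.5 * s_max
        v = np.exp(-rb2 / (2.0 * beta**2)) * (1.0 - np.exp(-(s_norm**2) / (2.0 * c_eff**2)))
        v = np.where(l2 < 0, v, 0.0)  # bright ridge: strong negative curvature
        angle = angle_from_vector(v_r, v_c)
        angle = np.where(degenerate, np.nan, angle)
        take = v > best_v
        best_angle = np.where(take, angle, best_angle)
        best_scale = np.where(take, sigma, best_scale)
        best_v = np.where(take, v, best_v)
    best_angle = np.where(best_v > 0, best_angle, np.nan)
    return OrientationField(
        orientation_deg=best_angle, vesselness=best_v, scale_of_max=best_scale
    )


def alignment_fraction(
    field: OrientationField,
    threshold: float = DEFAULT_VESSELNESS_THRESHOLD,
    restrict_mask: np.ndarray | None = None,
    pattern_angle_deg: float = 0.0,
    cutoff_deg: float = 30.0,
) -> AlignmentResult:
    """Percentage of supra-threshold pixels aligned with the pattern.

    A pixel counts as aligned when the axial difference between its ridge
    orientation and ``pattern_angle_deg`` is strictly below ``cutoff_deg``.
    An empty support yields a result with ``percent_aligned`` NaN and
    ``defined`` False.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if not 0.0 < cutoff_deg < 90.0:
        raise ValueError("cutoff_deg must lie in (0, 90)")
    support = field.support_mask(threshold)
    if restrict_mask is not None:
        if restrict_mask.shape != support.shape:
            raise ValueError("restrict_mask shape mismatch")
        support = support & restrict_mask.astype(bool)
    n = int(support.sum())
    pattern = float(wrap_axial(pattern_angle_deg))
    if n == 0:
        return AlignmentResult(float("nan"), 0, pattern, cutoff_deg)
    diffs = axial_difference(field.orientation_deg[support], pattern)
    percent = 100.0 * float(np.mean(diffs < cutoff_deg))
    return AlignmentResult(percent, n, pattern, cutoff_deg)
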