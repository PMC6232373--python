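"""Substrate identity: nanogroove notation and pattern-angle estimation.

Substrates are named ``DxxxLyyy`` where the D-value is the pattern period
in nm (one groove + ridge repeat) and the L-value the ridge width in nm;
the groove width is the period minus the ridge width, and L/D is the
ridge-to-period ratio.  Flat controls (``FLAT_PDMS``, ``FLAT_PS``) carry a
conventional pattern angle of 0 degrees.  For grooved substrates the
groove direction is estimated from a reference image of the pattern edge
via the Fourier directionality histogram; a manual angle always takes
precedence when supplied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from ._angles import axial_difference, wrap_axial
from .directionality import DEFAULT_N_BINS, directionality_histogram, spectral_samples
from .errors import AngleEstimationError, PatternNameError

__all__ = [
    "PatternSpec",
    "parse_pattern_name",
    "derive_pattern_metrics",
    "estimate_pattern_angle",
    "FLAT_NAMES",
]

FLAT_NAMES = ("FLAT_PDMS", "FLAT_PS")
_GROOVE_RE = re.compile(r"^D(\d+)L(\d+)$")


@dataclass(frozen=True)
class PatternSpec:
    """Identity and geometry of one substrate."""

    name: str
    period_nm: int | None  # None for flat substrates
    ridge_nm: int | None
    pattern_angle_deg: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.pattern_angle_deg < 90.0:
            raise ValueError("pattern_angle_deg must lie in [-90, 90)")
        if self.is_flat:
            if self.pattern_angle_deg != 0.0:
                raise ValueError("flat substrates carry the conventional angle 0")
        else:
            derive_pattern_metrics(self.period_nm, self.ridge_nm)  # validates

    @property
    def is_flat(self) -> bool:
        return self.period_nm is None

    @property
    def groove_nm(self) -> int | None:
        if self.is_flat:
            return None
        return self.period_nm - self.ridge_nm

    @property
    def ridge_period_ratio(self) -> float | None:
        if self.is_flat:
            return None
        return self.ridge_nm / self.period_nm

    @classmethod
    def from_name(cls, name: str, pattern_angle_deg: float = 0.0) -> "PatternSpec":
        parsed = parse_pattern_name(name)
        if parsed is None:
            return cls(name=name.upper(), period_nm=None, ridge_nm=None, pattern_angle_deg=0.0)
        period, ridge = parsed
        return cls(name=name, period_nm=period, ridge_nm=ridge, pattern_angle_deg=pattern_angle_deg)


def parse_pattern_name(name: str) -> tuple[int, int] | None:
    """Parse ``DxxxLyyy`` into (period_nm, ridge_nm); flat names give None.

    >>> parse_pattern_name("D450L180")
    (450, 180)
    """
    if not isinstance(name, str):
        raise PatternNameError("pattern name must be a string")
    if name.upper() in FLAT_NAMES or name.upper() == "FLAT":
        return None
    m = _GROOVE_RE.match(name)
    if not m:
        raise PatternNameError(
            f"malformed pattern name {name!r}: expected 'D<period_nm>L<ridge_nm>' "
            f"(e.g. D450L180) or one of {FLAT_NAMES}"
        )
    return int(m.group(1)), int(m.group(2))


def derive_pattern_metrics(period_nm: int, ridge_nm: int) -> tuple[int, float]:
    """Groove width (period minus ridge) and ridge-to-period ratio L/D."""
    if not 0 < ridge_nm < period_nm:
        raise PatternNameError(
            f"ridge width must satisfy 0 < L < D, got L={ridge_nm}, D={period_nm}"
        )
    return period_nm - ridge_nm, ridge_nm / period_nm


def estimate_pattern_angle(
    reference_image: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    dominance: float = 2.0,
) -> float:
    """Groove direction (deg in [-90, 90)) from a pattern-edge image.

    The modal bin of the directionality histogram locates the direction
    coarsely; it is then refined to sub-bin precision by a power-weighted
    axial (period-180) circular mean over the spectral samples within one
    bin width of the mode, which avoids the angular quantisation of the
    coarse frequency samples.  When the peak mass is below ``dominance``
    times the uniform level the image has no dominant direction and
    estimation fails, prompting manual entry.
    """
    hist = directionality_histogram(reference_image, n_bins=n_bins)
    mass = hist.mass
    k = int(np.argmax(mass))
    uniform = 1.0 / hist.n_bins
    if mass[k] < dominance * uniform:
        raise AngleEstimationError(
            f"no dominant direction: peak mass {mass[k]:.4f} is below "
            f"{dominance:.1f}x the uniform level {uniform:.4f}; supply a manual angle"
        )
    angles, power = spectral_samples(reference_image)
    centre = float(hist.bin_centers_deg[k])
    window = 2.0 * hist.bin_width_deg
    # the modal bin can sit a bin edge away from the true peak; one
    # re-centring pass removes the window-truncation bias
    for _ in range(2):
        near = axial_difference(angles, centre) <= window
        two_theta = np.deg2rad(2.0 * angles[near])
        w = power[near]
        centre = 0.5 * np.degrees(
            np.arctan2(np.sum(w * np.sin(two_theta)), np.sum(w * np.cos(two_theta)))
        )
    return float(wrap_axial(centre))
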