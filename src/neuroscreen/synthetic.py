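"""Seeded generator of synthetic neuronal-culture micrographs with ground truth.

Emulates 10x-objective epifluorescence images of sparse differentiated
SH-SY5Y-like cultures on (nano)patterned substrates: blob-like somata with
nuclei, thin curvilinear neurites rendered as Gaussian-profile ridges,
optional branching, Poisson shot noise plus Gaussian read noise, and an
uneven background.  Neurite orientations follow a two-component mixture —
an isotropic component and a wrapped-normal component concentrated around
the pattern direction — so that the true aligned fraction of every scene
is known exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._angles import angle_from_vector, axial_difference, wrap_axial
from .containers import ChannelStack, DEFAULT_PIXEL_SIZE_UM
from .errors import GenerationError

__all__ = [
    "SceneSpec",
    "NeuriteTruth",
    "GroundTruth",
    "sample_orientations",
    "generate_culture_image",
    "generate_neurite_field",
    "generate_reference_edge_image",
    "save_scene",
]

ALIGNMENT_CUTOFF_DEG = 30.0


@dataclass
class SceneSpec:
    """Parameters of one synthetic culture scene.

    Defaults describe a sparse differentiated culture imaged at 10x:
    a 384x384 crop at 0.65 um/px (~250 um field) holding a handful of
    well-separated cells (sparse, as after low-density seeding and
    differentiation), neurites a few tens of micrometres long and
    2-4 px wide after rendering.
    """

    image_shape: tuple[int, int] = (384, 384)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_cells: int = 8
    soma_radius_um: tuple[float, float] = (6.0, 1.0)  # mean, sd
    neurites_per_cell_probs: tuple[float, ...] = (0.15, 0.30, 0.35, 0.20)  # P(0,1,2,3+)
    neurite_length_um: tuple[float, float] = (45.0, 10.0)  # mean, sd
    branch_prob: float = 0.15
    pattern_angle_deg: float = 0.0
    aligned_fraction: float = 0.0
    concentration_deg: float = 5.0
    curvature_step_deg: float = 5.0
    poisson_gain: float = 1.0
    read_noise_sd: float = 2.0
    background_level: float = 8.0

    def __post_init__(self) -> None:
        probs = np.asarray(self.neurites_per_cell_probs, dtype=float)
        if probs.ndim != 1 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("neurites_per_cell_probs must be nonnegative and sum to 1")
        if not 0.0 <= self.aligned_fraction <= 1.0:
            raise ValueError("aligned_fraction must lie in [0, 1]")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must lie in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not -90.0 <= self.pattern_angle_deg < 90.0:
            raise ValueError("pattern_angle_deg must lie in [-90, 90)")


@dataclass
class NeuriteTruth:
    cell_index: int
    polyline: np.ndarray  # (N, 2) float (row, col) px, soma boundary -> tip
    chord_angle_deg: float
    arc_length_um: float
    branch_count: int
    branch_polylines: list = field(default_factory=list)


@dataclass
class GroundTruth:
    cells: list  # list of ((row, col) centroid px, soma radius px)
    neurites: list  # list of NeuriteTruth
    pattern_angle_deg: float
    true_aligned_fraction: float

    def __post_init__(self) -> None:
        for nt in self.neurites:
            if not 0 <= nt.cell_index < len(self.cells):
                raise ValueError("neurite references a nonexistent cell")
        if self.neurites and not 0.0 <= self.true_aligned_fraction <= 1.0:
            raise ValueError("true_aligned_fraction must lie in [0, 1]")


def sample_orientations(
    n: int,
    aligned_fraction: float,
    pattern_angle_deg: float,
    concentration_deg: float,
    seed,
) -> np.ndarray:
    """Draw axial neurite orientations from the isotropic/aligned mixture.

    With probability ``aligned_fraction`` an angle comes from a wrapped
    normal (sd ``concentration_deg``) around the pattern direction, treated
    axially (180-degree periodic); otherwise it is uniform on [-90, 90).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if concentration_deg <= 0:
        raise ValueError("concentration_deg must be > 0")
    if not 0.0 <= aligned_fraction <= 1.0:
        raise ValueError("aligned_fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from_aligned = rng.random(n) < aligned_fraction
    angles = rng.uniform(-90.0, 90.0, size=n)
    n_aligned = int(from_aligned.sum())
    if n_aligned:
        angles[from_aligned] = wrap_axial(
            rng.normal(pattern_angle_deg, concentration_deg, size=n_aligned)
        )
    return angles


# ---------------------------------------------------------------------------
# rendering helpers


def _splat_polyline(canvas: np.ndarray, polyline: np.ndarray, step: float = 0.3) -> None:
    """Deposit unit line density along a polyline with bilinear splatting."""
    pts = np.asarray(polyline, dtype=float)
    if len(pts) < 2:
        return
    seg = np.diff(pts, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    total = seg_len.sum()
    if total <= 0:
        return
    n_samples = max(int(np.ceil(total / step)), 2)
    # arc-length parameterisation
    t = np.linspace(0.0, total, n_samples)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    rows = np.interp(t, cum, pts[:, 0])
    cols = np.interp(t, cum, pts[:, 1])
    weight = total / n_samples  # deposit = arc length, so density is 1/px
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    h, w = canvas.shape
    for dr, dc, wgt in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        np.add.at(canvas, (rr[ok], cc[ok]), weight * wgt[ok])


def _render_lines(shape, polylines, ridge_sigma_px: float, amplitude: float) -> np.ndarray:
    """Render polylines as Gaussian-profile ridges of peak ``amplitude``."""
    canvas = np.zeros(shape, dtype=float)
    for pl in polylines:
        _splat_polyline(canvas, pl)
    canvas = gaussian_filter(canvas, ridge_sigma_px)
    # a unit-density line blurred by a Gaussian peaks at 1/(sqrt(2*pi)*sigma)
    return canvas * (amplitude * np.sqrt(2.0 * np.pi) * ridge_sigma_px)


def _render_blobs(shape, centers, sigmas, amplitude: float) -> np.ndarray:
    canvas = np.zeros(shape, dtype=float)
    h, w = shape
    for (r, c), s in zip(centers, sigmas):
        ext = int(np.ceil(4 * s))
        r0, r1 = max(int(r) - ext, 0), min(int(r) + ext + 1, h)
        c0, c1 = max(int(c) - ext, 0), min(int(c) + ext + 1, w)
        if r0 >= r1 or c0 >= c1:
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        canvas[r0:r1, c0:c1] += amplitude * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * s**2)
        )
    return canvas


def _apply_noise(clean: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    g = max(spec.poisson_gain, 1e-9)
    noisy = g * rng.poisson(np.clip(clean, 0, None) / g).astype(float)
    noisy += rng.normal(0.0, spec.read_noise_sd, size=clean.shape)
    return np.clip(noisy, 0.0, None)


def _uneven_background(shape, level: float, rng: np.random.Generator) -> np.ndarray:
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    slope_r, slope_c = rng.uniform(-0.25, 0.25, size=2)
    plane = 1.0 + slope_r * (rr / max(h - 1, 1) - 0.5) + slope_c * (cc / max(w - 1, 1) - 0.5)
    return level * np.clip(plane, 0.0, None)


def _walk_polyline(
    start: np.ndarray,
    heading_deg: float,
    length_px: float,
    curvature_step_deg: float,
    shape,
    rng: np.random.Generator,
    step_px: float = 1.5,
) -> np.ndarray:
    """Bounded-turn random walk; truncated at the image boundary."""
    h, w = shape
    pts = [start.copy()]
    pos = start.copy()
    heading = heading_deg
    travelled = 0.0
    while travelled < length_px:
        step = min(step_px, length_px - travelled)
        rad = np.deg2rad(heading)
        pos = pos + step * np.array([-np.sin(rad), np.cos(rad)])
        if not (1.0 <= pos[0] <= h - 2.0 and 1.0 <= pos[1] <= w - 2.0):
            break
        pts.append(pos.copy())
        travelled += step
        heading += rng.uniform(-curvature_step_deg, curvature_step_deg)
    return np.asarray(pts)


def _polyline_length(pl: np.ndarray) -> float:
    if len(pl) < 2:
        return 0.0
    seg = np.diff(pl, axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def _place_somata(spec: SceneSpec, rng: np.random.Generator):
    h, w = spec.image_shape
    mean_r_px = spec.soma_radius_um[0] / spec.pixel_size_um
    margin = 2.0 * mean_r_px
    if spec.n_cells > 0 and (h <= 2 * margin or w <= 2 * margin):
        raise GenerationError(
            f"image {spec.image_shape} too small to place a soma of mean radius "
            f"{mean_r_px:.1f} px with margin {margin:.1f} px"
        )
    min_sep = 5.0 * mean_r_px
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < spec.n_cells:
        attempts += 1
        if attempts > 2000:
            raise GenerationError(
                f"could not place {spec.n_cells} somata with separation "
                f"{min_sep:.1f} px in a {spec.image_shape} image"
            )
        cand = np.array([rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)])
        if all(np.hypot(*(cand - c)) >= min_sep for c in centers):
            centers.append(cand)
    radii = np.clip(
        rng.normal(spec.soma_radius_um[0], spec.soma_radius_um[1], size=spec.n_cells),
        0.5 * spec.soma_radius_um[0],
        2.0 * spec.soma_radius_um[0],
    ) / spec.pixel_size_um
    return centers, radii


def _pick_emanation_side(axial_deg: float, chosen_dirs: list[float]) -> float:
    """Pick theta or theta+180 so neurites of one cell spread apart."""
    cands = [axial_deg % 360.0, (axial_deg + 180.0) % 360.0]
    if not chosen_dirs:
        return cands[0]

    def min_sep(d):
        return min(
            min(abs((d - e + 180.0) % 360.0 - 180.0) for e in chosen_dirs) for _ in (0,)
        )

    return max(cands, key=min_sep)


def generate_culture_image(spec: SceneSpec, seed) -> tuple[ChannelStack, GroundTruth]:
    """Render one three-channel culture scene and its exact ground truth."""
    rng = np.random.default_rng(seed)
    shape = tuple(spec.image_shape)
    centers, radii = _place_somata(spec, rng)

    n_choices = np.arange(len(spec.neurites_per_cell_probs))
    neurites: list[NeuriteTruth] = []
    main_polylines: list[np.ndarray] = []
    branch_polylines: list[np.ndarray] = []
    for idx, (center, radius) in enumerate(zip(centers, radii)):
        n_neur = int(rng.choice(n_choices, p=spec.neurites_per_cell_probs))
        axials = sample_orientations(
            n_neur, spec.aligned_fraction, spec.pattern_angle_deg, spec.concentration_deg, rng
        )
        chosen_dirs: list[float] = []
        for ax in axials:
            direction = _pick_emanation_side(float(ax), chosen_dirs)
            if chosen_dirs and rng.random() < 0.5 and len(chosen_dirs) == 1:
                # bipolar cells often extend opposite processes; keep the spread
                pass
            chosen_dirs.append(direction)
            rad = np.deg2rad(direction)
            start = center + (radius + 1.0) * np.array([-np.sin(rad), np.cos(rad)])
            length_um = max(rng.normal(*spec.neurite_length_um), 10.0)
            pl = _walk_polyline(
                start,
                direction,
                length_um / spec.pixel_size_um,
                spec.curvature_step_deg,
                shape,
                rng,
            )
            if len(pl) < 4:
                continue
            branch_count = 0
            branches: list[np.ndarray] = []
            if rng.random() < spec.branch_prob:
                at = rng.integers(len(pl) // 3, 2 * len(pl) // 3 + 1)
                base_heading = angle_from_vector(*(pl[min(at + 1, len(pl) - 1)] - pl[at - 1]))
                side = rng.choice([-1.0, 1.0])
                b_heading = base_heading + side * rng.uniform(30.0, 55.0)
                b_len = 0.45 * _polyline_length(pl[at:])
                bpl = _walk_polyline(
                    pl[at].copy(), b_heading, max(b_len, 6.0), spec.curvature_step_deg, shape, rng
                )
                if len(bpl) >= 4:
                    branch_count = 1
                    branches.append(bpl)
            chord = pl[-1] - pl[0]
            neurites.append(
                NeuriteTruth(
                    cell_index=idx,
                    polyline=pl,
                    chord_angle_deg=angle_from_vector(chord[0], chord[1]),
                    arc_length_um=_polyline_length(pl) * spec.pixel_size_um,
                    branch_count=branch_count,
                    branch_polylines=branches,
                )
            )
            main_polylines.append(pl)
            branch_polylines.extend(branches)

    # --- render channels ------------------------------------------------
    ridge_sigma = 1.0  # px; FWHM ~2.4 px, matching thin neurites at 10x
    neurite_canvas = _render_lines(shape, main_polylines + branch_polylines, ridge_sigma, 60.0)
    soma_sigmas = 0.60 * radii if len(radii) else radii
    nuclei = _render_blobs(shape, centers, 0.45 * radii if len(radii) else radii, 150.0)
    soma_blob = _render_blobs(shape, centers, soma_sigmas, 120.0)
    tubulin = soma_blob + neurite_canvas
    actin = _render_blobs(shape, centers, soma_sigmas, 140.0) + 0.35 * neurite_canvas

    stacks = {}
    for name, clean in (("nuclei", nuclei), ("actin", actin), ("tubulin", tubulin)):
        clean = clean + _uneven_background(shape, spec.background_level, rng)
        stacks[name] = _apply_noise(clean, spec, rng)

    stack = ChannelStack(
        nuclei=stacks["nuclei"],
        actin=stacks["actin"],
        tubulin=stacks["tubulin"],
        pixel_size_um=spec.pixel_size_um,
    )
    if neurites:
        aligned = [
            axial_difference(nt.chord_angle_deg, spec.pattern_angle_deg) < ALIGNMENT_CUTOFF_DEG
            for nt in neurites
        ]
        frac = float(np.mean(aligned))
    else:
        frac = 0.0
    truth = GroundTruth(
        cells=[(tuple(c), float(r)) for c, r in zip(centers, radii)],
        neurites=neurites,
        pattern_angle_deg=spec.pattern_angle_deg,
        true_aligned_fraction=frac,
    )
    return stack, truth


def generate_neurite_field(
    n_neurites: int,
    shape: tuple[int, int],
    seed,
    aligned_fraction: float = 0.0,
    pattern_angle_deg: float = 0.0,
    concentration_deg: float = 5.0,
    length_px: float = 60.0,
    amplitude: float = 60.0,
    ridge_sigma_px: float = 1.0,
    background_level: float = 2.0,
    read_noise_sd: float = 1.0,
    angles: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a neurite-only image of straight Gaussian-profile segments.

    Segment centres are placed so every segment lies fully inside the
    frame (no angle-dependent boundary clipping), which keeps the pixel
    mass per neurite independent of its orientation.  Returns the image
    and the array of true chord angles.
    """
    rng = np.random.default_rng(seed)
    if angles is None:
        angles = sample_orientations(
            n_neurites, aligned_fraction, pattern_angle_deg, concentration_deg, rng
        )
    else:
        angles = np.asarray(angles, dtype=float)
    h, w = shape
    half = length_px / 2.0 + 2.0
    if h <= 2 * half or w <= 2 * half:
        raise GenerationError("image too small for the requested neurite length")
    polylines = []
    for ang in angles:
        center = np.array([rng.uniform(half, h - half), rng.uniform(half, w - half)])
        rad = np.deg2rad(ang)
        d = np.array([-np.sin(rad), np.cos(rad)])
        polylines.append(np.vstack([center - d * length_px / 2, center + d * length_px / 2]))
    img = _render_lines(shape, polylines, ridge_sigma_px, amplitude) + background_level
    img = rng.poisson(np.clip(img, 0, None)).astype(float)
    img += rng.normal(0.0, read_noise_sd, size=shape)
    return np.clip(img, 0.0, None), angles


def generate_reference_edge_image(
    angle_deg: float,
    shape: tuple[int, int] = (256, 256),
    seed=0,
    stripe_width_px: float = 1.5,
    amplitude: float = 120.0,
    background_level: float = 10.0,
    read_noise_sd: float = 2.0,
) -> np.ndarray:
    """Render a high-contrast straight stripe (pattern edge) at ``angle_deg``.

    Stands in for the photograph of the pattern edge used to measure the
    groove direction of each substrate.
    """
    if not -90.0 <= angle_deg < 90.0:
        raise ValueError("angle_deg must lie in the axial interval [-90, 90)")
    rng = np.random.default_rng(seed)
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    cr, ccol = (h - 1) / 2.0, (w - 1) / 2.0
    rad = np.deg2rad(angle_deg)
    # signed distance to the centre line along the stripe direction
    d = -np.sin(rad) * (cc - ccol) - np.cos(rad) * (rr - cr)
    clean = background_level + amplitude * np.exp(-(d**2) / (2.0 * stripe_width_px**2))
    img = rng.poisson(clean).astype(float) + rng.normal(0.0, read_noise_sd, size=shape)
    return np.clip(img, 0.0, None)


# ---------------------------------------------------------------------------
# persistence


def save_scene(
    directory, image_id: str, spec: SceneSpec, seed: int, stack: ChannelStack, truth: GroundTruth
) -> dict:
    """Write per-channel 16-bit TIFFs, a ground-truth CSV and a JSON sidecar."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in stack.channels().items():
        p = directory / f"{image_id}_{name}.tif"
        tifffile.imwrite(p, np.clip(arr, 0, 65535).astype(np.uint16))
        paths[name] = str(p)
    rows = [
        {
            "image_id": image_id,
            "cell_index": nt.cell_index,
            "chord_angle_deg": nt.chord_angle_deg,
            "arc_length_um": nt.arc_length_um,
            "branch_count": nt.branch_count,
            "n_points": len(nt.polyline),
        }
        for nt in truth.neurites
    ]
    gt_path = directory / f"{image_id}_truth.csv"
    pd.DataFrame(rows).to_csv(gt_path, index=False)
    sidecar = {
        "image_id": image_id,
        "seed": int(seed),
        "spec": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(spec).items()},
        "pattern_angle_deg": truth.pattern_angle_deg,
        "true_aligned_fraction": truth.true_aligned_fraction,
        "channels": paths,
    }
    json_path = directory / f"{image_id}_scene.json"
    json_path.write_text(json.dumps(sidecar, indent=2))
    return {"channels": paths, "truth_csv": str(gt_path), "sidecar": str(json_path)}
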