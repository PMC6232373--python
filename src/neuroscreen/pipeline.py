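"""Batch orchestration: manifest-driven screening of image sets.

Each image runs through detection -> neurite-only masking -> the three
alignment pathways (per-pixel vesselness, FFT directionality histogram,
and the per-neurite chord oracle that mirrors manual measurement), then
the per-image rows are grouped by substrate and fed to the statistics
layer.  Failures are isolated per image and logged, never aborting the
batch; the whole run is deterministic given config and seed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from ._angles import axial_difference, wrap_axial
from .containers import ChannelStack
from .detection import (
    DetectionParams,
    NeuriteRecord,
    ScreeningRecord,
    detect_neurites,
    neurite_only_image,
    segment_somata,
    summarize_image,
    trace_and_link,
)
from .directionality import DEFAULT_N_BINS, directionality_histogram, histogram_alignment
from .errors import ConfigError, DegenerateInputError
from .orientation import (
    DEFAULT_BETA,
    DEFAULT_SCALES,
    DEFAULT_VESSELNESS_THRESHOLD,
    alignment_fraction,
    frangi_vesselness,
)
from .patterns import PatternSpec, estimate_pattern_angle, parse_pattern_name
from .stats import derive_screening_variables, run_stats

__all__ = [
    "RunConfig",
    "ChordAlignment",
    "manual_chord_alignment",
    "analyze_stack",
    "run_batch",
    "load_channel_stack",
]


@dataclass
class RunConfig:
    """Every tunable of a batch run, serialisable to/from YAML."""

    manifest: str = ""
    output_dir: str = "neuroscreen_out"
    channel_suffixes: dict = field(
        default_factory=lambda: {"nuclei": "_nuclei.tif", "actin": "_actin.tif", "tubulin": "_tubulin.tif"}
    )
    pixel_size_um: float = 0.65
    detection: DetectionParams = field(default_factory=DetectionParams)
    vesselness_threshold: float = DEFAULT_VESSELNESS_THRESHOLD
    cutoff_deg: float = 30.0
    n_bins: int = DEFAULT_N_BINS
    aggregation: str = "image"  # or "substrate"
    dunn_adjust: str = "bonferroni"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff_deg < 90.0:
            raise ConfigError("cutoff_deg must lie in (0, 90)")
        if not 0.0 < self.vesselness_threshold < 1.0:
            raise ConfigError("vesselness_threshold must lie in (0, 1)")
        if self.aggregation not in ("image", "substrate"):
            raise ConfigError("aggregation must be 'image' or 'substrate'")
        if isinstance(self.detection, dict):
            self.detection = DetectionParams(**self.detection)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        det = data.pop("detection", None)
        cfg = cls(**data)
        if det is not None:
            det = {k: tuple(v) if isinstance(v, list) else v for k, v in det.items()}
            cfg.detection = DetectionParams(**det)
        return cfg


class ChordAlignment(NamedTuple):
    percent_aligned: float  # NaN when undefined
    n_neurites: int

    @property
    def defined(self) -> bool:
        return self.n_neurites > 0


def manual_chord_alignment(
    neurites: list[NeuriteRecord], pattern_angle_deg: float, cutoff_deg: float = 30.0
) -> ChordAlignment:
    """Per-neurite chord alignment, mirroring manual straight-line measurement.

    A neurite is aligned when the axial angle of the straight line from
    its start to its end differs from the pattern direction by strictly
    less than the cutoff; the percentage is over neurites, not pixels.
    """
    if not 0.0 < cutoff_deg < 90.0:
        raise ValueError("cutoff_deg must lie in (0, 90)")
    if not neurites:
        return ChordAlignment(float("nan"), 0)
    pattern = wrap_axial(pattern_angle_deg)
    aligned = [
        axial_difference(n.chord_angle_deg, pattern) < cutoff_deg for n in neurites
    ]
    return ChordAlignment(100.0 * float(np.mean(aligned)), len(neurites))


def analyze_stack(
    stack: ChannelStack,
    image_id: str,
    pattern_name: str,
    pattern_angle_deg: float,
    config: RunConfig | None = None,
) -> tuple[ScreeningRecord, dict]:
    """Full single-image analysis; returns the screening row and QC details."""
    cfg = config or RunConfig()
    det = cfg.detection
    soma_mask, _stubs = segment_somata(stack, det)
    skeleton = detect_neurites(stack, soma_mask, det)
    neurites, cells, qc = trace_and_link(skeleton, soma_mask, det, stack.pixel_size_um)
    record = summarize_image(cells, neurites, image_id, pattern_name)

    neurite_img = neurite_only_image(stack, soma_mask, skeleton, det)
    if np.any(neurite_img > 0):
        ofield = frangi_vesselness(neurite_img, scales=det.ridge_scales_px, beta=det.ridge_beta)
        ves = alignment_fraction(
            ofield,
            threshold=cfg.vesselness_threshold,
            pattern_angle_deg=pattern_angle_deg,
            cutoff_deg=cfg.cutoff_deg,
        )
        record.alignment_vesselness = ves.percent_aligned
        qc["n_support_pixels"] = ves.n_support_pixels
        try:
            hist = directionality_histogram(neurite_img, n_bins=cfg.n_bins)
            record.alignment_fft = histogram_alignment(hist, pattern_angle_deg, cfg.cutoff_deg)
        except DegenerateInputError:
            qc["fft_degenerate"] = True
    else:
        qc["empty_neurite_image"] = True
    chord = manual_chord_alignment(neurites, pattern_angle_deg, cfg.cutoff_deg)
    record.alignment_chord = chord.percent_aligned
    return record, qc


def load_channel_stack(base: str, config: RunConfig) -> ChannelStack:
    """Read the three per-channel TIFFs sharing a base path."""
    import tifffile

    arrays = {}
    for name, suffix in config.channel_suffixes.items():
        path = Path(base + suffix)
        if not path.exists():
            raise ConfigError(f"channel file not found: {path}")
        arrays[name] = tifffile.imread(path).astype(float)
    return ChannelStack(pixel_size_um=config.pixel_size_um, **arrays)


def _resolve_pattern_angles(manifest: pd.DataFrame, config: RunConfig) -> dict[str, float]:
    """Per-substrate groove angle: manual override > reference image > flat = 0."""
    angles: dict[str, float] = {}
    for pattern, sub in manifest.groupby("pattern_name"):
        manual = sub.get("manual_angle_deg")
        if manual is not None and manual.notna().any():
            angles[pattern] = float(manual.dropna().iloc[0])
            continue
        if parse_pattern_name(pattern) is None:  # flat control: conventional 0
            angles[pattern] = 0.0
            continue
        ref = sub.get("reference_image")
        ref_path = None
        if ref is not None and ref.notna().any():
            ref_path = ref.dropna().iloc[0]
        if not ref_path:
            raise ConfigError(
                f"grooved substrate {pattern!r} has neither a manual angle "
                f"nor a reference image in the manifest"
            )
        import tifffile

        angles[pattern] = estimate_pattern_angle(tifffile.imread(ref_path).astype(float))
    return angles


def run_batch(config: RunConfig):
    """Process every manifest row, derive variables, and run the statistics.

    Manifest CSV columns: ``image_id``, ``pattern_name``, ``image_base``
    (channel files are ``image_base + suffix``), optional
    ``reference_image`` and ``manual_angle_deg``.

    Returns ``(records_df, reports, qc_log)``.
    """
    manifest = pd.read_csv(config.manifest)
    required = {"image_id", "pattern_name", "image_base"}
    if not required.issubset(manifest.columns):
        raise ConfigError(f"manifest must contain columns {sorted(required)}")
    angles = _resolve_pattern_angles(manifest, config)

    records: list[ScreeningRecord] = []
    qc_log: dict[str, dict] = {"images": {}, "pattern_angles_deg": angles}
    for _, row in manifest.iterrows():
        image_id = str(row["image_id"])
        try:
            stack = load_channel_stack(str(row["image_base"]), config)
            rec, qc = analyze_stack(
                stack, image_id, str(row["pattern_name"]), angles[str(row["pattern_name"])], config
            )
            records.append(rec)
            qc_log["images"][image_id] = qc
        except Exception as exc:  # isolate per-image failures
            warnings.warn(f"image {image_id} failed: {exc}", stacklevel=2)
            qc_log["images"][image_id] = {"error": str(exc)}

    records_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    variables, var_qc = derive_screening_variables(records)
    qc_log["variables"] = var_qc
    if config.aggregation == "substrate":
        for var in variables.values():
            var.groups = {k: np.array([np.median(v)]) for k, v in var.groups.items()}
    reports = run_stats(variables, alpha=config.alpha, adjust=config.dunn_adjust)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records_df.to_csv(out_dir / "screening_records.csv", index=False)
    if reports:
        pd.concat(
            [r.dunn.assign(variable=r.variable) for r in reports], ignore_index=True
        ).to_csv(out_dir / "dunn_pairwise.csv", index=False)
        (out_dir / "stats_report.txt").write_text("\n\n".join(r.to_text() for r in reports))
    return records_df, reports, qc_log
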