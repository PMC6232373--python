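"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConsistencyError

DEFAULT_PIXEL_SIZE_UM = 0.65  # plausible calibration for a 10x objective


@dataclass
class ChannelStack:
    """One field of view: per-channel 2D intensity rasters plus pixel size.

    Channels follow the standard triple staining of differentiated
    neuronal cultures: nuclear counterstain, F-actin, and beta-Tubulin III
    (the neuron-specific cytoskeletal marker used for neurite detection).
    """

    nuclei: np.ndarray
    actin: np.ndarray
    tubulin: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.nuclei = np.asarray(self.nuclei, dtype=float)
        self.actin = np.asarray(self.actin, dtype=float)
        self.tubulin = np.asarray(self.tubulin, dtype=float)
        if not (self.nuclei.shape == self.actin.shape == self.tubulin.shape):
            raise ConsistencyError("all channels must share the same shape")
        if self.nuclei.ndim != 2:
            raise ConsistencyError("channels must be 2D rasters")
        for name in ("nuclei", "actin", "tubulin"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ConsistencyError(f"channel {name!r} contains non-finite values")
            if np.any(arr < 0):
                raise ConsistencyError(f"channel {name!r} contains negative intensities")
        if self.pixel_size_um <= 0:
            raise ConsistencyError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nuclei.shape

    def channels(self) -> dict[str, np.ndarray]:
        return {"nuclei": self.nuclei, "actin": self.actin, "tubulin": self.tubulin}
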