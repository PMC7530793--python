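"""In-memory containers for acquired and unmixed multichannel images.

A :class:`MultichannelImage` holds the raw filter-channel planes exactly as
an epifluorescence scanner would deliver them: one plane per acquisition
channel, each integrated over that channel's exposure time.  A
:class:`UnmixedImage` holds the per-fluorophore abundance planes produced by
spectral unmixing, expressed in exposure-normalized "counts", together with
the autofluorescence plane and a per-pixel reconstruction-residual plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["MultichannelImage", "UnmixedImage"]


@dataclass
class MultichannelImage:
    """Raw acquisition: ``planes[c]`` is the image for ``channel_names[c]``."""

    planes: np.ndarray  # (C, H, W)
    channel_names: list[str]
    exposures_ms: dict[str, float]

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=float)
        if self.planes.ndim != 3:
            raise ConfigurationError("planes must be a (C, H, W) array")
        if self.planes.shape[0] != len(self.channel_names):
            raise ConfigurationError("one plane per channel name required")
        missing = [c for c in self.channel_names if c not in self.exposures_ms]
        if missing:
            raise ConfigurationError(f"missing exposure for channels: {missing}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    @property
    def exposure_vector(self) -> np.ndarray:
        return np.array([self.exposures_ms[c] for c in self.channel_names], dtype=float)


@dataclass
class UnmixedImage:
    """Per-fluorophore abundance planes in counts, plus AF and residual."""

    abundances: dict[str, np.ndarray]  # fluorophore -> (H, W), counts
    autofluorescence: np.ndarray  # (H, W), counts
    residual: np.ndarray  # (H, W), per-pixel reconstruction error norm (counts)
    excluded: bool = False
    exclusion_reason: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.autofluorescence.shape
        for name, plane in self.abundances.items():
            if plane.shape != shape:
                raise ConfigurationError(f"abundance plane {name!r} has mismatched shape")
        if self.residual.shape != shape:
            raise ConfigurationError("residual plane has mismatched shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.autofluorescence.shape

    def plane(self, fluorophore: str) -> np.ndarray:
        return self.abundances[fluorophore]
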