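"""The three-channel acquisition container shared by generator and pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelStack"]


@dataclass
class ChannelStack:
    """Donor (CFP), acceptor (YFP) and FRET-channel image stacks.

    Arrays are either (z, rows, cols) raw stacks or (rows, cols) after
    projection.  ``invalid`` flags pixels excluded from all statistics
    (e.g. saturated detectors); ``meta`` carries provenance such as the
    generating photophysics parameters or preprocessing settings.
    """

    cfp: np.ndarray
    yfp: np.ndarray
    fret: np.ndarray
    bit_depth: int = 16
    pixel_size: float = 0.2
    invalid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.cfp.shape == self.yfp.shape == self.fret.shape):
            raise ValueError("cfp/yfp/fret shapes differ")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")
        for name in ("cfp", "yfp", "fret"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} contains negative counts")

    @property
    def saturation_level(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def is_projected(self) -> bool:
        return self.cfp.ndim == 2

    @property
    def n_slices(self) -> int:
        return 1 if self.is_projected else self.cfp.shape[0]

    def channels(self) -> dict[str, np.ndarray]:
        return {"cfp": self.cfp, "yfp": self.yfp, "fret": self.fret}
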