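"""Multi-channel single-cell image container.

Axis convention: channel first, spatial axes (z, y, x) for 3D or (y, x)
for 2D, 0-based indices.  Channel semantics are carried by name; the
canonical order is (MEMB, NUC[, STRUCT]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MEMB, NUC, STRUCT = "MEMB", "NUC", "STRUCT"
REFERENCE_CHANNELS = (MEMB, NUC)


@dataclass
class CellImage:
    """Intensity array plus channel semantics and pixel/voxel size."""

    data: np.ndarray  # (C, *spatial), float32, values in [0, 1]
    channel_names: tuple = REFERENCE_CHANNELS
    pixel_size: float = 1.0  # isotropic, microns per pixel/voxel
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim not in (3, 4):
            raise ValueError("data must be (C, y, x) or (C, z, y, x)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} channels but "
                f"{len(self.channel_names)} channel names"
            )

    @property
    def is_3d(self) -> bool:
        return self.data.ndim == 4

    @property
    def dimensionality(self) -> int:
        return self.data.ndim - 1

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[1:]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channel_names.index(name)]
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None

    def reference(self) -> np.ndarray:
        """(2, *spatial) stack of the membrane and nucleus channels."""
        return np.stack([self.channel(MEMB), self.channel(NUC)])

    def with_channel(self, name: str, channel: np.ndarray) -> "CellImage":
        """Copy of this image with one channel replaced (or appended)."""
        channel = np.asarray(channel, dtype=np.float32)
        if channel.shape != self.spatial_shape:
            raise ValueError("channel shape mismatch")
        if name in self.channel_names:
            data = self.data.copy()
            data[self.channel_names.index(name)] = channel
            return CellImage(data, self.channel_names, self.pixel_size, dict(self.meta))
        data = np.concatenate([self.data, channel[None]])
        return CellImage(
            data, self.channel_names + (name,), self.pixel_size, dict(self.meta)
        )
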