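"""Multi-channel image container with physical pixel calibration.

Every image statistic in the package consumes an :class:`ImageScene`: a
``(z, channel, y, x)`` intensity array plus the pixel size in nanometres.
2D single-channel data are accepted and promoted to singleton z/channel
axes so downstream code never branches on dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default pixel size in nm: a 106.3 µm confocal field imaged at 512×512 px.
DEFAULT_PIXEL_SIZE_NM = 106_300.0 / 512


@dataclass
class ImageScene:
    """A calibrated fluorescence image stack.

    Parameters
    ----------
    data : ndarray
        Intensity array. Accepted shapes: ``(y, x)``, ``(channel, y, x)``
        or ``(z, channel, y, x)``; stored internally as 4D.
    pixel_size : float
        Lateral pixel size in nanometres.
    channel_names : list of str, optional
        One label per channel; autogenerated as ``ch0, ch1, ...`` if absent.
    """

    data: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE_NM
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 2:
            arr = arr[np.newaxis, np.newaxis]
        elif arr.ndim == 3:
            arr = arr[np.newaxis]
        elif arr.ndim != 4:
            raise ValueError(
                f"expected 2D, 3D (channel, y, x) or 4D (z, channel, y, x) data, "
                f"got ndim={arr.ndim}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("image intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("image intensities must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (nm)")
        self.data = arr
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(arr.shape[1])]
        if len(self.channel_names) != arr.shape[1]:
            raise ValueError("channel_names length must match the channel axis")

    @property
    def n_z(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel_index(self, channel: int | str) -> int:
        """Resolve a channel given by index or by name."""
        if isinstance(channel, str):
            try:
                return self.channel_names.index(channel)
            except ValueError:
                raise KeyError(
                    f"unknown channel {channel!r}; have {self.channel_names}"
                ) from None
        if not 0 <= channel < self.n_channels:
            raise IndexError(f"channel {channel} out of range [0, {self.n_channels})")
        return int(channel)

    def stack(self, channel: int | str) -> np.ndarray:
        """Return the ``(z, y, x)`` stack of one channel."""
        return self.data[:, self.channel_index(channel)]
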