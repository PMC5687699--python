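"""Time-ordered grayscale frame stacks.

A :class:`CineSequence` holds an H x W x T non-negative intensity grid and
its sampling rate; each pixel is a time signal at its spatial location.
Lossless I/O via NPZ or multi-page TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["CineSequence", "load_cine"]


@dataclass
class CineSequence:
    frames: np.ndarray              # (H, W, T) float, finite, >= 0
    sampling_rate: float            # Hz
    pixel_size: float | None = None  # mm / pixel

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] < 2:
            raise ValueError("frames must be (H, W, T) with T >= 2")
        if not np.all(np.isfinite(self.frames)) or np.any(self.frames < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def duration(self) -> float:
        return self.n_frames / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate

    def check_nyquist(self, cardiac_freq: float) -> None:
        if cardiac_freq >= self.sampling_rate / 2.0:
            raise ValueError(
                f"cardiac frequency {cardiac_freq} Hz is not below the Nyquist "
                f"frequency {self.sampling_rate / 2.0} Hz"
            )

    def save(self, path) -> None:
        """Write NPZ (``.npz``) or multi-page 8-bit TIFF (``.tif``/``.tiff``)."""
        path = Path(path)
        if path.suffix == ".npz":
            np.savez_compressed(path, frames=self.frames,
                                sampling_rate=self.sampling_rate,
                                pixel_size=np.nan if self.pixel_size is None else self.pixel_size)
        elif path.suffix in (".tif", ".tiff"):
            import tifffile

            peak = self.frames.max() or 1.0
            stack = np.clip(self.frames / peak * 255.0, 0, 255).astype(np.uint8)
            tifffile.imwrite(path, np.moveaxis(stack, 2, 0))
        else:
            raise ValueError(f"unsupported cine format: {path.suffix}")


def load_cine(path) -> CineSequence:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path) as z:
            px = float(z["pixel_size"])
            return CineSequence(z["frames"], float(z["sampling_rate"]),
                                None if np.isnan(px) else px)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        stack = tifffile.imread(path)
        raise ValueError(
            "TIFF stacks carry no sampling rate; load with "
            f"CineSequence(np.moveaxis(stack, 0, 2), fs) (read {stack.shape})"
        )
    raise ValueError(f"unsupported cine format: {path.suffix}")
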