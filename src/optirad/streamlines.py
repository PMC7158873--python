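"""Streamline container and TCK I/O.

Streamlines are ordered 3-D polylines in world RAS millimetres.  They are
consumed (filtered, rasterised), never tracked, by this package; tracking is
an upstream step performed by external tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["StreamlineSet"]


@dataclass
class StreamlineSet:
    """A set of polylines in world mm with optional step-size metadata."""

    polylines: list[np.ndarray]
    step_size: float | None = None

    def __post_init__(self) -> None:
        cleaned = []
        for line in self.polylines:
            line = np.asarray(line, dtype=float)
            if line.ndim != 2 or line.shape[1] != 3:
                raise ValueError("each streamline must be an (n, 3) array")
            if len(line) < 2:
                raise ValueError("each streamline needs at least 2 points")
            if not np.all(np.isfinite(line)):
                raise ValueError("streamline coordinates must be finite")
            cleaned.append(line)
        self.polylines = cleaned

    @property
    def count(self) -> int:
        return len(self.polylines)

    def __iter__(self):
        return iter(self.polylines)

    def __len__(self) -> int:
        return self.count

    def save_tck(self, path: str) -> None:
        tractogram = nib.streamlines.Tractogram(self.polylines, affine_to_rasmm=np.eye(4))
        nib.streamlines.save(tractogram, path)

    @classmethod
    def load_tck(cls, path: str) -> "StreamlineSet":
        tck = nib.streamlines.load(path)
        return cls([np.asarray(s) for s in tck.tractogram.streamlines])
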