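"""Acquisition protocol descriptions for the gradient-echo imaging stages.

An :class:`ImagingProtocol` captures the geometry and timing of one spoiled
gradient-echo acquisition: the cine angiography protocol used for the
vasomotor-response readout and the multi-flip-angle (VFA) protocol used for
T1 mapping.  Array data are indexed ``(slice, row, col[, frame])``; the
``matrix`` and ``fov_mm`` fields follow the scanner convention
``(rows, cols, slices)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

__all__ = ["ImagingProtocol", "functional_cine_protocol", "permeability_vfa_protocol"]


@dataclass(frozen=True)
class ImagingProtocol:
    """Geometry and timing of a spoiled gradient-echo acquisition.

    Parameters
    ----------
    tr_ms, te_ms:
        Repetition and echo time in milliseconds.
    fov_mm:
        Field of view ``(rows, cols, slices)`` in millimetres.
    matrix:
        Voxel counts ``(rows, cols, slices)``.
    flip_angles_deg:
        Ordered excitation flip angles in degrees.  A single-angle tuple for
        cine imaging, several strictly increasing angles for VFA T1 mapping.
    n_frames:
        Cardiac frames reconstructed per cycle (1 for non-gated imaging).
    label:
        Free-text protocol name carried into output metadata.
    """

    tr_ms: float
    te_ms: float
    fov_mm: Tuple[float, float, float]
    matrix: Tuple[int, int, int]
    flip_angles_deg: Tuple[float, ...]
    n_frames: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        if self.tr_ms <= 0 or self.te_ms <= 0:
            raise ValueError("tr_ms and te_ms must be positive")
        if len(self.fov_mm) != 3 or len(self.matrix) != 3:
            raise ValueError("fov_mm and matrix must be 3-vectors (rows, cols, slices)")
        if any(f <= 0 for f in self.fov_mm):
            raise ValueError("all FOV extents must be positive")
        if any(int(m) <= 0 or int(m) != m for m in self.matrix):
            raise ValueError("matrix entries must be positive integers")
        if not self.flip_angles_deg:
            raise ValueError("at least one flip angle is required")
        if any(not (0.0 < a <= 90.0) for a in self.flip_angles_deg):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if len(self.flip_angles_deg) > 1:
            diffs = np.diff(np.asarray(self.flip_angles_deg, dtype=float))
            if np.any(diffs <= 0):
                raise ValueError("flip angles must be strictly increasing")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        object.__setattr__(self, "fov_mm", tuple(float(f) for f in self.fov_mm))
        object.__setattr__(self, "matrix", tuple(int(m) for m in self.matrix))
        object.__setattr__(
            self, "flip_angles_deg", tuple(float(a) for a in self.flip_angles_deg)
        )

    @property
    def voxel_mm(self) -> Tuple[float, float, float]:
        """Voxel size ``(row, col, slice)`` in millimetres."""
        return tuple(f / m for f, m in zip(self.fov_mm, self.matrix))

    @property
    def shape(self) -> Tuple[int, int, int]:
        """Array shape ``(slices, rows, cols)`` of one reconstructed volume."""
        return (self.matrix[2], self.matrix[0], self.matrix[1])

    @property
    def slice_thickness_mm(self) -> float:
        return self.fov_mm[2] / self.matrix[2]

    @property
    def in_plane_pitch_mm(self) -> float:
        """Mean in-plane voxel pitch, used as the partial-volume edge width."""
        v = self.voxel_mm
        return 0.5 * (v[0] + v[1])

    def with_matrix(self, matrix: Tuple[int, int, int]) -> "ImagingProtocol":
        """Return a copy at a different reconstruction matrix (same FOV)."""
        return replace(self, matrix=matrix)


def functional_cine_protocol() -> ImagingProtocol:
    """Retrospectively gated 3D cine protocol for the vasomotor readout.

    TR 6.4 ms, TE 1.4 ms, FOV 30 x 30 x 5 mm, matrix 256 x 256 x 30,
    flip angle 30 deg, seven reconstructed cardiac frames.
    """
    return ImagingProtocol(
        tr_ms=6.4,
        te_ms=1.4,
        fov_mm=(30.0, 30.0, 5.0),
        matrix=(256, 256, 30),
        flip_angles_deg=(30.0,),
        n_frames=7,
        label="functional-cine",
    )


def permeability_vfa_protocol() -> ImagingProtocol:
    """Variable-flip-angle protocol for permeability T1 mapping.

    TR 10 ms, TE 1.1 ms, FOV 30 x 30 x 4 mm, matrix 192 x 160 x 8, one frame,
    eight flip angles 2, 4, 6, 8, 14, 20, 30, 50 deg.
    """
    return ImagingProtocol(
        tr_ms=10.0,
        te_ms=1.1,
        fov_mm=(30.0, 30.0, 4.0),
        matrix=(192, 160, 8),
        flip_angles_deg=(2.0, 4.0, 6.0, 8.0, 14.0, 20.0, 30.0, 50.0),
        n_frames=1,
        label="permeability-vfa",
    )
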