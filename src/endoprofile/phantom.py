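"""Digital vessel phantoms with known ground truth.

This module builds a stand-in for the imaged aortic arch: a branched vessel
embedded in tissue, rendered through the same spoiled gradient-echo signal
model the analysis assumes.  Every downstream stage (diastolic-frame
selection, lumen segmentation, volumetry, VFA T1 fitting, the Npx50
permeability count) can therefore be validated against exact ground truth.

The phantom encodes the two experimental manipulations directly:

* ``dilation_factor`` scales the end-diastolic lumen *volume* between the
  pre- and post-acetylcholine states (radius scales by its square root), so
  a factor of 0.9282 encodes a -7.18 % vasoconstrictor response.
* ``leak_fraction`` selects the fraction of perivascular-rim voxels whose
  T1 is shortened after the albumin-binding contrast agent, emulating
  endothelial leak.

Magnitude images carry Rician noise, as reconstructed magnitude MRI does.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

from .protocol import ImagingProtocol
from .t1map import spgr_signal

__all__ = [
    "BACKGROUND",
    "BLOOD",
    "WALL",
    "PERIVASCULAR",
    "COMPARTMENT_NAMES",
    "CompartmentParams",
    "TissueParams",
    "VesselGeometry",
    "CineVolume",
    "VfaSeries",
    "bifurcating_geometry",
    "rasterize_phantom",
    "render_cine_frame",
    "simulate_cine",
    "simulate_vfa_series",
    "leaky_rim_mask",
    "add_rician_noise",
]

# Compartment label codes used throughout the package.
BACKGROUND, BLOOD, WALL, PERIVASCULAR = 0, 1, 2, 3
COMPARTMENT_NAMES = {
    BACKGROUND: "background",
    BLOOD: "blood",
    WALL: "wall",
    PERIVASCULAR: "perivascular",
}


@dataclass(frozen=True)
class CompartmentParams:
    """Relaxation and signal parameters of one tissue compartment.

    ``t1_pre_ms``/``t1_post_ms`` are the longitudinal relaxation times before
    and after contrast (the agent only shortens T1, so post <= pre).  ``m0``
    is the equilibrium-signal weight entering the SPGR model.  ``cine_signal``
    is the apparent steady-state intensity in the gated cine angiogram, where
    inflow enhancement makes blood hyperintense regardless of its long T1.
    """

    t1_pre_ms: float
    t1_post_ms: float
    m0: float
    cine_signal: float

    def __post_init__(self) -> None:
        if self.t1_pre_ms <= 0 or self.t1_post_ms <= 0:
            raise ValueError("T1 values must be positive")
        if self.t1_post_ms > self.t1_pre_ms:
            raise ValueError(
                "t1_post_ms must not exceed t1_pre_ms (T1-shortening agent)"
            )
        if self.m0 < 0 or self.cine_signal < 0:
            raise ValueError("m0 and cine_signal must be non-negative")

    def t1_ms(self, ca_state: str) -> float:
        return self.t1_pre_ms if ca_state == "pre" else self.t1_post_ms


@dataclass(frozen=True)
class TissueParams:
    """Per-compartment tissue parameters plus the leak and noise model.

    ``leak_fraction`` is the fraction of perivascular-rim voxels that take
    the rim's post-contrast (shortened) T1 after contrast administration;
    the remaining rim voxels keep their pre-contrast T1 because the agent is
    confined to an intact vasculature.  ``noise_sigma`` is the Rician noise
    scale in signal units.
    """

    blood: CompartmentParams
    wall: CompartmentParams
    perivascular: CompartmentParams
    background: CompartmentParams
    leak_fraction: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.leak_fraction <= 1.0):
            raise ValueError("leak_fraction must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    @classmethod
    def default(
        cls, leak_fraction: float = 0.0, noise_sigma: float = 0.0
    ) -> "TissueParams":
        """Plausible 9.4 T defaults.

        Blood T1 1900 ms pre / 400 ms post (intravascular agent), vessel wall
        1200 ms unchanged, perivascular tissue 1200 ms pre with leaky voxels
        shortened to 500 ms, background 900 ms.  Cine intensities put
        inflow-enhanced blood at 100 against a dark wall and a background of
        20, as in bright-blood gradient-echo angiography.
        """
        return cls(
            blood=CompartmentParams(1900.0, 400.0, 1000.0, 100.0),
            wall=CompartmentParams(1200.0, 1200.0, 800.0, 25.0),
            perivascular=CompartmentParams(1200.0, 500.0, 850.0, 30.0),
            background=CompartmentParams(900.0, 900.0, 700.0, 20.0),
            leak_fraction=leak_fraction,
            noise_sigma=noise_sigma,
        )

    def compartment(self, label: int) -> CompartmentParams:
        return {
            BLOOD: self.blood,
            WALL: self.wall,
            PERIVASCULAR: self.perivascular,
            BACKGROUND: self.background,
        }[label]


@dataclass(frozen=True)
class VesselGeometry:
    """Branched-vessel geometry in scanner (mm) coordinates.

    The main vessel and one branch are piecewise-linear tubes sampled along
    the slice axis: ``centerline_mm`` rows are ``(z, row, col)`` positions
    with matching per-point ``radius_mm``.  ``dilation_factor`` multiplies
    the end-diastolic lumen volume between the pre- and post-acetylcholine
    states; ``pulsation_amplitude`` modulates the radius sinusoidally over
    the cardiac cycle with its minimum at ``diastolic_frame``.
    """

    centerline_mm: np.ndarray
    radius_mm: np.ndarray
    wall_thickness_mm: float
    pulsation_amplitude: float
    dilation_factor: float
    branch_centerline_mm: Optional[np.ndarray] = None
    branch_radius_mm: Optional[np.ndarray] = None
    rim_thickness_voxels: int = 2
    diastolic_frame: int = 0
    branch_slice: Optional[int] = None  # first slice with two lumen components

    def __post_init__(self) -> None:
        cl = np.asarray(self.centerline_mm, dtype=float)
        r = np.asarray(self.radius_mm, dtype=float)
        if cl.ndim != 2 or cl.shape[1] != 3 or cl.shape[0] < 2:
            raise ValueError("centerline_mm must be an (n >= 2, 3) array")
        if r.shape != (cl.shape[0],):
            raise ValueError("radius_mm must match the centerline sample count")
        if np.any(r <= 0):
            raise ValueError("radius_mm must be positive everywhere")
        if self.wall_thickness_mm < 0:
            raise ValueError("wall_thickness_mm must be non-negative")
        if not (0.0 <= self.pulsation_amplitude < 0.5):
            raise ValueError("pulsation_amplitude must lie in [0, 0.5)")
        if self.dilation_factor <= 0:
            raise ValueError("dilation_factor must be positive")
        if self.rim_thickness_voxels < 1:
            raise ValueError("rim_thickness_voxels must be >= 1")
        if (self.branch_centerline_mm is None) != (self.branch_radius_mm is None):
            raise ValueError("branch centerline and radius must be given together")
        if self.branch_centerline_mm is not None:
            bcl = np.asarray(self.branch_centerline_mm, dtype=float)
            br = np.asarray(self.branch_radius_mm, dtype=float)
            if bcl.ndim != 2 or bcl.shape[1] != 3:
                raise ValueError("branch_centerline_mm must be an (m, 3) array")
            if br.shape != (bcl.shape[0],):
                raise ValueError("branch_radius_mm must match the branch samples")
            if np.any(br <= 0):
                raise ValueError("branch_radius_mm must be positive everywhere")
            z0, z1 = cl[:, 0].min(), cl[:, 0].max()
            if not (z0 < bcl[:, 0].min() < z1):
                raise ValueError(
                    "branch must attach strictly interior to the main vessel"
                )
            object.__setattr__(self, "branch_centerline_mm", bcl)
            object.__setattr__(self, "branch_radius_mm", br)
        object.__setattr__(self, "centerline_mm", cl)
        object.__setattr__(self, "radius_mm", r)

    def with_dilation(self, dilation_factor: float) -> "VesselGeometry":
        return replace(self, dilation_factor=dilation_factor)

    def pulsation_scale(self, frame: int, n_frames: int) -> float:
        """Radius multiplier for a cardiac frame; 1.0 at the diastolic frame."""
        if n_frames <= 1:
            return 1.0
        phase = 2.0 * np.pi * (frame - self.diastolic_frame) / n_frames
        return 1.0 + self.pulsation_amplitude * 0.5 * (1.0 - np.cos(phase))

    def seed_voxel(self, protocol: ImagingProtocol, slice_index: int) -> Tuple[int, int]:
        """Voxel ``(row, col)`` on the main-vessel centerline at a slice."""
        z = (slice_index + 0.5) * protocol.slice_thickness_mm
        cl = self.centerline_mm
        row = np.interp(z, cl[:, 0], cl[:, 1])
        col = np.interp(z, cl[:, 0], cl[:, 2])
        vr, vc, _ = protocol.voxel_mm
        return int(row / vr), int(col / vc)


def bifurcating_geometry(
    protocol: ImagingProtocol,
    radius_mm: float = 1.25,
    branch_radius_mm: float = 0.7,
    wall_thickness_mm: float = 0.12,
    rim_thickness_voxels: int = 2,
    pulsation_amplitude: float = 0.08,
    dilation_factor: float = 1.0,
    diastolic_frame: Optional[int] = None,
    branch_slice: Optional[int] = None,
    drift_row_mm: float = 0.071,
    drift_col_mm: float = 0.043,
) -> VesselGeometry:
    """Straight main vessel that bifurcates part-way through the slab.

    The main vessel runs along the slice axis with a small in-plane drift
    (vessels are never perfectly axis-aligned; the incommensurate row/col
    drifts also dither the voxel grid so that per-slice discretisation
    errors of the pixel-counted cross-section average out).  From
    ``branch_slice`` on, a second lumen appears at a clear in-plane offset,
    so the first slice whose lumen mask splits into two connected components
    is ``branch_slice`` itself — the generator's ground truth for the
    analysis-slice selection rule ("end just before the branch").
    """
    n_slices = protocol.matrix[2]
    dz = protocol.slice_thickness_mm
    if branch_slice is None:
        branch_slice = (2 * n_slices) // 3
    if not (1 <= branch_slice < n_slices):
        raise ValueError("branch_slice must lie inside the slab")
    if diastolic_frame is None:
        diastolic_frame = protocol.n_frames // 2 + 1 if protocol.n_frames > 1 else 0
    fov_r, fov_c, _ = protocol.fov_mm

    z = (np.arange(n_slices + 1)) * dz  # sample one point past the last slice centre
    row = 0.5 * fov_r + drift_row_mm * np.arange(n_slices + 1)
    col = 0.40 * fov_c + drift_col_mm * np.arange(n_slices + 1)
    centerline = np.column_stack([z, row, col])
    radii = np.full(n_slices + 1, float(radius_mm))

    # Branch: disjoint second lumen from the branch slice onward, drifting
    # further from the main vessel with depth.
    sep0 = 1.3 * (radius_mm + branch_radius_mm) + 0.6
    # branch begins at the *centre* of branch_slice so that slice is the
    # first whose lumen mask shows two components
    zb = (np.arange(branch_slice, n_slices + 1) + 0.5) * dz
    k = np.arange(len(zb))
    brow = np.interp(zb, z, row)
    bcol = np.interp(zb, z, col) + sep0 + 0.12 * k
    branch_cl = np.column_stack([zb, brow, bcol])
    branch_r = np.full(len(zb), float(branch_radius_mm))

    return VesselGeometry(
        centerline_mm=centerline,
        radius_mm=radii,
        wall_thickness_mm=wall_thickness_mm,
        pulsation_amplitude=pulsation_amplitude,
        dilation_factor=dilation_factor,
        branch_centerline_mm=branch_cl,
        branch_radius_mm=branch_r,
        rim_thickness_voxels=rim_thickness_voxels,
        diastolic_frame=diastolic_frame,
        branch_slice=branch_slice,
    )


@dataclass
class CineVolume:
    """Reconstructed 4D cine magnitude stack, indexed (slice, row, col, frame)."""

    intensities: np.ndarray
    protocol: ImagingProtocol
    voxel_mm: Tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        expected = self.protocol.shape + (self.protocol.n_frames,)
        if arr.shape != expected:
            raise ValueError(
                f"cine shape {arr.shape} inconsistent with protocol {expected}"
            )
        if np.any(arr < 0):
            raise ValueError("magnitude intensities must be non-negative")
        self.intensities = arr

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[-1]

    def frame(self, index: int) -> np.ndarray:
        return self.intensities[..., index]


@dataclass
class VfaSeries:
    """Co-registered magnitude volumes, one per flip angle (angle-major 4D)."""

    volumes: np.ndarray  # (n_angles, slices, rows, cols)
    flip_angles_deg: Tuple[float, ...]
    protocol: ImagingProtocol

    def __post_init__(self) -> None:
        vols = np.asarray(self.volumes)
        if vols.ndim != 4:
            raise ValueError("volumes must be a 4D (angle, slice, row, col) array")
        if vols.shape[0] != len(self.flip_angles_deg):
            raise ValueError(
                f"{vols.shape[0]} volumes for {len(self.flip_angles_deg)} flip angles"
            )
        angles = np.asarray(self.flip_angles_deg, dtype=float)
        if len(angles) >= 2 and np.any(np.diff(angles) <= 0):
            raise ValueError("flip angles must be strictly increasing")
        self.volumes = vols
        self.flip_angles_deg = tuple(float(a) for a in angles)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.volumes.shape[1:]


def _slice_signed_distance(
    geometry: VesselGeometry,
    protocol: ImagingProtocol,
    slice_index: int,
    radius_scale: float,
) -> np.ndarray:
    """Signed distance (mm) to the nearest lumen surface on one slice.

    Negative inside the lumen.  The branch contributes from its own z-extent
    only.  Raises if any vessel (including wall and rim) leaves the FOV.
    """
    vr, vc, dz = protocol.voxel_mm
    n_rows, n_cols = protocol.matrix[0], protocol.matrix[1]
    z = (slice_index + 0.5) * dz
    rows = (np.arange(n_rows) + 0.5) * vr
    cols = (np.arange(n_cols) + 0.5) * vc
    rr = rows[:, None]
    cc = cols[None, :]

    rim_mm = geometry.rim_thickness_voxels * protocol.in_plane_pitch_mm
    margin = geometry.wall_thickness_mm + rim_mm

    signed = np.full((n_rows, n_cols), np.inf)
    for cl, rad in (
        (geometry.centerline_mm, geometry.radius_mm),
        (geometry.branch_centerline_mm, geometry.branch_radius_mm),
    ):
        if cl is None:
            continue
        zs = cl[:, 0]
        if not (zs.min() - 0.5 * dz <= z <= zs.max() + 0.5 * dz):
            continue
        crow = np.interp(z, zs, cl[:, 1])
        ccol = np.interp(z, zs, cl[:, 2])
        r = float(np.interp(z, zs, rad)) * radius_scale
        outer = r + margin
        fov_r, fov_c, _ = protocol.fov_mm
        if (
            crow - outer < 0
            or crow + outer > fov_r
            or ccol - outer < 0
            or ccol + outer > fov_c
        ):
            raise ValueError(
                f"vessel extent (centre ({crow:.2f}, {ccol:.2f}) mm, outer radius "
                f"{outer:.2f} mm) leaves the {fov_r:.1f} x {fov_c:.1f} mm FOV at "
                f"slice {slice_index}"
            )
        dist = np.hypot(rr - crow, cc - ccol)
        signed = np.minimum(signed, dist - r)
    return signed


def _radius_scale(
    geometry: VesselGeometry, protocol: ImagingProtocol, frame: int, state: str
) -> float:
    if state not in ("pre", "post"):
        raise ValueError("state must be 'pre' or 'post'")
    if not (0 <= frame < protocol.n_frames):
        raise ValueError(f"frame {frame} out of range for {protocol.n_frames} frames")
    scale = geometry.pulsation_scale(frame, protocol.n_frames)
    if state == "post":
        # dilation_factor scales lumen volume; radius scales by its sqrt
        scale *= float(np.sqrt(geometry.dilation_factor))
    return scale


def rasterize_phantom(
    geometry: VesselGeometry,
    protocol: ImagingProtocol,
    frame: int = 0,
    state: str = "pre",
) -> np.ndarray:
    """Rasterise the phantom into a per-voxel compartment label volume.

    Each voxel is assigned exactly one label by the signed distance of its
    centre to the nearest lumen surface: blood inside the lumen, wall within
    ``wall_thickness_mm`` outside it, perivascular rim within a further
    ``rim_thickness_voxels`` in-plane voxels, background beyond.
    """
    scale = _radius_scale(geometry, protocol, frame, state)
    rim_mm = geometry.rim_thickness_voxels * protocol.in_plane_pitch_mm
    wt = geometry.wall_thickness_mm
    n_slices = protocol.matrix[2]
    labels = np.zeros(protocol.shape, dtype=np.uint8)
    for k in range(n_slices):
        s = _slice_signed_distance(geometry, protocol, k, scale)
        lab = np.full(s.shape, BACKGROUND, dtype=np.uint8)
        lab[s <= wt + rim_mm] = PERIVASCULAR
        lab[s <= wt] = WALL
        lab[s <= 0.0] = BLOOD
        labels[k] = lab
    return labels


def render_cine_frame(
    geometry: VesselGeometry,
    tissue: TissueParams,
    protocol: ImagingProtocol,
    frame: int,
    state: str,
) -> np.ndarray:
    """Noiseless cine frame with partial-volume (linear) edge profiles.

    Voxels straddling a compartment boundary mix the two intensities over a
    one-pixel-wide linear ramp, emulating the partial-volume appearance of
    reconstructed magnitude images; half-maximum thresholding of such an
    edge recovers the true boundary with sub-pixel accuracy.
    """
    scale = _radius_scale(geometry, protocol, frame, state)
    rim_mm = geometry.rim_thickness_voxels * protocol.in_plane_pitch_mm
    wt = geometry.wall_thickness_mm
    w = protocol.in_plane_pitch_mm
    i_blood = tissue.blood.cine_signal
    i_wall = tissue.wall.cine_signal
    i_rim = tissue.perivascular.cine_signal
    i_bg = tissue.background.cine_signal

    def inside(s: np.ndarray, boundary: float) -> np.ndarray:
        # fraction of the voxel inside the given boundary (linear ramp)
        return np.clip(0.5 - (s - boundary) / w, 0.0, 1.0)

    n_slices = protocol.matrix[2]
    out = np.empty(protocol.shape, dtype=np.float64)
    for k in range(n_slices):
        s = _slice_signed_distance(geometry, protocol, k, scale)
        img = np.full(s.shape, i_bg)
        img += (i_rim - i_bg) * inside(s, wt + rim_mm)
        img += (i_wall - i_rim) * inside(s, wt)
        img += (i_blood - i_wall) * inside(s, 0.0)
        out[k] = img
    return out


def add_rician_noise(
    signal: np.ndarray, sigma: float, rng: np.random.Generator, model: str = "rician"
) -> np.ndarray:
    """Apply magnitude-image noise to a noiseless signal array.

    Rician by default (the magnitude of a complex Gaussian-perturbed signal;
    Rayleigh-distributed where the signal is zero); a plain additive Gaussian
    model is available for debugging.
    """
    if sigma < 0:
        raise ValueError("noise sigma must be non-negative")
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    if model == "rician":
        re = signal + rng.normal(0.0, sigma, size=signal.shape)
        im = rng.normal(0.0, sigma, size=signal.shape)
        return np.hypot(re, im)
    if model == "gaussian":
        return np.clip(signal + rng.normal(0.0, sigma, size=signal.shape), 0.0, None)
    raise ValueError(f"unknown noise model {model!r}")


def simulate_cine(
    geometry: VesselGeometry,
    tissue: TissueParams,
    protocol: ImagingProtocol,
    seed: int,
    noise_model: str = "rician",
) -> Tuple[CineVolume, CineVolume]:
    """Simulate pre- and post-acetylcholine cine stacks of the same vessel.

    The two stacks share every geometric parameter except that the post
    stack's lumen volume is scaled by ``geometry.dilation_factor``.  Noise
    (scale ``tissue.noise_sigma``) is drawn independently per voxel, frame
    and state from a generator seeded with ``seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x11]))
    stacks = []
    for state in ("pre", "post"):
        frames = [
            add_rician_noise(
                render_cine_frame(geometry, tissue, protocol, f, state),
                tissue.noise_sigma,
                rng,
                noise_model,
            )
            for f in range(protocol.n_frames)
        ]
        arr = np.stack(frames, axis=-1).astype(np.float32)
        stacks.append(CineVolume(arr, protocol, protocol.voxel_mm))
    return stacks[0], stacks[1]


def leaky_rim_mask(
    labels: np.ndarray, leak_fraction: float, seed: int
) -> np.ndarray:
    """Reproducibly choose the perivascular voxels that leak contrast.

    Exactly ``round(leak_fraction * n_rim)`` rim voxels are selected without
    replacement by a generator derived from ``seed``; the same seed always
    selects the same voxels.
    """
    if not (0.0 <= leak_fraction <= 1.0):
        raise ValueError("leak_fraction must lie in [0, 1]")
    rim_idx = np.flatnonzero(labels == PERIVASCULAR)
    n_leak = int(round(leak_fraction * rim_idx.size))
    mask = np.zeros(labels.shape, dtype=bool)
    if n_leak:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1EA4]))
        chosen = rng.choice(rim_idx, size=n_leak, replace=False)
        mask.flat[np.sort(chosen)] = True
    return mask


def t1_ground_truth(
    labels: np.ndarray, tissue: TissueParams, ca_state: str, seed: int = 0
) -> np.ndarray:
    """Per-voxel ground-truth T1 (ms) for a label volume and contrast state."""
    if ca_state not in ("pre", "post"):
        raise ValueError("ca_state must be 'pre' or 'post'")
    t1 = np.empty(labels.shape, dtype=float)
    for lab in (BACKGROUND, BLOOD, WALL, PERIVASCULAR):
        t1[labels == lab] = tissue.compartment(lab).t1_ms(ca_state)
    if ca_state == "post":
        leak = leaky_rim_mask(labels, tissue.leak_fraction, seed)
        t1[leak] = tissue.perivascular.t1_post_ms
        t1[(labels == PERIVASCULAR) & ~leak] = tissue.perivascular.t1_pre_ms
    return t1


def simulate_vfa_series(
    labels: np.ndarray,
    tissue: TissueParams,
    protocol: ImagingProtocol,
    ca_state: str,
    seed: int,
    noise_model: str = "rician",
) -> VfaSeries:
    """Forward-simulate a variable-flip-angle series from a label volume.

    Each voxel's noiseless intensity at every flip angle is the spoiled
    gradient-echo steady-state signal for its compartment's (m0, T1); in the
    post-contrast state the leaky rim voxels (chosen reproducibly from
    ``seed``) use the shortened perivascular T1.  Rician noise of scale
    ``tissue.noise_sigma`` is applied independently per voxel per angle.
    """
    if len(protocol.flip_angles_deg) < 2:
        raise ValueError("VFA simulation requires at least two flip angles")
    t1 = t1_ground_truth(labels, tissue, ca_state, seed)
    m0 = np.empty(labels.shape, dtype=float)
    for lab in (BACKGROUND, BLOOD, WALL, PERIVASCULAR):
        m0[labels == lab] = tissue.compartment(lab).m0
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x22]))
    vols = []
    for alpha in protocol.flip_angles_deg:
        clean = spgr_signal(m0, t1, protocol.tr_ms, alpha)
        vols.append(add_rician_noise(clean, tissue.noise_sigma, rng, noise_model))
    return VfaSeries(np.stack(vols, axis=0), protocol.flip_angles_deg, protocol)
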