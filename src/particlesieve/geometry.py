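"""Forward projection geometry: Euler rotations, shifts, central-slice projection.

The forward operator A maps a 3D map to the expected 2D image of a particle:
rotate the map by the particle's Euler angles, project along the rotated
z-axis (a central Fourier slice), translate by the particle's shift and
modulate with its CTF. Euler angles follow the RELION ZYZ intrinsic
convention (rot, tilt, psi in degrees); the rotation maps reference-frame
coordinates to the particle frame, so the projection direction is the
rotated z-axis.

FFT conventions (global, shared with the reconstruction code): forward
transforms unnormalized, inverse divided by the element count; real-space
images are centered, so every transform is wrapped in an
ifftshift/fftshift sandwich. The central slice is extracted by trilinear
interpolation from the FFT of the volume zero-padded 2x, which keeps the
interpolation error of a smooth phantom below the percent level.

The particle shift is folded into the forward-projected image (A x carries
the shift), so an observed image is compared against an already-shifted
projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import CTFParams, ctf_value

__all__ = [
    "Pose",
    "rotation_matrix",
    "apply_shift",
    "forward_project",
    "FourierProjector",
]


@dataclass
class Pose:
    """ZYZ intrinsic Euler angles (degrees) and in-plane shift (Angstrom)."""

    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    shift_x: float = 0.0
    shift_y: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.rot, self.tilt, self.psi,
                            self.shift_x, self.shift_y]).all():
            raise ValueError("pose fields must be finite")


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_matrix(pose: Pose) -> np.ndarray:
    """R = Rz(rot) @ Ry(tilt) @ Rz(psi), det(R) = 1."""
    return (
        _rz(np.deg2rad(pose.rot))
        @ _ry(np.deg2rad(pose.tilt))
        @ _rz(np.deg2rad(pose.psi))
    )


def apply_shift(image: np.ndarray, shift_x: float, shift_y: float,
                pixel_size: float = 1.0) -> np.ndarray:
    """Translate image content by (+shift_x, +shift_y) Angstrom via a Fourier
    phase ramp. Integer-pixel shifts equal a circular roll exactly."""
    L = image.shape[-1]
    sx = shift_x / pixel_size
    sy = shift_y / pixel_size
    k = np.fft.fftfreq(L)  # cycles / pixel
    ramp = np.exp(-2j * np.pi * (k[None, :] * sx + k[:, None] * sy))
    return np.fft.ifft2(np.fft.fft2(image) * ramp).real


class FourierProjector:
    """Precomputed padded 3D FFT of a map, for repeated slice extraction.

    Building the FFT once amortizes the dominant cost when projecting many
    particles against the same reference.
    """

    def __init__(self, volume, pad: int = 3):
        data = volume.data if hasattr(volume, "data") else np.asarray(volume)
        L = data.shape[0]
        if data.shape != (L, L, L):
            raise ValueError(f"volume must be a cube, got {data.shape}")
        self.L = L
        self.pad = pad
        self.pixel_size = getattr(volume, "voxel_size", 1.0)
        P = pad * L
        padded = np.zeros((P, P, P), dtype=np.float64)
        s = (P - L) // 2
        padded[s:s + L, s:s + L, s:s + L] = data
        self.F = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(padded)))
        self.P = P
        # centered integer frequency grid of the L-sized output image
        k = np.fft.fftshift(np.fft.fftfreq(L)) * L  # -L/2 ... L/2-1
        self._kx = np.broadcast_to(k[None, :], (L, L))
        self._ky = np.broadcast_to(k[:, None], (L, L))

    def slice(self, R: np.ndarray) -> np.ndarray:
        """Centered complex L x L Fourier slice on the plane normal to the
        rotated z-axis. R is the pose rotation matrix."""
        kx = self._kx.ravel()
        ky = self._ky.ravel()
        # reference-frame frequency of each in-plane sample: q = R^T (kx,ky,0)
        q = R.T @ np.vstack([kx, ky, np.zeros_like(kx)])
        pts = q[::-1].T * self.pad + self.P // 2  # (n, 3) as (z, y, x) indices
        vals = _trilinear_gather(self.F, pts)
        return vals.reshape(self.L, self.L)


def _trilinear_gather(F: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Trilinearly interpolate complex grid F at fractional (z,y,x) points;
    samples outside the grid contribute zero."""
    P = F.shape[0]
    base = np.floor(pts).astype(np.int64)
    frac = pts - base
    out = np.zeros(pts.shape[0], dtype=np.complex128)
    for dz in (0, 1):
        wz = frac[:, 0] if dz else 1.0 - frac[:, 0]
        iz = base[:, 0] + dz
        for dy in (0, 1):
            wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
            iy = base[:, 1] + dy
            for dx in (0, 1):
                wx = frac[:, 2] if dx else 1.0 - frac[:, 2]
                ix = base[:, 2] + dx
                ok = (
                    (iz >= 0) & (iz < P)
                    & (iy >= 0) & (iy < P)
                    & (ix >= 0) & (ix < P)
                )
                w = wz * wy * wx
                idx = (iz[ok], iy[ok], ix[ok])
                out[ok] += w[ok] * F[idx]
    return out


def _shift_ramp(L: int, sx_px: float, sy_px: float) -> np.ndarray:
    """Centered-layout phase ramp translating content by (+sx, +sy) pixels."""
    k = np.fft.fftshift(np.fft.fftfreq(L))
    return np.exp(-2j * np.pi * (k[None, :] * sx_px + k[:, None] * sy_px))


def project_slice_to_image(slc: np.ndarray) -> np.ndarray:
    """Inverse-transform a centered Fourier slice to a centered real image."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(slc))).real


def forward_project(
    volume,
    pose: Pose,
    ctf: CTFParams | None,
    L: int | None = None,
    pixel_size: float | None = None,
    projector: FourierProjector | None = None,
) -> np.ndarray:
    """Apply the forward operator A: rotate, central-slice project, shift, CTF.

    ``projector`` may carry a precomputed :class:`FourierProjector` for the
    volume; otherwise one is built on the fly.
    """
    if projector is None:
        projector = FourierProjector(volume)
    if L is not None and L != projector.L:
        raise ValueError(f"requested edge {L} != volume edge {projector.L}")
    px = pixel_size if pixel_size is not None else projector.pixel_size
    if pixel_size is not None and abs(px - projector.pixel_size) > 1e-9:
        raise ValueError("pixel_size must match the volume voxel size")
    slc = projector.slice(rotation_matrix(pose))
    if pose.shift_x or pose.shift_y:
        slc = slc * _shift_ramp(projector.L, pose.shift_x / px, pose.shift_y / px)
    if ctf is not None:
        f = np.fft.fftshift(np.fft.fftfreq(projector.L, d=px))
        slc = slc * ctf_value(ctf, f[None, :] + 0.0 * f[:, None],
                              f[:, None] + 0.0 * f[None, :])
    return project_slice_to_image(slc)
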