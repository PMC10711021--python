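"""Direct Fourier-inversion reconstruction, soft masks and FSC resolution.

Reconstruction inserts each particle's CTF-premultiplied Fourier transform
as a central slice into an oversampled 3D grid (trilinear spreading),
accumulates CTF^2 weights, and divides by the weights plus a small Wiener
constant before inverse transforming — the same direct-inversion scheme
used by standard SPA reconstruction programs, without their iterative
gridding correction. Half-set independence is the caller's contract: a
reconstruction only ever touches the images whose records it is given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import ndimage

from .formats import ParticleStack, VoxelGrid
from .geometry import _shift_ramp, rotation_matrix
from .optics import ctf_value

__all__ = [
    "FSCCurve",
    "MaskSpec",
    "ResolutionEstimate",
    "reconstruct",
    "make_mask",
    "fsc",
    "resolution_at_threshold",
]


@dataclass
class FSCCurve:
    """Per-shell Fourier correlation between two maps."""

    shell_freq: np.ndarray  # 1/A, strictly increasing
    correlation: np.ndarray  # dimensionless, in [-1, 1]

    def __post_init__(self) -> None:
        self.shell_freq = np.asarray(self.shell_freq, dtype=np.float64)
        self.correlation = np.asarray(self.correlation, dtype=np.float64)
        if self.shell_freq.size != self.correlation.size:
            raise ValueError("shell_freq and correlation length mismatch")
        if self.shell_freq.size and np.any(np.diff(self.shell_freq) <= 0):
            raise ValueError("shell_freq must be strictly increasing")


@dataclass
class MaskSpec:
    """Soft-mask construction parameters (lowpass, binarize, dilate, cosine)."""

    lowpass_A: float = 8.0
    extend_px: int = 4
    cosine_edge_px: int = 4
    threshold: float = 0.2  # fraction of the lowpassed map's maximum

    def __post_init__(self) -> None:
        if min(self.lowpass_A, self.extend_px, self.cosine_edge_px,
               self.threshold) <= 0:
            raise ValueError("all MaskSpec fields must be positive")


class ResolutionEstimate(NamedTuple):
    resolution_A: float
    crossed: bool  # False when the curve never drops below the threshold


def reconstruct(
    stack: ParticleStack,
    records_subset: Optional[Sequence] = None,
    pad: int = 2,
    wiener_eps_rel: float = 1e-3,
    chunk: int = 256,
) -> VoxelGrid:
    """Rebuild a 3D map from the given particle records by Fourier inversion.

    records_subset defaults to all records in the stack. Each record's
    ``image_index`` addresses the image used. Duplicated particles leave the
    result unchanged (numerator and weights scale together).
    """
    records = list(stack.records if records_subset is None else records_subset)
    if not records:
        raise ValueError("cannot reconstruct from an empty particle subset")
    L = stack.edge
    px = stack.pixel_size
    P = pad * L
    num = np.zeros(P * P * P, dtype=np.complex128)
    wt = np.zeros(P * P * P, dtype=np.float64)

    k = np.fft.fftshift(np.fft.fftfreq(L)) * L
    kx = np.broadcast_to(k[None, :], (L, L)).ravel()
    ky = np.broadcast_to(k[:, None], (L, L)).ravel()
    f = np.fft.fftshift(np.fft.fftfreq(L, d=px))
    fx = np.broadcast_to(f[None, :], (L, L))
    fy = np.broadcast_to(f[:, None], (L, L))

    pos = {r.image_index: i for i, r in enumerate(stack.records)}

    for start in range(0, len(records), chunk):
        batch = records[start:start + chunk]
        pts_list, val_list = [], []
        for r in batch:
            img = stack.images[pos[r.image_index]].astype(np.float64)
            F = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))
            p = r.pose
            if p.shift_x or p.shift_y:
                # undo the shift carried by the observed image
                F = F * np.conj(_shift_ramp(L, p.shift_x / px, p.shift_y / px))
            if r.ctf is None:
                c = np.ones((L, L))
            else:
                c = ctf_value(r.ctf, fx + 0.0 * fy, fy + 0.0 * fx)
            R = rotation_matrix(p)
            q = R.T @ np.vstack([kx, ky, np.zeros_like(kx)])
            pts = q[::-1].T * pad + P // 2  # (n, 3) fractional (z, y, x)
            pts_list.append(pts)
            val_list.append(np.stack([(F * c).ravel(), (c * c).ravel()]))
        pts = np.concatenate(pts_list, axis=0)
        vals = np.concatenate(val_list, axis=1)
        _trilinear_scatter(num, wt, pts, vals[0], vals[1].real, P)

    eps = wiener_eps_rel * wt[wt > 0].mean() if np.any(wt > 0) else 1.0
    grid = (num / (wt + eps)).reshape(P, P, P)
    vol = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(grid))).real
    s = (P - L) // 2
    return VoxelGrid(data=vol[s:s + L, s:s + L, s:s + L], voxel_size=px)


def _trilinear_scatter(num, wt, pts, values, weights, P):
    base = np.floor(pts).astype(np.int64)
    frac = pts - base
    size = P * P * P
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
                    (iz >= 0) & (iz < P) & (iy >= 0) & (iy < P)
                    & (ix >= 0) & (ix < P)
                )
                w = (wz * wy * wx)[ok]
                flat = (iz[ok] * P + iy[ok]) * P + ix[ok]
                num.real += np.bincount(flat, w * values.real[ok], minlength=size)
                num.imag += np.bincount(flat, w * values.imag[ok], minlength=size)
                wt += np.bincount(flat, w * weights[ok], minlength=size)


def make_mask(volume: VoxelGrid, spec: MaskSpec = MaskSpec()) -> VoxelGrid:
    """Soft binary mask: lowpass, threshold at a fraction of the maximum,
    dilate, then apply a raised-cosine edge. Values lie in [0, 1]."""
    data = volume.data.astype(np.float64)
    if not np.any(data):
        raise ValueError("cannot build a mask from an all-zero volume")
    L = volume.edge
    f = np.fft.fftfreq(L, d=volume.voxel_size)
    fz, fy, fx = np.meshgrid(f, f, f, indexing="ij")
    radial = np.sqrt(fx * fx + fy * fy + fz * fz)
    F = np.fft.fftn(data)
    F[radial > 1.0 / spec.lowpass_A] = 0.0
    low = np.fft.ifftn(F).real
    binary = low >= spec.threshold * low.max()
    if spec.extend_px > 0:
        binary = ndimage.binary_dilation(binary, iterations=int(spec.extend_px))
    dist = ndimage.distance_transform_edt(~binary)
    edge = float(spec.cosine_edge_px)
    t = np.clip(dist / edge, 0.0, 1.0)
    soft = 0.5 * (1.0 + np.cos(np.pi * t))
    soft[binary] = 1.0
    return VoxelGrid(data=soft, voxel_size=volume.voxel_size)


def _shell_index(L: int) -> np.ndarray:
    k = np.fft.fftfreq(L) * L
    kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
    return np.rint(np.sqrt(kx * kx + ky * ky + kz * kz)).astype(np.int64)


def fsc(volume_a: VoxelGrid, volume_b: VoxelGrid) -> FSCCurve:
    """Fourier shell correlation between two maps, shells one voxel wide."""
    if volume_a.data.shape != volume_b.data.shape:
        raise ValueError("FSC requires volumes of identical shape")
    if abs(volume_a.voxel_size - volume_b.voxel_size) > 1e-9:
        raise ValueError("FSC requires identical voxel sizes")
    L = volume_a.edge
    Fa = np.fft.fftn(volume_a.data)
    Fb = np.fft.fftn(volume_b.data)
    shell = _shell_index(L).ravel()
    nshell = L // 2
    cross = np.bincount(shell, (Fa * np.conj(Fb)).real.ravel(), minlength=nshell)
    pa = np.bincount(shell, (np.abs(Fa) ** 2).ravel(), minlength=nshell)
    pb = np.bincount(shell, (np.abs(Fb) ** 2).ravel(), minlength=nshell)
    denom = np.sqrt(pa[:nshell] * pb[:nshell])
    corr = np.where(denom > 0, cross[:nshell] / np.where(denom > 0, denom, 1.0), 0.0)
    freq = np.arange(nshell) / (L * volume_a.voxel_size)
    return FSCCurve(shell_freq=freq, correlation=corr)


def resolution_at_threshold(curve: FSCCurve, threshold: float = 0.143
                            ) -> ResolutionEstimate:
    """Resolution at the first threshold crossing, linearly interpolated
    between shells; Nyquist (flagged) when the curve never crosses."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    f = curve.shell_freq
    c = curve.correlation
    if f.size == 0:
        raise ValueError("empty FSC curve")
    below = np.nonzero(c < threshold)[0]
    if below.size == 0:
        # never crossed: report Nyquist (one shell step past the last shell)
        nyquist = f[-1] + (f[1] - f[0]) if f.size > 1 else f[-1]
        return ResolutionEstimate(1.0 / nyquist, False)
    i = int(below[0])
    if i == 0:
        # below threshold already in the lowest shell: no finite crossing
        first = f[1] if f.size > 1 else f[0]
        return ResolutionEstimate(1.0 / first if first > 0 else np.inf, True)
    f_cross = f[i - 1] + (c[i - 1] - threshold) / (c[i - 1] - c[i]) * (f[i] - f[i - 1])
    return ResolutionEstimate(1.0 / f_cross, True)
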