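"""Synthetic particle stacks with controllable corruption.

The generator emulates the statistical structure the sieve exploits:
CTF-modulated noise-free projections of a phantom at uniform random
orientations, per-particle dose-dependent high-frequency attenuation
(a B-factor envelope exp(-B_dose f^2 / 4) with B_dose proportional to the
accumulated dose), additive white Gaussian pixel noise, and optional
corruption of a fraction of the metadata records with independently
re-drawn poses or defocus values. Every draw comes from a single seeded
generator, so an identical spec reproduces the stack bit for bit.

Defaults mirror a typical high-end data collection: 300 kV, defocus
uniform in 0.5-1.5 um, four dose groups at the mean accumulated doses of
frame windows 5-14, 10-19, 15-24 and 20-29 of a 32-frame movie carrying
50 e-/A^2 in total (14.8, 22.7, 30.5 and 38.3 e-/A^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .formats import ParticleRecord, ParticleStack, VoxelGrid
from .geometry import FourierProjector, Pose, rotation_matrix, project_slice_to_image
from .optics import CTFParams, ctf_value

__all__ = [
    "SimSpec",
    "DEFAULT_DOSE_GROUPS",
    "make_phantom",
    "damage_envelope",
    "simulate_stack",
]

# mean accumulated dose of frame windows 5-14/10-19/15-24/20-29 at 50/32 e-/A^2 per frame
DEFAULT_DOSE_GROUPS: Tuple[float, ...] = (14.84375, 22.65625, 30.46875, 38.28125)


@dataclass
class SimSpec:
    """Everything that defines a simulated stack, including the seed."""

    phantom: str = "gaussian_blobs"  # gaussian_blobs | ball | c4_test_object
    n_particles: int = 400
    L: int = 48
    pixel_size: float = 1.5  # A/px
    noise_sigma: Optional[float] = None  # absolute pixel-noise sigma
    target_snr: Optional[float] = None  # alternative: variance ratio signal/noise
    wrong_pose_fraction: float = 0.0
    wrong_ctf_fraction: float = 0.0
    damage_levels: Sequence[Tuple[float, float]] = ()  # (fraction, dose e-/A^2)
    damage_b_per_dose: float = 2.0  # A^2 per e-/A^2
    defocus_range_um: Tuple[float, float] = (0.5, 1.5)
    voltage: float = 300.0
    cs: float = 2.7
    amplitude_contrast: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.noise_sigma is not None and self.target_snr is not None:
            raise ValueError("give noise_sigma or target_snr, not both")
        if not 0.0 <= self.wrong_pose_fraction <= 1.0:
            raise ValueError("wrong_pose_fraction must be in [0, 1]")
        if not 0.0 <= self.wrong_ctf_fraction <= 1.0:
            raise ValueError("wrong_ctf_fraction must be in [0, 1]")
        if self.damage_levels and sum(f for f, _ in self.damage_levels) > 1.0 + 1e-9:
            raise ValueError("damage_levels fractions must sum to <= 1")


def make_phantom(kind: str, L: int, pixel_size: float = 1.0, seed: int = 0,
                 n_blobs: Optional[int] = None,
                 blob_sigma_frac: Optional[Tuple[float, float]] = None
                 ) -> VoxelGrid:
    """Positive test density: random Gaussian blobs, a soft-edged ball, or
    an exactly C4-symmetric blob arrangement.

    The default ``gaussian_blobs`` phantom is built from many small
    scatterers (300 blobs, sigma 1.5-2.5% of the box) so that, like a real
    protein, it carries substantial spectral power at secondary-structure
    scales and not just a smooth low-frequency envelope. Pass ``n_blobs``
    and ``blob_sigma_frac`` to get a smoother object (useful for
    interpolation-accuracy oracles). Blob sigmas are floored at 0.9 voxels
    to keep the density band-limited.
    """
    if L % 2 != 0:
        raise ValueError("L must be even")
    rng = np.random.default_rng(seed)
    z, y, x = np.mgrid[:L, :L, :L] - L // 2
    vol = np.zeros((L, L, L))
    if kind == "ball":
        r0, w = 0.28 * L, 0.095 * L
        r = np.sqrt(x * x + y * y + z * z)
        t = np.clip((r - (r0 - w)) / (2 * w), 0.0, 1.0)
        vol = 0.5 * (1.0 + np.cos(np.pi * t))
    elif kind == "gaussian_blobs":
        nb = 300 if n_blobs is None else n_blobs
        lo, hi = blob_sigma_frac if blob_sigma_frac else (0.015, 0.025)
        centers = rng.uniform(-0.20 * L, 0.20 * L, (nb, 3))
        sigmas = np.maximum(rng.uniform(lo * L, hi * L, nb), 0.9)
        amps = rng.uniform(0.5, 1.0, nb)
        for c, s, a in zip(centers, sigmas, amps):
            vol += a * np.exp(
                -(((z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2)
                  / (2 * s * s))
            )
    elif kind == "c4_test_object":
        # blobs replicated at 4 rotations about z -> exact C4 symmetry;
        # kept compact so wrap-around tails stay below float32 noise
        for _ in range(4):
            c = rng.uniform(-0.15 * L, 0.15 * L, 3)
            s = rng.uniform(0.04 * L, 0.06 * L)
            for rot in range(4):
                cz, cy, cx = c
                for _ in range(rot):
                    cy, cx = cx, -cy  # 90 deg rotation in the xy-plane
                vol += np.exp(
                    -(((z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2)
                      / (2 * s * s))
                )
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    return VoxelGrid(data=vol, voxel_size=pixel_size)


def damage_envelope(accumulated_dose: float, damage_b_per_dose: float, f):
    """Dose-dependent amplitude attenuation exp(-(b * dose) * f^2 / 4).

    Equals 1 at zero dose or zero frequency and decreases strictly in both;
    f in 1/Angstrom, b in A^2 per (e-/A^2).
    """
    if accumulated_dose < 0:
        raise ValueError("dose must be >= 0")
    f = np.asarray(f, dtype=np.float64)
    out = np.exp(-(damage_b_per_dose * accumulated_dose) * f * f / 4.0)
    return out if out.ndim else float(out)


def _random_pose(rng: np.random.Generator) -> Pose:
    return Pose(
        rot=rng.uniform(0.0, 360.0),
        tilt=np.degrees(np.arccos(rng.uniform(-1.0, 1.0))),
        psi=rng.uniform(0.0, 360.0),
    )


def simulate_stack(volume: VoxelGrid, spec: SimSpec
                   ) -> Tuple[ParticleStack, pd.DataFrame]:
    """Generate a particle stack plus a per-particle truth table.

    Images are rendered from the *true* pose/CTF; for corrupted particles
    the metadata record carries an independently re-drawn pose or defocus,
    so the recorded parameters disagree with the image content. The truth
    table flags corruption and stores each particle's dose group.
    """
    rng = np.random.default_rng(spec.seed)
    n, L, px = spec.n_particles, volume.edge, spec.pixel_size
    if volume.edge != spec.L:
        raise ValueError(f"volume edge {volume.edge} != spec.L {spec.L}")
    projector = FourierProjector(volume)

    # per-particle dose group assignment (group 0 = undamaged remainder)
    doses = np.zeros(n)
    groups = np.zeros(n, dtype=int)
    if spec.damage_levels:
        order = rng.permutation(n)
        start = 0
        for gi, (frac, dose) in enumerate(spec.damage_levels, start=1):
            cnt = int(round(frac * n))
            sel = order[start:start + cnt]
            doses[sel] = dose
            groups[sel] = gi
            start += cnt

    wrong_pose = np.zeros(n, dtype=bool)
    wrong_pose[rng.permutation(n)[: int(round(spec.wrong_pose_fraction * n))]] = True
    wrong_ctf = np.zeros(n, dtype=bool)
    wrong_ctf[rng.permutation(n)[: int(round(spec.wrong_ctf_fraction * n))]] = True

    lo, hi = (d * 1e4 for d in spec.defocus_range_um)  # um -> A
    f1d = np.fft.fftshift(np.fft.fftfreq(L, d=px))
    fr = np.hypot(f1d[None, :], f1d[:, None])

    images = np.empty((n, L, L), dtype=np.float32)
    records: List[ParticleRecord] = []
    truth_rows = []
    clean_var = np.empty(n)
    for i in range(n):
        true_pose = _random_pose(rng)
        true_defocus = rng.uniform(lo, hi)
        ctf = CTFParams(voltage=spec.voltage, cs=spec.cs,
                        amplitude_contrast=spec.amplitude_contrast,
                        defocus_u=true_defocus, defocus_v=true_defocus)
        slc = projector.slice(rotation_matrix(true_pose))
        if doses[i] > 0:
            slc = slc * damage_envelope(doses[i], spec.damage_b_per_dose, fr)
        slc = slc * ctf_value(ctf, f1d[None, :] + 0 * f1d[:, None],
                              f1d[:, None] + 0 * f1d[None, :])
        img = project_slice_to_image(slc)
        clean_var[i] = img.var()
        images[i] = img

        rec_pose = _random_pose(rng) if wrong_pose[i] else true_pose
        rec_defocus = rng.uniform(lo, hi) if wrong_ctf[i] else true_defocus
        rec_ctf = (CTFParams(voltage=spec.voltage, cs=spec.cs,
                             amplitude_contrast=spec.amplitude_contrast,
                             defocus_u=rec_defocus, defocus_v=rec_defocus)
                   if wrong_ctf[i] else ctf)
        records.append(ParticleRecord(
            image_index=i, pose=rec_pose, ctf=rec_ctf,
            half_set=1 if i % 2 == 0 else 2,
        ))
        truth_rows.append({
            "index": i,
            "true_rot": true_pose.rot, "true_tilt": true_pose.tilt,
            "true_psi": true_pose.psi, "true_defocus_A": true_defocus,
            "wrong_pose": bool(wrong_pose[i]),
            "wrong_ctf": bool(wrong_ctf[i]),
            "dose_group": int(groups[i]), "dose_e_per_A2": float(doses[i]),
        })

    sigma = spec.noise_sigma or 0.0
    if spec.target_snr is not None:
        sigma = float(np.sqrt(clean_var.mean() / spec.target_snr))
    if sigma > 0:
        images += rng.normal(0.0, sigma, size=images.shape).astype(np.float32)

    truth = pd.DataFrame(truth_rows)
    truth.attrs["noise_sigma"] = sigma
    stack = ParticleStack(images=images, pixel_size=px, records=records)
    return stack, truth
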